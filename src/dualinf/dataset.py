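"""Dataset handling: structured case I/O, raw-text curation, statistics,
splitting, and the seeded synthetic-case generator.

The on-disk case format is JSON, one record per case::

    {"note_id": ..., "text": ..., "specialty": ...,
     "ddx": [{"diagnosis": ..., "explanations": [...]}, ...]}

Raw diagnosis-exercise texts pass through four curation filters applied
in order — duplicate removal, UTF-8 enforcement, special-character
correction, and a minimum length of 130 characters — after multiple-
choice option blocks have been stripped (stripping first is the
stricter reading: a note must clear the length bar on its narrative
alone).

The synthetic generator emulates the annotated corpus: per note it
samples a specialty, draws a ground-truth differential of on average
4.6 diagnoses (minimum 2) from that specialty's diseases, samples on
average 3.1 findings (minimum 3) per diagnosis from the knowledge base,
and composes the note from those finding sentences plus a demographic
opener. The sampled findings double as the ground-truth explanations,
which is what makes every generated case solvable in closed loop by the
zero-noise simulated clinician.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from ._text import normalize_text
from .backend import KnowledgeBase
from .errors import ConfigurationError, ValidationError
from .types import AnnotatedCase, ClinicalNote, GroundTruthDx, Specialty

# ---------------------------------------------------------------------------
# default knowledge base
# ---------------------------------------------------------------------------


def default_knowledge_base() -> KnowledgeBase:
    """The bundled knowledge base: 72 diseases, 8 per specialty, each
    with 5 representative findings; some findings are deliberately
    shared between related diseases."""
    text = resources.files("dualinf").joinpath("data", "knowledge_base.json").read_text("utf-8")
    return KnowledgeBase.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# raw-text preprocessing
# ---------------------------------------------------------------------------

_OPTION_LINE_RE = re.compile(r"^\s*\(?[A-Ea-e][.)]\s+\S")
_CHAR_FIXES = {
    "‘": "'", "’": "'", "“": '"', "”": '"',
    "–": "-", "—": "-", "…": "...", " ": " ",
}
_CONTROL_RE = re.compile(r"[\x00-\x08\x0b\x0c\x0e-\x1f\x7f]")

MIN_NOTE_CHARS = 130


def strip_option_block(text: str) -> str:
    """Remove a trailing multiple-choice option block (two or more
    consecutive lettered lines like "A. …" at the end of the text)."""
    lines = text.rstrip().splitlines()
    i = len(lines)
    while i > 0 and (_OPTION_LINE_RE.match(lines[i - 1]) or not lines[i - 1].strip()):
        i -= 1
    n_options = sum(1 for ln in lines[i:] if _OPTION_LINE_RE.match(ln))
    if n_options >= 2:
        return "\n".join(lines[:i]).rstrip()
    return text


def _fix_characters(text: str) -> str:
    for bad, good in _CHAR_FIXES.items():
        text = text.replace(bad, good)
    return _CONTROL_RE.sub("", text)


def _force_utf8(text: str) -> str:
    # drop surrogates / undecodable sequences, normalize composition
    clean = text.encode("utf-8", errors="ignore").decode("utf-8", errors="ignore")
    return unicodedata.normalize("NFC", clean)


def preprocess_raw(
    texts: list[str], *, id_prefix: str = "note", source: str = "exam-bank"
) -> tuple[list[ClinicalNote], dict[str, int]]:
    """Curate raw diagnosis-exercise texts into clinical notes.

    Filters run in order: option-block stripping, duplicate removal
    (exact on case-folded, whitespace-collapsed text), UTF-8
    enforcement, special-character correction, and removal of notes
    shorter than 130 characters. Returns the surviving notes and a
    per-filter report. Idempotent: reapplying to its own output changes
    nothing.
    """
    report = {
        "input": len(texts),
        "option_blocks_stripped": 0,
        "duplicates_removed": 0,
        "characters_corrected": 0,
        "too_short_removed": 0,
        "kept": 0,
    }
    stripped: list[str] = []
    for t in texts:
        s = strip_option_block(t)
        if s != t:
            report["option_blocks_stripped"] += 1
        stripped.append(s)
    seen: set[str] = set()
    deduped: list[str] = []
    for t in stripped:
        key = normalize_text(t)
        if key in seen:
            report["duplicates_removed"] += 1
            continue
        seen.add(key)
        deduped.append(t)
    notes: list[ClinicalNote] = []
    for t in deduped:
        fixed = _fix_characters(_force_utf8(t))
        if fixed != t:
            report["characters_corrected"] += 1
        fixed = fixed.strip()
        if len(fixed) < MIN_NOTE_CHARS:
            report["too_short_removed"] += 1
            continue
        notes.append(
            ClinicalNote(
                note_id=f"{id_prefix}-{len(notes):04d}", text=fixed, source=source
            )
        )
    report["kept"] = len(notes)
    return notes, report


# ---------------------------------------------------------------------------
# structured case I/O
# ---------------------------------------------------------------------------


def _case_to_dict(case: AnnotatedCase) -> dict:
    return {
        "note_id": case.note.note_id,
        "text": case.note.text,
        "specialty": case.note.specialty.value,
        "source": case.note.source,
        "ddx": [
            {"diagnosis": d.diagnosis, "explanations": list(d.explanations)}
            for d in case.ddx
        ],
    }


def _case_from_dict(record: dict, index: int) -> AnnotatedCase:
    def require(fld: str, kind):
        if fld not in record:
            raise ValidationError(
                f"record {index}: missing field {fld!r}", record_index=index, field=fld
            )
        value = record[fld]
        if not isinstance(value, kind):
            raise ValidationError(
                f"record {index}: field {fld!r} must be {kind.__name__}",
                record_index=index,
                field=fld,
            )
        return value

    note_id = require("note_id", str)
    text = require("text", str)
    ddx_raw = require("ddx", list)
    specialty = record.get("specialty", "unknown")
    try:
        note = ClinicalNote(
            note_id=note_id,
            text=text,
            specialty=Specialty.from_string(specialty),
            source=record.get("source", "book"),
        )
    except ValueError as exc:
        raise ValidationError(f"record {index}: {exc}", record_index=index) from None
    ddx = []
    for j, d in enumerate(ddx_raw):
        if not isinstance(d, dict) or "diagnosis" not in d:
            raise ValidationError(
                f"record {index}: ddx[{j}] must be an object with a 'diagnosis' field",
                record_index=index,
                field="ddx",
            )
        explanations = d.get("explanations", [])
        if not isinstance(explanations, list) or not all(
            isinstance(e, str) for e in explanations
        ):
            raise ValidationError(
                f"record {index}: ddx[{j}].explanations must be a list of strings",
                record_index=index,
                field="ddx",
            )
        ddx.append(GroundTruthDx(diagnosis=d["diagnosis"], explanations=list(explanations)))
    return AnnotatedCase(note=note, ddx=ddx)


def write_xddx(cases: list[AnnotatedCase], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([_case_to_dict(c) for c in cases], indent=1), "utf-8"
    )


def read_xddx(path: str | Path) -> list[AnnotatedCase]:
    """Read structured cases; schema violations name the record index
    and field."""
    data = json.loads(Path(path).read_text("utf-8"))
    if not isinstance(data, list):
        raise ValidationError("case file must contain a JSON array of records")
    return [_case_from_dict(rec, i) for i, rec in enumerate(data)]


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


@dataclass
class DatasetStats:
    """Corpus statistics. Note length counts whitespace tokens;
    standard deviations are population (ddof=0), so a single-case corpus
    reports 0."""

    n_notes: int
    note_length_mean: float
    note_length_sd: float
    diagnoses_per_note_mean: float
    diagnoses_per_note_sd: float
    explanations_per_note_mean: float
    explanations_per_note_sd: float
    explanations_per_diagnosis_mean: float
    explanations_per_diagnosis_sd: float
    specialty_counts: dict[str, int]
    specialty_percentages: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_notes": self.n_notes,
            "note_length_mean": round(self.note_length_mean, 1),
            "note_length_sd": round(self.note_length_sd, 1),
            "diagnoses_per_note_mean": round(self.diagnoses_per_note_mean, 1),
            "diagnoses_per_note_sd": round(self.diagnoses_per_note_sd, 1),
            "explanations_per_note_mean": round(self.explanations_per_note_mean, 1),
            "explanations_per_note_sd": round(self.explanations_per_note_sd, 1),
            "explanations_per_diagnosis_mean": round(self.explanations_per_diagnosis_mean, 1),
            "explanations_per_diagnosis_sd": round(self.explanations_per_diagnosis_sd, 1),
            "specialty_counts": dict(self.specialty_counts),
            "specialty_percentages": {
                k: round(v, 1) for k, v in self.specialty_percentages.items()
            },
        }

    def to_frame(self):
        import pandas as pd

        d = self.to_dict()
        d.pop("specialty_counts")
        d.pop("specialty_percentages")
        return pd.DataFrame([d])


def dataset_statistics(cases: list[AnnotatedCase]) -> DatasetStats:
    """Means and population SDs of note length (whitespace words),
    differential size, and explanation counts, plus the per-specialty
    breakdown. Full precision is retained here; rounding to one decimal
    happens only in ``DatasetStats.to_dict`` for display."""
    if not cases:
        raise ValueError("dataset_statistics requires a non-empty case list")
    lengths = np.array([len(c.note.text.split()) for c in cases], dtype=float)
    n_dx = np.array([len(c.ddx) for c in cases], dtype=float)
    n_expl = np.array([c.n_explanations() for c in cases], dtype=float)
    per_dx = np.array(
        [len(d.explanations) for c in cases for d in c.ddx], dtype=float
    )
    counts: dict[str, int] = {}
    for c in cases:
        counts[c.note.specialty.value] = counts.get(c.note.specialty.value, 0) + 1
    return DatasetStats(
        n_notes=len(cases),
        note_length_mean=float(lengths.mean()),
        note_length_sd=float(lengths.std()),
        diagnoses_per_note_mean=float(n_dx.mean()),
        diagnoses_per_note_sd=float(n_dx.std()),
        explanations_per_note_mean=float(n_expl.mean()),
        explanations_per_note_sd=float(n_expl.std()),
        explanations_per_diagnosis_mean=float(per_dx.mean()) if per_dx.size else 0.0,
        explanations_per_diagnosis_sd=float(per_dx.std()) if per_dx.size else 0.0,
        specialty_counts=counts,
        specialty_percentages={k: 100.0 * v / len(cases) for k, v in counts.items()},
    )


def split_dev_eval(
    cases: list[AnnotatedCase], n_dev: int, seed: int = 0
) -> tuple[list[AnnotatedCase], list[AnnotatedCase]]:
    """Seeded disjoint, exhaustive split into a small prompt-development
    set and the held-out evaluation set (corpus convention: 10 of 570
    for development, 560 for evaluation)."""
    if not 0 < n_dev < len(cases):
        raise ValueError(f"n_dev must be in (0, {len(cases)}), got {n_dev}")
    rng = np.random.default_rng(seed)
    dev_idx = set(rng.choice(len(cases), size=n_dev, replace=False).tolist())
    dev = [c for i, c in enumerate(cases) if i in dev_idx]
    hold = [c for i, c in enumerate(cases) if i not in dev_idx]
    return dev, hold


# ---------------------------------------------------------------------------
# synthetic-case generation
# ---------------------------------------------------------------------------

#: Default specialty sampling weights, proportional to the annotated
#: corpus breakdown (nervous 24.0%, digestive 18.4%, circulatory 11.6%,
#: respiratory 10.2%, reproductive 9.5%, orthopedic 8.9%, endocrine
#: 7.5%, skin 5.3%, cardiovascular 4.6%).
DEFAULT_SPECIALTY_WEIGHTS: dict[str, float] = {
    "nervous": 0.240,
    "digestive": 0.184,
    "circulatory": 0.116,
    "respiratory": 0.102,
    "reproductive": 0.095,
    "orthopedic": 0.089,
    "endocrine": 0.075,
    "skin": 0.053,
    "cardiovascular": 0.046,
}


@dataclass
class SynthesisConfig:
    """Knobs of the synthetic-case generator.

    ``mean_diagnoses`` and ``mean_explanations`` are the target corpus
    means (4.6 diagnoses per note, 3.1 explanations per diagnosis);
    differential sizes are drawn as ``min_diagnoses + Poisson(mean -
    min)`` and explanation counts analogously. ``min_explanations``
    defaults to 3 so that at the reference support threshold (beta=3)
    every ground-truth diagnosis is verifiable from the note alone —
    the closed-loop solvability guarantee.
    """

    n_cases: int = 100
    mean_diagnoses: float = 4.6
    mean_explanations: float = 3.1
    min_diagnoses: int = 2
    min_explanations: int = 3
    specialty_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECIALTY_WEIGHTS))
    seed: int = 0
    id_prefix: str = "synth"

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ConfigurationError("n_cases must be >= 1")
        if self.mean_diagnoses < self.min_diagnoses:
            raise ConfigurationError("mean_diagnoses must be >= min_diagnoses")
        if self.mean_explanations < self.min_explanations:
            raise ConfigurationError("mean_explanations must be >= min_explanations")


_OPENER_SEXES = ("man", "woman")


def generate_cases(kb: KnowledgeBase, config: SynthesisConfig) -> list[AnnotatedCase]:
    """Generate a fully annotated synthetic corpus from a knowledge base.

    Per case: sample a specialty, a differential of diseases from that
    specialty, and per disease a set of representative findings; the
    note is the shuffled finding sentences behind a demographic opener,
    and the per-diagnosis sampled findings are the ground-truth
    explanations. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    available = {s.value: kb.diseases_in(s) for s in Specialty if kb.diseases_in(s)}
    weights = {
        s: w for s, w in config.specialty_weights.items() if s in available
    }
    if not weights:
        raise ConfigurationError(
            "no overlap between specialty_weights and knowledge-base specialties"
        )
    specs = sorted(weights)
    p = np.array([weights[s] for s in specs], dtype=float)
    p /= p.sum()
    for s in specs:
        if len(available[s]) < config.min_diagnoses:
            raise ConfigurationError(
                f"specialty {s!r} has {len(available[s])} diseases; "
                f"cannot draw a differential of {config.min_diagnoses}"
            )
    cases: list[AnnotatedCase] = []
    for i in range(config.n_cases):
        spec = specs[int(rng.choice(len(specs), p=p))]
        pool = available[spec]
        m = config.min_diagnoses + int(rng.poisson(config.mean_diagnoses - config.min_diagnoses))
        m = min(m, len(pool))
        diseases = [pool[j] for j in rng.choice(len(pool), size=m, replace=False)]
        ddx: list[GroundTruthDx] = []
        sentences: list[str] = []
        seen_norm: set[str] = set()
        for disease in diseases:
            symptoms = kb.symptoms(disease) or []
            k = config.min_explanations + int(
                rng.poisson(config.mean_explanations - config.min_explanations)
            )
            k = min(k, len(symptoms))
            chosen = [symptoms[j] for j in rng.choice(len(symptoms), size=k, replace=False)]
            ddx.append(GroundTruthDx(diagnosis=disease, explanations=list(chosen)))
            for s in chosen:
                key = normalize_text(s)
                if key not in seen_norm:
                    seen_norm.add(key)
                    sentences.append(s)
        order = rng.permutation(len(sentences))
        body = [sentences[j] for j in order]
        age = int(rng.integers(18, 90))
        sex = _OPENER_SEXES[int(rng.integers(2))]
        opener = f"A {age} year old {sex} presents with the following findings"
        text = ". ".join(
            s[:1].upper() + s[1:] for s in [opener, *body]
        ) + "."
        note = ClinicalNote(
            note_id=f"{config.id_prefix}-{i:04d}",
            text=text,
            specialty=Specialty.from_string(spec),
            source="synthetic",
        )
        cases.append(AnnotatedCase(note=note, ddx=ddx))
    return cases
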