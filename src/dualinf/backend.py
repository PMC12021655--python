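"""Text-generation backends.

The provider contract is a single method::

    complete(prompt: str, *, temperature: float, seed: int) -> str

Real chat-API adapters live in :mod:`dualinf.adapters`. The workhorse
here is :class:`MockClinicianBackend`, a deterministic simulated
clinician driven by an explicit, inspectable :class:`KnowledgeBase`,
with seeded error injection through :class:`NoiseModel`. With zero
noise the mock is an oracle: it proposes exactly the diseases whose
findings appear in the note and cites exactly those findings, which is
what makes closed-loop testing of the whole pipeline possible offline.

The three noise channels mirror the explanation error taxonomy:

* ``omission_rate`` — a true supporting finding is dropped from the
  response (→ missing content downstream);
* ``hallucination_rate`` — a medically wrong evidence line (a finding
  belonging to a *different* disease, absent from the note) is inserted
  (→ factual error);
* ``irrelevance_rate`` — an off-topic, non-medical line is inserted
  (→ low relevance).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from ._text import normalize_diagnosis, normalize_text, split_sentences
from .errors import ConfigurationError
from .grammar import render_blocks
from .judge import LexicalJudge
from .prompts import extract_feedback_names, extract_listed_names, extract_section
from .types import SPECIALTIES, Specialty


@runtime_checkable
class TextBackend(Protocol):
    """The provider contract every strategy talks to."""

    name: str
    supports_seed: bool
    is_deterministic: bool

    def complete(self, prompt: str, *, temperature: float = 0.1, seed: int = 0) -> str:
        ...


@dataclass
class DiseaseEntry:
    specialty: Specialty
    symptoms: list[str]


class KnowledgeBase:
    """Explicit disease → {specialty, representative findings} mapping.

    This makes the "internal knowledge" a backend recalls during
    backward inference inspectable: synthetic cases are generated from
    it, and the mock backend answers from it.
    """

    def __init__(self, diseases: dict[str, DiseaseEntry]):
        if not diseases:
            raise ConfigurationError("knowledge base must contain at least one disease")
        for name, entry in diseases.items():
            if not entry.symptoms:
                raise ConfigurationError(f"disease {name!r} has no symptoms")
            if entry.specialty not in SPECIALTIES:
                raise ConfigurationError(
                    f"disease {name!r}: specialty must be one of the nine "
                    f"clinical specialties, got {entry.specialty!r}"
                )
        self.diseases = dict(diseases)
        self._by_norm = {normalize_diagnosis(n): n for n in self.diseases}

    def __len__(self) -> int:
        return len(self.diseases)

    def __contains__(self, name: str) -> bool:
        return normalize_diagnosis(name) in self._by_norm

    def canonical_name(self, name: str) -> str | None:
        return self._by_norm.get(normalize_diagnosis(name))

    def symptoms(self, name: str) -> list[str] | None:
        canon = self.canonical_name(name)
        return list(self.diseases[canon].symptoms) if canon else None

    def specialty(self, name: str) -> Specialty | None:
        canon = self.canonical_name(name)
        return self.diseases[canon].specialty if canon else None

    def diseases_in(self, specialty: Specialty) -> list[str]:
        return sorted(
            n for n, e in self.diseases.items() if e.specialty == specialty
        )

    def all_symptom_lines(self) -> list[str]:
        """All finding strings, deduplicated, sorted (deterministic pools)."""
        cached = getattr(self, "_all_lines", None)
        if cached is None:
            seen: dict[str, str] = {}
            for entry in self.diseases.values():
                for s in entry.symptoms:
                    seen.setdefault(normalize_text(s), s)
            cached = sorted(seen.values())
            self._all_lines = cached
        return cached

    def to_dict(self) -> dict[str, dict]:
        return {
            name: {"specialty": e.specialty.value, "symptoms": list(e.symptoms)}
            for name, e in sorted(self.diseases.items())
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), "utf-8")

    @classmethod
    def from_dict(cls, d: dict[str, dict]) -> "KnowledgeBase":
        return cls(
            {
                name: DiseaseEntry(
                    specialty=Specialty.from_string(spec["specialty"]),
                    symptoms=list(spec["symptoms"]),
                )
                for name, spec in d.items()
            }
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "KnowledgeBase":
        return cls.from_dict(json.loads(Path(path).read_text("utf-8")))


@dataclass(frozen=True)
class NoiseModel:
    """Seeded error-injection rates for the simulated clinician.

    All rates live in [0, 1]; the all-zero model turns the mock into an
    oracle. ``omission_rate`` applies per evidence line (in both forward
    evidence and backward recall); the two insertion rates apply once
    per diagnosis block.
    """

    omission_rate: float = 0.0
    hallucination_rate: float = 0.0
    irrelevance_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("omission_rate", "hallucination_rate", "irrelevance_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")

    @property
    def is_zero(self) -> bool:
        return (
            self.omission_rate == 0.0
            and self.hallucination_rate == 0.0
            and self.irrelevance_rate == 0.0
        )


#: Off-topic filler lines for the irrelevance channel: deliberately free
#: of clinical vocabulary so they match neither note nor knowledge base.
IRRELEVANT_LINES: tuple[str, ...] = (
    "the weather was unseasonably cold that week",
    "enjoys gardening and long walks on weekends",
    "recently adopted a rescue dog named biscuit",
    "works part time at a local bookshop",
    "is planning a holiday to the seaside next month",
    "prefers tea over coffee in the mornings",
    "drives a small hatchback to visit relatives",
    "keeps a collection of vintage postcards",
)


class MockClinicianBackend:
    """Deterministic knowledge-base-driven stand-in for a hosted model.

    Dispatches on the machine-readable prompt sections:

    * a ``[DIAGNOSES]`` block → backward inference (recall findings);
    * a ``[NOTE]`` block → forward-style generation (any of the
      forward/CoT/self-contrast prompts look the same to the mock);
    * a ``[CLAIM]`` block → consistency judging.

    Proposal rule: a disease is proposed when at least ``min_overlap``
    of its representative findings appear (as sentences) in the note,
    ranked by overlap size with lexicographic tie-break. Diagnoses named
    in the ``[FEEDBACK]`` block are always re-proposed ("think twice"),
    with freshly drawn evidence. Noise perturbs evidence lines only,
    never the proposal decision itself.

    All stochastic choices flow from ``NoiseModel.seed`` combined with
    the per-call seed and a prompt digest: identical (prompt, seed)
    pairs always produce identical text.
    """

    name = "mock"
    supports_seed = True
    is_deterministic = True

    def __init__(
        self,
        kb: KnowledgeBase,
        noise: NoiseModel | None = None,
        *,
        min_overlap: int = 2,
        judge: LexicalJudge | None = None,
    ):
        if kb is None or len(kb) == 0:
            raise ConfigurationError("mock backend requires a non-empty knowledge base")
        self.kb = kb
        self.noise = noise or NoiseModel()
        self.min_overlap = min_overlap
        self.judge = judge or LexicalJudge()
        self._wrong_pool: dict[str, list[str]] = {}

    # -- rng ------------------------------------------------------------
    def _rng(self, prompt: str, seed: int) -> np.random.Generator:
        return np.random.default_rng(
            [self.noise.seed % (2**31), seed % (2**31), zlib.crc32(prompt.encode("utf-8"))]
        )

    # -- noise channels -------------------------------------------------
    def _wrong_line_for(
        self, disease: str, note_sentences: list[str], rng: np.random.Generator
    ) -> str | None:
        """A finding that is medically wrong for ``disease``: present in
        the knowledge base for other diseases, judged inconsistent with
        this disease's findings and (when a note is given) with the note."""
        key = self.kb.canonical_name(disease) or disease
        pool = self._wrong_pool.get(key)
        if pool is None:
            own = self.kb.symptoms(disease) or []
            pool = [
                line
                for line in self.kb.all_symptom_lines()
                if not self.judge.consistent(line, own)
            ]
            self._wrong_pool[key] = pool
        if not pool:
            return None
        # rejection-sample a candidate that is also inconsistent with the
        # note, so the inserted line is unambiguously wrong for this case
        for _ in range(16):
            cand = pool[int(rng.integers(len(pool)))]
            if not note_sentences or not self.judge.consistent(cand, note_sentences):
                return cand
        return None

    def _perturb(
        self,
        disease: str,
        evidence: list[str],
        note_sentences: list[str],
        rng: np.random.Generator,
    ) -> list[str]:
        out = [line for line in evidence if rng.random() >= self.noise.omission_rate]
        if self.noise.hallucination_rate > 0 and rng.random() < self.noise.hallucination_rate:
            wrong = self._wrong_line_for(disease, note_sentences, rng)
            if wrong is not None:
                out.append(wrong)
        if self.noise.irrelevance_rate > 0 and rng.random() < self.noise.irrelevance_rate:
            out.append(IRRELEVANT_LINES[int(rng.integers(len(IRRELEVANT_LINES)))])
        return out

    # -- tasks ----------------------------------------------------------
    def _forward(self, prompt: str, rng: np.random.Generator) -> str:
        note = extract_section(prompt, "NOTE") or ""
        sentences = split_sentences(note)
        sentence_set = {normalize_text(s) for s in sentences}
        proposals: list[tuple[str, list[str]]] = []
        for name in sorted(self.kb.diseases):
            overlap = [
                s
                for s in self.kb.diseases[name].symptoms
                if normalize_text(s) in sentence_set
            ]
            if len(overlap) >= self.min_overlap:
                proposals.append((name, overlap))
        proposals.sort(key=lambda p: (-len(p[1]), p[0]))
        proposed = {normalize_diagnosis(n) for n, _ in proposals}
        for fb in extract_feedback_names(prompt):
            if normalize_diagnosis(fb) in proposed:
                continue
            canon = self.kb.canonical_name(fb)
            if canon is None:
                proposals.append((fb, []))
            else:
                overlap = [
                    s
                    for s in self.kb.diseases[canon].symptoms
                    if normalize_text(s) in sentence_set
                ]
                proposals.append((canon, overlap))
            proposed.add(normalize_diagnosis(fb))
        blocks = [
            (name, self._perturb(name, evidence, sentences, rng))
            for name, evidence in proposals
        ]
        return render_blocks(blocks)

    def _backward(self, prompt: str, rng: np.random.Generator) -> str:
        names = extract_listed_names(prompt, "DIAGNOSES")
        blocks: list[tuple[str, list[str]]] = []
        for name in names:
            symptoms = self.kb.symptoms(name)
            if symptoms is None:
                blocks.append((name, []))
            else:
                blocks.append((name, self._perturb(name, symptoms, [], rng)))
        return render_blocks(blocks)

    def _judge_task(self, prompt: str) -> str:
        claim = extract_section(prompt, "CLAIM") or ""
        refs_block = extract_section(prompt, "REFERENCES") or ""
        refs = [
            line[2:].strip() for line in refs_block.splitlines() if line.startswith("- ")
        ]
        return "CONSISTENT" if self.judge.consistent(claim, refs) else "INCONSISTENT"

    def complete(self, prompt: str, *, temperature: float = 0.1, seed: int = 0) -> str:
        # temperature is accepted for contract compatibility; the mock's
        # variability is controlled entirely by the noise model and seed.
        rng = self._rng(prompt, seed)
        if "[CLAIM]" in prompt:
            return self._judge_task(prompt)
        if "[DIAGNOSES]" in prompt:
            return self._backward(prompt, rng)
        if "[NOTE]" in prompt:
            return self._forward(prompt, rng)
        raise ConfigurationError("mock backend cannot interpret this prompt")


class ScriptedBackend:
    """Replays a fixed list of responses; records every prompt it sees.

    Test/debug utility: the last response repeats once the script is
    exhausted.
    """

    name = "scripted"
    supports_seed = True
    is_deterministic = True

    def __init__(self, responses: list[str]):
        if not responses:
            raise ConfigurationError("scripted backend needs at least one response")
        self.responses = list(responses)
        self.prompts: list[str] = []
        self._i = 0

    def complete(self, prompt: str, *, temperature: float = 0.1, seed: int = 0) -> str:
        self.prompts.append(prompt)
        resp = self.responses[min(self._i, len(self.responses) - 1)]
        self._i += 1
        return resp
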