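"""Domain types for explainable differential diagnosis.

The central objects are:

* :class:`ClinicalNote` — one free-text symptom narrative.
* :class:`AnnotatedCase` — a note plus its ground-truth differential,
  each ground-truth diagnosis carrying a list of explanation snippets.
* :class:`DDxPrediction` — an ordered differential produced by any
  prompting strategy; each :class:`DDxItem` carries explanation items
  with provenance (forward-generated vs supplemented by the examiner)
  and kept/discarded status.
* :class:`RecalledProfile` — backward-inference output: per diagnosis,
  the representative symptoms/findings the backend recalled.
* :class:`DualInfConfig` — the knobs of the bidirectional-inference
  loop: support threshold ``beta``, iteration cap ``lam``, sampling
  temperature, component flags for ablations, and the run seed.
* :class:`TraceLog` — a replayable per-iteration record of the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any

from ._text import normalize_diagnosis


class Specialty(str, Enum):
    """The nine clinical specialties covered by the corpus, plus unknown."""

    CARDIOVASCULAR = "cardiovascular"
    DIGESTIVE = "digestive"
    RESPIRATORY = "respiratory"
    ENDOCRINE = "endocrine"
    NERVOUS = "nervous"
    REPRODUCTIVE = "reproductive"
    CIRCULATORY = "circulatory"
    SKIN = "skin"
    ORTHOPEDIC = "orthopedic"
    UNKNOWN = "unknown"

    @classmethod
    def from_string(cls, value: str) -> "Specialty":
        try:
            return cls(value.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown specialty {value!r}; expected one of "
                f"{[s.value for s in cls]}"
            ) from None


#: The nine real specialties (excludes UNKNOWN).
SPECIALTIES: tuple[Specialty, ...] = tuple(s for s in Specialty if s is not Specialty.UNKNOWN)


@dataclass
class ClinicalNote:
    """A free-text clinical note: symptoms, exam and lab findings."""

    note_id: str
    text: str
    specialty: Specialty = Specialty.UNKNOWN
    source: str = "synthetic"  # book | exam-bank | synthetic

    def __post_init__(self) -> None:
        if not self.text or not self.text.strip():
            raise ValueError(f"note {self.note_id!r}: text must be non-empty")
        if isinstance(self.specialty, str):
            self.specialty = Specialty.from_string(self.specialty)


@dataclass
class ExplanationItem:
    """One evidence sentence linking note findings to a diagnosis.

    ``provenance`` is "forward" for explanations generated by the
    forward-inference pass and "supplemented" for ones the examination
    stage added from recalled knowledge present in the note. ``status``
    only ever moves kept → discarded (during examination), never back.
    """

    text: str
    provenance: str = "forward"  # forward | supplemented
    status: str = "kept"  # kept | discarded

    def __post_init__(self) -> None:
        if self.provenance not in ("forward", "supplemented"):
            raise ValueError(f"bad provenance {self.provenance!r}")
        if self.status not in ("kept", "discarded"):
            raise ValueError(f"bad status {self.status!r}")

    def to_dict(self) -> dict[str, str]:
        return {"text": self.text, "provenance": self.provenance, "status": self.status}


@dataclass
class DDxItem:
    """One candidate diagnosis with its supporting explanations."""

    diagnosis: str
    explanations: list[ExplanationItem] = field(default_factory=list)
    support_count: int = 0
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self._normalized = normalize_diagnosis(self.diagnosis)
        self.support_count = sum(1 for e in self.explanations if e.status == "kept")

    @property
    def normalized(self) -> str:
        return self._normalized

    def kept_explanations(self) -> list[ExplanationItem]:
        return [e for e in self.explanations if e.status == "kept"]

    def refresh_support(self) -> None:
        """Re-derive support_count from explanation statuses."""
        self.support_count = sum(1 for e in self.explanations if e.status == "kept")

    def to_dict(self) -> dict[str, Any]:
        return {
            "diagnosis": self.diagnosis,
            "explanations": [e.to_dict() for e in self.explanations],
            "support_count": self.support_count,
            "low_confidence": self.low_confidence,
        }


@dataclass
class DDxPrediction:
    """An ordered differential for one note, as produced by a strategy."""

    items: list[DDxItem]
    iteration: int = 1
    strategy: str = "unknown"
    note_id: str = ""

    def __post_init__(self) -> None:
        if self.iteration < 1:
            raise ValueError("iteration must be >= 1")
        seen: set[str] = set()
        for item in self.items:
            if item.normalized in seen:
                raise ValueError(
                    f"duplicate diagnosis {item.diagnosis!r} after normalization"
                )
            seen.add(item.normalized)

    def diagnosis_names(self) -> list[str]:
        return [i.diagnosis for i in self.items]

    def normalized_names(self) -> list[str]:
        return [i.normalized for i in self.items]

    def get(self, name: str) -> DDxItem | None:
        key = normalize_diagnosis(name)
        for item in self.items:
            if item.normalized == key:
                return item
        return None

    def to_dict(self) -> dict[str, Any]:
        return {
            "note_id": self.note_id,
            "strategy": self.strategy,
            "iteration": self.iteration,
            "items": [i.to_dict() for i in self.items],
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "DDxPrediction":
        items = [
            DDxItem(
                diagnosis=it["diagnosis"],
                explanations=[ExplanationItem(**e) for e in it.get("explanations", [])],
                low_confidence=bool(it.get("low_confidence", False)),
            )
            for it in d["items"]
        ]
        return cls(
            items=items,
            iteration=int(d.get("iteration", 1)),
            strategy=d.get("strategy", "unknown"),
            note_id=d.get("note_id", ""),
        )


@dataclass
class RecalledProfile:
    """Backward-inference output: representative findings per diagnosis.

    Keys are normalized diagnosis names; an empty list signals that the
    backend recalled nothing for that diagnosis (a valid outcome).
    """

    per_diagnosis: dict[str, list[str]] = field(default_factory=dict)

    def get(self, name: str) -> list[str]:
        return self.per_diagnosis.get(normalize_diagnosis(name), [])

    def has(self, name: str) -> bool:
        return normalize_diagnosis(name) in self.per_diagnosis

    def to_dict(self) -> dict[str, list[str]]:
        return dict(self.per_diagnosis)


@dataclass
class DualInfConfig:
    """Configuration of the bidirectional-inference loop.

    Defaults are the reference operating point: support threshold
    ``beta=3``, iteration cap ``lam=5``, sampling ``temperature=0.1``,
    all components enabled, and five reasoning paths for the
    self-consistency baseline. Ablation variants are pure flag settings
    (see :func:`dualinf.engine.configure_variant`).
    """

    beta: int = 3
    lam: int = 5
    temperature: float = 0.1
    use_backward: bool = True
    use_examination: bool = True
    use_reflection: bool = True
    seed: int = 0
    n_paths: int = 5

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.lam < 1:
            raise ValueError("lam must be >= 1")
        if self.n_paths < 1:
            raise ValueError("n_paths must be >= 1")


@dataclass
class GroundTruthDx:
    """One annotated ground-truth diagnosis with its explanation snippets."""

    diagnosis: str
    explanations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._normalized = normalize_diagnosis(self.diagnosis)

    @property
    def normalized(self) -> str:
        return self._normalized


@dataclass
class AnnotatedCase:
    """A clinical note together with its ground-truth differential."""

    note: ClinicalNote
    ddx: list[GroundTruthDx] = field(default_factory=list)

    @property
    def note_id(self) -> str:
        return self.note.note_id

    def truth_names(self) -> list[str]:
        return [d.diagnosis for d in self.ddx]

    def n_explanations(self) -> int:
        return sum(len(d.explanations) for d in self.ddx)


@dataclass
class IterationRecord:
    """Snapshot of one reflection iteration (replayable)."""

    iteration: int
    prediction: dict[str, Any]  # serialized examined DDxPrediction
    recalled: dict[str, list[str]]
    feedback_sent: list[str]
    accepted: list[str]  # normalized names accepted by the end of this iteration
    converged: bool

    def to_dict(self) -> dict[str, Any]:
        return {
            "iteration": self.iteration,
            "prediction": self.prediction,
            "recalled": self.recalled,
            "feedback_sent": list(self.feedback_sent),
            "accepted": list(self.accepted),
            "converged": self.converged,
        }


@dataclass
class TraceLog:
    """Per-iteration records of a reflection run.

    Re-running with the same seed and a deterministic backend reproduces
    the trace byte-for-byte (see ``to_json``).
    """

    note_id: str
    records: list[IterationRecord] = field(default_factory=list)
    terminal_reason: str = "converged"  # converged | max_iterations | backend_failure

    def n_iterations(self) -> int:
        return len(self.records)

    def to_dict(self) -> dict[str, Any]:
        return {
            "note_id": self.note_id,
            "terminal_reason": self.terminal_reason,
            "records": [r.to_dict() for r in self.records],
        }

    def to_json(self) -> str:
        import json

        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
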