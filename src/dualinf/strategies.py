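"""Baseline prompting strategies.

Four baselines are provided, all producing the same
:class:`~dualinf.types.DDxPrediction` so the evaluation layer is
strategy-agnostic:

* ``cot`` — a single step-by-step prompt;
* ``diagnosis_cot`` — a diagnosis-specialized staged prompt
  (summarize findings → hypothesize → justify);
* ``self_contrast`` — three differently phrased prompts whose
  disagreements are arbitrated by a re-examination prompt;
* ``sc_cot`` — self-consistency: ``n_paths`` sampled reasoning paths,
  keeping each diagnosis that wins a strict majority vote.

The bidirectional-inference variants (``fi``, ``fi_em``, ``fi_em_star``,
``dual_inf_star``, ``dual_inf``) are reachable through the same
:func:`run_strategy` entry point.

Malformed backend output is retried once (with a fresh derived seed);
a second failure is recorded as a per-case parsing failure rather than
crashing a batch.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from ._text import normalize_text, stable_seed
from .errors import MalformedOutputError
from .grammar import parse_structured_output, render_prediction
from .prompts import format_diagnoses, render_prompt
from .types import AnnotatedCase, ClinicalNote, DDxItem, DDxPrediction, DualInfConfig, TraceLog

BASELINES = ("cot", "diagnosis_cot", "self_contrast", "sc_cot")
VARIANTS = ("fi", "fi_em", "fi_em_star", "dual_inf_star", "dual_inf")
STRATEGIES = BASELINES + VARIANTS


@dataclass
class FailureRecord:
    """A case that produced no usable prediction."""

    note_id: str
    strategy: str
    reason: str
    raw: str = ""


@dataclass
class BatchResult:
    """Predictions (aligned with the input cases; None on failure),
    failure records, and traces for reflective strategies."""

    strategy: str
    predictions: list[DDxPrediction | None] = field(default_factory=list)
    failures: list[FailureRecord] = field(default_factory=list)
    traces: list[TraceLog | None] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.predictions)


def _complete_parsed(
    backend,
    prompt: str,
    config: DualInfConfig,
    *,
    strategy: str,
    note_id: str,
    seed_parts: tuple,
) -> DDxPrediction:
    """One completion with a single retry on malformed output."""
    last: MalformedOutputError | None = None
    for attempt in (0, 1):
        seed = stable_seed(*seed_parts, attempt)
        raw = backend.complete(prompt, temperature=config.temperature, seed=seed)
        try:
            return parse_structured_output(raw, strategy=strategy, note_id=note_id)
        except MalformedOutputError as exc:
            last = exc
    raise last  # type: ignore[misc]


def run_cot(note: ClinicalNote, backend, config: DualInfConfig) -> DDxPrediction:
    """Single chain-of-thought forward pass."""
    prompt = render_prompt("cot", note=note.text)
    return _complete_parsed(
        backend,
        prompt,
        config,
        strategy="cot",
        note_id=note.note_id,
        seed_parts=(config.seed, note.note_id, "cot"),
    )


def run_diagnosis_cot(note: ClinicalNote, backend, config: DualInfConfig) -> DDxPrediction:
    """Diagnosis-specialized staged prompt in a single pass."""
    prompt = render_prompt("diagnosis_cot", note=note.text)
    return _complete_parsed(
        backend,
        prompt,
        config,
        strategy="diagnosis_cot",
        note_id=note.note_id,
        seed_parts=(config.seed, note.note_id, "diagnosis_cot"),
    )


def _prediction_signature(pred: DDxPrediction) -> dict[str, tuple[str, ...]]:
    return {
        item.normalized: tuple(normalize_text(e.text) for e in item.explanations)
        for item in pred.items
    }


def run_self_contrast(note: ClinicalNote, backend, config: DualInfConfig) -> DDxPrediction:
    """Three contrasting prompt phrasings plus arbitration of disagreements.

    If the three drafts agree exactly, arbitration is skipped. Otherwise
    the diagnoses that are not shared by all drafts are listed as
    disputed items in a re-examination prompt whose output is final.
    """
    drafts: list[DDxPrediction] = []
    for phase in ("a", "b", "c"):
        prompt = render_prompt(f"self_contrast_{phase}", note=note.text)
        try:
            drafts.append(
                _complete_parsed(
                    backend,
                    prompt,
                    config,
                    strategy="self_contrast",
                    note_id=note.note_id,
                    seed_parts=(config.seed, note.note_id, "self_contrast", phase),
                )
            )
        except MalformedOutputError:
            continue
    if not drafts:
        raise MalformedOutputError("all self-contrast drafts were malformed")
    signatures = [_prediction_signature(d) for d in drafts]
    if all(sig == signatures[0] for sig in signatures[1:]):
        return drafts[0]
    in_all = set.intersection(*(set(s) for s in signatures))
    disputed: list[str] = []
    seen: set[str] = set()
    for draft in drafts:
        for item in draft.items:
            if item.normalized not in in_all and item.normalized not in seen:
                disputed.append(item.diagnosis)
                seen.add(item.normalized)
    prompt = render_prompt(
        "self_contrast_arbitrate", note=note.text, disputed=format_diagnoses(disputed)
    )
    return _complete_parsed(
        backend,
        prompt,
        config,
        strategy="self_contrast",
        note_id=note.note_id,
        seed_parts=(config.seed, note.note_id, "self_contrast", "arbitrate"),
    )


def run_sc_cot(note: ClinicalNote, backend, config: DualInfConfig) -> DDxPrediction:
    """Self-consistency chain-of-thought.

    ``config.n_paths`` reasoning paths are sampled with per-path derived
    seeds. A diagnosis is kept iff it appears (after normalization) in
    strictly more than ``n_paths / 2`` paths. Its explanations are taken
    from the path containing it whose diagnoses carry the highest total
    vote agreement; ties break on the path's raw text (order-invariant).
    With ``n_paths=1`` this reduces exactly to :func:`run_cot`.
    """
    paths: list[tuple[DDxPrediction, str]] = []
    for path_id in range(config.n_paths):
        # path 0 uses the run seed itself, so n_paths=1 is exactly run_cot;
        # later paths get derived seed offsets to force diversity
        path_config = (
            config
            if path_id == 0
            else replace(config, seed=stable_seed(config.seed, "sc_cot", path_id))
        )
        try:
            pred = run_cot(note, backend, path_config)
        except MalformedOutputError:
            continue
        paths.append((pred, render_prediction(pred)))
    if not paths:
        raise MalformedOutputError("all reasoning paths were malformed")
    votes: Counter[str] = Counter()
    first_seen: dict[str, int] = {}
    for pred, _ in paths:
        votes.update(pred.normalized_names())
        for n in pred.normalized_names():
            first_seen.setdefault(n, len(first_seen))
    kept = {name for name, v in votes.items() if v > config.n_paths / 2}
    items: list[DDxItem] = []
    for name in sorted(kept, key=lambda n: (-votes[n], first_seen[n])):
        best: tuple[float, str, DDxItem] | None = None
        for pred, raw in paths:
            item = pred.get(name)
            if item is None:
                continue
            agreement = sum(votes[n] for n in pred.normalized_names())
            cand = (-agreement, raw, item)
            if best is None or cand < best:
                best = cand
        assert best is not None
        src = best[2]
        items.append(DDxItem(diagnosis=src.diagnosis, explanations=list(src.explanations)))
    return DDxPrediction(items=items, strategy="sc_cot", note_id=note.note_id)


def run_strategy(
    name: str, note: ClinicalNote, backend, config: DualInfConfig
) -> tuple[DDxPrediction, TraceLog | None]:
    """Run any strategy or loop variant on one note.

    Returns the prediction and, for reflective variants, the trace log.
    """
    if name == "cot":
        return run_cot(note, backend, config), None
    if name == "diagnosis_cot":
        return run_diagnosis_cot(note, backend, config), None
    if name == "self_contrast":
        return run_self_contrast(note, backend, config), None
    if name == "sc_cot":
        return run_sc_cot(note, backend, config), None
    if name in VARIANTS:
        from .engine import configure_variant, reflect_loop

        variant_config = configure_variant(name, config)
        prediction, trace = reflect_loop(note, backend, variant_config)
        prediction.strategy = name
        return prediction, trace
    raise ValueError(f"unknown strategy {name!r}; expected one of {STRATEGIES}")


def run_batch(
    name: str,
    cases: list[AnnotatedCase] | list[ClinicalNote],
    backend,
    config: DualInfConfig,
) -> BatchResult:
    """Run a strategy over a batch; every case yields a prediction or a
    recorded failure (conservation: len(predictions) == len(cases))."""
    result = BatchResult(strategy=name)
    for case in cases:
        note = case.note if isinstance(case, AnnotatedCase) else case
        try:
            pred, trace = run_strategy(name, note, backend, config)
        except MalformedOutputError as exc:
            result.predictions.append(None)
            result.traces.append(None)
            result.failures.append(
                FailureRecord(
                    note_id=note.note_id, strategy=name, reason=str(exc), raw=exc.raw
                )
            )
            continue
        result.predictions.append(pred)
        result.traces.append(trace)
    return result
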