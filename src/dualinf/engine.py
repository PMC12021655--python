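"""The bidirectional-inference engine.

One reflection iteration runs:

1. **forward inference** — note (plus any feedback) → candidate
   diagnoses with supporting explanations;
2. **backward inference** — each candidate diagnosis → the
   representative symptoms, exam findings and laboratory results the
   backend recalls for it;
3. **examination** — each forward explanation is judged against the
   recalled knowledge and the note (erroneous ones discarded), missing
   interpretations are supplemented from recalled findings present in
   the note, and every diagnosis's support count (kept + supplemented
   explanations) is compared against the threshold ``beta``: diagnoses
   with fewer than ``beta`` supporting interpretations are flagged
   low-confidence;
4. **self-reflection** — the low-confidence diagnoses are fed back to
   the forward module, neutrally phrased, to "think twice".

The loop stops when no diagnosis is low-confidence (convergence) or
after ``lam`` iterations. Diagnoses that reach the support threshold are
treated as settled and persist; kept explanations for still-pending
diagnoses accumulate across iterations, so the set of accepted correct
diagnoses grows monotonically over iterations. Diagnoses still
unresolved at the cap are emitted flagged rather than dropped —
evaluation decides (default: excluded) — so no information is lost.

Ablation variants are pure flag settings over the same loop
(:func:`configure_variant`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from ._text import normalize_diagnosis, normalize_text, split_sentences, stable_seed
from .errors import ConfigurationError, MalformedOutputError
from .grammar import parse_recall, parse_structured_output
from .judge import LexicalJudge
from .prompts import format_diagnoses, format_feedback, render_prompt
from .types import (
    ClinicalNote,
    DDxItem,
    DDxPrediction,
    DualInfConfig,
    ExplanationItem,
    IterationRecord,
    RecalledProfile,
    TraceLog,
)

#: Component settings of the ablation variants.
VARIANT_FLAGS: dict[str, dict[str, bool]] = {
    "fi": {"use_backward": False, "use_examination": False, "use_reflection": False},
    "fi_em": {"use_backward": False, "use_examination": True, "use_reflection": True},
    "fi_em_star": {"use_backward": False, "use_examination": True, "use_reflection": False},
    "dual_inf_star": {"use_backward": True, "use_examination": True, "use_reflection": False},
    "dual_inf": {"use_backward": True, "use_examination": True, "use_reflection": True},
}


def configure_variant(name: str, base: DualInfConfig | None = None) -> DualInfConfig:
    """Configuration for a named variant of the loop.

    ``fi`` is forward-inference only; ``fi_em`` adds examination (no
    backward recall); ``fi_em_star`` is ``fi_em`` without reflection;
    ``dual_inf_star`` is the full framework minus reflection;
    ``dual_inf`` enables every component.
    """
    if name not in VARIANT_FLAGS:
        raise ConfigurationError(
            f"unknown variant {name!r}; expected one of {sorted(VARIANT_FLAGS)}"
        )
    base = base or DualInfConfig()
    return replace(base, **VARIANT_FLAGS[name])


@dataclass
class DiagnosisExamination:
    """Examination outcome for one diagnosis."""

    decisions: list[tuple[str, str, str]]  # (explanation text, kept|discarded, reason)
    supplemented: list[str]
    support_count: int
    low_confidence: bool
    recall_missing: bool = False  # no profile entry: judged against the note only


@dataclass
class ExaminationReport:
    """Per-diagnosis keep/discard/supplement decisions plus the examined
    prediction. ``converged`` is true iff no diagnosis is low-confidence."""

    entries: dict[str, DiagnosisExamination]
    prediction: DDxPrediction
    converged: bool


def forward_infer(
    note: ClinicalNote,
    feedback: list[str],
    backend,
    config: DualInfConfig,
    *,
    iteration: int = 1,
) -> DDxPrediction:
    """Forward pass: note (+ neutral feedback) → diagnoses with explanations.

    Retries once on malformed output; a second failure propagates as
    :class:`MalformedOutputError` for the caller to record.
    """
    prompt = render_prompt("forward", note=note.text, feedback=format_feedback(feedback))
    last: MalformedOutputError | None = None
    for attempt in (0, 1):
        seed = stable_seed(config.seed, note.note_id, "forward", iteration, attempt)
        raw = backend.complete(prompt, temperature=config.temperature, seed=seed)
        try:
            return parse_structured_output(
                raw, strategy="dual_inf", note_id=note.note_id, iteration=iteration
            )
        except MalformedOutputError as exc:
            last = exc
    raise last  # type: ignore[misc]


def backward_infer(
    prediction: DDxPrediction,
    backend,
    config: DualInfConfig,
    *,
    iteration: int = 1,
) -> RecalledProfile:
    """Backward pass: recall representative findings for each predicted
    diagnosis. Empty recall lists are valid (unknown diseases)."""
    names = prediction.diagnosis_names()
    if not names:
        return RecalledProfile()
    prompt = render_prompt("backward", diagnoses=format_diagnoses(names))
    seed = stable_seed(config.seed, prediction.note_id, "backward", iteration)
    raw = backend.complete(prompt, temperature=config.temperature, seed=seed)
    return parse_recall(raw, names)


def _judge_of(backend) -> LexicalJudge:
    judge = getattr(backend, "judge", None)
    return judge if judge is not None else LexicalJudge()


def examine(
    note: ClinicalNote,
    prediction: DDxPrediction,
    profile: RecalledProfile,
    backend=None,
    config: DualInfConfig | None = None,
) -> ExaminationReport:
    """Verify and refine a forward prediction against recalled knowledge.

    For each diagnosis: (i) every forward explanation is checked — an
    explanation inconsistent with the note is discarded, with reason
    "contradicts-recalled" when non-empty recalled knowledge also fails
    to support it, else "unsupported"; (ii) recalled findings that are
    present in the note but not yet covered by a kept explanation are
    added as supplemented interpretations; (iii) the support count
    (kept + supplemented) is compared against ``beta`` and diagnoses
    below the threshold are flagged low-confidence.

    A diagnosis absent from the profile is treated as having empty
    recall and judged against the note only (``recall_missing``).
    """
    config = config or DualInfConfig()
    judge = _judge_of(backend)
    note_sentences = split_sentences(note.text)
    entries: dict[str, DiagnosisExamination] = {}
    examined_items: list[DDxItem] = []
    for item in prediction.items:
        recall_missing = not profile.has(item.diagnosis)
        recall = profile.get(item.diagnosis)
        decisions: list[tuple[str, str, str]] = []
        new_explanations: list[ExplanationItem] = []
        kept_texts: list[str] = []
        for expl in item.explanations:
            in_note = judge.consistent(expl.text, note_sentences)
            in_recall = bool(recall) and judge.consistent(expl.text, recall)
            if in_note:
                decisions.append((expl.text, "kept", "kept"))
                new_explanations.append(
                    ExplanationItem(expl.text, provenance=expl.provenance, status="kept")
                )
                kept_texts.append(expl.text)
            else:
                reason = "contradicts-recalled" if (recall and not in_recall) else "unsupported"
                decisions.append((expl.text, "discarded", reason))
                new_explanations.append(
                    ExplanationItem(expl.text, provenance=expl.provenance, status="discarded")
                )
        supplemented: list[str] = []
        for finding in recall:
            if normalize_text(finding) in {normalize_text(t) for t in kept_texts + supplemented}:
                continue
            if judge.consistent(finding, note_sentences) and not judge.consistent(
                finding, kept_texts + supplemented
            ):
                supplemented.append(finding)
        for finding in supplemented:
            new_explanations.append(
                ExplanationItem(finding, provenance="supplemented", status="kept")
            )
        support = sum(1 for e in new_explanations if e.status == "kept")
        low_confidence = support < config.beta
        entries[item.normalized] = DiagnosisExamination(
            decisions=decisions,
            supplemented=supplemented,
            support_count=support,
            low_confidence=low_confidence,
            recall_missing=recall_missing,
        )
        examined_items.append(
            DDxItem(
                diagnosis=item.diagnosis,
                explanations=new_explanations,
                low_confidence=low_confidence,
            )
        )
    examined = DDxPrediction(
        items=examined_items,
        iteration=prediction.iteration,
        strategy=prediction.strategy,
        note_id=prediction.note_id,
    )
    converged = not any(e.low_confidence for e in entries.values())
    return ExaminationReport(entries=entries, prediction=examined, converged=converged)


def _merge_kept(target: DDxItem, new_kept: list[ExplanationItem]) -> None:
    """Union kept explanations into ``target`` (dedup on normalized text)."""
    have = {normalize_text(e.text) for e in target.explanations}
    for e in new_kept:
        key = normalize_text(e.text)
        if key not in have:
            target.explanations.append(ExplanationItem(e.text, e.provenance, "kept"))
            have.add(key)
    target.refresh_support()


def reflect_loop(
    note: ClinicalNote, backend, config: DualInfConfig
) -> tuple[DDxPrediction, TraceLog]:
    """Run the full loop on one note, up to ``config.lam`` iterations.

    Returns the final prediction (settled diagnoses first, still-pending
    ones flagged ``low_confidence``) and the per-iteration trace. The
    trace's ``terminal_reason`` is "converged" when an iteration ends
    with no low-confidence diagnosis, "max_iterations" when the cap is
    hit first, and "backend_failure" when forward inference failed
    mid-loop (a partial trace is still returned).
    """
    trace = TraceLog(note_id=note.note_id)
    accepted: dict[str, DDxItem] = {}
    pending: dict[str, DDxItem] = {}
    order: list[str] = []
    feedback: list[str] = []
    final: DDxPrediction | None = None
    trace.terminal_reason = "max_iterations"
    for iteration in range(1, config.lam + 1):
        try:
            pred = forward_infer(note, feedback, backend, config, iteration=iteration)
        except MalformedOutputError:
            trace.terminal_reason = "backend_failure"
            break
        if not config.use_examination:
            # forward-only: the raw prediction is final, nothing to verify
            final = pred
            trace.records.append(
                IterationRecord(
                    iteration=iteration,
                    prediction=pred.to_dict(),
                    recalled={},
                    feedback_sent=[],
                    accepted=pred.normalized_names(),
                    converged=True,
                )
            )
            trace.terminal_reason = "converged"
            break
        if config.use_backward:
            profile = backward_infer(pred, backend, config, iteration=iteration)
        else:
            profile = RecalledProfile(
                per_diagnosis={normalize_diagnosis(n): [] for n in pred.diagnosis_names()}
            )
        report = examine(note, pred, profile, backend, config)
        for item in report.prediction.items:
            key = item.normalized
            kept = item.kept_explanations()
            if key in accepted:
                _merge_kept(accepted[key], kept)
                continue
            if key not in pending:
                pending[key] = DDxItem(diagnosis=item.diagnosis, explanations=[])
                order.append(key)
            _merge_kept(pending[key], kept)
            if pending[key].support_count >= config.beta:
                item_final = pending.pop(key)
                item_final.low_confidence = False
                accepted[key] = item_final
        for key in accepted:
            if key not in order:
                order.append(key)
        feedback = [pending[k].diagnosis for k in order if k in pending]
        converged = not feedback
        trace.records.append(
            IterationRecord(
                iteration=iteration,
                prediction=report.prediction.to_dict(),
                recalled=profile.to_dict(),
                feedback_sent=list(feedback),
                accepted=[k for k in order if k in accepted],
                converged=converged,
            )
        )
        if converged:
            trace.terminal_reason = "converged"
            break
        if not config.use_reflection:
            trace.terminal_reason = "max_iterations"
            break
    if final is None:
        items: list[DDxItem] = []
        for key in order:
            if key in accepted:
                items.append(accepted[key])
            else:
                flagged = pending[key]
                flagged.low_confidence = True
                items.append(flagged)
        final = DDxPrediction(
            items=items,
            iteration=max(1, trace.n_iterations()),
            strategy="dual_inf",
            note_id=note.note_id,
        )
    return final, trace
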