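"""Evaluation of predicted differentials against annotated ground truth.

Two headline accuracies, both cumulative over the case set:

* **diagnostic accuracy** — correct diagnoses / total diagnoses. A
  predicted diagnosis is correct when the matcher pairs it one-to-one
  with a ground-truth diagnosis. The default denominator is the total
  number of *ground-truth* diagnoses (recall-style, since correctness is
  only meaningful against the annotated differential); a precision-style
  denominator over predicted diagnoses is available behind
  ``denominator="predicted"`` for sensitivity analysis.
* **interpretation accuracy** — correct interpretations / total
  interpretations. A ground-truth explanation counts as correctly
  interpreted when some kept predicted explanation of the matched
  diagnosis is judged consistent with it; unmatched diagnoses contribute
  no correct interpretations. Denominator conventions mirror
  diagnostic accuracy.

Predictions flagged low-confidence (unresolved at the iteration cap)
are excluded from the evaluated differential by default
(``include_flagged=False``); including them gives the unfiltered
comparison.

Also here: semantic similarity scoring (METEOR-style in core; embedding
metrics pluggable via :func:`register_metric`), the explanation error
taxonomy (missing content / factual error / low relevance), paired
bootstrap confidence intervals with a sign-flip permutation test, and
five-number distribution summaries for per-note score vectors.
"""

from __future__ import annotations

from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

from ._text import normalize_diagnosis, split_sentences
from .errors import ConfigurationError, UndefinedMetricError
from .judge import LexicalJudge
from .meteor import meteor_score
from .types import AnnotatedCase, DDxItem, DDxPrediction

# ---------------------------------------------------------------------------
# diagnosis matching
# ---------------------------------------------------------------------------

#: Small auditable synonym table for diagnosis-name matching; extend via
#: ``SynonymMatcher(extra_pairs=...)``.
DIAGNOSIS_SYNONYMS: tuple[tuple[str, str], ...] = (
    ("heart attack", "myocardial infarction"),
    ("stroke", "cerebrovascular accident"),
    ("high blood pressure", "hypertension"),
    ("collapsed lung", "pneumothorax"),
    ("blood in the pleural cavity", "hemothorax"),
    ("kidney stones", "nephrolithiasis"),
    ("gallstones", "cholelithiasis"),
    ("chickenpox", "varicella"),
    ("shingles", "herpes zoster"),
    ("piles", "hemorrhoids"),
)


class ExactMatcher:
    """Diagnoses match iff their normalized forms are identical."""

    def score(self, predicted: str, truth: str) -> float:
        return 1.0 if normalize_diagnosis(predicted) == normalize_diagnosis(truth) else 0.0


class SynonymMatcher(ExactMatcher):
    """Exact-normalized matching extended by a synonym table."""

    def __init__(self, extra_pairs: Iterable[tuple[str, str]] = ()):
        self._canon: dict[str, str] = {}
        for a, b in tuple(DIAGNOSIS_SYNONYMS) + tuple(extra_pairs):
            na, nb = normalize_diagnosis(a), normalize_diagnosis(b)
            root = self._canon.get(na, self._canon.get(nb, na))
            self._canon[na] = root
            self._canon[nb] = root

    def _c(self, name: str) -> str:
        n = normalize_diagnosis(name)
        return self._canon.get(n, n)

    def score(self, predicted: str, truth: str) -> float:
        return 1.0 if self._c(predicted) == self._c(truth) else 0.0


class JudgeMatcher:
    """Fuzzy matching through a consistency judge (lexical or backend)."""

    def __init__(self, judge: LexicalJudge | None = None):
        self.judge = judge or LexicalJudge()

    def score(self, predicted: str, truth: str) -> float:
        s = self.judge.score(predicted, [truth])
        return s if s >= self.judge.threshold else 0.0


def match_diagnoses(
    predicted: Sequence[str], truth: Sequence[str], matcher=None
) -> list[tuple[str, str]]:
    """Greedy one-to-one matching of predicted to truth diagnosis names,
    by descending match quality; each truth name is matched at most once."""
    matcher = matcher or ExactMatcher()
    scored = []
    for i, p in enumerate(predicted):
        for j, t in enumerate(truth):
            s = matcher.score(p, t)
            if s > 0:
                scored.append((-s, i, j))
    scored.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[str, str]] = []
    for _, i, j in scored:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        pairs.append((predicted[i], truth[j]))
    return pairs


# ---------------------------------------------------------------------------
# accuracies
# ---------------------------------------------------------------------------


def _evaluated_items(pred: DDxPrediction | None, include_flagged: bool) -> list[DDxItem]:
    if pred is None:
        return []
    return [i for i in pred.items if include_flagged or not i.low_confidence]


def _case_matches(
    pred: DDxPrediction | None,
    case: AnnotatedCase,
    matcher,
    include_flagged: bool,
) -> tuple[list[DDxItem], dict[str, DDxItem]]:
    """Evaluated items and {normalized truth name -> matched predicted item}."""
    items = _evaluated_items(pred, include_flagged)
    by_norm = {i.normalized: i for i in items}
    pairs = match_diagnoses([i.diagnosis for i in items], case.truth_names(), matcher)
    matched = {
        normalize_diagnosis(t): by_norm[normalize_diagnosis(p)] for p, t in pairs
    }
    return items, matched


def diagnostic_accuracy(
    predictions: Sequence[DDxPrediction | None],
    cases: Sequence[AnnotatedCase],
    *,
    matcher=None,
    include_flagged: bool = False,
    denominator: str = "truth",
) -> float:
    """Cumulative correct diagnoses over all cases divided by the total
    diagnosis count (ground-truth total by default)."""
    matcher = matcher or ExactMatcher()
    correct = 0
    denom = 0
    for pred, case in zip(predictions, cases, strict=True):
        items, matched = _case_matches(pred, case, matcher, include_flagged)
        correct += len(matched)
        denom += len(case.ddx) if denominator == "truth" else len(items)
    if denom == 0:
        raise UndefinedMetricError("diagnostic accuracy undefined: zero diagnoses")
    return correct / denom


def per_note_diagnostic_accuracy(
    predictions: Sequence[DDxPrediction | None],
    cases: Sequence[AnnotatedCase],
    *,
    matcher=None,
    include_flagged: bool = False,
) -> np.ndarray:
    """Per-case fraction of ground-truth diagnoses recovered."""
    matcher = matcher or ExactMatcher()
    out = []
    for pred, case in zip(predictions, cases, strict=True):
        _, matched = _case_matches(pred, case, matcher, include_flagged)
        out.append(len(matched) / len(case.ddx) if case.ddx else np.nan)
    return np.asarray(out, dtype=float)


def _covered_truth_items(
    case: AnnotatedCase, matched: dict[str, DDxItem], judge
) -> tuple[int, int]:
    """(covered, total) ground-truth explanation items for one case."""
    covered = 0
    total = 0
    for truth_dx in case.ddx:
        total += len(truth_dx.explanations)
        item = matched.get(truth_dx.normalized)
        if item is None:
            continue
        kept = [e.text for e in item.kept_explanations()]
        for truth_expl in truth_dx.explanations:
            if any(judge.consistent(k, [truth_expl]) for k in kept):
                covered += 1
    return covered, total


def interpretation_accuracy(
    predictions: Sequence[DDxPrediction | None],
    cases: Sequence[AnnotatedCase],
    *,
    judge: LexicalJudge | None = None,
    matcher=None,
    include_flagged: bool = False,
    denominator: str = "truth",
) -> float:
    """Cumulative correct interpretations over total interpretations.

    With the default ground-truth denominator the numerator is the
    number of ground-truth explanation items covered by some consistent
    kept predicted explanation of the matched diagnosis. With
    ``denominator="predicted"`` the numerator is the number of kept
    predicted explanation items consistent with some ground-truth
    explanation of their matched diagnosis, over all kept predicted
    items.
    """
    judge = judge or LexicalJudge()
    matcher = matcher or ExactMatcher()
    num = 0
    denom = 0
    for pred, case in zip(predictions, cases, strict=True):
        items, matched = _case_matches(pred, case, matcher, include_flagged)
        if denominator == "truth":
            c, t = _covered_truth_items(case, matched, judge)
            num += c
            denom += t
        else:
            truth_of = {normalize_diagnosis(t.diagnosis): t.explanations for t in case.ddx}
            matched_norms = {i.normalized for i in matched.values()}
            for item in items:
                for e in item.kept_explanations():
                    denom += 1
                    if item.normalized in matched_norms:
                        refs = truth_of.get(item.normalized, [])
                        if refs and judge.consistent(e.text, refs):
                            num += 1
    if denom == 0:
        raise UndefinedMetricError("interpretation accuracy undefined: zero interpretations")
    return num / denom


def per_note_interpretation_accuracy(
    predictions: Sequence[DDxPrediction | None],
    cases: Sequence[AnnotatedCase],
    *,
    judge: LexicalJudge | None = None,
    matcher=None,
    include_flagged: bool = False,
) -> np.ndarray:
    judge = judge or LexicalJudge()
    matcher = matcher or ExactMatcher()
    out = []
    for pred, case in zip(predictions, cases, strict=True):
        _, matched = _case_matches(pred, case, matcher, include_flagged)
        c, t = _covered_truth_items(case, matched, judge)
        out.append(c / t if t else np.nan)
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# semantic similarity
# ---------------------------------------------------------------------------

_METRICS: dict[str, Callable[[str, str], float]] = {"meteor": meteor_score}


def register_metric(name: str, fn: Callable[[str, str], float]) -> None:
    """Register a sentence-pair metric (e.g. an embedding-based scorer).

    Embedding metrics are deliberately not bundled so the core package
    never downloads model weights; plug them in here.
    """
    _METRICS[name] = fn


def semantic_scores(
    predictions: Sequence[DDxPrediction | None],
    cases: Sequence[AnnotatedCase],
    metrics: Sequence[str] = ("meteor",),
    *,
    matcher=None,
    include_flagged: bool = False,
) -> dict[str, float]:
    """Mean per-case semantic score per metric.

    Per case, each ground-truth explanation of a matched diagnosis is
    scored against the best-scoring kept predicted explanation of that
    diagnosis (explanations of unmatched diagnoses score 0); the case
    score is the mean over ground-truth explanation items.
    """
    for m in metrics:
        if m not in _METRICS:
            raise ConfigurationError(
                f"metric {m!r} is not registered; known: {sorted(_METRICS)}"
            )
    vectors = {
        m: per_note_semantic_scores(
            predictions, cases, m, matcher=matcher, include_flagged=include_flagged
        )
        for m in metrics
    }
    return {m: float(np.nanmean(v)) for m, v in vectors.items()}


def per_note_semantic_scores(
    predictions: Sequence[DDxPrediction | None],
    cases: Sequence[AnnotatedCase],
    metric: str = "meteor",
    *,
    matcher=None,
    include_flagged: bool = False,
) -> np.ndarray:
    if metric not in _METRICS:
        raise ConfigurationError(f"metric {metric!r} is not registered")
    fn = _METRICS[metric]
    matcher = matcher or ExactMatcher()
    out = []
    for pred, case in zip(predictions, cases, strict=True):
        _, matched = _case_matches(pred, case, matcher, include_flagged)
        scores: list[float] = []
        for truth_dx in case.ddx:
            item = matched.get(truth_dx.normalized)
            kept = [e.text for e in item.kept_explanations()] if item else []
            for truth_expl in truth_dx.explanations:
                scores.append(max((fn(k, truth_expl) for k in kept), default=0.0))
        out.append(float(np.mean(scores)) if scores else np.nan)
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# error taxonomy
# ---------------------------------------------------------------------------


@dataclass
class ErrorProfile:
    """Counts of cases exhibiting each explanation error type.

    ``missing_content`` — at least two ground-truth evidence pieces have
    no consistent predicted counterpart; ``factual_error`` — some
    predicted evidence line is medically wrong for its diagnosis
    (contradicts the knowledge base); ``low_relevance`` — some predicted
    evidence line is pertinent neither to the ground truth nor to the
    note.
    """

    missing_content: int = 0
    factual_error: int = 0
    low_relevance: int = 0
    per_specialty: dict[str, dict[str, int]] = field(default_factory=dict)
    specialty_sizes: dict[str, int] = field(default_factory=dict)

    def add(self, other: "ErrorProfile", specialty: str | None = None) -> None:
        self.missing_content += other.missing_content
        self.factual_error += other.factual_error
        self.low_relevance += other.low_relevance
        if specialty is not None:
            bucket = self.per_specialty.setdefault(
                specialty, {"missing_content": 0, "factual_error": 0, "low_relevance": 0}
            )
            bucket["missing_content"] += other.missing_content
            bucket["factual_error"] += other.factual_error
            bucket["low_relevance"] += other.low_relevance
            self.specialty_sizes[specialty] = self.specialty_sizes.get(specialty, 0) + 1

    def normalized_rates(self) -> dict[str, dict[str, float]]:
        """Per-specialty error counts divided by specialty sample size."""
        out: dict[str, dict[str, float]] = {}
        for spec, counts in self.per_specialty.items():
            n = self.specialty_sizes.get(spec, 0)
            if n == 0:
                raise UndefinedMetricError(f"no sample size recorded for {spec!r}")
            out[spec] = {k: v / n for k, v in counts.items()}
        return out


def classify_errors(
    prediction: DDxPrediction | None,
    case: AnnotatedCase,
    judge: LexicalJudge | None = None,
    kb=None,
    *,
    include_flagged: bool = False,
) -> ErrorProfile:
    """Error-type flags (0/1 each) for one case's prediction.

    The factual-error channel needs knowledge-base access (``kb``) to
    decide that a line is a real medical finding attached to the wrong
    diagnosis; without it the channel stays 0.
    """
    judge = judge or LexicalJudge()
    items, matched = _case_matches(prediction, case, ExactMatcher(), include_flagged)
    covered, total = _covered_truth_items(case, matched, judge)
    profile = ErrorProfile()
    if total - covered >= 2:
        profile.missing_content = 1
    truth_of = {t.normalized: t.explanations for t in case.ddx}
    note_sentences = split_sentences(case.note.text)
    for item in items:
        truth_expls = truth_of.get(item.normalized, [])
        own_kb = kb.symptoms(item.diagnosis) if kb is not None else None
        for e in item.kept_explanations():
            if truth_expls and judge.consistent(e.text, truth_expls):
                continue
            if (
                kb is not None
                and own_kb
                and not judge.consistent(e.text, own_kb)
                and judge.consistent(e.text, kb.all_symptom_lines())
            ):
                profile.factual_error = 1
                continue
            if not judge.consistent(e.text, note_sentences):
                profile.low_relevance = 1
    return profile


def error_profile(
    predictions: Sequence[DDxPrediction | None],
    cases: Sequence[AnnotatedCase],
    judge: LexicalJudge | None = None,
    kb=None,
    *,
    include_flagged: bool = False,
) -> ErrorProfile:
    """Aggregate error profile with a per-specialty breakdown."""
    total = ErrorProfile()
    for pred, case in zip(predictions, cases, strict=True):
        contribution = classify_errors(
            pred, case, judge, kb, include_flagged=include_flagged
        )
        total.add(contribution, specialty=case.note.specialty.value)
    return total


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapComparison:
    difference: float
    ci_low: float
    ci_high: float
    p_value: float


def bootstrap_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    reps: int = 1000,
    seed: int = 0,
) -> BootstrapComparison:
    """Paired comparison of per-note score vectors.

    Reports the mean paired difference (A − B), a percentile 95%
    bootstrap CI over resampled paired differences, and a two-sided
    sign-flip permutation p-value. Fully seeded and deterministic.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score vectors must be 1-D and equal length")
    if len(a) == 0:
        raise ValueError("empty score vectors")
    diff = a - b
    mean_diff = float(diff.mean())
    rng = np.random.default_rng(seed)
    n = len(diff)
    idx = rng.integers(0, n, size=(reps, n))
    boot_means = diff[idx].mean(axis=1)
    ci_low, ci_high = np.percentile(boot_means, [2.5, 97.5])
    signs = rng.choice([-1.0, 1.0], size=(reps, n))
    perm_means = (diff * signs).mean(axis=1)
    p = (1 + int(np.sum(np.abs(perm_means) >= abs(mean_diff)))) / (reps + 1)
    return BootstrapComparison(
        difference=mean_diff, ci_low=float(ci_low), ci_high=float(ci_high), p_value=float(p)
    )


@dataclass(frozen=True)
class DistributionReport:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    outliers: tuple[float, ...]

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def distribution_report(scores: Sequence[float]) -> DistributionReport:
    """Five-number summary with 1.5×IQR outliers.

    Quartiles use linear interpolation between order statistics (the
    numpy default), so [1,2,3,4,5] reports quartiles 2 and 4.
    """
    x = np.asarray(scores, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("cannot summarize an empty score vector")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = tuple(float(v) for v in np.sort(x[(x < lo) | (x > hi)]))
    return DistributionReport(
        minimum=float(x.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(x.max()),
        outliers=outliers,
    )


# ---------------------------------------------------------------------------
# human-evaluation score schema
# ---------------------------------------------------------------------------

HUMAN_METRICS = ("correctness", "completeness", "usefulness")


@dataclass(frozen=True)
class HumanScore:
    """One clinician rating of one case under one method (1–5 scales)."""

    case_id: str
    method: str
    correctness: int
    completeness: int
    usefulness: int

    def __post_init__(self) -> None:
        for m in HUMAN_METRICS:
            v = getattr(self, m)
            if not 1 <= int(v) <= 5:
                raise ValueError(f"{m} must be an integer in [1, 5], got {v}")


def read_human_scores(path) -> list[HumanScore]:
    """Read clinician ratings from CSV with columns
    case_id,method,correctness,completeness,usefulness."""
    import pandas as pd

    df = pd.read_csv(path)
    required = ["case_id", "method", *HUMAN_METRICS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"human-score CSV missing columns: {missing}")
    return [
        HumanScore(
            case_id=str(row.case_id),
            method=str(row.method),
            correctness=int(row.correctness),
            completeness=int(row.completeness),
            usefulness=int(row.usefulness),
        )
        for row in df.itertuples()
    ]


def summarize_human_scores(scores: Sequence[HumanScore]):
    """Score-value counts per method and metric (1–5 histogram), as a
    pandas DataFrame indexed by (method, metric)."""
    import pandas as pd

    rows = []
    for metric in HUMAN_METRICS:
        for s in scores:
            rows.append({"method": s.method, "metric": metric, "score": getattr(s, metric)})
    df = pd.DataFrame(rows)
    return (
        df.groupby(["method", "metric", "score"]).size().unstack(fill_value=0)
        if len(df)
        else pd.DataFrame()
    )


# ---------------------------------------------------------------------------
# aggregate result
# ---------------------------------------------------------------------------


@dataclass
class EvalResult:
    """Bundle of the headline metrics for one strategy's predictions."""

    diagnostic_accuracy: float
    interpretation_accuracy: float
    semantic_scores: dict[str, float]
    per_note: dict[str, np.ndarray]
    ci: dict[str, BootstrapComparison] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "diagnostic_accuracy": self.diagnostic_accuracy,
            "interpretation_accuracy": self.interpretation_accuracy,
            "semantic_scores": dict(self.semantic_scores),
            "per_note": {k: list(map(float, v)) for k, v in self.per_note.items()},
            "ci": {
                k: {
                    "difference": c.difference,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "p_value": c.p_value,
                }
                for k, c in self.ci.items()
            },
        }


def evaluate(
    predictions: Sequence[DDxPrediction | None],
    cases: Sequence[AnnotatedCase],
    *,
    matcher=None,
    judge: LexicalJudge | None = None,
    metrics: Sequence[str] = ("meteor",),
    include_flagged: bool = False,
) -> EvalResult:
    """Compute both accuracies, semantic scores, and per-note vectors."""
    kwargs = dict(matcher=matcher, include_flagged=include_flagged)
    return EvalResult(
        diagnostic_accuracy=diagnostic_accuracy(predictions, cases, **kwargs),
        interpretation_accuracy=interpretation_accuracy(
            predictions, cases, judge=judge, **kwargs
        ),
        semantic_scores=semantic_scores(predictions, cases, metrics, **kwargs),
        per_note={
            "diagnostic": per_note_diagnostic_accuracy(predictions, cases, **kwargs),
            "interpretation": per_note_interpretation_accuracy(
                predictions, cases, judge=judge, **kwargs
            ),
        },
    )
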