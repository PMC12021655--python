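"""Accuracies, semantic scoring, error taxonomy, comparison statistics."""

import numpy as np
import pytest

from dualinf import (
    AnnotatedCase,
    ClinicalNote,
    ConfigurationError,
    DDxItem,
    DDxPrediction,
    ExplanationItem,
    GroundTruthDx,
    HumanScore,
    LexicalJudge,
    SynonymMatcher,
    UndefinedMetricError,
    bootstrap_compare,
    classify_errors,
    diagnostic_accuracy,
    distribution_report,
    interpretation_accuracy,
    match_diagnoses,
    meteor_score,
    register_metric,
    semantic_scores,
)
from dualinf.evaluation import (
    per_note_diagnostic_accuracy,
    read_human_scores,
    summarize_human_scores,
)
from meteor_reference import reference_meteor


def case_of(note_id, truth):
    """truth: list of (diagnosis, [explanations])."""
    return AnnotatedCase(
        note=ClinicalNote(note_id=note_id, text="Synthetic note body for testing."),
        ddx=[GroundTruthDx(d, list(e)) for d, e in truth],
    )


def pred_of(note_id, items):
    """items: list of (diagnosis, [explanation texts])."""
    return DDxPrediction(
        note_id=note_id,
        items=[DDxItem(d, [ExplanationItem(t) for t in e]) for d, e in items],
    )


class TestMatching:
    def test_identical_lists_fully_matched(self):
        pairs = match_diagnoses(["gout", "cellulitis"], ["cellulitis", "gout"])
        assert len(pairs) == 2

    def test_empty_prediction_matches_nothing(self):
        assert match_diagnoses([], ["gout"]) == []

    def test_synonym_table_bridges_surface_forms(self):
        pairs = match_diagnoses(
            ["heart attack"], ["myocardial infarction"], matcher=SynonymMatcher()
        )
        assert pairs == [("heart attack", "myocardial infarction")]

    def test_one_to_one_each_truth_used_once(self):
        pairs = match_diagnoses(["gout", "gouts"], ["gout"], matcher=SynonymMatcher())
        assert len(pairs) == 1


class TestDiagnosticAccuracy:
    def test_perfect_prediction(self):
        cases = [case_of("a", [("gout", ["x"]), ("cellulitis", ["y"])])]
        preds = [pred_of("a", [("gout", []), ("cellulitis", [])])]
        assert diagnostic_accuracy(preds, cases) == 1.0

    def test_hand_enumerated_fraction(self):
        """3 cases with 5+4+5 ground-truth diagnoses and 7 total matches
        give 7/14 = 0.5."""
        t1 = [(f"disease a{i}", []) for i in range(5)]
        t2 = [(f"disease b{i}", []) for i in range(4)]
        t3 = [(f"disease c{i}", []) for i in range(5)]
        cases = [case_of("a", t1), case_of("b", t2), case_of("c", t3)]
        preds = [
            pred_of("a", [("disease a0", []), ("disease a1", []), ("disease a2", [])]),
            pred_of("b", [("disease b0", []), ("disease b1", []), ("wrong", [])]),
            pred_of("c", [("disease c0", []), ("disease c1", []), ("other", [])]),
        ]
        assert diagnostic_accuracy(preds, cases) == pytest.approx(7 / 14)

    def test_no_matches_floor(self):
        cases = [case_of("a", [("gout", [])])]
        preds = [pred_of("a", [("cellulitis", [])])]
        assert diagnostic_accuracy(preds, cases) == 0.0

    def test_zero_denominator_raises(self):
        cases = [case_of("a", [])]
        with pytest.raises(UndefinedMetricError):
            diagnostic_accuracy([pred_of("a", [])], cases)

    def test_invariant_to_case_and_diagnosis_order(self):
        cases = [
            case_of("a", [("gout", []), ("cellulitis", [])]),
            case_of("b", [("migraine", [])]),
        ]
        preds = [
            pred_of("a", [("cellulitis", []), ("gout", [])]),
            pred_of("b", [("tension headache", [])]),
        ]
        forward = diagnostic_accuracy(preds, cases)
        backward = diagnostic_accuracy(preds[::-1], cases[::-1])
        assert forward == backward

    def test_flagged_items_excluded_by_default(self):
        pred = pred_of("a", [("gout", [])])
        pred.items[0].low_confidence = True
        cases = [case_of("a", [("gout", [])])]
        assert diagnostic_accuracy([pred], cases) == 0.0
        assert diagnostic_accuracy([pred], cases, include_flagged=True) == 1.0

    def test_failed_case_counts_in_denominator(self):
        cases = [case_of("a", [("gout", [])]), case_of("b", [("migraine", [])])]
        preds = [pred_of("a", [("gout", [])]), None]
        assert diagnostic_accuracy(preds, cases) == 0.5
        vec = per_note_diagnostic_accuracy(preds, cases)
        assert vec.tolist() == [1.0, 0.0]


class TestInterpretationAccuracy:
    def test_perfect_prediction(self):
        cases = [case_of("a", [("gout", ["hot red toe", "urate crystals"])])]
        preds = [pred_of("a", [("gout", ["hot red toe", "urate crystals"])])]
        assert interpretation_accuracy(preds, cases) == 1.0

    def test_enumerated_fixture_four_of_ten(self):
        """10 ground-truth explanation items, exactly 4 covered -> 0.4."""
        gout_truth = [
            "hot red swollen toe joint",
            "needle shaped crystals in aspirate",
            "attack began after alcohol binge",
            "elevated serum uric acid",
            "excruciating pain starting overnight",
        ]
        cellulitis_truth = [
            "spreading warm tender redness",
            "poorly demarcated advancing edge",
            "fever with general malaise",
            "enlarged painful groin lymph nodes",
            "cracked skin between the toes",
        ]
        cases = [case_of("a", [("gout", gout_truth), ("cellulitis", cellulitis_truth)])]
        preds = [
            pred_of(
                "a",
                [
                    ("gout", gout_truth[:2]),
                    ("cellulitis", cellulitis_truth[:2]),
                ],
            )
        ]
        assert interpretation_accuracy(preds, cases) == pytest.approx(0.4)

    def test_unmatched_diagnoses_contribute_nothing(self):
        cases = [case_of("a", [("gout", ["hot red toe"])])]
        preds = [pred_of("a", [("cellulitis", ["hot red toe"])])]
        assert interpretation_accuracy(preds, cases) == 0.0

    def test_stricter_judge_never_increases_accuracy(self, kb):
        from dualinf import MockClinicianBackend, NoiseModel, run_batch, DualInfConfig
        from conftest import make_cases

        cases = make_cases(kb, 15, seed=42)
        backend = MockClinicianBackend(
            kb, NoiseModel(omission_rate=0.3, hallucination_rate=0.3, seed=2)
        )
        result = run_batch("cot", cases, backend, DualInfConfig(seed=1))
        accs = [
            interpretation_accuracy(
                result.predictions, cases, judge=LexicalJudge(threshold=th)
            )
            for th in (0.3, 0.5, 0.7, 0.9)
        ]
        assert accs == sorted(accs, reverse=True)


class TestMeteorStyleScore:
    def test_identity_scores_one(self):
        assert meteor_score("absent breath sounds", "absent breath sounds") == 1.0

    def test_disjoint_vocabulary_scores_zero(self):
        assert meteor_score("red itchy rash", "elevated troponin") == 0.0

    def test_matches_reference_implementation_on_sentence_pairs(self):
        pairs = [
            ("absent breath sounds on left", "breath sounds absent on the left side"),
            ("sudden chest pain", "chest pain of sudden onset"),
            ("fever with chills", "high fever and shaking chills"),
            ("the patient reports vomiting", "patient reported emesis"),
            ("pain radiating to the arm", "arm pain radiating upward"),
            ("heart rate elevated", "cardiac rate is high"),
            ("swelling of both ankles", "edema of the ankles"),
            ("dull ache in the shoulder", "shoulder ache described as dull"),
            ("blood pressure low", "low blood pressure reading"),
            ("night sweats for weeks", "weeks of drenching night sweats"),
            ("cough producing sputum", "productive cough with sputum"),
            ("weight loss despite appetite", "appetite preserved despite weight loss"),
            ("tingling in the feet", "feet tingling at night"),
            ("blurred vision", "vision becomes blurred"),
            ("lung fields clear", "clear pulmonary fields"),
            ("kidney function reduced", "renal function is reduced"),
            ("severe headache", "intense headache"),
            ("stiff neck", "neck stiffness"),
            ("abdominal pain after meals", "pain in the abdomen after meals"),
            ("no relief with rest", "rest brings no relief"),
        ]
        assert len(pairs) == 20
        for cand, ref in pairs:
            assert meteor_score(cand, ref) == pytest.approx(
                reference_meteor(cand, ref), abs=1e-12
            ), (cand, ref)

    def test_score_bounded(self):
        for cand, ref in [("a b c", "c b a"), ("x", "x y z"), ("p q", "q")]:
            assert 0.0 <= meteor_score(cand, ref) <= 1.0


class TestSemanticScores:
    def test_identical_explanations_score_one(self):
        cases = [case_of("a", [("gout", ["hot red toe joint"])])]
        preds = [pred_of("a", [("gout", ["hot red toe joint"])])]
        assert semantic_scores(preds, cases)["meteor"] == 1.0

    def test_unregistered_metric_rejected(self):
        cases = [case_of("a", [("gout", ["x"])])]
        with pytest.raises(ConfigurationError):
            semantic_scores([pred_of("a", [])], cases, metrics=("bertscore",))

    def test_metric_registry_is_extensible(self):
        register_metric("constant_half", lambda c, r: 0.5)
        cases = [case_of("a", [("gout", ["x"])])]
        preds = [pred_of("a", [("gout", ["anything"])])]
        assert semantic_scores(preds, cases, metrics=("constant_half",)) == {
            "constant_half": 0.5
        }


class TestErrorTaxonomy:
    def test_perfect_prediction_has_no_errors(self):
        case = case_of("a", [("gout", ["hot red toe", "urate crystals seen"])])
        pred = pred_of("a", [("gout", ["hot red toe", "urate crystals seen"])])
        profile = classify_errors(pred, case)
        assert (profile.missing_content, profile.factual_error, profile.low_relevance) == (
            0, 0, 0,
        )

    def test_single_missing_piece_not_counted(self):
        """Missing content requires at least two absent evidence pieces."""
        case = case_of("a", [("gout", ["hot red toe", "urate crystals seen"])])
        pred = pred_of("a", [("gout", ["hot red toe"])])
        assert classify_errors(pred, case).missing_content == 0

    def test_two_missing_pieces_counted_once(self):
        case = case_of(
            "a", [("gout", ["hot red toe", "urate crystals seen", "attack overnight"])]
        )
        pred = pred_of("a", [("gout", ["hot red toe"])])
        assert classify_errors(pred, case).missing_content == 1

    def test_dropped_and_offtopic_fixture(self):
        """Two dropped truth items plus one injected off-topic line:
        missing_content and low_relevance each increment once."""
        case = case_of(
            "a", [("gout", ["hot red toe", "urate crystals seen", "attack overnight"])]
        )
        pred = pred_of(
            "a", [("gout", ["hot red toe", "prefers tea over coffee in the mornings"])]
        )
        profile = classify_errors(pred, case)
        assert profile.missing_content == 1
        assert profile.low_relevance == 1
        assert profile.factual_error == 0


class TestBootstrap:
    def test_identical_vectors_degenerate(self):
        r = bootstrap_compare([0.4, 0.5, 0.6], [0.4, 0.5, 0.6], reps=200, seed=1)
        assert r.difference == 0.0
        assert (r.ci_low, r.ci_high) == (0.0, 0.0)
        assert r.p_value == 1.0

    def test_constant_shift(self):
        a = np.full(50, 0.6)
        b = np.full(50, 0.5)
        r = bootstrap_compare(a, b, reps=500, seed=2)
        assert r.difference == pytest.approx(0.1)
        assert r.ci_low == pytest.approx(0.1)
        assert r.ci_high == pytest.approx(0.1)

    def test_gaussian_shift_matches_analytic_ci(self):
        """Percentile bootstrap CI agrees with the closed-form normal CI
        within Monte-Carlo error at n=500."""
        rng = np.random.default_rng(11)
        diff = rng.normal(loc=0.05, scale=0.1, size=500)
        a = np.zeros(500) + diff
        b = np.zeros(500)
        r = bootstrap_compare(a, b, reps=4000, seed=3)
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert r.ci_low == pytest.approx(diff.mean() - 1.96 * se, abs=0.005)
        assert r.ci_high == pytest.approx(diff.mean() + 1.96 * se, abs=0.005)
        assert r.p_value < 0.01

    def test_seed_determinism(self):
        a = [0.1, 0.4, 0.3, 0.9]
        b = [0.2, 0.1, 0.5, 0.4]
        assert bootstrap_compare(a, b, seed=7) == bootstrap_compare(a, b, seed=7)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_compare([1.0], [1.0, 2.0])


class TestDistributionReport:
    def test_two_point_median(self):
        assert distribution_report([0.0, 1.0]).median == 0.5

    def test_documented_quartile_rule(self):
        r = distribution_report([1, 2, 3, 4, 5])
        assert (r.q1, r.median, r.q3) == (2.0, 3.0, 4.0)

    def test_constant_vector_no_outliers(self):
        r = distribution_report([0.3] * 10)
        assert r.iqr == 0.0
        assert r.outliers == ()

    def test_extreme_value_flagged(self):
        r = distribution_report([1, 2, 3, 4, 5, 100])
        assert 100.0 in r.outliers

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            distribution_report([])


class TestHumanScores:
    def test_range_validation(self):
        with pytest.raises(ValueError):
            HumanScore("c1", "cot", correctness=6, completeness=3, usefulness=3)

    def test_csv_round_trip_and_summary(self, tmp_path):
        path = tmp_path / "scores.csv"
        path.write_text(
            "case_id,method,correctness,completeness,usefulness\n"
            "c1,dual_inf,4,4,4\nc1,sc_cot,3,2,3\nc2,dual_inf,5,3,4\n"
        )
        scores = read_human_scores(path)
        assert len(scores) == 3
        summary = summarize_human_scores(scores)
        assert summary.loc[("dual_inf", "correctness"), 4] == 1
        assert summary.loc[("dual_inf", "correctness"), 5] == 1
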