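"""Bidirectional-inference loop: examination, reflection, ablations."""

import pytest

from dualinf import (
    ClinicalNote,
    ConfigurationError,
    DDxItem,
    DDxPrediction,
    DualInfConfig,
    ExplanationItem,
    MockClinicianBackend,
    NoiseModel,
    RecalledProfile,
    backward_infer,
    configure_variant,
    diagnostic_accuracy,
    examine,
    forward_infer,
    reflect_loop,
    run_batch,
)
from dualinf.engine import VARIANT_FLAGS

from conftest import make_cases

NOTE = ClinicalNote(
    note_id="fix-1",
    text=(
        "Sharp stabbing pain in the chest. Dull ache in the left shoulder. "
        "Ringing sound in both ears. Blurred vision in dim light."
    ),
)


def fixture_prediction():
    return DDxPrediction(
        note_id="fix-1",
        items=[
            DDxItem(
                "costochondritis",
                [
                    ExplanationItem("sharp stabbing pain in the chest"),
                    ExplanationItem("dull ache in the left shoulder"),
                    ExplanationItem("green discoloration of the toenails"),
                ],
            )
        ],
    )


def fixture_profile():
    return RecalledProfile(
        per_diagnosis={
            "costochondritis": [
                "sharp stabbing pain in the chest",
                "dull ache in the left shoulder",
                "ringing sound in both ears",
                "blurred vision in dim light",
            ]
        }
    )


class TestExamination:
    def test_discard_supplement_and_support_count(self):
        """3 forward explanations, one contradicting recall, plus two
        recalled note-present findings -> kept 2 + supplemented 2 = 4."""
        report = examine(NOTE, fixture_prediction(), fixture_profile(),
                         config=DualInfConfig(beta=3))
        exam = report.entries["costochondritis"]
        assert exam.support_count == 4
        assert exam.supplemented == [
            "ringing sound in both ears",
            "blurred vision in dim light",
        ]
        statuses = {t: s for t, s, _ in exam.decisions}
        assert statuses["green discoloration of the toenails"] == "discarded"
        reasons = {t: r for t, _, r in exam.decisions}
        assert reasons["green discoloration of the toenails"] == "contradicts-recalled"
        assert not exam.low_confidence
        assert report.converged

    def test_below_beta_is_flagged_low_confidence(self):
        """A diagnosis with 2 supports at beta=3 is low-confidence (2 < 3)."""
        pred = DDxPrediction(
            note_id="fix-1",
            items=[
                DDxItem(
                    "costochondritis",
                    [
                        ExplanationItem("sharp stabbing pain in the chest"),
                        ExplanationItem("dull ache in the left shoulder"),
                    ],
                )
            ],
        )
        profile = RecalledProfile(
            per_diagnosis={"costochondritis": ["sharp stabbing pain in the chest"]}
        )
        report = examine(NOTE, pred, profile, config=DualInfConfig(beta=3))
        assert report.entries["costochondritis"].support_count == 2
        assert report.entries["costochondritis"].low_confidence
        assert not report.converged

    def test_beta_zero_never_flags(self):
        pred = DDxPrediction(note_id="fix-1", items=[DDxItem("costochondritis")])
        report = examine(NOTE, pred, RecalledProfile({"costochondritis": []}),
                         config=DualInfConfig(beta=0))
        assert report.converged
        assert not report.entries["costochondritis"].low_confidence

    def test_missing_profile_entry_judged_against_note_only(self):
        report = examine(NOTE, fixture_prediction(), RecalledProfile(),
                         config=DualInfConfig(beta=2))
        exam = report.entries["costochondritis"]
        assert exam.recall_missing
        assert exam.support_count == 2  # the two note-supported ones survive
        assert exam.supplemented == []
        reasons = {t: r for t, _, r in exam.decisions}
        assert reasons["green discoloration of the toenails"] == "unsupported"

    def test_supplemented_items_only_created_by_examination(self):
        report = examine(NOTE, fixture_prediction(), fixture_profile(),
                         config=DualInfConfig())
        provs = [e.provenance for e in report.prediction.items[0].explanations]
        assert provs.count("supplemented") == 2
        # forward items keep their provenance even when discarded
        assert provs.count("forward") == 3

    def test_flag_count_monotone_in_beta(self, kb, cases20):
        backend = MockClinicianBackend(kb, NoiseModel(omission_rate=0.6, seed=13))
        note = cases20[0].note
        pred = forward_infer(note, [], backend, DualInfConfig(seed=3))
        profile = backward_infer(pred, backend, DualInfConfig(seed=3))
        flagged = []
        for beta in range(0, 7):
            report = examine(note, pred, profile, backend, DualInfConfig(beta=beta))
            flagged.append(
                sum(1 for e in report.entries.values() if e.low_confidence)
            )
        assert flagged == sorted(flagged)
        assert flagged[0] == 0


class TestForwardBackward:
    def test_forward_oracle_on_iteration_one(self, tiny_kb):
        text = ". ".join(tiny_kb.symptoms("hemothorax")) + "."
        note = ClinicalNote(note_id="n1", text=text)
        pred = forward_infer(note, [], MockClinicianBackend(tiny_kb), DualInfConfig())
        assert "hemothorax" in pred.normalized_names()

    def test_forward_determinism(self, kb, cases20):
        backend = MockClinicianBackend(kb, NoiseModel(omission_rate=0.5, seed=2))
        cfg = DualInfConfig(seed=9)
        a = forward_infer(cases20[0].note, [], backend, cfg)
        b = forward_infer(cases20[0].note, [], backend, cfg)
        assert a.to_dict() == b.to_dict()

    def test_feedback_redraws_evidence(self, tiny_kb):
        # omitted evidence can be restored on a later iteration's fresh draw
        text = ". ".join(tiny_kb.symptoms("hemothorax")) + "."
        note = ClinicalNote(note_id="n2", text=text)
        backend = MockClinicianBackend(tiny_kb, NoiseModel(omission_rate=0.5, seed=6))
        cfg = DualInfConfig(seed=1)
        draws = set()
        for iteration in (1, 2, 3, 4):
            pred = forward_infer(note, ["hemothorax"], backend, cfg, iteration=iteration)
            item = pred.get("hemothorax")
            assert item is not None  # feedback forces re-proposal
            draws.add(tuple(e.text for e in item.explanations))
        assert len(draws) > 1  # evidence was actually refreshed across draws

    def test_backward_empty_prediction_gives_empty_profile(self, zero_backend):
        pred = DDxPrediction(note_id="x", items=[DDxItem("acute gout")])
        empty = DDxPrediction(note_id="x", items=[])
        assert backward_infer(empty, zero_backend, DualInfConfig()).per_diagnosis == {}
        assert backward_infer(pred, zero_backend, DualInfConfig()).get("acute gout")

    def test_profile_keys_match_prediction(self, kb, cases20):
        backend = MockClinicianBackend(kb, NoiseModel(omission_rate=0.3, seed=1))
        cfg = DualInfConfig(seed=4)
        for case in cases20[:10]:
            pred = forward_infer(case.note, [], backend, cfg)
            profile = backward_infer(pred, backend, cfg)
            assert set(profile.per_diagnosis) == set(pred.normalized_names())


class TestVariants:
    def test_variant_flag_table(self):
        fi = configure_variant("fi")
        assert (fi.use_backward, fi.use_examination, fi.use_reflection) == (
            False, False, False,
        )
        star = configure_variant("dual_inf_star")
        assert (star.use_backward, star.use_examination, star.use_reflection) == (
            True, True, False,
        )
        full = configure_variant("dual_inf")
        assert full.use_backward and full.use_examination and full.use_reflection
        assert set(VARIANT_FLAGS) == {"fi", "fi_em", "fi_em_star", "dual_inf_star", "dual_inf"}

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            configure_variant("triple_inf")

    def test_base_parameters_preserved(self):
        cfg = configure_variant("fi_em", DualInfConfig(beta=4, lam=2, seed=77))
        assert (cfg.beta, cfg.lam, cfg.seed) == (4, 2, 77)
        assert not cfg.use_backward and cfg.use_examination

    def test_dual_inf_with_lam_one_equals_no_reflection_variant(self, kb, cases20):
        backend = MockClinicianBackend(kb, NoiseModel(omission_rate=0.5, seed=3))
        for case in cases20[:5]:
            capped, _ = reflect_loop(
                case.note, backend, configure_variant("dual_inf", DualInfConfig(lam=1, seed=2))
            )
            star, _ = reflect_loop(
                case.note, backend, configure_variant("dual_inf_star", DualInfConfig(seed=2))
            )
            assert capped.to_dict() == star.to_dict()


class TestReflectLoop:
    def test_lam_one_runs_exactly_one_forward_pass(self, kb, cases20):
        backend = MockClinicianBackend(kb, NoiseModel(omission_rate=0.7, seed=5))
        _, trace = reflect_loop(cases20[0].note, backend, DualInfConfig(lam=1, seed=1))
        assert trace.n_iterations() == 1

    def test_zero_noise_converges_at_iteration_one(self, tiny_kb):
        text = (
            ". ".join(tiny_kb.symptoms("community acquired pneumonia")[:3]) + "."
        )
        note = ClinicalNote(note_id="n3", text=text)
        pred, trace = reflect_loop(note, MockClinicianBackend(tiny_kb), DualInfConfig())
        assert trace.terminal_reason == "converged"
        assert trace.n_iterations() == 1
        assert pred.normalized_names() == ["community acquired pneumonia"]
        assert not pred.items[0].low_confidence

    def test_iteration_cap_respected_under_heavy_noise(self, kb, cases20):
        backend = MockClinicianBackend(kb, NoiseModel(omission_rate=0.9, seed=8))
        cfg = DualInfConfig(seed=6)
        for case in cases20[:10]:
            _, trace = reflect_loop(case.note, backend, cfg)
            assert trace.n_iterations() <= cfg.lam
            if trace.terminal_reason == "converged":
                assert trace.records[-1].converged

    def test_final_diagnoses_subset_of_forward_proposals(self, kb, cases20):
        backend = MockClinicianBackend(kb, NoiseModel(omission_rate=0.6, seed=4))
        cfg = DualInfConfig(seed=11)
        for case in cases20[:10]:
            pred, trace = reflect_loop(case.note, backend, cfg)
            proposed = set()
            for rec in trace.records:
                proposed.update(i["diagnosis"].lower() for i in rec.prediction["items"])
            assert {i.diagnosis.lower() for i in pred.items} <= proposed

    def test_unresolved_at_cap_emitted_flagged_not_dropped(self, tiny_kb):
        # a two-finding presentation can never reach beta=3 support
        text = (
            "One sided chest pain after blunt trauma. "
            "Falling hematocrit after chest injury."
        )
        note = ClinicalNote(note_id="n4", text=text)
        pred, trace = reflect_loop(note, MockClinicianBackend(tiny_kb), DualInfConfig())
        assert trace.terminal_reason == "max_iterations"
        item = pred.get("hemothorax")
        assert item is not None and item.low_confidence
        assert item.support_count == 2

    def test_trace_replay_is_byte_identical(self, kb, cases20):
        backend = MockClinicianBackend(kb, NoiseModel(omission_rate=0.5, seed=7))
        cfg = DualInfConfig(seed=3)
        _, t1 = reflect_loop(cases20[1].note, backend, cfg)
        _, t2 = reflect_loop(cases20[1].note, backend, cfg)
        assert t1.to_json() == t2.to_json()

    def test_correct_diagnoses_accumulate_monotonically(self, kb):
        cases = make_cases(kb, 10, seed=55)
        backend = MockClinicianBackend(kb, NoiseModel(omission_rate=0.5, seed=19))
        result = run_batch("dual_inf", cases, backend, DualInfConfig(seed=5))
        for trace, case in zip(result.traces, cases):
            truth = {d.normalized for d in case.ddx}
            correct = [
                len(set(rec.accepted) & truth) for rec in trace.records
            ]
            assert correct == sorted(correct)

    def test_all_variants_reach_oracle_accuracy_without_noise(self, kb, cases20):
        backend = MockClinicianBackend(kb)
        for variant in VARIANT_FLAGS:
            result = run_batch(variant, cases20[:10], backend, DualInfConfig(seed=1))
            assert diagnostic_accuracy(result.predictions, cases20[:10]) == 1.0, variant
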