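import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nahrkit.estimator import (
    BDR_TYPES,
    ClassFrequencies,
    CloneAssayCounts,
    Condition,
    CultureRejected,
    EstimatorError,
    FrequencyStage,
    GeneticClass,
    OutcomeTable,
    OutcomeType,
    PlugSurvey,
    SemEdgeCase,
    SemInputs,
    background_subtract,
    bdr_total,
    categorize_copy_number,
    class_frequencies,
    classify_sem_inputs,
    estimate_outcomes,
    loss_sem,
    normalize_classes,
    outcome_sem,
    repair_type_frequencies,
)

I, II, III, OTH = (
    GeneticClass.CLASS_I,
    GeneticClass.CLASS_II,
    GeneticClass.CLASS_III,
    GeneticClass.CLASS_OTHER,
)


def counts(ci, cii, ciii, other=0, n_scored=None, condition=Condition.INDUCED):
    n_hygs = ci + cii + ciii + other
    return CloneAssayCounts(
        condition=condition,
        n_scored=n_scored if n_scored is not None else n_hygs,
        n_hygs=n_hygs,
        class_counts={I: ci, II: cii, III: ciii, OTH: other},
    )


# Published frequency rows used as fixture inputs: 163cs wild-type hybrid
# and purebred diploids, and the in-repeat (RAHScs) hybrid row.
ROW_HYBRID_WT = {
    OutcomeType.INTERNAL_DELETION: 60.6,
    OutcomeType.ISOCHROMOSOME: 10.8,
    OutcomeType.RING: 3.2,
    OutcomeType.TRANSLOCATION: 1.4,
    OutcomeType.OTHER: 0.4,
    OutcomeType.ALLELIC: 2.9,
}
ROW_HYBRID_WT_LOSS = 20.7
ROW_PUREBRED_WT = {
    OutcomeType.INTERNAL_DELETION: 13.4,
    OutcomeType.ISOCHROMOSOME: 3.2,
    OutcomeType.RING: 0.3,
    OutcomeType.TRANSLOCATION: 0.3,
    OutcomeType.OTHER: 0.3,
    OutcomeType.ALLELIC: 81.5,
}
ROW_PUREBRED_WT_LOSS = 1.0
ROW_HYBRID_RAHSCS = {
    OutcomeType.TY_GC: 22.1,
    OutcomeType.INTRA_TY_DELETION: 59.1,
    OutcomeType.INTERNAL_DELETION: 7.4,
    OutcomeType.ISOCHROMOSOME: 3.7,
    OutcomeType.RING: 1.5,
    OutcomeType.TRANSLOCATION: 0.3,
    OutcomeType.OTHER: 3.9,
    OutcomeType.ALLELIC: 3.9,
}
ROW_HYBRID_RAHSCS_LOSS = 5.8
ROW_HYBRID_RAHSCS_BOUNDS = [OutcomeType.OTHER, OutcomeType.ALLELIC]


class TestClassFrequencies:
    def test_worked_percentages(self):
        freqs = class_frequencies(counts(857, 100, 43))
        assert (freqs.class_i, freqs.class_ii, freqs.class_iii) == (85.7, 10.0, 4.3)
        assert freqs.stage is FrequencyStage.RAW

    def test_all_loss(self):
        freqs = class_frequencies(counts(0, 0, 500))
        assert (freqs.class_i, freqs.class_ii, freqs.class_iii) == (0.0, 0.0, 100.0)

    def test_no_cut_clones_errors(self):
        with pytest.raises(EstimatorError, match="no cut clones"):
            class_frequencies(counts(0, 0, 0, n_scored=100))

    def test_class_other_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluding"):
            freqs = class_frequencies(counts(90, 0, 0, other=10))
        assert freqs.class_i == 90.0  # denominator still n_hygs = 100

    def test_scored_denominator_switch(self):
        freqs = class_frequencies(counts(50, 0, 0, n_scored=200), denominator="scored")
        assert freqs.class_i == 25.0

    def test_counts_invariants(self):
        with pytest.raises(EstimatorError):
            CloneAssayCounts(Condition.INDUCED, 10, 20, {I: 20})
        with pytest.raises(EstimatorError):
            CloneAssayCounts(Condition.INDUCED, 10, 5, {I: 4})  # sum mismatch


class TestBackgroundSubtract:
    def test_zero_background_unchanged(self):
        induced = ClassFrequencies(85.7, 10.0, 4.3, FrequencyStage.RAW)
        zero = ClassFrequencies(0, 0, 0, FrequencyStage.RAW, hygs_fraction=0.0)
        out = background_subtract(induced, zero)
        assert (out.class_i, out.class_ii, out.class_iii) == (85.7, 10.0, 4.3)
        assert out.stage is FrequencyStage.BACKGROUND_SUBTRACTED

    def test_high_background_rejected(self):
        induced = ClassFrequencies(85.7, 10.0, 4.3, FrequencyStage.RAW)
        noisy = ClassFrequencies(10, 10, 10, FrequencyStage.RAW, hygs_fraction=0.6)
        with pytest.raises(CultureRejected) as exc_info:
            background_subtract(induced, noisy)
        assert exc_info.value.hygs_fraction == 0.6

    def test_negative_clamped_with_warning(self):
        induced = ClassFrequencies(1.0, 50.0, 49.0, FrequencyStage.RAW)
        background = ClassFrequencies(1.5, 0.0, 0.0, FrequencyStage.RAW, hygs_fraction=0.1)
        with pytest.warns(UserWarning, match="clamping"):
            out = background_subtract(induced, background)
        assert out.class_i == 0.0

    def test_stage_checked(self):
        normalized = ClassFrequencies(50, 30, 20, FrequencyStage.NORMALIZED)
        raw = ClassFrequencies(0, 0, 0, FrequencyStage.RAW)
        with pytest.raises(EstimatorError):
            background_subtract(normalized, raw)


class TestNormalize:
    def test_already_100(self):
        freqs = ClassFrequencies(40, 40, 20, FrequencyStage.BACKGROUND_SUBTRACTED)
        out = normalize_classes(freqs)
        assert (out.class_i, out.class_ii, out.class_iii) == (40, 40, 20)

    def test_rescaling(self):
        freqs = ClassFrequencies(40.5, 40.5, 9.0, FrequencyStage.BACKGROUND_SUBTRACTED)
        out = normalize_classes(freqs)
        assert out.class_i == pytest.approx(45.0)
        assert out.class_iii == pytest.approx(10.0)
        assert out.total == pytest.approx(100.0)

    def test_zero_sum_errors(self):
        freqs = ClassFrequencies(0, 0, 0, FrequencyStage.BACKGROUND_SUBTRACTED)
        with pytest.raises(EstimatorError, match="sum to 0"):
            normalize_classes(freqs)

    @given(
        a=st.floats(0.01, 100),
        b=st.floats(0.01, 100),
        c=st.floats(0.01, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_always_sums_to_100(self, a, b, c):
        freqs = ClassFrequencies(a, b, c, FrequencyStage.BACKGROUND_SUBTRACTED)
        assert normalize_classes(freqs).total == pytest.approx(100.0)

    def test_subtract_then_normalize_differs_from_reverse(self):
        # the supported order is subtract -> normalize; reversing the
        # order yields different numbers on this crafted input, so a
        # silent reordering would be caught
        induced = ClassFrequencies(60, 20, 10, FrequencyStage.RAW)
        background = ClassFrequencies(10, 0, 0, FrequencyStage.RAW, hygs_fraction=0.1)
        supported = normalize_classes(background_subtract(induced, background))
        # reverse order, computed by hand: normalize induced to 100 first
        scale = 100.0 / 90.0
        reversed_i = 60 * scale - 10
        assert supported.class_i != pytest.approx(reversed_i)


class TestRepairTypeFrequencies:
    def worked_example_inputs(self):
        class_freqs = ClassFrequencies(85.7, 13.3, 1.0, FrequencyStage.NORMALIZED)
        survey = PlugSurvey(
            {
                I: {OutcomeType.INTERNAL_DELETION: 5, OutcomeType.ALLELIC: 27},
                II: {
                    OutcomeType.ISOCHROMOSOME: 40,
                    OutcomeType.RING: 3,
                    OutcomeType.TRANSLOCATION: 3,
                },
            }
        )
        return class_freqs, survey

    def test_worked_example_cell(self):
        class_freqs, survey = self.worked_example_inputs()
        table = repair_type_frequencies(class_freqs, survey, n_hygs=1062)
        entry = table.entries[OutcomeType.INTERNAL_DELETION]
        assert round(entry.frequency, 1) == 13.4
        assert round(entry.sem, 1) == 5.5

    def test_loss_reported_directly(self):
        class_freqs, survey = self.worked_example_inputs()
        table = repair_type_frequencies(class_freqs, survey)
        assert table.loss_percent == 1.0

    def test_conservation_to_100(self):
        class_freqs, survey = self.worked_example_inputs()
        table = repair_type_frequencies(class_freqs, survey)
        assert table.total_percent == pytest.approx(100.0, abs=1e-9)

    def test_class_zero_types_become_bounds(self):
        class_freqs = ClassFrequencies(100.0, 0.0, 0.0, FrequencyStage.NORMALIZED)
        survey = PlugSurvey(
            {
                I: {OutcomeType.INTERNAL_DELETION: 10},
                II: {OutcomeType.RING: 0},
            }
        )
        table = repair_type_frequencies(class_freqs, survey, n_hygs=500)
        ring = table.entries[OutcomeType.RING]
        assert ring.is_bound and ring.frequency == 0.0
        assert ring.bound == pytest.approx(100.0 / 500)

    def test_cross_class_additivity(self):
        class_freqs = ClassFrequencies(30.0, 20.0, 50.0, FrequencyStage.NORMALIZED)
        survey = PlugSurvey(
            {
                I: {OutcomeType.ALLELIC: 10, OutcomeType.INTERNAL_DELETION: 10},
                II: {OutcomeType.ALLELIC: 5, OutcomeType.RING: 5},
            }
        )
        table = repair_type_frequencies(class_freqs, survey)
        # 30 * 10/20 + 20 * 5/10 = 15 + 10 = 25
        assert table.entries[OutcomeType.ALLELIC].frequency == pytest.approx(25.0)

    def test_no_plugs_bound_is_class_percent(self):
        class_freqs = ClassFrequencies(95.0, 5.0, 0.0, FrequencyStage.NORMALIZED)
        survey = PlugSurvey(
            {
                I: {OutcomeType.INTERNAL_DELETION: 8},
                II: {OutcomeType.RING: 0, OutcomeType.TRANSLOCATION: 0},
            }
        )
        # class II percent > 0 but no plugs analyzed
        table = repair_type_frequencies(class_freqs, survey)
        ring = table.entries[OutcomeType.RING]
        assert ring.is_bound and ring.bound == pytest.approx(5.0)

    def test_requires_normalized_stage(self):
        raw = ClassFrequencies(50, 40, 10, FrequencyStage.RAW)
        with pytest.raises(EstimatorError):
            repair_type_frequencies(raw, PlugSurvey({I: {OutcomeType.ALLELIC: 1}}))


class TestOutcomeSem:
    def test_worked_example(self):
        # p = 5/32, n = 32, weight 85.7 -> 5.5 at one decimal
        sem = outcome_sem(SemInputs(85.7, 32, 5))
        assert round(sem, 1) == 5.5
        assert sem == pytest.approx(math.sqrt((5 / 32) * (27 / 32) / 32) * 85.7)

    def test_all_of_class_reproduces_hybrid_cell(self):
        # 18/18 class-I plugs were deletions; recomputed with 17 of 18
        # this must give the printed 60.6 +/- 3.3
        sem = outcome_sem(classify_sem_inputs(60.6, 18, 18))
        assert round(sem, 1) == 3.3

    def test_zero_of_type_upper_bound(self):
        sem = outcome_sem(classify_sem_inputs(85.7, 32, 0))
        expected = math.sqrt((1 / 32) * (31 / 32) / 32) * 85.7
        assert sem == pytest.approx(expected)
        assert round(sem, 2) == 2.64

    def test_class_zero_and_no_plugs(self):
        assert outcome_sem(classify_sem_inputs(0.0, 10, 0)) == 0.0
        assert outcome_sem(classify_sem_inputs(12.0, 0, 0)) == 0.0

    def test_monotone_decreasing_in_n(self):
        sems = [
            outcome_sem(SemInputs(50.0, n, n // 2, SemEdgeCase.NONE))
            for n in (8, 16, 32, 64, 128)
        ]
        assert all(x > y for x, y in zip(sems, sems[1:]))

    def test_limit_large_n(self):
        assert outcome_sem(SemInputs(50.0, 10**8, 5 * 10**7)) < 0.01

    def test_inconsistent_edge_case_rejected(self):
        with pytest.raises(EstimatorError):
            SemInputs(50.0, 10, 10, SemEdgeCase.NONE)  # saturated but marked NONE
        with pytest.raises(EstimatorError):
            SemInputs(50.0, 10, 3, SemEdgeCase.ALL_OF_CLASS)
        with pytest.raises(EstimatorError):
            SemInputs(50.0, 10, 2, SemEdgeCase.ZERO_OF_TYPE)

    @given(
        n=st.integers(2, 500),
        e=st.integers(0, 500),
        weight=st.floats(0.0, 100.0),
    )
    @settings(max_examples=80, deadline=None)
    def test_sem_never_negative(self, n, e, weight):
        e = min(e, n)
        sem = outcome_sem(classify_sem_inputs(weight, n, e))
        assert sem >= 0.0


class TestLossSem:
    def test_two_replicates(self):
        assert loss_sem([20, 22]) == pytest.approx(1.0)

    def test_identical_replicates(self):
        assert loss_sem([5.0, 5.0, 5.0]) == 0.0

    def test_three_replicates(self):
        assert loss_sem([10, 20, 30]) == pytest.approx(5.7735, abs=1e-4)

    def test_single_replicate_rejected(self):
        with pytest.raises(EstimatorError):
            loss_sem([20.0])


class TestDerivedSummaries:
    def test_bdr_hybrid_76(self):
        table = OutcomeTable.from_frequencies(ROW_HYBRID_WT, ROW_HYBRID_WT_LOSS)
        assert bdr_total(table) == 76

    def test_bdr_purebred_17(self):
        table = OutcomeTable.from_frequencies(ROW_PUREBRED_WT, ROW_PUREBRED_WT_LOSS)
        assert bdr_total(table) == 17  # 17.2 rounded

    def test_bdr_empty_table(self):
        table = OutcomeTable.from_frequencies({}, 0.0)
        assert bdr_total(table) == 0

    def test_bdr_bounds_count_zero(self):
        table = OutcomeTable.from_frequencies(
            {OutcomeType.INTERNAL_DELETION: 40.0, OutcomeType.RING: 9.0},
            0.0,
            bounds=[OutcomeType.RING],
        )
        assert bdr_total(table) == 40

    def test_copy_number_hybrid_97(self):
        table = OutcomeTable.from_frequencies(ROW_HYBRID_WT, ROW_HYBRID_WT_LOSS)
        change, no_change = categorize_copy_number(table)
        assert change == 97
        assert no_change == 3  # allelic 2.9 only

    def test_copy_number_rahscs_19(self):
        table = OutcomeTable.from_frequencies(
            ROW_HYBRID_RAHSCS, ROW_HYBRID_RAHSCS_LOSS, bounds=ROW_HYBRID_RAHSCS_BOUNDS
        )
        change, no_change = categorize_copy_number(table, dsb_in_repeat=True)
        assert change == 19
        assert no_change == 81

    def test_all_allelic(self):
        table = OutcomeTable.from_frequencies({OutcomeType.ALLELIC: 100.0}, 0.0)
        assert categorize_copy_number(table) == (0, 100)


class TestFullPipeline:
    def test_end_to_end_conservation(self):
        induced = counts(600, 155, 200, n_scored=955)
        uninduced = counts(2, 1, 1, n_scored=900)
        survey = PlugSurvey(
            {
                I: {OutcomeType.INTERNAL_DELETION: 15, OutcomeType.ALLELIC: 3},
                II: {OutcomeType.ISOCHROMOSOME: 30, OutcomeType.RING: 12,
                     OutcomeType.TRANSLOCATION: 10},
            }
        )
        # the scored denominator keeps the uninduced background small
        # relative to the induced percentages in this fixture
        table = estimate_outcomes(induced, uninduced, survey, denominator="scored")
        assert table.total_percent == pytest.approx(100.0, abs=1e-9)

    def test_uninduced_none_means_no_background(self):
        induced = counts(600, 155, 200)
        survey = PlugSurvey({I: {OutcomeType.INTERNAL_DELETION: 10}})
        table = estimate_outcomes(induced, None, survey)
        assert table.entries[OutcomeType.INTERNAL_DELETION].frequency > 0

    def test_loss_sem_attached(self):
        induced = counts(600, 155, 200)
        survey = PlugSurvey({I: {OutcomeType.INTERNAL_DELETION: 10}})
        table = estimate_outcomes(induced, None, survey, loss_percents_across_inductions=[20, 22])
        assert table.loss_sem == pytest.approx(1.0)
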