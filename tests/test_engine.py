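"""Cohort engine: tree traversal, occupancy, length of stay."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from cyp2d6cea import (Arm, DoseState, ParameterError, base_case,
                       initial_state_split, run_cohort, solve_suboptimal_los)
from cyp2d6cea.engine import (assign_length_of_stay, correct_at_eval1_fraction,
                              los_pair)
from cyp2d6cea.parameters import GENOTYPES, apply_overrides


def override(p=None, **kv):
    return apply_overrides(p or base_case(), kv)


class TestInitialSplit:
    def test_care_as_usual_poor_metabolizer(self, params):
        split = initial_state_split("PM", Arm.CARE_AS_USUAL, params)
        assert split == pytest.approx({"correct": 0.24, "subtherapeutic": 0.0,
                                       "supratherapeutic": 0.76})

    def test_extensive_metabolizers_unaffected_by_genotyping(self, params):
        for arm in Arm:
            split = initial_state_split("EM", arm, params)
            assert split == pytest.approx({"correct": 0.63,
                                           "subtherapeutic": 0.25,
                                           "supratherapeutic": 0.12})

    def test_guided_dosing_scales_um_subtherapeutic_fraction(self, params):
        split = initial_state_split("UM", Arm.GENOTYPING, params)
        assert split["subtherapeutic"] == pytest.approx(0.57 * (1 - 0.35))
        assert split["correct"] == pytest.approx(1 - 0.57 * 0.65)
        assert split["supratherapeutic"] == 0.0

    def test_unknown_genotype_rejected(self, params):
        with pytest.raises(ParameterError):
            initial_state_split("XX", Arm.CARE_AS_USUAL, params)

    @pytest.mark.parametrize("genotype", GENOTYPES)
    @pytest.mark.parametrize("arm", list(Arm))
    def test_fractions_sum_to_one(self, params, genotype, arm):
        split = initial_state_split(genotype, arm, params)
        assert sum(split.values()) == pytest.approx(1.0, abs=1e-12)


class TestTreeCounts:
    def test_washout_entries_at_first_evaluation(self, params):
        trace = run_cohort(Arm.CARE_AS_USUAL, params)
        assert trace.events["washout_eval1"] == pytest.approx(220.0)

    def test_second_tdm_group_size(self, params):
        # incorrectly dosed at eval1 surviving dropout:
        # 1000 x 0.4261 x 0.78
        trace = run_cohort(Arm.CARE_AS_USUAL, params)
        assert trace.events["second_tdm"] == pytest.approx(426.1 * 0.78, rel=1e-9)

    def test_discontinued_counts_both_arms(self, params):
        care = run_cohort(Arm.CARE_AS_USUAL, params)
        geno = run_cohort(Arm.GENOTYPING, params)
        assert care.events["discontinued"] == pytest.approx(248, abs=0.5)
        assert geno.events["discontinued"] == pytest.approx(247, abs=0.5)

    def test_no_eval2_dropout_leaves_only_eval1_washouts(self, params):
        p = override(params, p_discontinue_eval2=0.0)
        trace = run_cohort(Arm.CARE_AS_USUAL, p)
        assert trace.events["discontinued"] == \
            pytest.approx(trace.events["washout_eval1"])

    def test_degenerate_probabilities_correct_everyone_at_eval1(self, params):
        p = override(params, p_discontinue_eval1=0.0,
                     p_discontinue_eval2=0.0, p_incorrect_eval2=0.0)
        trace = run_cohort(Arm.CARE_AS_USUAL, p)
        assert trace.events["third_tdm"] == 0.0
        for seg in trace.segments[1:]:
            incorrect = sum(c for (g, s), c in seg.occupancy.items()
                            if s in (DoseState.SUBTHERAPEUTIC,
                                     DoseState.SUPRATHERAPEUTIC))
            assert incorrect == pytest.approx(0.0, abs=1e-9)

    def test_zero_effect_makes_arms_identical(self, params):
        p = override(params, effect_genotyping=0.0)
        care = run_cohort(Arm.CARE_AS_USUAL, p)
        geno = run_cohort(Arm.GENOTYPING, p)
        for s_care, s_geno in zip(care.segments, geno.segments):
            assert s_care.occupancy == pytest.approx(s_geno.occupancy)
        assert care.events == pytest.approx(geno.events)

    def test_cohort_size_linearity(self, params):
        double = override(params, cohort_size=2000)
        t1 = run_cohort(Arm.GENOTYPING, params)
        t2 = run_cohort(Arm.GENOTYPING, double)
        for s1, s2 in zip(t1.segments, t2.segments):
            for key, count in s1.occupancy.items():
                assert s2.occupancy[key] == pytest.approx(2 * count)
        for key, val in t1.events.items():
            assert t2.events[key] == pytest.approx(2 * val)


class TestOccupancyInvariants:
    @pytest.mark.parametrize("arm", list(Arm))
    def test_conservation(self, params, arm):
        trace = run_cohort(arm, params)
        for seg in trace.segments:
            assert seg.total() == pytest.approx(params.cohort_size, abs=1e-9)
            assert all(c >= 0 for c in seg.occupancy.values())

    def test_direction_retention(self, params):
        for arm in Arm:
            trace = run_cohort(arm, params)
            for seg in trace.segments:
                for (g, state), count in seg.occupancy.items():
                    if count == 0:
                        continue
                    if state is DoseState.SUBTHERAPEUTIC:
                        assert g not in ("PM", "IM")
                    if state is DoseState.SUPRATHERAPEUTIC:
                        assert g != "UM"

    def test_correct_or_resolved_monotone_and_absorbing(self, params):
        # correct occupancy itself can dip at eval2 (recovered patients may
        # still discontinue), but flow out of the incorrect states is one-way
        trace = run_cohort(Arm.CARE_AS_USUAL, params)
        prev = -1.0
        for seg in trace.segments:
            incorrect = sum(c for (g, s), c in seg.occupancy.items()
                            if s in (DoseState.SUBTHERAPEUTIC,
                                     DoseState.SUPRATHERAPEUTIC))
            resolved = params.cohort_size - incorrect
            assert resolved >= prev - 1e-9
            prev = resolved
        last = trace.segments[-1]
        on_therapy_incorrect = sum(
            c for (g, s), c in last.occupancy.items()
            if s in (DoseState.SUBTHERAPEUTIC, DoseState.SUPRATHERAPEUTIC))
        assert on_therapy_incorrect == pytest.approx(0.0, abs=1e-9)

    def test_genotyping_never_increases_incorrect_occupancy(self, params):
        care = run_cohort(Arm.CARE_AS_USUAL, params)
        geno = run_cohort(Arm.GENOTYPING, params)
        for s_care, s_geno in zip(care.segments, geno.segments):
            for states in [(DoseState.SUBTHERAPEUTIC, DoseState.SUPRATHERAPEUTIC)]:
                inc_care = sum(c for (g, s), c in s_care.occupancy.items()
                               if s in states)
                inc_geno = sum(c for (g, s), c in s_geno.occupancy.items()
                               if s in states)
                assert inc_geno <= inc_care + 1e-9

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(effect=st.floats(0.0, 0.9),
           d1=st.floats(0.0, 0.6),
           d2=st.floats(0.0, 0.6),
           r=st.floats(0.0, 1.0),
           e1=st.floats(2.0, 19.0))
    def test_conservation_under_random_inputs(self, effect, d1, d2, r, e1):
        p = apply_overrides(base_case(), {
            "effect_genotyping": effect, "p_discontinue_eval1": d1,
            "p_discontinue_eval2": d2, "p_incorrect_eval2": r,
            "day_eval1": e1})
        for arm in Arm:
            trace = run_cohort(arm, p)
            for seg in trace.segments:
                assert seg.total() == pytest.approx(p.cohort_size, abs=1e-9)
                assert all(c >= -1e-12 for c in seg.occupancy.values())


class TestLengthOfStay:
    def test_short_stay_from_published_reduction(self, params):
        short, _ = los_pair(params)
        assert short == pytest.approx(28.6 * 0.87)
        assert round(short, 1) == 24.9

    def test_long_stay_solved_value(self):
        assert solve_suboptimal_los(28.6, 24.9, 0.448) == \
            pytest.approx(31.60, abs=0.01)
        assert solve_suboptimal_los(28.6, 24.9, 0.483) == \
            pytest.approx(32.06, abs=0.01)

    def test_no_reduction_collapses_to_mean(self, params):
        assert solve_suboptimal_los(28.6, 28.6, 0.3) == pytest.approx(28.6)
        p = override(params, los_reduction_frac=0.0)
        assert los_pair(p) == (28.6, 28.6)

    def test_degenerate_correct_fraction_rejected(self):
        with pytest.raises(ParameterError, match="p_correct"):
            solve_suboptimal_los(28.6, 24.9, 1.0)
        with pytest.raises(ParameterError, match="p_correct"):
            solve_suboptimal_los(28.6, 24.9, 0.0)

    def test_care_arm_mean_reconstructs_registered_average(self, params):
        trace = run_cohort(Arm.CARE_AS_USUAL, params)
        total = sum(trace.discharge_profile.values())
        mean = sum(los * n for los, n in trace.discharge_profile.items()) / total
        assert mean == pytest.approx(params.hospital.mean_los, abs=1e-12)

    def test_genotyping_arm_mean_stay_is_shorter(self, params):
        care = run_cohort(Arm.CARE_AS_USUAL, params)
        geno = run_cohort(Arm.GENOTYPING, params)

        def mean(t):
            return sum(l * n for l, n in t.discharge_profile.items()) / \
                sum(t.discharge_profile.values())

        assert mean(care) == pytest.approx(28.60, abs=0.005)
        assert mean(geno) == pytest.approx(28.47, abs=0.01)
        assert mean(geno) < mean(care)

    def test_same_los_values_in_both_arms(self, params):
        care = run_cohort(Arm.CARE_AS_USUAL, params)
        geno = run_cohort(Arm.GENOTYPING, params)
        assert (care.short_los, care.long_los) == (geno.short_los, geno.long_los)

    def test_solved_long_stay_weighted_mean_identity(self, params):
        short, long = los_pair(params)
        pc = correct_at_eval1_fraction(params)
        assert pc * short + (1 - pc) * long == \
            pytest.approx(params.hospital.mean_los, abs=1e-12)
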