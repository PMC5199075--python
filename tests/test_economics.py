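"""Costs, QALYs, ICER and threshold search."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from cyp2d6cea import (Arm, accumulate_costs, accumulate_qaly_loss, base_case,
                       net_monetary_benefit, run_cohort, run_model,
                       threshold_test_cost)
from cyp2d6cea.economics import (ArmResult, CostBreakdown, cheapest_daily_units,
                                 compare, nortriptyline_daily_cost,
                                 threshold_test_cost_bisect)
from cyp2d6cea.engine import CohortTrace, Pathway, Segment
from cyp2d6cea.parameters import apply_overrides


def override(p=None, **kv):
    return apply_overrides(p or base_case(), kv)


def _single_state_trace(p, n, direction, days):
    """Hand-built trace: n patients in one incorrect state for `days` days."""
    pw = Pathway(genotype="EM", direction=direction, label="persist_correct",
                 count=n, incorrect_days=days, washout_day=None,
                 nortriptyline_end=p.schedule.horizon_days,
                 tdm_days=(p.schedule.day_eval1,), short_stay=False)
    return CohortTrace(arm=Arm.CARE_AS_USUAL, cohort_size=n, pathways=[pw],
                       segments=[Segment(0, days, {("EM", None): n})],
                       events={}, short_los=24.882, long_los=31.6,
                       discharge_profile={31.6: n})


class TestQALYLoss:
    def test_hand_computed_single_state(self, params):
        # 100 patients subtherapeutic for 12 days: 100 x 0.2 x 12 / 365
        trace = _single_state_trace(params, 100, "sub", 12.0)
        assert accumulate_qaly_loss(trace, params) == \
            pytest.approx(100 * 0.2 * 12 / 365)

    def test_zero_disutilities_give_zero_loss(self, params):
        p = override(params, disutility_supra=0.0, disutility_sub=0.0,
                     disutility_washout=0.0)
        trace = run_cohort(Arm.CARE_AS_USUAL, p)
        assert accumulate_qaly_loss(trace, p) == 0.0

    def test_base_case_cohort_loss_magnitude(self, params, base_result):
        # published magnitude ~4.6 QALYs lost per 1000 patients over 12 weeks
        assert base_result.care_as_usual.qaly_loss == pytest.approx(4.57, rel=0.05)
        assert base_result.genotyping.qaly_loss < base_result.care_as_usual.qaly_loss


class TestCosts:
    def test_genotyping_component_is_cohort_times_test_price(self, base_result):
        assert base_result.genotyping.costs.genotyping == pytest.approx(188_200.0)
        assert base_result.care_as_usual.costs.genotyping == 0.0

    def test_care_as_usual_total_matches_published_scale(self, base_result):
        assert base_result.care_as_usual.costs.total == \
            pytest.approx(7_374_826, rel=0.02)

    def test_breakdown_additivity(self, base_result):
        for arm in (base_result.care_as_usual, base_result.genotyping):
            c = arm.costs
            assert c.total == pytest.approx(
                c.hospitalization + c.monitoring + c.drugs + c.genotyping,
                abs=1e-9)
            assert c.total == pytest.approx(c.care + c.genotyping, abs=1e-9)

    def test_zero_prices_leave_only_genotyping(self, params):
        p = override(params, per_diem=0.0, tdm_per_measurement=0.0,
                     consult=0.0, nortriptyline_10mg=0.0,
                     nortriptyline_25mg=0.0, nortriptyline_50mg=0.0,
                     tranylcypromine_40mg=0.0)
        res = run_model(p)
        assert res.care_as_usual.costs.total == 0.0
        assert res.genotyping.costs.total == pytest.approx(188_200.0)

    def test_monitoring_billed_only_after_discharge(self, params):
        trace = run_cohort(Arm.CARE_AS_USUAL, params)
        costs = accumulate_costs(trace, params)
        fee = 23.11 + 0.25 * 190.62
        # with base LOS values only third-TDM evaluations (day 38) fall
        # outside the hospital stay
        assert costs.monitoring == pytest.approx(
            trace.events["third_tdm"] * fee)

    def test_cheapest_tablet_combination(self, params):
        strengths = ((10.0, 0.08), (25.0, 0.15), (50.0, 0.29))
        assert cheapest_daily_units(75.0, strengths) == pytest.approx(0.44)
        # 30 mg: 25+10 = 35 mg at 0.23 beats 3x10 at 0.24
        assert cheapest_daily_units(30.0, strengths) == pytest.approx(0.23)
        assert cheapest_daily_units(0.0, strengths) == 0.0

    def test_guided_dose_costing_by_genotype(self, params):
        assert nortriptyline_daily_cost("PM", Arm.CARE_AS_USUAL, params) == \
            pytest.approx(0.44)
        assert nortriptyline_daily_cost("PM", Arm.GENOTYPING, params) == \
            pytest.approx(0.23)
        # IMs keep the standard dose outside the IM-adaptation scenario
        assert nortriptyline_daily_cost("IM", Arm.GENOTYPING, params) == \
            pytest.approx(0.44)


class TestIncrementalComparison:
    def test_identical_arms_have_zero_increments(self, params):
        arm = ArmResult(Arm.CARE_AS_USUAL,
                        CostBreakdown(hospitalization=100.0), 1.0,
                        trace=None)
        res = compare(arm, dataclasses.replace(arm, arm=Arm.GENOTYPING),
                      cohort_size=1000, test_cost=0.0)
        assert res.delta_cost == 0.0 and res.delta_qaly == 0.0
        assert res.icer is None

    @pytest.mark.parametrize("dc,dq,expected", [
        (-10.0, 0.5, "dominant"),
        (10.0, -0.5, "dominated"),
        (10.0, 0.5, "trade-off"),
        (-10.0, -0.5, "trade-off"),
    ])
    def test_quadrant_classification(self, dc, dq, expected):
        care = ArmResult(Arm.CARE_AS_USUAL, CostBreakdown(), 2.0, None)
        geno = ArmResult(Arm.GENOTYPING,
                         CostBreakdown(hospitalization=dc), 2.0 - dq, None)
        res = compare(care, geno, cohort_size=1000, test_cost=0.0)
        assert res.dominance == expected
        if expected == "trade-off":
            assert res.icer * res.delta_qaly == pytest.approx(res.delta_cost)
        else:
            assert res.icer is None

    def test_icer_identity_base_case(self, base_result):
        assert base_result.dominance == "trade-off"
        assert base_result.icer * base_result.delta_qaly == \
            pytest.approx(base_result.delta_cost, rel=1e-9)

    def test_genotyping_saves_care_costs_but_adds_test_costs(self, base_result):
        assert base_result.care_savings > 0
        assert base_result.delta_cost > 0
        assert base_result.delta_qaly > 0


class TestThresholdSearch:
    def test_threshold_against_bisection(self, params):
        for wtp in (0.0, 50_000.0):
            closed = threshold_test_cost(params, wtp)
            bisected = threshold_test_cost_bisect(params, wtp)
            assert closed == pytest.approx(bisected, abs=0.01)

    def test_threshold_consistency_identity(self, params, base_result):
        t_wtp = threshold_test_cost(params, 50_000.0, result=base_result)
        t_0 = threshold_test_cost(params, 0.0, result=base_result)
        assert t_wtp - t_0 == pytest.approx(
            50_000.0 * base_result.delta_qaly / params.cohort_size, rel=1e-9)

    def test_zero_effect_without_stay_reduction_breaks_even_at_zero(self, params):
        # dose fractions also set to 1 so the arms are truly identical
        # (guided start doses otherwise shift drug costs by a few cents/day)
        p = override(params, effect_genotyping=0.0, los_reduction_frac=0.0,
                     dose_fraction_pm=1.0, dose_fraction_um=1.0)
        assert threshold_test_cost(p, 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_icer_strictly_increasing_in_test_price(self, params):
        icers = [run_model(params, test_cost=c).icer for c in (50, 150, 250)]
        assert icers[0] < icers[1] < icers[2]

    def test_per_patient_quantities_scale_invariant(self, params):
        small = override(params, cohort_size=250)
        r1, r2 = run_model(params), run_model(small)
        assert r1.delta_cost / 1000 == pytest.approx(r2.delta_cost / 250)
        assert r1.delta_qaly / 1000 == pytest.approx(r2.delta_qaly / 250)
        assert threshold_test_cost(params, 50_000.0) == \
            pytest.approx(threshold_test_cost(small, 50_000.0))


class TestNetMonetaryBenefit:
    def test_zero_at_threshold_price(self, params, base_result):
        wtp = 50_000.0
        c_star = threshold_test_cost(params, wtp, result=base_result)
        assert net_monetary_benefit(base_result, wtp, c_star) == \
            pytest.approx(0.0, abs=1e-6)

    def test_slope_is_minus_cohort_size(self, base_result):
        n0 = net_monetary_benefit(base_result, 50_000.0, 10.0)
        n1 = net_monetary_benefit(base_result, 50_000.0, 11.0)
        assert n0 - n1 == pytest.approx(1000.0)

    def test_wtp_zero_at_zero_price_equals_savings(self, base_result):
        assert net_monetary_benefit(base_result, 0.0, 0.0) == \
            pytest.approx(base_result.care_savings)
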