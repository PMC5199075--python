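"""Costs, QALY loss and incremental cost-effectiveness measures.

Health effects are accumulated as disutility-days: each day a patient
spends sub- or supratherapeutically dosed, or in the post-discontinuation
washout, subtracts the state's utility decrement; divided by days-per-year
this yields the cohort QALY loss.  Costs are direct medical costs from a
payer perspective: hospitalization per diem, post-discharge therapeutic
drug monitoring (plus a quarter psychiatric consult per interpretation),
post-discharge drugs, and the genotyping test itself.  Neither costs nor
utilities are discounted over the 12-week horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from .engine import Arm, CohortTrace, DoseState, run_cohort
from .parameters import ModelParameters, ParameterError


@dataclass(frozen=True)
class CostBreakdown:
    hospitalization: float = 0.0
    monitoring: float = 0.0
    drugs: float = 0.0
    genotyping: float = 0.0

    @property
    def total(self) -> float:
        return self.hospitalization + self.monitoring + self.drugs + self.genotyping

    @property
    def care(self) -> float:
        """Costs of care excluding the genotyping test."""
        return self.hospitalization + self.monitoring + self.drugs


@dataclass(frozen=True)
class ArmResult:
    arm: Arm
    costs: CostBreakdown
    qaly_loss: float
    trace: CohortTrace


@dataclass(frozen=True)
class EconomicResult:
    """Two-arm comparison: genotyping vs care as usual.

    ``delta_cost`` is the extra total cost of genotyping, ``delta_qaly`` the
    QALY gain (care-as-usual loss minus genotyping loss).  ``icer`` is
    defined only in the trade-off quadrants; otherwise ``dominance`` is
    'dominant' (cheaper and more effective) or 'dominated'.
    """

    care_as_usual: ArmResult
    genotyping: ArmResult
    cohort_size: float
    test_cost: float

    @property
    def delta_cost(self) -> float:
        return self.genotyping.costs.total - self.care_as_usual.costs.total

    @property
    def delta_qaly(self) -> float:
        return self.care_as_usual.qaly_loss - self.genotyping.qaly_loss

    @property
    def care_savings(self) -> float:
        """Care-cost savings of genotyping, excluding the test itself."""
        return self.care_as_usual.costs.care - self.genotyping.costs.care

    @property
    def dominance(self) -> str:
        dc, dq = self.delta_cost, self.delta_qaly
        if dq > 0 and dc <= 0:
            return "dominant"
        if dq < 0 and dc >= 0:
            return "dominated"
        if dq == 0:
            return "dominant" if dc < 0 else ("equivalent" if dc == 0 else "dominated")
        return "trade-off"

    @property
    def icer(self) -> float | None:
        if self.dominance != "trade-off":
            return None
        return self.delta_cost / self.delta_qaly


def nortriptyline_daily_cost(genotype: str, arm: Arm,
                             p: ModelParameters) -> float:
    """Daily nortriptyline cost; genotype-guided arms use the adapted dose."""
    fraction = 1.0
    if Arm(arm) is Arm.GENOTYPING:
        if genotype == "PM":
            fraction = p.adaptation_rules.dose_fraction_pm
        elif genotype == "UM":
            fraction = p.adaptation_rules.dose_fraction_um
        elif genotype == "IM" and p.scenario.im_adaptation:
            fraction = p.adaptation_rules.dose_fraction_im
    return cheapest_daily_units(
        fraction * p.costs.standard_dose_mg,
        ((10.0, p.costs.nortriptyline_10mg),
         (25.0, p.costs.nortriptyline_25mg),
         (50.0, p.costs.nortriptyline_50mg)))


@lru_cache(maxsize=256)
def _cheapest(target_mg: float, strengths: tuple[tuple[float, float], ...]) -> float:
    if target_mg <= 0:
        return 0.0
    best = math.inf
    max_units = int(math.ceil(target_mg / min(s for s, _ in strengths))) + 1
    (s1, c1), (s2, c2), (s3, c3) = strengths

    def reach(total: float) -> bool:
        return total >= target_mg - 1e-9

    for n3 in range(max_units + 1):
        for n2 in range(max_units + 1):
            for n1 in range(max_units + 1):
                if reach(n1 * s1 + n2 * s2 + n3 * s3):
                    best = min(best, n1 * c1 + n2 * c2 + n3 * c3)
                    break
    return best


def cheapest_daily_units(target_mg: float,
                         strengths: tuple[tuple[float, float], ...]) -> float:
    """Cheapest combination of tablet strengths reaching ``target_mg``."""
    return _cheapest(round(float(target_mg), 6), tuple(strengths))


def state_patient_days(trace: CohortTrace, p: ModelParameters) -> dict[DoseState, float]:
    """Expected patient-days in each adverse health state."""
    days = {DoseState.SUBTHERAPEUTIC: 0.0, DoseState.SUPRATHERAPEUTIC: 0.0,
            DoseState.DISCONTINUED_WASHOUT: 0.0}
    for pw in trace.pathways:
        if pw.direction == "sub":
            days[DoseState.SUBTHERAPEUTIC] += pw.count * pw.incorrect_days
        elif pw.direction == "supra":
            days[DoseState.SUPRATHERAPEUTIC] += pw.count * pw.incorrect_days
        days[DoseState.DISCONTINUED_WASHOUT] += pw.count * pw.washout_days(p)
    return days


def accumulate_qaly_loss(trace: CohortTrace, p: ModelParameters) -> float:
    """Cohort QALY loss: disutility-weighted patient-days / days-per-year."""
    days = state_patient_days(trace, p)
    c = p.clinical
    dd = (days[DoseState.SUBTHERAPEUTIC] * c.disutility_sub
          + days[DoseState.SUPRATHERAPEUTIC] * c.disutility_supra
          + days[DoseState.DISCONTINUED_WASHOUT] * c.disutility_washout)
    return dd / p.days_per_year


def accumulate_costs(trace: CohortTrace, p: ModelParameters,
                     arm: Arm | None = None,
                     test_cost: float | None = None) -> CostBreakdown:
    """Direct medical costs of one arm.

    Monitoring events and drugs are billed only after discharge (in-hospital
    they are covered by the per diem); an evaluation on day t is billed iff
    t exceeds the patient's length of stay.
    """
    arm = Arm(arm if arm is not None else trace.arm)
    horizon = p.schedule.horizon_days
    monitoring_fee = (p.costs.tdm_per_measurement
                      + p.costs.consult_fraction_per_monitoring * p.costs.consult)
    hospitalization = sum(count * los * p.hospital.per_diem
                          for los, count in trace.discharge_profile.items())
    monitoring = 0.0
    drugs = 0.0
    for pw in trace.pathways:
        los = trace.short_los if pw.short_stay else trace.long_los
        billed = sum(1 for t in pw.tdm_days if t > los)
        monitoring += pw.count * billed * monitoring_fee
        nort_days = max(0.0, pw.nortriptyline_end - los)
        drug_cost = nort_days * nortriptyline_daily_cost(pw.genotype, arm, p)
        sl_start = pw.secondline_start(p)
        if sl_start is not None:
            sl_days = max(0.0, horizon - max(sl_start, los))
            drug_cost += sl_days * p.costs.tranylcypromine_40mg
        drugs += pw.count * drug_cost
    genotyping = 0.0
    if arm is Arm.GENOTYPING:
        fee = p.costs.genotyping_test if test_cost is None else test_cost
        genotyping = trace.cohort_size * fee
    return CostBreakdown(hospitalization=hospitalization, monitoring=monitoring,
                         drugs=drugs, genotyping=genotyping)


def evaluate_arm(arm: Arm, p: ModelParameters,
                 test_cost: float | None = None) -> ArmResult:
    trace = run_cohort(arm, p)
    return ArmResult(arm=Arm(arm), costs=accumulate_costs(trace, p, arm, test_cost),
                     qaly_loss=accumulate_qaly_loss(trace, p), trace=trace)


def compare(care_as_usual: ArmResult, genotyping: ArmResult,
            cohort_size: float, test_cost: float) -> EconomicResult:
    return EconomicResult(care_as_usual=care_as_usual, genotyping=genotyping,
                          cohort_size=cohort_size, test_cost=test_cost)


def run_model(p: ModelParameters,
              test_cost: float | None = None) -> EconomicResult:
    """Run both arms under identical parameters and compare them."""
    fee = p.costs.genotyping_test if test_cost is None else float(test_cost)
    return compare(evaluate_arm(Arm.CARE_AS_USUAL, p),
                   evaluate_arm(Arm.GENOTYPING, p, fee),
                   cohort_size=p.cohort_size, test_cost=fee)


def net_monetary_benefit(result: EconomicResult, wtp: float,
                         test_cost: float | None = None) -> float:
    """NMB of genotyping at a willingness-to-pay threshold.

    Linear in the test price with slope -cohort_size:
    NMB = wtp x dQALY + care savings - cohort x test price.
    """
    fee = result.test_cost if test_cost is None else float(test_cost)
    return (wtp * result.delta_qaly + result.care_savings
            - result.cohort_size * fee)


def threshold_test_cost(p: ModelParameters, wtp: float,
                        result: EconomicResult | None = None) -> float:
    """Genotyping test price at which the ICER equals ``wtp`` (closed form).

    At the threshold the NMB is zero, so the price equals per-patient care
    savings plus wtp x per-patient QALY gain.  ``wtp = 0`` gives the
    break-even price.  With a non-positive QALY gain and positive wtp the
    value still equals the zero-NMB price, which then understates nothing
    but no longer corresponds to a trade-off ICER.
    """
    if wtp < 0:
        raise ParameterError("wtp must be >= 0")
    res = result if result is not None else run_model(p)
    return (res.care_savings + wtp * res.delta_qaly) / res.cohort_size


def threshold_test_cost_bisect(p: ModelParameters, wtp: float,
                               lo: float = 0.0, hi: float = 10_000.0,
                               tol: float = 1e-4) -> float:
    """Bisection on the NMB over the test price; cross-checks the closed form."""
    res = run_model(p, test_cost=0.0)

    def nmb(c: float) -> float:
        return net_monetary_benefit(res, wtp, c)

    if nmb(lo) < 0:
        return lo
    while nmb(hi) > 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - NMB always decreases in price
            raise RuntimeError("no sign change found for threshold search")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if nmb(mid) >= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
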