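"""Deterministic and probabilistic sensitivity analyses.

One-way analysis re-evaluates an outcome (threshold test price at the
willingness-to-pay, or break-even price) at the ends of each input's
plausible range, producing tornado-diagram data.  The probabilistic
analysis draws every uncertain input from its distribution (beta for
proportions, gamma for durations, uniform for genotype frequencies with the
EM share as remainder, Beta-PERT for the supratherapeutic disutility),
pushes each draw through the full two-arm model, and summarizes the draws
as cost-effectiveness acceptability curves over the genotyping test price.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import economics
from .parameters import (DistributionSpec, ModelParameters, ParameterError,
                         apply_overrides, get_value, moment_matched_beta)

PERT_SHAPE = 4.0

_GENOTYPE_FREQ_KEYS = ("freq_pm", "freq_im", "freq_um")


def _frozen(spec: DistributionSpec):
    a = spec.params
    if spec.family == "beta":
        return stats.beta(a[0], a[1])
    if spec.family == "gamma":
        return stats.gamma(a[0], scale=a[1])
    if spec.family == "uniform":
        return stats.uniform(a[0], a[1] - a[0])
    if spec.family == "pert":
        lo, mode, hi = a
        alpha = 1.0 + PERT_SHAPE * (mode - lo) / (hi - lo)
        beta = 1.0 + PERT_SHAPE * (hi - mode) / (hi - lo)
        return stats.beta(alpha, beta, loc=lo, scale=hi - lo)
    raise ParameterError(f"cannot freeze family {spec.family!r}")


def distribution_mean(spec: DistributionSpec) -> float:
    """Analytic mean of a sampling distribution."""
    if spec.family == "fixed":
        return spec.params[0]
    return float(_frozen(spec).mean())


def sample_distribution(spec: DistributionSpec,
                        rng: np.random.Generator,
                        size: int | None = None):
    """Draw from one input distribution using an explicit generator state."""
    if spec.family == "fixed":
        value = spec.params[0]
        return value if size is None else np.full(size, value)
    frozen = _frozen(spec)
    return frozen.rvs(size=size if size is not None else 1,
                      random_state=rng)[0 if size is None else slice(None)]


def effective_psa_specs(p: ModelParameters) -> dict[str, DistributionSpec]:
    """PSA specs with the optional moment-matched stay-reduction swap applied."""
    specs = dict(p.psa_specs)
    if p.los_reduction_moment_matched and "los_reduction_frac" in specs:
        specs["los_reduction_frac"] = moment_matched_beta(
            p.hospital.los_reduction_frac)
    return specs


# --------------------------------------------------------------------------
# one-way deterministic sensitivity (tornado data)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    outcome_low: float
    outcome_high: float

    @property
    def spread(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def outcome_threshold_at_wtp(p: ModelParameters) -> float:
    return economics.threshold_test_cost(p, p.wtp)


def outcome_break_even(p: ModelParameters) -> float:
    return economics.threshold_test_cost(p, 0.0)


OUTCOME_FUNCTIONS: dict[str, Callable[[ModelParameters], float]] = {
    "threshold_at_wtp": outcome_threshold_at_wtp,
    "break_even": outcome_break_even,
}


def one_way_dsa(p: ModelParameters,
                outcome_fn: Callable[[ModelParameters], float] | str = "threshold_at_wtp",
                ranges: Mapping[str, tuple[float, float]] | None = None,
                ) -> list[TornadoEntry]:
    """Evaluate the outcome at each range end, all else at base case.

    Entries come back sorted by descending spread (tornado order).
    """
    if isinstance(outcome_fn, str):
        try:
            outcome_fn = OUTCOME_FUNCTIONS[outcome_fn]
        except KeyError:
            raise ParameterError(
                f"unknown outcome {outcome_fn!r}; expected one of "
                f"{sorted(OUTCOME_FUNCTIONS)}") from None
    ranges = dict(p.dsa_ranges if ranges is None else ranges)
    entries = []
    for key, (lo, hi) in ranges.items():
        if lo > hi:
            raise ParameterError(f"dsa range for {key} has min > max")
        out_lo = outcome_fn(apply_overrides(p, {key: lo}))
        out_hi = outcome_fn(apply_overrides(p, {key: hi}))
        entries.append(TornadoEntry(key, lo, hi, out_lo, out_hi))
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def tornado_frame(entries: Iterable[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.parameter, "low": e.low, "high": e.high,
        "outcome_low": e.outcome_low, "outcome_high": e.outcome_high,
        "spread": e.spread} for e in entries])


# --------------------------------------------------------------------------
# probabilistic sensitivity analysis


def sample_draw(p: ModelParameters, rng: np.random.Generator) -> dict[str, float]:
    """One joint draw of all uncertain inputs.

    Genotype frequencies are drawn marginally and EM takes the remainder;
    the draw is rejected and repeated if the remainder would be negative
    (impossible with the table bounds, guarded regardless).
    """
    specs = effective_psa_specs(p)
    for _ in range(1000):
        values = {key: float(sample_distribution(spec, rng))
                  for key, spec in specs.items()}
        if "day_eval1" in values:
            # keep the derived second/third evaluations inside the horizon
            # (astronomically unlikely to bind for the gamma(11, 1.06) prior)
            s = p.schedule
            gaps = (s.day_eval2 - s.day_eval1) + (s.day_eval3 - s.day_eval2)
            values["day_eval1"] = float(np.clip(
                values["day_eval1"], 0.5, s.horizon_days - gaps - 1.0))
        freq_sum = sum(values.get(k, get_value(p, k))
                       for k in _GENOTYPE_FREQ_KEYS)
        if freq_sum <= 1.0:
            return values
    raise RuntimeError("genotype-frequency rejection loop failed to terminate")


def run_psa(p: ModelParameters, n_draws: int = 5000,
            seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Monte-Carlo propagation of the input distributions.

    Returns one row per draw with every sampled input plus the model
    outputs needed downstream: per-cohort QALY gain (``delta_qaly``),
    care-cost savings excluding the test (``care_savings``), the total
    incremental cost at the base test price (``delta_cost``) and the
    per-patient equivalents.  Reproducible for a given seed; draw ``i``
    uses an independent child stream of the master seed, so results do not
    depend on execution order.
    """
    if n_draws < 1:
        raise ParameterError("n_draws must be >= 1")
    master = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
    rows = []
    for i, child in enumerate(master.spawn(n_draws)):
        rng = np.random.default_rng(child)
        values = sample_draw(p, rng)
        sampled = apply_overrides(p, values)
        result = economics.run_model(sampled)
        row = dict(values)
        row.update({
            "draw": i,
            "delta_qaly": result.delta_qaly,
            "care_savings": result.care_savings,
            "delta_cost": result.delta_cost,
            "delta_qaly_per_patient": result.delta_qaly / result.cohort_size,
            "delta_cost_per_patient": result.delta_cost / result.cohort_size,
            "cohort_size": result.cohort_size,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def psa_net_monetary_benefit(draws: pd.DataFrame, wtp: float,
                             test_cost: float) -> np.ndarray:
    """Per-draw NMB of genotyping at the given test price."""
    cohort = draws["cohort_size"].to_numpy()
    return (wtp * draws["delta_qaly"].to_numpy()
            + draws["care_savings"].to_numpy() - cohort * test_cost)


def probability_cost_effective(draws: pd.DataFrame, wtp: float,
                               test_cost: float) -> float:
    return float(np.mean(psa_net_monetary_benefit(draws, wtp, test_cost) >= 0.0))


@dataclass(frozen=True)
class CEACPoint:
    test_cost: float
    p_cost_effective: float
    p_cost_saving: float


def ceac_over_test_cost(draws: pd.DataFrame, wtp: float,
                        test_cost_grid: Sequence[float]) -> pd.DataFrame:
    """Acceptability curves over the genotyping test price.

    ``p_cost_effective`` is the share of draws with non-negative net
    monetary benefit at the given willingness-to-pay; ``p_cost_saving``
    uses wtp = 0 (genotyping pays for itself).  Both are non-increasing in
    the price by construction.
    """
    if len(draws) == 0:
        raise ParameterError("no PSA draws supplied")
    grid = list(test_cost_grid)
    if not grid:
        raise ParameterError("empty test-cost grid")
    rows = [CEACPoint(c, probability_cost_effective(draws, wtp, c),
                      probability_cost_effective(draws, 0.0, c))
            for c in grid]
    return pd.DataFrame([{"test_cost": pt.test_cost,
                          "p_cost_effective": pt.p_cost_effective,
                          "p_cost_saving": pt.p_cost_saving} for pt in rows])
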