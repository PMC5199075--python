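"""Patient-level Monte Carlo companion to the expected-value engine.

The microsimulation realizes the same decision tree patient by patient —
genotype, initial dose state and every transition are Bernoulli draws with
the engine's probabilities — and then summarizes the sample with the *same*
economic accounting the cohort engine uses.  Agreement between the two
(within Monte-Carlo error) therefore isolates errors in the expected-value
bookkeeping rather than differences in inputs.

A small generator of synthetic therapeutic-drug-monitoring request records
emulates the retrospective laboratory data from which the persistence
fraction at the second evaluation was estimated (a first request for every
patient, a second for a fraction of them, a third for a fraction of those).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import economics
from .engine import (Arm, initial_state_split, remain_incorrect_fraction,
                     run_cohort, trace_from_pathway_counts)
from .parameters import (GENOTYPES, EvaluationSchedule, ModelParameters,
                         ParameterError)

_PATHWAY_COLUMNS = ["patient_id", "genotype", "arm", "direction", "pathway",
                    "state_initial", "state_eval1", "state_eval2",
                    "discontinue_day", "length_of_stay", "disutility_days",
                    "billed_monitoring", "drug_cost"]


def simulate_patients(n: int, arm: Arm, p: ModelParameters,
                      seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Simulate ``n`` independent patients through one arm of the tree.

    Returns one row per patient.  ``pathway`` matches the engine's pathway
    labels; per-patient economics (length of stay, disutility-days, billed
    monitoring events, drug cost) are taken from the engine's pathway
    accounting so the two routes share one definition of every quantity.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    arm = Arm(arm)
    rng = np.random.default_rng(seed)

    freqs = np.array([p.genotype_mix.frequency(g) for g in GENOTYPES])
    genotype_idx = rng.choice(len(GENOTYPES), size=n, p=freqs / freqs.sum())
    genotypes = np.array(GENOTYPES)[genotype_idx]

    # initial state: 0 = correct, 1 = sub, 2 = supra
    initial = np.zeros(n, dtype=int)
    u = rng.random(n)
    for gi, g in enumerate(GENOTYPES):
        mask = genotype_idx == gi
        split = initial_state_split(g, arm, p)
        initial[mask] = np.select(
            [u[mask] < split["subtherapeutic"],
             u[mask] < split["subtherapeutic"] + split["supratherapeutic"]],
            [1, 2], default=0)

    drop1 = rng.random(n) < p.clinical.p_discontinue_eval1
    remain = np.empty(n, dtype=bool)
    u_remain = rng.random(n)
    for gi, g in enumerate(GENOTYPES):
        mask = genotype_idx == gi
        remain[mask] = u_remain[mask] < remain_incorrect_fraction(g, arm, p)
    drop2 = rng.random(n) < p.clinical.p_discontinue_eval2

    incorrect = initial > 0
    pathway = np.where(
        drop1, np.where(incorrect, "incorrect_drop1", "correct_drop1"),
        np.where(~incorrect, "correct_stay",
                 np.where(remain,
                          np.where(drop2, "persist_drop2", "persist_correct"),
                          np.where(drop2, "recover_drop2", "recover_stay"))))

    # the empty string stands for "no error direction" (initially correct);
    # it keeps join keys non-null and is mapped back to None when aggregating
    df = pd.DataFrame({
        "patient_id": np.arange(n),
        "genotype": genotypes,
        "arm": arm.value,
        "direction": np.where(initial == 1, "sub",
                              np.where(initial == 2, "supra", "")),
        "pathway": pathway,
    })
    return _attach_pathway_economics(df, arm, p)


def _attach_pathway_economics(df: pd.DataFrame, arm: Arm,
                              p: ModelParameters) -> pd.DataFrame:
    """Join per-pathway quantities from the engine template onto patients."""
    template = run_cohort(arm, p)
    fee = (p.costs.tdm_per_measurement
           + p.costs.consult_fraction_per_monitoring * p.costs.consult)
    rows = {}
    for pw in template.pathways:
        los = template.short_los if pw.short_stay else template.long_los
        billed = sum(1 for t in pw.tdm_days if t > los)
        drug = max(0.0, pw.nortriptyline_end - los) * \
            economics.nortriptyline_daily_cost(pw.genotype, arm, p)
        sl_start = pw.secondline_start(p)
        if sl_start is not None:
            drug += max(0.0, p.schedule.horizon_days - max(sl_start, los)) \
                * p.costs.tranylcypromine_40mg
        disutility = {"sub": p.clinical.disutility_sub,
                      "supra": p.clinical.disutility_supra}.get(pw.direction, 0.0)
        dd = pw.incorrect_days * disutility \
            + pw.washout_days(p) * p.clinical.disutility_washout
        rows[(pw.genotype, pw.direction or "", pw.label)] = {
            "state_initial": ("correct" if pw.direction is None
                              else f"{pw.direction}therapeutic"),
            "state_eval1": pw.state_at(p.schedule.day_eval1, p).value,
            "state_eval2": pw.state_at(p.schedule.day_eval2, p).value,
            "discontinue_day": pw.washout_day,
            "length_of_stay": los,
            "disutility_days": dd,
            "billed_monitoring": billed,
            "drug_cost": drug,
        }
    lookup = pd.DataFrame.from_dict(rows, orient="index")
    lookup.index = pd.MultiIndex.from_tuples(lookup.index,
                                             names=["genotype", "direction",
                                                    "pathway"])
    out = df.join(lookup, on=["genotype", "direction", "pathway"])
    if out["length_of_stay"].isna().any():  # pragma: no cover
        raise RuntimeError("patient fell outside the engine's pathway set")
    return out[_PATHWAY_COLUMNS]


def summarize_microsim(records: pd.DataFrame, p: ModelParameters,
                       cohort_scale: float | None = None
                       ) -> economics.ArmResult:
    """Aggregate patient records with the cohort engine's economics.

    Empirical pathway counts (rescaled to the nominal cohort size unless
    ``cohort_scale`` overrides it) are injected into a trace, and QALY loss
    and costs come from the very same functions the cohort path uses.
    """
    if len(records) == 0:
        raise ParameterError("no patient records to summarize")
    arms = records["arm"].unique()
    if len(arms) != 1:
        raise ParameterError(f"records mix arms {sorted(arms)}")
    arm = Arm(arms[0])
    scale = (p.cohort_size / len(records)) if cohort_scale is None else cohort_scale
    counts = records.groupby(["genotype", "direction", "pathway"]).size()
    mapping = {}
    for (g, direction, label), n in counts.items():
        mapping[(g, direction or None, label)] = n * scale
    trace = trace_from_pathway_counts(arm, p, mapping,
                                      cohort_size=len(records) * scale)
    return economics.ArmResult(
        arm=arm, costs=economics.accumulate_costs(trace, p, arm),
        qaly_loss=economics.accumulate_qaly_loss(trace, p), trace=trace)


def microsim_economic_result(n: int, p: ModelParameters,
                             seed: int | np.random.SeedSequence = 0
                             ) -> economics.EconomicResult:
    """Both arms simulated patient-by-patient, compared like the cohort model."""
    master = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
    seeds = master.spawn(2)
    care = summarize_microsim(
        simulate_patients(n, Arm.CARE_AS_USUAL, p, seeds[0]), p)
    geno = summarize_microsim(
        simulate_patients(n, Arm.GENOTYPING, p, seeds[1]), p)
    return economics.compare(care, geno, cohort_size=p.cohort_size,
                             test_cost=p.costs.genotyping_test)


# --------------------------------------------------------------------------
# synthetic TDM request records


def generate_tdm_records(n_patients: int, p_second: float, p_third: float,
                         schedule=None,
                         seed: int | np.random.SeedSequence = 0,
                         jitter_days: float = 0.0) -> pd.DataFrame:
    """Synthetic laboratory request records for nortriptyline TDM.

    Every patient has a first request at the first evaluation day; a
    fraction ``p_second`` a second; of those, ``p_third`` a third.
    ``jitter_days`` optionally spreads request days uniformly by +/- that
    many days to mimic real scheduling noise (off by default so the
    proportion estimators can be tested exactly).
    """
    for name, value in (("p_second", p_second), ("p_third", p_third)):
        if not 0.0 <= value <= 1.0:
            raise ParameterError(f"{name} must be in [0, 1], got {value}")
    if n_patients < 1:
        raise ParameterError("n_patients must be >= 1")
    sched = schedule if schedule is not None else EvaluationSchedule()
    rng = np.random.default_rng(seed)
    second = rng.random(n_patients) < p_second
    third = second & (rng.random(n_patients) < p_third)
    days = [sched.day_eval1, sched.day_eval2, sched.day_eval3]
    pid, idx, day = [], [], []
    counts = 1 + second.astype(int) + third.astype(int)
    for i, c in enumerate(counts):
        for k in range(c):
            pid.append(i)
            idx.append(k + 1)
            day.append(days[k])
    df = pd.DataFrame({"patient_id": pid, "request_index": idx, "day": day})
    if jitter_days > 0:
        df["day"] = df["day"] + rng.uniform(-jitter_days, jitter_days, len(df))
    return df


def estimate_eval_proportions(records: pd.DataFrame
                              ) -> tuple[float, float | None]:
    """Recover (share with a 2nd request, share of those with a 3rd).

    The second element is ``None`` when no patient had a second request.
    """
    if len(records) == 0:
        raise ParameterError("no TDM records supplied")
    per_patient = records.groupby("patient_id")["request_index"].max()
    n = len(per_patient)
    n2 = int((per_patient >= 2).sum())
    n3 = int((per_patient >= 3).sum())
    p_second = n2 / n
    p_third = (n3 / n2) if n2 > 0 else None
    return p_second, p_third
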