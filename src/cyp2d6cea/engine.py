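"""Deterministic expected-value engine for the nortriptyline decision tree.

The tree follows two cohorts of hospitalized depressed patients (60+)
through the 12-week titration phase of nortriptyline.  Patients start
correctly, sub- or supratherapeutically dosed according to their CYP2D6
phenotype (genotype-guided dosing lowers the incorrect fractions for PMs and
UMs); plasma levels are evaluated on days 12, 31 and 38; a fixed share of
patients discontinues after the first and second evaluation, washes out for
14 days and switches to tranylcypromine; everyone still on nortriptyline is
correctly dosed by the end of the horizon.

The engine decomposes each arm into a small set of mutually exclusive
*pathways* (phenotype x error direction x course through the tree) and
carries expected patient counts through them.  All downstream quantities —
state occupancy per time segment, disutility-days, monitoring events,
lengths of stay, drug exposure — are exact functions of that decomposition,
so the patient-level microsimulation can reuse the identical accounting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .parameters import (GENOTYPES, ModelParameters, ParameterError,
                         effect_adjusted_incorrect_fraction)


class Arm(str, enum.Enum):
    """The two strategies being compared."""

    CARE_AS_USUAL = "care_as_usual"
    GENOTYPING = "genotyping"


class DoseState(str, enum.Enum):
    CORRECT = "correct"
    SUBTHERAPEUTIC = "subtherapeutic"
    SUPRATHERAPEUTIC = "supratherapeutic"
    DISCONTINUED_WASHOUT = "discontinued_washout"
    DISCONTINUED_SECONDLINE = "discontinued_secondline"


_DIRECTION_STATE = {"sub": DoseState.SUBTHERAPEUTIC,
                    "supra": DoseState.SUPRATHERAPEUTIC}

#: Pathway labels, in tree order.  ``direction`` below is None for initially
#: correct patients and 'sub'/'supra' otherwise; the direction never flips
#: (an EM dosed too high can only stay too high or become correct).
PATHWAY_LABELS = (
    "correct_stay",      # correct at eval1, completes therapy
    "correct_drop1",     # correct at eval1, discontinues at eval1
    "incorrect_drop1",   # incorrect at eval1, discontinues at eval1
    "recover_stay",      # incorrect at eval1, correct from eval1 onward
    "recover_drop2",     # corrected after eval1 but discontinues at eval2
    "persist_correct",   # incorrect until eval3, then correct (third TDM)
    "persist_drop2",     # incorrect until eval2, discontinues at eval2
)


@dataclass(frozen=True)
class Pathway:
    """One mutually exclusive course through the tree, with expected count."""

    genotype: str
    direction: str | None        # 'sub' | 'supra' | None
    label: str
    count: float
    incorrect_days: float        # days spent sub/supratherapeutic
    washout_day: float | None    # day nortriptyline stops (None: never)
    nortriptyline_end: float     # last day on nortriptyline
    tdm_days: tuple[float, ...]  # evaluation days attended
    short_stay: bool             # correct at eval1 and still on therapy

    def washout_days(self, p: ModelParameters) -> float:
        if self.washout_day is None:
            return 0.0
        return max(0.0, min(p.clinical.washout_days,
                            p.schedule.horizon_days - self.washout_day))

    def secondline_start(self, p: ModelParameters) -> float | None:
        if self.washout_day is None:
            return None
        return self.washout_day + p.clinical.washout_days

    def state_at(self, t: float, p: ModelParameters) -> DoseState:
        """Dose state just after the transitions of day ``t``."""
        if self.washout_day is not None and t >= self.washout_day:
            if t < self.washout_day + p.clinical.washout_days:
                return DoseState.DISCONTINUED_WASHOUT
            return DoseState.DISCONTINUED_SECONDLINE
        if self.direction is not None and t < self.incorrect_days:
            return _DIRECTION_STATE[self.direction]
        return DoseState.CORRECT


@dataclass
class Segment:
    start_day: float
    end_day: float
    occupancy: dict[tuple[str, DoseState], float]

    def total(self) -> float:
        return sum(self.occupancy.values())


@dataclass
class CohortTrace:
    """Result of one deterministic arm run."""

    arm: Arm
    cohort_size: float
    pathways: list[Pathway]
    segments: list[Segment]
    events: dict[str, float]
    short_los: float = 0.0
    long_los: float = 0.0
    #: expected patient count at each length-of-stay value
    discharge_profile: dict[float, float] = field(default_factory=dict)

    def pathway_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "genotype": pw.genotype, "direction": pw.direction,
            "pathway": pw.label, "count": pw.count,
            "incorrect_days": pw.incorrect_days,
            "washout_day": pw.washout_day,
            "nortriptyline_end": pw.nortriptyline_end,
            "n_tdm": len(pw.tdm_days), "short_stay": pw.short_stay,
        } for pw in self.pathways])

    def occupancy_frame(self) -> pd.DataFrame:
        rows = []
        for seg in self.segments:
            for (g, state), count in sorted(seg.occupancy.items()):
                rows.append({"start_day": seg.start_day, "end_day": seg.end_day,
                             "genotype": g, "state": state.value, "count": count})
        return pd.DataFrame(rows)


def initial_state_split(genotype: str, arm: Arm,
                        p: ModelParameters) -> dict[str, float]:
    """Occupancy over {correct, subtherapeutic, supratherapeutic} at therapy start.

    Genotype-guided dosing multiplies the PM supratherapeutic and UM
    subtherapeutic fractions by (1 - effect); IMs and EMs are unaffected
    unless the IM-adaptation scenario is active, in which case the IM
    incorrect fraction shrinks by the IM effect and a false-positive share
    of the remainder lands subtherapeutic instead of supratherapeutic.
    """
    if genotype not in GENOTYPES:
        raise ParameterError(f"unknown genotype {genotype!r}")
    prof = p.dose_profile
    supra, sub = prof.p_supra(genotype), prof.p_sub(genotype)
    if arm is Arm.GENOTYPING:
        effect = p.clinical.effect_genotyping
        if genotype == "PM":
            supra = effect_adjusted_incorrect_fraction(supra, effect)
        elif genotype == "UM":
            sub = effect_adjusted_incorrect_fraction(sub, effect)
        elif genotype == "IM" and p.scenario.im_adaptation:
            incorrect = effect_adjusted_incorrect_fraction(
                supra, p.scenario.im_effect)
            sub = incorrect * p.scenario.im_fp_fraction
            supra = incorrect - sub
    return {"correct": 1.0 - supra - sub, "subtherapeutic": sub,
            "supratherapeutic": supra}


def remain_incorrect_fraction(genotype: str, arm: Arm,
                              p: ModelParameters) -> float:
    """Share of the second-TDM group still incorrectly dosed at eval2."""
    if not p.scenario.genotype_specific_eval2:
        return p.clinical.p_incorrect_eval2
    split = initial_state_split(genotype, arm, p)
    return split["subtherapeutic"] + split["supratherapeutic"]


# --------------------------------------------------------------------------
# tree traversal.  The intermediate state is a mapping from
# (genotype, direction, node) -> expected count, where ``node`` tracks the
# position in the tree; apply_eval1/apply_eval2 advance it.

_Node = tuple[str, str | None, str]
State = dict[_Node, float]


def _initial_state(arm: Arm, p: ModelParameters) -> State:
    state: State = {}
    for g in GENOTYPES:
        f = p.genotype_mix.frequency(g) * p.cohort_size
        split = initial_state_split(g, arm, p)
        state[(g, None, "on_therapy")] = f * split["correct"]
        for direction, key in (("sub", "subtherapeutic"),
                               ("supra", "supratherapeutic")):
            if split[key] > 0.0:
                state[(g, direction, "on_therapy")] = f * split[key]
    return state


def apply_eval1(state: State, p: ModelParameters, arm: Arm) -> State:
    """First evaluation: discontinuation, absorption of correct patients,
    and the split of incorrect survivors into corrected vs still-incorrect.

    A fraction ``p_discontinue_eval1`` of *every* on-therapy patient stops
    (dropout is independent of dose state); correctly dosed survivors never
    see another evaluation; incorrectly dosed survivors form the second-TDM
    group, of which ``remain_incorrect_fraction`` stays in its original
    error direction until eval2 and the rest responds to the dose change.
    """
    d1 = p.clinical.p_discontinue_eval1
    out: State = {}
    for (g, direction, node), count in state.items():
        if node != "on_therapy":
            out[(g, direction, node)] = out.get((g, direction, node), 0.0) + count
            continue
        out[(g, direction, "drop1")] = count * d1
        survivors = count * (1.0 - d1)
        if direction is None:
            out[(g, None, "correct_stay")] = survivors
        else:
            r = remain_incorrect_fraction(g, arm, p)
            out[(g, direction, "recovered")] = survivors * (1.0 - r)
            out[(g, direction, "still_incorrect")] = survivors * r
    return out


def apply_eval2(state: State, p: ModelParameters) -> State:
    """Second evaluation: dropout from the whole second-TDM group; patients
    still incorrect stay so until eval3 (third TDM), then are correct."""
    d2 = p.clinical.p_discontinue_eval2
    out: State = {}
    for (g, direction, node), count in state.items():
        if node == "recovered":
            out[(g, direction, "recover_stay")] = count * (1.0 - d2)
            out[(g, direction, "recover_drop2")] = count * d2
        elif node == "still_incorrect":
            out[(g, direction, "persist_correct")] = count * (1.0 - d2)
            out[(g, direction, "persist_drop2")] = count * d2
        else:
            out[(g, direction, node)] = count
    return out


def _pathways_from_leaves(leaves: State, p: ModelParameters) -> list[Pathway]:
    e1, e2, e3 = (p.schedule.day_eval1, p.schedule.day_eval2,
                  p.schedule.day_eval3)
    horizon = p.schedule.horizon_days
    out: list[Pathway] = []
    for (g, direction, node), count in sorted(
            leaves.items(), key=lambda kv: (kv[0][0], str(kv[0][1]), kv[0][2])):
        if node == "drop1":
            label = "correct_drop1" if direction is None else "incorrect_drop1"
            pw = Pathway(g, direction, label, count,
                         incorrect_days=0.0 if direction is None else e1,
                         washout_day=e1, nortriptyline_end=e1,
                         tdm_days=(e1,), short_stay=False)
        elif node == "correct_stay":
            pw = Pathway(g, None, "correct_stay", count, 0.0, None, horizon,
                         (e1,), short_stay=True)
        elif node == "recover_stay":
            pw = Pathway(g, direction, "recover_stay", count, e1, None,
                         horizon, (e1, e2), short_stay=False)
        elif node == "recover_drop2":
            pw = Pathway(g, direction, "recover_drop2", count, e1, e2, e2,
                         (e1, e2), short_stay=False)
        elif node == "persist_correct":
            pw = Pathway(g, direction, "persist_correct", count, e3, None,
                         horizon, (e1, e2, e3), short_stay=False)
        elif node == "persist_drop2":
            pw = Pathway(g, direction, "persist_drop2", count, e2, e2, e2,
                         (e1, e2), short_stay=False)
        else:  # pragma: no cover - leaves are exhaustive by construction
            raise RuntimeError(f"unexpected tree node {node!r}")
        out.append(pw)
    return out


def _events(leaves: State, p: ModelParameters) -> dict[str, float]:
    ev = {"washout_eval1": 0.0, "washout_eval2": 0.0,
          "second_tdm": 0.0, "third_tdm": 0.0}
    for (g, direction, node), count in leaves.items():
        if node == "drop1":
            ev["washout_eval1"] += count
        elif node in ("recover_drop2", "persist_drop2"):
            ev["washout_eval2"] += count
        if node in ("recover_stay", "recover_drop2",
                    "persist_correct", "persist_drop2"):
            ev["second_tdm"] += count
        if node == "persist_correct":
            ev["third_tdm"] += count
    ev["discontinued"] = ev["washout_eval1"] + ev["washout_eval2"]
    return ev


def solve_suboptimal_los(mean_los: float, short_los: float,
                         p_correct: float) -> float:
    """Length of stay of not-correctly-dosed patients such that the cohort
    mean reproduces the registered average exactly."""
    if not 0.0 < p_correct < 1.0:
        raise ParameterError(
            f"p_correct must lie strictly inside (0, 1), got {p_correct}; "
            "the suboptimal length of stay is undefined at the extremes")
    return (mean_los - p_correct * short_los) / (1.0 - p_correct)


def correct_at_eval1_fraction(p: ModelParameters) -> float:
    """Care-as-usual share of the cohort correctly dosed and on therapy at
    the first evaluation; anchors the long length of stay in both arms."""
    d1 = p.clinical.p_discontinue_eval1
    total = 0.0
    for g in GENOTYPES:
        split = initial_state_split(g, Arm.CARE_AS_USUAL, p)
        total += p.genotype_mix.frequency(g) * split["correct"]
    return total * (1.0 - d1)


def los_pair(p: ModelParameters) -> tuple[float, float]:
    """(short, long) lengths of stay shared by both arms.

    Correctly-dosed-at-eval1 patients are discharged after
    ``mean_los x (1 - reduction)`` days; everyone else (including patients
    who discontinue) stays ``long`` days, solved so that the care-as-usual
    mean equals the registered average.
    """
    m, r = p.hospital.mean_los, p.hospital.los_reduction_frac
    if r == 0.0:
        return m, m
    short = m * (1.0 - r)
    return short, solve_suboptimal_los(m, short, correct_at_eval1_fraction(p))


def assign_length_of_stay(trace: CohortTrace,
                          p: ModelParameters) -> dict[float, float]:
    """Attach the discharge profile (expected count per LOS value) to a trace."""
    short, long = los_pair(p)
    n_short = sum(pw.count for pw in trace.pathways if pw.short_stay)
    n_long = trace.cohort_size - n_short
    trace.short_los, trace.long_los = short, long
    if short == long:
        trace.discharge_profile = {short: trace.cohort_size}
    else:
        trace.discharge_profile = {short: n_short, long: n_long}
    return trace.discharge_profile


def _segments(pathways: Iterable[Pathway], p: ModelParameters) -> list[Segment]:
    s = p.schedule
    bounds = [0.0, s.day_eval1, s.day_eval2, s.day_eval3, s.horizon_days]
    segments = []
    for start, end in zip(bounds[:-1], bounds[1:]):
        occ: dict[tuple[str, DoseState], float] = {}
        for pw in pathways:
            key = (pw.genotype, pw.state_at(start, p))
            occ[key] = occ.get(key, 0.0) + pw.count
        segments.append(Segment(start, end, occ))
    return segments


def run_cohort(arm: Arm, p: ModelParameters) -> CohortTrace:
    """Run the expected-value tree for one arm."""
    from .parameters import validate_parameters
    issues = validate_parameters(p)
    if issues:
        raise ParameterError("; ".join(issues))
    arm = Arm(arm)
    leaves = apply_eval2(apply_eval1(_initial_state(arm, p), p, arm), p)
    pathways = _pathways_from_leaves(leaves, p)
    trace = CohortTrace(arm=arm, cohort_size=p.cohort_size, pathways=pathways,
                        segments=_segments(pathways, p),
                        events=_events(leaves, p))
    assign_length_of_stay(trace, p)
    return trace


def trace_from_pathway_counts(arm: Arm, p: ModelParameters,
                              counts: Mapping[tuple[str, str | None, str], float],
                              cohort_size: float | None = None) -> CohortTrace:
    """Build a trace whose pathway counts are given externally.

    Used by the microsimulation: empirical per-pathway counts replace the
    expected ones, and every downstream economic calculation is then shared
    verbatim with the cohort engine.
    """
    template = run_cohort(arm, p)
    pathways = [replace(pw, count=float(counts.get(
        (pw.genotype, pw.direction, pw.label), 0.0)))
        for pw in template.pathways]
    size = sum(pw.count for pw in pathways) if cohort_size is None else cohort_size
    leaves: State = {}
    node_by_label = {"correct_drop1": "drop1", "incorrect_drop1": "drop1"}
    for pw in pathways:
        node = node_by_label.get(pw.label, pw.label)
        leaves[(pw.genotype, pw.direction, node)] = pw.count
    trace = CohortTrace(arm=Arm(arm), cohort_size=size, pathways=pathways,
                        segments=_segments(pathways, p),
                        events=_events(leaves, p))
    # LOS values are parameter-determined, not count-determined: keep the
    # analytic pair so microsim and cohort price identical stays.
    trace.short_los, trace.long_los = template.short_los, template.long_los
    n_short = sum(pw.count for pw in pathways if pw.short_stay)
    if trace.short_los == trace.long_los:
        trace.discharge_profile = {trace.short_los: size}
    else:
        trace.discharge_profile = {trace.short_los: n_short,
                                   trace.long_los: size - n_short}
    return trace
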