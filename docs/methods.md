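# Methods

## Model structure

The model is a deterministic expected-value decision tree followed over a
fixed 12-week horizon, evaluated once per arm (care as usual vs routine
CYP2D6 genotyping before nortriptyline start). Time is partitioned by the
three plasma-concentration evaluations at days `e1 = 12`, `e2 = 31`,
`e3 = 38` (horizon 84 days). Within each segment occupancy is piecewise
constant; the only exception is the 14-day washout after discontinuation,
which is tracked in exact days on the pathway records rather than at
segment granularity.

Each arm decomposes into at most seven mutually exclusive pathways per
(phenotype × error direction):

| pathway | course |
|---|---|
| `correct_stay` | correctly dosed at e1, completes therapy |
| `correct_drop1` | correctly dosed, discontinues at e1 |
| `incorrect_drop1` | incorrectly dosed, discontinues at e1 |
| `recover_stay` | corrected by the e1 dose adaptation |
| `recover_drop2` | corrected, but discontinues at e2 |
| `persist_correct` | incorrect until e3 (third TDM), then correct |
| `persist_drop2` | incorrect until e2, discontinues at e2 |

Structural rules: PMs and IMs can only be correct or supratherapeutic, UMs
only correct or subtherapeutic, and an error direction never flips after a
dose adaptation. Discontinued patients wash out for 14 days (disutility
0.20/day) and then take tranylcypromine, never re-entering nortriptyline
dosing states.

## Key conventions (where the design was genuinely open)

* **Discontinuation targeting.** The 22% dropout at e1 applies to *all*
  on-therapy patients, independent of dose state; the 8.5% dropout at e2
  applies to the whole re-monitored (second-TDM) group — including members
  already corrected — not to the full cohort. This is the unique simple
  targeting that reproduces the expected discontinuation counts of 248
  (care as usual) and 247 (genotyping) per 1000 patients.
* **Persistence at e2.** Among the second-TDM group, a fraction 43%
  (estimated from third TDM requests in retrospective laboratory data)
  remains incorrectly dosed from e1 until e2 and on to e3; the remainder is
  corrected immediately after the e1 adaptation.
* **Disutility timing.** Incorrect-dose disutility accrues from day 0 until
  the evaluation at which the patient's state changes (e1 for recovered
  patients, e3 for third-TDM patients, the discontinuation day for
  dropouts); washout disutility accrues for exactly 14 days (clipped at the
  horizon); second-line treatment carries no disutility. The ICER is very
  sensitive to this convention because ΔQALY is a small difference of two
  ~4.7-QALY losses: one extra accrual segment for third-TDM patients moves
  the base-case ICER by roughly 10%. The convention above keeps both arms'
  absolute QALY losses at their reported magnitudes.
* **Length of stay.** Patients correctly dosed at e1 (and not discontinued)
  are discharged after `28.6 × (1 − 0.13) = 24.882` days; everyone else,
  including discontinued patients, stays `long = (mean − p·short)/(1 − p)`
  days with `p` the care-as-usual correct-at-e1 share, so the care-as-usual
  mean stay reproduces the registered 28.6 days exactly. The same two LOS
  values price both arms. With a 0% stay reduction both collapse to the
  mean; with `p` ∈ {0, 1} the long stay is undefined and the engine raises.
* **Post-discharge billing.** A monitoring event (TDM 23.11 EUR + ¼ of a
  190.62 EUR psychiatric consult) is billed iff its evaluation day exceeds
  the patient's length of stay; at base-case values only third-TDM
  evaluations (day 38 > 31.6) incur costs. Drugs are likewise billed only
  after discharge: nortriptyline at the cheapest tablet combination
  reaching the (possibly genotype-adapted) daily dose, tranylcypromine
  0.96 EUR/day for second-line days after washout. Drug and monitoring
  costs are three orders of magnitude below hospitalization costs.
* **QALY conversion** uses 365 days/year (configurable).

## Sensitivity analyses

*One-way (tornado):* every tabulated input is set to the ends of its range
with all else at base; outcomes are the threshold test price at the
willingness-to-pay and the break-even price. The stay-reduction fraction
(range 0–26%) dominates.

*Probabilistic:* inputs are drawn independently (no correlations are
reported for these inputs) — betas for proportions, gamma(11, 1.06) for the
first evaluation day (the second keeps its 19-day base gap; the third stays
at day 38 unless overtaken, then follows 7 days after the second),
gamma(61, 0.47) for mean stay, uniforms for PM/IM/UM frequencies with EM as
the simplex remainder (a rejection guard re-draws if the remainder would be
negative, which the tabulated bounds cannot produce), and a Beta-PERT
(shape 4) for the supratherapeutic disutility. Per-draw substreams are
spawned deterministically from one master seed. Default 5000 draws (the
source analysis does not state its draw count); at ~7 ms per draw this runs
in about half a minute.

Four tabulated distribution/base-value pairings are internally
inconsistent and are kept as printed, with the discrepancy documented and
asserted in the tests: the stay-reduction beta(40, 53) has mean 0.43 (the
value belongs to the e2-persistence row) versus base 0.13 — a config switch
(`los_reduction_moment_matched`) substitutes a beta moment-matched at 0.13
for users who judge the printed pairing a typesetting error; the
e2-discontinuation beta(3, 37) has mean 0.075 vs 0.085; the PERT(0, 0.04,
0.13) has mean 0.0483 vs 0.04; the UM-frequency uniform(0.01, 0.02) has
mean 0.015 vs 0.02.

*Scenarios* are parameter transforms applied before any sampling, so they
compose with both sensitivity analyses. Scenario 1 makes e2 persistence
genotype- and arm-specific (equal to each genotype's incorrect-at-e1
fraction). Scenario 2 extends dose guidance to IMs: the 35% effect is
applied to the 56% supratherapeutic IM fraction first, then 38% of the
remaining incorrectly dosed IMs are switched to the subtherapeutic branch
(false-positive genotype calls), in that order, matching the narrative
sequence of the source description; false-positive IMs behave exactly like
other subtherapeutic patients.

## Synthetic data

The patient-level microsimulation realizes the identical tree with
Bernoulli draws using the same parameter objects and the same economic
accounting, so cohort-vs-microsim disagreement isolates bookkeeping errors
rather than input drift; it converges to the cohort results as 1/√n and is
asserted to agree within three Monte-Carlo standard errors at n = 200,000.
The TDM-record generator emulates the retrospective laboratory cascade
(first request for all, second for 38%, third for 43% of those) with
optional ±day jitter; it emulates request *counts and timing only* — no
plasma concentrations, covariates, or genotype linkage — so round-trip
recovery of the two proportions is the only inferential claim the synthetic
records support about real data.

## Numerical choices

Occupancy conservation holds to 1e-9 per segment by construction. The
threshold price is closed-form (`savings/N + λ·ΔQ/N`); a bisection fallback
is cross-checked to 0.01 EUR in the tests. Cheapest-tablet costing solves a
tiny bounded integer search (strengths 10/25/50 mg, "reach at least the
target dose"). Reported tables round to whole EUR and two-decimal QALYs;
all JSON outputs keep full precision. Currency is 2014 EUR throughout; no
discounting (12-week horizon), no indirect costs, no EVPI.

## Known limitations

* The tree carries no within-segment dynamics: dose states change only at
  evaluations, and adverse-event disutility is a constant decrement rather
  than an event process.
* ΔQALY (~0.11 per 1000 patients) is a difference of large, nearly equal
  losses; conclusions expressed as ICERs inherit the timing-convention
  sensitivity noted above, whereas the threshold prices — which add the
  small QALY term to the dominant cost savings — are robust to it.
* The reported inputs contain internal inconsistencies (the
  distribution/base pairings above; a correctly-dosed patient count of
  483 vs 447 that implies fewer correctly dosed patients under genotyping
  and matches no parameter reading; a tornado sentence whose break-even
  exceeds its threshold price). The engine always reports its own
  consistent values and documents the discrepancies rather than resolving
  them silently.
* Genotype frequencies describe European Caucasian populations; the
  35% effect stems from one pharmacokinetic modelling study and is applied
  to PMs and UMs only (IMs in scenario 2; EMs never).
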