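# cyp2d6cea

A decision-analytic cost-effectiveness model of routine **CYP2D6 genotyping**
versus care as usual for older (60+) depressed inpatients starting
**nortriptyline** pharmacotherapy, written for health economists and
pharmacoepidemiologists who want a reusable, tested implementation of the
full analysis: deterministic base case, threshold/break-even search over the
genotyping test price, one-way deterministic sensitivity analysis (tornado),
probabilistic sensitivity analysis with cost-effectiveness acceptability
curves, two scenario analyses, and a patient-level microsimulation that
cross-checks the cohort engine.

## The model

Two virtual cohorts of 1000 hospitalized patients are followed through the
12-week titration phase of nortriptyline (evaluations of plasma
concentration on days 12, 31 and 38). Nortriptyline is metabolized by the
polymorphic CYP2D6 enzyme; depending on phenotype — poor (PM, 8%),
intermediate (IM, 11%), extensive (EM, 79%) or ultra-rapid (UM, 2%)
metabolizer — patients start correctly, sub- or supratherapeutically dosed
(e.g. 76% of PMs too high, 57% of UMs too low). Genotype-guided start doses
(40% of standard for PMs, 160% for UMs) reduce the incorrect fractions by a
multiplicative effect *e* = 35%, derived from pharmacokinetic modelling
(78.5% → 51.1% supratherapeutic PMs: 1 − 51.1/78.5 ≈ 0.35).

At each evaluation, incorrectly dosed patients receive a dose adaptation;
22% of patients discontinue after the first evaluation and 8.5% of the
re-monitored group after the second, entering a 14-day washout before
second-line tranylcypromine. Health effects accumulate as disutility-days
(0.04/day supratherapeutic, 0.20/day subtherapeutic or washout), converted
to QALYs. Costs (2014 EUR, payer perspective, undiscounted) cover
hospitalization (255.62/day; correctly dosed patients are discharged after
28.6 × 0.87 ≈ 24.9 days, the rest after ~31.6 days so the average stay is
28.6), post-discharge therapeutic drug monitoring (23.11 + ¼ psychiatric
consult per interpretation), drugs, and the genotyping test (188.20/test).
The headline statistics are the incremental cost-effectiveness ratio

    ICER = ΔC / ΔQ  (EUR per QALY gained by genotyping)

and the net-monetary-benefit threshold prices: the test price at which
total costs break even, and the price at which the ICER equals the
willingness-to-pay λ = 50,000 EUR/QALY, via
`price* = savings/N + λ·ΔQ/N`.

## Worked example

```bash
python examples/01_base_case.py
```

prints (abbreviated):

```
                        quantity  care_as_usual  genotyping  difference
   Days of inpatient care (mean)          28.60       28.47       -0.13
Patients who stopped therapy (n)         248.00      247.00       -1.00
             Costs of care (EUR)     7350761.00  7315879.00   -34882.00
   Costs CYP2D6 genotyping (EUR)           0.00   188200.00   188200.00
               Total costs (EUR)     7350761.00  7504079.00   153318.00
                       QALY loss           4.74        4.64       -0.10

ICER: 1,452,244 EUR per QALY gained
```

Genotyping prevents some mis-dosing (0.13 fewer hospital days and ~0.11
QALYs of loss avoided per 1000 patients) but the test adds 188,200 EUR, so
it is not cost-effective at current prices. `examples/02_threshold_search.py`
shows it breaks even at ~35 EUR per test and meets the 50,000 EUR/QALY
threshold at ~40 EUR; the other examples cover the tornado analysis, the
PSA/CEAC (probability of cost-effectiveness ≈ 100% at 17 EUR per test, ~1%
at 188.20 EUR), the two scenario analyses, the microsimulation cross-check
and the synthetic TDM-record generator.

A thin CLI mirrors the examples:

```bash
cyp2d6cea base-case --out-dir results
cyp2d6cea psa --seed 1 --n-draws 5000
cyp2d6cea tornado --outcome break_even
```

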