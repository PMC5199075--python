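"""Scenario analyses.

Scenario 1 lets the persistence of incorrect dosing at the second
evaluation differ per genotype (reusing each genotype's first-evaluation
fraction).  Scenario 2 extends dose guidance to intermediate metabolizers,
38% of whom are false-positive genotype calls ending up underdosed.
"""

from cyp2d6cea import (base_case, run_model, scenario_genotype_specific_eval2,
                       scenario_im_dose_adaptation, threshold_test_cost)

base = base_case()
rows = [("base", base),
        ("eval2 by genotype", scenario_genotype_specific_eval2(base)),
        ("IM dosing (38% FP)", scenario_im_dose_adaptation(base, 0.38))]

print(f"{'scenario':<20} {'dQALY':>7} {'ICER':>12} {'thr@50k':>8} {'break-even':>10}")
for name, p in rows:
    res = run_model(p)
    print(f"{name:<20} {res.delta_qaly:7.3f} {res.icer:12,.0f} "
          f"{threshold_test_cost(p, p.wtp):8.2f} "
          f"{threshold_test_cost(p, 0.0):10.2f}")
print()
print("IM dose adaptation saves more inpatient care (higher affordable test "
      "price) but false-positive IMs are underdosed, eroding the QALY gain "
      "and raising the ICER.")
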