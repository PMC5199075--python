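"""Threshold analysis over the genotyping test price.

Finds the test price at which genotyping breaks even (total costs equal)
and the price at which the ICER hits the 50,000 EUR/QALY willingness-to-pay.
"""

from cyp2d6cea import base_case, net_monetary_benefit, run_model, threshold_test_cost

p = base_case()
result = run_model(p, test_cost=0.0)

break_even = threshold_test_cost(p, 0.0)
at_wtp = threshold_test_cost(p, p.wtp)

print(f"Break-even test price:              {break_even:6.2f} EUR")
print(f"Max price at {p.wtp:,.0f} EUR/QALY:   {at_wtp:6.2f} EUR")
print(f"NMB at the threshold price (check): "
      f"{net_monetary_benefit(result, p.wtp, at_wtp):+.6f} EUR")
print()
print("Below the break-even price genotyping is dominant (cheaper and more "
      "effective); between the two prices it is cost-effective at the "
      "willingness-to-pay; above the upper price it is not.")
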