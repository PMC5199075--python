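"""Cross-check: patient-level Monte Carlo vs the expected-value engine.

Simulates 100,000 individual patients per arm through the same tree and
compares the aggregates with the deterministic cohort run.  Agreement
within Monte-Carlo error validates the expected-value bookkeeping.
"""

from cyp2d6cea import base_case, run_model
from cyp2d6cea.microsim import microsim_economic_result

p = base_case()
cohort = run_model(p)
sim = microsim_economic_result(100_000, p, seed=7)

print(f"{'quantity':<32} {'cohort':>12} {'microsim':>12}")
for label, get in [
        ("care-as-usual QALY loss", lambda r: r.care_as_usual.qaly_loss),
        ("genotyping QALY loss", lambda r: r.genotyping.qaly_loss),
        ("care-as-usual total cost", lambda r: r.care_as_usual.costs.total),
        ("genotyping total cost", lambda r: r.genotyping.costs.total),
        ("QALY gain", lambda r: r.delta_qaly)]:
    print(f"{label:<32} {get(cohort):12,.3f} {get(sim):12,.3f}")
print()
print("Both routes use identical parameters and economics; the microsim "
      "only replaces expected fractions by Bernoulli draws, so differences "
      "shrink as 1/sqrt(n).  The QALY gain is a difference of two "
      "independently simulated ~4.7-QALY losses, so its relative "
      "Monte-Carlo error is much larger than the per-arm errors.")
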