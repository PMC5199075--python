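"""Synthetic therapeutic-drug-monitoring request records.

Emulates the retrospective laboratory cascade behind the model's
second-evaluation persistence input: every patient has a first request,
38% a second, and 43% of those a third; the estimator recovers the two
proportions from the records.
"""

from cyp2d6cea import estimate_eval_proportions, generate_tdm_records

records = generate_tdm_records(264, p_second=0.38, p_third=0.43, seed=11)
counts = records.groupby("patient_id")["request_index"].max().value_counts().sort_index()
print("patients by number of TDM requests:")
print(counts.to_string())

p2, p3 = estimate_eval_proportions(records)
print(f"\nestimated p(second request)        = {p2:.3f}  (true 0.380)")
print(f"estimated p(third | second request) = {p3:.3f}  (true 0.430)")
print("\nThe 43% third-request share is the model's probability that a "
      "patient dosed incorrectly at the first evaluation is still "
      "incorrectly dosed at the second.")
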