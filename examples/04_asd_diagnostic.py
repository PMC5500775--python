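"""Average score difference: why style gaps break total-score matching.

For each item of the 20-item benchmark test, draws 100,000 simulees per group
under the large style-gap condition and computes the absolute difference in
mean model-expected item scores between the groups (the ASD).  The items are
DIF-free, so any non-zero ASD is contamination: those are the items a naive
total-score-matched detector tends to flag.
"""

from ersdif import PopulationSpec, benchmark_items, compute_asd

items = benchmark_items(20)
ref = PopulationSpec(n=1, log_omega_mean=0.3, log_omega_var=0.6)
foc = PopulationSpec(n=1, log_omega_mean=-0.3, log_omega_var=0.6)

asd = compute_asd(items, items, ref, foc, n_sim=100_000, seed=5)
print("item  beta   delta    ASD")
for i, (it, v) in enumerate(zip(items, asd), start=1):
    print(f"{i:4d}  {it.beta:5.3f}  {it.delta:6.3f}  {v:.4f}")
print(
    "\nASD is largest for discriminating items located far from the trait\n"
    "mean (large beta, large |delta|) and near zero for items at delta ~ 0:\n"
    "the same pattern as the false-positive rates of the standard detectors."
)
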