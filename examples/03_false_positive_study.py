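"""Small Monte-Carlo study: false-positive rates across style-gap conditions.

Runs 100 replications (scaled down from the full 1,000 for a quick demo) of
the null 10-item design under no / moderate / large group differences in
extreme response style and prints the average false-positive rate of each
detector.  The standard detectors inflate with the gap; the modified ones
stay near the 5% nominal level.
"""

from ersdif import DetectorConfig, StudyCondition, run_study

methods = [DetectorConfig(m) for m in ("olr", "ldfa", "olr_m", "ldfa_m")]

print("condition   olr     ldfa    olr_m   ldfa_m   (average FP, nominal 0.05)")
for cond_name in ("I", "II", "III"):
    condition = StudyCondition(
        n_items=10, ers_condition=cond_name, n_replications=100, seed=2024
    )
    tables = run_study(condition, methods)
    row = "  ".join(f"{tables[m.method].average_fp:6.3f}" for m in methods)
    print(f"  {cond_name:6s} {row}")
print(
    "\nCondition I has no style gap (all rates ~0.05); II and III raise the\n"
    "gap in mean log omega to 0.4 and 0.6, inflating the standard OLR/LDFA\n"
    "while the variance-augmented OLR-m/LDFA-m stay close to nominal."
)
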