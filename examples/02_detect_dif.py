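"""Screen a dataset for uniform DIF with the standard and modified detectors.

Simulates a DIF-free dataset under a large group gap in extreme response
style and screens every item with the standard OLR and the modified OLR-m.
Any flag here is a false positive: the standard detector typically flags
several items, the modified one close to none.
"""

import numpy as np

from ersdif import (
    DetectorConfig,
    Persons,
    PopulationSpec,
    benchmark_items,
    detect_dif_all,
    sample_persons,
    simulate_responses,
)

items = benchmark_items(10)
reference = sample_persons(
    PopulationSpec(n=500, log_omega_mean=0.3, log_omega_var=0.6), seed=11, group=0
)
focal = sample_persons(
    PopulationSpec(n=500, log_omega_mean=-0.3, log_omega_var=0.6), seed=12, group=1
)
data = simulate_responses(Persons.concat(reference, focal), items, seed=13)

print("item   OLR p      flag   OLR-m p    flag")
for r_std, r_mod in zip(
    detect_dif_all(data, DetectorConfig(method="olr")),
    detect_dif_all(data, DetectorConfig(method="olr_m")),
):
    print(
        f"{r_std.item_index + 1:4d}   {r_std.p_value:8.4f}  {str(r_std.flagged):5s}"
        f"  {r_mod.p_value:8.4f}  {r_mod.flagged}"
    )
print(
    "\nEvery item is DIF-free by construction, so each flag is a false\n"
    "positive caused by the response-style gap. Adding the per-person score\n"
    "variance (OLR-m) absorbs the style difference and clears most flags."
)
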