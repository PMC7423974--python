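"""Per-sample node frequencies and Mann-Whitney differential abundance.

The proportion of each node is computed for every sample; nodes are then
compared between groups with a two-sided unpaired Mann-Whitney test at
alpha = 0.05 (no multiplicity correction by default).
"""

import dataclasses

import pandas as pd

import cytoarch as ca
from cytoarch import abundance as ab

# population-level frequencies with a planted 2-fold MAIT reduction
spec = ca.default_cohort_spec(seed=4)
obs, _ = ca.sample_observed_frequencies(spec)
meta = pd.DataFrame(
    {"group": ["SSc"] * spec.n_group1 + ["HC"] * spec.n_group2},
    index=obs.index)
table = ab.FrequencyTable(freq=obs, meta=meta)

res = ab.differential_nodes(table, groups=("SSc", "HC"))
print(res.round(4).to_string())
sig = res[res["significant"]]
print(f"\n{len(sig)} populations differ at p < 0.05: {list(sig.index)}")

rho, p = ab.frequency_marker_correlation(
    obs["MAIT"].iloc[:20], 1 - obs["MAIT"].iloc[:20] * 4)
print(f"\nSpearman demo (frequency vs a derived marker score): "
      f"rho={rho:.2f}, p={p:.3g}")
print("\nThe significant populations should include those with planted "
      "effects (e.g. reduced MAIT and double-negative T cells in the "
      "patient-like group).")
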