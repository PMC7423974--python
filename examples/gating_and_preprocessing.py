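"""Transform, downsample, and gate one sample into canonical subsets.

Raw intensities are arcsinh-transformed (cofactor 5), downsampled to a
common cell count, then assigned to lineage subsets by threshold gates
(T: CD3+, B: CD19+, monocytes: CD14+, NK/ILC: CD3-CD14-CD19-, MAIT:
TCR Va7.2+ CD161+ T cells, ...).
"""

import dataclasses

import cytoarch as ca
from cytoarch import preprocess as pp

spec = dataclasses.replace(
    ca.default_cohort_spec(seed=2, n_group1=1, n_group2=1,
                           cells_per_sample=3000),
    emit_raw=True)
sample = ca.generate_cohort(spec).samples[0]
print(f"raw sample: {sample.n_cells} cells, transformed={sample.transformed}")

sample = pp.transform(sample, cofactor=5.0)
sample = pp.downsample(sample, target=2000, seed=0)
print(f"after preprocessing: {sample.n_cells} cells, "
      f"transformed={sample.transformed}")

result = pp.gate_subsets(sample, pp.default_gate_rules(1.5))
print("\nSubset frequencies (denominator = parent subset):")
print(result.frequencies.round(3).to_string(index=False))

pd1 = pp.marker_positive_fraction(sample, result.labels, "MAIT", "PD1", 1.5)
print(f"\nPD1+ fraction of MAIT cells: {pd1:.2f}")
print("\nEach frequency is relative to its parent gate, e.g. MAIT as a "
      "fraction of T cells; the PD1+ fraction is the kind of value used in "
      "frequency-vs-marker correlation analyses.")
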