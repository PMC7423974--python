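"""Per-group signed correlation networks and architecture statistics.

Nodes are connected when their frequencies correlate with |r| > 0.6 across
a group's samples. Modularity (community structure), Freeman degree
centralization (hub dominance) and the negative-edge fraction summarize
each group's immune architecture.
"""

import pandas as pd

import cytoarch as ca
from cytoarch import network as nw

spec = ca.default_cohort_spec(seed=5, n_group2=20)
obs, _ = ca.sample_observed_frequencies(spec)

net_ssc = nw.build_network(obs.iloc[:20], threshold=0.6, group="SSc")
net_hc = nw.build_network(obs.iloc[20:], threshold=0.6, group="HC")

print(nw.compare_architectures(net_ssc, net_hc).round(3).to_string())

q, comms = nw.modularity(net_ssc)
print(f"\nDetected communities in the patient network (Q={q:.3f}):")
for c in comms:
    print("  ", sorted(c))
print("\nPlanted modules for comparison:")
for c in ca.planted_network_truth(spec, "SSc"):
    print("  ", sorted(c))

print("\nThe patient group's planted covariance modules produce a modular, "
      "positively-correlated network; the unstructured control group "
      "yields few (often no) edges above the threshold.")
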