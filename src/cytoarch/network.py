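"""Signed correlation networks over nodes and their architecture statistics.

For one sample group, every pair of nodes is correlated across samples
(Spearman by default; proportions are compositional, so rank correlation is
the robust choice) and connected by an edge when the absolute correlation
exceeds a threshold (0.6 by default). Edges keep the signed coefficient as
weight. Three statistics summarize each group's architecture:

* **modularity Q** — strength of division into communities, computed by
  greedy modularity maximization (Louvain available) on absolute edge
  weights (edges are grouped by |r| regardless of sign);
* **Freeman degree centralization C** — dominance of the best-connected
  vertex, ``sum(d_max - d_i) / ((n-1)(n-2))`` on unweighted degrees: 1 for
  a star, 0 when all degrees are equal;
* **negative-edge fraction** — percentage of edges with negative
  correlation.

Caveat: node proportions sum to 1 per sample, so compositional closure
induces some spurious negative correlation; no correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ImmunomeNetwork:
    """Signed, weighted, undirected graph over nodes for one group.

    Edge attributes: ``r`` (signed correlation), ``sign`` (+1/-1) and
    ``abs_r``. Vertices are node ids; annotations (lineage, functional
    class) live in vertex attributes.
    """

    graph: nx.Graph
    threshold: float
    group: str
    method: str
    excluded: list = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NetworkProperties:
    """Architecture statistics of one group's network."""

    group: str
    n_vertices: int
    n_edges: int
    modularity: float
    centralization: float
    negative_edge_pct: float
    communities: list[set] | None = None


def build_network(freq: pd.DataFrame, threshold: float = 0.6,
                  method: str = "spearman", group: str = "") -> ImmunomeNetwork:
    """Correlation network over nodes from one group's frequency rows.

    ``freq`` is samples x nodes for a single group (e.g.
    ``FrequencyTable.group(label)``). Node pairs with ``|r| > threshold``
    become edges carrying the signed coefficient. Nodes with zero variance
    across samples cannot be correlated; they are excluded and logged.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    if len(freq) < 4:
        raise ValueError(f"need >= 4 samples to correlate, got {len(freq)}")
    variances = freq.var(axis=0)
    excluded = variances.index[variances == 0].tolist()
    if excluded:
        logger.warning("build_network(%s): excluding zero-variance nodes %s",
                       group, excluded)
    kept = freq.drop(columns=excluded)
    corr = kept.corr(method=method)
    g = nx.Graph()
    g.add_nodes_from(kept.columns)
    cols = list(kept.columns)
    mat = corr.to_numpy()
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = mat[i, j]
            if abs(r) > threshold:
                g.add_edge(cols[i], cols[j], r=float(r),
                           sign=1 if r > 0 else -1, abs_r=float(abs(r)))
    return ImmunomeNetwork(graph=g, threshold=threshold, group=group,
                           method=method, excluded=excluded)


def modularity(net: ImmunomeNetwork, seed: int = 0,
               algorithm: str = "greedy") -> tuple[float, list[set]]:
    """Community partition and Newman modularity Q on absolute weights.

    Communities are found by greedy modularity maximization (default,
    deterministic) or Louvain (seeded); Q is the modularity of that
    partition with |r| as edge weight, so it lies in [-0.5, 1]. An edgeless
    network has no defined Q: returns (nan, None) with a warning.
    """
    if algorithm not in ("greedy", "louvain"):
        raise ValueError(f"algorithm must be 'greedy' or 'louvain', got {algorithm!r}")
    if net.n_edges == 0:
        logger.warning("modularity: network for group %r is edgeless; "
                       "Q undefined", net.group)
        return float("nan"), None
    if algorithm == "greedy":
        comms = nx.community.greedy_modularity_communities(net.graph,
                                                           weight="abs_r")
    else:
        comms = nx.community.louvain_communities(net.graph, weight="abs_r",
                                                 seed=seed)
    comms = [set(c) for c in comms]
    q = nx.community.modularity(net.graph, comms, weight="abs_r")
    return float(q), comms


def modularity_of_partition(net: ImmunomeNetwork, partition: list[set]) -> float:
    """Newman modularity of a given vertex partition, on absolute weights."""
    if net.n_edges == 0:
        raise ValueError("modularity undefined for an edgeless network")
    return float(nx.community.modularity(net.graph, partition, weight="abs_r"))


def centralization(net: ImmunomeNetwork) -> float:
    """Freeman degree centralization on the unweighted edge set.

    ``C = sum_i(d_max - d_i) / ((n-1)(n-2))``: 1 for a star, 0 for any
    degree-regular graph (e.g. complete).
    """
    n = net.n_vertices
    if n < 3:
        raise ValueError(f"centralization needs >= 3 vertices, got {n}")
    degrees = np.array([d for _, d in net.graph.degree()])
    return float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))


def negative_edge_fraction(net: ImmunomeNetwork) -> float:
    """Percentage of edges with a negative underlying correlation."""
    if net.n_edges == 0:
        logger.warning("negative_edge_fraction: edgeless network (group %r); "
                       "0 by convention", net.group)
        return 0.0
    neg = sum(1 for _, _, d in net.graph.edges(data=True) if d["sign"] < 0)
    return 100.0 * neg / net.n_edges


def properties(net: ImmunomeNetwork, seed: int = 0,
               algorithm: str = "greedy") -> NetworkProperties:
    """All architecture statistics for one network."""
    q, comms = modularity(net, seed=seed, algorithm=algorithm)
    c = centralization(net) if net.n_vertices >= 3 else float("nan")
    return NetworkProperties(
        group=net.group, n_vertices=net.n_vertices, n_edges=net.n_edges,
        modularity=q, centralization=c,
        negative_edge_pct=negative_edge_fraction(net), communities=comms)


def compare_architectures(net_a: ImmunomeNetwork, net_b: ImmunomeNetwork,
                          seed: int = 0, algorithm: str = "greedy"
                          ) -> pd.DataFrame:
    """Side-by-side architecture statistics for two group networks.

    Both networks must have been built at the same correlation threshold;
    no inferential test is attached to the comparison.
    """
    if net_a.threshold != net_b.threshold:
        raise ValueError(f"networks built at different thresholds "
                         f"({net_a.threshold} vs {net_b.threshold})")
    rows = []
    for p in (properties(net_a, seed, algorithm),
              properties(net_b, seed, algorithm)):
        rows.append({"group": p.group, "n_vertices": p.n_vertices,
                     "n_edges": p.n_edges, "modularity": p.modularity,
                     "centralization": p.centralization,
                     "negative_edge_pct": p.negative_edge_pct})
    return pd.DataFrame(rows).set_index("group")


def edge_list(net: ImmunomeNetwork) -> pd.DataFrame:
    """Edges as a tidy frame: source, target, r, sign."""
    rows = [{"source": u, "target": v, "r": d["r"], "sign": d["sign"]}
            for u, v, d in net.graph.edges(data=True)]
    return pd.DataFrame(rows, columns=["source", "target", "r", "sign"])


def to_graphml(net: ImmunomeNetwork, path: str | Path) -> None:
    """GraphML export with signed correlations and vertex annotations."""
    g = nx.relabel_nodes(net.graph, {v: str(v) for v in net.graph.nodes})
    g.graph.update(group=net.group, threshold=net.threshold, method=net.method)
    nx.write_graphml(g, str(path))
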