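"""Cytokine-based functional classification of stimulated-condition nodes.

After mitogenic stimulation, each node is flagged positive for a cytokine
when the fraction of its cells above the cytokine's positivity threshold
exceeds a minimum producer fraction (default 20%). The four flags map to
five functional classes:

* ``Pro``   — IFN-gamma or TNF-alpha or both (and nothing else):
  pro-inflammatory;
* ``IL-17`` — IL-17 only;
* ``Anti``  — IL-4 only: anti-inflammatory;
* ``Multi`` — any cross-category combination of the above;
* ``NC``    — no cytokine.

IFN-gamma together with TNF-alpha stays ``Pro`` (both are the
pro-inflammatory category); ``Multi`` requires crossing categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from cytoarch.clustering import NodeAssignment
from cytoarch.network import ImmunomeNetwork

logger = logging.getLogger(__name__)

CYTOKINES = ("IFNg", "TNFa", "IL17", "IL4")
CLASSES = ("Pro", "IL-17", "Anti", "Multi", "NC")


def classify(flags: dict[str, bool]) -> str:
    """Map the four cytokine positivity flags to one functional class.

    Total over all 16 flag combinations; exactly one class per input.
    """
    unknown = set(flags) - set(CYTOKINES)
    if unknown:
        raise KeyError(f"unknown cytokine flags {sorted(unknown)}; "
                       f"expected {CYTOKINES}")
    pro = bool(flags.get("IFNg")) or bool(flags.get("TNFa"))
    il17 = bool(flags.get("IL17"))
    il4 = bool(flags.get("IL4"))
    n_categories = sum([pro, il17, il4])
    if n_categories == 0:
        return "NC"
    if n_categories > 1:
        return "Multi"
    if pro:
        return "Pro"
    return "IL-17" if il17 else "Anti"


def cytokine_positivity(node_cells: pd.DataFrame, thresholds: dict[str, float],
                        min_fraction: float = 0.2) -> dict[str, bool]:
    """Positivity flags for one node's cells across the four cytokines.

    A node is positive for a cytokine when the fraction of its cells above
    ``thresholds[cytokine]`` (transformed scale) exceeds ``min_fraction``.
    """
    flags = {}
    for c in CYTOKINES:
        if c not in node_cells.columns:
            raise KeyError(f"cytokine channel {c!r} missing from node matrix "
                           "(stimulated samples required)")
        frac = float((node_cells[c] > thresholds[c]).mean())
        flags[c] = frac > min_fraction
    return flags


def classify_nodes(assignment: NodeAssignment, pooled: pd.DataFrame,
                   thresholds: dict[str, float],
                   min_fraction: float = 0.2) -> pd.DataFrame:
    """Per-node cytokine flags and functional class over a pooled cohort.

    Returns a frame indexed by node_id with one boolean column per cytokine
    plus ``functional_class``.
    """
    node_col = assignment.assignments["node_id"].to_numpy()
    rows = []
    for node in assignment.node_ids:
        cells = pooled.loc[node_col == node]
        if len(cells) == 0:
            flags = {c: False for c in CYTOKINES}
        else:
            flags = cytokine_positivity(cells, thresholds, min_fraction)
        rows.append({"node_id": node, **flags,
                     "functional_class": classify(flags)})
    return pd.DataFrame(rows).set_index("node_id")


def annotate_network(net: ImmunomeNetwork, labels: pd.DataFrame | pd.Series
                     ) -> ImmunomeNetwork:
    """Attach functional classes as a vertex attribute (copy of the graph).

    ``labels`` is either a Series (node_id -> class) or the frame from
    :func:`classify_nodes`. Every network vertex must be labelled.
    """
    if isinstance(labels, pd.DataFrame):
        labels = labels["functional_class"]
    missing = [v for v in net.graph.nodes if v not in labels.index]
    if missing:
        raise KeyError(f"functional labels missing for vertices {missing}")
    g = net.graph.copy()
    nx.set_node_attributes(
        g, {v: str(labels.loc[v]) for v in g.nodes}, "functional_class")
    return ImmunomeNetwork(graph=g, threshold=net.threshold, group=net.group,
                           method=net.method, excluded=list(net.excluded))


def community_class_composition(net: ImmunomeNetwork,
                                communities: list[set]) -> pd.DataFrame:
    """Functional-class counts per community of an annotated network."""
    attrs = nx.get_node_attributes(net.graph, "functional_class")
    if not attrs:
        raise ValueError("network has no functional_class annotations; "
                         "call annotate_network first")
    rows = []
    for i, comm in enumerate(communities):
        counts = pd.Series([attrs[v] for v in comm]).value_counts()
        for cls in CLASSES:
            rows.append({"community": i, "functional_class": cls,
                         "n_nodes": int(counts.get(cls, 0))})
    return pd.DataFrame(rows)
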