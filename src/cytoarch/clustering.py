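"""Pooled embedding and partitioning of cells into nodes.

Cells from all samples are pooled (equal per-sample counts after
downsampling, so no sample dominates), embedded in 2-D with Barnes-Hut
tSNE over all panel markers, and partitioned by k-means into ``k`` "nodes"
— clusters of cells with similar marker expression. Node phenotypes are
summarized as per-node marker medians, with a min-max-normalized copy for
display.

k-means runs on the 2-D embedding by default, matching workflows that
cluster the dimension-reduced map; ``space="markers"`` clusters in the full
marker space instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

logger = logging.getLogger(__name__)


@dataclass
class NodeAssignment:
    """Per-cell node labels over the pooled cohort.

    ``assignments`` has one row per pooled cell: sample_id, cell_index
    (0-based within-sample), node_id (1..k). ``embedding`` holds the 2-D
    coordinates in the same row order.
    """

    assignments: pd.DataFrame
    k: int
    embedding: np.ndarray | None
    params: dict

    def __post_init__(self) -> None:
        ids = np.unique(self.assignments["node_id"])
        if ids.min() < 1 or ids.max() > self.k:
            raise ValueError(f"node ids must lie in 1..{self.k}")

    @property
    def node_ids(self) -> list[int]:
        return list(range(1, self.k + 1))


@dataclass
class PhenotypeTable:
    """Per-node marker medians plus a display-normalized copy.

    ``normalized`` rescales each marker column to [0, 1] across nodes;
    columns that are constant across nodes map to 0 by convention.
    """

    medians: pd.DataFrame
    normalized: pd.DataFrame


def pool_samples(samples: list) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate samples into one pooled matrix plus a cell index.

    Returns ``(pooled values, index)`` where the index frame carries
    ``sample_id`` and the 0-based ``cell_index`` within each sample.
    Warns when per-sample cell counts are unequal (pooling is meant to run
    after downsampling to a common target).
    """
    counts = {s.sample_id: s.n_cells for s in samples}
    if len(set(counts.values())) > 1:
        logger.warning("pooling unequal sample sizes %s; downsample first so "
                       "no sample dominates the embedding", counts)
    frames, idx_rows = [], []
    for s in samples:
        frames.append(s.data.reset_index(drop=True))
        idx_rows.append(pd.DataFrame({
            "sample_id": s.sample_id,
            "cell_index": np.arange(s.n_cells),
        }))
    pooled = pd.concat(frames, ignore_index=True)
    index = pd.concat(idx_rows, ignore_index=True)
    return pooled, index


def embed(pooled: pd.DataFrame | np.ndarray, perplexity: float = 30.0,
          seed: int = 0) -> np.ndarray:
    """Barnes-Hut tSNE embedding of the pooled cells into 2-D.

    Deterministic given the seed (PCA initialization). Requires at least
    ``3 * perplexity`` cells for a meaningful neighborhood size.
    """
    X = np.asarray(pooled, dtype=float)
    if X.shape[0] < 3 * perplexity:
        raise ValueError(f"too few cells ({X.shape[0]}) for perplexity "
                         f"{perplexity}; need >= {int(3 * perplexity)}")
    tsne = TSNE(n_components=2, perplexity=perplexity, method="barnes_hut",
                init="pca", random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        return tsne.fit_transform(X)


def cluster(X: pd.DataFrame | np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means partition into ``k`` non-empty nodes, labels 1..k.

    Uses k-means++ with 10 restarts, keeping the best inertia; sklearn's
    k-means relocates empty clusters, so all k nodes are populated whenever
    there are >= k distinct points. Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of pooled cells ({n})")
    if k > n / 10:
        logger.warning("k=%d is large relative to %d pooled cells", k, n)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(X) + 1


def assign_nodes(samples: list, k: int = 133, perplexity: float = 30.0,
                 seed: int = 0, space: str = "embedding") -> NodeAssignment:
    """Pool, embed, and partition cells into nodes in one call.

    ``space`` selects whether k-means runs on the tSNE coordinates
    (``"embedding"``, default) or on the full marker matrix
    (``"markers"``); the embedding is computed either way for plotting.
    """
    if space not in ("embedding", "markers"):
        raise ValueError(f"space must be 'embedding' or 'markers', got {space!r}")
    pooled, index = pool_samples(samples)
    coords = embed(pooled, perplexity=perplexity, seed=seed)
    labels = cluster(coords if space == "embedding" else pooled, k, seed=seed)
    assignments = index.assign(node_id=labels)
    params = {"k": k, "perplexity": perplexity, "seed": seed, "space": space}
    return NodeAssignment(assignments=assignments, k=k, embedding=coords,
                          params=params)


def phenotype(assignment: NodeAssignment, pooled: pd.DataFrame) -> PhenotypeTable:
    """Node phenotype table: median marker expression per node.

    The normalized copy rescales each marker column to [0, 1] across nodes
    (min-max); markers constant across nodes map to 0.
    """
    if len(pooled) != len(assignment.assignments):
        raise ValueError("pooled matrix and assignment cover different cells")
    med = pooled.groupby(assignment.assignments["node_id"].to_numpy()).median()
    med = med.reindex(assignment.node_ids)
    med.index.name = "node_id"
    rng_ = med.max() - med.min()
    normalized = (med - med.min()) / rng_.replace(0, np.nan)
    normalized = normalized.fillna(0.0)
    return PhenotypeTable(medians=med, normalized=normalized)
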