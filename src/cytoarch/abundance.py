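"""Node frequency tables, differential abundance, and rank correlations.

The proportion of each node is calculated for every sample (denominator:
the sample's total pooled cells, i.e. the downsampled cell count), giving a
samples x nodes table whose rows sum to 1. Group differences per node are
tested with an unpaired two-sided Mann-Whitney test (exact when both groups
are small and tie-free, tie-corrected normal approximation otherwise) at
alpha = 0.05 with no multiplicity correction by default; a Welch t-test and
Benjamini-Hochberg correction are available behind flags. Frequency-vs-
marker associations use Spearman's rank correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cytoarch.clustering import NodeAssignment

logger = logging.getLogger(__name__)


@dataclass
class FrequencyTable:
    """Samples x nodes proportion matrix plus sample metadata.

    ``freq`` rows are samples, columns node ids; every row sums to 1.
    ``meta`` is indexed by sample_id with at least a ``group`` column.
    """

    freq: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.freq.to_numpy()
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("frequencies must lie in [0, 1]")
        rows = v.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            bad = self.freq.index[~np.isclose(rows, 1.0, atol=1e-9)].tolist()
            raise ValueError(f"frequency rows must sum to 1 +- 1e-9; violated by {bad}")
        if not self.freq.index.equals(self.meta.index):
            missing = set(self.freq.index) ^ set(self.meta.index)
            raise ValueError(f"metadata does not cover samples: {sorted(missing)}")

    def group(self, label: str) -> pd.DataFrame:
        """Rows of the frequency matrix belonging to one group."""
        ids = self.meta.index[self.meta["group"] == label]
        if len(ids) == 0:
            raise KeyError(f"no samples in group {label!r}")
        return self.freq.loc[ids]


def node_frequencies(assignment: NodeAssignment, meta: pd.DataFrame) -> FrequencyTable:
    """Per-sample node proportions from a pooled node assignment.

    Entry (s, v) = cells of sample s assigned to node v / total cells of
    sample s; nodes absent from a sample get 0.
    """
    df = assignment.assignments
    counts = pd.crosstab(df["sample_id"], df["node_id"])
    counts = counts.reindex(columns=assignment.node_ids, fill_value=0)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("every sample must have at least one assigned cell")
    freq = counts.div(totals, axis=0)
    meta = meta.loc[freq.index]
    return FrequencyTable(freq=freq, meta=meta)


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided unpaired Mann-Whitney U: (statistic, p).

    Exact null distribution when both groups have <= 8 observations and the
    pooled values are tie-free; otherwise the tie-corrected normal
    approximation (no continuity correction, so identical group multisets
    give p = 1).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    exact = len(x) <= 8 and len(y) <= 8 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def differential_nodes(table: FrequencyTable, groups: tuple[str, str],
                       alpha: float = 0.05, test: str = "mannwhitney",
                       fdr: bool = False) -> pd.DataFrame:
    """Per-node two-group differential abundance.

    Returns one row per node: group medians, test statistic, two-sided p,
    and a significance flag at ``alpha`` (on BH-adjusted p when ``fdr``).
    Groups with fewer than 2 samples yield undefined p (NaN) with a warning.
    """
    if test not in ("mannwhitney", "welch"):
        raise ValueError(f"test must be 'mannwhitney' or 'welch', got {test!r}")
    a = table.group(groups[0])
    b = table.group(groups[1])
    degenerate = len(a) < 2 or len(b) < 2
    if degenerate:
        logger.warning("differential_nodes: a group has < 2 samples "
                       "(%d vs %d); p undefined", len(a), len(b))
    rows = []
    for node in table.freq.columns:
        x, y = a[node].to_numpy(), b[node].to_numpy()
        if degenerate:
            stat, p = float("nan"), float("nan")
        elif test == "mannwhitney":
            stat, p = mann_whitney(x, y)
        else:
            r = stats.ttest_ind(x, y, equal_var=False)
            stat, p = float(r.statistic), float(r.pvalue)
        rows.append({"node_id": node,
                     f"median_{groups[0]}": float(np.median(x)),
                     f"median_{groups[1]}": float(np.median(y)),
                     "statistic": stat, "p": p})
    out = pd.DataFrame(rows).set_index("node_id")
    if fdr:
        mask = out["p"].notna()
        out["p_adj"] = np.nan
        out.loc[mask, "p_adj"] = stats.false_discovery_control(
            out.loc[mask, "p"], method="bh")
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def frequency_marker_correlation(freq: pd.Series | np.ndarray,
                                 marker_fraction: pd.Series | np.ndarray
                                 ) -> tuple[float, float]:
    """Spearman rank correlation between a subset's frequency and a marker.

    Average ranks on ties, two-sided p. Returns (nan, nan) with a warning
    when either vector is constant (rho undefined).
    """
    x = np.asarray(freq, float)
    y = np.asarray(marker_fraction, float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have the same length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 paired observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("frequency_marker_correlation: constant input, "
                       "rho undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
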