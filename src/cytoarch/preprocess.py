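"""Per-sample preprocessing: arcsinh transform, downsampling, rule gating.

Raw mass-cytometry intensities are variance-stabilized with
``x -> asinh(x / cofactor)`` (cofactor 5 by default, the community
convention for CyTOF). Samples are then downsampled to a common cell count
so that no sample dominates pooled analyses, and cells are assigned to
manually defined subsets by ordered threshold gates (e.g. T cells CD3+;
MAIT cells TCR Va7.2+ CD161+ within T cells; NK/ILC CD3- CD14- CD19-).

Upstream instrument-level steps (bead normalization, debarcoding,
live/doublet gating) are assumed done before data enter this module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)


@dataclass
class SampleMatrix:
    """One sample's cells x markers matrix with identity metadata.

    ``data`` rows are cells (index = stable 0-based cell ids that survive
    downsampling), columns are marker channels. ``transformed`` records
    whether values are on the arcsinh scale.
    """

    sample_id: str
    data: pd.DataFrame
    group: str = ""
    stimulated: bool = False
    transformed: bool = False

    def __post_init__(self) -> None:
        if self.data.shape[0] < 1:
            raise ValueError(f"sample {self.sample_id}: needs at least one cell")
        if self.data.isna().any().any():
            raise ValueError(f"sample {self.sample_id}: missing values in matrix")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"sample {self.sample_id}: duplicate markers {dup}")

    @property
    def markers(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_cells(self) -> int:
        return int(self.data.shape[0])


def transform(sample: SampleMatrix, cofactor: float = 5.0) -> SampleMatrix:
    """arcsinh-transform a raw sample: ``x -> asinh(x / cofactor)``."""
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    if sample.transformed:
        raise ValueError(f"sample {sample.sample_id} is already transformed")
    out = np.arcsinh(sample.data / cofactor)
    return replace(sample, data=out, transformed=True)


def downsample(sample: SampleMatrix, target: int = 5000,
               seed: int | np.random.Generator = 0) -> SampleMatrix:
    """Uniform random subset of exactly ``target`` cells, without replacement.

    Samples at or below the target are returned unchanged (no upsampling).
    The original cell ids (row index) are preserved so truth sidecars keep
    matching. Deterministic given the seed.
    """
    if target < 1:
        raise ValueError(f"target must be >= 1, got {target}")
    if sample.n_cells <= target:
        return sample
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    keep = np.sort(rng.choice(sample.n_cells, size=target, replace=False))
    return replace(sample, data=sample.data.iloc[keep])


@dataclass(frozen=True)
class GateRule:
    """One gating rule: a named subset defined by per-marker sign constraints.

    ``constraints`` is a sequence of ``(marker, sign, threshold)`` with sign
    ``"+"`` (value > threshold) or ``"-"`` (value <= threshold), thresholds
    on the transformed scale. ``parent=None`` gates on all cells; otherwise
    the rule applies only to cells already inside the parent subset, and the
    subset's frequency is reported relative to that parent.
    """

    name: str
    constraints: tuple[tuple[str, str, float], ...]
    parent: str | None = None

    def __post_init__(self) -> None:
        for marker, sign, thr in self.constraints:
            if sign not in ("+", "-"):
                raise ValueError(f"rule {self.name}: sign must be '+' or '-', got {sign!r}")
            if not math.isfinite(thr):
                raise ValueError(f"rule {self.name}: non-finite threshold for {marker}")


@dataclass
class GatingResult:
    """Deepest-match subset label per cell plus per-subset frequencies."""

    labels: pd.Series          # cell id -> deepest subset name ("" = ungated)
    membership: dict[str, pd.Series]  # subset -> boolean mask over cells
    frequencies: pd.DataFrame  # subset, parent, n_cells, n_parent, frequency


def gate_subsets(sample: SampleMatrix, rules: list[GateRule]) -> GatingResult:
    """Assign each cell to the deepest matching subset in an ordered rule list.

    Rules must list parents before children. Frequencies are always reported
    with an explicit denominator: the parent subset's cell count (all cells
    for root rules).
    """
    n = sample.n_cells
    index = sample.data.index
    membership: dict[str, pd.Series] = {}
    labels = pd.Series([""] * n, index=index, dtype=object)
    rows = []
    for rule in rules:
        for marker, _, _ in rule.constraints:
            if marker not in sample.data.columns:
                raise KeyError(
                    f"gate rule {rule.name!r} references marker {marker!r} "
                    f"absent from sample {sample.sample_id}")
        if rule.parent is None:
            base = pd.Series(True, index=index)
        else:
            if rule.parent not in membership:
                raise ValueError(
                    f"gate rule {rule.name!r}: parent {rule.parent!r} not defined "
                    "earlier in the rule list")
            base = membership[rule.parent]
        mask = base.copy()
        for marker, sign, thr in rule.constraints:
            col = sample.data[marker]
            mask &= (col > thr) if sign == "+" else (col <= thr)
        membership[rule.name] = mask
        labels[mask] = rule.name  # later (deeper) rules overwrite within parent
        n_parent = int(base.sum())
        n_sub = int(mask.sum())
        rows.append({
            "subset": rule.name,
            "parent": rule.parent if rule.parent is not None else "all",
            "n_cells": n_sub,
            "n_parent": n_parent,
            "frequency": n_sub / n_parent if n_parent else float("nan"),
        })
    return GatingResult(labels=labels, membership=membership,
                        frequencies=pd.DataFrame(rows))


def marker_positive_fraction(sample: SampleMatrix, labels: pd.Series,
                             subset: str, marker: str,
                             threshold: float) -> float:
    """Fraction of a gated subset's cells above a threshold on one marker.

    Returns NaN (and logs a warning) for an empty subset.
    """
    if marker not in sample.data.columns:
        raise KeyError(f"marker {marker!r} absent from sample {sample.sample_id}")
    mask = labels == subset
    n = int(mask.sum())
    if n == 0:
        logger.warning("marker_positive_fraction: subset %r empty in sample %s",
                       subset, sample.sample_id)
        return float("nan")
    return float((sample.data.loc[mask, marker] > threshold).mean())


def auto_thresholds(samples: list[SampleMatrix], markers: list[str] | None = None,
                    seed: int = 0) -> dict[str, float]:
    """Data-driven positivity thresholds: midpoint of a 2-component fit.

    Pools all cells across samples and fits a two-component Gaussian mixture
    per marker on the transformed scale; the threshold is the midpoint of
    the two component means. A stand-in for unrecoverable manual gates —
    override per marker where a manual threshold is known.
    """
    if not all(s.transformed for s in samples):
        raise ValueError("auto_thresholds expects transformed samples")
    pooled = pd.concat([s.data for s in samples], ignore_index=True)
    markers = markers if markers is not None else list(pooled.columns)
    out: dict[str, float] = {}
    for m in markers:
        x = pooled[m].to_numpy().reshape(-1, 1)
        gm = GaussianMixture(n_components=2, random_state=seed, n_init=2).fit(x)
        lo, hi = sorted(gm.means_.ravel())
        out[m] = float((lo + hi) / 2.0)
        logger.info("auto threshold %s = %.3f (component means %.3f / %.3f)",
                    m, out[m], lo, hi)
    return out


def default_gate_rules(thresholds: dict[str, float] | float = 1.5) -> list[GateRule]:
    """Canonical lineage/subset gating hierarchy on the transformed scale.

    Major lineages from all cells (T: CD3+; B: CD19+; monocytes: CD14+;
    NK/ILC: CD3- CD14- CD19-), then T subsets relative to T cells
    (CD4, CD8, double-negative, MAIT as TCR Va7.2+ CD161+) and B subsets
    relative to B cells by CD27 (naive CD27-, memory CD27+).

    ``thresholds`` is either one global threshold or a per-marker dict
    (e.g. from :func:`auto_thresholds`).
    """
    def t(marker: str) -> float:
        if isinstance(thresholds, dict):
            return thresholds[marker]
        return float(thresholds)

    return [
        GateRule("T", (("CD3", "+", t("CD3")),)),
        GateRule("B", (("CD19", "+", t("CD19")),)),
        GateRule("Monocyte", (("CD14", "+", t("CD14")),)),
        GateRule("NK/ILC", (("CD3", "-", t("CD3")), ("CD14", "-", t("CD14")),
                            ("CD19", "-", t("CD19")))),
        GateRule("T-CD4", (("CD4", "+", t("CD4")), ("CD8", "-", t("CD8"))), parent="T"),
        GateRule("T-CD8", (("CD8", "+", t("CD8")), ("CD4", "-", t("CD4"))), parent="T"),
        GateRule("T-DN", (("CD4", "-", t("CD4")), ("CD8", "-", t("CD8"))), parent="T"),
        GateRule("MAIT", (("TCRVa7.2", "+", t("TCRVa7.2")), ("CD161", "+", t("CD161"))),
                 parent="T"),
        GateRule("B-naive", (("CD27", "-", t("CD27")),), parent="B"),
        GateRule("B-memory", (("CD27", "+", t("CD27")),), parent="B"),
    ]
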