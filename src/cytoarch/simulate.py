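"""Synthetic two-group CyTOF cohorts with known ground truth.

The generator emulates the study design the analysis modules are built for:
~30 samples in two groups (20 patient-like, 10 control-like), a 36-channel
panel, and a mixture of immune cell populations per sample. Ground truth is
returned alongside the data: the population label of every cell, each
sample's true population abundance vector, and the planted frequency-
covariance modules per group.

Model
-----
* Sample-level abundance variation is logistic-normal: a latent Gaussian
  vector centred at ``log(base_abundance * effect)`` with a per-group block
  correlation structure is pushed through a softmax onto the simplex. Blocks
  of populations with high within-block latent correlation produce
  correlated observed frequencies -- the planted "modules" that the network
  stage should recover.
* Cell marker values are Gaussian per population on the arcsinh-transformed
  scale (the scale the pipeline operates on); a raw-scale export is
  available by inverting the transform.
* In stimulated mode, cytokine channels are appended and are bimodal:
  producer cells (a configurable fraction of the cells of populations whose
  cytokine program includes that cytokine) are drawn from a high mode,
  everything else from a zero-centred background mode.

All randomness flows from the single ``seed`` in the spec; two runs with the
same spec are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cytoarch.panel import PanelManifest, default_panel
from cytoarch.preprocess import SampleMatrix

logger = logging.getLogger(__name__)

LINEAGES = ("T-CD4", "T-CD8", "T-DN", "MAIT", "B-naive", "B-memory",
            "plasmablast", "monocyte", "NK-ILC")

# Marker-value modes on the arcsinh scale (cofactor 5): background,
# intermediate, bright. Positive vs. negative populations are separated by
# ~9.5 population SDs, i.e. clearly resolvable as on a real instrument.
NEG, MID, POS = 0.15, 1.8, 3.5
DEFAULT_SD = 0.35
CYTOKINE_HIGH_MEAN, CYTOKINE_HIGH_SD = 3.0, 0.5
CYTOKINE_BG_MEAN, CYTOKINE_BG_SD = 0.0, 0.3


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated cell population: phenotype and cytokine program."""

    name: str
    lineage: str
    marker_means: dict[str, float]
    marker_sds: dict[str, float] = field(default_factory=dict)
    cytokine_program: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise ValueError(f"population {self.name}: unknown lineage "
                             f"{self.lineage!r}; allowed {LINEAGES}")
        for m, sd in self.marker_sds.items():
            if sd <= 0:
                raise ValueError(f"population {self.name}: sd for {m} must be "
                                 f"strictly positive, got {sd}")

    def mean(self, marker: str) -> float:
        return self.marker_means.get(marker, NEG)

    def sd(self, marker: str) -> float:
        return self.marker_sds.get(marker, DEFAULT_SD)


@dataclass(frozen=True)
class BlockCovariance:
    """Planted correlation structure among population frequencies for one group.

    ``blocks`` partitions the population names; latent abundances correlate
    ``r_within`` inside a block and ``r_between`` across blocks, with latent
    standard deviation ``latent_sd`` on the log/softmax scale.
    """

    blocks: tuple[tuple[str, ...], ...]
    r_within: float = 0.8
    r_between: float = 0.0
    latent_sd: float = 0.5

    def __post_init__(self) -> None:
        if not abs(self.r_within) < 1 or not abs(self.r_between) < 1:
            raise ValueError(f"|r_within| and |r_between| must be < 1, got "
                             f"{self.r_within}, {self.r_between}")
        if self.latent_sd <= 0:
            raise ValueError("latent_sd must be positive")
        names = [p for b in self.blocks for p in b]
        if len(names) != len(set(names)):
            raise ValueError("covariance blocks must not overlap")

    def population_order(self) -> list[str]:
        return [p for b in self.blocks for p in b]

    def matrix(self, populations: list[str]) -> np.ndarray:
        """Covariance matrix over ``populations`` (must equal the block union)."""
        if set(populations) != set(self.population_order()):
            missing = set(populations) ^ set(self.population_order())
            raise ValueError(f"covariance blocks must cover the populations "
                             f"exactly once; mismatch on {sorted(missing)}")
        block_of = {p: i for i, b in enumerate(self.blocks) for p in b}
        n = len(populations)
        corr = np.full((n, n), self.r_between)
        for i, pi in enumerate(populations):
            for j, pj in enumerate(populations):
                if block_of[pi] == block_of[pj]:
                    corr[i, j] = self.r_within
        np.fill_diagonal(corr, 1.0)
        cov = corr * self.latent_sd ** 2
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-10:
            raise ValueError(
                f"covariance from blocks (r_within={self.r_within}, "
                f"r_between={self.r_between}, {len(self.blocks)} blocks) is "
                f"not positive semi-definite (min eigenvalue {eig.min():.3g})")
        return cov

    def partition(self) -> list[set[str]]:
        return [set(b) for b in self.blocks]


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort.

    ``effect_map`` multiplies the base abundance of listed populations in
    group 1 (the patient-like group) before renormalization through the
    softmax; group 2 uses the base abundances. ``covariance_blocks`` gives
    each group its own planted module structure.
    """

    populations: tuple[PopulationSpec, ...]
    base_abundance: dict[str, float]
    covariance_blocks: dict[str, BlockCovariance]
    effect_map: dict[str, float] = field(default_factory=dict)
    n_group1: int = 20
    n_group2: int = 10
    cells_per_sample: int = 5000
    group1_label: str = "SSc"
    group2_label: str = "HC"
    stimulated: bool = False
    producer_fraction: float = 0.7
    panel: PanelManifest = field(default_factory=default_panel)
    emit_raw: bool = False
    cofactor: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if len(names) != len(set(names)):
            raise ValueError("population names must be unique")
        if set(self.base_abundance) != set(names):
            raise ValueError("base_abundance keys must match population names")
        total = sum(self.base_abundance.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"base_abundance must sum to 1 +- 1e-9, got {total!r}")
        if set(self.covariance_blocks) != {self.group1_label, self.group2_label}:
            raise ValueError("covariance_blocks must have one entry per group "
                             f"({self.group1_label!r}, {self.group2_label!r})")
        for g, bc in self.covariance_blocks.items():
            if set(bc.population_order()) != set(names):
                raise ValueError(f"covariance blocks for group {g!r} must "
                                 "cover all populations exactly once")
        for p in self.effect_map:
            if p not in set(names):
                raise ValueError(f"effect_map names unknown population {p!r}")
        if self.n_group1 < 1 or self.n_group2 < 1 or self.cells_per_sample < 1:
            raise ValueError("sample and cell counts must be >= 1")
        if not 0 < self.producer_fraction <= 1:
            raise ValueError("producer_fraction must be in (0, 1]")
        for p in self.populations:
            unknown = set(p.marker_means) - set(self.panel.markers)
            if unknown:
                raise ValueError(f"population {p.name}: markers {sorted(unknown)} "
                                 "not in panel")

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    @property
    def channels(self) -> list[str]:
        """Measured channels: cytokines appear only in stimulated mode."""
        non_cyto = [m for m in self.panel.markers
                    if self.panel.roles[m] != "cytokine"]
        return non_cyto + (self.panel.cytokines if self.stimulated else [])

    def sample_groups(self) -> list[tuple[str, str]]:
        ids = [(f"{self.group1_label}{i + 1:02d}", self.group1_label)
               for i in range(self.n_group1)]
        ids += [(f"{self.group2_label}{i + 1:02d}", self.group2_label)
                for i in range(self.n_group2)]
        return ids


@dataclass
class SyntheticCohort:
    """Generated samples plus full ground truth."""

    spec: CohortSpec
    samples: list[SampleMatrix]
    truth: dict[str, pd.Series]            # sample_id -> per-cell population
    true_abundances: pd.DataFrame          # samples x populations, rows sum to 1
    metadata: pd.DataFrame                 # sample_id, group, stimulated


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def sample_true_abundances(spec: CohortSpec,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-sample true population abundance vectors (logistic-normal draw).

    Each row is the softmax of a latent Gaussian centred at
    ``log(base * effect)`` with the group's block covariance, so rows sum
    to 1 exactly (up to float rounding).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    pops = spec.population_names
    base = np.array([spec.base_abundance[p] for p in pops])
    effect = np.array([spec.effect_map.get(p, 1.0) for p in pops])
    rows, index = [], []
    for sample_id, group in spec.sample_groups():
        mult = effect if group == spec.group1_label else np.ones_like(effect)
        mu = np.log(base * mult)
        cov = spec.covariance_blocks[group].matrix(pops)
        z = rng.multivariate_normal(mu, cov, method="cholesky")
        rows.append(_softmax(z))
        index.append(sample_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="sample_id"), columns=pops)


def sample_observed_frequencies(spec: CohortSpec,
                                rng: np.random.Generator | None = None
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed per-sample population frequencies after multinomial counting.

    Fast path for calibration studies: draws the true abundances, then
    multinomial cell counts at ``cells_per_sample``, skipping marker-level
    synthesis. Returns ``(observed frequencies, true abundances)``.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    truth = sample_true_abundances(spec, rng)
    counts = np.vstack([
        rng.multinomial(spec.cells_per_sample, row)
        for row in truth.to_numpy()
    ])
    obs = pd.DataFrame(counts / spec.cells_per_sample, index=truth.index,
                       columns=truth.columns)
    return obs, truth


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the full cohort: per-cell marker matrices plus ground truth.

    Deterministic given ``spec.seed``. In stimulated mode cytokine channels
    are appended, bimodal per the populations' cytokine programs. With
    ``emit_raw`` the arcsinh-scale draws are inverted
    (``x -> sinh(x) * cofactor``) so the matrices enter the pipeline on the
    raw intensity scale.
    """
    rng = np.random.default_rng(spec.seed)
    pops = {p.name: p for p in spec.populations}
    names = spec.population_names
    channels = spec.channels
    cytos = spec.panel.cytokines if spec.stimulated else []
    abundances = sample_true_abundances(spec, rng)

    samples: list[SampleMatrix] = []
    truth: dict[str, pd.Series] = {}
    meta_rows = []
    for sample_id, group in spec.sample_groups():
        p = abundances.loc[sample_id].to_numpy()
        labels = rng.choice(names, size=spec.cells_per_sample, p=p)
        values = np.empty((spec.cells_per_sample, len(channels)))
        for pop_name in names:
            mask = labels == pop_name
            n = int(mask.sum())
            if n == 0:
                continue
            pop = pops[pop_name]
            for j, marker in enumerate(channels):
                if marker in cytos:
                    producer = (marker in pop.cytokine_program) and spec.stimulated
                    if producer:
                        is_hi = rng.random(n) < spec.producer_fraction
                        v = np.where(
                            is_hi,
                            rng.normal(CYTOKINE_HIGH_MEAN, CYTOKINE_HIGH_SD, n),
                            rng.normal(CYTOKINE_BG_MEAN, CYTOKINE_BG_SD, n))
                    else:
                        v = rng.normal(CYTOKINE_BG_MEAN, CYTOKINE_BG_SD, n)
                else:
                    v = rng.normal(pop.mean(marker), pop.sd(marker), n)
                values[mask, j] = v
        df = pd.DataFrame(values, columns=channels)
        transformed = True
        if spec.emit_raw:
            df = np.sinh(df.clip(lower=0.0)) * spec.cofactor
            transformed = False
        samples.append(SampleMatrix(sample_id=sample_id, data=df, group=group,
                                    stimulated=spec.stimulated,
                                    transformed=transformed))
        truth[sample_id] = pd.Series(labels, name="population")
        meta_rows.append({"sample_id": sample_id, "group": group,
                          "stimulated": spec.stimulated})
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    return SyntheticCohort(spec=spec, samples=samples, truth=truth,
                           true_abundances=abundances, metadata=metadata)


def planted_network_truth(spec: CohortSpec, group: str) -> list[set[str]]:
    """The planted module partition of populations for one group."""
    if group not in spec.covariance_blocks:
        raise KeyError(f"unknown group {group!r}; cohort groups are "
                       f"{sorted(spec.covariance_blocks)}")
    return spec.covariance_blocks[group].partition()


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write per-sample matrices, truth sidecars and metadata as CSV.

    One ``<sample_id>.csv`` per sample (header = marker names), one
    ``<sample_id>.truth.csv`` (0-based ``cell_index`` -> population), and a
    cohort-level ``metadata.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in cohort.samples:
        s.data.to_csv(outdir / f"{s.sample_id}.csv", index=False)
        t = cohort.truth[s.sample_id]
        t.rename_axis("cell_index").to_frame().to_csv(
            outdir / f"{s.sample_id}.truth.csv")
    cohort.metadata.to_csv(outdir / "metadata.csv")


# ---------------------------------------------------------------------------
# Default study-like cohort
# ---------------------------------------------------------------------------

def default_populations() -> tuple[PopulationSpec, ...]:
    """Twelve immune populations over nine lineages, 36-channel phenotypes.

    Phenotypes follow standard surface definitions (e.g. MAIT as
    TCR Va7.2+ CD161+ T cells; B memory CD19+ CD27+; NK CD56+ CD16+
    CD3-) with unlisted markers at background.
    """
    def pop(name, lineage, means, program=()):
        base = {"CD45": POS}
        base.update(means)
        return PopulationSpec(name=name, lineage=lineage, marker_means=base,
                              cytokine_program=frozenset(program))

    return (
        pop("CD4-naive", "T-CD4",
            {"CD3": POS, "CD4": POS, "CD45RA": POS, "CCR7": POS, "CD27": POS,
             "CD28": POS, "CD127": POS}),
        pop("CD4-memory", "T-CD4",
            {"CD3": POS, "CD4": POS, "CD45RO": POS, "CCR4": POS, "ICOS": MID,
             "CD27": POS, "CD28": POS, "PD1": MID}, ("IFNg", "TNFa")),
        pop("CD4-Th17", "T-CD4",
            {"CD3": POS, "CD4": POS, "CD45RO": POS, "CCR6": POS, "CD161": MID,
             "CD28": POS}, ("IL17",)),
        pop("CD8-naive", "T-CD8",
            {"CD3": POS, "CD8": POS, "CD45RA": POS, "CCR7": POS, "CD27": POS,
             "CD28": POS}),
        pop("CD8-effector", "T-CD8",
            {"CD3": POS, "CD8": POS, "CD45RA": MID, "CD57": POS, "KLRG1": POS,
             "TIGIT": MID}, ("IFNg", "TNFa")),
        pop("T-DN", "T-DN",
            {"CD3": POS, "CD45RA": MID, "PD1": MID}, ("IL4",)),
        pop("MAIT", "MAIT",
            {"CD3": POS, "TCRVa7.2": POS, "CD161": POS, "CD45RO": POS,
             "CD127": POS, "PD1": MID}, ("IFNg", "TNFa", "IL17")),
        pop("B-naive", "B-naive",
            {"CD19": POS, "CD20": POS, "IgD": POS, "CD24": MID, "HLA-DR": POS}),
        pop("B-memory", "B-memory",
            {"CD19": POS, "CD20": POS, "CD27": POS, "HLA-DR": POS}),
        pop("Plasmablast", "plasmablast",
            {"CD19": POS, "CD27": POS, "CD38": POS, "HLA-DR": MID}),
        pop("Monocyte", "monocyte",
            {"CD14": POS, "HLA-DR": POS, "CD11c": POS, "CD16": MID},
            ("TNFa",)),
        pop("NK", "NK-ILC",
            {"CD56": POS, "CD16": POS, "CD57": MID}, ("IFNg",)),
    )


DEFAULT_BASE_ABUNDANCE = {
    "CD4-naive": 0.16, "CD4-memory": 0.14, "CD4-Th17": 0.04,
    "CD8-naive": 0.08, "CD8-effector": 0.08, "T-DN": 0.03, "MAIT": 0.04,
    "B-naive": 0.07, "B-memory": 0.05, "Plasmablast": 0.01,
    "Monocyte": 0.17, "NK": 0.13,
}

# Patient-like abundance shifts in a minority of populations: reduced MAIT
# and double-negative T cells, fewer memory / more naive B cells.
DEFAULT_EFFECT_MAP = {
    "MAIT": 0.40, "T-DN": 0.50, "B-memory": 0.55, "B-naive": 1.60,
    "CD4-memory": 1.30,
}

# Patient-group planted modules: five cell-type blocks (CD4 T, CD8 T,
# unconventional T, B, innate). Finer blocks are deliberate: frequencies
# live on the simplex, so planting strong positive within-block correlation
# forces negative between-block-mass correlation of roughly -1/(B-1); with
# B=5 that closure stays well below the 0.6 edge threshold, with B=3 it
# would merge the planted modules through negative edges.
_CD4_BLOCK = ("CD4-naive", "CD4-memory", "CD4-Th17")
_CD8_BLOCK = ("CD8-naive", "CD8-effector")
_UNCONV_BLOCK = ("T-DN", "MAIT")
_B_BLOCK = ("B-naive", "B-memory", "Plasmablast")
_INNATE_BLOCK = ("Monocyte", "NK")


def default_cohort_spec(seed: int = 0, stimulated: bool = False,
                        n_group1: int = 20, n_group2: int = 10,
                        cells_per_sample: int = 5000,
                        emit_raw: bool = False) -> CohortSpec:
    """Study-like cohort: 20 patient-like vs 10 control-like samples.

    The patient group carries five planted frequency-covariance modules
    (CD4 T / CD8 T / unconventional T / B / innate, r_within 0.8,
    r_between 0) producing a modular, positively-correlated network; the
    control group has one weakly correlated block (r 0.3) — a global latent
    mode cancels in the softmax, so control frequencies are effectively
    unstructured and any control edges are noise plus compositional
    closure, including negative ones.
    """
    populations = default_populations()
    blocks = {
        "SSc": BlockCovariance(blocks=(_CD4_BLOCK, _CD8_BLOCK, _UNCONV_BLOCK,
                                       _B_BLOCK, _INNATE_BLOCK),
                               r_within=0.8, r_between=0.0),
        "HC": BlockCovariance(blocks=(tuple(DEFAULT_BASE_ABUNDANCE),),
                              r_within=0.3, r_between=0.0),
    }
    return CohortSpec(
        populations=populations,
        base_abundance=dict(DEFAULT_BASE_ABUNDANCE),
        covariance_blocks=blocks,
        effect_map=dict(DEFAULT_EFFECT_MAP),
        n_group1=n_group1, n_group2=n_group2,
        cells_per_sample=cells_per_sample,
        stimulated=stimulated, emit_raw=emit_raw, seed=seed,
    )
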