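"""Shared fixtures: small synthetic cohorts with known ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cytoarch import simulate as sim
from cytoarch.panel import default_panel


def two_population_spec(seed: int = 0, n_group1: int = 2, n_group2: int = 2,
                        cells: int = 300) -> sim.CohortSpec:
    """Two well-separated populations (marker-mean gap ~9.5 SDs), no effects."""
    a = sim.PopulationSpec("A", "T-CD4", {"CD3": 3.5, "CD4": 3.5})
    b = sim.PopulationSpec("B", "B-naive", {"CD19": 3.5, "CD20": 3.5})
    blocks = {
        "SSc": sim.BlockCovariance(blocks=(("A", "B"),), r_within=0.0),
        "HC": sim.BlockCovariance(blocks=(("A", "B"),), r_within=0.0),
    }
    return sim.CohortSpec(populations=(a, b),
                          base_abundance={"A": 0.5, "B": 0.5},
                          covariance_blocks=blocks,
                          n_group1=n_group1, n_group2=n_group2,
                          cells_per_sample=cells, seed=seed)


def null_cohort_spec(seed: int) -> sim.CohortSpec:
    """Study-sized cohort with no group differences at all.

    Identity effect map and identical covariance in both groups: the only
    valid null for type-I calibration, since differing per-group covariance
    shifts softmax means slightly even with identical base abundances.
    """
    base = sim.default_cohort_spec(seed=seed)
    hc = base.covariance_blocks["HC"]
    import dataclasses
    return dataclasses.replace(base, effect_map={},
                               covariance_blocks={"SSc": hc, "HC": hc})


@pytest.fixture(scope="session")
def two_pop_cohort():
    return sim.generate_cohort(two_population_spec(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled-down study-like cohort (6 + 4 samples, 250 cells each)."""
    spec = sim.default_cohort_spec(seed=7, n_group1=6, n_group2=4,
                                   cells_per_sample=250)
    return sim.generate_cohort(spec)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def pooled_with_truth(cohort) -> tuple[pd.DataFrame, pd.Series]:
    """Pooled cell matrix and matching per-cell truth labels."""
    pooled = pd.concat([s.data for s in cohort.samples], ignore_index=True)
    truth = pd.concat([cohort.truth[s.sample_id] for s in cohort.samples],
                      ignore_index=True)
    return pooled, truth


def iter_set_partitions(items: list):
    """All set partitions of ``items`` (Bell(n) of them; keep n small)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in iter_set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1:]
        yield part + [{first}]
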