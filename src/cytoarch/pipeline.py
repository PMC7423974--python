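"""End-to-end pipeline: simulate/load -> preprocess -> cluster -> analyse.

``run_pipeline`` executes the full analysis on either a synthetic cohort
spec or a directory of per-sample CSV matrices, writing every stage's
artifacts plus a run manifest (config echo, seeds, SHA-256 checksums of
every artifact) so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cytoarch import abundance as ab
from cytoarch import clustering as cl
from cytoarch import functional as fn
from cytoarch import network as nw
from cytoarch import preprocess as pp
from cytoarch import simulate as sim

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline constants, with the workflow's defaults materialized."""

    outdir: str = "cytoarch_run"
    input_dir: str | None = None      # per-sample CSVs + metadata.csv; None = synthetic
    synthetic_seed: int = 0
    synthetic_stimulated: bool = False
    synthetic_cells_per_sample: int = 5000
    synthetic_n_group1: int = 20
    synthetic_n_group2: int = 10
    cofactor: float = 5.0
    downsample_target: int = 5000
    perplexity: float = 30.0
    tsne_seed: int = 0
    k: int = 133
    cluster_space: str = "embedding"
    corr_method: str = "spearman"
    corr_threshold: float = 0.6
    test: str = "mannwhitney"
    alpha: float = 0.05
    fdr: bool = False
    community_algorithm: str = "greedy"
    community_seed: int = 0
    min_producer_fraction: float = 0.2
    cytokine_threshold: float = 1.5
    groups: tuple[str, str] = ("SSc", "HC")


@dataclass
class PipelineResult:
    """In-memory handles to every stage's output."""

    assignment: cl.NodeAssignment
    phenotype: cl.PhenotypeTable
    frequencies: ab.FrequencyTable
    differential: pd.DataFrame
    networks: dict[str, nw.ImmunomeNetwork]
    architecture: pd.DataFrame
    functional_labels: pd.DataFrame | None
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_samples(input_dir: Path) -> list[pp.SampleMatrix]:
    meta = pd.read_csv(input_dir / "metadata.csv").set_index("sample_id")
    samples = []
    for sample_id, row in meta.iterrows():
        data = pd.read_csv(input_dir / f"{sample_id}.csv")
        samples.append(pp.SampleMatrix(
            sample_id=str(sample_id), data=data, group=str(row["group"]),
            stimulated=bool(row.get("stimulated", False)),
            transformed=bool(row.get("transformed", False))))
    return samples


def run_pipeline(config: RunConfig,
                 samples: list[pp.SampleMatrix] | None = None) -> PipelineResult:
    """Run every stage and write the artifact bundle to ``config.outdir``.

    Inputs come from (in precedence order) the ``samples`` argument, the
    ``input_dir`` CSVs, or the built-in synthetic cohort generator.
    Identical config and seeds reproduce identical numeric outputs.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def write_csv(name: str, df: pd.DataFrame, **kw) -> None:
        path = out / name
        df.to_csv(path, **kw)
        artifacts[name] = path

    # --- input -------------------------------------------------------------
    stage = "input"
    try:
        if samples is None and config.input_dir is not None:
            samples = _load_samples(Path(config.input_dir))
            provenance = f"csv:{config.input_dir}"
        elif samples is None:
            spec = sim.default_cohort_spec(
                seed=config.synthetic_seed,
                stimulated=config.synthetic_stimulated,
                n_group1=config.synthetic_n_group1,
                n_group2=config.synthetic_n_group2,
                cells_per_sample=config.synthetic_cells_per_sample)
            samples = sim.generate_cohort(spec).samples
            provenance = f"synthetic:seed={config.synthetic_seed}"
        else:
            provenance = "in-memory samples"

        # --- preprocess ------------------------------------------------------
        stage = "preprocess"
        processed = []
        for i, s in enumerate(samples):
            if not s.transformed:
                s = pp.transform(s, cofactor=config.cofactor)
            s = pp.downsample(s, target=config.downsample_target,
                              seed=config.synthetic_seed * 100003 + i)
            processed.append(s)
        meta = pd.DataFrame({
            "sample_id": [s.sample_id for s in processed],
            "group": [s.group for s in processed],
            "stimulated": [s.stimulated for s in processed],
        }).set_index("sample_id")

        # --- clustering ------------------------------------------------------
        stage = "clustering"
        assignment = cl.assign_nodes(
            processed, k=config.k, perplexity=config.perplexity,
            seed=config.tsne_seed, space=config.cluster_space)
        pooled, _ = cl.pool_samples(processed)
        pheno = cl.phenotype(assignment, pooled)
        write_csv("assignment.csv", assignment.assignments, index=False)
        write_csv("embedding.csv", pd.DataFrame(
            assignment.embedding, columns=["tsne1", "tsne2"]), index=False)
        write_csv("phenotype.csv", pheno.medians)

        # --- abundance -------------------------------------------------------
        stage = "abundance"
        freq = ab.node_frequencies(assignment, meta)
        diff = ab.differential_nodes(freq, groups=config.groups,
                                     alpha=config.alpha, test=config.test,
                                     fdr=config.fdr)
        write_csv("frequencies.csv", freq.freq)
        write_csv("differential.csv", diff)

        # --- network ---------------------------------------------------------
        stage = "network"
        networks: dict[str, nw.ImmunomeNetwork] = {}
        for g in config.groups:
            net = nw.build_network(freq.group(g), threshold=config.corr_threshold,
                                   method=config.corr_method, group=g)
            networks[g] = net
            nw.to_graphml(net, out / f"network_{g}.graphml")
            artifacts[f"network_{g}.graphml"] = out / f"network_{g}.graphml"
            write_csv(f"edges_{g}.csv", nw.edge_list(net), index=False)
        arch = nw.compare_architectures(networks[config.groups[0]],
                                        networks[config.groups[1]],
                                        seed=config.community_seed,
                                        algorithm=config.community_algorithm)
        path = out / "architecture.json"
        path.write_text(json.dumps(json.loads(arch.to_json(orient="index")),
                                   indent=2))
        artifacts["architecture.json"] = path

        # --- functional (stimulated samples only) ----------------------------
        stage = "functional"
        labels = None
        if all(s.stimulated for s in processed):
            thresholds = {c: config.cytokine_threshold for c in fn.CYTOKINES}
            labels = fn.classify_nodes(assignment, pooled, thresholds,
                                       min_fraction=config.min_producer_fraction)
            write_csv("functional_labels.csv", labels)
            for g, net in networks.items():
                annotated = fn.annotate_network(net, labels)
                nw.to_graphml(annotated, out / f"network_{g}.graphml")
                networks[g] = annotated
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed "
                           f"(input: {config.input_dir or 'synthetic'})") from err

    # --- manifest ------------------------------------------------------------
    manifest = {
        "config": asdict(config),
        "provenance": provenance,
        "artifacts": {name: _sha256(p) for name, p in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return PipelineResult(assignment=assignment, phenotype=pheno,
                          frequencies=freq, differential=diff,
                          networks=networks, architecture=arch,
                          functional_labels=labels, manifest=manifest)
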