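"""Run the complete pipeline on a small synthetic cohort.

simulate -> transform/downsample -> tSNE + k-means nodes -> frequency
table -> Mann-Whitney differential nodes -> per-group networks with
architecture statistics, all written to an artifact directory with a
reproducibility manifest.
"""

from cytoarch.pipeline import RunConfig, run_pipeline

config = RunConfig(outdir="pipeline_demo", synthetic_seed=1,
                   synthetic_n_group1=6, synthetic_n_group2=4,
                   synthetic_cells_per_sample=150, downsample_target=150,
                   k=10, perplexity=12.0)
result = run_pipeline(config)

print("Architecture statistics per group:")
print(result.architecture.round(3).to_string())
n_sig = int(result.differential["significant"].sum())
print(f"\n{n_sig} of {result.assignment.k} nodes differ at p < 0.05")
print(f"artifacts + manifest written to {config.outdir}/")
print("\nRe-running with the same config reproduces byte-identical "
      "artifacts; the manifest records the config and SHA-256 checksums.")
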