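# Methods

This note documents the models, defaults, and design choices behind
`cytoarch`, and what the synthetic-data tests do and do not demonstrate
about real data.

## The analysis model

The pipeline treats a two-group cytometry cohort as follows. Each sample
is a cells × markers matrix of non-negative intensities. Intensities are
variance-stabilized with the inverse hyperbolic sine, `x → asinh(x/c)`;
the cofactor defaults to `c = 5`, the community convention for CyTOF
(for fluorescence data larger cofactors, ~150, are customary). Samples
are downsampled to a common cell count (default 5,000) by uniform
sampling without replacement so that pooled analyses weight samples
equally.

Pooled cells are embedded in 2-D by Barnes-Hut tSNE (perplexity 30, PCA
initialization, fixed seed) over all panel markers and partitioned by
k-means (k-means++ with 10 restarts, best inertia kept) into **nodes** —
clusters of phenotypically similar cells. k defaults to 133; this is an
outcome-scale choice, not a principled constant, and is exposed in the
configuration. k-means runs on the embedding coordinates by default; a
`space="markers"` switch clusters in full marker space instead, since
workflows differ on this point and neither is uniquely correct.

The samples × nodes frequency table has entries `F[s,v] = n_sv / n_s`
with `n_s` the sample's downsampled cell count; rows sum to 1. Per-node
group differences use a two-sided unpaired Mann-Whitney U test at
α = 0.05, with no multiplicity correction by default (Benjamini-Hochberg
behind a flag); a Welch t-test is available as an alternative. The exact
null distribution is used when both groups have ≤ 8 samples and the
pooled values are tie-free; otherwise the tie-corrected normal
approximation **without** continuity correction, so that identical group
multisets give exactly p = 1. The asymptotic path is mildly liberal at
small sizes; calibration at the design sizes (20 vs 10) is verified by
simulation (per-population type-I error within Monte-Carlo bounds of the
nominal 5% over 400 null cohorts).

Per group, every node pair is correlated across samples — Spearman by
default, because proportions are non-Gaussian and compositional; Pearson
behind a flag — and pairs with `|r| > 0.6` (strict) become edges carrying
the signed coefficient. Architecture statistics:

* **Modularity Q** of the partition found by greedy modularity
  maximization (Louvain behind a flag, seeded) on absolute weights —
  edges are grouped by correlation magnitude regardless of sign; signed
  modularity variants are out of scope. The partition used for Q is always
  returned, so any reported Q is reproducible. An edgeless network has no
  defined Q and is reported as NaN with a warning.
* **Freeman degree centralization** on the unweighted edge set,
  `C = Σ_i (d_max − d_i) / ((n−1)(n−2))`: 1 for a star, 0 for any
  degree-regular graph.
* **Negative-edge percentage**, `100 · m_neg / m`; 0 by convention for an
  edgeless network.

Stimulated-condition nodes are classified from four cytokine positivity
flags (IFN-γ, TNF-α, IL-17, IL-4). A node is positive for a cytokine when
more than a minimum fraction (default 20%, configurable) of its cells
exceed the cytokine's threshold. Classes: **Pro** for IFN-γ and/or TNF-α
alone (both belong to the pro-inflammatory category, so their
co-occurrence is still Pro); **IL-17** and **Anti** (IL-4) for a single
other category; **Multi** for any cross-category combination; **NC** for
none. The cell-to-node aggregation rule (producer fraction) is a design
choice; published workflows describe cell-level classification without
stating the aggregation.

Clinical tables follow a standard Table-1 schema. Onset age is derived as
age − disease duration, i.e. the age column is taken as age at blood
collection. Summaries round half-up to conventional printed precision
(% female and onset age to integers, duration to one decimal). Subgroup
labels: ILD by organ-involvement code; early/late disease cut at 3 years
with exactly-3 assigned to late (and logged); missing lung-function
values are excluded pairwise from means.

## The synthetic-cohort generator

The generator emulates the target study design: 20 patient-like and 10
control-like samples, 5,000 cells per sample, a 36-channel panel (30
lineage, 2 checkpoint, 4 cytokine markers), and 12 populations across 9
lineages with textbook surface phenotypes. Its purpose is ground truth:
every downstream stage is tested against the generator's known labels,
abundances, and planted covariance.

* **Abundance model.** Per sample, a latent Gaussian vector centred at
  `log(base_abundance × effect)` with latent SD 0.5 and a per-group block
  correlation structure is softmaxed onto the simplex (logistic-normal).
  Cell counts are multinomial. The latent SD was chosen so that
  population frequencies show the large inter-individual spread typical
  of human blood (coefficients of variation around 50%).
* **Planted modules.** Within-block latent correlation 0.8, between-block
  0. Two structural facts shaped the defaults. First, the softmax is
  invariant to a common additive mode, so a single equicorrelated block —
  the control group's structure — is *invisible* in the frequencies: the
  control group is effectively unstructured, and its networks carry only
  noise and closure edges. Second, frequencies sum to 1, so strong
  positive within-block correlation forces between-block-mass correlation
  of roughly −1/(B−1); with B = 3 blocks this closure (−0.5) crosses the
  0.6 edge threshold and merges planted modules through negative edges,
  so the default plants B = 5 finer cell-type modules (CD4 T, CD8 T,
  unconventional T, B, innate), keeping closure near −0.25.
* **Effects.** Patient-like abundance shifts in a minority of
  populations: MAIT ×0.4, double-negative T ×0.5, memory B ×0.55, naive
  B ×1.6, memory CD4 ×1.3 — the direction and rough magnitude of subset
  changes reported in autoimmune cohorts.
* **Markers.** Gaussian per population on the arcsinh scale (background
  0.15, intermediate 1.8, bright 3.5; SD 0.35, i.e. ~9.5 SD separation
  between negative and positive modes). A raw-scale export inverts the
  transform for pipelines that start from raw intensities.
* **Stimulated mode.** Cytokine channels are appended, bimodal: a
  producer fraction (default 0.7) of the cells of populations whose
  program includes the cytokine draws from N(3.0, 0.5), everything else
  from N(0, 0.3).
* **Determinism.** All randomness flows from the spec's single seed; no
  global RNG state. Identical specs produce byte-identical cohorts.

**What passing tests do not show.** The generator omits instrument
artifacts (spillover, bead drift, doublets, debarcoding errors),
non-Gaussian marker distributions, batch effects, and any real biological
covariance beyond the planted blocks. Tests passing on this model
demonstrate that the *algorithms* are correct and calibrated under known
conditions — not that real cohorts satisfy those conditions.

## Numerical choices and degenerate inputs

* Mann-Whitney: exact vs asymptotic switch as above; groups with < 2
  samples yield NaN p with a warning.
* Spearman with constant input: undefined, returned as NaN and flagged.
* Zero-variance nodes cannot be correlated and are excluded from
  networks, logged.
* Min-max phenotype normalization maps constant marker columns to 0.
* Positivity thresholds default to the midpoint of a two-component
  Gaussian-mixture fit per marker on pooled cells (manual thresholds are
  rarely recoverable from published work); all defaults are logged and
  overridable per marker.
* Gating assigns each cell to the deepest matching rule, parents before
  children; frequencies always carry an explicit parent denominator.
* k-means: k must satisfy 2 ≤ k ≤ n cells (a warning is emitted above
  n/10); scikit-learn's implementation relocates empty clusters, so all k
  nodes are populated when ≥ k distinct points exist.
* Exactly-3-year disease duration goes to "late" (documented, logged).

## Problem sizes used in tests and the acceptance script

Statistical suites run at full design strength where the statistic is
cheap (400 null cohorts for calibration, 200 for power, 100 for
planted-module recovery, all at 5,000 cells/sample via the fast
frequency-level path that skips marker synthesis). Marker-level and
tSNE-based checks run on scaled-down cohorts (hundreds of cells per
sample, 2–20 populations) chosen so the whole suite completes in a few
minutes; the properties tested (determinism, recovery of well-separated
populations, closed-form statistics) do not depend on scale.

The planted-module recovery comparison uses 20 samples per group: with
only 10 unstructured samples the Spearman null critical value (~0.65)
sits at the edge threshold, so a 10-sample noise network contains a
handful of spurious edges whose detected modularity is itself high
(disjoint edge pairs score Q = 1 − 1/m); at 20 samples per group the
contrast between planted structure and no structure is the one actually
being tested. In that comparison an edgeless network counts as zero
detectable modular structure.

## Known limitations

* Compositional closure induces negative correlation among proportions;
  no correction (e.g. log-ratio transforms) is applied, matching common
  practice in cytometry network analyses — interpret negative edges with
  care.
* Published modularity/centralization values from specific studies are
  not reproducible without their raw data (correlation type and community
  algorithm typically unstated); such numbers are treated as context, not
  test oracles.
* No inferential test is attached to differences in network properties;
  the comparison is descriptive.
* FCS ingestion is not implemented; CSV matrices are the interchange
  format.
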