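# Methods

This note documents the models and procedures implemented in `rnanet`,
the parameter choices that matter, what the synthetic-data generator
does and does not emulate, and the numerical conventions a user relying
on the results should know.

## Scope and data flow

The package operates strictly downstream of read alignment and
differential-expression testing. Count matrices (genes × samples),
per-sample abundance tables, and DE result tables (beta coefficients or
log-fold-changes with p/q-values) are inputs; alignment,
quantification, and DE model fitting are not performed here. The six
pipeline stages communicate through files in a fixed output tree
(`drem/ edger/ kallisto/ network_analysis/ sleuth/ wgcna/`), so any
suffix of the chain can be re-run in isolation and intermediate results
inspected as plain TSV.

## Normalization

**CPM / log-CPM.** `cpm(g, s) = 1e6 · count(g, s) / libsize(s)`;
`log_cpm = log2(cpm + prior_count)` with `prior_count` defaulting to
0.5. The additive prior is a simple variance-stabilizing offset; it is
exposed as a parameter because the appropriate value scales inversely
with library size in millions.

**Filtering.** A gene is kept when its CPM reaches `min_cpm` (default 1)
in at least `min_samples` (default 2) samples and its missing-value
fraction is at most `max_missing_fraction`. Counts are complete by
construction; the missing-fraction rule exists for NA cells in imported
abundance/DE tables.

**TMM factors.** Between-sample normalization follows the weighted
trimmed mean of M-values: reference sample = the one whose
75th-percentile relative abundance is closest to the cross-sample mean;
per sample, genes positive in both sample and reference contribute
`M = log2(p_s / p_r)` and `A = ½·log2(p_s · p_r)` on relative abundances
`p = y/N`; M-values are trimmed 30 % per tail and A-values 5 %; the
surviving M-values are averaged with inverse asymptotic-variance
weights; factors are rescaled to geometric mean 1.

One deliberate deviation from the textbook weights: the raw binomial
variance `(N−y)/(N·y)` makes the obs-side term shrink with sequencing
depth, so the resulting factors change (by order 1 %) when one sample's
depth is rescaled — an artifact of weighting, not of composition. The
default weighting therefore uses the per-read form `(1−p)/p` on relative
abundances, which makes the factors exactly depth-invariant while
preserving the trimming and reference conventions.
`tmm_factors(..., weight_mode="binomial")` restores the raw-variance
weighting; that variant reproduces the Bioconductor reference
implementation to ~1e-8 and is cross-checked against it in the test
suite.

## Weighted co-expression network

**Similarity.** Unsigned: `s_ij = |cor(x_i, x_j)|` on log-CPM profiles,
Pearson by default. Biweight midcorrelation (bicor) is available for
robustness to outlying samples: values are standardized by median and
MAD, Tukey biweights `(1−u²)²·1[|u|<1]` with `u = (x−med)/(9·MAD)`
downweight points beyond 9 MADs to zero; pairs involving a MAD-zero
gene fall back to Pearson (recorded in the result's metadata). Note
that at small sample counts (n ≈ 24) bicor's downweighting of tails
attenuates true correlations by roughly 0.05–0.1 relative to Pearson —
relevant when choosing the regulatory-network threshold `tau`.

**Soft threshold.** For each candidate power β (default 1…20) the
connectivities `k_i = Σ_{j≠i} s_ij^β` are binned into `degree_bins`
(default 10) equal-width bins; the scale-free fit R² is the squared
correlation between log10 bin frequency and log10 mean bin
connectivity, and selection requires a negative slope. The selected β
is the smallest reaching `rsq_cutoff` (default 0.85), else the best
fitting candidate, flagged. Caveat: on densely block-structured
similarity (a few large modules, not a scale-free topology) R² rises
monotonically with β toward powers that flatten all TOM contrast; the
selection rule is meaningful for networks that are plausibly scale-free.
For module-recovery analyses on block-structured data the conventional
unsigned-network power β = 6 is used and can be passed explicitly
(`fit(power=6)`, or `soft_power` in the pipeline configuration).

**TOM.** `ω_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)` with
`ℓ_ij = Σ_{u≠i,j} a_iu·a_uj`, computed vectorized as `A·A − 2A` with the
unit diagonal convention; `ω_ii = 1`, and the dissimilarity is
`d = 1 − ω`. Entries are clipped to [0, 1] against floating-point
drift only; mathematically `0 ≤ ω ≤ 1` holds for any symmetric
adjacency with entries in [0, 1] and unit diagonal. (The often-quoted
bound `a_ij ≤ ω_ij` is *not* generally true — two adjacent hubs with
disjoint neighborhoods violate it — and is not asserted.)

**Module detection.** Average-linkage hierarchical clustering of `d`
(scipy implementation; its deterministic tie-handling is accepted as
the platform convention) with a *static absolute cut* at dissimilarity
`tree_cut_height` (default 0.98). Clusters below `min_module_size`
(default 30) are relabeled 0 (unassigned); modules are numbered by
decreasing size. A quantile-of-merge-heights cut was evaluated and
rejected: on data with a sizeable unclustered background the upper
quantiles of merge heights sit above the background agglomeration
level, so the cut returns a single giant cluster regardless of module
structure. The absolute cut, just below the asymptotic TOM
dissimilarity of unrelated genes (≈ 1), separates planted modules
reliably. The adaptive (dynamic branch-analysis) cut is a possible
extension point.

**Eigengenes and merging.** Each module's genes are z-scored across
samples; the eigengene is the leading right-singular vector (unit norm,
sign aligned with the module mean profile) and `variance_explained` the
leading singular value's share of total variance. Modules whose
eigengene dissimilarity `1 − cor` falls below `merge_cut_height`
(default 0.25) under average linkage are merged and eigengenes
recomputed, iterating to a fixed point.

## GO enrichment

Annotations are propagated up the ontology (is_a and part_of edges)
before testing, so every term inherits its descendants' genes. Per
term with at least `min_annotated` (default 10) annotated genes in the
score universe — and not all of it — a one-sided two-sample KS test
compares the term genes' scores against the complement, alternative
"term scores stochastically smaller" (appropriate when scores are DE
p-values). The statistic is `D⁺ = sup(F_term − F_rest)`; p-values are
exact for combined n ≤ 30, asymptotic otherwise. Raw p-values are the
primary output — the DAG-induced dependence between terms makes naive
FDR control misleading — with a Benjamini–Hochberg column provided for
convenience. The elim/weight style decorrelation algorithms are not
implemented (classic scoring only). "Top enrichment genes" are the
union of genes annotated to the k most significant terms, ties at the
cutoff included.

## Network analytics

Reference networks are reduced to unique undirected edges (reversed
duplicates collapsed, self-loops dropped by default since they distort
centrality, malformed rows reported). DEG overlap induces the subgraph
on network ∩ DEG nodes and attaches effect and mean-count attributes;
isoform-level effects are averaged to gene level with a sign-conflict
flag when isoforms disagree in direction. Metrics: degree, betweenness
(exact, pair-normalized), closeness (component-scaled convention),
eigenvector centrality per connected component (power iteration,
tolerance 1e-10), diameter per component, mean clustering coefficient.
Hub genes are the top-k nodes by centrality (default eigenvector;
degree/betweenness selectable) on each module's induced subgraph, ties
broken by ascending gene id for determinism; per-module hubs are merged
and intersected with the top enrichment genes. Visual encoding: shape
by effect sign, size min–max scaled from mean counts, opacity min–max
scaled from |effect| (degenerate all-equal cases get opacity 1 / top
size). Outputs are GraphML plus TSV attribute tables.

## Regulatory networks

The predicted network thresholds |bicor| between TF profiles and
significant-gene profiles at a user threshold `tau` (edge weight =
signed bicor, so sign hints activation vs repression); a gene that is
itself a TF stays on the TF side, preserving bipartiteness. Miner-style
path tables (files named with a literal `path` token; gene column plus
regulator column or `.regulators.tsv` sidecar) yield the inferred
network via the incidence rule B[t, g] = 1 iff t regulates a path
containing g. Both forms share the incidence-matrix representation;
merging unions nodes and edges and keeps per-edge provenance
({predicted}, {drem}, or both). Incidence ↔ graph conversion is a
bijection, asserted on every construction.

## Synthetic data generator

The generator emulates a stress time-course: by default 4 time points ×
2 conditions × 3 replicates (24 samples) and 500 genes. Per-module
latent profiles are standard normal over samples; a module gene's
log-mean is `baseline + √ρ·z_module + √(1−ρ)·ε` with ρ =
`within_module_cor` (default 0.8), baselines log-normal around 300
counts. Counts are negative-binomial via gamma–Poisson mixing with
dispersion φ (default 0.05, variance = μ + φμ²). DEG genes (default
100) receive a ±`deg_log2fc` (default 2) shift in treatment samples;
planted TFs' targets track the TF's latent profile plus noise of sd
`tf_noise_sd` (default 0.25). The toy ontology has one root, three
branches, and `go_terms` leaves; the planted leaf draws
`planted_term_effect` (default 80 %) of its genes from the DEG list.
The reference network is preferential-attachment (heavy-tailed degrees)
over gene ids with DEGs included.

What the generator does **not** emulate: GC/length biases, batch
effects, isoform-level structure (transcripts are single-isoform with a
`.1` suffix), correlated noise between samples, and annotation
incompleteness. Passing recovery tests therefore demonstrates
correctness of the algorithms under the stated generative model, not
robustness to every artifact of real libraries.

Analysis-specific study conditions used by the verification runs, chosen
once: module recovery is scored on a module-only configuration
(`n_deg=0` — the DEG overlay is a separate planted structure with its
own tests) at power 6, with ARI computed over the planted-module genes
(background genes have no true module); regulatory recovery uses
small-noise conditions (`tf_noise_sd=0.1`, `nb_dispersion=0.01`) under
which the planted correlations clear the `tau=0.8` threshold that the
analysis prescribes.

## Numerical conventions and degenerate inputs

* Zero-variance genes are rejected by similarity construction with the
  offending ids named; the pipeline drops them before fitting.
* `bicor` values and similarity entries are clipped to their
  theoretical ranges against floating-point drift; the predicted-network
  threshold comparison allows 1e-12 slack so exact profile duplicates
  pass `tau = 1`.
* Empty filter results, empty DEG overlap, and single-gene modules are
  allowed and flagged rather than raised.
* All randomness in the generator flows from a single integer seed;
  repeated runs are bit-identical.
* Pipeline problem sizes in the bundled verification runs (500 genes,
  24 samples, 20–30-node oracle graphs, 1000-replicate null
  calibration) were chosen to make each check sharp while keeping the
  whole suite interactive.

## Known limitations

* The static tree cut needs its height adapted if adjacency powers far
  from 6 are used (TOM dissimilarities compress toward 1 at high β).
* KS enrichment assumes exchangeable scores under the null; strongly
  discrete score ties reduce the exact test's resolution.
* The soft-threshold selection rule presumes approximate scale-freeness;
  its R² is monotone-increasing on dense block similarity (see above).
* Reference networks are treated as undirected for overlap and metrics;
  direction is preserved only in the bipartite regulatory
  representation.
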