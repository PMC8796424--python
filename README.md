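# rnanet

Post-alignment RNA-seq network analysis for comparative, time-series
experimental designs. `rnanet` takes the outputs of read
quantification — featureCounts-style gene count matrices or
pseudo-aligner abundance tables — together with differential-expression
result tables, and carries them through:

* **normalization** — CPM / log2-CPM scaling, low-expression filtering,
  and TMM (trimmed mean of M-values) normalization factors;
* **weighted co-expression networks** — unsigned similarity
  `s_ij = |cor(x_i, x_j)|`, soft-threshold power selection by scale-free
  topology fit, adjacency `a_ij = s_ij^β`, the topological overlap matrix
  (TOM) `ω_ij = (ℓ_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij)`, average-linkage
  module detection, module eigengenes (first principal component of each
  module), and merging of modules with correlated eigengenes;
* **GO enrichment** — one-sided two-sample Kolmogorov–Smirnov tests of
  gene significance scores per ontology term, over annotations
  propagated up the GO DAG (true-path rule);
* **network analytics** — reference-network edge reduction, overlap with
  DEG sets, degree/betweenness/closeness/eigenvector centrality,
  per-module hub-gene extraction, and visualization attribute encoding
  (shape by effect sign, size by mean count, opacity by effect
  magnitude, color by module);
* **regulatory networks** — bipartite TF–gene graphs built either from
  biweight midcorrelation (bicor) thresholding of TF–gene expression
  profiles or from the path tables of a dynamic regulatory-events miner,
  represented as TF × gene incidence matrices with per-edge provenance.

A deterministic synthetic-data generator with planted modules, DEGs,
enriched GO terms, and TF–target relationships provides full
ground-truth test coverage and a self-contained demo.

Audience: bioinformaticians running comparative RNA-seq studies
(multiple genotypes, treatments, and time points) who want a scriptable,
testable route from count tables to co-expression and regulatory network
results.

## Worked example

Generate a synthetic study (500 genes, 4 planted co-expression modules,
24 samples: 4 time points × 2 conditions × 3 replicates) and run the
whole pipeline from its configuration file:

```sh
rnanet simulate demo --n-genes 500 --n-modules 4 --seed 1
rnanet run demo/config.yaml
```

The run executes the six stages `io → normalize → coexpression →
enrichment → netanalysis → regnet`, builds the output tree
(`drem/ edger/ kallisto/ network_analysis/ sleuth/ wgcna/`), and writes
`results/run_manifest.json`. The module summary
(`results/wgcna/module_summary.tsv`) for this seed reads:

```
 module  n_genes  variance_explained  mean_connectivity
      1       74               0.650             10.765
      2       72               0.592              6.787
      3       52               0.561              3.053
      4       52               0.578              3.574
```

Four modules are recovered (the four planted 62-gene blocks, minus genes
claimed by the DEG overlay or filtering), each with a single dominant
expression pattern — the eigengene explains 56–65 % of its module's
variance. The GO enrichment table
(`results/network_analysis/go_enrichment.tsv`) ranks the planted term
and its parent at the top:

```
      term  annotated_count  ks_statistic  p_value     bh_q
GO:0000004              110      0.266900 0.000004 0.000106
GO:0000005               15      0.624742 0.000008 0.000106
GO:0000013               15      0.419931 0.004428 0.041324
GO:0000016               15      0.355326 0.019879 0.125093
```

`GO:0000005` is the planted DEG-enriched leaf term (KS statistic 0.62:
its genes' p-values are strongly left-shifted); `GO:0000004` is its
ancestor, pulled up by propagation. The same library calls are available
programmatically:

```python
from rnanet import CoexpressionAnalysis, compute_cpm, filter_genes, FilterSpec
from rnanet.io import read_count_matrix

expr = read_count_matrix("demo/counts.tsv")
kept, removed, _ = filter_genes(expr, FilterSpec(min_cpm=1, min_samples=2))
fit = CoexpressionAnalysis(compute_cpm(kept).log_cpm).fit(power=6)
print(fit.summary())
```

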