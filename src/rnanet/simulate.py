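"""Deterministic synthetic RNA-seq data with planted structure.

Generates every input the pipeline consumes — counts, design matrix,
comparison matrix, DE tables, transcript-to-gene map, toy ontology and
annotations, TF table, and a reference network — with known ground truth
(module membership, DEG list, TF targets, the enriched term) so that
parameter-recovery tests can score the pipeline against what was
planted.

The default design mirrors a stress time-course: 4 time points x 2
conditions x 3 replicates (24 samples). Counts are negative-binomial
around log-linear means driven by per-module latent factors; a module's
genes share a latent profile with loading ``sqrt(rho)``, so their
log-scale correlation approaches ``rho``. DEG genes receive a log2
fold-change shift in treatment samples; each planted TF's targets track
the TF's own latent profile plus small noise, making them recoverable by
biweight midcorrelation thresholding.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["SimulationSpec", "SimulationTruth", "simulate_counts", "simulate_annotations",
           "simulate_reference_network", "simulate_deg_table", "write_bundle"]

_LN2 = float(np.log(2.0))


@dataclass
class SimulationSpec:
    """Study-condition knobs of the generator.

    ``within_module_cor`` is the target log-scale correlation between
    genes of one module; ``nb_dispersion`` the negative-binomial
    dispersion (variance = mu + phi * mu^2); ``deg_log2fc`` the planted
    treatment shift; ``tf_noise_sd`` the latent noise of a TF target
    around its regulator's profile.
    """

    n_genes: int = 500
    n_modules: int = 4
    module_size: int | None = None  # default: n_genes // (2 * n_modules)
    within_module_cor: float = 0.8
    nb_dispersion: float = 0.05
    n_timepoints: int = 4
    n_conditions: int = 2
    n_genotypes: int = 1
    n_replicates: int = 3
    n_deg: int = 100
    deg_log2fc: float = 2.0
    n_tfs: int = 3
    targets_per_tf: int = 10
    tf_noise_sd: float = 0.25
    go_terms: int = 25
    genes_per_term: int = 15
    planted_term_effect: float = 0.8
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_timepoints * self.n_conditions * self.n_genotypes * self.n_replicates

    def resolved_module_size(self) -> int:
        size = self.module_size or self.n_genes // (2 * self.n_modules)
        if self.n_modules * size > self.n_genes:
            raise ValidationError("modules do not fit into n_genes")
        return size


@dataclass
class SimulationTruth:
    """Ground truth planted by the generator."""

    module_labels: pd.Series  # gene -> module (0 = background)
    deg_genes: list[str]
    deg_effects: pd.Series  # planted log2 fold-changes of DEG genes
    tf_targets: dict[str, list[str]]
    decoy_genes: list[str]
    planted_term: str | None = None
    term_genes: dict[str, list[str]] = field(default_factory=dict)


def _design(spec: SimulationSpec) -> pd.DataFrame:
    rows = []
    for g in range(1, spec.n_genotypes + 1):
        for c in range(1, spec.n_conditions + 1):
            for t in range(1, spec.n_timepoints + 1):
                for r in range(1, spec.n_replicates + 1):
                    sid = f"g{g}_c{c}_t{t}_r{r}"
                    rows.append(
                        {
                            "sample_id": sid,
                            "sample_path": f"reads/{sid}.fastq",
                            "genotype": f"g{g}",
                            "condition": f"c{c}",
                            "time": f"t{t}",
                            "replicate": f"r{r}",
                        }
                    )
    return pd.DataFrame(rows)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi < 1e-8:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def simulate_counts(spec: SimulationSpec) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate the count matrix, design matrix, and ground truth.

    Gene layout: ``n_modules`` co-expression modules of equal size, then
    ``n_tfs`` regulators with ``targets_per_tf`` targets each, the rest
    independent background genes. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    dm = _design(spec)
    n_samples = spec.n_samples
    module_size = spec.resolved_module_size()

    genes = [f"G{i:05d}" for i in range(1, spec.n_genes + 1)]
    labels = np.zeros(spec.n_genes, dtype=int)
    cursor = 0
    for m in range(1, spec.n_modules + 1):
        labels[cursor : cursor + module_size] = m
        cursor += module_size
    tf_ids: list[str] = []
    tf_targets: dict[str, list[str]] = {}
    for _ in range(spec.n_tfs):
        if cursor + 1 + spec.targets_per_tf > spec.n_genes:
            raise ValidationError("TF block does not fit into n_genes")
        tf = genes[cursor]
        targets = genes[cursor + 1 : cursor + 1 + spec.targets_per_tf]
        tf_ids.append(tf)
        tf_targets[tf] = targets
        cursor += 1 + spec.targets_per_tf
    decoys = genes[cursor:]

    rho = spec.within_module_cor
    latent_modules = rng.normal(size=(spec.n_modules, n_samples))
    latent_tfs = rng.normal(size=(spec.n_tfs, n_samples))

    signal = np.empty((spec.n_genes, n_samples))
    for i in range(spec.n_genes):
        eps = rng.normal(size=n_samples)
        if labels[i] > 0:
            signal[i] = np.sqrt(rho) * latent_modules[labels[i] - 1] + np.sqrt(1 - rho) * eps
        else:
            signal[i] = eps
    for t_idx, tf in enumerate(tf_ids):
        signal[genes.index(tf)] = latent_tfs[t_idx]
        for target in tf_targets[tf]:
            signal[genes.index(target)] = latent_tfs[t_idx] + spec.tf_noise_sd * rng.normal(
                size=n_samples
            )

    deg_pool = rng.permutation(spec.n_genes)[: spec.n_deg]
    deg_genes = [genes[i] for i in sorted(deg_pool)]
    deg_signs = rng.choice([-1.0, 1.0], size=len(deg_genes))
    deg_effects = pd.Series(deg_signs * spec.deg_log2fc, index=deg_genes)

    treatment = (dm["condition"] != dm["condition"].iloc[0]).to_numpy()
    baseline = rng.normal(loc=np.log(300.0), scale=1.0, size=spec.n_genes)
    log_mu = baseline[:, None] + signal
    for gene, fc in deg_effects.items():
        log_mu[genes.index(gene), treatment] += _LN2 * fc
    mu = np.exp(log_mu)
    counts = _nb_counts(rng, mu, spec.nb_dispersion)

    expr = pd.DataFrame(counts, index=genes, columns=dm["sample_id"].tolist())
    expr.index.name = "gene_id"
    truth = SimulationTruth(
        module_labels=pd.Series(labels, index=genes),
        deg_genes=deg_genes,
        deg_effects=deg_effects,
        tf_targets=tf_targets,
        decoy_genes=decoys,
    )
    return expr, dm, truth


def simulate_deg_table(
    spec: SimulationSpec, truth: SimulationTruth, expr: pd.DataFrame
) -> pd.DataFrame:
    """Emit a pseudo-aligner-dialect DE table consistent with the truth.

    DEG genes get their planted beta and small p-values; background
    genes get near-zero betas and uniform p-values. q-values are
    Benjamini-Hochberg over the column.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = list(expr.index)
    is_deg = pd.Series([g in set(truth.deg_genes) for g in genes], index=genes)
    b = pd.Series(rng.normal(scale=0.1, size=len(genes)), index=genes)
    b[truth.deg_genes] = truth.deg_effects + rng.normal(scale=0.1, size=len(truth.deg_genes))
    pval = pd.Series(rng.uniform(size=len(genes)), index=genes)
    pval[truth.deg_genes] = 10.0 ** rng.uniform(-12, -4, size=len(truth.deg_genes))
    order = np.argsort(pval.to_numpy())
    m = len(genes)
    q = np.empty(m)
    ranked = pval.to_numpy()[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        ranked[i] = min(ranked[i], ranked[i + 1])
    q[order] = np.clip(ranked, 0, 1)
    return pd.DataFrame(
        {
            "target_id": genes,
            "b": b.to_numpy(),
            "pval": pval.to_numpy(),
            "qval": q,
            "mean_obs": expr.mean(axis=1).to_numpy(),
        }
    )


def simulate_annotations(
    spec: SimulationSpec, truth: SimulationTruth
) -> tuple[str, dict[str, set[str]], str]:
    """Toy ontology plus a gene->term annotation with one planted term.

    The DAG has one root, three branch terms, and ``go_terms`` leaf
    terms. The planted (first) leaf draws ``planted_term_effect`` of its
    genes from the DEG list, decoy leaves draw uniformly. Returns
    ``(obo text, direct annotation, planted term id)``.
    """
    rng = np.random.default_rng(spec.seed + 2)
    genes = list(truth.module_labels.index)
    n_branches = 3
    root = "GO:0000001"
    branches = [f"GO:{1 + i + 1:07d}" for i in range(n_branches)]
    leaves = [f"GO:{n_branches + 2 + i:07d}" for i in range(spec.go_terms)]

    chunks = [f"format-version: 1.2\nontology: toy\n"]
    chunks.append(f"[Term]\nid: {root}\nname: root\nnamespace: biological_process\n")
    for b in branches:
        chunks.append(
            f"[Term]\nid: {b}\nname: branch {b}\nnamespace: biological_process\nis_a: {root} ! root\n"
        )
    direct: dict[str, set[str]] = {}
    term_genes: dict[str, list[str]] = {}
    for i, leaf in enumerate(leaves):
        parent = branches[i % n_branches]
        chunks.append(
            f"[Term]\nid: {leaf}\nname: leaf {leaf}\nnamespace: biological_process\nis_a: {parent} ! branch\n"
        )
        if i == 0:
            n_from_deg = int(round(spec.planted_term_effect * spec.genes_per_term))
            n_from_deg = min(n_from_deg, len(truth.deg_genes))
            picked = list(
                rng.choice(truth.deg_genes, size=n_from_deg, replace=False)
            )
            others = [g for g in genes if g not in set(picked)]
            picked += list(
                rng.choice(others, size=spec.genes_per_term - n_from_deg, replace=False)
            )
        else:
            picked = list(rng.choice(genes, size=spec.genes_per_term, replace=False))
        term_genes[leaf] = picked
        for g in picked:
            direct.setdefault(g, set()).add(leaf)
    # every gene gets at least the root so the universe is annotated
    for g in genes:
        direct.setdefault(g, set()).add(root)
    truth.planted_term = leaves[0]
    truth.term_genes = term_genes
    return "\n".join(chunks), direct, leaves[0]


def simulate_scale_free_similarity(
    n_genes: int = 300, planted_power: float = 6.0, seed: int = 0
) -> pd.DataFrame:
    """Similarity matrix whose soft-thresholded network is scale-free.

    Expected-degree (Chung-Lu) construction: power-law weights ``w_i``
    give an adjacency ``a_ij = 0.9 * w_i * w_j`` with heavy-tailed
    connectivity; the returned similarity is ``a ** (1/planted_power)``,
    so soft-thresholding recovers a scale-free topology and the log-log
    degree-distribution fit reaches a high R^2.
    """
    rng = np.random.default_rng(seed)
    x = rng.pareto(1.5, size=n_genes) + 1.0
    w = x / x.max()
    a = np.outer(w, w) * 0.9
    s = a ** (1.0 / planted_power)
    np.fill_diagonal(s, 1.0)
    return pd.DataFrame(
        s, index=[f"G{i:05d}" for i in range(n_genes)], columns=[f"G{i:05d}" for i in range(n_genes)]
    )


def simulate_reference_network(
    spec: SimulationSpec, truth: SimulationTruth, n_nodes: int | None = None, m_attach: int = 2
) -> list[tuple[str, str]]:
    """Scale-free-ish reference network over gene ids including all DEGs.

    Preferential attachment produces the heavy-tailed degree
    distribution typical of curated interactomes; DEG genes are placed
    first so each appears in the network.
    """
    rng = np.random.default_rng(spec.seed + 3)
    genes = list(truth.module_labels.index)
    n_nodes = n_nodes or min(len(genes), max(3 * len(truth.deg_genes), 100))
    ordered = truth.deg_genes + [g for g in genes if g not in set(truth.deg_genes)]
    node_ids = ordered[:n_nodes]
    graph = nx.barabasi_albert_graph(n_nodes, m_attach, seed=int(rng.integers(2**31 - 1)))
    mapping = dict(enumerate(node_ids))
    return [(mapping[u], mapping[v]) for u, v in graph.edges()]


def write_bundle(out_dir: str | os.PathLike, spec: SimulationSpec) -> dict[str, Path]:
    """Write a complete, self-consistent input bundle for the pipeline.

    Produces counts, design matrix, DGECM, transcript-to-gene map, DE
    table, TF table, reference network, toy OBO + annotations, a YAML
    configuration wired to those paths, and a truth sidecar for
    recovery scoring. Returns the path of each artifact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, dm, truth = simulate_counts(spec)
    deg_table = simulate_deg_table(spec, truth, expr)
    obo_text, direct, planted = simulate_annotations(spec, truth)
    edges = simulate_reference_network(spec, truth)

    paths: dict[str, Path] = {}

    paths["counts"] = out / "counts.tsv"
    expr.to_csv(paths["counts"], sep="\t")

    paths["design_matrix"] = out / "design_matrix.tsv"
    dm.to_csv(paths["design_matrix"], sep="\t", index=False)

    ref_ids = dm.loc[dm["condition"] == dm["condition"].iloc[0], "sample_id"]
    trt_ids = dm.loc[dm["condition"] != dm["condition"].iloc[0], "sample_id"]
    dgecm = pd.DataFrame(
        [
            {
                "comparison_id": "treatment_vs_control",
                "reference": ";".join(ref_ids),
                "treatment": ";".join(trt_ids),
            }
        ]
    )
    paths["dgecm"] = out / "dgecm.tsv"
    dgecm.to_csv(paths["dgecm"], sep="\t", index=False)

    t2g = pd.DataFrame(
        {"transcript_id": [f"{g}.1" for g in expr.index], "gene_id": list(expr.index)}
    )
    paths["t2g"] = out / "transcript2gene.tsv"
    t2g.to_csv(paths["t2g"], sep="\t", index=False)

    paths["deg_table"] = out / "deg_sleuth.tsv"
    deg_table.to_csv(paths["deg_table"], sep="\t", index=False)

    tf_families = pd.DataFrame(
        {"tf_id": list(truth.tf_targets), "family": [f"FAM{i + 1}" for i in range(len(truth.tf_targets))]}
    )
    paths["tf_table"] = out / "tf_table.tsv"
    tf_families.to_csv(paths["tf_table"], sep="\t", index=False)

    paths["reference_network"] = out / "reference_network.tsv"
    pd.DataFrame(edges, columns=["source", "target"]).to_csv(
        paths["reference_network"], sep="\t", index=False
    )

    paths["obo"] = out / "ontology.obo"
    paths["obo"].write_text(obo_text)

    ann_rows = [(g, t) for g, terms in sorted(direct.items()) for t in sorted(terms)]
    paths["annotations"] = out / "annotations.tsv"
    pd.DataFrame(ann_rows, columns=["gene_id", "term_id"]).to_csv(
        paths["annotations"], sep="\t", index=False
    )

    truth_frame = pd.DataFrame(
        {
            "gene_id": truth.module_labels.index,
            "module": truth.module_labels.to_numpy(),
            "is_deg": [g in set(truth.deg_genes) for g in truth.module_labels.index],
        }
    )
    paths["truth"] = out / "truth.tsv"
    truth_frame.to_csv(paths["truth"], sep="\t", index=False)

    config = {
        "analysis_type": "network",
        "covariates": "genotype,condition,time,replicate",
        "dgecm_path": str(paths["dgecm"]),
        "design_matrix_path": str(paths["design_matrix"]),
        "significance_level": 0.05,
        "read_dir": str(out),
        "output_dir": str(out / "results"),
        "reference_path": str(out / "reference.fa"),
        "run_kallisto": True,
        "run_star": False,
        "analysis_level": "gene",
        "counts_path": str(paths["counts"]),
        "deg_table_path": str(paths["deg_table"]),
        "deg_source": "sleuth",
        "t2g_path": str(paths["t2g"]),
        "obo_path": str(paths["obo"]),
        "annotation_path": str(paths["annotations"]),
        "tf_table_path": str(paths["tf_table"]),
        "reference_network_path": str(paths["reference_network"]),
        "tau": 0.8,
        "soft_power": 6,
        "planted_term": planted,
    }
    import yaml

    paths["config"] = out / "config.yaml"
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=False))
    return paths
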