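"""Config-driven orchestration of the analysis stages.

Stages run in dependency order ``io -> normalize -> coexpression ->
enrichment -> netanalysis -> regnet``, each reading its inputs from the
output tree written by its producer, so any suffix of the chain can be
re-run in isolation. A :class:`RunManifest` records what ran, with which
parameters, and where every output landed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import config as cfg
from . import coexpression as coex
from . import enrichment as enr
from . import io as qio
from . import netanalysis as na
from . import normalize as norm
from . import regnet as rn
from .errors import DependencyError, ValidationError

__all__ = ["RunManifest", "STAGES", "run_pipeline"]

STAGES = ("io", "normalize", "coexpression", "enrichment", "netanalysis", "regnet")

#: which stage produces the file each stage needs first
_PRODUCER = {
    "normalize": ("io", "edger/counts.tsv"),
    "coexpression": ("normalize", "wgcna/log_cpm_filtered.tsv"),
    "netanalysis": ("coexpression", "wgcna/modules.tsv"),
    "regnet": ("normalize", "wgcna/log_cpm_filtered.tsv"),
}


@dataclass
class RunManifest:
    stages: list[dict] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def record(self, name: str, outputs: list[Path], seconds: float, inputs: list[str] | None = None) -> None:
        self.stages.append(
            {
                "stage": name,
                "inputs": inputs or [],
                "outputs": [str(p) for p in outputs],
                "seconds": round(seconds, 3),
            }
        )

    def write(self, path: Path) -> Path:
        payload = {
            "stages": self.stages,
            "parameters": self.parameters,
            "versions": self.versions,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    def validate_outputs(self) -> None:
        missing = [
            out
            for stage in self.stages
            for out in stage["outputs"]
            if not Path(out).exists()
        ]
        if missing:
            raise ValidationError(f"declared outputs missing after run: {missing}")


def _require(tree_root: Path, stage: str) -> None:
    if stage in _PRODUCER:
        producer, artifact = _PRODUCER[stage]
        if not (tree_root / artifact).exists():
            raise DependencyError(
                f"stage {stage!r} needs {artifact} produced by stage {producer!r}; run it first"
            )


def _significant_genes(deg: pd.DataFrame, alpha: float) -> set[str]:
    return set(deg.index[deg["q_value"] < alpha].astype(str))


def _stage_io(config: cfg.PipelineConfig, tree: dict[str, Path], root: Path) -> list[Path]:
    dm = cfg.load_design_matrix(config.design_matrix_path, config.covariates)
    dgecm = cfg.load_dgecm(config.dgecm_path)
    comparisons = cfg.resolve_comparisons(dm, dgecm)
    comp_path = root / "comparisons.tsv"
    pd.DataFrame(
        [
            {
                "comparison_id": c.comparison_id,
                "reference": ";".join(c.reference_samples),
                "treatment": ";".join(c.treatment_samples),
            }
            for c in comparisons
        ]
    ).to_csv(comp_path, sep="\t", index=False)

    counts_path = config.extras.get("counts_path")
    abundance_dir = config.extras.get("abundance_dir")
    if counts_path:
        expr = qio.read_count_matrix(counts_path)
    elif abundance_dir:
        tables = qio.read_abundance_dir(abundance_dir)
        t2g = qio.read_transcript2gene(config.extras["t2g_path"])
        agg = qio.aggregate_to_genes(tables, t2g)
        expr = agg.matrix
        agg.rejects.to_csv(tree["kallisto"] / "aggregation_rejects.tsv", sep="\t", index=False)
    else:
        raise ValidationError("configuration needs counts_path or abundance_dir to ingest")
    out = qio.write_count_matrix(expr, tree["edger"] / "counts.tsv")
    return [comp_path, out]


def _stage_normalize(config: cfg.PipelineConfig, tree: dict[str, Path], root: Path) -> list[Path]:
    expr = qio.read_count_matrix(tree["edger"] / "counts.tsv")
    spec = norm.FilterSpec(
        min_cpm=float(config.extras.get("min_cpm", 1.0)),
        min_samples=int(config.extras.get("min_samples", 2)),
    )
    kept, removed, _ = norm.filter_genes(expr, spec)
    result = norm.compute_cpm(kept, prior_count=float(config.extras.get("prior_count", 0.5)))
    factors = norm.tmm_factors(kept)
    dist, _ = norm.sample_distance_tree(result.log_cpm)
    k = min(5, min(kept.shape))
    pcs, fractions = norm.pca_coordinates(result.log_cpm, k)

    outputs = []
    out = tree["edger"] / "cpm.tsv"
    result.cpm.to_csv(out, sep="\t")
    outputs.append(out)
    out = tree["wgcna"] / "log_cpm_filtered.tsv"
    result.log_cpm.to_csv(out, sep="\t")
    outputs.append(out)
    out = tree["edger"] / "tmm_factors.tsv"
    factors.to_frame().to_csv(out, sep="\t")
    outputs.append(out)
    out = tree["edger"] / "removed_genes.txt"
    out.write_text("\n".join(removed) + ("\n" if removed else ""))
    outputs.append(out)
    out = tree["edger"] / "sample_distances.tsv"
    dist.to_csv(out, sep="\t")
    outputs.append(out)
    out = tree["edger"] / "pca_coordinates.tsv"
    pcs.assign().to_csv(out, sep="\t")
    outputs.append(out)
    out = tree["edger"] / "pca_variance_fractions.tsv"
    pd.Series(fractions, index=pcs.columns, name="variance_fraction").to_csv(out, sep="\t")
    outputs.append(out)
    return outputs


def _coexpression_params(config: cfg.PipelineConfig) -> coex.CoexpressionParams:
    return coex.CoexpressionParams(
        correlation_kind=str(config.extras.get("correlation_kind", "pearson")),
        min_module_size=int(config.extras.get("min_module_size", 30)),
        merge_cut_height=float(config.extras.get("merge_cut_height", 0.25)),
        tree_cut_height=float(config.extras.get("tree_cut_height", 0.98)),
    )


def _stage_coexpression(config: cfg.PipelineConfig, tree: dict[str, Path], root: Path) -> list[Path]:
    log_cpm = pd.read_csv(tree["wgcna"] / "log_cpm_filtered.tsv", sep="\t", index_col=0)
    log_cpm = log_cpm.loc[log_cpm.std(axis=1) > 0]
    model = coex.CoexpressionAnalysis(log_cpm, _coexpression_params(config))
    power = config.extras.get("soft_power")
    fit = model.fit(power=float(power) if power is not None else None)

    outputs = []
    out = tree["wgcna"] / "modules.tsv"
    fit.partition.assignment.rename("module").to_csv(out, sep="\t", index_label="gene_id")
    outputs.append(out)
    out = tree["wgcna"] / "eigengenes.tsv"
    fit.eigengenes.eigengenes.to_csv(out, sep="\t", index_label="sample_id")
    outputs.append(out)
    out = tree["wgcna"] / "soft_threshold.tsv"
    fit.soft_threshold.table.to_csv(out, sep="\t", index=False)
    outputs.append(out)
    out = tree["wgcna"] / "module_summary.tsv"
    summary = fit.summary()
    summary.to_csv(out, sep="\t", index=False)
    outputs.append(out)
    out = tree["wgcna"] / "similarity.tsv"
    fit.similarity.to_csv(out, sep="\t")
    outputs.append(out)
    out = tree["wgcna"] / "power.txt"
    out.write_text(f"{fit.soft_threshold.power}\n")
    outputs.append(out)
    return outputs


def _load_deg(config: cfg.PipelineConfig) -> pd.DataFrame:
    path = config.extras.get("deg_table_path")
    if not path:
        raise ValidationError("configuration needs deg_table_path")
    return qio.read_deg_table(path, str(config.extras.get("deg_source", "sleuth")))


def _stage_enrichment(config: cfg.PipelineConfig, tree: dict[str, Path], root: Path) -> list[Path]:
    deg = _load_deg(config)
    dag = enr.load_obo(config.extras["obo_path"])
    direct = enr.read_annotation_table(config.extras["annotation_path"])
    annotation = enr.propagate_annotations(dag, direct)
    scores = {str(g): float(p) for g, p in deg["p_value"].items()}
    result = enr.ks_enrichment(
        scores, annotation, min_annotated=int(config.extras.get("min_annotated", 10))
    )
    top = enr.top_significant_genes(
        result, annotation, k_terms=int(config.extras.get("k_terms", 10))
    )
    outputs = []
    out = tree["network_analysis"] / "go_enrichment.tsv"
    result.to_csv(out, sep="\t", index=False)
    outputs.append(out)
    out = tree["network_analysis"] / "go_top_genes.txt"
    out.write_text("\n".join(sorted(top)) + "\n")
    outputs.append(out)
    return outputs


def _stage_netanalysis(config: cfg.PipelineConfig, tree: dict[str, Path], root: Path) -> list[Path]:
    deg = _load_deg(config)
    edges = na.read_edge_list(config.extras["reference_network_path"])
    graph, report = na.reduce_edges(edges)
    significant = deg.loc[sorted(_significant_genes(deg, config.significance_level))]
    sub, empty = na.overlap_deg(graph, significant)
    outputs = []
    out = tree["network_analysis"] / "reduction_report.txt"
    out.write_text(
        f"input_rows\t{report.input_rows}\nkept_edges\t{report.kept_edges}\n"
        f"self_loops_dropped\t{report.self_loops_dropped}\nrejects\t{len(report.rejects)}\n"
    )
    outputs.append(out)
    if not empty:
        sub = na.encode_visual_attributes(sub)
        modules_path = tree["wgcna"] / "modules.tsv"
        assignment = pd.read_csv(modules_path, sep="\t", index_col=0)["module"]
        partition = coex.ModulePartition(assignment=assignment.astype(int))
        sub = na.module_colored_graph(sub, partition)
        metrics = na.compute_metrics(sub)
        go_genes_path = tree["network_analysis"] / "go_top_genes.txt"
        go_genes = (
            set(go_genes_path.read_text().split()) if go_genes_path.exists() else set()
        )
        hubs, merged, inter = na.hub_genes(
            sub, partition, top_k=int(config.extras.get("hub_top_k", 5)), go_genes=go_genes
        )
        out = tree["network_analysis"] / "deg_network.graphml"
        na.write_graphml(sub, out)
        outputs.append(out)
        out = tree["network_analysis"] / "node_metrics.tsv"
        metrics.node_table.to_csv(out, sep="\t", index_label="gene_id")
        outputs.append(out)
        out = tree["network_analysis"] / "hub_genes.tsv"
        pd.DataFrame(
            [(m, g) for m, gs in hubs.items() for g in gs], columns=["module", "gene_id"]
        ).to_csv(out, sep="\t", index=False)
        outputs.append(out)
        out = tree["network_analysis"] / "hub_go_intersection.txt"
        out.write_text("\n".join(sorted(inter)) + ("\n" if inter else ""))
        outputs.append(out)
    return outputs


def _stage_regnet(config: cfg.PipelineConfig, tree: dict[str, Path], root: Path) -> list[Path]:
    deg = _load_deg(config)
    log_cpm = pd.read_csv(tree["wgcna"] / "log_cpm_filtered.tsv", sep="\t", index_col=0)
    tfs = rn.read_tf_table(config.extras["tf_table_path"])
    significant = _significant_genes(deg, config.significance_level)
    tau = float(config.extras.get("tau", 0.8))
    predicted, missing_tfs = rn.predicted_regulatory_network(log_cpm, tfs, significant, tau)
    network = predicted
    drem_dir = tree["drem"]
    if any("path" in p.name for p in drem_dir.iterdir() if p.is_file()):
        paths = rn.parse_drem_tables(drem_dir)
        inferred = rn.drem_bipartite(paths, deg=significant)
        network = rn.merge_regulatory_networks(predicted, inferred)
    outputs = []
    out = tree["network_analysis"] / "regulatory_incidence.tsv"
    network.incidence.to_csv(out, sep="\t", index_label="tf_id")
    outputs.append(out)
    out = tree["network_analysis"] / "regulatory_network.graphml"
    na.write_graphml(network.to_graph(), out)
    outputs.append(out)
    out = tree["network_analysis"] / "missing_tfs.txt"
    out.write_text("\n".join(missing_tfs) + ("\n" if missing_tfs else ""))
    outputs.append(out)
    return outputs


_STAGE_FUNCS = {
    "io": _stage_io,
    "normalize": _stage_normalize,
    "coexpression": _stage_coexpression,
    "enrichment": _stage_enrichment,
    "netanalysis": _stage_netanalysis,
    "regnet": _stage_regnet,
}


def run_pipeline(config_path, stages: list[str] | None = None) -> RunManifest:
    """Execute the requested stages (all by default) in dependency order.

    Raises :class:`DependencyError` naming the producing stage when a
    stage is run before its upstream artifact exists.
    """
    config = cfg.load_config(config_path)
    selected = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stage(s): {sorted(unknown)}; valid: {STAGES}")
    root = Path(config.output_dir)
    tree = cfg.build_directory_tree(root)
    manifest = RunManifest(
        parameters={"config": str(config_path), "stages": selected, **config.extras},
        versions={
            "rnanet": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    )
    for stage in selected:
        _require(root, stage)
        start = time.perf_counter()
        outputs = _STAGE_FUNCS[stage](config, tree, root)
        manifest.record(stage, outputs, time.perf_counter() - start)
    manifest.validate_outputs()
    manifest.write(root / "run_manifest.json")
    return manifest
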