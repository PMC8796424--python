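"""Graph analytics on differential-expression networks.

Consumes reference gene networks (2-column edge lists from public
interactome resources), reduces them to unique undirected edges,
intersects them with DEG sets, computes classical graph metrics, and
extracts per-module hub genes. Visualization is limited to attribute
encoding (shape by effect sign, size by mean count, opacity by scaled
effect magnitude, node color by co-expression module) written to
GraphML/TSV; rendering is left to downstream tools.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import ModulePartition
from .errors import ValidationError

__all__ = [
    "ReductionReport",
    "NetworkMetrics",
    "read_edge_list",
    "reduce_edges",
    "overlap_deg",
    "gene_effect_summary",
    "aggregate_deg_to_genes",
    "encode_visual_attributes",
    "compute_metrics",
    "hub_genes",
    "module_colored_graph",
    "correlation_module_graph",
    "write_graphml",
    "read_graphml",
]

#: deterministic module palette (matplotlib tab10 hex values, cycled)
_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)
UNASSIGNED_COLOR = "#bdbdbd"


@dataclass
class ReductionReport:
    input_rows: int
    kept_edges: int
    self_loops_dropped: int
    rejects: list = field(default_factory=list)


def read_edge_list(path: str | os.PathLike) -> list[tuple]:
    """Read a (source, target[, weight]) tab-separated edge list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"edge list {path} needs at least 2 columns")
    rows = []
    for row in df.itertuples(index=False):
        if len(row) >= 3 and row[2] is not None and str(row[2]) != "nan":
            rows.append((row[0], row[1], float(row[2])))
        else:
            rows.append((row[0], row[1]))
    return rows


def reduce_edges(
    raw_edges: list[tuple], keep_self_loops: bool = False
) -> tuple[nx.Graph, ReductionReport]:
    """Collapse a raw edge list to unique undirected edges.

    Duplicates and reversed duplicates become one edge; self-loops are
    dropped (they distort centrality) unless ``keep_self_loops``.
    Malformed rows (empty tokens) go to the rejects report. Idempotent.
    """
    graph = nx.Graph()
    seen: set[frozenset] = set()
    report = ReductionReport(input_rows=len(raw_edges), kept_edges=0, self_loops_dropped=0)
    for row in raw_edges:
        if len(row) < 2 or not str(row[0]).strip() or not str(row[1]).strip():
            report.rejects.append(row)
            continue
        u, v = str(row[0]).strip(), str(row[1]).strip()
        weight = float(row[2]) if len(row) > 2 else None
        if u == v and not keep_self_loops:
            report.self_loops_dropped += 1
            continue
        key = frozenset((u, v))
        if key in seen:
            continue
        seen.add(key)
        if weight is None:
            graph.add_edge(u, v)
        else:
            graph.add_edge(u, v, weight=weight)
    report.kept_edges = graph.number_of_edges()
    return graph, report


def overlap_deg(graph: nx.Graph, deg: pd.DataFrame) -> tuple[nx.Graph, bool]:
    """Induced subgraph on the network nodes that are DEGs.

    Attaches ``effect`` and ``mean_count`` node attributes from the DEG
    table. Returns ``(subgraph, empty_flag)``.
    """
    nodes = set(graph.nodes) & set(deg.index.astype(str))
    sub = graph.subgraph(nodes).copy()
    for node in sub.nodes:
        sub.nodes[node]["effect"] = float(deg.loc[node, "effect"])
        mc = deg.loc[node, "mean_count"]
        sub.nodes[node]["mean_count"] = float(mc) if pd.notna(mc) else 0.0
    return sub, sub.number_of_nodes() == 0


def gene_effect_summary(effects, mean_counts=None) -> tuple[float, float, bool]:
    """Average a gene's isoform-level effects and mean counts.

    Returns ``(mean effect, mean count, sign_conflict)``; the flag marks
    isoforms with opposing effect signs, whose average is ambiguous.
    """
    effects = np.asarray(list(effects), dtype=float)
    if effects.size == 0:
        raise ValidationError("gene_effect_summary needs at least one isoform row")
    if mean_counts is None:
        counts = np.full(effects.shape, np.nan)
    else:
        counts = np.asarray(list(mean_counts), dtype=float)
    conflict = bool((effects > 0).any() and (effects < 0).any())
    mean_count = float(np.nanmean(counts)) if not np.all(np.isnan(counts)) else float("nan")
    return float(effects.mean()), mean_count, conflict


def aggregate_deg_to_genes(deg: pd.DataFrame, t2g: dict[str, str] | None = None) -> pd.DataFrame:
    """Collapse an isoform-level DEG table to gene level by averaging.

    Transcript ids map through ``t2g`` (falling back to stripping a
    trailing ``.<int>`` suffix); per-gene effect and mean_count are
    isoform means, p/q-values the isoform minima, with a
    ``sign_conflict`` column flagging mixed-sign isoforms.
    """
    import re

    suffix = re.compile(r"\.\d+$")

    def to_gene(t: str) -> str:
        if t2g and t in t2g:
            return t2g[t]
        return suffix.sub("", t)

    work = deg.copy()
    work["gene_id"] = [to_gene(str(t)) for t in work.index]
    rows = []
    for gene, grp in work.groupby("gene_id", sort=True):
        effect, mean_count, conflict = gene_effect_summary(grp["effect"], grp["mean_count"])
        rows.append(
            {
                "gene_id": gene,
                "effect": effect,
                "mean_count": mean_count,
                "p_value": float(grp["p_value"].min()),
                "q_value": float(grp["q_value"].min()),
                "sign_conflict": conflict,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def encode_visual_attributes(
    graph: nx.Graph, size_range: tuple[float, float] = (10.0, 50.0)
) -> nx.Graph:
    """Set shape/size/opacity node attributes from effect and mean count.

    Shape is categorical by effect sign, size min-max scales mean count
    into ``size_range``, and opacity min-max scales the effect magnitude
    into [0, 1] (all-equal magnitudes get opacity 1, a single node the
    top of the size range).
    """
    graph = graph.copy()
    nodes = list(graph.nodes)
    if not nodes:
        return graph
    effects = np.array([graph.nodes[n].get("effect", 0.0) for n in nodes], dtype=float)
    counts = np.array([graph.nodes[n].get("mean_count", 0.0) for n in nodes], dtype=float)
    abs_eff = np.abs(effects)
    lo_e, hi_e = abs_eff.min(), abs_eff.max()
    lo_c, hi_c = counts.min(), counts.max()
    for n, eff, cnt, mag in zip(nodes, effects, counts, abs_eff):
        graph.nodes[n]["shape"] = "triangle-up" if eff > 0 else ("triangle-down" if eff < 0 else "circle")
        if hi_c > lo_c:
            size = size_range[0] + (cnt - lo_c) / (hi_c - lo_c) * (size_range[1] - size_range[0])
        else:
            size = size_range[1]
        graph.nodes[n]["size"] = float(size)
        opacity = (mag - lo_e) / (hi_e - lo_e) if hi_e > lo_e else 1.0
        graph.nodes[n]["opacity"] = float(opacity)
    return graph


@dataclass
class NetworkMetrics:
    """Classical per-node and whole-graph statistics."""

    node_table: pd.DataFrame  # degree, betweenness, closeness, eigenvector
    diameter_per_component: dict
    mean_clustering: float
    component_count: int


def _eigenvector_by_component(graph: nx.Graph) -> dict:
    cent: dict = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if sub.number_of_nodes() == 1:
            cent[next(iter(comp))] = 1.0
        else:
            cent.update(nx.eigenvector_centrality(sub, max_iter=10_000, tol=1e-10))
    return cent


def compute_metrics(graph: nx.Graph) -> NetworkMetrics:
    """Degree, betweenness, closeness, eigenvector centrality, diameter
    per component, mean clustering coefficient, and component count."""
    if graph.number_of_nodes() == 0:
        raise ValidationError("cannot compute metrics of an empty graph")
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    closeness = {n: nx.closeness_centrality(graph, n) for n in graph.nodes}
    eigen = _eigenvector_by_component(graph)
    table = pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "betweenness": pd.Series(betweenness),
            "closeness": pd.Series(closeness),
            "eigenvector": pd.Series(eigen),
        }
    ).sort_index()
    diameters = {}
    for i, comp in enumerate(sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))):
        diameters[i] = nx.diameter(graph.subgraph(comp)) if len(comp) > 1 else 0
    return NetworkMetrics(
        node_table=table,
        diameter_per_component=diameters,
        mean_clustering=float(nx.average_clustering(graph)),
        component_count=nx.number_connected_components(graph),
    )


_CENTRALITIES = ("eigenvector", "degree", "betweenness")


def hub_genes(
    graph: nx.Graph,
    partition: ModulePartition,
    centrality: str = "eigenvector",
    top_k: int = 5,
    go_genes: set[str] | None = None,
) -> tuple[dict[int, list[str]], list[str], set[str]]:
    """Per-module hub extraction and cross-reference with enriched genes.

    Centrality is computed on each module's induced subgraph; the top
    ``top_k`` nodes per module (descending centrality, ascending gene id
    on ties) are its hubs. Returns ``(hubs per module, merged top gene
    list, intersection with go_genes)``. Modules smaller than ``top_k``
    contribute all their nodes.
    """
    if centrality not in _CENTRALITIES:
        raise ValidationError(f"centrality must be one of {_CENTRALITIES}")
    hubs: dict[int, list[str]] = {}
    for label in partition.labels:
        members = [g for g in partition.genes_in(label) if g in graph]
        if not members:
            continue
        sub = graph.subgraph(members)
        if centrality == "degree":
            scores = dict(sub.degree())
        elif centrality == "betweenness":
            scores = nx.betweenness_centrality(sub, normalized=False)
        else:
            scores = _eigenvector_by_component(sub)
        ranked = sorted(scores, key=lambda n: (-scores[n], n))
        hubs[label] = ranked[: min(top_k, len(ranked))]
    merged = sorted(set().union(*hubs.values())) if hubs else []
    intersection = set(merged) & (go_genes or set())
    return hubs, merged, intersection


def module_colored_graph(graph: nx.Graph, partition: ModulePartition) -> nx.Graph:
    """Attach each node's module label and a deterministic module color."""
    graph = graph.copy()
    for node in graph.nodes:
        label = int(partition.assignment.get(node, 0))
        graph.nodes[node]["module"] = label
        graph.nodes[node]["color"] = (
            UNASSIGNED_COLOR if label == 0 else _PALETTE[(label - 1) % len(_PALETTE)]
        )
    return graph


def correlation_module_graph(
    similarity: pd.DataFrame,
    partition: ModulePartition,
    modules: list[int],
    threshold: float,
) -> nx.Graph:
    """Correlation network over selected modules' genes.

    Edges connect gene pairs with similarity at or above ``threshold``
    and carry the similarity as weight; node ``size`` is the node degree
    (for degree-proportional display) and ``module`` its label.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")
    unknown = set(modules) - set(partition.labels)
    if unknown:
        raise ValidationError(f"unknown module label(s): {sorted(unknown)}")
    genes = [g for m in modules for g in partition.genes_in(m) if g in similarity.index]
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    s = similarity.loc[genes, genes].to_numpy()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if s[i, j] >= threshold:
                graph.add_edge(genes[i], genes[j], weight=float(s[i, j]))
    for gene in genes:
        graph.nodes[gene]["module"] = int(partition.assignment.get(gene, 0))
        graph.nodes[gene]["size"] = graph.degree(gene)
    return graph


def write_graphml(graph: nx.Graph, path: str | os.PathLike) -> None:
    nx.write_graphml(graph, str(path))


def read_graphml(path: str | os.PathLike) -> nx.Graph:
    return nx.read_graphml(str(path))
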