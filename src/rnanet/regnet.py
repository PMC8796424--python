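"""Bipartite TF-gene regulatory networks.

Two construction routes:

* **predicted** — edges between transcription factors and significant
  genes whose expression profiles have biweight midcorrelation magnitude
  at or above a user threshold ``tau`` (the signed correlation is kept as
  the edge weight, hinting activation vs repression);
* **drem** — edges read off the regulator/gene membership of the paths a
  dynamic regulatory-events miner inferred from the time series, encoded
  as a TF x gene incidence matrix.

Both produce a :class:`BipartiteRegulatoryNetwork`; networks from the two
routes can be merged with per-edge provenance preserved. A gene that is
also a TF appears on the TF side only, preserving bipartiteness.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .coexpression import bicor_matrix
from .errors import ParseError, ValidationError

__all__ = [
    "BipartiteRegulatoryNetwork",
    "read_tf_table",
    "predicted_regulatory_network",
    "parse_drem_tables",
    "drem_bipartite",
    "merge_regulatory_networks",
    "incidence_to_graph",
    "graph_to_incidence",
]


@dataclass
class BipartiteRegulatoryNetwork:
    """TF x gene incidence matrix plus edge provenance.

    ``incidence`` rows are TFs, columns genes; nonzero cells are edges
    (weighted for predicted networks, 0/1 for miner-derived ones).
    ``provenance`` maps each (tf, gene) edge to the set of routes that
    produced it.
    """

    incidence: pd.DataFrame
    provenance: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.incidence.index) & set(self.incidence.columns)
        if overlap:
            raise ValidationError(
                f"bipartiteness violated: id(s) on both sides: {sorted(overlap)[:5]}"
            )

    @property
    def tf_set(self) -> set[str]:
        return set(self.incidence.index)

    @property
    def gene_set(self) -> set[str]:
        return set(self.incidence.columns)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        arr = self.incidence.to_numpy()
        tfs, genes = list(self.incidence.index), list(self.incidence.columns)
        for i, tf in enumerate(tfs):
            for j, gene in enumerate(genes):
                if arr[i, j] != 0:
                    out.append((tf, gene, float(arr[i, j])))
        return out

    def to_graph(self) -> nx.Graph:
        return incidence_to_graph(self)


def read_tf_table(path: str | os.PathLike) -> dict[str, str]:
    """Read a 2-column (tf_id, family) table; TF ids must be unique."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"TF table {path} needs 2 columns (tf_id, family)")
    ids = df.iloc[:, 0]
    if ids.duplicated().any():
        raise ValidationError(f"duplicate tf_id(s): {ids[ids.duplicated()].tolist()[:5]}")
    return dict(zip(ids, df.iloc[:, 1]))


def predicted_regulatory_network(
    expr: pd.DataFrame,
    tfs: dict[str, str] | set[str],
    significant_genes: set[str],
    tau: float,
) -> tuple[BipartiteRegulatoryNetwork, list[str]]:
    """Threshold TF-gene biweight midcorrelations into a bipartite network.

    An edge (t, g) exists iff ``|bicor(x_t, x_g)| >= tau`` for TF ``t``
    and significant gene ``g != t``; its weight is the signed bicor.
    TFs absent from the expression matrix are returned as the second
    element rather than silently ignored.

    The edge set is monotone non-increasing in ``tau``.
    """
    if not 0.0 < tau <= 1.0:
        raise ValidationError("tau must lie in (0, 1]")
    tf_ids = sorted(set(tfs) if not isinstance(tfs, dict) else set(tfs))
    present = [t for t in tf_ids if t in expr.index]
    missing = [t for t in tf_ids if t not in expr.index]
    if not present:
        raise ValidationError("no TF from the table is present in the expression matrix")
    genes = sorted((significant_genes & set(expr.index)) - set(present))
    sub = expr.loc[present + genes]
    c = bicor_matrix(sub)
    block = c.loc[present, genes]
    # tiny slack so exact duplicates (|bicor| = 1 - fp eps) pass tau = 1
    weights = block.where(block.abs() >= tau - 1e-12, 0.0)
    provenance = {
        (t, g): {"predicted"}
        for t in present
        for g in genes
        if weights.loc[t, g] != 0.0
    }
    return BipartiteRegulatoryNetwork(incidence=weights, provenance=provenance), missing


def parse_drem_tables(directory: str | os.PathLike) -> pd.DataFrame:
    """Collect per-path gene tables saved from the regulatory-events miner.

    Files whose names contain the literal token ``path`` are parsed; each
    must have a ``gene`` column, with regulator TFs either in a
    ``regulator`` column or in a sidecar ``<name>.regulators.tsv`` with
    columns ``tf`` (and optionally ``score``). Returns one row per path:
    ``path``, ``genes`` (tuple), ``tfs`` (tuple).
    """
    directory = Path(directory)
    files = sorted(
        p
        for p in directory.iterdir()
        if p.is_file() and "path" in p.name and p.suffixes[-1:] != [".regulators"]
        and not p.name.endswith(".regulators.tsv")
    )
    if not files:
        raise IOError(f"no files containing 'path' found under {directory}")
    rows = []
    seen: set[str] = set()
    for f in files:
        label = f.stem
        if label in seen:
            raise ValidationError(f"duplicate path label {label!r}")
        seen.add(label)
        df = pd.read_csv(f, sep="\t", dtype=str)
        if "gene" not in df.columns:
            raise ParseError(f"path table {f.name} lacks a 'gene' column")
        genes = tuple(dict.fromkeys(g for g in df["gene"].dropna() if g))
        tf_list: list[str] = []
        if "regulator" in df.columns:
            tf_list = [t for t in df["regulator"].dropna().unique().tolist() if t]
        sidecar = f.with_name(f.stem + ".regulators.tsv")
        if sidecar.exists():
            side = pd.read_csv(sidecar, sep="\t", dtype=str)
            if "tf" not in side.columns:
                raise ParseError(f"regulator sidecar {sidecar.name} lacks a 'tf' column")
            tf_list.extend(t for t in side["tf"].dropna() if t)
        rows.append({"path": label, "genes": genes, "tfs": tuple(dict.fromkeys(tf_list))})
    return pd.DataFrame(rows)


def drem_bipartite(
    paths: pd.DataFrame, deg: set[str] | None = None
) -> BipartiteRegulatoryNetwork:
    """Incidence matrix from miner paths: B[t, g] = 1 iff TF ``t``
    regulates a path containing gene ``g`` (optionally restricted to the
    DEG set)."""
    if paths.empty:
        raise ValidationError("no paths to build a network from")
    pairs: set[tuple[str, str]] = set()
    for row in paths.itertuples(index=False):
        genes = [g for g in row.genes if deg is None or g in deg]
        for tf in row.tfs:
            for gene in genes:
                if gene != tf:
                    pairs.add((tf, gene))
    tfs = sorted({t for t, _ in pairs})
    genes = sorted({g for _, g in pairs} - set(tfs))
    incidence = pd.DataFrame(0.0, index=tfs, columns=genes)
    provenance = {}
    for tf, gene in pairs:
        if gene in incidence.columns:
            incidence.loc[tf, gene] = 1.0
            provenance[(tf, gene)] = {"drem"}
    return BipartiteRegulatoryNetwork(incidence=incidence, provenance=provenance)


def merge_regulatory_networks(
    a: BipartiteRegulatoryNetwork, b: BipartiteRegulatoryNetwork
) -> BipartiteRegulatoryNetwork:
    """Union of two bipartite networks with provenance preserved per edge.

    Weights from the first network win on shared edges; an edge present
    in both carries both provenance tags.
    """
    tfs = sorted(a.tf_set | b.tf_set)
    genes = sorted((a.gene_set | b.gene_set) - set(tfs))
    incidence = pd.DataFrame(0.0, index=tfs, columns=genes)
    provenance: dict[tuple[str, str], set[str]] = {}
    for net in (b, a):  # a second so its weights win
        for tf, gene, w in net.edges:
            if gene not in incidence.columns:
                continue  # id became a TF in the union; stays on TF side
            incidence.loc[tf, gene] = w
            provenance.setdefault((tf, gene), set()).update(net.provenance.get((tf, gene), set()))
    return BipartiteRegulatoryNetwork(incidence=incidence, provenance=provenance)


def incidence_to_graph(net: BipartiteRegulatoryNetwork) -> nx.Graph:
    """Bipartite graph with node attribute ``side`` in {TF, gene} and
    edge attributes ``weight`` and ``provenance``."""
    graph = nx.Graph()
    for tf in net.incidence.index:
        graph.add_node(tf, side="TF")
    for gene in net.incidence.columns:
        graph.add_node(gene, side="gene")
    for tf, gene, w in net.edges:
        graph.add_edge(
            tf, gene, weight=w,
            provenance=",".join(sorted(net.provenance.get((tf, gene), set()))),
        )
    return graph


def graph_to_incidence(graph: nx.Graph) -> BipartiteRegulatoryNetwork:
    """Inverse of :func:`incidence_to_graph` (round-trip identity)."""
    tfs = sorted(n for n, d in graph.nodes(data=True) if d.get("side") == "TF")
    genes = sorted(n for n, d in graph.nodes(data=True) if d.get("side") == "gene")
    incidence = pd.DataFrame(0.0, index=tfs, columns=genes)
    provenance: dict[tuple[str, str], set[str]] = {}
    for u, v, data in graph.edges(data=True):
        tf, gene = (u, v) if graph.nodes[u].get("side") == "TF" else (v, u)
        incidence.loc[tf, gene] = float(data.get("weight", 1.0))
        prov = data.get("provenance", "")
        if prov:
            provenance[(tf, gene)] = set(prov.split(","))
    return BipartiteRegulatoryNetwork(incidence=incidence, provenance=provenance)
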