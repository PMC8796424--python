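"""GO enrichment by Kolmogorov-Smirnov testing over a propagated ontology.

Gene-level significance scores (typically DE p-values, lower = more
significant) are compared, per GO term, between the genes annotated to
the term and the rest of the universe with a one-sided two-sample KS
test (alternative: term genes' scores stochastically smaller). The
annotation is first propagated up the ontology (true-path rule), so a
gene annotated to a leaf counts for every ancestor term.

Raw p-values are reported as the primary column — the DAG-induced
dependence between terms invalidates naive FDR control — with an
optional Benjamini-Hochberg column for convenience.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import ks_2samp

from .errors import ParseError, ValidationError

__all__ = [
    "OntologyDAG",
    "GeneAnnotation",
    "load_obo",
    "read_annotation_table",
    "propagate_annotations",
    "ks_enrichment",
    "top_significant_genes",
]

_RELATIONS = {"is_a", "part_of"}


@dataclass
class OntologyDAG:
    """Directed acyclic ontology; edges run child -> parent."""

    graph: nx.DiGraph
    alt_ids: dict[str, str] = field(default_factory=dict)
    roots: dict[str, str] = field(default_factory=dict)  # namespace -> root id

    def resolve(self, term: str) -> str | None:
        if term in self.graph:
            return term
        return self.alt_ids.get(term)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` by following parent edges."""
        return nx.descendants(self.graph, term)

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)


def load_obo(path: str | os.PathLike) -> OntologyDAG:
    """Parse an OBO 1.2 ontology into a child -> parent DAG.

    Obsolete terms are skipped; ``alt_id`` aliases resolve to their
    canonical term. Only ``is_a`` and ``part_of`` edges are kept.
    """
    multigraph = obonet.read_obo(path)  # skips obsolete terms by default
    graph = nx.DiGraph()
    graph.add_nodes_from((n, d) for n, d in multigraph.nodes(data=True))
    for child, parent, relation in multigraph.edges(keys=True):
        if relation in _RELATIONS:
            graph.add_edge(child, parent, relation=relation)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ParseError(f"ontology contains a cycle through {cycle[0][0]!r}")
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    roots: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        if graph.out_degree(node) == 0:
            roots[data.get("namespace", "default")] = node
    return OntologyDAG(graph=graph, alt_ids=alt_ids, roots=roots)


@dataclass
class GeneAnnotation:
    """Direct and ancestor-closed gene -> GO term annotations."""

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]
    rejects: list[tuple[str, str]] = field(default_factory=list)

    def term_to_genes(self) -> dict[str, set[str]]:
        table: dict[str, set[str]] = {}
        for gene, terms in self.propagated.items():
            for term in terms:
                table.setdefault(term, set()).add(gene)
        return table


def read_annotation_table(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a 2-column (gene_id, term_id) annotation TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"annotation table {path} needs 2 columns (gene_id, term_id)")
    direct: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        direct.setdefault(gene, set()).add(term)
    return direct


def propagate_annotations(
    dag: OntologyDAG, direct: dict[str, set[str]]
) -> GeneAnnotation:
    """Close annotations under the ancestor relation (true-path rule).

    Term ids unknown to the ontology (after alt_id resolution) go to the
    rejects report. Idempotent: propagating a propagated annotation
    changes nothing.
    """
    ancestor_cache: dict[str, set[str]] = {}
    propagated: dict[str, set[str]] = {}
    resolved_direct: dict[str, set[str]] = {}
    rejects: list[tuple[str, str]] = []
    for gene, terms in direct.items():
        closed: set[str] = set()
        kept: set[str] = set()
        for term in terms:
            canonical = dag.resolve(term)
            if canonical is None:
                rejects.append((gene, term))
                continue
            kept.add(canonical)
            if canonical not in ancestor_cache:
                ancestor_cache[canonical] = dag.ancestors(canonical)
            closed |= {canonical} | ancestor_cache[canonical]
        resolved_direct[gene] = kept
        propagated[gene] = closed
    return GeneAnnotation(direct=resolved_direct, propagated=propagated, rejects=rejects)


def ks_enrichment(
    scores: dict[str, float],
    annotation: GeneAnnotation,
    min_annotated: int = 10,
    add_bh: bool = True,
    exact_max_n: int = 30,
) -> pd.DataFrame:
    """Per-term one-sided two-sample KS test of gene scores.

    For each term annotated to at least ``min_annotated`` genes of the
    universe (and not to all of them), the scores of its genes are tested
    against the complement with alternative "term scores stochastically
    smaller". The statistic is D+ = sup(F_term - F_rest); the p-value is
    exact when the combined sample size is at most ``exact_max_n``,
    asymptotic otherwise.

    Returns a table sorted by p-value with columns ``term``,
    ``annotated_count``, ``ks_statistic``, ``p_value`` (and ``bh_q`` when
    ``add_bh``), plus the skipped universe-covering terms in
    ``attrs['skipped_terms']``.
    """
    universe = set(scores)
    term_genes = annotation.term_to_genes()
    rows = []
    skipped: list[str] = []
    for term, genes in term_genes.items():
        in_term = sorted(genes & universe)
        n = len(in_term)
        if n < min_annotated:
            continue
        complement = universe - set(in_term)
        if not complement:
            skipped.append(term)
            continue
        x = [scores[g] for g in in_term]
        y = [scores[g] for g in sorted(complement)]
        method = "exact" if (len(x) + len(y)) <= exact_max_n else "asymp"
        # alternative='greater': ECDF of x lies above that of y, i.e. x smaller
        res = ks_2samp(x, y, alternative="greater", method=method)
        rows.append(
            {
                "term": term,
                "annotated_count": n,
                "ks_statistic": float(res.statistic),
                "p_value": float(res.pvalue),
            }
        )
    table = pd.DataFrame(rows, columns=["term", "annotated_count", "ks_statistic", "p_value"])
    table = table.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
    if add_bh and len(table):
        m = len(table)
        ranked = table["p_value"].to_numpy() * m / (pd.RangeIndex(1, m + 1).to_numpy())
        # enforce monotonicity from the largest p down
        for i in range(m - 2, -1, -1):
            ranked[i] = min(ranked[i], ranked[i + 1])
        table["bh_q"] = ranked.clip(max=1.0)
    table.attrs["skipped_terms"] = skipped
    return table


def top_significant_genes(
    result: pd.DataFrame,
    annotation: GeneAnnotation,
    k_terms: int = 10,
) -> set[str]:
    """Union of genes annotated to the ``k_terms`` most significant terms.

    Terms tied in p-value with the k-th term are all included. When
    fewer than ``k_terms`` terms exist, every term is used.
    """
    if result.empty:
        raise ValidationError("enrichment result is empty")
    ordered = result.sort_values(["p_value", "term"], kind="stable")
    if k_terms >= len(ordered):
        chosen = ordered
    else:
        cutoff = ordered["p_value"].iloc[k_terms - 1]
        chosen = ordered[ordered["p_value"] <= cutoff]
    term_genes = annotation.term_to_genes()
    genes: set[str] = set()
    for term in chosen["term"]:
        genes |= term_genes.get(term, set())
    return genes
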