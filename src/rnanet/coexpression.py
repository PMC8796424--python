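"""Weighted gene co-expression network construction and module detection.

The network is built from a genes x samples expression matrix in the
usual weighted-correlation-network sequence:

1. similarity ``s_ij = |cor(x_i, x_j)|`` (Pearson by default, biweight
   midcorrelation optionally);
2. soft-threshold selection: the smallest power ``beta`` whose
   thresholded network ``a_ij = s_ij**beta`` approximates scale-free
   topology (log-log degree-distribution fit R^2 above a cutoff);
3. topological overlap ``omega_ij`` measuring shared weighted
   neighborhoods, and its dissimilarity ``d_ij = 1 - omega_ij``;
4. average-linkage hierarchical clustering of ``d`` with a static tree
   cut, small clusters left unassigned (label 0);
5. module eigengenes (first principal component of each module's
   standardized expression) and merging of modules whose eigengenes are
   highly correlated.

:class:`CoexpressionAnalysis` bundles the sequence as a model object
whose :meth:`~CoexpressionAnalysis.fit` returns a
:class:`CoexpressionResult` carrying every intermediate matrix plus a
``summary()`` table; the standalone functions remain the primitive API.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError

__all__ = [
    "CoexpressionParams",
    "CoexpressionAnalysis",
    "CoexpressionResult",
    "ModulePartition",
    "EigengeneSet",
    "SoftThresholdResult",
    "similarity_matrix",
    "bicor",
    "bicor_matrix",
    "pick_soft_threshold",
    "adjacency_matrix",
    "topological_overlap",
    "detect_modules",
    "module_eigengenes",
    "merge_similar_modules",
    "tom_plot_data",
]


@dataclass
class CoexpressionParams:
    """Tunable knobs of network construction.

    ``rsq_cutoff`` is the minimum scale-free fit R^2 a candidate power
    must reach; ``tree_cut_height`` is the static dissimilarity height at
    which the gene dendrogram is cut (branches joining above it stay
    separate); ``merge_cut_height`` merges modules whose eigengene
    dissimilarity (1 - correlation) falls below it.
    """

    correlation_kind: str = "pearson"
    candidate_powers: tuple = tuple(range(1, 21))
    rsq_cutoff: float = 0.85
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    tree_cut_height: float = 0.98
    degree_bins: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.rsq_cutoff <= 1.0:
            raise ValidationError("rsq_cutoff must lie in (0, 1]")
        if not 0.0 <= self.merge_cut_height <= 1.0:
            raise ValidationError("merge_cut_height must lie in [0, 1]")
        if list(self.candidate_powers) != sorted(self.candidate_powers):
            raise ValidationError("candidate_powers must be sorted ascending")
        if self.correlation_kind not in ("pearson", "bicor"):
            raise ValidationError("correlation_kind must be 'pearson' or 'bicor'")


@dataclass
class ModulePartition:
    """Gene -> module assignment; label 0 means unassigned."""

    assignment: pd.Series  # index: gene ids, values: int labels
    linkage_matrix: np.ndarray | None = None
    cut_height: float | None = None

    @property
    def sizes(self) -> pd.Series:
        labels = self.assignment[self.assignment != 0]
        return labels.value_counts().sort_index()

    def genes_in(self, label: int) -> list[str]:
        return self.assignment.index[self.assignment == label].tolist()

    @property
    def labels(self) -> list[int]:
        return sorted(set(self.assignment) - {0})


@dataclass
class EigengeneSet:
    """Per-module first principal component across samples (unit norm)."""

    eigengenes: pd.DataFrame  # samples x modules, columns "ME<label>"
    variance_explained: pd.Series  # index: module label
    flagged_singletons: list[int] = field(default_factory=list)


@dataclass
class SoftThresholdResult:
    power: float
    table: pd.DataFrame  # per candidate: power, r_squared, slope, mean_connectivity
    reached_cutoff: bool


def _check_gene_variance(x: np.ndarray, genes) -> None:
    sd = x.std(axis=1)
    bad = np.asarray(genes)[sd == 0]
    if bad.size:
        raise ValidationError(f"zero-variance gene(s) reached network construction: {bad[:5].tolist()}")


def similarity_matrix(expr: pd.DataFrame, kind: str = "pearson") -> pd.DataFrame:
    """Unsigned similarity ``s_ij = |cor(x_i, x_j)|`` between gene profiles."""
    if expr.shape[1] < 3:
        raise ValidationError("need at least 3 samples for correlation networks")
    x = expr.to_numpy(dtype=float)
    _check_gene_variance(x, expr.index)
    if kind == "pearson":
        c = np.corrcoef(x)
    elif kind == "bicor":
        c = bicor_matrix(expr).to_numpy()
    else:
        raise ValidationError(f"unknown correlation kind {kind!r}")
    s = np.abs(c)
    np.clip(s, 0.0, 1.0, out=s)
    np.fill_diagonal(s, 1.0)
    return pd.DataFrame(s, index=expr.index, columns=expr.index)


def _bicor_transform(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise biweight transform; returns (normalized rows, MAD-zero mask)."""
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    mad_zero = (mad == 0).ravel()
    safe_mad = np.where(mad == 0, 1.0, mad)
    u = (x - med) / (9.0 * safe_mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    xt = (x - med) * w
    norm = np.sqrt(np.sum(xt**2, axis=1, keepdims=True))
    norm = np.where(norm == 0, 1.0, norm)
    return xt / norm, mad_zero


def _pearson_rows(x: np.ndarray) -> np.ndarray:
    z = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt(np.sum(z**2, axis=1, keepdims=True))
    norm = np.where(norm == 0, 1.0, norm)
    return z / norm


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors.

    Values are standardized by median and MAD; Tukey biweights vanish
    beyond 9 MADs, so isolated gross outliers get zero weight. When
    either vector has MAD 0 the pair falls back to Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("bicor needs two equal-length vectors of length >= 3")
    stacked = np.vstack([x, y])
    xt, mad_zero = _bicor_transform(stacked)
    if mad_zero.any():
        z = _pearson_rows(stacked)
        return float(np.clip(z[0] @ z[1], -1.0, 1.0))
    return float(np.clip(xt[0] @ xt[1], -1.0, 1.0))


def bicor_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise biweight midcorrelation of all gene profiles.

    Pairs involving a MAD-zero gene are computed as Pearson (recorded in
    the result's ``attrs['pearson_fallback_genes']``).
    """
    x = expr.to_numpy(dtype=float)
    xt, mad_zero = _bicor_transform(x)
    c = xt @ xt.T
    if mad_zero.any():
        z = _pearson_rows(x)
        p = z @ z.T
        c[mad_zero, :] = p[mad_zero, :]
        c[:, mad_zero] = p[:, mad_zero]
    np.clip(c, -1.0, 1.0, out=c)
    np.fill_diagonal(c, 1.0)
    out = pd.DataFrame(c, index=expr.index, columns=expr.index)
    out.attrs["pearson_fallback_genes"] = expr.index[mad_zero].tolist()
    return out


def adjacency_matrix(s: pd.DataFrame, power: float) -> pd.DataFrame:
    """Soft-thresholded adjacency ``a_ij = s_ij ** power`` (diagonal 1)."""
    if power < 1:
        raise ValidationError("soft-threshold power must be >= 1")
    a = s.to_numpy(dtype=float) ** power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=s.index, columns=s.columns)


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """R^2 and slope of the log10 frequency vs log10 mean-connectivity fit."""
    if np.allclose(k, k[0]):
        raise ValidationError("degenerate fit: all connectivities identical")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k = np.array([k[idx == b].mean() if (idx == b).any() else np.nan for b in range(n_bins)])
    freq = np.array([(idx == b).sum() for b in range(n_bins)], dtype=float)
    ok = (~np.isnan(mean_k)) & (freq > 0) & (mean_k > 0)
    if ok.sum() < 2:
        raise ValidationError("degenerate fit: fewer than 2 populated connectivity bins")
    lx, ly = np.log10(mean_k[ok]), np.log10(freq[ok] / freq[ok].sum())
    slope, _ = np.polyfit(lx, ly, 1)
    r = np.corrcoef(lx, ly)[0, 1]
    return float(r**2), float(slope)


def pick_soft_threshold(
    s: pd.DataFrame, params: CoexpressionParams | None = None
) -> SoftThresholdResult:
    """Choose the soft-threshold power by scale-free topology fit.

    For each candidate power the connectivities ``k_i = sum_j a_ij`` are
    binned and the squared correlation between log10 bin frequency and
    log10 mean bin connectivity computed; the selected power is the
    smallest whose fit reaches ``rsq_cutoff`` with a negative slope,
    otherwise the best-fitting candidate (flagged via
    ``reached_cutoff=False``).
    """
    params = params or CoexpressionParams()
    sm = s.to_numpy(dtype=float)
    if sm.shape[0] < 20:
        import warnings

        warnings.warn("fewer than 20 genes: scale-free fit is unreliable", stacklevel=2)
    rows = []
    for power in params.candidate_powers:
        a = sm**power
        k = a.sum(axis=1) - np.diag(a)
        r2, slope = _scale_free_fit(k, params.degree_bins)
        rows.append(
            {"power": power, "r_squared": r2, "slope": slope, "mean_connectivity": float(k.mean())}
        )
    table = pd.DataFrame(rows)
    eligible = table[(table.r_squared >= params.rsq_cutoff) & (table.slope < 0)]
    if len(eligible):
        chosen = float(eligible.iloc[0]["power"])
        reached = True
    else:
        chosen = float(table.loc[table.r_squared.idxmax(), "power"])
        reached = False
    return SoftThresholdResult(power=chosen, table=table, reached_cutoff=reached)


def topological_overlap(a: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a symmetric adjacency with unit diagonal.

    ``omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` where
    ``l_ij = sum_u a_iu a_uj`` over ``u != i, j`` and ``k_i`` is the
    connectivity of node ``i``; ``omega_ii = 1``.
    """
    am = a.to_numpy(dtype=float)
    if not np.allclose(am, am.T):
        raise ValidationError("adjacency must be symmetric")
    if not np.allclose(np.diag(am), 1.0):
        raise ValidationError("adjacency must have unit diagonal")
    k = am.sum(axis=1) - 1.0
    # (A @ A)_ij includes u = i and u = j; both contribute a_ij (diag = 1)
    l = am @ am - 2.0 * am
    numer = l + am
    denom = np.minimum.outer(k, k) + 1.0 - am
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(omega, 1.0)
    omega = np.clip(omega, 0.0, 1.0)
    return pd.DataFrame(omega, index=a.index, columns=a.columns)


def _relabel_by_size(labels: np.ndarray, min_size: int, genes) -> pd.Series:
    """Drop clusters below ``min_size`` to 0 and rank the rest by size."""
    series = pd.Series(labels, index=genes)
    counts = series.value_counts()
    keep = counts[counts >= min_size].index
    series[~series.isin(keep)] = 0
    # stable ordering: size descending, then first-occurrence index
    order = sorted(
        (lab for lab in series.unique() if lab != 0),
        key=lambda lab: (-(series == lab).sum(), np.argmax((series == lab).to_numpy())),
    )
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    remap[0] = 0
    return series.map(remap).astype(int)


def detect_modules(
    d: pd.DataFrame, params: CoexpressionParams | None = None
) -> ModulePartition:
    """Average-linkage clustering of TOM dissimilarity with a static cut.

    The dendrogram is cut at the fixed dissimilarity height
    ``tree_cut_height``; clusters smaller than ``min_module_size`` are
    relabeled 0 (unassigned) and the rest numbered by decreasing size.
    """
    params = params or CoexpressionParams()
    dm = d.to_numpy(dtype=float)
    condensed = squareform((dm + dm.T) / 2.0, checks=False)
    z = linkage(condensed, method="average")
    cut = float(params.tree_cut_height)
    labels = fcluster(z, t=cut, criterion="distance")
    assignment = _relabel_by_size(labels, params.min_module_size, d.index)
    return ModulePartition(assignment=assignment, linkage_matrix=z, cut_height=cut)


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def module_eigengenes(expr: pd.DataFrame, partition: ModulePartition) -> EigengeneSet:
    """First principal component of each module's standardized expression.

    Gene profiles are z-scored across samples; the eigengene is the
    leading right-singular vector over samples (unit norm), its sign
    fixed so it correlates non-negatively with the module's mean profile.
    ``variance_explained`` is the leading singular value's share of the
    total variance in the module.
    """
    eigs: dict[str, np.ndarray] = {}
    var_exp: dict[int, float] = {}
    singletons: list[int] = []
    for label in partition.labels:
        genes = partition.genes_in(label)
        x = _zscore_rows(expr.loc[genes].to_numpy(dtype=float))
        if x.shape[0] == 1:
            v = x[0] / np.linalg.norm(x[0])
            var_exp[label] = 1.0
            singletons.append(label)
        else:
            _, s, vt = np.linalg.svd(x, full_matrices=False)
            v = vt[0]
            var_exp[label] = float(s[0] ** 2 / np.sum(s**2))
        mean_profile = x.mean(axis=0)
        if float(v @ mean_profile) < 0:
            v = -v
        eigs[f"ME{label}"] = v
    frame = pd.DataFrame(eigs, index=expr.columns)
    return EigengeneSet(
        eigengenes=frame,
        variance_explained=pd.Series(var_exp, dtype=float),
        flagged_singletons=singletons,
    )


def merge_similar_modules(
    expr: pd.DataFrame,
    partition: ModulePartition,
    eigengenes: EigengeneSet,
    merge_cut_height: float = 0.25,
) -> tuple[ModulePartition, EigengeneSet]:
    """Merge modules whose eigengenes are highly correlated.

    Eigengene dissimilarity ``1 - cor(E_p, E_q)`` is clustered with
    average linkage; branches below ``merge_cut_height`` merge and
    eigengenes are recomputed, iterating until stable.
    """
    assignment = partition.assignment.copy()
    eig = eigengenes
    while True:
        labels = sorted(set(assignment) - {0})
        if len(labels) <= 1 or merge_cut_height <= 0:
            break
        e = eig.eigengenes[[f"ME{lab}" for lab in labels]].to_numpy().T
        diss = 1.0 - np.corrcoef(e)
        np.fill_diagonal(diss, 0.0)
        diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
        z = linkage(squareform(diss, checks=False), method="average")
        groups = fcluster(z, t=merge_cut_height, criterion="distance")
        if len(set(groups)) == len(labels):
            break
        for group in set(groups):
            members = [lab for lab, g in zip(labels, groups) if g == group]
            target = members[0]
            for lab in members[1:]:
                assignment[assignment == lab] = target
        # renumber by size after merging
        part = ModulePartition(
            assignment=_relabel_by_size(assignment.to_numpy(), 1, assignment.index),
            linkage_matrix=partition.linkage_matrix,
            cut_height=partition.cut_height,
        )
        assignment = part.assignment
        eig = module_eigengenes(expr, part)
    final = ModulePartition(
        assignment=assignment,
        linkage_matrix=partition.linkage_matrix,
        cut_height=partition.cut_height,
    )
    return final, module_eigengenes(expr, final)


def tom_plot_data(
    d: pd.DataFrame, partition: ModulePartition
) -> tuple[pd.DataFrame, list[str], pd.Series]:
    """Dissimilarity matrix in dendrogram leaf order plus the module band."""
    if partition.linkage_matrix is None:
        order_idx = np.argsort(partition.assignment.to_numpy(), kind="stable")
    else:
        order_idx = leaves_list(partition.linkage_matrix)
    order = [d.index[i] for i in order_idx]
    ordered = d.loc[order, order]
    band = partition.assignment.loc[order]
    return ordered, order, band


class CoexpressionAnalysis:
    """Co-expression network model over a genes x samples matrix.

    Parameters
    ----------
    expr
        Filtered, normalized expression (typically log-CPM), genes as
        rows. Zero-variance genes must already be removed.
    params
        Network construction knobs; see :class:`CoexpressionParams`.
    """

    def __init__(self, expr: pd.DataFrame, params: CoexpressionParams | None = None):
        self.expr = expr
        self.params = params or CoexpressionParams()

    @classmethod
    def from_dataframe(cls, expr: pd.DataFrame, **kwargs) -> "CoexpressionAnalysis":
        return cls(expr, CoexpressionParams(**kwargs))

    def fit(self, power: float | None = None) -> "CoexpressionResult":
        """Run the full construction sequence and return the results.

        ``power`` overrides soft-threshold selection when given.
        """
        p = self.params
        s = similarity_matrix(self.expr, kind=p.correlation_kind)
        if power is None:
            soft = pick_soft_threshold(s, p)
        else:
            soft = SoftThresholdResult(power=float(power), table=pd.DataFrame(), reached_cutoff=True)
        a = adjacency_matrix(s, soft.power)
        omega = topological_overlap(a)
        d = 1.0 - omega
        np.fill_diagonal(d.values, 0.0)
        partition = detect_modules(d, p)
        eig = (
            module_eigengenes(self.expr, partition)
            if partition.labels
            else EigengeneSet(pd.DataFrame(index=self.expr.columns), pd.Series(dtype=float))
        )
        if partition.labels:
            partition, eig = merge_similar_modules(self.expr, partition, eig, p.merge_cut_height)
        return CoexpressionResult(
            model=self,
            similarity=s,
            soft_threshold=soft,
            adjacency=a,
            tom=omega,
            dissimilarity=d,
            partition=partition,
            eigengenes=eig,
        )


@dataclass
class CoexpressionResult:
    """Fitted co-expression network: matrices, modules, and eigengenes."""

    model: CoexpressionAnalysis
    similarity: pd.DataFrame
    soft_threshold: SoftThresholdResult
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    dissimilarity: pd.DataFrame
    partition: ModulePartition
    eigengenes: EigengeneSet

    @property
    def connectivity(self) -> pd.Series:
        a = self.adjacency.to_numpy()
        return pd.Series(a.sum(axis=1) - np.diag(a), index=self.adjacency.index, name="k")

    def summary(self) -> pd.DataFrame:
        """One row per module: size, variance explained by the eigengene,
        and mean intramodular connectivity."""
        rows = []
        for label in self.partition.labels:
            genes = self.partition.genes_in(label)
            rows.append(
                {
                    "module": label,
                    "n_genes": len(genes),
                    "variance_explained": self.eigengenes.variance_explained.get(label, np.nan),
                    "mean_connectivity": float(self.connectivity.loc[genes].mean()),
                }
            )
        n_unassigned = int((self.partition.assignment == 0).sum())
        frame = pd.DataFrame(
            rows, columns=["module", "n_genes", "variance_explained", "mean_connectivity"]
        )
        frame.attrs["power"] = self.soft_threshold.power
        frame.attrs["n_unassigned"] = n_unassigned
        return frame
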