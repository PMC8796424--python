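"""Count normalization and sample-level diagnostics.

Implements the standard pre-network steps on a gene x sample count
matrix: counts-per-million (CPM) and log2-CPM scaling, low-expression
filtering, trimmed-mean-of-M-values (TMM) normalization factors
(Robinson & Oshlack's weighted trimmed mean of log expression ratios),
Euclidean sample clustering, PCA coordinates, and UpSet-style exclusive
intersection counts for comparing DEG sets between pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .errors import ValidationError

__all__ = [
    "NormalizationResult",
    "FilterSpec",
    "compute_cpm",
    "filter_genes",
    "tmm_factors",
    "sample_distance_tree",
    "pca_coordinates",
    "deg_set_intersections",
]


@dataclass
class NormalizationResult:
    cpm: pd.DataFrame
    log_cpm: pd.DataFrame
    tmm_factors: pd.Series | None = None
    effective_library_sizes: pd.Series | None = None


@dataclass
class FilterSpec:
    """Low-expression filter: keep genes with CPM >= ``min_cpm`` in at
    least ``min_samples`` samples and a missing-value (NaN) fraction at
    most ``max_missing_fraction``."""

    min_cpm: float = 1.0
    min_samples: int = 2
    max_missing_fraction: float = 1.0

    def validate(self, n_samples: int) -> None:
        if self.min_samples > n_samples:
            raise ValidationError(
                f"min_samples={self.min_samples} exceeds sample count {n_samples}"
            )
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValidationError("max_missing_fraction must lie in [0, 1]")


def _library_sizes(expr: pd.DataFrame) -> pd.Series:
    lib = expr.sum(axis=0)
    zero = lib.index[lib <= 0].tolist()
    if zero:
        raise ValidationError(f"zero-count sample(s): {zero}")
    return lib


def compute_cpm(expr: pd.DataFrame, prior_count: float = 0.5) -> NormalizationResult:
    """Counts per million and log2-CPM with a small prior offset.

    ``cpm(g, s) = 1e6 * count(g, s) / libsize(s)``;
    ``log_cpm = log2(cpm + prior_count)``.
    """
    lib = _library_sizes(expr)
    cpm = expr.div(lib, axis=1) * 1e6
    log_cpm = np.log2(cpm + prior_count)
    return NormalizationResult(cpm=cpm, log_cpm=log_cpm, effective_library_sizes=lib)


def filter_genes(
    expr: pd.DataFrame, spec: FilterSpec
) -> tuple[pd.DataFrame, list[str], bool]:
    """Remove lowly expressed genes.

    Returns ``(kept matrix, removed gene ids, emptied flag)``; the flag
    is set when no gene survives (allowed, but worth warning about).
    """
    spec.validate(expr.shape[1])
    lib = _library_sizes(expr.fillna(0.0))
    cpm = expr.div(lib, axis=1) * 1e6
    expressed = (cpm >= spec.min_cpm).sum(axis=1) >= spec.min_samples
    missing_ok = expr.isna().mean(axis=1) <= spec.max_missing_fraction
    keep = expressed & missing_ok
    removed = expr.index[~keep].tolist()
    kept = expr.loc[keep]
    return kept, removed, kept.empty


def _quantile_factor(counts: np.ndarray, lib: float, q: float = 0.75) -> float:
    return float(np.quantile(counts, q) / lib)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    weight_mode: str = "relative",
) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference.

    Genes with zero counts in either sample are excluded; the M-values
    (log2 relative-abundance ratios) are trimmed 30% at each end and the
    A-values (mean log2 abundance) 5%; the surviving M-values are
    averaged with inverse asymptotic-variance weights.

    ``weight_mode='relative'`` computes each side's variance per read,
    ``(1 - p) / p`` on relative abundances, making the factors exactly
    invariant to sequencing depth; ``'binomial'`` uses the raw binomial
    variance ``(N - y) / (N y)``, whose obs-side term shrinks with depth.
    """
    positive = (obs > 0) & (ref > 0)
    obs, ref = obs[positive].astype(float), ref[positive].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    if weight_mode == "relative":
        v = (1.0 - p_obs) / p_obs + (1.0 - p_ref) / p_ref
    elif weight_mode == "binomial":
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    else:
        raise ValidationError(f"unknown weight_mode {weight_mode!r}")
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n + 1 - (np.floor(n * sum_trim) + 1)
    rank_m, rank_a = rankdata(m), rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(expr: pd.DataFrame, weight_mode: str = "relative") -> pd.Series:
    """TMM normalization factor per sample, rescaled to geometric mean 1.

    The reference sample is the one whose 75th-percentile relative
    abundance is closest to the mean of those percentiles across samples.
    With the default per-read weighting the factors are invariant to
    rescaling any sample's counts by a positive constant
    (sequencing-depth invariance); ``weight_mode='binomial'`` reproduces
    the raw binomial-variance weighting instead (see :func:`_tmm_pair`).
    """
    if expr.shape[1] < 2:
        raise ValidationError("TMM requires at least 2 samples")
    lib = _library_sizes(expr)
    counts = expr.to_numpy(dtype=float)
    f75 = np.array(
        [_quantile_factor(counts[:, j], lib.iloc[j]) for j in range(counts.shape[1])]
    )
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(
                counts[:, j], counts[:, ref_idx], lib.iloc[j], lib.iloc[ref_idx],
                weight_mode=weight_mode,
            )
            for j in range(counts.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=expr.columns, name="tmm_factor")


def sample_distance_tree(log_expr: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Euclidean distances between sample columns plus an average-linkage tree.

    Returns the symmetric sample x sample distance matrix and a scipy
    linkage matrix whose merge heights are non-decreasing.
    """
    if log_expr.shape[1] < 2:
        raise ValidationError("need at least 2 samples to cluster")
    d = pdist(log_expr.T.to_numpy(), metric="euclidean")
    dm = pd.DataFrame(squareform(d), index=log_expr.columns, columns=log_expr.columns)
    z = linkage(d, method="average")
    return dm, z


def pca_coordinates(
    log_expr: pd.DataFrame, k: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component coordinates of the samples.

    Samples are observations, genes features; the gene dimension is
    mean-centered and the top ``k`` axes extracted by SVD. Returns the
    samples x k coordinate table and the fraction of variance captured by
    each axis (non-increasing, summing to at most 1).
    """
    n_samples, n_genes = log_expr.shape[1], log_expr.shape[0]
    if k > min(n_genes, n_samples):
        raise ValidationError(f"k={k} exceeds min(genes, samples)={min(n_genes, n_samples)}")
    x = log_expr.T.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0.0:  # identical samples
        coords = np.zeros((n_samples, k))
        fractions = np.zeros(k)
    else:
        coords = u[:, :k] * s[:k]
        fractions = (s[:k] ** 2) / total
    table = pd.DataFrame(
        coords, index=log_expr.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return table, fractions


def deg_set_intersections(sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive intersection sizes over every non-empty combination.

    UpSet semantics: a gene counts toward exactly the combination of set
    names that contain it, so the counts sum to the size of the union.
    """
    if not sets:
        raise ValidationError("need at least one set")
    names = list(sets)
    tally: dict[frozenset, int] = {}
    for gene in set().union(*sets.values()):
        pattern = frozenset(n for n in names if gene in sets[n])
        tally[pattern] = tally.get(pattern, 0) + 1
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            rows.append(
                {
                    "sets": "&".join(combo),
                    "degree": r,
                    "count": tally.get(frozenset(combo), 0),
                }
            )
    return pd.DataFrame(rows)
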