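"""Quantification I/O: count matrices, abundance tables, DE tables, DREM inputs.

Count matrices are genes x samples :class:`pandas.DataFrame` objects with
gene identifiers as the index and sample identifiers as columns — the
substrate of every downstream stage. Per-sample abundance tables follow
the pseudo-aligner convention (columns ``target_id``, ``length``,
``eff_length``, ``est_counts``, ``tpm``), one subdirectory per sample.

Transcript-level abundances are aggregated to gene level by summing
estimated counts over each gene's transcript models; transcripts missing
from the mapping fall back to stripping a trailing ``.<integer>`` isoform
suffix (Arabidopsis-style gene models) and are otherwise reported in a
rejects table, never silently dropped.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_abundance_dir",
    "read_transcript2gene",
    "aggregate_to_genes",
    "AggregationResult",
    "read_deg_table",
    "write_drem_inputs",
    "edit_drem_defaults",
]

_ABUNDANCE_COLUMNS = ("target_id", "length", "eff_length", "est_counts", "tpm")
_ISOFORM_SUFFIX = re.compile(r"\.\d+$")

# column dialects of the two supported differential-expression tools
_DEG_DIALECTS = {
    "sleuth": {"id": "target_id", "effect": "b", "p": "pval", "q": "qval", "mean": "mean_obs"},
    "edger": {"id": "gene_id", "effect": "logFC", "p": "PValue", "q": "FDR", "mean": "logCPM"},
}


def read_count_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a tab-separated gene x sample count matrix.

    First column holds gene identifiers, header row holds sample
    identifiers; sample order is preserved.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"count matrix {path} is empty") from exc
    if df.empty and df.columns.empty:
        raise ParseError(f"count matrix {path} has no samples")
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate gene id(s) in count matrix: {dupes}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][:1].tolist()
            raise ParseError(
                f"non-numeric cell in count matrix at gene {bad[0]!r}, sample {col!r}"
            )
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df


def write_count_matrix(expr: pd.DataFrame, path: str | os.PathLike) -> Path:
    path = Path(path)
    out = expr.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    return path


def _validate_abundance(df: pd.DataFrame, sample: str) -> pd.DataFrame:
    missing = [c for c in _ABUNDANCE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"abundance table for sample {sample!r} lacks column(s) {missing}")
    if df["target_id"].duplicated().any():
        dupes = df["target_id"][df["target_id"].duplicated()].tolist()
        raise ValidationError(f"sample {sample!r}: duplicate target_id(s) {dupes[:3]}")
    for col in ("est_counts", "tpm"):
        if (df[col] < 0).any():
            bad = df.loc[df[col] < 0, "target_id"].iloc[0]
            raise ValidationError(f"sample {sample!r}: negative {col} for {bad!r}")
    return df


def read_abundance_dir(root: str | os.PathLike) -> dict[str, pd.DataFrame]:
    """Read one abundance table per sample subdirectory of ``root``.

    Sample identifiers are the subdirectory names (the quantifier creates
    one directory per sample). Each directory must contain exactly one
    ``abundance.tsv``.
    """
    root = Path(root)
    samples = sorted(p for p in root.iterdir() if p.is_dir())
    if not samples:
        raise IOError(f"no sample subdirectories under {root}")
    out: dict[str, pd.DataFrame] = {}
    for sample_dir in samples:
        table = sample_dir / "abundance.tsv"
        if not table.exists():
            raise IOError(f"sample directory {sample_dir.name!r} lacks an abundance.tsv")
        df = pd.read_csv(table, sep="\t")
        out[sample_dir.name] = _validate_abundance(df, sample_dir.name)
    return out


def read_transcript2gene(path: str | os.PathLike) -> dict[str, str]:
    """Read a 2-column transcript_id -> gene_id table (tab-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"transcript-to-gene table {path} needs 2 columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


@dataclass
class AggregationResult:
    """Gene-level matrix plus the transcripts that could not be resolved.

    Mass is conserved per sample: summed estimated counts in the input
    equal the matrix column sum plus the rejected counts.
    """

    matrix: pd.DataFrame
    rejects: pd.DataFrame  # columns: sample_id, target_id, est_counts


def aggregate_to_genes(
    tables: dict[str, pd.DataFrame], t2g: dict[str, str]
) -> AggregationResult:
    """Sum transcript-level estimated counts to gene level.

    A transcript absent from ``t2g`` is retried with its trailing
    ``.<integer>`` suffix stripped; if still unresolved it is listed in
    the rejects report and excluded from the matrix.
    """
    per_sample: dict[str, dict[str, float]] = {}
    rejects: list[tuple[str, str, float]] = []
    for sample, df in tables.items():
        sums: dict[str, float] = {}
        for target, counts in zip(df["target_id"], df["est_counts"]):
            gene = t2g.get(target)
            if gene is None:
                stripped = _ISOFORM_SUFFIX.sub("", target)
                gene = t2g.get(stripped)
                if gene is None and stripped != target:
                    # dot-suffix convention: the stripped id IS the gene id
                    gene = stripped
            if gene is None:
                rejects.append((sample, target, float(counts)))
                continue
            sums[gene] = sums.get(gene, 0.0) + float(counts)
        per_sample[sample] = sums
    matrix = pd.DataFrame(per_sample).fillna(0.0)
    matrix = matrix[list(tables)]  # preserve sample order
    matrix.index.name = "gene_id"
    matrix.sort_index(inplace=True)
    rejects_df = pd.DataFrame(rejects, columns=["sample_id", "target_id", "est_counts"])
    return AggregationResult(matrix=matrix, rejects=rejects_df)


def read_deg_table(path: str | os.PathLike, source: str) -> pd.DataFrame:
    """Read a differential-expression result table in a tool dialect.

    ``source='sleuth'`` maps the beta coefficient column ``b`` to
    ``effect`` and ``qval`` to ``q_value``; ``source='edger'`` maps
    ``logFC`` and ``FDR``. The result is a unified table indexed by
    gene/transcript id with columns ``effect``, ``p_value``, ``q_value``,
    ``mean_count``; regulation direction is the sign of ``effect``.
    """
    if source not in _DEG_DIALECTS:
        raise ValueError(f"source must be one of {sorted(_DEG_DIALECTS)}, got {source!r}")
    dialect = _DEG_DIALECTS[source]
    df = pd.read_csv(path, sep="\t")
    required = [dialect["id"], dialect["effect"], dialect["p"], dialect["q"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{source} table {path} lacks column(s) {missing}; expected headers {required}"
        )
    out = pd.DataFrame(
        {
            "effect": pd.to_numeric(df[dialect["effect"]], errors="coerce").to_numpy(),
            "p_value": pd.to_numeric(df[dialect["p"]], errors="coerce").to_numpy(),
            "q_value": pd.to_numeric(df[dialect["q"]], errors="coerce").to_numpy(),
        },
        index=pd.Index(df[dialect["id"]].astype(str), name="id"),
    )
    if dialect["mean"] in df.columns:
        out["mean_count"] = pd.to_numeric(df[dialect["mean"]], errors="coerce").to_numpy()
    else:
        out["mean_count"] = np.nan
    for col in ("p_value", "q_value"):
        vals = out[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError(f"{col} outside [0, 1] in {path}")
    return out


def write_drem_inputs(
    expr: pd.DataFrame,
    dm: pd.DataFrame,
    out_dir: str | os.PathLike,
    average_replicates: bool = False,
) -> list[Path]:
    """Rearrange counts into per-(genotype, condition, replicate) time series.

    Each output file is tab-separated with header ``gene`` followed by
    the ordered time labels; values are the (aggregated) counts of each
    gene at that time point. Time order follows first appearance in the
    design matrix. With ``average_replicates=True`` one file per
    (genotype, condition) holds the replicate mean.
    """
    required = {"sample_id", "genotype", "condition", "time", "replicate"}
    missing = required - set(dm.columns)
    if missing:
        raise ValidationError(f"design matrix lacks column(s) {sorted(missing)} for DREM input")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    time_order = list(dict.fromkeys(dm["time"]))

    group_cols = ["genotype", "condition"] if average_replicates else ["genotype", "condition", "replicate"]
    written: list[Path] = []
    for keys, sub in dm.groupby(group_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        columns = {}
        for t in time_order:
            sample_ids = sub.loc[sub["time"] == t, "sample_id"].tolist()
            sample_ids = [s for s in sample_ids if s in expr.columns]
            if not sample_ids:
                label = dict(zip(group_cols, keys))
                raise ValidationError(
                    f"missing time point {t!r} for {label} when writing DREM input"
                )
            block = expr[sample_ids]
            columns[t] = block.mean(axis=1) if average_replicates else block.iloc[:, 0]
            if not average_replicates and len(sample_ids) > 1:
                raise ValidationError(
                    f"multiple samples for time {t!r} within replicate group {dict(zip(group_cols, keys))}"
                )
        table = pd.DataFrame(columns)
        table.index.name = "gene"
        name = "_".join(str(k) for k in keys)
        path = out_dir / f"timeseries_{name}.tsv"
        table.to_csv(path, sep="\t")
        written.append(path)
    return written


def edit_drem_defaults(
    template_path: str | os.PathLike,
    dataset_path: str | os.PathLike,
    out_path: str | os.PathLike,
    key: str = "Expression_Data_File",
) -> Path:
    """Copy a DREM defaults file, inserting the time-series dataset path.

    Only the value of ``key`` changes; every other line is preserved
    byte-for-byte. Accepts both tab- and ``=``-separated key/value lines.
    Idempotent for a fixed ``dataset_path``.
    """
    template = Path(template_path).read_text()
    lines = template.splitlines(keepends=True)
    found = False
    out_lines = []
    for line in lines:
        stripped = line.rstrip("\r\n")
        for sep in ("\t", "="):
            if stripped.startswith(key + sep):
                newline = line[len(stripped):]
                out_lines.append(f"{key}{sep}{dataset_path}{newline}")
                found = True
                break
        else:
            out_lines.append(line)
    if not found:
        raise ParseError(f"defaults template {template_path} lacks key {key!r}")
    out_path = Path(out_path)
    out_path.write_text("".join(out_lines))
    return out_path
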