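"""Pipeline configuration, experimental design matrix, and comparison matrix.

The pipeline is driven by three small files:

* a configuration file (flat ``key=value`` or YAML) naming the analysis
  type, covariates, significance level, paths, and quantifier flags;
* a design matrix (DM): one row per sample with its path and the
  experimental covariates (genotype, condition, time, replicate, ...);
* a differential-expression comparison matrix (DGECM): one row per
  two-group comparison, each group given as semicolon-separated sample
  identifiers drawn from the DM.

A comparison row selects samples by the union ("logical or") of the
identifiers listed in each group cell.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError

__all__ = [
    "PipelineConfig",
    "ComparisonSpec",
    "load_config",
    "load_design_matrix",
    "write_design_matrix",
    "load_dgecm",
    "resolve_comparisons",
    "build_directory_tree",
    "OUTPUT_COMPONENTS",
]

#: Subdirectories of the output tree, one per pipeline component.
OUTPUT_COMPONENTS = ("drem", "edger", "kallisto", "network_analysis", "sleuth", "wgcna")

_MANDATORY_KEYS = (
    "analysis_type",
    "covariates",
    "dgecm_path",
    "design_matrix_path",
    "significance_level",
    "read_dir",
    "output_dir",
    "reference_path",
    "run_kallisto",
    "run_star",
    "analysis_level",
)

_ANALYSIS_LEVELS = ("transcript", "gene", "both")

_TRUTHY = {"true", "yes", "1", "t", "y"}
_FALSY = {"false", "no", "0", "f", "n"}


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration.

    ``extras`` preserves any key not in the mandatory set so that
    downstream stages (e.g. regulatory-network thresholds, annotation
    paths) can be configured from the same file.
    """

    analysis_type: str
    covariates: list[str]
    dgecm_path: str
    design_matrix_path: str
    significance_level: float
    read_dir: str
    output_dir: str
    reference_path: str
    run_kallisto: bool
    run_star: bool
    analysis_level: str
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.significance_level < 1.0:
            raise ValidationError(
                f"significance_level must lie in (0, 1), got {self.significance_level}"
            )
        if self.analysis_level not in _ANALYSIS_LEVELS:
            raise ValidationError(
                f"analysis_level must be one of {_ANALYSIS_LEVELS}, got {self.analysis_level!r}"
            )
        for key in ("dgecm_path", "design_matrix_path", "read_dir", "output_dir", "reference_path"):
            if not str(getattr(self, key)).strip():
                raise ValidationError(f"configuration path {key!r} is empty")


@dataclass(frozen=True)
class ComparisonSpec:
    """One resolved DGECM row: two disjoint, non-empty sample groups."""

    comparison_id: str
    reference_samples: tuple[str, ...]
    treatment_samples: tuple[str, ...]


def _coerce_bool(value, key: str) -> bool:
    if isinstance(value, bool):
        return value
    token = str(value).strip().lower()
    if token in _TRUTHY:
        return True
    if token in _FALSY:
        return False
    raise ConfigurationError(f"cannot interpret {value!r} as a boolean for key {key!r}")


def _parse_flat(text: str) -> dict:
    out: dict = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(f"expected key=value, got line {line!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Parse a configuration file in flat ``key=value`` or YAML dialect.

    Raises
    ------
    ConfigurationError
        If a mandatory key is missing or a flag cannot be interpreted.
    ValidationError
        If ``significance_level`` lies outside (0, 1) or a path is empty.
    """
    text = Path(path).read_text()
    raw: dict | None
    try:
        loaded = yaml.safe_load(text)
        raw = loaded if isinstance(loaded, dict) else None
    except yaml.YAMLError:
        raw = None
    if raw is None:
        raw = _parse_flat(text)

    missing = [k for k in _MANDATORY_KEYS if k not in raw]
    if missing:
        raise ConfigurationError(f"missing mandatory configuration key(s): {', '.join(missing)}")

    covariates = raw["covariates"]
    if isinstance(covariates, str):
        covariates = [c.strip() for c in covariates.replace(";", ",").split(",") if c.strip()]

    try:
        significance = float(raw["significance_level"])
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"significance_level is not numeric: {raw['significance_level']!r}") from exc

    extras = {k: v for k, v in raw.items() if k not in _MANDATORY_KEYS}
    return PipelineConfig(
        analysis_type=str(raw["analysis_type"]),
        covariates=list(covariates),
        dgecm_path=str(raw["dgecm_path"]),
        design_matrix_path=str(raw["design_matrix_path"]),
        significance_level=significance,
        read_dir=str(raw["read_dir"]),
        output_dir=str(raw["output_dir"]),
        reference_path=str(raw["reference_path"]),
        run_kallisto=_coerce_bool(raw["run_kallisto"], "run_kallisto"),
        run_star=_coerce_bool(raw["run_star"], "run_star"),
        analysis_level=str(raw["analysis_level"]),
        extras=extras,
    )


def build_directory_tree(output_dir: str | os.PathLike) -> dict[str, Path]:
    """Create the six component subdirectories under ``output_dir``.

    Idempotent: re-running on a populated tree changes nothing and
    returns the same mapping.
    """
    root = Path(output_dir)
    try:
        root.mkdir(parents=True, exist_ok=True)
        tree = {}
        for name in OUTPUT_COMPONENTS:
            sub = root / name
            sub.mkdir(exist_ok=True)
            tree[name] = sub
    except OSError as exc:
        raise OSError(f"cannot create output tree under {root}: {exc}") from exc
    return tree


def load_design_matrix(path: str | os.PathLike, covariates: list[str] | None = None) -> pd.DataFrame:
    """Read a tab-separated design matrix (first column ``sample_id``)."""
    dm = pd.read_csv(path, sep="\t", dtype=str)
    if dm.columns[0] != "sample_id":
        raise ValidationError(
            f"design matrix must start with a 'sample_id' column, found {dm.columns[0]!r}"
        )
    dupes = dm["sample_id"][dm["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate sample_id(s) in design matrix: {dupes}")
    if covariates:
        absent = [c for c in covariates if c not in dm.columns]
        if absent:
            raise ValidationError(f"covariate column(s) missing from design matrix: {absent}")
    return dm


def write_design_matrix(dm: pd.DataFrame, path: str | os.PathLike) -> Path:
    path = Path(path)
    dm.to_csv(path, sep="\t", index=False)
    return path


def load_dgecm(path: str | os.PathLike) -> pd.DataFrame:
    """Read a tab-separated DGECM with header comparison_id, reference, treatment."""
    dgecm = pd.read_csv(path, sep="\t", dtype=str)
    required = {"comparison_id", "reference", "treatment"}
    if not required.issubset(dgecm.columns):
        raise ValidationError(
            f"DGECM must have columns {sorted(required)}, found {list(dgecm.columns)}"
        )
    return dgecm


def resolve_comparisons(dm: pd.DataFrame, dgecm: pd.DataFrame) -> list[ComparisonSpec]:
    """Resolve each DGECM row against the design matrix.

    Group membership is the union of the semicolon-separated sample
    identifiers in the cell. Order-preserving over rows and
    deterministic.

    Raises
    ------
    ValidationError
        Naming the row and token for any identifier absent from the DM,
        overlapping groups, or an empty group.
    """
    known = set(dm["sample_id"])
    specs: list[ComparisonSpec] = []
    for row_number, row in enumerate(dgecm.itertuples(index=False), start=1):
        groups = {}
        for role in ("reference", "treatment"):
            tokens = [t.strip() for t in str(getattr(row, role)).split(";") if t.strip()]
            if not tokens:
                raise ValidationError(
                    f"DGECM row {row_number}: {role} group is empty"
                )
            unknown = [t for t in tokens if t not in known]
            if unknown:
                raise ValidationError(
                    f"DGECM row {row_number}: unknown sample_id(s) {unknown} in {role} group"
                )
            # union semantics with stable order, duplicates collapsed
            groups[role] = tuple(dict.fromkeys(tokens))
        overlap = set(groups["reference"]) & set(groups["treatment"])
        if overlap:
            raise ValidationError(
                f"DGECM row {row_number}: groups overlap on {sorted(overlap)}"
            )
        specs.append(
            ComparisonSpec(
                comparison_id=str(row.comparison_id),
                reference_samples=groups["reference"],
                treatment_samples=groups["treatment"],
            )
        )
    return specs
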