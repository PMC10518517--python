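"""Reading, validating and rescaling GWAS summary-statistic tables.

A summary-statistic table is tab-separated with one row per variant and ten
required columns: variant id, chromosome, position, effect allele, other
allele, effect-allele frequency (EAF), beta, SE, p-value and sample size.
Column names follow GWAS-SSF conventions by default but can be remapped.

Binary-trait effects estimated on the BOLT-LMM linear scale are converted to
log odds ratios with the case-fraction approximation

    log OR ~= beta / (mu * (1 - mu)),   SE -> SE / (mu * (1 - mu)),

where ``mu`` is the case fraction of the binary trait.  The conversion leaves
per-variant z-scores (and hence p-values) unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("bidirmr")

__all__ = [
    "VariantAssociation",
    "SummaryDataset",
    "TraitMetadata",
    "FormatError",
    "EmptyDatasetError",
    "ConfigurationError",
    "DEFAULT_COLUMNS",
    "read_summary_table",
    "dataset_from_frame",
    "convert_boltlmm_to_logor",
    "write_results_table",
    "read_results_table",
]

#: canonical column order, GWAS-SSF-like field names
DEFAULT_COLUMNS: tuple[str, ...] = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p_value",
    "n",
)

_VALID_BASES = frozenset("ACGT")

#: smallest positive normal double; replaces p == 0 so -log10(p) stays finite
TINY_P = float(np.finfo(float).tiny)


class FormatError(ValueError):
    """A required column is missing or the table is malformed."""


class EmptyDatasetError(ValueError):
    """No valid rows survived validation."""


class ConfigurationError(ValueError):
    """Trait metadata is inconsistent with the requested operation."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP-trait association row.

    ``beta`` is the per-effect-allele effect on the trait's stated scale;
    ``eaf`` the effect-allele frequency.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p_value: float
    n: float

    def validate(self) -> str | None:
        """Return a rejection reason, or None if the row satisfies all invariants."""
        if self.effect_allele not in _VALID_BASES or self.other_allele not in _VALID_BASES:
            return "invalid allele (SNP-only pipeline)"
        if self.effect_allele == self.other_allele:
            return "identical alleles"
        if not np.isfinite(self.se) or self.se <= 0:
            return "nonpositive SE"
        if not np.isfinite(self.eaf) or not (0.0 < self.eaf < 1.0):
            return "EAF outside (0,1)"
        if not np.isfinite(self.p_value) or not (0.0 < self.p_value <= 1.0):
            return "p-value outside (0,1]"
        if not np.isfinite(self.beta):
            return "non-finite beta"
        return None


@dataclass(frozen=True)
class TraitMetadata:
    """Trait descriptor attached to a summary dataset.

    scale is one of ``inverse-normal`` (rank-normalised cytokine
    concentrations), ``natural-log`` (log-transformed CRP/PCT), ``linear-boltlmm``
    (BOLT-LMM linear-scale binary trait) or ``log-odds``.
    ``case_fraction`` (mu) is required for binary traits before scale
    conversion.
    """

    trait_id: str
    trait_type: str = "continuous"  # continuous | binary
    scale: str = "inverse-normal"
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigurationError(f"unknown trait_type {self.trait_type!r}")
        if self.scale not in ("inverse-normal", "natural-log", "linear-boltlmm", "log-odds"):
            raise ConfigurationError(f"unknown scale {self.scale!r}")
        if self.case_fraction is not None and not (0.0 < self.case_fraction < 1.0):
            raise ConfigurationError("case_fraction must lie in (0,1)")


@dataclass
class SummaryDataset:
    """A trait's validated association table plus metadata.

    ``table`` is indexed by unique ``variant_id``; ``drop_log`` records every
    row removed during validation as (variant_id, reason) pairs.
    """

    meta: TraitMetadata
    table: pd.DataFrame
    drop_log: list[tuple[str, str]] = field(default_factory=list)

    @property
    def trait_id(self) -> str:
        return self.meta.trait_id

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.table.index

    def record(self, variant_id: str) -> VariantAssociation:
        row = self.table.loc[variant_id]
        return VariantAssociation(
            variant_id=variant_id,
            chromosome=str(row["chromosome"]),
            position=int(row["position"]),
            effect_allele=str(row["effect_allele"]),
            other_allele=str(row["other_allele"]),
            eaf=float(row["eaf"]),
            beta=float(row["beta"]),
            se=float(row["se"]),
            p_value=float(row["p_value"]),
            n=float(row["n"]),
        )


def _validate_frame(df: pd.DataFrame, trait_id: str) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Row-level invariant enforcement; returns (clean frame, drop log)."""
    drops: list[tuple[str, str]] = []
    df = df.copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "p_value", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["position"] = pd.to_numeric(df["position"], errors="coerce").astype("Int64")
    df["variant_id"] = df["variant_id"].astype(str)
    df["chromosome"] = df["chromosome"].astype(str)

    # p == 0 is kept but bumped to the smallest positive normal double
    zero_p = df["p_value"] == 0.0
    if zero_p.any():
        for vid in df.loc[zero_p, "variant_id"]:
            logger.warning("%s: %s p-value of 0 replaced by %.3e", trait_id, vid, TINY_P)
        df.loc[zero_p, "p_value"] = TINY_P

    keep = pd.Series(True, index=df.index)
    reasons = {}

    def mark(mask: pd.Series, reason: str) -> None:
        bad = mask & keep
        for vid in df.loc[bad, "variant_id"]:
            reasons[vid] = reason
        keep[bad] = False

    mark(~df["effect_allele"].isin(_VALID_BASES) | ~df["other_allele"].isin(_VALID_BASES),
         "invalid allele (SNP-only pipeline)")
    mark(df["effect_allele"] == df["other_allele"], "identical alleles")
    mark(~(df["se"] > 0) | ~np.isfinite(df["se"]), "nonpositive SE")
    mark(~df["eaf"].between(0, 1, inclusive="neither") | ~np.isfinite(df["eaf"]),
         "EAF outside (0,1)")
    mark(~(df["p_value"] > 0) | ~(df["p_value"] <= 1) | ~np.isfinite(df["p_value"]),
         "p-value outside (0,1]")
    mark(~np.isfinite(df["beta"]), "non-finite beta")
    mark(df["position"].isna(), "missing position")

    for vid, reason in reasons.items():
        drops.append((vid, reason))
        logger.info("%s: dropped %s (%s)", trait_id, vid, reason)

    df = df[keep]

    # duplicate variant ids: keep the smallest-p row, matching how
    # instruments are later ranked
    if df["variant_id"].duplicated().any():
        df = df.sort_values(["p_value", "variant_id"], kind="mergesort")
        dup = df["variant_id"].duplicated(keep="first")
        for vid in df.loc[dup, "variant_id"]:
            drops.append((vid, "duplicate variant_id (larger p)"))
            logger.info("%s: duplicate %s dropped (larger p)", trait_id, vid)
        df = df[~dup]

    df = df.set_index(df["variant_id"].rename(None), drop=False)
    df["position"] = df["position"].astype(int)
    return df[list(DEFAULT_COLUMNS)], drops


def dataset_from_frame(df: pd.DataFrame, meta: TraitMetadata) -> SummaryDataset:
    """Build a validated SummaryDataset from an in-memory frame."""
    missing = [c for c in DEFAULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    clean, drops = _validate_frame(df, meta.trait_id)
    if len(clean) == 0:
        raise EmptyDatasetError(f"{meta.trait_id}: no valid rows after validation")
    return SummaryDataset(meta=meta, table=clean, drop_log=drops)


def read_summary_table(
    path,
    trait_metadata: TraitMetadata,
    column_map: Mapping[str, str] | None = None,
) -> SummaryDataset:
    """Read a tab-separated GWAS summary table into a validated dataset.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    trait_metadata
        Trait descriptor (id, type, scale, case fraction).
    column_map
        Optional mapping from canonical names (``DEFAULT_COLUMNS``) to the
        file's column names, for non-GWAS-SSF dialects.

    Rows violating row-level invariants are dropped and recorded in the
    returned dataset's ``drop_log`` with a reason.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    return dataset_from_frame(df, trait_metadata)


def convert_boltlmm_to_logor(dataset: SummaryDataset) -> SummaryDataset:
    """Convert BOLT-LMM linear-scale binary-trait effects to log odds ratios.

    Divides every beta and SE by mu*(1-mu) where mu is the trait's case
    fraction; p-values are scale-free and unchanged.  Returns a new dataset
    on the ``log-odds`` scale.
    """
    meta = dataset.meta
    if meta.scale == "log-odds":
        logger.warning("%s already on log-odds scale; conversion is a no-op", meta.trait_id)
        return dataset
    if meta.trait_type != "binary" or meta.scale != "linear-boltlmm":
        raise ConfigurationError(
            f"{meta.trait_id}: conversion requires a binary linear-boltlmm trait"
        )
    if meta.case_fraction is None:
        raise ConfigurationError(f"{meta.trait_id}: case_fraction required for conversion")
    mu = meta.case_fraction
    divisor = mu * (1.0 - mu)
    table = dataset.table.copy()
    table["beta"] = table["beta"] / divisor
    table["se"] = table["se"] / divisor
    return SummaryDataset(
        meta=replace(meta, scale="log-odds"),
        table=table,
        drop_log=list(dataset.drop_log),
    )


def write_results_table(rows: Sequence[Mapping] | pd.DataFrame, path) -> None:
    """Write result rows as a tab-separated table (header always present).

    Floats are serialised with 10 significant digits so a write/read
    round-trip preserves values to that precision.
    """
    df = pd.DataFrame(rows) if not isinstance(rows, pd.DataFrame) else rows
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results_table(path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t")


def attach_run_log(path) -> logging.Handler:
    """Send the package's structured run log to ``path`` (plain text)."""
    handler = logging.FileHandler(path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s\t%(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler
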