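"""Paired expression/drug-activity panel: loading, imputation, variation filtering.

A panel couples two delimited numeric matrices over one set of tumour cell
lines: a gene (or miRNA) expression matrix of log-ratio values and a drug
activity matrix of log10(GI50) values. Missing entries are carried as NaN
until :func:`impute_missing` replaces each one with the mean of the observed
values of its feature across the panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKENS = ["", "NA", "NaN", "nan", "na", "N/A"]


class PanelLoadError(ValueError):
    """Raised when the two input tables cannot be combined into a panel."""


@dataclass
class CellLinePanel:
    """Gene-expression and drug-activity matrices over one cell-line panel.

    Rows of both matrices are aligned: row *i* of ``gene_matrix`` and of
    ``drug_matrix`` describe the cell line ``cell_ids[i]``. Missing entries
    are NaN.
    """

    cell_ids: list[str]
    gene_matrix: np.ndarray
    drug_matrix: np.ndarray
    gene_ids: list[str]
    drug_ids: list[str]

    def __post_init__(self) -> None:
        self.gene_matrix = np.asarray(self.gene_matrix, dtype=float)
        self.drug_matrix = np.asarray(self.drug_matrix, dtype=float)
        n = len(self.cell_ids)
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell ids must be unique")
        if self.gene_matrix.shape != (n, len(self.gene_ids)):
            raise ValueError("gene_matrix shape inconsistent with ids")
        if self.drug_matrix.shape != (n, len(self.drug_ids)):
            raise ValueError("drug_matrix shape inconsistent with ids")
        if len(self.gene_ids) < 1 or len(self.drug_ids) < 1:
            raise ValueError("panel needs at least one gene and one drug")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def gene_missing_mask(self) -> np.ndarray:
        return np.isnan(self.gene_matrix)

    @property
    def drug_missing_mask(self) -> np.ndarray:
        return np.isnan(self.drug_matrix)

    @property
    def joint_matrix(self) -> np.ndarray:
        """Cell lines as vectors in R^(m+n): expression and drug profiles side by side."""
        return np.hstack([self.gene_matrix, self.drug_matrix])

    def subset_cells(self, index: np.ndarray | list[int]) -> "CellLinePanel":
        index = np.asarray(index, dtype=int)
        return CellLinePanel(
            cell_ids=[self.cell_ids[i] for i in index],
            gene_matrix=self.gene_matrix[index],
            drug_matrix=self.drug_matrix[index],
            gene_ids=list(self.gene_ids),
            drug_ids=list(self.drug_ids),
        )


@dataclass(frozen=True)
class FilterSpec:
    """Per-feature variation filter: missing-value cap + extreme-ratio count.

    A feature is retained iff it has at most ``max_missing`` missing entries
    and strictly more than ``min_extreme_count`` measurements whose intensity
    ratio exceeds ``ratio_high`` or falls below ``ratio_low``. Defaults match
    the usual cDNA-panel screen (<=5 missing, >3 ratios outside [0.38, 2.6]).
    """

    max_missing: int = 5
    ratio_high: float = 2.6
    ratio_low: float = 0.38
    min_extreme_count: int = 3

    def __post_init__(self) -> None:
        if not (self.ratio_low < 1.0 < self.ratio_high):
            raise ValueError("require ratio_low < 1 < ratio_high")
        if self.max_missing < 0 or self.min_extreme_count < 0:
            raise ValueError("counts must be non-negative")


def _read_table(path: str) -> pd.DataFrame:
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=MISSING_TOKENS, keep_default_na=True
    )
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[np.flatnonzero(bad.to_numpy())[0]]
                raise PanelLoadError(
                    f"non-numeric value in {path!r} at row {row!r}, column {col!r}"
                )
            df[col] = coerced
    return df.astype(float)


def read_panel(
    gene_path: str, drug_path: str, orientation: str = "features_in_columns"
) -> CellLinePanel:
    """Load a paired panel from two delimited tables.

    Both tables must share one axis of cell-line identifiers; the other axis
    holds feature identifiers. ``orientation`` states where the features live.
    Cell lines are aligned on the intersection of the two id sets, preserving
    the gene file's order; discarded ids are logged.
    """
    if orientation not in ("features_in_columns", "features_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    gene_df = _read_table(gene_path)
    drug_df = _read_table(drug_path)
    if orientation == "features_in_rows":
        gene_df = gene_df.T
        drug_df = drug_df.T

    gene_cells = [str(c) for c in gene_df.index]
    drug_cells = set(str(c) for c in drug_df.index)
    shared = [c for c in gene_cells if c in drug_cells]
    if not shared:
        raise PanelLoadError("gene and drug tables share no cell-line identifiers")
    dropped = (set(gene_cells) | set(str(c) for c in drug_df.index)) - set(shared)
    if dropped:
        logger.warning(
            "discarding %d cell line(s) absent from one table: %s",
            len(dropped),
            sorted(dropped),
        )
    gene_df.index = gene_df.index.map(str)
    drug_df.index = drug_df.index.map(str)
    gene_df = gene_df.loc[shared]
    drug_df = drug_df.loc[shared]
    return CellLinePanel(
        cell_ids=shared,
        gene_matrix=gene_df.to_numpy(),
        drug_matrix=drug_df.to_numpy(),
        gene_ids=[str(g) for g in gene_df.columns],
        drug_ids=[str(d) for d in drug_df.columns],
    )


def _impute_matrix(matrix: np.ndarray, feature_ids: list[str]) -> np.ndarray:
    out = matrix.copy()
    observed = ~np.isnan(out)
    empty = ~observed.any(axis=0)
    if empty.any():
        raise ValueError(
            f"feature(s) with no observed values: {[feature_ids[j] for j in np.flatnonzero(empty)]}"
        )
    with np.errstate(invalid="ignore"):
        means = np.nanmean(out, axis=0)
    rows, cols = np.nonzero(~observed)
    out[rows, cols] = means[cols]
    return out


def impute_missing(panel: CellLinePanel) -> CellLinePanel:
    """Replace every missing entry with its feature's mean over the observed cells.

    Observed entries are unchanged; the operation is idempotent.
    """
    return replace(
        panel,
        gene_matrix=_impute_matrix(panel.gene_matrix, panel.gene_ids),
        drug_matrix=_impute_matrix(panel.drug_matrix, panel.drug_ids),
    )


def filter_features(
    matrix: np.ndarray, spec: FilterSpec, value_scale: str = "log2"
) -> np.ndarray:
    """Indices (original order) of features passing the variation filter.

    ``value_scale`` declares how the stored values relate to the intensity
    ratios the thresholds are expressed in: ``"ratio"`` compares directly,
    ``"log2"`` (the cDNA log-ratio convention, the default) compares against
    log2(ratio_high) and log2(ratio_low). Missing entries count toward the
    missing cap and never toward the extreme count.
    """
    matrix = np.asarray(matrix, dtype=float)
    if value_scale == "log2":
        hi, lo = np.log2(spec.ratio_high), np.log2(spec.ratio_low)
    elif value_scale == "ratio":
        hi, lo = spec.ratio_high, spec.ratio_low
    else:
        raise ValueError(f"unknown value_scale {value_scale!r}")
    missing = np.isnan(matrix)
    n_missing = missing.sum(axis=0)
    with np.errstate(invalid="ignore"):
        extreme = (matrix > hi) | (matrix < lo)
    extreme &= ~missing
    n_extreme = extreme.sum(axis=0)
    keep = (n_missing <= spec.max_missing) & (n_extreme > spec.min_extreme_count)
    return np.flatnonzero(keep)
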