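"""Quantification quality control.

Two-axis valid-value filtering (cells first, then proteins), the threshold
grid with per-cell-type median protein variances, per-sample missingness
profiling, and the minimum-PSM-count exclusion applied before differential
expression.

Thresholds are inclusive: a column/row whose valid percentage equals the
threshold is retained. Variance summaries use observed values only (no
imputation) with the n-1 denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scpquant.io_tables import AnnotationSet, ProteinGroupRecord
from scpquant.matrix import QuantMatrix

logger = logging.getLogger(__name__)

DEFAULT_GRID_THRESHOLDS = (0, 10, 30, 50, 70, 90)

MISSINGNESS_CUTOFF_PERCENT = 30.0


@dataclass
class FilterThresholds:
    """Valid-value thresholds (percent) and the minimum PSM count for DE."""

    min_valid_within_cell: float = 70.0
    min_valid_across_samples: float = 50.0
    min_psm_count: int = 2

    def __post_init__(self) -> None:
        for v in (self.min_valid_within_cell, self.min_valid_across_samples):
            if not 0 <= v <= 100:
                raise ValueError(f"threshold percent out of [0, 100]: {v}")
        if self.min_psm_count < 1:
            raise ValueError("min_psm_count must be >= 1")


@dataclass
class GridResult:
    """Full cross-product of (cell threshold, protein threshold) evaluations."""

    cell_thresholds: list[float]
    protein_thresholds: list[float]
    protein_counts: pd.DataFrame   # rows: cell threshold, cols: protein threshold
    cell_counts: pd.Series         # indexed by cell threshold (cells depend on it alone)
    median_variances: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_table(self) -> pd.DataFrame:
        """Table layout: protein counts per grid point plus the cell-count column."""
        out = self.protein_counts.copy()
        out["cells"] = self.cell_counts
        return out


def cell_filter(matrix: QuantMatrix, min_valid_within_cell: float) -> QuantMatrix:
    """Retain sample columns with >= the given percent of valid values."""
    if matrix.n_proteins == 0 or matrix.n_samples == 0:
        raise ValueError("cannot filter an empty matrix")
    frac = matrix.valid_fraction_per_sample() * 100.0
    keep = frac >= min_valid_within_cell
    kept = matrix.subset(samples=matrix.samples[keep])
    logger.info(
        "cell filter @%g%%: kept %d/%d samples", min_valid_within_cell, kept.n_samples, matrix.n_samples
    )
    return kept


def protein_filter(matrix: QuantMatrix, min_valid_across_samples: float) -> QuantMatrix:
    """Retain protein rows with >= the given percent of valid values.

    Runs after :func:`cell_filter`; the valid fraction is computed over the
    retained sample columns.
    """
    frac = matrix.valid_fraction_per_protein() * 100.0
    keep = frac >= min_valid_across_samples
    kept = matrix.subset(proteins=matrix.proteins[keep])
    logger.info(
        "protein filter @%g%%: kept %d/%d proteins",
        min_valid_across_samples, kept.n_proteins, matrix.n_proteins,
    )
    return kept


def _median_protein_variance(matrix: QuantMatrix, labels: pd.Series) -> dict[str, float]:
    """Per cell type: median over proteins of the observed-value sample variance.

    Proteins with fewer than two valid values in the type are skipped.
    """
    out: dict[str, float] = {}
    for cell_type in sorted({l for l in labels if l}):
        cols = labels.index[labels == cell_type]
        cols = [c for c in cols if c in matrix.samples]
        if not cols:
            out[cell_type] = np.nan
            continue
        sub = matrix.data[cols]
        counts = sub.notna().sum(axis=1)
        variances = sub.var(axis=1, ddof=1)[counts >= 2]
        out[cell_type] = float(variances.median()) if len(variances) else np.nan
    return out


def qc_grid(
    matrix: QuantMatrix,
    cell_thresholds: list[float] | None = None,
    protein_thresholds: list[float] | None = None,
    labels: pd.Series | None = None,
) -> GridResult:
    """Evaluate every (cell, protein) threshold pair.

    Cell counts depend only on the cell threshold (cells are filtered first);
    degenerate grid points with no retained columns report zero proteins.
    ``labels`` maps sample id -> cell type for the variance summaries.
    """
    cell_thresholds = list(cell_thresholds if cell_thresholds is not None else DEFAULT_GRID_THRESHOLDS)
    protein_thresholds = list(
        protein_thresholds if protein_thresholds is not None else DEFAULT_GRID_THRESHOLDS
    )
    if labels is None and matrix.sample_meta is not None:
        labels = matrix.sample_meta["cell_type"]

    protein_counts = pd.DataFrame(
        0, index=pd.Index(cell_thresholds, name="cell_threshold"),
        columns=pd.Index(protein_thresholds, name="protein_threshold"), dtype=int,
    )
    cell_counts = pd.Series(0, index=protein_counts.index, dtype=int)
    variances: dict[str, pd.DataFrame] = {}
    if labels is not None:
        for ct in sorted({l for l in labels if l}):
            variances[ct] = pd.DataFrame(
                np.nan, index=protein_counts.index, columns=protein_counts.columns
            )

    for ct_thr in cell_thresholds:
        after_cells = cell_filter(matrix, ct_thr)
        cell_counts[ct_thr] = after_cells.n_samples
        for pt_thr in protein_thresholds:
            if after_cells.n_samples == 0:
                protein_counts.loc[ct_thr, pt_thr] = 0
                continue
            after_both = protein_filter(after_cells, pt_thr)
            protein_counts.loc[ct_thr, pt_thr] = after_both.n_proteins
            if labels is not None:
                for ct, v in _median_protein_variance(after_both, labels).items():
                    variances[ct].loc[ct_thr, pt_thr] = v

    return GridResult(
        cell_thresholds=cell_thresholds,
        protein_thresholds=protein_thresholds,
        protein_counts=protein_counts,
        cell_counts=cell_counts,
        median_variances=variances,
    )


def missingness_profile(
    matrix: QuantMatrix,
    annotation: AnnotationSet | None = None,
    cutoff_percent: float = MISSINGNESS_CUTOFF_PERCENT,
) -> pd.DataFrame:
    """Per-sample missing-value percentage, tagged with role/cell type.

    ``above_cutoff`` flags samples crossing the reporting line (default 30%).
    """
    missing_pct = matrix.mask.mean(axis=0) * 100.0
    df = pd.DataFrame({"missing_percent": missing_pct})
    df.index.name = "sample_id"
    if matrix.sample_meta is not None:
        df["role"] = matrix.sample_meta["role"]
        df["cell_type"] = matrix.sample_meta["cell_type"]
    elif annotation is not None:
        roles, types = [], []
        for sid in df.index:
            batch, channel = sid.rsplit(":", 1)
            ann = annotation[(batch, int(channel))]
            roles.append(ann.role)
            types.append(ann.cell_type or "")
        df["role"] = roles
        df["cell_type"] = types
    df["above_cutoff"] = df["missing_percent"] > cutoff_percent
    return df


def min_psm_filter(
    matrix: QuantMatrix,
    protein_groups: list[ProteinGroupRecord] | dict[str, int],
    min_psm_count: int = 2,
) -> QuantMatrix:
    """Drop proteins whose total PSM count is below ``min_psm_count``.

    Single-PSM proteins are identifiable but too unstable for differential
    expression, so the default removes them. Proteins absent from the count
    table count as zero (with a warning).
    """
    if isinstance(protein_groups, dict):
        counts = dict(protein_groups)
    else:
        counts = {pg.protein_id: pg.psm_count for pg in protein_groups}
    unknown = [p for p in matrix.proteins if p not in counts]
    if unknown:
        logger.warning(
            "%d protein(s) missing from the PSM count table; treated as count 0 (e.g. %s)",
            len(unknown), unknown[0],
        )
    keep = [p for p in matrix.proteins if counts.get(p, 0) >= min_psm_count]
    kept = matrix.subset(proteins=keep)
    logger.info(
        "min-PSM filter @%d: kept %d/%d proteins", min_psm_count, kept.n_proteins, matrix.n_proteins
    )
    return kept


def psm_counts_from_records(psms) -> dict[str, int]:
    """Total PSM count per protein across all batches."""
    counts: dict[str, int] = {}
    for p in psms:
        counts[p.protein_id] = counts.get(p.protein_id, 0) + 1
    return counts
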