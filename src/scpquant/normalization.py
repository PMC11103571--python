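"""PSM-level weighted-ratio normalization and weighted-median protein rollup.

For each protein and sample channel within a batch, the PSM reporter
intensities are converted to ratios (against the reference channel, or a
channel/PSM sum when no reference exists), weighted by
``(precursor_intensity * fill_time) ** 0.75`` normalized to sum to one, and
collapsed to a single protein value by the weighted median: the sorted ratio
at the smallest index k whose cumulative weight on either side does not
exceed one half.

Normalization runs within each batch independently; the reference-channel
ratio is what makes values comparable across batches.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scpquant.io_tables import AnnotationSet, PSMRecord
from scpquant.matrix import QuantMatrix

logger = logging.getLogger(__name__)

RATIO_MODES = ("reference", "channel_sum", "psm_sum")

DEFAULT_WEIGHT_EXPONENT = 0.75


class NormalizationError(ValueError):
    pass


@dataclass
class PSMGroup:
    """The PSMs of one protein for one target channel.

    ``X``: target-channel reporter intensities; ``R``: paired reference
    intensities (NaN when absent); ``P``/``T``: precursor intensities and
    fill times; ``channel_sums``: per-PSM sum of reporter intensities over
    all non-missing channels (denominator for channel_sum mode).
    """

    protein_id: str
    channel: int
    X: np.ndarray
    R: np.ndarray
    P: np.ndarray
    T: np.ndarray
    channel_sums: np.ndarray

    @property
    def n(self) -> int:
        return len(self.X)

    def retained(self, mode: str) -> "PSMGroup":
        """Drop PSMs whose ratio is undefined: missing X, or (reference mode)
        missing/zero reference."""
        keep = ~np.isnan(self.X)
        if mode == "reference":
            keep &= ~np.isnan(self.R) & (self.R > 0)
        return PSMGroup(
            protein_id=self.protein_id,
            channel=self.channel,
            X=self.X[keep],
            R=self.R[keep],
            P=self.P[keep],
            T=self.T[keep],
            channel_sums=self.channel_sums[keep],
        )


def compute_ratios(group: PSMGroup, mode: str = "reference") -> np.ndarray:
    """Normalized per-PSM ratios Xr for one protein/channel group.

    reference:   Xr_i = X_i / R_i
    channel_sum: Xr_i = X_i / (sum of PSM i's reporter intensities over channels)
    psm_sum:     Xr_i = X_i / sum_j X_j over the group's PSMs
    """
    if mode not in RATIO_MODES:
        raise NormalizationError(f"unknown ratio mode {mode!r}; expected one of {RATIO_MODES}")
    if group.n == 0:
        return np.empty(0)
    if mode == "reference":
        if np.isnan(group.R).any() or (group.R <= 0).any():
            raise NormalizationError(
                f"reference mode requires positive reference intensities "
                f"(protein {group.protein_id}, channel {group.channel})"
            )
        return group.X / group.R
    if mode == "channel_sum":
        return group.X / group.channel_sums
    total = np.nansum(group.X)
    return group.X / total


def compute_weights(
    P: np.ndarray, T: np.ndarray, exponent: float = DEFAULT_WEIGHT_EXPONENT
) -> tuple[np.ndarray, np.ndarray]:
    """Raw and normalized PSM weights: F_i = (P_i * T_i)^exponent, Fr = F / sum(F).

    A PSM with missing fill time falls back to precursor intensity alone; if
    every product is zero or missing the weights degrade to uniform.
    """
    P = np.asarray(P, dtype=float)
    T = np.asarray(T, dtype=float)
    prod = P * T
    fallback = np.isnan(T) & ~np.isnan(P)
    if fallback.any():
        logger.warning("fill time missing for %d PSM(s); weighting by precursor alone", int(fallback.sum()))
        prod = np.where(fallback, P, prod)
    prod = np.where(np.isnan(prod), 0.0, prod)
    F = np.power(prod, exponent)
    total = F.sum()
    if total <= 0:
        logger.warning("all PSM weight products are zero; using uniform weights")
        n = len(F)
        return F, np.full(n, 1.0 / n)
    return F, F / total


def weighted_median(Xr: np.ndarray, Fr: np.ndarray, tol: float = 1e-9) -> float:
    """Weighted median of ratios Xr under normalized weights Fr.

    Sorts Xr ascending, permutes Fr identically, and returns the element at
    the smallest index k with cumulative weight strictly before k <= 1/2 and
    strictly after k <= 1/2 (lower weighted median on ties).
    """
    Xr = np.asarray(Xr, dtype=float)
    Fr = np.asarray(Fr, dtype=float)
    if Xr.size == 0:
        return np.nan
    if Xr.shape != Fr.shape:
        raise NormalizationError("Xr and Fr must have equal length")
    total = Fr.sum()
    if abs(total - 1.0) > 1e-6:
        raise NormalizationError(f"weights must sum to 1 (got {total})")
    order = np.argsort(Xr, kind="stable")
    Xs = Xr[order]
    W = Fr[order]
    cum = np.cumsum(W)
    before = cum - W          # sum of weights strictly before each position
    after = total - cum       # sum of weights strictly after each position
    ok = (before <= 0.5 + tol) & (after <= 0.5 + tol)
    k = int(np.flatnonzero(ok)[0])  # smallest valid k
    return float(Xs[k])


def _build_groups(psms: list[PSMRecord]) -> dict[str, dict[str, list[PSMRecord]]]:
    """batch -> protein -> PSM list."""
    out: dict[str, dict[str, list[PSMRecord]]] = defaultdict(lambda: defaultdict(list))
    for p in psms:
        out[p.batch_id][p.protein_id].append(p)
    return out


def normalize_protein_table(
    psms: list[PSMRecord],
    annotation: AnnotationSet,
    mode: str = "reference",
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
    keep_control_channels: bool = True,
) -> QuantMatrix:
    """Roll PSMs up to a linear-scale protein x sample ratio matrix.

    Output columns are the single-cell channels (plus control/empty channels
    when ``keep_control_channels``); carrier, reference and unused channels
    never appear as columns. Entries with no usable PSM are missing.
    """
    if mode not in RATIO_MODES:
        raise NormalizationError(f"unknown ratio mode {mode!r}")
    by_batch = _build_groups(psms)

    sample_anns = []
    for batch in annotation.batches:
        sample_anns.extend(annotation.sample_channels(batch, keep_control=keep_control_channels))
    columns = [a.sample_id for a in sample_anns]
    proteins = sorted({p.protein_id for p in psms})
    values = np.full((len(proteins), len(columns)), np.nan)
    protein_idx = {p: i for i, p in enumerate(proteins)}
    col_idx = {c: j for j, c in enumerate(columns)}

    for batch in annotation.batches:
        batch_psms = by_batch.get(batch, {})
        ref_channel = annotation.reference_channel(batch)
        if mode == "reference" and ref_channel is None:
            raise NormalizationError(f"batch {batch!r} has no reference channel annotated")
        targets = annotation.sample_channels(batch, keep_control=keep_control_channels)
        if not targets:
            continue
        for protein_id, plist in batch_psms.items():
            reporters = np.vstack([p.reporter_intensity for p in plist])
            R = reporters[:, ref_channel] if ref_channel is not None else np.full(len(plist), np.nan)
            P = np.array([p.precursor_intensity for p in plist])
            T = np.array([p.fill_time for p in plist])
            channel_sums = np.nansum(reporters, axis=1)
            row = protein_idx[protein_id]
            for ann in targets:
                group = PSMGroup(
                    protein_id=protein_id,
                    channel=ann.channel_index,
                    X=reporters[:, ann.channel_index],
                    R=R,
                    P=P,
                    T=T,
                    channel_sums=channel_sums,
                ).retained(mode)
                if group.n == 0:
                    continue
                Xr = compute_ratios(group, mode)
                _, Fr = compute_weights(group.P, group.T, exponent=weight_exponent)
                values[row, col_idx[ann.sample_id]] = weighted_median(Xr, Fr)

    meta = pd.DataFrame(
        {
            "batch": [a.batch_id for a in sample_anns],
            "channel": [a.channel_index for a in sample_anns],
            "role": [a.role for a in sample_anns],
            "cell_type": [a.cell_type or "" for a in sample_anns],
        },
        index=pd.Index(columns, name="sample_id"),
    )
    data = pd.DataFrame(values, index=pd.Index(proteins, name="protein_id"), columns=columns)
    logger.info(
        "normalized %d proteins x %d sample channels (mode=%s)", len(proteins), len(columns), mode
    )
    return QuantMatrix(data, scale="linear", sample_meta=meta)


def log2_transform(matrix: QuantMatrix) -> QuantMatrix:
    """log2 every non-missing entry; the mask is unchanged."""
    if matrix.scale == "log2":
        raise NormalizationError("matrix is already log2 scale")
    vals = matrix.data.to_numpy()
    if np.any(vals[~np.isnan(vals)] <= 0):
        raise NormalizationError("log2 transform requires strictly positive values")
    out = matrix.copy()
    out.data = np.log2(out.data)
    out.scale = "log2"
    return out
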