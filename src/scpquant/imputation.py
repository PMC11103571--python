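"""Left-censored missing-value imputation by down-shifted Gaussian draws.

Each missing entry is replaced by a draw from Normal(mu - d*sigma,
(w*sigma)^2), where mu and sigma are the mean and standard deviation of the
observed values of the column (per_sample scope) or of the whole matrix
(global scope). d is the tunable down-shift (a standard-deviation
multiplier); w controls the spread of the imputed peak.

A large down-shift plants a separate low-intensity mode into the value
distribution; :func:`distribution_report` detects that bimodality so the
user can tune d until the imputed values blend into the main distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scpquant.matrix import QuantMatrix

logger = logging.getLogger(__name__)


@dataclass
class ImputationParams:
    """Down-shift d (SD multiplier), draw width w (SD multiplier), scope, seed."""

    down_shift: float = 1.8
    width: float = 0.3
    scope: str = "per_sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.down_shift < 0:
            raise ValueError("down_shift must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.scope not in ("per_sample", "global"):
            raise ValueError(f"scope must be per_sample or global, got {self.scope!r}")


def downshift_impute(
    matrix: QuantMatrix, params: ImputationParams | None = None
) -> tuple[QuantMatrix, pd.DataFrame]:
    """Fill every missing entry; return the completed matrix and the imputed mask.

    Observed values are never modified. Columns with fewer than two observed
    values fall back to global statistics (with a warning). Identical
    (matrix, params, seed) inputs yield identical outputs.
    """
    if params is None:
        params = ImputationParams()
    values = matrix.data.to_numpy(copy=True)
    observed = ~np.isnan(values)
    if not observed.any():
        raise ValueError("cannot impute a matrix with zero observed values")
    rng = np.random.default_rng(params.seed)
    imputed_mask = ~observed

    global_mu = float(np.nanmean(values))
    global_sigma = float(np.nanstd(values, ddof=1))

    if params.scope == "global":
        missing = imputed_mask
        loc = global_mu - params.down_shift * global_sigma
        scale = params.width * global_sigma
        values[missing] = rng.normal(loc, scale, size=int(missing.sum()))
    else:
        for j in range(values.shape[1]):
            col = values[:, j]
            miss = np.isnan(col)
            if not miss.any():
                continue
            obs = col[~miss]
            if obs.size < 2:
                logger.warning(
                    "column %s has <2 observed values; falling back to global statistics",
                    matrix.samples[j],
                )
                mu, sigma = global_mu, global_sigma
            else:
                mu = float(obs.mean())
                sigma = float(obs.std(ddof=1))
            values[miss, j] = rng.normal(
                mu - params.down_shift * sigma, params.width * sigma, size=int(miss.sum())
            )

    out = matrix.copy()
    out.data = pd.DataFrame(values, index=matrix.proteins, columns=matrix.samples)
    mask_df = pd.DataFrame(imputed_mask, index=matrix.proteins, columns=matrix.samples)
    logger.info("imputed %d/%d entries (d=%g, w=%g, scope=%s)",
                int(imputed_mask.sum()), imputed_mask.size, params.down_shift,
                params.width, params.scope)
    return out, mask_df


@dataclass
class DistributionReport:
    """Aligned histograms of all values and of imputed values, plus a bimodality flag."""

    bin_edges: np.ndarray
    all_counts: np.ndarray
    imputed_counts: np.ndarray
    bimodal: bool
    mode_gap_sd: float  # separation of imputed vs observed mode, in observed-SD units


def distribution_report(
    matrix_complete: QuantMatrix,
    imputed_mask: pd.DataFrame,
    bins: int = 60,
) -> DistributionReport:
    """Histogram the completed matrix against its imputed subset.

    The bimodality flag fires when the imputed values form their own mode:
    the imputed and observed modes are separated by more than ~1.25 observed
    SDs and the combined histogram dips between them.
    """
    flat = matrix_complete.data.to_numpy().ravel()
    flat_mask = imputed_mask.to_numpy().ravel()
    all_values = flat[~np.isnan(flat)]
    imputed_values = flat[flat_mask]

    edges = np.histogram_bin_edges(all_values, bins=bins)
    all_counts, _ = np.histogram(all_values, bins=edges)
    imputed_counts, _ = np.histogram(imputed_values, bins=edges)

    observed_values = flat[~flat_mask]
    observed_values = observed_values[~np.isnan(observed_values)]
    if imputed_values.size == 0 or observed_values.size < 2:
        return DistributionReport(edges, all_counts, imputed_counts, False, 0.0)

    centers = 0.5 * (edges[:-1] + edges[1:])
    observed_counts = all_counts - imputed_counts
    obs_mode = centers[int(np.argmax(observed_counts))]
    imp_mode = centers[int(np.argmax(imputed_counts))]
    sigma = float(observed_values.std(ddof=1))
    gap_sd = abs(obs_mode - imp_mode) / sigma if sigma > 0 else 0.0

    bimodal = False
    if gap_sd > 1.25:
        lo, hi = sorted((imp_mode, obs_mode))
        between = (centers > lo) & (centers < hi)
        if between.any():
            valley = all_counts[between].min()
            peak_imp = all_counts[int(np.argmax(imputed_counts))]
            peak_obs = all_counts[int(np.argmax(observed_counts))]
            bimodal = valley < 0.8 * min(peak_imp, peak_obs)
    return DistributionReport(edges, all_counts, imputed_counts, bool(bimodal), float(gap_sd))
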