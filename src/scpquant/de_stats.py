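"""Two-group differential expression with empirical-Bayes variance moderation.

Per protein, the pooled within-group variance s_g^2 (d_g = n1 + n2 - 2 df)
is shrunk toward a prior (d0, s0^2) estimated by moment-matching on
log s_g^2 (digamma/trigamma equations):

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_g    = (mean_A - mean_B) / (s~_g * sqrt(1/n1 + 1/n2))

with two-sided p-values on d0 + d_g degrees of freedom and
Benjamini-Hochberg q-values across all tested proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from scpquant.matrix import QuantMatrix

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    protein_id: str
    log2_fc: float
    s2: float
    s2_posterior: float
    t_mod: float
    df_total: float
    p_value: float
    q_value: float = np.nan
    is_significant: bool = False


@dataclass
class VariancePrior:
    df: float          # d0; may be inf
    scale: float       # s0^2


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> VariancePrior:
    """Moment-matching prior for the variances: fit a scaled inverse chi-square.

    Matches the mean and variance of log(s2) against the theoretical
    digamma/trigamma moments. Near-equal variances (non-positive excess
    spread) fall back to an infinite prior df.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        logger.warning("too few positive variances for prior estimation; using d0=inf")
        m = float(np.nanmean(s2[ok])) if ok.any() else 1.0
        return VariancePrior(df=np.inf, scale=m)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    n = e.size
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        logger.warning("variance spread at or below sampling noise; falling back to d0=inf")
        return VariancePrior(df=np.inf, scale=float(np.exp(e_mean)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(df=d0, scale=s0)


def moderated_t_test(
    matrix_complete: QuantMatrix,
    labels: pd.Series,
    prior: VariancePrior | None = None,
    q_cutoff: float = 0.05,
) -> list[DEResult]:
    """Moderated two-sample t-test for every protein.

    ``labels`` maps sample id -> group; exactly two groups, each with >= 2
    samples, are required. log2_fc is mean(first group) - mean(second group)
    with groups taken in sorted label order. Pass ``prior`` to bypass the
    empirical-Bayes estimate (e.g. VariancePrior(0, 0) for the ordinary
    pooled t-test).
    """
    labels = labels.loc[[s for s in matrix_complete.samples if s in labels.index]]
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    cols_a = labels.index[labels == groups[0]]
    cols_b = labels.index[labels == groups[1]]
    n1, n2 = len(cols_a), len(cols_b)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples (got {n1} and {n2})")

    a = matrix_complete.data[cols_a].to_numpy()
    b = matrix_complete.data[cols_b].to_numpy()
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("moderated_t_test requires a complete (imputed) matrix")

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2_fc = mean_a - mean_b
    df_resid = n1 + n2 - 2
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if prior is None:
        prior = estimate_variance_prior(s2, df_resid)
    d0, s0 = prior.df, prior.scale

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2_fc / se, 0.0)
        t = np.where((se == 0) & (log2_fc != 0), np.sign(log2_fc) * np.inf, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, 0.0, 1.0)
    q = bh_adjust(p)

    results = []
    for i, pid in enumerate(matrix_complete.proteins):
        results.append(
            DEResult(
                protein_id=str(pid),
                log2_fc=float(log2_fc[i]),
                s2=float(s2[i]),
                s2_posterior=float(s2_post[i]),
                t_mod=float(t[i]),
                df_total=float(df_total),
                p_value=float(p[i]),
                q_value=float(q[i]),
                is_significant=bool(q[i] <= q_cutoff),
            )
        )
    n_sig_p = int((p <= 0.05).sum())
    n_sig_q = int((q <= q_cutoff).sum())
    logger.info(
        "DE: %d proteins tested (%s vs %s), %d with p<=0.05, %d with q<=%g (prior df=%.3g)",
        len(results), groups[0], groups[1], n_sig_p, n_sig_q, q_cutoff, d0,
    )
    return results


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment: q_(i) = min_{j>=i} p_(j)*m/j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def volcano_table(results: list[DEResult], q_cutoff: float = 0.05) -> pd.DataFrame:
    """Volcano-plot table (log2_fc vs -log10 q), sorted by q."""
    if not results:
        return pd.DataFrame(
            columns=["protein_id", "log2_fc", "t", "p", "q", "neg_log10_q", "significant"]
        ).set_index("protein_id")
    df = pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in results],
            "log2_fc": [r.log2_fc for r in results],
            "t": [r.t_mod for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
        }
    ).set_index("protein_id")
    with np.errstate(divide="ignore"):
        df["neg_log10_q"] = -np.log10(df["q"])
    df["significant"] = df["q"] <= q_cutoff
    return df.sort_values("q")
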