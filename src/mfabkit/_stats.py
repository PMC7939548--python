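"""Shared statistical machinery: BH adjustment, empirical-Bayes moderated t,
closed-form 2x2 chi-square, and Tukey HSD p-values from the studentized range.

The moderated t follows the standard empirical-Bayes treatment of gene-wise
variances: gene variances s_g^2 (d_g residual df) are shrunk toward a prior
s_0^2 (d_0 df) estimated by method of moments on log s_g^2, giving

    s_post^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g)

and a t statistic with d_0 + d_g degrees of freedom. With d_0 = 0 this
reduces exactly to the ordinary t test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "fit_variance_prior",
    "moderated_t",
    "chisq_2x2",
    "tukey_pvalue",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values. NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


@dataclass(frozen=True)
class VariancePrior:
    """Moment-estimated prior on gene-wise residual variances."""

    df_prior: float   # d0; inf means complete shrinkage, 0 means none
    s2_prior: float   # s0^2


def fit_variance_prior(s2: np.ndarray, df_residual: float) -> VariancePrior:
    """Estimate (d0, s0^2) from observed residual variances by matching the
    first two moments of log s^2 against the scaled-F sampling model."""
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2 or df_residual <= 0:
        return VariancePrior(0.0, float(np.median(s2)) if s2.size else 1.0)
    z = np.log(s2)
    e = z - special.digamma(df_residual / 2.0) + np.log(df_residual / 2.0)
    emean = e.mean()
    evar = np.var(e, ddof=1) * (s2.size - 1) / s2.size  # n-normalized, matches moments
    excess = evar - special.polygamma(1, df_residual / 2.0)
    if excess <= 0:
        # observed variances are less dispersed than pure sampling noise:
        # infinite prior df, all genes share s0^2
        s0 = float(np.exp(emean))
        return VariancePrior(np.inf, s0)
    d0 = 2.0 * _trigamma_inverse(float(excess))
    s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return VariancePrior(d0, s0)


def moderated_t(coef, stdev_unscaled, s2, df_residual, prior: VariancePrior | None = None):
    """Moderated t statistics and two-sided p-values.

    Parameters
    ----------
    coef : array of coefficient estimates (one per gene)
    stdev_unscaled : sqrt of the coefficient's diagonal of (X'X)^-1
    s2 : gene-wise residual variances
    df_residual : residual degrees of freedom of the per-gene fit
    prior : variance prior; estimated from ``s2`` when None

    Returns
    -------
    t, p, df_total, s2_post
    """
    coef = np.asarray(coef, dtype=float)
    stdev_unscaled = np.asarray(stdev_unscaled, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if prior is None:
        prior = fit_variance_prior(s2, df_residual)
    d0, s02 = prior.df_prior, prior.s2_prior
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 <= 0:
        s2_post = s2.copy()
        df_total = df_residual
    else:
        s2_post = (d0 * s02 + df_residual * s2) / (d0 + df_residual)
        df_total = d0 + df_residual
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / (stdev_unscaled * np.sqrt(s2_post))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p, df_total, s2_post


def chisq_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for a 2x2 table.

    Uses the closed form n(ad - bc)^2 / (r1 r2 c1 c2). Any empty margin
    yields (0.0, 1.0).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    if denom == 0 or n == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def tukey_pvalue(estimate: float, se: float, n_groups: int, df: float) -> float:
    """Tukey-HSD family-wise p-value for one pairwise contrast.

    The contrast t = estimate/se is referred to the studentized range
    distribution with ``n_groups`` means: q = |t| * sqrt(2).
    """
    if se <= 0 or not np.isfinite(se):
        return np.nan
    q = abs(estimate / se) * np.sqrt(2.0)
    return float(stats.studentized_range.sf(q, n_groups, df))
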