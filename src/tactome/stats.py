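"""Shared statistical helpers: BH false-discovery control and moderated
two-group linear models with empirical-Bayes variance shrinkage.

The moderated test follows the standard limma formulation: per-gene
residual variances are shrunk toward a pooled prior fitted by moment
matching on log variances (scaled inverse-chi-square prior); the moderated
t statistic gains the prior degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


def adjust_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matched scaled inverse-chi-square prior for gene variances.

    Returns ``(d0, s0_sq)``; ``d0 = inf`` means all variances are shrunk to
    the common value (no excess dispersion beyond sampling noise).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) if e.size > 1 else 0.0
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_ttest(
    expr: np.ndarray, group: np.ndarray
) -> pd.DataFrame:
    """Two-group moderated t-test per gene (rows of *expr*).

    *group* is a boolean/0-1 vector over columns; the reported log2FC is
    group-1 minus group-0 (for log2-space input).  Returns a DataFrame with
    columns ``log2fc``, ``t``, ``p``, ``q``.
    """
    expr = np.asarray(expr, dtype=float)
    g = np.asarray(group).astype(bool)
    n1, n0 = int(g.sum()), int((~g).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least two samples per group")
    m1 = expr[:, g].mean(axis=1)
    m0 = expr[:, ~g].mean(axis=1)
    rss = ((expr[:, g] - m1[:, None]) ** 2).sum(axis=1) + (
        (expr[:, ~g] - m0[:, None]) ** 2
    ).sum(axis=1)
    df = n1 + n0 - 2
    s2 = rss / df
    d0, s0_sq = fit_variance_prior(s2[s2 > 0], df) if np.any(s2 > 0) else (np.inf, 0.0)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_post = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_post = d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    delta = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, 0.0)
    if np.isinf(df_post):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_post)
    return pd.DataFrame({"log2fc": delta, "t": t, "p": p, "q": adjust_fdr(p)})
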