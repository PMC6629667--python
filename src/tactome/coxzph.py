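"""Score test for proportional hazards (Grambsch–Therneau).

For each covariate the fitted Cox model is augmented with a time-varying
term ``x_k · g(t)`` and tested by a score test at the fitted
coefficients, with the exact block variance

    V_k = I_gg − I_gθ · I_θθ⁻¹ · I_θg

rather than the classical approximation ``I_gg ≈ d · V̄_kk`` (which is
anti-conservative for strong effects).  ``g`` is the centred
Kaplan–Meier transform of event time.  Ties are handled Breslow-style
(all tied events share a risk set), which is adequate for a diagnostic.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def _km_transform(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Left-continuous Kaplan–Meier survival evaluated at each time."""
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    n = len(times)
    km = np.ones(n)
    s = 1.0
    at_risk = n
    i = 0
    km_at = {}
    while i < n:
        j = i
        d = 0
        while j < n and t_sorted[j] == t_sorted[i]:
            d += int(e_sorted[j])
            j += 1
        km_at[t_sorted[i]] = s  # value just before this time
        if d > 0 and at_risk > 0:
            s *= 1.0 - d / at_risk
        at_risk -= j - i
        i = j
    return np.array([km_at[t] for t in times])


def ph_score_test(
    times: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
) -> np.ndarray:
    """Per-covariate PH score-test p-values for a fitted Cox model.

    Parameters
    ----------
    times, events
        Follow-up and 0/1 event indicators, length n.
    X
        Covariate matrix, shape (n, p).
    beta
        Fitted Cox coefficients, length p.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    n, p = X.shape
    beta = np.asarray(beta, dtype=float)

    order = np.argsort(-times, kind="stable")  # decreasing: running risk sets
    t_o = times[order]
    e_o = events[order]
    x_o = X[order]
    w_o = np.exp(x_o @ beta)

    g_all = 1.0 - _km_transform(times, events)
    g_o = g_all[order]

    # running risk-set sums (samples with time >= current, processed in
    # decreasing-time order)
    S0 = np.cumsum(w_o)
    S1 = np.cumsum(w_o[:, None] * x_o, axis=0)
    # S2 per event only (p small, events moderate): accumulate lazily
    U = np.zeros(p)
    I_gg = np.zeros(p)
    I_gth = np.zeros((p, p))
    I_thth = np.zeros((p, p))
    g_events = []
    # Breslow ties: risk set includes all with time >= t, i.e. the largest
    # index among equal times in the decreasing ordering
    last_idx_for_time = {}
    for i in range(n):
        last_idx_for_time[t_o[i]] = i

    S2_run = np.zeros((p, p))
    idx_done = -1
    per_event = []
    for i in range(n):
        if not e_o[i]:
            continue
        k = last_idx_for_time[t_o[i]]
        while idx_done < k:
            idx_done += 1
            xi = x_o[idx_done]
            S2_run += w_o[idx_done] * np.outer(xi, xi)
        s0 = S0[k]
        xbar = S1[k] / s0
        V = S2_run / s0 - np.outer(xbar, xbar)
        resid = x_o[i] - xbar
        per_event.append((g_o[i], resid, V))
    if not per_event:
        return np.full(p, np.nan)
    gs = np.array([g for g, _, _ in per_event])
    g_mean = gs.mean()
    for (g, resid, V) in per_event:
        gc = g - g_mean
        U += gc * resid
        I_gg += gc**2 * np.diag(V)
        I_gth += gc * V
        I_thth += V
    pvals = np.full(p, np.nan)
    try:
        I_inv = np.linalg.pinv(I_thth)
    except np.linalg.LinAlgError:
        return pvals
    for k in range(p):
        v = I_gg[k] - I_gth[k] @ I_inv @ I_gth[k]
        if v <= 0:
            continue
        stat = U[k] ** 2 / v
        pvals[k] = float(stats.chi2.sf(stat, 1))
    return pvals
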