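"""Purity / TC / TAC deconvolution from bulk expression and a normal panel.

A bulk tumour profile is modelled as a convex mixture of one cancer
reference profile ``m`` (shared within a subtype) and the columns of a
non-cancerous reference panel ``h_1 … h_R``::

    x_n ≈ p_n · m + Σ_r θ_nr · h_r,    p_n + Σ_r θ_nr = 1,  p_n, θ_nr ≥ 0

after normalizing every profile to sum 1, so that the purity ``p_n`` is the
fraction of the sample's RNA signal attributed to tumour cells.  The
estimator is deterministic alternating constrained least squares:

* **step 1** — per-sample non-negative least squares against ``[m | H]``
  alternated with a weighted-residual update of ``m``, yielding purities and
  the subtype cancer reference;
* **step 2** — per-sample TC profiles ``t_n ≥ 0`` from
  ``min ‖x_n − p_n t_n − Hθ_n‖² + λ‖t_n − m‖²`` with ``Σθ_n = 1 − p_n``,
  a ridge pull toward ``m`` keeping low-purity samples identifiable;
* **step 3** — exact algebraic inversion of the mixing identity,
  ``s = (b − p·t)/(1 − p)``, so the reconstruction ``b = p·t + (1−p)·s``
  holds to machine precision before any flooring.

Log2 transformation applies the study floor rule: negative (and zero) TAC
entries are replaced by the minimum positive intensity observed across the
bulk and TC matrices before taking log2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .config import DeconvolutionParams, RunConfig
from .datatypes import (
    ClinicalTable,
    DeconvolutionResult,
    ExpressionMatrix,
    ValidationError,
)

_EPS = 1e-8


def _as_normalized(values: np.ndarray, what: str) -> tuple[np.ndarray, np.ndarray]:
    sums = values.sum(axis=0)
    if np.any(sums <= 0):
        bad = np.where(sums <= 0)[0].tolist()
        raise ValidationError(f"all-zero {what} column(s) at positions {bad}")
    return values / sums, sums


def _check_alignment(bulk: ExpressionMatrix, panel: ExpressionMatrix) -> None:
    if bulk.gene_ids != panel.gene_ids:
        raise ValidationError("bulk and panel gene lists are not aligned")


def _fit_reference(
    X: np.ndarray,
    H: np.ndarray,
    max_iter: int,
    tol: float,
    p_max: float,
    ridge_frac: float,
) -> tuple[np.ndarray, dict]:
    """Alternating constrained least squares for the cancer reference ``m``.

    The reference is seeded from the bulk columns with the largest
    panel-orthogonal mass (the most tumour-rich samples), so it starts with
    its full panel-shared component rather than a rectified difference of
    means.  A small ridge on the purity coefficient keeps the reference from
    absorbing sample noise when the data contain no tumour signal.
    """
    G, n = X.shape
    R = H.shape[1]
    overflow = np.empty(n)
    for j in range(n):
        w, _ = nnls(H, X[:, j])
        overflow[j] = max(float(np.sum(X[:, j] - H @ w)), 0.0)
    k = max(1, n // 20)
    top = np.argsort(overflow)[-k:]
    m = X[:, top].mean(axis=1) + _EPS
    m /= m.sum()

    p = np.zeros(n)
    objectives: list[float] = []
    converged = False
    for it in range(max_iter):
        p_new, theta, obj = _score_against(X, H, m, p_max, ridge_frac)
        objectives.append(obj)
        delta = np.max(np.abs(p_new - p)) if it > 0 else np.inf
        p = p_new
        resid = X - H @ theta.T
        denom = float(np.sum(p**2))
        if denom > 0:
            m = resid @ p / denom
        m = np.maximum(m, 0.0) + _EPS
        m /= m.sum()
        if delta < tol:
            converged = True
            break
    convergence = {
        "iterations": len(objectives),
        "final_objective": objectives[-1] if objectives else float("nan"),
        "tolerance_met": bool(converged),
        "objectives": objectives,
    }
    return m, convergence


def _score_against(
    X: np.ndarray, H: np.ndarray, m: np.ndarray, p_max: float, ridge_frac: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-sample NNLS of each bulk column against ``[m | H]``.

    Weights are rescaled onto the simplex so ``p + Σθ = 1``; the tiny ridge
    on the ``m`` coefficient breaks exact-fit ties toward zero tumour
    content.  Returns ``(p, theta, objective)``.
    """
    n = X.shape[1]
    R = H.shape[1]
    mu = ridge_frac * float(np.sum(m**2))
    A = np.vstack(
        [np.column_stack([m, H]), np.concatenate([[np.sqrt(mu)], np.zeros(R)])]
    )
    p = np.empty(n)
    theta = np.empty((n, R))
    obj = 0.0
    for j in range(n):
        target = np.concatenate([X[:, j], [0.0]])
        w, _ = nnls(A, target)
        obj += float(np.sum((X[:, j] - A[:-1] @ w) ** 2))
        total = w.sum()
        if total <= 0:
            w = np.full_like(w, 1.0 / w.size)
            total = 1.0
        w = w / total
        p[j] = min(w[0], p_max)
        theta[j] = w[1:]
        theta[j] *= (1.0 - p[j]) / max(theta[j].sum(), _EPS)
    return p, theta, obj


def _calibrate_purity_scale(X: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Affine purity calibration from non-negativity of the extrapolated
    pure-tumour profile.

    Regressing each gene on the raw purity estimate, genes silenced in
    tumour cells hit zero exactly at purity one and tumour-specific genes
    (absent in normal tissue) hit zero at purity zero.  Robust quantiles of
    those crossing points give the affine map that puts the estimates on
    the absolute purity scale.  Applied only when the cohort spans enough
    purity range to support the regression.
    """
    n = X.shape[1]
    if n < 10 or (p.max() - p.min()) <= 0.3:
        return p
    D = np.column_stack([np.ones(n), p])
    coef, *_ = np.linalg.lstsq(D, X.T, rcond=None)
    a, b = coef[0], coef[1]
    scale = float(np.abs(a).mean())
    down = b < -1e-3 * scale
    up = b > 1e-3 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        cross1 = -a[down] / b[down]
        cross0 = -a[up] / b[up]
    cross1 = cross1[(cross1 > 0.5) & (cross1 < 2.5)]
    cross0 = cross0[(cross0 > -0.5) & (cross0 < 0.5)]
    if cross1.size < 20 or cross0.size < 20:
        return p
    gamma = float(np.quantile(cross1, 0.05))
    delta0 = float(np.quantile(cross0, 0.95))
    if gamma - delta0 <= 0.3:
        return p
    return np.clip((p - delta0) / (gamma - delta0), 0.0, 0.999)


def estimate_reference_and_purity(
    bulk: ExpressionMatrix,
    panel: ExpressionMatrix,
    max_iter: int = 60,
    tol: float = 5e-4,
    seed: int = 374,
    p_max: float = 0.999,
    ridge_frac: float = 0.01,
    n_folds: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Step 1: cancer reference profile ``m``, purities ``p``, panel weights ``θ``.

    Purities are cross-fitted: samples are scored against a reference
    learned with their fold held out, so a sample's own noise cannot be
    credited to its tumour fraction (pure-normal inputs then score near
    zero).  The raw estimates are put on the absolute scale by the
    non-negativity calibration.  Deterministic given inputs; ``seed`` is
    accepted for interface stability only.  Returns ``(m, p, theta,
    convergence)`` with ``p + theta.sum(1) == 1``.
    """
    _check_alignment(bulk, panel)
    if bulk.n_samples < 1 or panel.n_samples < 1:
        raise ValidationError("need at least one bulk and one panel column")
    X, _ = _as_normalized(bulk.values, "bulk")
    H, _ = _as_normalized(panel.values, "panel")
    n = X.shape[1]

    m, convergence = _fit_reference(X, H, max_iter, tol, p_max, ridge_frac)

    p = np.empty(n)
    if n >= 3 * n_folds:
        folds = np.arange(n) % n_folds
        for f in range(n_folds):
            hold = folds == f
            m_f, _ = _fit_reference(X[:, ~hold], H, max_iter, tol, p_max, ridge_frac)
            p[hold], _, _ = _score_against(X[:, hold], H, m_f, p_max, ridge_frac)
    else:
        p, _, _ = _score_against(X, H, m, p_max, ridge_frac)
    p = _calibrate_purity_scale(X, p)

    # final panel weights consistent with the calibrated purities
    theta = np.empty((n, H.shape[1]))
    for j in range(n):
        w, _ = nnls(H, X[:, j] - p[j] * m)
        total = w.sum()
        theta[j] = (
            w * (1.0 - p[j]) / total if total > 0 else np.full(H.shape[1], (1.0 - p[j]) / H.shape[1])
        )
    return m, p, theta, convergence


def estimate_tc_profiles(
    bulk: ExpressionMatrix,
    panel: ExpressionMatrix,
    m: np.ndarray,
    p: np.ndarray,
    lam: float = 0.3,
    theta_init: np.ndarray | None = None,
    max_iter: int = 30,
    tol: float = 1e-6,
    p_max: float = 0.999,
) -> np.ndarray:
    """Step 2: per-sample non-negative TC profiles in the bulk's linear units."""
    if lam < 0:
        raise ValidationError("λ must be ≥ 0")
    if np.any(p > p_max):
        bad = np.where(p > p_max)[0].tolist()
        raise ValidationError(f"degenerate purity > p_max for sample(s) {bad}")
    _check_alignment(bulk, panel)
    X, col_sums = _as_normalized(bulk.values, "bulk")
    H, _ = _as_normalized(panel.values, "panel")
    G, n = X.shape
    R = H.shape[1]
    # equality constraint Σθ = 1−p enforced by a dominant augmented row
    constraint_weight = 10.0
    A_aug = np.vstack([H, constraint_weight * np.ones((1, R))])
    t_out = np.empty((G, n))
    for j in range(n):
        pj = float(p[j])
        if theta_init is not None:
            th = theta_init[j].copy()
        else:
            th = np.full(R, (1.0 - pj) / R)
        t = m.copy()
        prev_obj = np.inf
        for _ in range(max_iter):
            resid = X[:, j] - H @ th
            t = np.maximum((pj * resid + lam * m) / (pj**2 + lam), 0.0)
            target = np.concatenate([X[:, j] - pj * t, [constraint_weight * (1.0 - pj)]])
            th, _ = nnls(A_aug, target)
            ssum = th.sum()
            if ssum > 0:
                th *= (1.0 - pj) / ssum
            obj = float(np.sum((X[:, j] - pj * t - H @ th) ** 2) + lam * np.sum((t - m) ** 2))
            if prev_obj - obj < tol * max(prev_obj, 1e-30):
                break
            prev_obj = obj
        t_out[:, j] = t * col_sums[j]
    return t_out


def estimate_tac_profiles(
    bulk: ExpressionMatrix, tc: np.ndarray, p: np.ndarray, eps: float = 1e-9
) -> np.ndarray:
    """Step 3: exact inversion ``s = (b − p·t) / (1 − p)``, element-wise.

    No clamping happens here; the returned TAC matrix may contain negative
    values that the log2 floor handles later.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p >= 1.0 - eps):
        bad = [bulk.sample_ids[i] for i in np.where(p >= 1.0 - eps)[0]]
        raise ValidationError(
            f"purity ≥ 1 − ε makes the TAC inversion singular for sample(s) {bad}"
        )
    b = bulk.values
    return (b - p[None, :] * tc) / (1.0 - p[None, :])


def to_log2_with_floor(
    bulk: ExpressionMatrix, tc: ExpressionMatrix, tac: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix, float]:
    """Log2-transform all three matrices with the shared floor rule.

    The floor is the minimum strictly positive intensity across the bulk and
    TC matrices; every non-positive entry (negative TAC values from the
    inversion, exact zeros from the non-negativity constraint) is replaced
    by the floor before log2.  Returns the transformed matrices and the
    linear-space floor used.
    """
    for mat, name in ((bulk, "bulk"), (tc, "tc"), (tac, "tac")):
        if mat.space != "linear":
            raise ValidationError(f"{name} matrix must be in linear space")
    pool = np.concatenate([bulk.values.ravel(), tc.values.ravel()])
    positive = pool[pool > 0]
    if positive.size == 0:
        raise ValidationError("no positive intensity in bulk/TC; cannot derive floor")
    floor = float(positive.min())

    def _log2(mat: ExpressionMatrix) -> ExpressionMatrix:
        v = np.where(mat.values <= 0, floor, mat.values)
        return ExpressionMatrix(
            np.log2(v), "log2", list(mat.gene_ids), list(mat.sample_ids),
            mat.gene_chromosomes,
        )

    return _log2(bulk), _log2(tc), _log2(tac), floor


def deconvolve_cohort(
    bulk: ExpressionMatrix,
    panel: ExpressionMatrix,
    params: DeconvolutionParams | None = None,
) -> DeconvolutionResult:
    """Run steps 1–3 on one homogeneous cohort (single reference profile)."""
    params = params or DeconvolutionParams()
    m, p, theta, conv = estimate_reference_and_purity(
        bulk, panel, max_iter=params.max_iter, tol=params.tol, p_max=params.p_max,
        ridge_frac=params.ridge_frac, n_folds=params.n_folds,
    )
    t = estimate_tc_profiles(
        bulk, panel, m, p, lam=params.lam, theta_init=theta, p_max=params.p_max
    )
    s = estimate_tac_profiles(bulk, t, p)
    return DeconvolutionResult(
        purity=pd.Series(p, index=bulk.sample_ids, name="purity"),
        tc=ExpressionMatrix(t, "linear", list(bulk.gene_ids), list(bulk.sample_ids),
                            bulk.gene_chromosomes),
        tac=ExpressionMatrix(s, "linear", list(bulk.gene_ids), list(bulk.sample_ids),
                             bulk.gene_chromosomes, allow_negative=True),
        reference=pd.DataFrame({"cohort": m}, index=bulk.gene_ids),
        panel_weights=pd.DataFrame(theta, index=bulk.sample_ids,
                                   columns=panel.sample_ids),
        convergence={"cohort": conv},
    )


def run_deconvolution_by_subtype(
    bulk: ExpressionMatrix,
    panel: ExpressionMatrix,
    clinical: ClinicalTable,
    config: RunConfig | None = None,
    exclude_normal_like: bool = True,
) -> DeconvolutionResult:
    """Per-subtype deconvolution with a shared normal panel.

    NC samples are always excluded; normal-like samples are excluded by
    default.  Subtypes with fewer than two samples are skipped with a
    warning.  Results are concatenated in the original bulk sample order.
    """
    import warnings

    config = config or RunConfig()
    params = config.deconvolution
    keep = [s for s in clinical.analysis_samples(exclude_normal_like)
            if s in set(bulk.sample_ids)]
    subtype_of = clinical.frame["subtype"]

    purity = {}
    tc_cols: dict[str, np.ndarray] = {}
    tac_cols: dict[str, np.ndarray] = {}
    theta_rows: dict[str, np.ndarray] = {}
    references = {}
    convergence = {}
    for st in sorted(set(subtype_of.loc[keep])):
        members = [s for s in keep if subtype_of.loc[s] == st]
        if len(members) < 2:
            warnings.warn(f"subtype {st} has < 2 samples; skipped", stacklevel=2)
            continue
        sub_bulk = bulk.subset_samples(members)
        m, p, theta, conv = estimate_reference_and_purity(
            sub_bulk, panel, max_iter=params.max_iter, tol=params.tol,
            p_max=params.p_max, ridge_frac=params.ridge_frac,
            n_folds=params.n_folds,
        )
        t = estimate_tc_profiles(
            sub_bulk, panel, m, p, lam=params.lam, theta_init=theta,
            p_max=params.p_max,
        )
        s_mat = estimate_tac_profiles(sub_bulk, t, p)
        references[st] = m
        convergence[st] = conv
        for i, sid in enumerate(members):
            purity[sid] = p[i]
            tc_cols[sid] = t[:, i]
            tac_cols[sid] = s_mat[:, i]
            theta_rows[sid] = theta[i]

    ordered = [s for s in bulk.sample_ids if s in purity]
    if not ordered:
        raise ValidationError("no subtype had enough samples to deconvolve")
    t_full = np.column_stack([tc_cols[s] for s in ordered])
    s_full = np.column_stack([tac_cols[s] for s in ordered])
    return DeconvolutionResult(
        purity=pd.Series([purity[s] for s in ordered], index=ordered, name="purity"),
        tc=ExpressionMatrix(t_full, "linear", list(bulk.gene_ids), ordered,
                            bulk.gene_chromosomes),
        tac=ExpressionMatrix(s_full, "linear", list(bulk.gene_ids), ordered,
                             bulk.gene_chromosomes, allow_negative=True),
        reference=pd.DataFrame(references, index=bulk.gene_ids),
        panel_weights=pd.DataFrame(
            np.vstack([theta_rows[s] for s in ordered]),
            index=ordered, columns=panel.sample_ids,
        ),
        convergence=convergence,
    )
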