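"""Gene-wise dichotomized Cox screening of overall survival to five years.

Each gene splits the cohort into high/low expression groups — at the
median when the median is above the unexpressed threshold, otherwise at
the threshold itself provided enough patients (default 79, the 80%-power
point for a hazard ratio of 2) lie above it; otherwise the gene is
excluded.  Group membership uses a strict ``>`` so ties fall to "low".
A univariate Cox proportional-hazards model (five-year administrative
censoring at 1826.25 days) yields the Wald p-value; the Schoenfeld
residual score test checks the PH assumption; BH adjustment runs across
the gene family of each profile type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .coxzph import ph_score_test
from .datatypes import FIVE_YEARS_DAYS, ClinicalTable, ExpressionMatrix
from .stats import adjust_fdr

__all__ = [
    "Dichotomization",
    "CoxGeneResult",
    "dichotomize_gene",
    "cox_dichotomized",
    "adjust_fdr",
    "significant_genes",
    "intersecting_proportion",
    "survival_screen",
    "truncate_survival",
]


@dataclass
class Dichotomization:
    gene: str
    rule: str  # "median" | "threshold" | "excluded"
    cut: float | None
    high: np.ndarray | None  # boolean per sample
    n_high: int = 0
    n_low: int = 0


@dataclass
class CoxGeneResult:
    gene: str
    profile_type: str = ""
    hr: float = np.nan
    log2hr: float = np.nan
    wald_p: float = np.nan
    q: float = np.nan
    ph_test_p: float = np.nan
    n_events: int = 0
    rule: str = ""
    estimable: bool = False
    expressed_somewhere: bool = True
    flags: dict = field(default_factory=dict)


def dichotomize_gene(
    values: np.ndarray,
    gene: str = "",
    threshold: float = -np.inf,
    min_above: int = 79,
) -> Dichotomization:
    """Median / threshold / excluded dichotomization of one gene's log2 values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return Dichotomization(gene, "excluded", None, None)
    med = float(np.median(v))
    if med >= threshold:
        rule, cut = "median", med
    elif int((v > threshold).sum()) >= min_above:
        rule, cut = "threshold", float(threshold)
    else:
        return Dichotomization(gene, "excluded", None, None)
    high = v > cut
    return Dichotomization(gene, rule, cut, high, int(high.sum()), int((~high).sum()))


def truncate_survival(
    clinical: ClinicalTable, horizon: float = FIVE_YEARS_DAYS
) -> tuple[np.ndarray, np.ndarray]:
    """Administrative censoring at the horizon (days)."""
    t = clinical.frame["os_time"].to_numpy(dtype=float)
    e = clinical.frame["os_event"].to_numpy(dtype=int)
    e = np.where(t <= horizon, e, 0)
    t = np.minimum(t, horizon)
    return t, e


def cox_dichotomized(
    dich: Dichotomization,
    clinical: ClinicalTable,
    horizon: float = FIVE_YEARS_DAYS,
) -> CoxGeneResult:
    """Univariate Cox PH of high vs low expression, survival to *horizon*."""
    res = CoxGeneResult(gene=dich.gene, rule=dich.rule)
    if dich.rule == "excluded" or dich.high is None:
        res.flags["excluded"] = True
        return res
    t, e = truncate_survival(clinical, horizon)
    high = dich.high.astype(float)
    res.n_events = int(e.sum())
    if e.sum() == 0 or e[dich.high].sum() == 0 or e[~dich.high].sum() == 0:
        res.flags["monotone_likelihood"] = True
        return res
    df = pd.DataFrame({"T": t, "E": e, "high": high})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="T", event_col="E")
    except ConvergenceError:
        res.flags["non_convergence"] = True
        return res
    beta = float(cph.params_["high"])
    res.hr = float(np.exp(beta))
    res.log2hr = beta / np.log(2.0)
    res.wald_p = float(cph.summary.loc["high", "p"])
    ph = ph_score_test(t, e, high[:, None], cph.params_.to_numpy())
    res.ph_test_p = float(ph[0])
    if not np.isfinite(res.ph_test_p):
        res.flags["ph_test_failed"] = True
    res.estimable = True
    return res


def significant_genes(
    results: list[CoxGeneResult] | pd.DataFrame,
    q_max: float = 0.05,
    min_abs_log2hr: float = 0.4,
    ph_p_min: float = 0.1,
) -> set[str]:
    """Genes passing the full significance filter: q, effect size, PH check,
    expressed somewhere, and not excluded by the dichotomization rules."""
    if isinstance(results, pd.DataFrame):
        frame = results
    else:
        frame = results_to_frame(results)
    keep = (
        (frame["q"] < q_max)
        & (frame["log2hr"].abs() > min_abs_log2hr)
        & (frame["ph_test_p"] > ph_p_min)
        & frame["expressed_somewhere"]
        & frame["estimable"]
        & (frame["rule"] != "excluded")
    )
    return set(frame.index[keep.fillna(False)])


def intersecting_proportion(a: set, b: set) -> float:
    """|A ∩ B| / min(|A|, |B|) — concordance of two significant-gene lists."""
    if not a and not b:
        raise ValueError("intersecting proportion undefined for two empty sets")
    smaller = min(len(a), len(b))
    if smaller == 0:
        return 0.0
    return len(a & b) / smaller


def results_to_frame(results: list[CoxGeneResult]) -> pd.DataFrame:
    rows = {
        r.gene: {
            "profile_type": r.profile_type,
            "hr": r.hr,
            "log2hr": r.log2hr,
            "wald_p": r.wald_p,
            "q": r.q,
            "ph_test_p": r.ph_test_p,
            "n_events": r.n_events,
            "rule": r.rule,
            "estimable": r.estimable,
            "expressed_somewhere": r.expressed_somewhere,
        }
        for r in results
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "gene"
    return frame


def survival_screen(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    threshold: float = -np.inf,
    profile_type: str = "",
    min_above: int = 79,
    horizon: float = FIVE_YEARS_DAYS,
) -> pd.DataFrame:
    """Screen every gene of one profile type; BH-adjust across the tested
    (non-excluded, estimable) genes of this family."""
    clin = clinical.subset(expr.sample_ids)
    results: list[CoxGeneResult] = []
    for i, gene in enumerate(expr.gene_ids):
        v = expr.values[i]
        dich = dichotomize_gene(v, gene, threshold, min_above)
        res = cox_dichotomized(dich, clin, horizon)
        res.profile_type = profile_type
        res.expressed_somewhere = bool((v >= threshold).any())
        results.append(res)
    frame = results_to_frame(results)
    tested = frame["estimable"] & frame["wald_p"].notna()
    q = pd.Series(np.nan, index=frame.index)
    if tested.any():
        q.loc[tested] = adjust_fdr(frame.loc[tested, "wald_p"].to_numpy())
    frame["q"] = q
    return frame
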