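"""Gene-wise TC–TAC interaction survival modelling.

For each gene, patients fall into four groups by independent high/low
dichotomization of their tumour-cell (TC) and tumour-adjacent-cell (TAC)
expression (same rules as the univariate screen).  Genes whose four groups
differ in five-year survival (log-rank q < 0.05) get a Cox model

    survival ~ TAC + TC + TC × TAC

on the two binary indicators and their product.  Each gene is then
classified by the pattern of significant terms:

* ``tc_only`` / ``tac_only`` — one main effect carries the signal;
* ``additive`` — both main effects, no interaction;
* ``saturation`` — the interaction caps the combined high/high effect at
  the dominant main effect (no gain from the second compartment);
* ``antagonistic`` — the interaction cancels the dominant main effect
  (high/high patients look like low/low);
* ``synergistic`` — the interaction amplifies beyond the dominant effect;
* ``interaction_other`` — a significant interaction with none of the
  above geometries.

The effect-size constant 0.4 (log2 hazard-ratio units) doubles as the
tolerance in the pattern geometry, and classification uses the
interaction-model terms, not the univariate screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .coxzph import ph_score_test
from .datatypes import FIVE_YEARS_DAYS, ClinicalTable, ExpressionMatrix
from .stats import adjust_fdr
from .survival import Dichotomization, dichotomize_gene, truncate_survival

GROUP_LABELS = ("HH", "HL", "LH", "LL")
TERMS = ("tc", "tac", "interaction")

LN2 = np.log(2.0)


@dataclass
class InteractionGeneResult:
    gene: str
    groups: np.ndarray | None = None  # per-sample labels from GROUP_LABELS
    group_counts: dict = field(default_factory=dict)
    logrank_p: float = np.nan
    logrank_q: float = np.nan
    terms: pd.DataFrame | None = None  # index TERMS: beta(log2), hr, p, q, ph_p
    beta_hh: float = np.nan
    relationship: str = "none"
    flags: dict = field(default_factory=dict)


def four_group_classify(
    tc_values: np.ndarray,
    tac_values: np.ndarray,
    threshold: float = -np.inf,
    min_above: int = 79,
    gene: str = "",
) -> tuple[np.ndarray | None, Dichotomization, Dichotomization]:
    """HH/HL/LH/LL per sample; ``None`` if either profile is excluded."""
    d_tc = dichotomize_gene(tc_values, gene, threshold, min_above)
    d_tac = dichotomize_gene(tac_values, gene, threshold, min_above)
    if d_tc.rule == "excluded" or d_tac.rule == "excluded":
        return None, d_tc, d_tac
    groups = np.where(
        d_tc.high,
        np.where(d_tac.high, "HH", "HL"),
        np.where(d_tac.high, "LH", "LL"),
    )
    return groups, d_tc, d_tac


def logrank_four_groups(
    groups: np.ndarray,
    clinical: ClinicalTable,
    horizon: float = FIVE_YEARS_DAYS,
) -> float:
    """k-sample log-rank p-value over the occupied groups (five-year data)."""
    t, e = truncate_survival(clinical, horizon)
    occupied = [g for g in GROUP_LABELS if (groups == g).any()]
    if len(occupied) < 2 or e.sum() == 0:
        return np.nan
    res = multivariate_logrank_test(t, groups, e)
    return float(res.p_value)


def cox_interaction(
    groups_or_indicators,
    clinical: ClinicalTable,
    horizon: float = FIVE_YEARS_DAYS,
) -> pd.DataFrame | None:
    """Cox PH with binary TC-high, TAC-high and their product.

    Accepts either the group-label vector or an ``(tc_high, tac_high)``
    tuple of boolean arrays.  Returns a term table indexed by
    ``("tc", "tac", "interaction")`` with log2 coefficients, HRs, Wald p
    and Schoenfeld PH p per term, or ``None`` when inestimable.
    """
    if isinstance(groups_or_indicators, tuple):
        tc_high, tac_high = (np.asarray(v, dtype=bool) for v in groups_or_indicators)
    else:
        g = np.asarray(groups_or_indicators)
        tc_high = np.isin(g, ("HH", "HL"))
        tac_high = np.isin(g, ("HH", "LH"))
    if tc_high.all() or (~tc_high).all() or tac_high.all() or (~tac_high).all():
        return None
    t, e = truncate_survival(clinical, horizon)
    if e.sum() == 0:
        return None
    df = pd.DataFrame(
        {
            "T": t,
            "E": e,
            "tc": tc_high.astype(float),
            "tac": tac_high.astype(float),
            "interaction": (tc_high & tac_high).astype(float),
        }
    )
    cph = CoxPHFitter(penalizer=1e-6)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="T", event_col="E")
    except ConvergenceError:
        return None
    X = df[list(TERMS)].to_numpy()
    ph_p = ph_score_test(t, e, X, cph.params_.to_numpy())
    out = pd.DataFrame(index=list(TERMS))
    out["beta"] = [float(cph.params_[k]) / LN2 for k in TERMS]
    out["hr"] = [float(np.exp(cph.params_[k])) for k in TERMS]
    out["p"] = [float(cph.summary.loc[k, "p"]) for k in TERMS]
    out["ph_p"] = ph_p
    return out


def classify_relationship(
    terms: pd.DataFrame,
    q_max: float = 0.1,
    min_abs_log2hr: float = 0.4,
    ph_p_min: float = 0.1,
) -> str:
    """Map one gene's interaction-model term table to a relationship class.

    A term "passes" iff its q-value, |log2 HR| and PH check all clear their
    cutoffs.  With a passing interaction, the high/high log-effect
    ``βHH = βTC + βTAC + βI`` is compared against the dominant main effect:
    near zero → antagonistic; equal to the dominant effect with an opposing
    interaction sign → saturation; beyond it in the same direction →
    synergistic.
    """
    if terms is None or terms["beta"].isna().any():
        return "none"
    q = terms["q"] if "q" in terms else terms["p"]
    ph = terms["ph_p"].fillna(1.0)
    passes = (q < q_max) & (terms["beta"].abs() > min_abs_log2hr) & (ph > ph_p_min)
    b_tc, b_tac, b_int = (float(terms.loc[k, "beta"]) for k in TERMS)
    p_tc, p_tac, p_int = (bool(passes.loc[k]) for k in TERMS)
    if not (p_tc or p_tac or p_int):
        return "none"
    if not p_int:
        if p_tc and p_tac:
            return "additive"
        return "tc_only" if p_tc else "tac_only"
    # significant interaction: geometry relative to the dominant main effect
    mains = {"tc": (b_tc, p_tc), "tac": (b_tac, p_tac)}
    passing = {k: b for k, (b, ok) in mains.items() if ok}
    pool = passing if passing else {k: b for k, (b, _) in mains.items()}
    b_dom = max(pool.values(), key=abs)
    b_hh = b_tc + b_tac + b_int
    tol = min_abs_log2hr
    if abs(b_hh) < tol and abs(b_dom) >= tol:
        return "antagonistic"
    if (
        abs(b_hh - b_dom) < tol
        and np.sign(b_int) != np.sign(b_dom)
        and abs(b_hh) >= tol
    ):
        return "saturation"
    if np.sign(b_int) == np.sign(b_dom) and abs(b_hh) >= abs(b_dom) + tol:
        return "synergistic"
    return "interaction_other"


def interaction_screen(
    tc: ExpressionMatrix,
    tac: ExpressionMatrix,
    clinical: ClinicalTable,
    threshold: float = -np.inf,
    min_above: int = 79,
    logrank_q_max: float = 0.05,
    q_max: float = 0.1,
    min_abs_log2hr: float = 0.4,
    horizon: float = FIVE_YEARS_DAYS,
) -> list[InteractionGeneResult]:
    """Full screen: four-group split, log-rank filter, interaction Cox model
    on passing genes, per-term BH across fitted genes, classification."""
    clin = clinical.subset(tc.sample_ids)
    results: list[InteractionGeneResult] = []
    for i, gene in enumerate(tc.gene_ids):
        res = InteractionGeneResult(gene=gene)
        groups, d_tc, d_tac = four_group_classify(
            tc.values[i], tac.values[i], threshold, min_above, gene
        )
        if groups is None:
            res.flags["excluded"] = True
        else:
            res.groups = groups
            res.group_counts = {g: int((groups == g).sum()) for g in GROUP_LABELS}
            res.logrank_p = logrank_four_groups(groups, clin, horizon)
        results.append(res)

    tested = [r for r in results if np.isfinite(r.logrank_p)]
    if tested:
        qs = adjust_fdr([r.logrank_p for r in tested])
        for r, q in zip(tested, qs):
            r.logrank_q = float(q)

    fitted = []
    for r in results:
        if np.isfinite(r.logrank_q) and r.logrank_q < logrank_q_max:
            terms = cox_interaction(r.groups, clin, horizon)
            if terms is None:
                r.flags["inestimable_model"] = True
            else:
                r.terms = terms
                fitted.append(r)
    # per-term BH families across all fitted genes
    if fitted:
        for term in TERMS:
            qs = adjust_fdr([r.terms.loc[term, "p"] for r in fitted])
            for r, q in zip(fitted, qs):
                r.terms.loc[term, "q"] = float(q)
    for r in results:
        if r.terms is not None:
            r.beta_hh = float(r.terms["beta"].sum())
            r.relationship = classify_relationship(r.terms, q_max, min_abs_log2hr)
    return results


def summarize_relationships(results: list[InteractionGeneResult]) -> pd.DataFrame:
    """Counts and shares per relationship class over classified genes."""
    classes = [r.relationship for r in results if r.terms is not None]
    if not classes:
        return pd.DataFrame(columns=["count", "fraction"])
    counts = pd.Series(classes).value_counts()
    return pd.DataFrame({"count": counts, "fraction": counts / counts.sum()})


def interaction_results_frame(results: list[InteractionGeneResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "gene": r.gene,
            "logrank_p": r.logrank_p,
            "logrank_q": r.logrank_q,
            "beta_hh": r.beta_hh,
            "relationship": r.relationship,
        }
        for g, c in r.group_counts.items():
            row[f"n_{g}"] = c
        if r.terms is not None:
            for term in TERMS:
                row[f"beta_{term}"] = r.terms.loc[term, "beta"]
                row[f"q_{term}"] = r.terms.loc[term, "q"] if "q" in r.terms else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
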