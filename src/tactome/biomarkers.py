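"""Random multi-gene biomarker benchmarking with random forests.

Thousands of random gene signatures (50 genes each by default) are
evaluated per profile type (bulk, TC, TAC, TC+TAC) for predicting
five-year survival: patients dead within five years are cases, patients
alive with at least five years of follow-up are controls, and patients
censored earlier are excluded (the only leakage-free binary labelling).
The identical gene draws are reused across profile types so the
distributions are directly comparable.

Per signature and profile, a random forest is tuned by three-fold
cross-validation on the training split (feature-subsample size over
{√m, m/3, m/2}; classification threshold by Youden's J on the pooled
out-of-fold probabilities), refit on the full training split, and scored
on the withheld test split by AUC and by the Cox hazard ratio of the
predicted class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .datatypes import FIVE_YEARS_DAYS, ClinicalTable, ExpressionMatrix, ValidationError
from .survival import truncate_survival

LN2 = np.log(2.0)


@dataclass
class SignatureEvaluation:
    signature_id: int
    profile_type: str
    genes: list[str]
    mtry: int
    threshold: float
    cv_auc: float
    test_auc: float
    test_hr: float
    test_log2hr: float


def make_labels(
    clinical: ClinicalTable, horizon: float = FIVE_YEARS_DAYS
) -> tuple[pd.Series, pd.Series]:
    """Binary five-year survival labels and a usability mask.

    Label 1 = died within the horizon; label 0 = alive with follow-up of at
    least the horizon; censored before the horizon → masked out.
    """
    f = clinical.frame
    died = (f["os_event"] == 1) & (f["os_time"] <= horizon)
    alive = f["os_time"] >= horizon
    usable = died | alive
    if not usable.any():
        raise ValidationError("no sample has usable five-year survival status")
    labels = pd.Series(np.where(died, 1, 0), index=f.index, name="dead_5y")
    return labels, pd.Series(usable.to_numpy(), index=f.index, name="usable")


def split_cohort(
    sample_ids: list[str], n_train: int, n_test: int, seed: int
) -> tuple[list[str], list[str]]:
    """Disjoint, seed-deterministic train/test split."""
    if n_train + n_test > len(sample_ids):
        raise ValidationError("split sizes exceed the cohort")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(sample_ids))
    train = [sample_ids[i] for i in sorted(perm[:n_train])]
    test = [sample_ids[i] for i in sorted(perm[n_train : n_train + n_test])]
    return train, test


def draw_signatures(
    gene_ids: list[str], n_signatures: int, genes_per: int, seed: int
) -> list[list[str]]:
    """Seeded random gene sets, shared across profile types."""
    rng = np.random.default_rng(seed)
    return [
        [gene_ids[i] for i in rng.choice(len(gene_ids), genes_per, replace=False)]
        for _ in range(n_signatures)
    ]


def _mtry_grid(m: int) -> list[int]:
    grid = {max(1, int(round(np.sqrt(m)))), max(1, m // 3), max(1, m // 2)}
    return sorted(grid)


def _cv_folds(n: int, folds: int) -> list[np.ndarray]:
    idx = np.arange(n)
    return [idx[f::folds] for f in range(folds)]


def _fit_forest(X, y, mtry: int, n_trees: int, seed: int) -> RandomForestClassifier:
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_features=mtry, random_state=seed, n_jobs=1
    )
    clf.fit(X, y)
    return clf


def evaluate_signature(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    n_trees: int,
    folds: int,
    seed: int,
) -> tuple[int, float, float, float, np.ndarray]:
    """Tune, refit and test one signature on one profile type.

    Returns ``(mtry, threshold, cv_auc, test_auc, fitted_forest)``.
    """
    if len(np.unique(y_train)) < 2:
        raise ValidationError("training labels are single-class")
    m = X_train.shape[1]
    fold_idx = _cv_folds(len(y_train), folds)
    best = (None, -np.inf, None)  # (mtry, cv_auc, oof_probs)
    for mtry in _mtry_grid(m):
        oof = np.full(len(y_train), np.nan)
        for f, hold in enumerate(fold_idx):
            mask = np.ones(len(y_train), dtype=bool)
            mask[hold] = False
            if len(np.unique(y_train[mask])) < 2:
                continue
            clf = _fit_forest(X_train[mask], y_train[mask], mtry, n_trees, seed)
            oof[hold] = clf.predict_proba(X_train[hold])[:, 1]
        ok = ~np.isnan(oof)
        if ok.sum() == 0 or len(np.unique(y_train[ok])) < 2:
            continue
        auc = roc_auc_score(y_train[ok], oof[ok])
        if auc > best[1]:
            best = (mtry, auc, oof)
    if best[0] is None:
        raise ValidationError("cross-validation failed for every feature size")
    mtry, cv_auc, oof = best
    # classification threshold: Youden's J on pooled out-of-fold probabilities
    grid = np.arange(0.1, 0.91, 0.1)
    ok = ~np.isnan(oof)
    youden = [
        ((oof[ok] > th) & (y_train[ok] == 1)).sum() / max((y_train[ok] == 1).sum(), 1)
        - ((oof[ok] > th) & (y_train[ok] == 0)).sum() / max((y_train[ok] == 0).sum(), 1)
        for th in grid
    ]
    threshold = float(grid[int(np.argmax(youden))])
    clf = _fit_forest(X_train, y_train, mtry, n_trees, seed)
    probs = clf.predict_proba(X_test)[:, 1]
    test_auc = (
        roc_auc_score(y_test, probs) if len(np.unique(y_test)) > 1 else np.nan
    )
    return mtry, threshold, float(cv_auc), float(test_auc), clf


def _test_hazard_ratio(
    predicted_class: np.ndarray, clinical_test: ClinicalTable
) -> tuple[float, float]:
    """Cox HR of the predicted class over the full truncated test survival."""
    if predicted_class.all() or (~predicted_class).all():
        return np.nan, np.nan
    t, e = truncate_survival(clinical_test)
    if e.sum() == 0:
        return np.nan, np.nan
    df = pd.DataFrame({"T": t, "E": e, "x": predicted_class.astype(float)})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter(penalizer=1e-6).fit(df, "T", "E")
        beta = float(cph.params_["x"])
        return float(np.exp(beta)), beta / LN2
    except Exception:
        return np.nan, np.nan


def evaluate_signatures(
    profiles: dict[str, ExpressionMatrix],
    clinical: ClinicalTable,
    train_ids: list[str],
    test_ids: list[str],
    n_signatures: int = 100,
    genes_per: int = 50,
    n_trees: int = 500,
    folds: int = 3,
    seed: int = 42,
) -> pd.DataFrame:
    """Evaluate the same random signatures on every profile type.

    *profiles* maps profile-type name → log2 ExpressionMatrix.  For the
    combined ``tc_tac`` profile the feature block stacks the TC and TAC
    vectors of the signature genes (when both are present).
    """
    labels, usable = make_labels(clinical)
    first = next(iter(profiles.values()))
    gene_ids = first.gene_ids
    signatures = draw_signatures(gene_ids, n_signatures, genes_per, seed)

    tr_u = [s for s in train_ids if usable.get(s, False)]
    te_u = [s for s in test_ids if usable.get(s, False)]
    y_train = labels.loc[tr_u].to_numpy()
    y_test = labels.loc[te_u].to_numpy()
    clin_test = clinical.subset(test_ids)

    def blocks(name: str, genes: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if name == "tc_tac":
            parts_tr, parts_te, parts_all = [], [], []
            for sub_name in ("tc", "tac"):
                mat = profiles[sub_name].subset_genes(genes)
                fr = mat.to_frame()
                parts_tr.append(fr[tr_u].to_numpy().T)
                parts_te.append(fr[te_u].to_numpy().T)
                parts_all.append(fr[test_ids].to_numpy().T)
            return (
                np.hstack(parts_tr),
                np.hstack(parts_te),
                np.hstack(parts_all),
            )
        fr = profiles[name].subset_genes(genes).to_frame()
        return fr[tr_u].to_numpy().T, fr[te_u].to_numpy().T, fr[test_ids].to_numpy().T

    profile_names = list(profiles)
    if {"tc", "tac"} <= set(profile_names):
        profile_names.append("tc_tac")
    rows = []
    for sig_id, genes in enumerate(signatures):
        for name in profile_names:
            X_tr, X_te, X_all = blocks(name, genes)
            mtry, th, cv_auc, test_auc, clf = evaluate_signature(
                X_tr, y_train, X_te, y_test, n_trees, folds, seed + sig_id
            )
            # predicted class over the full test split for the Cox HR
            pred_all = clf.predict_proba(X_all)[:, 1] > th
            hr, log2hr = _test_hazard_ratio(pred_all, clin_test)
            rows.append(
                {
                    "signature_id": sig_id,
                    "profile_type": name,
                    "mtry": mtry,
                    "threshold": th,
                    "cv_auc": cv_auc,
                    "test_auc": test_auc,
                    "test_hr": hr,
                    "test_log2hr": log2hr,
                }
            )
    return pd.DataFrame(rows)


def summarize_distributions(evals: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of AUC and log2HR per profile type, plus the
    AUC rank-correlation between profile types."""
    if evals.empty:
        raise ValidationError("no signature evaluations to summarize")
    rows = {}
    for name, grp in evals.groupby("profile_type"):
        rows[name] = {
            "n": len(grp),
            "auc_median": grp["test_auc"].median(),
            "auc_q25": grp["test_auc"].quantile(0.25),
            "auc_q75": grp["test_auc"].quantile(0.75),
            "log2hr_median": grp["test_log2hr"].median(),
            "best_auc": grp["test_auc"].max(),
        }
    return pd.DataFrame(rows).T


def auc_rank_correlation(evals: pd.DataFrame, a: str, b: str) -> float:
    """Spearman correlation of per-signature AUC between two profile types."""
    pa = evals[evals["profile_type"] == a].set_index("signature_id")["test_auc"]
    pb = evals[evals["profile_type"] == b].set_index("signature_id")["test_auc"]
    common = pa.index.intersection(pb.index)
    from scipy.stats import spearmanr

    return float(spearmanr(pa.loc[common], pb.loc[common]).statistic)
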