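"""Expression QC: unexpressed-gene thresholding, gene-wise scaling,
variable-gene selection and purity-vs-pathology concordance.

In an all-female cohort, chromosome-Y genes cannot be expressed, so their
maximum observed log2 intensity defines the array's "unexpressed"
threshold (≈ 6.5 on HT-12-style data).  Genes below that threshold in
every patient carry no usable signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix, ValidationError


@dataclass
class ExpressionThreshold:
    value: float
    source: str  # "chrY_derived" or "manual"
    n_chry_genes: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValidationError("expression threshold must be finite")
        if self.source == "chrY_derived" and self.n_chry_genes < 1:
            raise ValidationError("chrY-derived threshold needs ≥ 1 chrY gene")


def unexpressed_threshold(
    expr: ExpressionMatrix,
    chry_genes: list[str] | None = None,
    override: float | None = None,
) -> ExpressionThreshold:
    """Threshold = max log2 intensity over all chrY genes and samples.

    An explicit *override* short-circuits the derivation (used when no
    chromosome annotation is available).
    """
    if override is not None:
        return ExpressionThreshold(float(override), "manual")
    if chry_genes is None:
        chry_genes = expr.chry_genes()
    present = [g for g in chry_genes if g in set(expr.gene_ids)]
    if not present:
        raise ValidationError("no chrY genes present and no override given")
    sub = expr.subset_genes(present)
    return ExpressionThreshold(float(sub.values.max()), "chrY_derived", len(present))


def flag_unexpressed(expr: ExpressionMatrix, threshold: ExpressionThreshold | float) -> pd.Series:
    """A gene is unexpressed iff its intensity is strictly below the
    threshold in every sample."""
    t = threshold.value if isinstance(threshold, ExpressionThreshold) else float(threshold)
    flags = (expr.values < t).all(axis=1)
    return pd.Series(flags, index=expr.gene_ids, name="unexpressed")


# pathologist cellularity is categorical: <40% (low-moderate), 40–70%
# (moderate), >70% (high).  The concordance rules flag only conservative,
# unambiguous disagreements with the molecular estimate.
_HIGHER_MOLECULAR = {"moderate": 0.95, "low_moderate": 0.65}
_HIGHER_PATHOLOGIST = {"moderate": 0.15, "high": 0.45}


def compare_purity_estimates(purity: pd.Series, clinical: ClinicalTable) -> pd.DataFrame:
    """Classify each sample's molecular purity against the pathologist
    cellularity category.

    ``higher_molecular``: moderate cellularity with purity > 0.95, or
    low-moderate with purity > 0.65.  ``higher_pathologist``: moderate with
    purity < 0.15, or high with purity < 0.45.  Everything else (boundaries
    included) is concordant.  Samples with unknown cellularity are skipped
    with a warning.
    """
    rows = []
    skipped = 0
    for sid, p in purity.items():
        if sid not in clinical.frame.index:
            continue
        cat = clinical.frame.loc[sid, "cellularity"]
        if cat not in ("low_moderate", "moderate", "high"):
            skipped += 1
            continue
        if cat in _HIGHER_MOLECULAR and p > _HIGHER_MOLECULAR[cat]:
            verdict = "higher_molecular"
        elif cat in _HIGHER_PATHOLOGIST and p < _HIGHER_PATHOLOGIST[cat]:
            verdict = "higher_pathologist"
        else:
            verdict = "concordant"
        rows.append((sid, cat, float(p), verdict))
    if skipped:
        warnings.warn(f"{skipped} samples with unknown cellularity skipped", stacklevel=2)
    return pd.DataFrame(rows, columns=["sample_id", "cellularity", "purity", "verdict"]).set_index("sample_id")


def scale_genewise(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene row (sample SD, n−1).  Constant rows become zeros
    with a warning."""
    v = expr.values
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=1, keepdims=True)
    zero = (sd.ravel() == 0) | ~np.isfinite(sd.ravel())
    if zero.any():
        warnings.warn(f"{int(zero.sum())} constant gene rows scaled to zeros", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = (v - mean) / sd
    scaled[zero, :] = 0.0
    return ExpressionMatrix(
        scaled, expr.space, list(expr.gene_ids), list(expr.sample_ids),
        expr.gene_chromosomes, allow_negative=True,
    )


def select_variable_genes(
    bulk: ExpressionMatrix, tc: ExpressionMatrix, tac: ExpressionMatrix,
    min_sd: float = 1.0,
) -> list[str]:
    """Keep a gene iff its log2 SD is strictly greater than *min_sd* in at
    least one of the bulk, TC or TAC matrices."""
    if not (bulk.gene_ids == tc.gene_ids == tac.gene_ids):
        raise ValidationError("variable-gene selection requires aligned gene lists")
    keep = np.zeros(len(bulk.gene_ids), dtype=bool)
    for mat in (bulk, tc, tac):
        keep |= mat.values.std(axis=1, ddof=1) > min_sd
    return [g for g, k in zip(bulk.gene_ids, keep) if k]
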