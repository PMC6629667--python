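"""Core domain containers for bulk-tumour transcriptome deconvolution.

An :class:`ExpressionMatrix` is a genes × samples block of microarray-style
intensities with an explicit ``space`` flag (``linear`` or ``log2``), because
the mixing identity ``b = p·t + (1−p)·s`` only holds in linear space while
all downstream statistics run in log2 space.  :class:`ClinicalTable` carries
overall survival, intrinsic subtype, pathologist cellularity and receptor
status; :class:`MutationMatrix` is a binary driver-gene × sample indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SUBTYPES = ("Basal", "Her2", "LumA", "LumB", "Normal", "NC")
CELLULARITY_LEVELS = ("low_moderate", "moderate", "high", "unknown")
RECEPTOR_LEVELS = ("pos", "neg", "unknown")

#: five-year horizon used for administrative censoring, in days
FIVE_YEARS_DAYS = 1826.25


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


class FormatError(ValueError):
    """Raised when an on-disk table cannot be parsed into a container."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with an explicit intensity space.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_genes, n_samples)``.
    space
        ``"linear"`` or ``"log2"``.  Linear-space values must be ≥ 0.
    gene_ids, sample_ids
        Ordered unique identifiers for rows and columns.
    gene_chromosomes
        Optional map gene id → chromosome label (used to locate chrY genes
        for the unexpressed-intensity threshold).
    """

    values: np.ndarray
    space: str
    gene_ids: list[str]
    sample_ids: list[str]
    gene_chromosomes: dict[str, str] | None = None
    #: pre-floor TAC matrices from the mixing inversion may carry negative
    #: linear values; they must opt out of the non-negativity invariant
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.space not in ("linear", "log2"):
            raise ValidationError(f"unknown expression space {self.space!r}")
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if (
            self.space == "linear"
            and not self.allow_negative
            and self.values.size
            and np.nanmin(self.values) < 0
        ):
            g, s = np.unravel_index(np.nanargmin(self.values), self.values.shape)
            raise ValidationError(
                "negative value in linear-space matrix at gene "
                f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        space: str,
        gene_chromosomes: Mapping[str, str] | None = None,
    ) -> "ExpressionMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            space=space,
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            gene_chromosomes=dict(gene_chromosomes) if gene_chromosomes else None,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            self.values[:, idx],
            self.space,
            list(self.gene_ids),
            [self.sample_ids[i] for i in idx],
            self.gene_chromosomes,
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(
            self.values[idx, :],
            self.space,
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.gene_chromosomes,
        )

    def chry_genes(self) -> list[str]:
        if not self.gene_chromosomes:
            return []
        return [g for g in self.gene_ids if self.gene_chromosomes.get(g) in ("Y", "chrY")]


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation (one row per sample)."""

    frame: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("os_time", "os_event", "subtype", "cellularity",
                "er_status", "pr_status", "her2_status")

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in self.REQUIRED if c not in f.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        if f.index.has_duplicates:
            dups = f.index[f.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids in clinical table: {dups}")
        if (f["os_time"] < 0).any():
            raise ValidationError("os_time must be ≥ 0")
        if not f["os_event"].isin([0, 1]).all():
            bad = f.loc[~f["os_event"].isin([0, 1])].index.tolist()
            raise ValidationError(f"os_event must be 0/1; offending samples: {bad}")
        unknown = ~f["subtype"].isin(SUBTYPES)
        if unknown.any():
            # unrecognized subtype strings collapse to NC so they can be
            # excluded downstream like any unclassified sample
            import warnings

            warnings.warn(
                f"{int(unknown.sum())} unknown subtype labels mapped to NC",
                stacklevel=2,
            )
            f.loc[unknown, "subtype"] = "NC"

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.frame.loc[list(sample_ids)].copy())

    def analysis_samples(self, exclude_normal_like: bool = True) -> list[str]:
        """Samples retained for the main analysis: NC always excluded,
        normal-like excluded by default."""
        drop = {"NC"}
        if exclude_normal_like:
            drop.add("Normal")
        keep = ~self.frame["subtype"].isin(drop)
        return [str(s) for s in self.frame.index[keep]]


@dataclass
class MutationMatrix:
    """Binary non-silent-mutation indicator, driver genes × samples."""

    indicator: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator)
        if self.indicator.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("mutation matrix shape does not match ids")
        if not np.isin(self.indicator, [0, 1]).all():
            raise ValidationError("mutation matrix entries must be 0/1")
        self.indicator = self.indicator.astype(np.int8)
        _check_unique(self.gene_ids, "driver gene")
        _check_unique(self.sample_ids, "sample")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.indicator, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class DeconvolutionResult:
    """Output of the three-step purity / TC / TAC deconvolution."""

    purity: pd.Series  # per sample, RNA-signal fraction in [0, 1]
    tc: ExpressionMatrix  # linear
    tac: ExpressionMatrix  # linear, may contain negatives pre-floor
    reference: pd.DataFrame  # per-subtype cancer reference profile (simplex)
    panel_weights: pd.DataFrame  # samples × panel columns, non-negative
    convergence: dict = field(default_factory=dict)
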