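"""TSV readers/writers for expression, clinical and mutation tables.

TSV is the canonical on-disk format (gene rows, sample columns).  The
intensity space of an expression matrix cannot be carried by a TSV, so each
matrix file gets a JSON sidecar ``<file>.meta.json`` holding the space flag
and, when known, the gene → chromosome map.  All writers emit full ``repr``
float precision so that write → read round-trips are bit-lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    FormatError,
    MutationMatrix,
)


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_expression(path: str | Path, space_hint: str | None = None) -> ExpressionMatrix:
    """Read a genes × samples TSV; space from the sidecar, else *space_hint*.

    Raises :class:`FormatError` on duplicate ids or unparseable numeric
    cells (reported with gene/sample context).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene id(s) in {path.name}: {dup}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample id(s) in {path.name}: {dup}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        try:
            # python-level float() is correctly rounded (pandas' fast
            # parser is not), keeping round-trips bit-exact
            values[:, j] = [float(v) for v in frame[col]]
        except (ValueError, TypeError):
            bad = pd.to_numeric(frame[col], errors="coerce")
            genes = frame.index[bad.isna() & frame[col].notna()].tolist()
            raise FormatError(
                f"non-numeric cell(s) in {path.name}, sample {col!r}, gene(s) {genes}"
            ) from None

    space = space_hint
    chrom = None
    meta_path = _sidecar(path)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        space = meta.get("space", space)
        chrom = meta.get("gene_chromosomes")
    if space is None:
        raise FormatError(
            f"no space sidecar for {path.name} and no space_hint given"
        )
    return ExpressionMatrix(
        values=values,
        space=space,
        gene_ids=[str(g) for g in frame.index],
        sample_ids=[str(s) for s in frame.columns],
        gene_chromosomes=chrom,
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV plus a JSON sidecar with the space flag."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # shortest decimal string that parses back bit-exactly
    matrix.to_frame().to_csv(
        path, sep="\t", float_format=lambda x: repr(float(x)), lineterminator="\n"
    )
    meta = {"space": matrix.space}
    if matrix.gene_chromosomes:
        meta["gene_chromosomes"] = matrix.gene_chromosomes
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def read_clinical(path: str | Path) -> ClinicalTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    return ClinicalTable(frame)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, sep="\t", index_label="sample_id", lineterminator="\n")


def read_mutations(path: str | Path) -> MutationMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return MutationMatrix(
        indicator=frame.to_numpy(),
        gene_ids=[str(g) for g in frame.index],
        sample_ids=[str(s) for s in frame.columns],
    )


def write_mutations(matrix: MutationMatrix, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_frame().to_csv(path, sep="\t", lineterminator="\n")
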