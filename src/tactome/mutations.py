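"""Mutation-associated differential expression per subtype.

Candidate driver genes mutated in more than 50 patients of a subtype
split that subtype into mutated vs wild-type; a moderated linear model
(empirical-Bayes variance shrinkage, BH adjustment) tests every gene for
differential abundance in each profile type (bulk, TC, TAC).  The report
marks cis effects (the driver's own expression responds) and counts
associations that bulk profiles alone would have missed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix, MutationMatrix, ValidationError
from .stats import moderated_ttest


@dataclass
class MutationDEResult:
    subtype: str
    driver: str
    n_mutated: int
    n_wildtype: int
    tables: dict = field(default_factory=dict)  # profile type → DE frame
    cis: dict = field(default_factory=dict)  # profile type → (log2fc, q) or None
    found_in: pd.DataFrame | None = None  # significant targets × profile types
    n_bulk_missed: int = 0


def select_testable(
    mutations: MutationMatrix,
    clinical: ClinicalTable,
    min_mutated: int = 50,
) -> list[tuple[str, str]]:
    """(subtype, driver) pairs with strictly more than *min_mutated* mutated
    patients inside the subtype."""
    mut = mutations.to_frame()
    subtype = clinical.frame["subtype"]
    common = [s for s in mutations.sample_ids if s in subtype.index]
    pairs = []
    for st in sorted(subtype.loc[common].unique()):
        members = [s for s in common if subtype.loc[s] == st]
        counts = mut[members].sum(axis=1)
        for driver in mutations.gene_ids:
            if counts[driver] > min_mutated:
                pairs.append((st, driver))
    return pairs


def differential_expression(
    expr: ExpressionMatrix, group: np.ndarray
) -> pd.DataFrame:
    """Moderated two-group DE (group-1 minus group-0 log2FC) over all genes."""
    table = moderated_ttest(expr.values, group)
    table.index = pd.Index(expr.gene_ids, name="gene")
    return table


def cis_trans_report(
    de_tables: dict[str, pd.DataFrame],
    driver: str,
    subtype: str = "",
    n_mutated: int = 0,
    n_wildtype: int = 0,
    q_max: float = 0.05,
) -> MutationDEResult:
    """Assemble the per-driver report from DE tables keyed by profile type."""
    res = MutationDEResult(subtype, driver, n_mutated, n_wildtype, dict(de_tables))
    sig = {}
    for name, table in de_tables.items():
        if driver in table.index:
            res.cis[name] = (
                float(table.loc[driver, "log2fc"]),
                float(table.loc[driver, "q"]),
            )
        else:
            res.cis[name] = None
        sig[name] = set(table.index[table["q"] < q_max])
    all_targets = sorted(set().union(*sig.values())) if sig else []
    res.found_in = pd.DataFrame(
        {name: [t in sig[name] for t in all_targets] for name in de_tables},
        index=pd.Index(all_targets, name="gene"),
    )
    if {"tc", "tac"} <= sig.keys() and "bulk" in sig:
        res.n_bulk_missed = len((sig["tc"] | sig["tac"]) - sig["bulk"])
    return res


def mutation_expression_screen(
    profiles: dict[str, ExpressionMatrix],
    mutations: MutationMatrix,
    clinical: ClinicalTable,
    min_mutated: int = 50,
    q_max: float = 0.05,
) -> list[MutationDEResult]:
    """Run the per-subtype mutated-vs-wildtype DE screen for every testable
    (subtype, driver) pair and every profile type."""
    if not profiles:
        raise ValidationError("no expression profiles given")
    pairs = select_testable(mutations, clinical, min_mutated)
    mut = mutations.to_frame()
    subtype = clinical.frame["subtype"]
    out = []
    for st, driver in pairs:
        members = [
            s
            for s in next(iter(profiles.values())).sample_ids
            if s in subtype.index and subtype.loc[s] == st and s in mut.columns
        ]
        status = mut.loc[driver, members].to_numpy() == 1
        if status.sum() < 2 or (~status).sum() < 2:
            continue
        tables = {}
        for name, expr in profiles.items():
            tables[name] = differential_expression(expr.subset_samples(members), status)
        out.append(
            cis_trans_report(
                tables, driver, st, int(status.sum()), int((~status).sum()), q_max
            )
        )
    return out
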