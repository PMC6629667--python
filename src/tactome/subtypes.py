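"""Intrinsic-subtype analysis: nearest-centroid classification over a gene
panel, divisive (DIANA) and consensus clustering, and one-vs-rest
differential expression for marker selection.

The nearest-centroid classifier is a trained stand-in with the shape of a
PAM50-style classifier: per-subtype mean profiles over a marker-gene
panel in gene-wise scaled log2 space, assignment by highest Spearman
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .datatypes import ExpressionMatrix, ValidationError
from .stats import moderated_ttest


@dataclass
class CentroidModel:
    centroids: pd.DataFrame  # genes × subtypes, scaled log2 space
    gene_panel: list[str]
    training_n: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.centroids.shape[1] < 2:
            raise ValidationError("need centroids for at least two subtypes")


@dataclass
class ClusteringResult:
    labels: pd.Series  # 1..k per sample
    method: str  # "diana" | "consensus"
    k: int
    consensus_matrix: pd.DataFrame | None = None
    parameters: dict = field(default_factory=dict)


def train_centroids(
    expr: ExpressionMatrix, labels: pd.Series, gene_panel: list[str]
) -> CentroidModel:
    """Per-subtype mean of scaled panel-gene values."""
    missing = [g for g in gene_panel if g not in set(expr.gene_ids)]
    if missing:
        raise ValidationError(f"panel genes missing from expression: {missing[:5]}")
    sub = expr.subset_genes(gene_panel)
    frame = sub.to_frame()
    cents = {}
    n = {}
    for st in sorted(labels.unique()):
        members = [s for s in sub.sample_ids if labels.get(s) == st]
        if not members:
            raise ValidationError(f"subtype {st} has no training samples")
        cents[st] = frame[members].mean(axis=1)
        n[st] = len(members)
    return CentroidModel(pd.DataFrame(cents), list(gene_panel), n)


def classify_nearest_centroid(
    expr: ExpressionMatrix, model: CentroidModel
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each sample to the centroid with the highest Spearman
    correlation over the panel; ties break by the model's subtype order."""
    if len(model.gene_panel) < 3:
        raise ValidationError("nearest-centroid needs at least three panel genes")
    sub = expr.subset_genes(model.gene_panel)
    # Spearman via Pearson on ranks
    sample_ranks = np.apply_along_axis(rankdata, 0, sub.values)
    cent_ranks = np.apply_along_axis(rankdata, 0, model.centroids.to_numpy())

    def _columns_standardized(m: np.ndarray) -> np.ndarray:
        c = m - m.mean(axis=0, keepdims=True)
        sd = c.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        return c / sd

    a = _columns_standardized(sample_ranks)
    b = _columns_standardized(cent_ranks)
    corr = a.T @ b / a.shape[0]  # samples × subtypes
    corr_df = pd.DataFrame(corr, index=sub.sample_ids, columns=model.centroids.columns)
    best = corr_df.to_numpy().argmax(axis=1)  # argmax takes first on ties
    labels = pd.Series(
        [model.centroids.columns[i] for i in best], index=sub.sample_ids, name="subtype"
    )
    return labels, corr_df


# ---------------------------------------------------------------------------
# DIANA — divisive analysis clustering (Kaufman & Rousseeuw)
# ---------------------------------------------------------------------------


def _diana_split(d: np.ndarray, members: list[int]) -> tuple[list[int], list[int]]:
    """Split one cluster: seed the splinter with the object of maximal
    average dissimilarity, then migrate objects with positive attraction
    difference toward the splinter."""
    old = list(members)
    sub = d[np.ix_(old, old)]
    avg = sub.sum(axis=1) / (len(old) - 1)
    seed = int(np.argmax(avg))
    splinter = [old.pop(seed)]
    while len(old) > 1:
        gains = []
        for i, obj in enumerate(old):
            a = d[obj, old].sum() / (len(old) - 1)  # to remaining (excl. self)
            b = d[obj, splinter].mean()
            gains.append(a - b)
        best = int(np.argmax(gains))
        if gains[best] <= 0:
            break
        splinter.append(old.pop(best))
    return old, splinter


def _diameter(d: np.ndarray, members: list[int]) -> float:
    if len(members) < 2:
        return 0.0
    return float(d[np.ix_(members, members)].max())


def diana_cluster(
    expr: ExpressionMatrix, gene_panel: list[str] | None = None, k: int = 2
) -> ClusteringResult:
    """Divisive hierarchical clustering of samples cut at *k* clusters.

    Distance is 1 − Pearson correlation between sample vectors over the
    panel genes.  Starting from one all-sample cluster, the cluster with
    the largest diameter is repeatedly split until *k* clusters exist.
    """
    if k < 2:
        raise ValidationError("k must be ≥ 2")
    if expr.n_samples < k:
        raise ValidationError("need at least k samples")
    sub = expr.subset_genes(gene_panel) if gene_panel else expr
    v = sub.values
    sd = v.std(axis=0)
    if np.any(sd == 0):
        bad = [sub.sample_ids[i] for i in np.where(sd == 0)[0]]
        raise ValidationError(f"constant sample vector(s), correlation undefined: {bad}")
    d = squareform(pdist(v.T, metric="correlation"))
    clusters: list[list[int]] = [list(range(sub.n_samples))]
    while len(clusters) < k:
        diams = [_diameter(d, c) for c in clusters]
        target = int(np.argmax(diams))
        if diams[target] == 0:
            break
        rest, splinter = _diana_split(d, clusters[target])
        clusters[target] = rest
        clusters.append(splinter)
    labels = np.empty(sub.n_samples, dtype=int)
    # deterministic label order: by smallest member index
    for lab, c in enumerate(sorted(clusters, key=min), start=1):
        labels[c] = lab
    return ClusteringResult(
        labels=pd.Series(labels, index=sub.sample_ids, name="cluster"),
        method="diana",
        k=len(clusters),
        parameters={"distance": "1-pearson"},
    )


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------


def consensus_cluster(
    expr: ExpressionMatrix,
    variable_genes: list[str] | None = None,
    k: int = 4,
    reps: int = 50,
    subsample: float = 0.8,
    seed: int = 17,
) -> ClusteringResult:
    """Subsampled consensus clustering with Ward linkage on Jaccard distances.

    Per repetition, 80% of samples and 80% of genes are drawn; each gene is
    binarized at its per-gene median (Jaccard needs binary data); samples
    are clustered by Ward linkage on pairwise Jaccard distances and cut at
    *k*.  The consensus matrix is the co-clustering frequency normalized by
    the co-sampling frequency; final labels come from Ward clustering of
    1 − consensus.
    """
    if reps < 10:
        raise ValidationError("need at least 10 consensus repetitions")
    sub = expr.subset_genes(variable_genes) if variable_genes else expr
    if sub.n_genes == 0:
        raise ValidationError("variable gene set is empty")
    n = sub.n_samples
    if int(np.ceil(subsample * n)) < k:
        raise ValidationError("k exceeds the samples available per repetition")
    rng = np.random.default_rng(seed)
    # binarize once on the full matrix: per-gene median split
    med = np.median(sub.values, axis=1, keepdims=True)
    binary = sub.values > med
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    n_s = int(np.ceil(subsample * n))
    n_g = max(1, int(np.ceil(subsample * sub.n_genes)))
    for _ in range(reps):
        s_idx = np.sort(rng.choice(n, n_s, replace=False))
        g_idx = np.sort(rng.choice(sub.n_genes, n_g, replace=False))
        block = binary[np.ix_(g_idx, s_idx)]
        dist = pdist(block.T, metric="jaccard")
        z = linkage(dist, method="ward")
        labs = fcluster(z, t=k, criterion="maxclust")
        sampled[np.ix_(s_idx, s_idx)] += 1.0
        same = labs[:, None] == labs[None, :]
        together[np.ix_(s_idx, s_idx)] += same
    with np.errstate(divide="ignore", invalid="ignore"):
        consensus = np.where(sampled > 0, together / sampled, 0.0)
    np.fill_diagonal(consensus, 1.0)
    final = fcluster(
        linkage(squareform(1.0 - consensus, checks=False), method="ward"),
        t=k,
        criterion="maxclust",
    )
    return ClusteringResult(
        labels=pd.Series(final, index=sub.sample_ids, name="cluster"),
        method="consensus",
        k=k,
        consensus_matrix=pd.DataFrame(consensus, index=sub.sample_ids, columns=sub.sample_ids),
        parameters={
            "linkage": "ward",
            "distance": "jaccard",
            "subsample": subsample,
            "reps": reps,
            "seed": seed,
        },
    )


def subtype_de_genes(
    expr: ExpressionMatrix, labels: pd.Series, top_n: int = 10
) -> dict[str, list[str]]:
    """One-vs-rest moderated differential expression per subtype.

    Genes are ranked by adjusted p and by |log2FC|; the *top_n* genes with
    the best (smallest) of their two ranks are selected, ties broken by
    adjusted p.
    """
    out: dict[str, list[str]] = {}
    lab = labels.reindex(expr.sample_ids)
    for st in sorted(lab.dropna().unique()):
        group = (lab == st).to_numpy()
        table = moderated_ttest(expr.values, group)
        table.index = expr.gene_ids
        rank_q = table["q"].rank(method="first")
        rank_fc = table["log2fc"].abs().rank(method="first", ascending=False)
        score = pd.concat([rank_q, rank_fc], axis=1).min(axis=1)
        order = pd.DataFrame({"score": score, "q": table["q"]}).sort_values(
            ["score", "q"]
        )
        if top_n > len(order):
            warnings.warn(
                f"top_n={top_n} exceeds gene count {len(order)}; returning all",
                stacklevel=2,
            )
        out[st] = order.index[:top_n].tolist()
    return out


def classification_agreement(
    labels_a: pd.Series, labels_b: pd.Series
) -> tuple[float, pd.DataFrame]:
    """Fraction of samples agreeing after maximum-agreement label matching.

    Cluster names need not coincide: the contingency table is matched by
    the Hungarian algorithm and agreement is the matched diagonal over n.
    """
    common = labels_a.index.intersection(labels_b.index)
    if len(common) == 0:
        raise ValidationError("labelings share no samples")
    a = labels_a.loc[common]
    b = labels_b.loc[common]
    table = pd.crosstab(a, b)
    rows, cols = linear_sum_assignment(-table.to_numpy())
    agreement = table.to_numpy()[rows, cols].sum() / len(common)
    return float(agreement), table
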