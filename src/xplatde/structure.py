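"""Clustering, PCA and chromosome-level summaries.

Hierarchical clustering is UPGMA (average linkage) on Euclidean
distances; k-means uses k-means++ initialization with an explicit seed
and best-of-restarts by inertia.  Masked entries are mean-imputed per
gene for clustering/PCA only — never for statistics — and the imputation
count is reported.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io_formats import CHROMOSOMES, GeneAnnotation, ValidationError
from .preprocess import RatioMatrix

#: cluster-count presets used for the corresponding published analyses
KMEANS_PRESETS = {"all_genes": 49, "codelink_full": 81, "pooled_full": 100,
                  "common_de": 24}

METHOD_PEARSON = "pearson"
METHOD_SPEARMAN = "spearman"


@dataclass
class Dendrogram:
    linkage: np.ndarray          # scipy linkage matrix, (n-1) x 4
    labels: list[str]
    leaf_order: list[int]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class KMeansResult:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float
    seed: int
    n_restarts: int


@dataclass
class PCAResult:
    components: np.ndarray        # orthonormal rows
    variance_fractions: np.ndarray
    scores: np.ndarray            # items x components
    loadings: np.ndarray          # biplot variable coordinates


@dataclass
class CorrelationMap:
    chromosome: str
    method: str
    matrix: pd.DataFrame          # sample x sample


def _impute(frame: pd.DataFrame) -> tuple[np.ndarray, int]:
    """Mean-impute masked entries per row (gene); rows with no data -> 0."""
    x = frame.to_numpy(dtype=float).copy()
    mask = ~np.isfinite(x)
    n_imputed = int(mask.sum())
    if n_imputed:
        row_mean = np.where(
            np.isfinite(x).any(axis=1), np.nanmean(np.where(mask, np.nan, x), axis=1), 0.0
        )
        x[mask] = np.take(row_mean, np.nonzero(mask)[0])
    return x, n_imputed


def hierarchical_cluster(frame: pd.DataFrame, axis: str = "genes") -> Dendrogram:
    """UPGMA on Euclidean distances over genes (rows) or samples (columns)."""
    if axis == "samples":
        frame = frame.T
    elif axis != "genes":
        raise ValidationError(f"unknown axis {axis!r}")
    if frame.shape[0] < 2:
        raise ValidationError("need at least two items to cluster")
    x, _ = _impute(frame)
    z = hierarchy.linkage(pdist(x, metric="euclidean"), method="average")
    return Dendrogram(
        linkage=z,
        labels=[str(i) for i in frame.index],
        leaf_order=[int(i) for i in hierarchy.leaves_list(z)],
    )


def to_newick(dend: Dendrogram) -> str:
    """Serialize a dendrogram as a Newick string with branch lengths."""
    n = len(dend.labels)
    # iterative merge walk (no recursion, so deep trees are fine)
    heights = {i: 0.0 for i in range(n)}
    texts = {i: dend.labels[i] for i in range(n)}
    for row_idx, (a, b, h, _) in enumerate(dend.linkage):
        a, b = int(a), int(b)
        ta, tb = texts.pop(a), texts.pop(b)
        ha, hb = heights.pop(a), heights.pop(b)
        new = n + row_idx
        texts[new] = f"({ta}:{h - ha:.10g},{tb}:{h - hb:.10g})"
        heights[new] = h
    (root,) = texts.values()
    return root + ";"


def kmeans_cluster(frame: pd.DataFrame, k: int, seed: int = 0,
                   n_restarts: int = 10) -> KMeansResult:
    """Best-of-restarts k-means with k-means++ init; deterministic per seed."""
    if k > frame.shape[0]:
        raise ValidationError(f"k={k} exceeds {frame.shape[0]} items")
    if k < 1:
        raise ValidationError("k must be at least 1")
    x, _ = _impute(frame)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed).fit(x)
    return KMeansResult(
        k=k,
        assignments=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
        n_restarts=n_restarts,
    )


def pca(frame: pd.DataFrame) -> PCAResult:
    """Centered PCA over rows (items x variables); fractions sum to 1."""
    x, _ = _impute(frame)
    if x.shape[0] < 2:
        raise ValidationError("need at least two items for PCA")
    centered = x - x.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValidationError("constant matrix has no principal components")
    n_comp = min(x.shape)
    model = PCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(x)
    fractions = model.explained_variance_ratio_
    loadings = model.components_.T * np.sqrt(model.explained_variance_)
    return PCAResult(
        components=model.components_,
        variance_fractions=fractions,
        scores=scores,
        loadings=loadings,
    )


# ---------------------------------------------------------------------------
# chromosome summaries
# ---------------------------------------------------------------------------

def chromosome_distribution(genes, annotation: GeneAnnotation) -> pd.DataFrame:
    """Gene counts and fractions per chromosome for a gene set."""
    genes = sorted(set(int(g) for g in genes))
    chrom = annotation.gene_to_chromosome()
    missing = [g for g in genes if g not in chrom.index]
    if missing:
        raise ValidationError(f"unannotated genes: {missing[:5]}")
    counts = pd.Series(0, index=list(CHROMOSOMES), dtype=int)
    if genes:
        observed = chrom.loc[genes].value_counts()
        counts.loc[observed.index] = observed
    out = pd.DataFrame({"count": counts})
    total = int(out["count"].sum())
    out["fraction"] = out["count"] / total if total else np.nan
    out.index.name = "chromosome"
    return out


def chromosome_mean_expression(
    ratios: RatioMatrix, annotation: GeneAnnotation,
    direction_sets: dict[str, set[int]],
) -> pd.DataFrame:
    """Mean log2 ratio per chromosome, separately per direction set.

    Chromosomes with no member genes get a masked (NaN) entry.
    """
    chrom = annotation.gene_to_chromosome()
    frame = ratios.to_frame()
    gene_mean = frame.mean(axis=1, skipna=True)
    out = pd.DataFrame(index=list(CHROMOSOMES), dtype=float)
    out.index.name = "chromosome"
    for name, genes in direction_sets.items():
        members = [g for g in gene_mean.index if int(g) in set(genes)]
        if not members:
            out[name] = np.nan
            continue
        sub = pd.DataFrame({
            "chromosome": chrom.reindex([int(g) for g in members]).to_numpy(),
            "value": gene_mean.loc[members].to_numpy(),
        })
        means = sub.groupby("chromosome")["value"].mean()
        out[name] = means.reindex(out.index)
    return out


def chromosome_correlation_map(
    ratios: RatioMatrix, annotation: GeneAnnotation, chromosome: str,
    method: str = METHOD_PEARSON,
) -> CorrelationMap:
    """Sample x sample correlation over one chromosome's genes."""
    if method not in (METHOD_PEARSON, METHOD_SPEARMAN):
        raise ValidationError(f"unknown method {method!r}")
    chrom = annotation.gene_to_chromosome()
    frame = ratios.to_frame()
    members = [g for g in frame.index if chrom.get(int(g)) == chromosome]
    if len(members) < 3:
        raise ValidationError(
            f"chromosome {chromosome!r} has {len(members)} genes; need >= 3"
        )
    sub = frame.loc[members]
    x, _ = _impute(sub)
    if method == METHOD_SPEARMAN:
        x = stats.rankdata(x, axis=0)
    corr = np.corrcoef(x, rowvar=False)
    mat = pd.DataFrame(corr, index=sub.columns, columns=sub.columns)
    return CorrelationMap(chromosome=chromosome, method=method, matrix=mat)
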