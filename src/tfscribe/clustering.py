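"""Expression clustering, BIC cluster-count selection, and gene-set enrichment.

Genes are clustered on their sum-of-squares-normalized cross-condition
expression with k-means (k-means++ initialization, best of restarts).  The
cluster count is chosen by a spherical-Gaussian BIC:

    BIC(k) = n*d*ln(WCSS / (n*d)) + k*d*ln(n)

with n genes, d conditions and WCSS the within-cluster sum of squares; the
minimizer over the candidate range wins.  Enrichment of user-supplied gene
sets in clusters uses the one-sided hypergeometric test with
Benjamini-Hochberg adjustment across the full cluster x set grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .mars import FitConfig, cv_select


@dataclass
class ClusterModel:
    """A k-means partition of genes with the BIC curve that selected k."""

    k: int
    assignments: pd.Series  # gene -> cluster id (0-based)
    centroids: np.ndarray  # k x conditions
    bic_curve: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    normalized_input: pd.DataFrame | None = None


@dataclass(frozen=True)
class EnrichmentResult:
    cluster: int
    set_name: str
    overlap: int
    cluster_size: int
    set_size: int
    p: float
    p_adjusted: float


def kmeans_bic(n: int, d: int, k: int, wcss: float) -> float:
    """Spherical equal-variance BIC for a k-means partition."""
    wcss = max(wcss, 1e-300)
    return n * d * np.log(wcss / (n * d)) + k * d * np.log(n)


def kmeans_bic_per_cluster(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """Alternative BIC with per-cluster variances (behind a flag in select_k_bic)."""
    n, d = X.shape
    k = centers.shape[0]
    ll = 0.0
    for j in range(k):
        pts = X[labels == j]
        nj = len(pts)
        if nj == 0:
            continue
        var = max(((pts - centers[j]) ** 2).sum() / (nj * d), 1e-12)
        ll += nj * d * np.log(var)
    return ll + k * d * np.log(n)


def select_k_bic(
    normalized: pd.DataFrame,
    k_range: Sequence[int] = range(2, 31),
    restarts: int = 10,
    seed: int | None = None,
    criterion: str = "gmm",
) -> tuple[pd.Series, int]:
    """BIC curve over candidate cluster counts and its minimizer k*.

    The default criterion is the BIC of a spherical Gaussian mixture (soft
    assignments), for which adding components beyond the true count gains
    only O(log n) likelihood and the penalty decides; the hard-assignment
    k-means variants (``criterion="hard"`` or ``"hard_per_cluster"``) are
    kept for diagnostics but systematically over-split well-separated data,
    because splitting any blob reduces within-cluster variance by a
    scale-free factor.
    """
    from sklearn.mixture import GaussianMixture

    X = normalized.to_numpy(dtype=float)
    n, d = X.shape
    ks = [k for k in k_range if 2 <= k <= n // 2]
    if not ks:
        raise ValueError("no admissible k in range")
    bics = {}
    for k in ks:
        if criterion == "gmm":
            gm = GaussianMixture(n_components=k, covariance_type="spherical",
                                 n_init=restarts, random_state=seed, reg_covar=1e-8)
            gm.fit(X)
            bics[k] = float(gm.bic(X))
        else:
            km = KMeans(n_clusters=k, n_init=restarts, init="k-means++", random_state=seed).fit(X)
            if criterion == "hard_per_cluster":
                bics[k] = kmeans_bic_per_cluster(X, km.labels_, km.cluster_centers_)
            else:
                bics[k] = kmeans_bic(n, d, k, float(km.inertia_))
    curve = pd.Series(bics, name="bic")
    curve.index.name = "k"
    return curve, int(curve.idxmin())


def cluster_genes(normalized: pd.DataFrame, k: int, seed: int | None = None,
                  restarts: int = 10) -> ClusterModel:
    """k-means partition (k-means++ init, best of ``restarts`` by WCSS)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(normalized):
        raise ValueError("k exceeds the number of genes")
    X = normalized.to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=restarts, init="k-means++", random_state=seed).fit(X)
    return ClusterModel(
        k=k,
        assignments=pd.Series(km.labels_, index=normalized.index, name="cluster"),
        centroids=km.cluster_centers_,
        normalized_input=normalized,
    )


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT-like gene-set file (name, description, members; tab-separated)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(parts[2:])
    return sets


def enrich(
    clusters: ClusterModel,
    gene_sets: Mapping[str, set[str]],
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment of each gene set in each cluster.

    The background universe is the clustered genes.  BH adjustment runs over
    the full cluster x set grid; results are returned for every test, with
    significance judged against ``alpha`` by the caller via ``p_adjusted``.
    """
    universe = set(clusters.assignments.index)
    N = len(universe)
    tests = []
    for cl in sorted(clusters.assignments.unique()):
        members = set(clusters.assignments[clusters.assignments == cl].index)
        if not members:
            continue
        for name, geneset in gene_sets.items():
            gs = geneset & universe
            if not gs:
                continue
            k_overlap = len(members & gs)
            # P(X >= k) for X ~ Hypergeom(N, |gs|, |members|)
            p = float(stats.hypergeom.sf(k_overlap - 1, N, len(gs), len(members)))
            tests.append((int(cl), name, k_overlap, len(members), len(gs), min(p, 1.0)))
    if not tests:
        return []
    pvals = np.array([t[5] for t in tests])
    padj = stats.false_discovery_control(pvals, method="bh")
    return [
        EnrichmentResult(cluster=c, set_name=s, overlap=o, cluster_size=m, set_size=g,
                         p=p, p_adjusted=float(min(max(a, p), 1.0)))
        for (c, s, o, m, g, p), a in zip(tests, padj)
    ]


def top_enrichment_per_cluster(results: Sequence[EnrichmentResult], alpha: float = 0.01):
    """The most significant set per cluster, where adjusted p < alpha."""
    best: dict[int, EnrichmentResult] = {}
    for r in results:
        if r.p_adjusted < alpha and (r.cluster not in best or r.p < best[r.cluster].p):
            best[r.cluster] = r
    return best


# ---------------------------------------------------------------------------
# Per-cluster regressions
# ---------------------------------------------------------------------------

def zscore_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Column-wise Z-score (mean 0, sd 1); constant columns become 0."""
    sd = df.std(ddof=0)
    sd = sd.replace(0, 1.0)
    return (df - df.mean()) / sd


def per_cluster_models(
    clusters: ClusterModel,
    binding_by_condition: Mapping[str, pd.DataFrame],
    fpkm: pd.DataFrame,
    config: FitConfig | None = None,
    min_cluster_size: int = 10,
    seed: int | None = None,
    folds: int = 5,
    repeats: int = 2,
) -> dict[tuple[int, str], dict]:
    """Linear-only cross-validated selection per cluster x condition.

    Returns per (cluster, condition): the fitted model, signed TF importance
    scores, and Z-scored binding + expression tables for heatmap export.
    Clusters below ``min_cluster_size`` are skipped with a diagnostic;
    zero-variance TF columns within a cluster are excluded from candidates.
    """
    from .regulatory import tf_importance

    config = config or FitConfig(linear_only=True)
    if not config.linear_only:
        config = FitConfig(**{**config.__dict__, "linear_only": True})
    out: dict[tuple[int, str], dict] = {}
    for cl in sorted(clusters.assignments.unique()):
        genes = list(clusters.assignments[clusters.assignments == cl].index)
        if len(genes) < min_cluster_size:
            warnings.warn(f"cluster {cl} has {len(genes)} genes (< {min_cluster_size}); skipped")
            continue
        for cond, X_all in binding_by_condition.items():
            X = X_all.loc[genes]
            keep = X.columns[X.std(ddof=0) > 0]
            X = X[keep]
            y = fpkm.loc[genes, cond]
            n_folds = min(folds, max(2, len(genes) // 2))
            model = cv_select(X, y, config, folds=n_folds, repeats=repeats, seed=seed)
            scores = tf_importance(model, X, y, condition=cond, cluster=str(cl),
                                   penalty=config.penalty)
            out[(int(cl), cond)] = {
                "model": model,
                "importance": scores,
                "binding_z": zscore_columns(X[model.selected_names]) if model.terms else X.iloc[:, :0],
                "expression_z": zscore_columns(y.to_frame(cond))[cond],
            }
    return out
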