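"""Cell-type identification from degree or expression matrices.

PCA to 20 dimensions, k-means / agglomerative (Ward) clustering, eight
external validation indexes against known labels, and the rank / re-rank
procedure that selects a (box size, z threshold) parameter combination
across several datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn import metrics
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics.cluster import pair_confusion_matrix

INDEX_NAMES = ("ARI", "FMI", "AMI", "CPT", "FMS", "HMG", "NMI", "VMS")


def reduce_dimensions(
    matrix: np.ndarray,
    n_components: int = 20,
    seed: int = 0,
    standardize: bool = False,
) -> np.ndarray:
    """PCA embedding of cells (columns of the genes x cells matrix).

    Returns an (n_cells, n_components) array.  Deterministic: full SVD with
    a fixed sign convention (the loading of largest magnitude on each
    component is positive).  ``standardize`` optionally z-scores each gene
    across cells first (off by default).
    """
    X = np.asarray(matrix, dtype=float).T  # cells as observations
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(m, n)={min(X.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    emb = pca.fit_transform(X)
    # sign convention: largest-|loading| entry of each component positive
    comps = pca.components_
    flip = np.sign(comps[np.arange(comps.shape[0]),
                         np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return emb * flip


def embed_2d(embedding: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """t-SNE to 2 dimensions, for visualization only (never for scoring)."""
    n = embedding.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(f"perplexity {perplexity} too large for {n} cells")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(np.asarray(embedding, dtype=float))


def cluster_cells(
    embedding: np.ndarray,
    k: int,
    method: str = "kmeans",
    seed: int = 0,
    linkage: str = "ward",
) -> np.ndarray:
    """k-means (10 seeded restarts) or agglomerative clustering cut at k."""
    X = np.asarray(embedding, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(X)
    if method == "hierarchical":
        agg = AgglomerativeClustering(n_clusters=k, linkage=linkage)
        return agg.fit_predict(X)
    raise ValueError(f"unknown clustering method {method!r}")


@dataclass
class ClusterEvaluation:
    method: str
    scores: dict[str, float]


def _pairwise_f1(predicted, truth) -> float:
    """Harmonic mean of pairwise precision and recall over co-clustered pairs.

    Distinct from the Fowlkes-Mallows score, which is their geometric mean.
    """
    (tn, fp), (fn, tp) = pair_confusion_matrix(truth, predicted)
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def score_clustering(predicted, truth, method: str = "") -> ClusterEvaluation:
    """All eight external indexes of a predicted partition against truth.

    ARI adjusted Rand, FMI pairwise F-measure, AMI adjusted MI, CPT
    completeness, FMS Fowlkes-Mallows, HMG homogeneity, NMI normalized MI,
    VMS V-measure.  Every index is invariant to relabeling of the predicted
    clusters.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth labels differ in length")
    scores = {
        "ARI": float(metrics.adjusted_rand_score(truth, predicted)),
        "FMI": float(_pairwise_f1(predicted, truth)),
        "AMI": float(metrics.adjusted_mutual_info_score(truth, predicted)),
        "CPT": float(metrics.completeness_score(truth, predicted)),
        "FMS": float(metrics.fowlkes_mallows_score(truth, predicted)),
        "HMG": float(metrics.homogeneity_score(truth, predicted)),
        "NMI": float(metrics.normalized_mutual_info_score(truth, predicted)),
        "VMS": float(metrics.v_measure_score(truth, predicted)),
    }
    return ClusterEvaluation(method=method, scores=scores)


# ---------------------------------------------------------------------------
# parameter grid ranking


@dataclass
class ParameterGridResult:
    """Rank / re-rank selection over (box size, z threshold) combinations."""

    combos: list[tuple[float, float]]
    f_scores: np.ndarray          # (datasets, combos, methods)
    ranking: np.ndarray           # (datasets, combos, methods) ranks, 1 = best
    re_ranking: np.ndarray        # (combos, methods) mean rank across datasets
    final_scores: np.ndarray      # (combos,) mean of methods' re-ranks
    recommended: tuple[float, float]


DEFAULT_BOX_SIZES = (0.05, 0.1, 0.15, 0.2, 0.25)
DEFAULT_Z_THRESHOLDS = (-2.0, -1.0, 0.0, 1.0, 2.0)


def default_grid() -> list[tuple[float, float]]:
    """The 25 default (box size, z threshold) combinations."""
    return [(b, z) for b in DEFAULT_BOX_SIZES for z in DEFAULT_Z_THRESHOLDS]


def rank_parameters(
    f_scores: np.ndarray,
    combos: list[tuple[float, float]] | None = None,
) -> ParameterGridResult:
    """Select the parameter combination by rank / re-rank aggregation.

    ``f_scores`` is (datasets, combos, methods).  Per dataset and method,
    combinations are ranked 1 = best by descending F-measure (average rank
    on ties); the re-ranking score of a combination is the mean rank across
    datasets, then the two clustering methods' re-ranks are averaged.  The
    smallest final score wins; ties break toward the higher mean F-measure,
    then toward the lexicographically smaller combination.
    """
    f = np.asarray(f_scores, dtype=float)
    if f.ndim != 3:
        raise ValueError("f_scores must be (datasets, combos, methods)")
    if np.isnan(f).any():
        raise ValueError("f_scores contains missing entries")
    n_datasets, n_combos, n_methods = f.shape
    if combos is None:
        combos = [(float(i), 0.0) for i in range(n_combos)]
    if len(combos) != n_combos:
        raise ValueError("combo list does not match f_scores")
    ranking = np.empty_like(f)
    for d in range(n_datasets):
        for meth in range(n_methods):
            ranking[d, :, meth] = rankdata(-f[d, :, meth], method="average")
    re_ranking = ranking.mean(axis=0)           # (combos, methods)
    final = re_ranking.mean(axis=1)             # (combos,)
    mean_f = f.mean(axis=(0, 2))
    order = sorted(
        range(n_combos), key=lambda i: (final[i], -mean_f[i], combos[i])
    )
    return ParameterGridResult(
        combos=list(combos),
        f_scores=f,
        ranking=ranking,
        re_ranking=re_ranking,
        final_scores=final,
        recommended=combos[order[0]],
    )
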