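"""Consensus k-means subtype discovery and silhouette-based sample selection.

Each resampling iteration subsamples samples, z-scores every event row, then
runs k-means under Pearson-correlation geometry (obtained exactly by
standardizing each sample profile, where squared Euclidean distance becomes
proportional to 1 - Pearson r). Co-clustering frequencies accumulate into a
consensus matrix; final labels come from average-linkage hierarchical
clustering of 1 - M cut at k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .types import PsiMatrix

logger = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    consensus: np.ndarray  # sample x sample co-clustering frequencies
    labels: np.ndarray  # per-sample cluster ids in 1..k
    silhouette: np.ndarray  # per-sample width on distance 1 - M
    k: int
    n_iterations: int
    sample_ids: list[str]


def _as_sample_matrix(matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, PsiMatrix):
        return matrix.imputed().T.copy(), list(matrix.sample_ids)
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("input contains missing values; impute first")
    return X.copy(), [str(i) for i in range(X.shape[0])]


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _normalize_for_pearson_kmeans(X: np.ndarray) -> np.ndarray:
    # z-score each event (column) across samples, then standardize each
    # sample profile so Euclidean k-means operates in Pearson geometry
    Z = _standardize_rows(X.T).T
    return _standardize_rows(Z)


def consensus_cluster(
    matrix,
    k: int = 2,
    n_iter: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    n_init: int = 10,
) -> ConsensusResult:
    """Consensus k-means over resampled subsets of samples.

    ``matrix`` is a PsiMatrix (missing entries imputed by per-event median)
    or a samples x features array without missing values.
    """
    X, sample_ids = _as_sample_matrix(matrix)
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples n={n}")
    if not (0.0 < subsample_frac <= 1.0):
        raise ValueError("subsample_frac must be in (0, 1]")

    rng = np.random.default_rng(seed)
    co_cluster = np.zeros((n, n))
    co_sampled = np.zeros((n, n))
    m = max(k, int(round(subsample_frac * n)))

    for it in range(n_iter):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        Xs = _normalize_for_pearson_kmeans(X[idx])
        km = KMeans(
            n_clusters=k,
            n_init=n_init,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(Xs)
        lab = km.labels_
        co_sampled[np.ix_(idx, idx)] += 1.0
        for c in range(k):
            members = idx[lab == c]
            co_cluster[np.ix_(members, members)] += 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(co_sampled > 0, co_cluster / np.maximum(co_sampled, 1), 0.0)
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)

    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")

    sil = _silhouette_on_distance(D, labels)
    logger.info(
        "consensus clustering: n=%d, k=%d, %d iterations, cluster sizes %s",
        n, k, n_iter, np.bincount(labels)[1:].tolist(),
    )
    return ConsensusResult(M, labels, sil, k, n_iter, sample_ids)


def _silhouette_on_distance(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    # singleton clusters get silhouette 0 (sklearn convention, documented)
    if len(np.unique(labels)) < 2:
        return np.zeros(len(labels))
    return silhouette_samples(D, labels, metric="precomputed")


def select_representatives(result: ConsensusResult, n_select: int) -> list[str]:
    """Top ``n_select`` samples by silhouette width, positive widths only."""
    order = np.lexsort((np.arange(len(result.silhouette)), -result.silhouette))
    chosen = [i for i in order if result.silhouette[i] > 0][:n_select]
    if not chosen:
        logger.warning("no samples with positive silhouette width")
    return [result.sample_ids[i] for i in chosen]


def consensus_cdf_report(
    matrix, k_values=(2, 3, 4, 5, 6), n_iter: int = 100, seed: int = 0, **kw
):
    """Delta-area report of the consensus CDF across candidate k (diagnostic)."""
    areas = {}
    for k in k_values:
        res = consensus_cluster(matrix, k=k, n_iter=n_iter, seed=seed, **kw)
        vals = np.sort(squareform(res.consensus - np.eye(len(res.consensus)), checks=False))
        # area under empirical CDF of off-diagonal consensus values
        grid = np.linspace(0, 1, 101)
        cdf = np.searchsorted(vals, grid, side="right") / max(len(vals), 1)
        areas[k] = float(np.trapezoid(cdf, grid))
    ks = sorted(areas)
    delta = {ks[0]: areas[ks[0]]}
    for prev, cur in zip(ks, ks[1:]):
        denom = areas[prev] if areas[prev] > 0 else 1.0
        delta[cur] = (areas[cur] - areas[prev]) / denom
    return {"area": areas, "delta_area": delta}
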