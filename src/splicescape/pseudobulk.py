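"""Cell-state pseudobulk aggregation and Cluster-3.0-style hierarchical clustering.

Pseudobulks sum junction counts over all cells sharing a (patient,
cellular_state) label; PSI is then estimated on the summed counts, never by
averaging per-cell PSIs. Hierarchical clustering uses uncentered correlation
``u(x, y) = sum(x*y) / sqrt(sum(x^2) * sum(y^2))`` over pairwise-complete
entries and centroid linkage: a merge joins centroids (element-wise available
mean of member rows) and distances are recomputed to the new centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import PsiMatrix

logger = logging.getLogger(__name__)

PB_SEP = "|"


def pseudobulk_id(patient: str, state: str) -> str:
    return f"{patient}{PB_SEP}{state}"


def aggregate(
    cell_counts: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Sum per-cell junction counts by (patient, cellular_state).

    ``cell_counts`` has columns event_id, cell_id, inc_count, skip_count;
    ``annotation`` has cell_id, patient, state. Returns a long-form counts
    table keyed by pseudobulk id plus a per-pseudobulk cell-count Series.
    """
    ann = annotation.set_index("cell_id")
    unknown = set(cell_counts["cell_id"].astype(str)) - set(ann.index.astype(str))
    if unknown:
        raise ValueError(f"unannotated cell ids: {sorted(unknown)[:5]}")

    ann_pb = (
        ann["patient"].astype(str) + PB_SEP + ann["state"].astype(str)
    ).rename("pseudobulk_id")
    merged = cell_counts.copy()
    merged["pseudobulk_id"] = merged["cell_id"].map(ann_pb)
    agg = (
        merged.groupby(["event_id", "pseudobulk_id"], sort=True)[
            ["inc_count", "skip_count"]
        ]
        .sum()
        .reset_index()
        .rename(columns={"pseudobulk_id": "sample_id"})
    )
    n_cells = ann_pb.value_counts().sort_index()
    n_cells.index.name = "pseudobulk_id"
    logger.info("aggregated %d cells into %d pseudobulks", len(ann), len(n_cells))
    return agg, n_cells


def filter_pseudobulks(
    matrix: PsiMatrix,
    signature_events: list[str],
    min_events: int = 50,
    min_pseudobulks: float = 100,
) -> tuple[list[str], list[str]]:
    """Detection filters on a pseudobulk PSI matrix.

    A pseudobulk is dropped when fewer than ``min_events`` of the signature
    events are detected in it; an event is then dropped when detected in fewer
    than ``min_pseudobulks`` of the kept pseudobulks. ``min_pseudobulks`` < 1
    is interpreted as a fraction of kept pseudobulks (scale-aware alternative
    to the absolute default for small simulations).
    """
    present = [e for e in signature_events if e in matrix.event_ids]
    sub = matrix.subset_events(present)
    det_per_pb = sub.detected.sum(axis=0)
    kept_pbs = [s for s, n in zip(sub.sample_ids, det_per_pb) if n >= min_events]

    sub2 = sub.subset_samples(kept_pbs) if kept_pbs else sub.subset_samples([])
    threshold = (
        min_pseudobulks
        if min_pseudobulks >= 1
        else min_pseudobulks * max(len(kept_pbs), 1)
    )
    det_per_ev = sub2.detected.sum(axis=1)
    kept_events = [e for e, n in zip(sub2.event_ids, det_per_ev) if n >= threshold]
    logger.info(
        "pseudobulk filter: kept %d/%d pseudobulks, %d/%d events",
        len(kept_pbs), matrix.n_samples, len(kept_events), len(present),
    )
    return kept_pbs, kept_events


def uncentered_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """sum(x*y)/sqrt(sum(x^2)*sum(y^2)) over co-present (finite) entries."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if not ok.any():
        return np.nan
    xs, ys = x[ok], y[ok]
    denom = np.sqrt((xs * xs).sum() * (ys * ys).sum())
    if denom == 0:
        return np.nan
    return float((xs * ys).sum() / denom)


@dataclass
class HClusterResult:
    merges: list  # (node_i, node_j, distance, new_size) in merge order
    leaf_order: list  # row labels in dendrogram order
    newick: str
    labels: list  # labels actually clustered (after drops)
    dropped: list  # labels dropped for undefined similarity


def hcluster_cluster3(data: pd.DataFrame) -> HClusterResult:
    """Centroid-linkage hierarchical clustering with uncentered correlation.

    Rows of ``data`` are the items clustered; NaN marks missing values
    (pairwise-complete handling). Rows with fewer than two finite values, or
    whose similarity is undefined (all-zero vectors), are dropped with a
    warning. Ties in the agglomeration break at the lowest-index pair and the
    leaf order is the input order within merges, so results are deterministic.
    """
    X = data.to_numpy(dtype=float)
    labels = [str(i) for i in data.index]

    keep, dropped = [], []
    for i in range(X.shape[0]):
        row = X[i]
        finite = np.isfinite(row)
        if finite.sum() < 2 or not np.any(row[finite] != 0):
            dropped.append(labels[i])
        else:
            keep.append(i)
    if dropped:
        logger.warning("dropped %d rows with undefined similarity: %s",
                       len(dropped), dropped[:5])
    X = X[keep]
    labels = [labels[i] for i in keep]
    n = X.shape[0]
    if n == 0:
        return HClusterResult([], [], ";", [], dropped)
    if n == 1:
        return HClusterResult([], labels, f"{labels[0]};", labels, dropped)

    # active clusters: node id -> (centroid, member count, subtree, height)
    centroids = {i: X[i].copy() for i in range(n)}
    counts = {i: np.isfinite(X[i]).astype(float) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    trees = {i: labels[i] for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    active = list(range(n))
    merges = []
    next_id = n

    def dist(a: int, b: int) -> float:
        u = uncentered_correlation(centroids[a], centroids[b])
        return np.inf if np.isnan(u) else 1.0 - u

    D = {}
    for ai in range(len(active)):
        for bi in range(ai + 1, len(active)):
            D[(active[ai], active[bi])] = dist(active[ai], active[bi])

    while len(active) > 1:
        best = None
        best_d = np.inf
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                pair = (active[ai], active[bi])
                d = D[pair]
                if d < best_d - 1e-15 or (abs(d - best_d) <= 1e-15 and (best is None or pair < best)):
                    best_d, best = d, pair
        i, j = best
        # merged centroid: element-wise mean over all member rows (available values)
        si = centroids[i] * counts[i]
        sj = centroids[j] * counts[j]
        tot = counts[i] + counts[j]
        with np.errstate(invalid="ignore"):
            new_centroid = np.where(tot > 0, (np.nan_to_num(si) + np.nan_to_num(sj)) / np.maximum(tot, 1), np.nan)
        new_centroid[tot == 0] = np.nan

        bl_i = max(best_d - heights[i], 0.0) / 2.0
        bl_j = max(best_d - heights[j], 0.0) / 2.0
        trees[next_id] = f"({trees[i]}:{bl_i:.6g},{trees[j]}:{bl_j:.6g})"
        heights[next_id] = best_d
        centroids[next_id] = new_centroid
        counts[next_id] = tot
        sizes[next_id] = sizes[i] + sizes[j]
        merges.append((i, j, float(best_d), sizes[next_id]))

        active = [a for a in active if a not in (i, j)]
        D = {p: d for p, d in D.items() if i not in p and j not in p}
        for a in active:
            D[(min(a, next_id), max(a, next_id))] = dist(a, next_id)
        active.append(next_id)
        next_id += 1

    root = active[0]
    newick = trees[root] + ";"
    leaf_order = _leaf_order(merges, labels, n)
    return HClusterResult(merges, leaf_order, newick, labels, dropped)


def _leaf_order(merges, labels, n):
    children = {}
    for step, (i, j, _, _) in enumerate(merges):
        children[n + step] = (i, j)

    def walk(node):
        if node < n:
            return [labels[node]]
        i, j = children[node]
        return walk(i) + walk(j)

    return walk(n + len(merges) - 1) if merges else list(labels)
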