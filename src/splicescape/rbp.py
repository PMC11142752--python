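"""RBP expression screens: correlation with AS scores and with event PSIs.

Bulk screen: Spearman correlation of each RBP's expression with the AS score
within each dataset, BH-adjusted within dataset; an RBP is "consistent" when
it is significant with the same correlation sign in every dataset. Single-cell
screen: RBP x event Spearman matrix over cells where the event is detected,
restricted to events detected in more than ``min_cells`` cells.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .pseudobulk import hcluster_cluster3
from .types import PsiMatrix

logger = logging.getLogger(__name__)


def correlate_rbp_score(
    expression: pd.DataFrame, scores: pd.Series, dataset: str = ""
) -> pd.DataFrame:
    """Per-RBP Spearman rho/p against the AS score, with BH q within dataset.

    ``expression`` is RBPs x samples; ``scores`` indexes samples. Constant
    expression vectors yield missing rho/p (recorded, not dropped).
    """
    shared = [s for s in expression.columns if s in scores.index and not np.isnan(scores[s])]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared samples (need >= 10)")
    sc = scores[shared].to_numpy(dtype=float)

    rows = []
    for rbp, expr in expression[shared].iterrows():
        x = expr.to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            rows.append((rbp, np.nan, np.nan))
            continue
        rho, p = spearmanr(x, sc)
        rows.append((rbp, rho, p))
    out = pd.DataFrame(rows, columns=["rbp", "rho", "p"])
    out["dataset"] = dataset
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def consistent_rbps(results: list[pd.DataFrame], alpha: float = 0.05) -> pd.DataFrame:
    """RBPs significant (q < alpha) with identical rho sign in every dataset."""
    if len(results) < 2:
        raise ValueError("need results from at least two datasets")
    combined = pd.concat(results, ignore_index=True)
    if combined.empty:
        return pd.DataFrame(columns=["rbp", "sign"])

    n_datasets = combined["dataset"].nunique()
    rows = []
    for rbp, grp in combined.groupby("rbp", sort=True):
        if len(grp) < n_datasets:
            continue
        sig = (grp["q"] < alpha).all()
        signs = np.sign(grp["rho"].to_numpy())
        if sig and len(set(signs)) == 1 and signs[0] != 0:
            rows.append((rbp, int(signs[0])))
    return pd.DataFrame(rows, columns=["rbp", "sign"])


def rbp_event_correlation(
    expression: pd.DataFrame,
    psi_matrix: PsiMatrix,
    min_cells: int = 200,
    cluster: bool = True,
):
    """RBP x event Spearman rho matrix at single-cell resolution.

    Events detected in <= ``min_cells`` cells are excluded (logged). For each
    kept event, rho is computed over the cells where the event is detected.
    Returns (rho matrix, HClusterResult of RBP rows or None).
    """
    cells = [c for c in psi_matrix.sample_ids if c in expression.columns]
    sub = psi_matrix.subset_samples(cells)
    expr = expression[cells]

    det_counts = sub.detected.sum(axis=1)
    kept = [e for e, n in zip(sub.event_ids, det_counts) if n > min_cells]
    excluded = sub.n_events - len(kept)
    if excluded:
        logger.info("excluded %d events detected in <= %d cells", excluded, min_cells)
    if not kept:
        empty = pd.DataFrame(index=expr.index, columns=[], dtype=float)
        return empty, None

    sub = sub.subset_events(kept)
    rho = np.full((expr.shape[0], len(kept)), np.nan)
    for j in range(len(kept)):
        mask = sub.detected[j]
        y = sub.psi[j, mask]
        X = expr.to_numpy(dtype=float)[:, mask]
        for i in range(X.shape[0]):
            if np.nanstd(X[i]) == 0 or np.nanstd(y) == 0:
                continue
            rho[i, j] = spearmanr(X[i], y)[0]

    rho_df = pd.DataFrame(rho, index=expr.index, columns=kept)
    tree = hcluster_cluster3(rho_df) if cluster and len(rho_df) > 1 else None
    return rho_df, tree
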