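"""Random-forest event ranking, survival-direction grouping, and the AS score.

The signature is built in three steps: (1) rank events by Mean Decrease Gini
(MDG) from a random forest classifying consensus cluster labels; (2) split the
selected events into group 1 (higher PSI in the worse-survival cluster) and
group 2 (lower PSI), keeping the top events by MDG in each group; (3) the AS
score of a sample is mean(detected group-1 PSI) - mean(detected group-2 PSI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.ensemble import RandomForestClassifier

from .types import PsiMatrix

logger = logging.getLogger(__name__)


@dataclass
class SignatureModel:
    importances: pd.Series  # event_id -> MDG, descending
    selected_events: list[str]
    group1: list[str] = field(default_factory=list)
    group2: list[str] = field(default_factory=list)
    worse_cluster: Optional[int] = None

    def __post_init__(self) -> None:
        if set(self.group1) & set(self.group2):
            raise ValueError("group1 and group2 overlap")
        sel = set(self.selected_events)
        if not (set(self.group1) <= sel and set(self.group2) <= sel):
            raise ValueError("groups must be drawn from selected events")
        if (self.importances < 0).any():
            raise ValueError("MDG importances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        grp = {e: 1 for e in self.group1}
        grp.update({e: 2 for e in self.group2})
        return pd.DataFrame(
            {
                "event_id": list(self.importances.index),
                "mdg": self.importances.to_numpy(),
                "selected": [e in set(self.selected_events) for e in self.importances.index],
                "group": [grp.get(e, 0) for e in self.importances.index],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, worse_cluster: Optional[int] = None):
        imp = pd.Series(df["mdg"].to_numpy(), index=df["event_id"].astype(str))
        sel = [str(e) for e, s in zip(df["event_id"], df["selected"]) if s]
        g1 = [str(e) for e, g in zip(df["event_id"], df["group"]) if g == 1]
        g2 = [str(e) for e, g in zip(df["event_id"], df["group"]) if g == 2]
        return cls(imp, sel, g1, g2, worse_cluster)


@dataclass
class AsScoreVector:
    scores: pd.Series  # sample_id -> score, NaN when insufficient detection
    n_group1_detected: pd.Series
    n_group2_detected: pd.Series


def rank_events_by_mdg(
    matrix: PsiMatrix,
    labels: Sequence[int],
    n_trees: int = 500,
    n_select: int = 200,
    seed: int = 0,
) -> SignatureModel:
    """Rank events by Mean Decrease Gini from a random forest on cluster labels.

    MDG is the per-tree sample-weighted Gini impurity decrease attributed to
    each event, averaged over trees (unnormalized, matching the classic
    randomForest definition up to scale).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes to rank events")
    X = matrix.imputed().T  # samples x events
    if X.shape[0] != len(labels):
        raise ValueError("labels length does not match number of samples")

    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    ).fit(X, labels)

    mdg = np.zeros(X.shape[1])
    for tree in rf.estimators_:
        mdg += tree.tree_.compute_feature_importances(normalize=False)
    mdg /= len(rf.estimators_)

    imp = pd.Series(mdg, index=matrix.event_ids).sort_values(
        ascending=False, kind="stable"
    )
    selected = list(imp.index[: min(n_select, len(imp))])
    logger.info("ranked %d events, selected top %d by MDG", len(imp), len(selected))
    return SignatureModel(importances=imp, selected_events=selected)


def _cluster_median_survival(survival: pd.DataFrame, mask: np.ndarray) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(survival.loc[mask, "time"], survival.loc[mask, "status"])
    return float(kmf.median_survival_time_)


def assign_groups(
    matrix: PsiMatrix,
    model: SignatureModel,
    labels: Sequence[int],
    survival: pd.DataFrame,
    n_per_group: int = 20,
    direction_by: str = "cluster",
    worse_cluster: Optional[int] = None,
) -> SignatureModel:
    """Split selected events into survival-direction groups.

    The worse cluster is the one with lower Kaplan-Meier median survival
    (log-rank reported). An event joins group 1 if its mean detected PSI in
    the worse cluster exceeds that in the other cluster, else group 2; the top
    ``n_per_group`` by MDG are kept per group. ``direction_by='survival'``
    instead signs events by their univariate Cox coefficient against
    continuous survival. ``survival`` must have columns sample_id, time,
    status covering the clustered samples.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(uniq)}")
    surv = survival.set_index("sample_id").loc[matrix.sample_ids]

    if worse_cluster is None:
        med = {c: _cluster_median_survival(surv, labels == c) for c in uniq}
        lr = logrank_test(
            surv.loc[labels == uniq[0], "time"],
            surv.loc[labels == uniq[1], "time"],
            surv.loc[labels == uniq[0], "status"],
            surv.loc[labels == uniq[1], "status"],
        )
        logger.info("cluster median survival: %s (log-rank p=%.3g)", med, lr.p_value)
        if med[uniq[0]] == med[uniq[1]]:
            raise ValueError(
                "clusters have equal median survival; pass worse_cluster explicitly"
            )
        worse_cluster = int(min(med, key=med.get))

    sel = model.selected_events
    sub = matrix.subset_events(sel)
    labels_arr = labels

    if direction_by == "cluster":
        worse_mask = labels_arr == worse_cluster
        with np.errstate(all="ignore"):
            mean_worse = np.nanmean(np.where(sub.detected, sub.psi, np.nan)[:, worse_mask], axis=1)
            mean_other = np.nanmean(np.where(sub.detected, sub.psi, np.nan)[:, ~worse_mask], axis=1)
        up_in_worse = mean_worse > mean_other
    elif direction_by == "survival":
        up_in_worse = np.zeros(len(sel), dtype=bool)
        X = sub.imputed()
        for j in range(len(sel)):
            df = pd.DataFrame(
                {"time": surv["time"].to_numpy(), "status": surv["status"].to_numpy(), "psi": X[j]}
            )
            cph = CoxPHFitter().fit(df, "time", "status")
            up_in_worse[j] = cph.params_["psi"] > 0
    else:
        raise ValueError("direction_by must be 'cluster' or 'survival'")

    g1_candidates = [e for e, up in zip(sel, up_in_worse) if up]
    g2_candidates = [e for e, up in zip(sel, up_in_worse) if not up]
    g1 = sorted(g1_candidates, key=lambda e: -model.importances[e])[:n_per_group]
    g2 = sorted(g2_candidates, key=lambda e: -model.importances[e])[:n_per_group]
    if len(g1) < n_per_group:
        logger.warning("only %d group-1 candidates (< %d)", len(g1), n_per_group)
    if len(g2) < n_per_group:
        logger.warning("only %d group-2 candidates (< %d)", len(g2), n_per_group)

    return SignatureModel(
        importances=model.importances,
        selected_events=model.selected_events,
        group1=g1,
        group2=g2,
        worse_cluster=worse_cluster,
    )


def as_score(
    matrix: PsiMatrix, model: SignatureModel, min_detected: int = 10
) -> AsScoreVector:
    """Per-sample AS score: mean group-1 PSI minus mean group-2 PSI.

    Only detected PSIs contribute; the score is missing when fewer than
    ``min_detected`` events of either group are detected in the sample. The
    event groups are frozen: no refitting happens at scoring time, and events
    absent from ``matrix`` simply reduce the group mean's support.
    """
    if not model.group1 or not model.group2:
        raise ValueError("signature model has empty groups")
    present1 = [e for e in model.group1 if e in matrix.event_ids]
    present2 = [e for e in model.group2 if e in matrix.event_ids]
    if not present1 or not present2:
        raise ValueError("no signature group events present in matrix")

    def group_stats(event_ids):
        sub = matrix.subset_events(event_ids)
        vals = np.where(sub.detected, sub.psi, 0.0)
        n_det = sub.detected.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(n_det > 0, vals.sum(axis=0) / np.maximum(n_det, 1), np.nan)
        return means, n_det

    m1, n1 = group_stats(present1)
    m2, n2 = group_stats(present2)
    score = m1 - m2
    ok = (n1 >= min_detected) & (n2 >= min_detected)
    score = np.where(ok, score, np.nan)
    idx = pd.Index(matrix.sample_ids, name="sample_id")
    return AsScoreVector(
        scores=pd.Series(score, index=idx, name="as_score"),
        n_group1_detected=pd.Series(n1, index=idx),
        n_group2_detected=pd.Series(n2, index=idx),
    )
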