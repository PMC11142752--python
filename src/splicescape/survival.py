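"""Kaplan-Meier curves, log-rank tests, and multivariable Cox fits for AS scores."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)


@dataclass
class KmResult:
    groups: pd.Series  # sample_id -> group label
    curves: dict  # group label -> KM survival table (DataFrame)
    statistic: float
    p_value: float


def _align(scores: pd.Series, survival: pd.DataFrame) -> pd.DataFrame:
    surv = survival.set_index("sample_id") if "sample_id" in survival.columns else survival
    df = surv.join(scores.rename("as_score"), how="inner").dropna(subset=["as_score"])
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["status"].isin([0, 1]).all():
        raise ValueError("status must be 0/1")
    return df


def km_logrank(scores: pd.Series, survival: pd.DataFrame, cut: float = 0.5) -> KmResult:
    """Median-split (or quantile ``cut``) KM curves with a log-rank test."""
    df = _align(scores, survival)
    threshold = df["as_score"].quantile(cut)
    groups = pd.Series(
        np.where(df["as_score"] > threshold, "high", "low"), index=df.index
    )
    sizes = groups.value_counts()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError(f"degenerate grouping at cut={cut}: sizes {sizes.to_dict()}")

    curves = {}
    for g in ("low", "high"):
        kmf = KaplanMeierFitter(label=g)
        kmf.fit(df.loc[groups == g, "time"], df.loc[groups == g, "status"])
        curves[g] = kmf.survival_function_

    lr = multivariate_logrank_test(df["time"], groups, df["status"])
    return KmResult(
        groups=groups,
        curves=curves,
        statistic=float(lr.test_statistic),
        p_value=float(lr.p_value),
    )


def cox_multivariable(
    scores: pd.Series,
    survival: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Proportional-hazards fit of survival on AS score plus covariates.

    Categorical covariates are dummy-coded (first level dropped); ties use the
    Efron approximation (lifelines default). Returns the lifelines summary
    with hazard ratios and 95% CIs; non-convergence propagates.
    """
    df = _align(scores, survival)
    covariates = list(covariates or [])
    if len(covariates) != len(set(covariates)):
        raise ValueError("duplicated covariate names")
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ValueError(f"covariates not in survival table: {missing}")

    design = df[["time", "status", "as_score"]].copy()
    for c in covariates:
        col = df[c]
        if col.nunique(dropna=False) < 2:
            raise ValueError(f"constant covariate {c!r}")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            design = design.join(dummies)
        else:
            design[c] = col.astype(float)

    numeric = design.drop(columns=["time", "status"])
    corr = numeric.corr()
    dup_pairs = [
        (a, b)
        for i, a in enumerate(corr.columns)
        for b in corr.columns[i + 1 :]
        if np.isclose(abs(corr.loc[a, b]), 1.0)
    ]
    if dup_pairs:
        raise ValueError(f"perfectly collinear covariate columns: {dup_pairs}")

    cph = CoxPHFitter()
    cph.fit(design, duration_col="time", event_col="status")
    summary = cph.summary[
        ["coef", "exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]
    ].rename(
        columns={
            "exp(coef)": "hr",
            "exp(coef) lower 95%": "hr_low",
            "exp(coef) upper 95%": "hr_high",
        }
    )
    return summary
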