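"""PSI estimation with 95% credible intervals under a two-isoform model.

The read-generating model for one event in one sample:

    I ~ Binomial(I + S, theta),   theta = psi*lI / (psi*lI + (1-psi)*lS)

where ``lI``/``lS`` are the effective lengths of the inclusion/skipping
isoforms. With a uniform prior on ``theta`` the posterior is
``theta ~ Beta(I+1, S+1)``; PSI quantiles follow by the exact monotone
transform ``psi = theta*lS / (theta*lS + (1-theta)*lI)``.

The point estimate reported is the length-normalized plug-in MLE
``psi = I*lS / (I*lS + S*lI)``; the posterior mean is reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import beta as beta_dist

from .types import PsiMatrix, SpliceEvent

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 10


@dataclass(frozen=True)
class PsiEstimate:
    """PSI point/posterior estimates for a single (event, sample) cell."""

    psi_point: float
    psi_posterior_mean: float
    ci_low: float
    ci_high: float
    ci_width: float
    detected: bool
    n_informative: int


def theta_to_psi(theta, lI: float, lS: float):
    """Monotone map from read-space fraction theta to isoform fraction psi."""
    theta = np.asarray(theta, dtype=float)
    return theta * lS / (theta * lS + (1.0 - theta) * lI)


def psi_to_theta(psi, lI: float, lS: float):
    psi = np.asarray(psi, dtype=float)
    return psi * lI / (psi * lI + (1.0 - psi) * lS)


def psi_point_estimate(I, S, lI, lS):
    """Length-normalized plug-in PSI: (I*lS) / (I*lS + S*lI)."""
    I = np.asarray(I, dtype=float)
    S = np.asarray(S, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return I * lS / (I * lS + S * lI)


def _posterior_mean_psi(I: int, S: int, lI: float, lS: float) -> float:
    """E[psi | I, S] under theta ~ Beta(I+1, S+1), by adaptive quadrature."""
    a, b = I + 1.0, S + 1.0
    if lI == lS:
        return a / (a + b)  # psi == theta

    def integrand(t: float) -> float:
        return float(theta_to_psi(t, lI, lS)) * beta_dist.pdf(t, a, b)

    # split at the posterior mode for peaked posteriors
    mode = a / (a + b)
    val, _ = integrate.quad(integrand, 0.0, 1.0, points=[mode], limit=200)
    return float(val)


def estimate_psi(
    I: int,
    S: int,
    lI: float = 2.0,
    lS: float = 1.0,
    min_reads: int = DEFAULT_MIN_READS,
    ci_level: float = 0.95,
) -> PsiEstimate:
    """Estimate PSI with an equal-tailed credible interval from junction counts.

    Parameters
    ----------
    I, S : int
        Inclusion and skipping junction read counts.
    lI, lS : float
        Effective lengths of the inclusion and skipping isoforms.
    min_reads : int
        Detection threshold on informative reads I + S; below it the estimate
        is flagged undetected and all numeric fields are NaN.
    ci_level : float
        Credible level of the equal-tailed interval (default 95%).
    """
    if I < 0 or S < 0:
        raise ValueError(f"negative counts: I={I}, S={S}")
    if lI <= 0 or lS <= 0:
        raise ValueError(f"non-positive effective length: lI={lI}, lS={lS}")
    n = int(I) + int(S)
    if n < min_reads:
        nan = float("nan")
        return PsiEstimate(nan, nan, nan, nan, nan, False, n)

    point = float(psi_point_estimate(I, S, lI, lS))
    alpha = (1.0 - ci_level) / 2.0
    t_lo, t_hi = beta_dist.ppf([alpha, 1.0 - alpha], I + 1, S + 1)
    # one-sided at the count boundary so the interval contains the MLE
    ci_low = 0.0 if I == 0 else float(theta_to_psi(t_lo, lI, lS))
    ci_high = 1.0 if S == 0 else float(theta_to_psi(t_hi, lI, lS))
    post_mean = _posterior_mean_psi(int(I), int(S), lI, lS)
    return PsiEstimate(
        psi_point=point,
        psi_posterior_mean=post_mean,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_width=ci_high - ci_low,
        detected=True,
        n_informative=n,
    )


def _ci_bounds_vectorized(I, S, lI, lS, ci_level: float = 0.95):
    alpha = (1.0 - ci_level) / 2.0
    t_lo = beta_dist.ppf(alpha, I + 1.0, S + 1.0)
    t_hi = beta_dist.ppf(1.0 - alpha, I + 1.0, S + 1.0)
    lo = np.where(np.asarray(I) == 0, 0.0, theta_to_psi(t_lo, lI, lS))
    hi = np.where(np.asarray(S) == 0, 1.0, theta_to_psi(t_hi, lI, lS))
    return lo, hi


def build_psi_matrix(
    counts: pd.DataFrame,
    events: Sequence[SpliceEvent] | pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    sample_ids: Optional[Sequence[str]] = None,
    ci_level: float = 0.95,
) -> PsiMatrix:
    """Build an events x samples PsiMatrix from long-form junction counts.

    ``counts`` must have columns event_id, sample_id, inc_count, skip_count.
    Event/sample pairs absent from the table are treated as zero coverage
    (undetected). Unknown event ids raise.
    """
    if isinstance(events, pd.DataFrame):
        ev_ids = [str(e) for e in events["event_id"]]
        lI_map = dict(zip(ev_ids, events["inc_eff_len"].astype(float)))
        lS_map = dict(zip(ev_ids, events["skip_eff_len"].astype(float)))
    else:
        ev_ids = [e.event_id for e in events]
        lI_map = {e.event_id: e.inc_eff_len for e in events}
        lS_map = {e.event_id: e.skip_eff_len for e in events}

    unknown = set(counts["event_id"].astype(str)) - set(ev_ids)
    if unknown:
        raise ValueError(f"unknown event ids in counts: {sorted(unknown)[:5]}")

    if sample_ids is None:
        sample_ids = list(pd.unique(counts["sample_id"].astype(str)))
    sample_ids = [str(s) for s in sample_ids]

    n_ev, n_sm = len(ev_ids), len(sample_ids)
    ev_pos = {e: i for i, e in enumerate(ev_ids)}
    sm_pos = {s: i for i, s in enumerate(sample_ids)}

    inc = np.zeros((n_ev, n_sm))
    skp = np.zeros((n_ev, n_sm))
    rows = counts["event_id"].astype(str).map(ev_pos).to_numpy()
    cols = counts["sample_id"].astype(str).map(sm_pos).to_numpy()
    inc[rows, cols] = counts["inc_count"].to_numpy(dtype=float)
    skp[rows, cols] = counts["skip_count"].to_numpy(dtype=float)

    lI = np.array([lI_map[e] for e in ev_ids])[:, None]
    lS = np.array([lS_map[e] for e in ev_ids])[:, None]

    total = inc + skp
    detected = total >= min_reads
    psi = np.full((n_ev, n_sm), np.nan)
    ciw = np.full((n_ev, n_sm), np.nan)
    if detected.any():
        r, c = np.where(detected)
        psi[r, c] = psi_point_estimate(inc[r, c], skp[r, c], lI[r, 0], lS[r, 0])
        lo, hi = _ci_bounds_vectorized(inc[r, c], skp[r, c], lI[r, 0], lS[r, 0], ci_level)
        ciw[r, c] = hi - lo

    rate = detected.mean() if detected.size else 0.0
    logger.info(
        "PSI matrix: %d events x %d samples, %.1f%% detected (min_reads=%d)",
        n_ev, n_sm, 100.0 * rate, min_reads,
    )
    return PsiMatrix(ev_ids, sample_ids, psi, ciw, detected)
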