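"""Sample QC and three-criterion selection of informative, reliable events.

Events are kept iff, over their *detected* entries:
(a) max(PSI) - min(PSI) > range_min, (b) SD(PSI) > sd_min (ddof=1), and
(c) the fraction of entries with CI width < ci_width_max exceeds ci_frac_min.
Samples are dropped when their undetected fraction exceeds
``sample_undetected_max``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import PsiMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    range_min: float = 0.6
    sd_min: float = 0.1
    ci_width_max: float = 0.5
    ci_frac_min: float = 0.8
    sample_undetected_max: float = 0.4
    # extra guard (not from the published criteria): require detection in at
    # least this fraction of QC-passed samples, preventing tiny-support events
    detection_frac_min: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "range_min",
            "sd_min",
            "ci_width_max",
            "ci_frac_min",
            "sample_undetected_max",
            "detection_frac_min",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")


def qc_samples(
    matrix: PsiMatrix, cfg: FilterConfig = FilterConfig()
) -> tuple[list[str], list[str]]:
    """Drop samples whose undetected-event fraction exceeds the QC threshold."""
    if matrix.n_events == 0 or matrix.n_samples == 0:
        raise ValueError("empty PSI matrix")
    undet_frac = 1.0 - matrix.detected.mean(axis=0)
    keep_mask = undet_frac <= cfg.sample_undetected_max
    kept = [s for s, k in zip(matrix.sample_ids, keep_mask) if k]
    dropped = [s for s, k in zip(matrix.sample_ids, keep_mask) if not k]
    logger.info("sample QC: kept %d, dropped %d", len(kept), len(dropped))
    return kept, dropped


def filter_events(
    matrix: PsiMatrix, cfg: FilterConfig = FilterConfig()
) -> tuple[list[str], pd.DataFrame]:
    """Apply the three event criteria; returns kept ids and per-criterion table.

    Criteria are evaluated over detected entries only; events with fewer than
    two detected entries fail (a) and (b) by definition. The per-criterion
    table has boolean columns pass_range, pass_sd, pass_ci, pass_detection.
    """
    psi = matrix.psi
    det = matrix.detected
    n_det = det.sum(axis=1)

    with np.errstate(all="ignore"):
        rng = np.nanmax(psi, axis=1) - np.nanmin(psi, axis=1)
        sd = np.nanstd(psi, axis=1, ddof=1)
        narrow = (matrix.ci_width < cfg.ci_width_max) & det
        frac_narrow = np.where(n_det > 0, narrow.sum(axis=1) / np.maximum(n_det, 1), 0.0)

    enough = n_det >= 2
    pass_range = enough & (rng > cfg.range_min)
    pass_sd = enough & (sd > cfg.sd_min)
    pass_ci = frac_narrow > cfg.ci_frac_min
    pass_detection = n_det >= cfg.detection_frac_min * matrix.n_samples

    keep = pass_range & pass_sd & pass_ci & pass_detection
    report = pd.DataFrame(
        {
            "event_id": matrix.event_ids,
            "n_detected": n_det,
            "psi_range": rng,
            "psi_sd": sd,
            "frac_narrow_ci": frac_narrow,
            "pass_range": pass_range,
            "pass_sd": pass_sd,
            "pass_ci": pass_ci,
            "pass_detection": pass_detection,
            "kept": keep,
        }
    )
    kept_ids = [e for e, k in zip(matrix.event_ids, keep) if k]
    logger.info("event filter: kept %d / %d events", len(kept_ids), matrix.n_events)
    return kept_ids, report


def intersect_across_datasets(kept_sets: list[set | list]) -> set:
    """Consensus events: intersection of kept sets across datasets."""
    if not kept_sets:
        raise ValueError("need at least one dataset")
    result = set(kept_sets[0])
    for s in kept_sets[1:]:
        result &= set(s)
    if not result:
        logger.warning("event intersection across datasets is empty")
    return result
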