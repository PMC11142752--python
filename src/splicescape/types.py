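"""Core domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

EVENT_TYPES = ("SE", "MXE", "A5SS", "A3SS", "RI")


@dataclass(frozen=True)
class SpliceEvent:
    """One annotated two-isoform splicing event.

    Coordinates are stored 0-based half-open. ``inc_eff_len`` / ``skip_eff_len``
    are the effective lengths (number of distinct supporting read positions) of
    the inclusion and skipping isoforms, used to de-bias PSI.
    """

    event_id: str
    gene: str
    event_type: str
    chrom: str = "chr1"
    strand: str = "+"
    start: int = 0
    end: int = 0
    inc_eff_len: float = 2.0
    skip_eff_len: float = 1.0

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(
                f"event_type must be one of {EVENT_TYPES}, got {self.event_type!r}"
            )
        if self.inc_eff_len <= 0 or self.skip_eff_len <= 0:
            raise ValueError("effective lengths must be positive")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.end < self.start:
            raise ValueError("end < start")


def events_to_frame(events: Iterable[SpliceEvent]) -> pd.DataFrame:
    rows = [
        {
            "event_id": e.event_id,
            "gene": e.gene,
            "event_type": e.event_type,
            "chrom": e.chrom,
            "strand": e.strand,
            "start": e.start,
            "end": e.end,
            "inc_eff_len": e.inc_eff_len,
            "skip_eff_len": e.skip_eff_len,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "gene",
            "event_type",
            "chrom",
            "strand",
            "start",
            "end",
            "inc_eff_len",
            "skip_eff_len",
        ],
    )


def events_from_frame(df: pd.DataFrame) -> list[SpliceEvent]:
    return [
        SpliceEvent(
            event_id=str(r.event_id),
            gene=str(r.gene),
            event_type=str(r.event_type),
            chrom=str(r.chrom),
            strand=str(r.strand),
            start=int(r.start),
            end=int(r.end),
            inc_eff_len=float(r.inc_eff_len),
            skip_eff_len=float(r.skip_eff_len),
        )
        for r in df.itertuples(index=False)
    ]


@dataclass
class PsiMatrix:
    """Events x samples PSI point estimates with CI widths and detection mask.

    ``psi`` and ``ci_width`` are NaN exactly where ``detected`` is False.
    """

    event_ids: list[str]
    sample_ids: list[str]
    psi: np.ndarray
    ci_width: np.ndarray
    detected: np.ndarray

    def __post_init__(self) -> None:
        self.event_ids = list(self.event_ids)
        self.sample_ids = list(self.sample_ids)
        self.psi = np.asarray(self.psi, dtype=float)
        self.ci_width = np.asarray(self.ci_width, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        shape = (len(self.event_ids), len(self.sample_ids))
        for name in ("psi", "ci_width", "detected"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if len(set(self.event_ids)) != len(self.event_ids):
            raise ValueError("duplicate event ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        und = ~self.detected
        if not (np.isnan(self.psi[und]).all() and np.isnan(self.ci_width[und]).all()):
            raise ValueError("undetected entries must carry NaN values")
        det = self.detected
        if det.any():
            vals = self.psi[det]
            if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
                raise ValueError("detected PSI values must lie in [0,1]")

    @property
    def n_events(self) -> int:
        return len(self.event_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def event_index(self, event_id: str) -> int:
        return self.event_ids.index(event_id)

    def subset_events(self, event_ids: Sequence[str]) -> "PsiMatrix":
        idx = [self.event_ids.index(e) for e in event_ids]
        return PsiMatrix(
            [self.event_ids[i] for i in idx],
            self.sample_ids,
            self.psi[idx],
            self.ci_width[idx],
            self.detected[idx],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "PsiMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return PsiMatrix(
            self.event_ids,
            [self.sample_ids[i] for i in idx],
            self.psi[:, idx],
            self.ci_width[:, idx],
            self.detected[:, idx],
        )

    def imputed(self) -> np.ndarray:
        """PSI with missing entries filled by per-event median of detected values.

        Events with no detected value anywhere are filled with 0.5.
        """
        out = self.psi.copy()
        with np.errstate(all="ignore"):
            med = np.nanmedian(out, axis=1)
        med = np.where(np.isnan(med), 0.5, med)
        rows, cols = np.where(~self.detected)
        out[rows, cols] = med[rows]
        return out

    def to_wide_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.psi, index=self.event_ids, columns=self.sample_ids)

    def to_long_frame(self) -> pd.DataFrame:
        ev = np.repeat(self.event_ids, self.n_samples)
        sm = np.tile(self.sample_ids, self.n_events)
        return pd.DataFrame(
            {
                "event_id": ev,
                "sample_id": sm,
                "psi": self.psi.ravel(),
                "ci_width": self.ci_width.ravel(),
                "detected": self.detected.ravel(),
            }
        )

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "PsiMatrix":
        piv_psi = df.pivot(index="event_id", columns="sample_id", values="psi")
        piv_ciw = df.pivot(index="event_id", columns="sample_id", values="ci_width")
        piv_det = (
            df.pivot(index="event_id", columns="sample_id", values="detected")
            .fillna(False)
            .astype(bool)
        )
        return cls(
            list(piv_psi.index),
            list(piv_psi.columns),
            piv_psi.to_numpy(dtype=float),
            piv_ciw.to_numpy(dtype=float),
            piv_det.to_numpy(),
        )


@dataclass
class Dataset:
    """A named cohort: junction counts plus sample metadata and optional expression."""

    name: str
    counts: pd.DataFrame
    samples: pd.DataFrame
    events: Optional[pd.DataFrame] = None
    expression: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if "sample_id" in self.samples.columns:
            ids = self.samples["sample_id"]
            if ids.duplicated().any():
                raise ValueError(f"duplicate sample ids in dataset {self.name!r}")
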