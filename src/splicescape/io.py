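"""Readers and writers for the tables and sequence files the pipeline touches.

All writers emit a deterministic column order; readers validate types and
report offending row numbers (1-based, counting the header as row 1).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import PsiMatrix

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["event_id", "sample_id", "inc_count", "skip_count"]


def read_junction_counts(path) -> pd.DataFrame:
    """Read a long-form junction-count TSV and validate it.

    Requires columns event_id, sample_id, inc_count, skip_count; counts must
    be non-negative integers and (event, sample) pairs unique. Errors name the
    offending file row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str, "sample_id": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("inc_count", "skip_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header is row 1
            raise ValueError(f"{path}: invalid {col} at row {row}")
        df[col] = vals.astype(int)
    dup = df.duplicated(subset=["event_id", "sample_id"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ValueError(f"{path}: duplicate (event, sample) pair at row {row}")
    return df[COUNT_COLUMNS]


def write_junction_counts(df: pd.DataFrame, path) -> None:
    df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_expression(path) -> pd.DataFrame:
    """Genes/RBPs x samples expression matrix with the id column first."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def write_psi_matrix(matrix: PsiMatrix, path, form: str = "long") -> None:
    if form == "long":
        matrix.to_long_frame().to_csv(path, sep="\t", index=False)
    elif form == "wide":
        matrix.to_wide_frame().to_csv(path, sep="\t", index_label="event_id")
    else:
        raise ValueError("form must be 'long' or 'wide'")


def read_psi_matrix(path) -> PsiMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str, "sample_id": str})
    return PsiMatrix.from_long_frame(df)


def read_miso_summary(path) -> tuple[pd.DataFrame, int]:
    """Read a MISO-style summary into PSI records with CI bounds.

    Expects tab-delimited columns event_name, miso_posterior_mean, ci_low,
    ci_high. Comma-separated multi-isoform PSI rows (e.g. "0.2,0.5,0.3") are
    skipped with a warning count (two-isoform events only); an empty file
    yields an empty frame. Returns (records, n_skipped).
    """
    cols = ["event_name", "miso_posterior_mean", "ci_low", "ci_high"]
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["event_id", "psi", "ci_low", "ci_high", "ci_width"]), 0
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    skipped = 0
    rows = []
    for i, r in df.iterrows():
        if any("," in str(r[c]) for c in cols[1:]):
            skipped += 1
            continue
        try:
            psi = float(r["miso_posterior_mean"])
            lo = float(r["ci_low"])
            hi = float(r["ci_high"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: unparseable CI fields at row {int(i) + 2}") from exc
        rows.append((str(r["event_name"]), psi, lo, hi, hi - lo))
    if skipped:
        logger.warning("%s: skipped %d multi-isoform rows", path, skipped)
    out = pd.DataFrame(rows, columns=["event_id", "psi", "ci_low", "ci_high", "ci_width"])
    return out, skipped


def read_rmats_table(path) -> pd.DataFrame:
    """Read an rMATS JC table into per-replicate junction-count records.

    Uses IJC_SAMPLE_1 / SJC_SAMPLE_1 (comma-separated replicates) together
    with IncFormLen / SkipFormLen. Returns long-form records with columns
    event_id, sample_id (rep index), inc_count, skip_count, inc_eff_len,
    skip_eff_len, plus recomputed plug-in PSI.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["IJC_SAMPLE_1", "SJC_SAMPLE_1", "IncFormLen", "SkipFormLen"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    id_col = "ID" if "ID" in df.columns else None

    rows = []
    for i, r in df.iterrows():
        lI = float(r["IncFormLen"])
        lS = float(r["SkipFormLen"])
        if lI <= 0 or lS <= 0:
            raise ValueError(f"{path}: non-positive effective length at row {int(i) + 2}")
        event_id = str(r[id_col]) if id_col else f"row{int(i)}"
        inc = [int(x) for x in str(r["IJC_SAMPLE_1"]).split(",")]
        skp = [int(x) for x in str(r["SJC_SAMPLE_1"]).split(",")]
        if len(inc) != len(skp):
            raise ValueError(f"{path}: replicate count mismatch at row {int(i) + 2}")
        for rep, (I, S) in enumerate(zip(inc, skp)):
            tot = I * lS + S * lI
            psi = I * lS / tot if tot > 0 else np.nan
            rows.append((event_id, f"rep{rep + 1}", I, S, lI, lS, psi))
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "sample_id", "inc_count", "skip_count",
            "inc_eff_len", "skip_eff_len", "psi",
        ],
    )


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Minimal FASTA reader; sequences returned uppercase with U mapped to T."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before first header")
                chunks.append(line.upper().replace("U", "T"))
        if name is not None:
            out[name] = "".join(chunks)
    return out


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def append_manifest(outdir, command: str, config: dict, seed: Optional[int]) -> None:
    """Append a JSON-lines run record (command, config hash, seed, versions)."""
    entry = {
        "command": command,
        "config_hash": config_hash(config),
        "seed": seed,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    path = Path(outdir) / "run_manifest.jsonl"
    with open(path, "a") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")
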