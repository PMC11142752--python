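"""Splice-site sequence features: GC profiling, site-strength models, motifs.

All sequence handling treats U and T as equivalent (RNA motifs against DNA
FASTA) and is case-insensitive. Motif presence is scored per sequence
(present/absent, not occurrence counts) to avoid length confounding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
BASES = "ACGT"
REGIONS = ("upstream_intron", "exon", "downstream_intron")


def normalize_seq(seq: str) -> str:
    """Uppercase and map U -> T."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class MotifSpec:
    pattern: str
    region: str = "upstream_intron"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = [c for c in self.pattern.upper().replace("U", "T") if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC letters in {self.pattern!r}: {bad}")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")

    @property
    def charsets(self) -> list[str]:
        return [IUPAC[c] for c in normalize_seq(self.pattern)]


def iupac_match(pattern: str | MotifSpec, seq: str) -> bool:
    """True iff the degenerate pattern occurs at least once in seq (U == T).

    Implemented as a direct sliding-window character-set scan (a regex oracle
    cross-checks this in the test suite).
    """
    spec = pattern if isinstance(pattern, MotifSpec) else MotifSpec(pattern)
    sets = spec.charsets
    s = normalize_seq(seq)
    m, n = len(sets), len(s)
    for start in range(n - m + 1):
        if all(s[start + k] in sets[k] for k in range(m)):
            return True
    return False


def gc_fraction(seq: str) -> float:
    s = normalize_seq(seq)
    if not s:
        return np.nan
    return (s.count("G") + s.count("C")) / len(s)


def gc_profile(sequences: Sequence[str], window_len: int = 100) -> np.ndarray:
    """Per-sequence GC fraction over the last ``window_len`` nt (3'SS-proximal).

    Sequences shorter than the window are excluded (NaN, counted in the log).
    """
    out = np.full(len(sequences), np.nan)
    short = 0
    for i, seq in enumerate(sequences):
        s = normalize_seq(seq)
        if len(s) < window_len:
            short += 1
            continue
        out[i] = gc_fraction(s[-window_len:])
    if short:
        logger.info("gc_profile: excluded %d sequences shorter than %d nt", short, window_len)
    return out


def gc_compare(
    set_a: Sequence[str], set_b: Sequence[str], window_len: int = 100
) -> dict:
    """Mean GC difference (A - B) over the 3'SS-upstream window + rank-sum test."""
    ga = gc_profile(set_a, window_len)
    gb = gc_profile(set_b, window_len)
    ga = ga[~np.isnan(ga)]
    gb = gb[~np.isnan(gb)]
    if len(ga) == 0 or len(gb) == 0:
        raise ValueError("no usable sequences in one of the sets")
    stat, p = mannwhitneyu(ga, gb, alternative="two-sided")
    return {
        "mean_gc_a": float(ga.mean()),
        "mean_gc_b": float(gb.mean()),
        "difference": float(ga.mean() - gb.mean()),
        "statistic": float(stat),
        "p_value": float(p),
        "n_a": len(ga),
        "n_b": len(gb),
    }


@dataclass
class SpliceSiteModel:
    """Log-odds splice-site strength model (bits) vs a background.

    kind: WMM (position weight matrix), MM1 (first-order inhomogeneous
    Markov), or DINUC (dinucleotide-composition log-odds). Windows follow the
    MaxEntScan convention: 9-mer for 5'SS (-3..+6), 23-mer for 3'SS (-20..+3).
    """

    kind: str
    window: int
    pos_probs: np.ndarray | None = None  # WMM: window x 4
    cond_probs: np.ndarray | None = None  # MM1: (window-1) x 4 x 4
    dinuc_probs: np.ndarray | None = None  # DINUC: 4 x 4
    bg_probs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    bg_dinuc: np.ndarray = field(default_factory=lambda: np.full((4, 4), 1 / 16))
    pseudocount: float = 0.5

    KINDS = ("WMM", "MM1", "DINUC")

    @classmethod
    def train(
        cls,
        kind: str,
        sequences: Sequence[str],
        background: Sequence[str] | None = None,
        pseudocount: float = 0.5,
    ) -> "SpliceSiteModel":
        if kind not in cls.KINDS:
            raise ValueError(f"kind must be one of {cls.KINDS}")
        seqs = [normalize_seq(s) for s in sequences]
        if not seqs:
            raise ValueError("no training sequences")
        W = len(seqs[0])
        if any(len(s) != W for s in seqs):
            raise ValueError("training sequences must share one length")
        idx = {b: i for i, b in enumerate(BASES)}
        for s in seqs:
            bad = set(s) - set(BASES)
            if bad:
                raise ValueError(f"unseen symbols in training sequence: {bad}")

        bg = np.full(4, pseudocount)
        bg_di = np.full((4, 4), pseudocount)
        bg_seqs = [normalize_seq(s) for s in background] if background else seqs
        for s in bg_seqs:
            for c in s:
                if c in idx:
                    bg[idx[c]] += 1
            for a, b in zip(s, s[1:]):
                if a in idx and b in idx:
                    bg_di[idx[a], idx[b]] += 1
        bg = bg / bg.sum()
        bg_di = bg_di / bg_di.sum()

        model = cls(kind=kind, window=W, bg_probs=bg, bg_dinuc=bg_di,
                    pseudocount=pseudocount)
        if kind == "WMM":
            counts = np.full((W, 4), pseudocount)
            for s in seqs:
                for p, c in enumerate(s):
                    counts[p, idx[c]] += 1
            model.pos_probs = counts / counts.sum(axis=1, keepdims=True)
        elif kind == "MM1":
            counts0 = np.full(4, pseudocount)
            for s in seqs:
                counts0[idx[s[0]]] += 1
            cond = np.full((W - 1, 4, 4), pseudocount)
            for s in seqs:
                for p in range(W - 1):
                    cond[p, idx[s[p]], idx[s[p + 1]]] += 1
            model.pos_probs = (counts0 / counts0.sum())[None, :]
            model.cond_probs = cond / cond.sum(axis=2, keepdims=True)
        else:  # DINUC
            di = np.full((4, 4), pseudocount)
            for s in seqs:
                for a, b in zip(s, s[1:]):
                    di[idx[a], idx[b]] += 1
            model.dinuc_probs = di / di.sum()
        return model

    def score(self, seq: str) -> float:
        """Log2-odds strength of ``seq`` under the trained model (bits)."""
        s = normalize_seq(seq)
        if len(s) != self.window:
            raise ValueError(f"sequence length {len(s)} != model window {self.window}")
        idx = {b: i for i, b in enumerate(BASES)}
        bad = set(s) - set(BASES)
        if bad:
            raise ValueError(f"unseen symbols: {bad}")
        code = [idx[c] for c in s]

        if self.kind == "WMM":
            return float(
                sum(np.log2(self.pos_probs[p, c] / self.bg_probs[c])
                    for p, c in enumerate(code))
            )
        if self.kind == "MM1":
            total = np.log2(self.pos_probs[0, code[0]] / self.bg_probs[code[0]])
            for p in range(self.window - 1):
                a, b = code[p], code[p + 1]
                bg_cond = self.bg_dinuc[a].sum()
                bg_cond = self.bg_dinuc[a, b] / bg_cond if bg_cond > 0 else 0.25
                total += np.log2(self.cond_probs[p, a, b] / bg_cond)
            return float(total)
        # DINUC
        total = 0.0
        for a, b in zip(code, code[1:]):
            total += np.log2(self.dinuc_probs[a, b] / self.bg_dinuc[a, b])
        return float(total)

    def to_frame(self) -> pd.DataFrame:
        if self.kind == "WMM":
            return pd.DataFrame(self.pos_probs, columns=list(BASES))
        if self.kind == "DINUC":
            return pd.DataFrame(self.dinuc_probs, index=list(BASES), columns=list(BASES))
        flat = self.cond_probs.reshape(self.window - 1, 16)
        cols = [a + b for a in BASES for b in BASES]
        return pd.DataFrame(flat, columns=cols)


def _haldane_or(a: int, b: int, c: int, d: int) -> float:
    return (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))


def motif_enrichment(
    set_a: Sequence[str], set_b: Sequence[str], motif: MotifSpec | str
) -> dict:
    """Per-sequence presence 2x2 table -> Haldane odds ratio + Fisher exact p."""
    if not set_a or not set_b:
        raise ValueError("both sequence sets must be non-empty")
    spec = motif if isinstance(motif, MotifSpec) else MotifSpec(motif)
    if len(spec.pattern) > max(len(s) for s in list(set_a) + list(set_b)):
        raise ValueError("motif longer than every sequence")
    a = sum(iupac_match(spec, s) for s in set_a)
    b = len(set_a) - a
    c = sum(iupac_match(spec, s) for s in set_b)
    d = len(set_b) - c
    _, p = fisher_exact([[a, b], [c, d]])
    return {
        "motif": spec.pattern,
        "present_a": a, "absent_a": b, "present_b": c, "absent_b": d,
        "odds_ratio": _haldane_or(a, b, c, d),
        "p_value": float(p),
    }


def denovo_kmers(
    set_a: Sequence[str], set_b: Sequence[str], k: int = 6
) -> pd.DataFrame:
    """Exhaustive k-mer presence enrichment of set A vs set B.

    Returns per-kmer presence counts, Fisher p, BH q, ranked by q then by
    descending odds ratio. k-mers never observed in either set are omitted.
    """
    sa = [normalize_seq(s) for s in set_a if len(s) >= k]
    sb = [normalize_seq(s) for s in set_b if len(s) >= k]
    if not sa or not sb:
        return pd.DataFrame(
            columns=["kmer", "present_a", "present_b", "odds_ratio", "p_value", "q_value"]
        )

    def presence(seqs):
        counts: dict[str, int] = {}
        for s in seqs:
            seen = {s[i : i + k] for i in range(len(s) - k + 1)}
            for km in seen:
                if set(km) <= set(BASES):
                    counts[km] = counts.get(km, 0) + 1
        return counts

    ca, cb = presence(sa), presence(sb)
    kmers = sorted(set(ca) | set(cb))
    rows = []
    for km in kmers:
        a, c = ca.get(km, 0), cb.get(km, 0)
        b, d = len(sa) - a, len(sb) - c
        _, p = fisher_exact([[a, b], [c, d]])
        rows.append((km, a, c, _haldane_or(a, b, c, d), p))
    out = pd.DataFrame(rows, columns=["kmer", "present_a", "present_b", "odds_ratio", "p_value"])
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1] if len(out) else []
    out = out.sort_values(
        ["q_value", "odds_ratio"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    return out
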