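"""Synthetic bulk / single-cell splicing datasets with known ground truth.

Generative model for bulk data, per sample i and event j:

    s_i  ~ equal-weight mixture of Beta(m1*c, (1-m1)*c) and Beta(m2*c, (1-m2)*c)
    mu_ij = logistic(a_j + b_j * s_i)
    psi_ij ~ Beta(mu_ij * kappa, (1 - mu_ij) * kappa)
    n_ij ~ NegBin(mean = reads_per_event), theta_ij = psi*lI / (psi*lI + (1-psi)*lS)
    I_ij ~ Binomial(n_ij, theta_ij),  S_ij = n_ij - I_ij

Group-1 events have b_j > 0, group-2 b_j < 0, noise b_j = 0. Survival times
are exponential with hazard proportional to exp(survival_beta * AS_true(i)),
AS_true = mean(true psi over group 1) - mean(true psi over group 2), with
uniform administrative censoring calibrated to the requested censor rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm, rankdata

from .seqfeat import IUPAC, MotifSpec, normalize_seq
from .types import SpliceEvent, events_to_frame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; defaults sized for desk-scale recovery tests."""

    n_samples: int = 300
    n_events: int = 1300
    n_informative: int = 200
    frac_group1: float = 0.5
    latent_modes: tuple[float, float] = (0.25, 0.75)
    latent_concentration: float = 40.0
    coupling_strength: float = 6.0
    psi_concentration: float = 60.0
    reads_per_event: float = 100.0
    nb_dispersion: float = 10.0
    inc_eff_len: float = 2.0
    skip_eff_len: float = 1.0
    survival_beta: float = math.log(3.0)
    base_hazard: float = 1.0 / 1000.0
    censor_rate: float = 0.3
    n_rbp_total: int = 276
    n_rbp_coupled: int = 29
    rbp_rho: float = 0.8
    sc_n_patients: int = 4
    sc_states: tuple[str, ...] = ("NPC-like", "OPC-like", "AC-like", "MES-like")
    sc_state_scores: Optional[tuple[float, ...]] = None
    sc_cells_per_state: int = 100
    sc_reads_per_cell_event: float = 2.0
    sc_patient_jitter: float = 0.05
    flank_len: int = 250
    exon_len: int = 120
    background_gc: float = 0.45
    gc_offset: float = -0.1
    gc_window: int = 100
    motif_upstream: str = "CYCUCY"
    motif_downstream: str = "CUBCCY"
    motif_exon: str = "CYUCWKC"
    motif_plant_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_events:
            raise ValueError("n_informative > n_events")
        if self.psi_concentration <= 0:
            raise ValueError("psi_concentration must be > 0")
        if self.latent_concentration <= 0:
            raise ValueError("latent_concentration must be > 0")
        m1, m2 = self.latent_modes
        if not (0 < m1 < 1 and 0 < m2 < 1):
            raise ValueError("latent modes must lie in (0,1)")
        if m1 == m2:
            raise ValueError("latent modes must differ")
        for name in ("frac_group1", "censor_rate", "motif_plant_rate", "background_gc"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if abs(self.rbp_rho) >= 1:
            raise ValueError("|rbp_rho| must be < 1")
        if self.n_rbp_coupled > self.n_rbp_total:
            raise ValueError("n_rbp_coupled > n_rbp_total")
        if self.sc_state_scores is not None and len(self.sc_state_scores) != len(self.sc_states):
            raise ValueError("sc_state_scores length must match sc_states")


@dataclass
class SimTruth:
    latent_score: np.ndarray  # per-sample s_i
    cluster_label: np.ndarray  # per-sample {1,2}, by mixture component
    event_role: np.ndarray  # per-event {"group1","group2","noise"}
    event_a: np.ndarray  # logit-scale intercepts
    event_b: np.ndarray  # logit-scale slopes
    true_psi: np.ndarray  # events x samples
    as_true: np.ndarray  # per-sample true AS score
    survival_beta: float
    event_ids: list[str]
    sample_ids: list[str]
    coupled_rbp: dict = field(default_factory=dict)  # rbp id -> +1/-1

    def __post_init__(self) -> None:
        if ((self.true_psi < 0) | (self.true_psi > 1)).any():
            raise ValueError("true_psi outside [0,1]")
        b = self.event_b
        if not (
            (b[self.event_role == "group1"] > 0).all()
            and (b[self.event_role == "group2"] < 0).all()
            and (b[self.event_role == "noise"] == 0).all()
        ):
            raise ValueError("event slopes inconsistent with roles")


@dataclass
class BulkSim:
    counts: pd.DataFrame  # event_id, sample_id, inc_count, skip_count
    events: pd.DataFrame  # annotation table
    samples: pd.DataFrame  # sample_id, time, status, covariates
    truth: SimTruth


def _make_events(config: SimConfig) -> list[SpliceEvent]:
    types = ["SE", "MXE", "A5SS", "A3SS", "RI"]
    return [
        SpliceEvent(
            event_id=f"EV{j:05d}",
            gene=f"GENE{j % max(config.n_events // 2, 1):05d}",
            event_type=types[j % len(types)],
            chrom=f"chr{(j % 22) + 1}",
            strand="+" if j % 2 == 0 else "-",
            start=1000 * j,
            end=1000 * j + 500,
            inc_eff_len=config.inc_eff_len,
            skip_eff_len=config.skip_eff_len,
        )
        for j in range(config.n_events)
    ]


def _draw_latent(config: SimConfig, rng: np.random.Generator):
    m1, m2 = config.latent_modes
    c = config.latent_concentration
    comp = rng.integers(0, 2, size=config.n_samples)
    s = np.where(
        comp == 0,
        rng.beta(m1 * c, (1 - m1) * c, size=config.n_samples),
        rng.beta(m2 * c, (1 - m2) * c, size=config.n_samples),
    )
    # cluster 1 = lower-mode component
    lower_first = m1 < m2
    label = np.where(comp == 0, 1 if lower_first else 2, 2 if lower_first else 1)
    return s, label


def _draw_event_params(config: SimConfig, rng: np.random.Generator):
    n = config.n_events
    roles = np.array(["noise"] * n, dtype=object)
    n_inf = config.n_informative
    n_g1 = int(round(config.frac_group1 * n_inf))
    inf_idx = np.arange(n_inf)  # first events are informative; ids are opaque anyway
    roles[inf_idx[:n_g1]] = "group1"
    roles[inf_idx[n_g1:]] = "group2"

    b = np.zeros(n)
    b[roles == "group1"] = config.coupling_strength
    b[roles == "group2"] = -config.coupling_strength
    # midpoint PSI (at s = 0.5) uniform on [0.15, 0.85]; the stored intercept
    # absorbs the slope so that mu_ij = logistic(a_j + b_j * s_i) exactly
    mid = rng.uniform(0.15, 0.85, size=n)
    a = logit(mid) - b * 0.5
    return roles, a, b


def true_as_score(true_psi: np.ndarray, roles: np.ndarray) -> np.ndarray:
    g1 = roles == "group1"
    g2 = roles == "group2"
    score = np.zeros(true_psi.shape[1])
    if g1.any():
        score = true_psi[g1].mean(axis=0)
    if g2.any():
        score = score - true_psi[g2].mean(axis=0)
    return score


def _censoring_horizon(times: np.ndarray, censor_rate: float) -> float:
    """Administrative horizon tau with E[fraction censored] = censor_rate."""
    if censor_rate <= 0:
        return np.inf

    def frac_censored(tau):
        return np.minimum(times, tau).mean() / tau - censor_rate

    lo, hi = times.min() * 1e-6, times.max() * 1e6
    return brentq(frac_censored, lo, hi)


def simulate_bulk(
    config: SimConfig,
    name: str = "bulk",
    share_events_from: Optional[SimTruth] = None,
) -> BulkSim:
    """Draw one bulk cohort (junction counts, survival metadata, ground truth).

    ``share_events_from`` reuses the event roles/intercepts/slopes of an
    earlier truth so that several cohorts (e.g. three-platform replication)
    share one generative event set while samples stay independent.
    """
    rng = np.random.default_rng(config.seed)
    events = _make_events(config)
    s, cluster = _draw_latent(config, rng)
    if share_events_from is not None:
        if len(share_events_from.event_ids) != config.n_events:
            raise ValueError("shared truth has a different number of events")
        roles = share_events_from.event_role.copy()
        a = share_events_from.event_a.copy()
        b = share_events_from.event_b.copy()
        _ = _draw_event_params(config, rng)  # keep the rng stream aligned
    else:
        roles, a, b = _draw_event_params(config, rng)

    mu = expit(a[:, None] + b[:, None] * s[None, :])
    kappa = config.psi_concentration
    psi = rng.beta(mu * kappa, (1 - mu) * kappa)
    psi = np.clip(psi, 1e-12, 1 - 1e-12)

    # negative binomial total reads via gamma-poisson mixture
    r = config.nb_dispersion
    lam = rng.gamma(r, config.reads_per_event / r, size=psi.shape)
    n_reads = rng.poisson(lam)
    lI, lS = config.inc_eff_len, config.skip_eff_len
    theta = psi * lI / (psi * lI + (1 - psi) * lS)
    inc = rng.binomial(n_reads, theta)
    skp = n_reads - inc

    ev_ids = [e.event_id for e in events]
    sm_ids = [f"{name}_S{i:04d}" for i in range(config.n_samples)]
    counts = pd.DataFrame(
        {
            "event_id": np.repeat(ev_ids, config.n_samples),
            "sample_id": np.tile(sm_ids, config.n_events),
            "inc_count": inc.ravel(),
            "skip_count": skp.ravel(),
        }
    )

    as_true = true_as_score(psi, roles)
    hazard = config.base_hazard * np.exp(
        config.survival_beta * (as_true - as_true.mean())
    )
    t_event = rng.exponential(1.0 / hazard)
    tau = _censoring_horizon(t_event, config.censor_rate)
    if np.isinf(tau):
        time, status = t_event, np.ones(len(t_event), dtype=int)
    else:
        c_time = rng.uniform(0, tau, size=len(t_event))
        time = np.minimum(t_event, c_time)
        status = (t_event <= c_time).astype(int)
    time = np.maximum(time, 1e-6)

    samples = pd.DataFrame(
        {
            "sample_id": sm_ids,
            "time": time,
            "status": status,
            "age": np.round(rng.uniform(20, 80, size=config.n_samples), 1),
            "sex": rng.choice(["F", "M"], size=config.n_samples),
        }
    )

    truth = SimTruth(
        latent_score=s,
        cluster_label=cluster,
        event_role=roles,
        event_a=a,
        event_b=b,
        true_psi=psi,
        as_true=as_true,
        survival_beta=config.survival_beta,
        event_ids=ev_ids,
        sample_ids=sm_ids,
    )
    return BulkSim(counts, events_to_frame(events), samples, truth)


@dataclass
class ScSim:
    counts: pd.DataFrame  # event_id, cell_id, inc_count, skip_count (nonzero rows)
    cells: pd.DataFrame  # cell_id, patient, state
    pb_true_psi: pd.DataFrame  # events x pseudobulk true PSI
    state_scores: dict


def simulate_sc(config: SimConfig, bulk_truth: SimTruth) -> ScSim:
    """Draw sparse per-cell junction counts structured by (patient, state).

    Each (patient, state) pseudobulk carries a latent score: the state's
    anchor value (evenly spaced on [0,1] unless ``sc_state_scores`` is given)
    plus a small patient jitter. True PSI comes from the bulk event parameters
    at that latent value; per-cell coverage is Poisson(sc_reads_per_cell_event)
    per event with binomial inclusion reads. Zero-coverage rows are omitted
    from the counts table.
    """
    if config.sc_n_patients <= 0 or not config.sc_states or config.sc_cells_per_state <= 0:
        raise ValueError("need at least one patient, one state and one cell per state")
    rng = np.random.default_rng(config.seed + 1)
    states = list(config.sc_states)
    if config.sc_state_scores is not None:
        anchors = dict(zip(states, config.sc_state_scores))
    elif len(states) == 1:
        anchors = {states[0]: 0.5}
    else:
        anchors = {st: k / (len(states) - 1) for k, st in enumerate(states)}

    a, b = bulk_truth.event_a, bulk_truth.event_b
    ev_ids = bulk_truth.event_ids
    lI, lS = config.inc_eff_len, config.skip_eff_len

    cell_rows, count_frames = [], []
    pb_psi = {}
    state_scores = {}
    for p in range(config.sc_n_patients):
        patient = f"P{p:02d}"
        for st in states:
            u = float(
                np.clip(anchors[st] + rng.normal(0, config.sc_patient_jitter), 0, 1)
            )
            state_scores[(patient, st)] = u
            psi = expit(a + b * u)
            pb_psi[f"{patient}|{st}"] = psi
            theta = psi * lI / (psi * lI + (1 - psi) * lS)
            for c in range(config.sc_cells_per_state):
                cell_id = f"{patient}_{st}_C{c:04d}"
                cell_rows.append((cell_id, patient, st))
                n = rng.poisson(config.sc_reads_per_cell_event, size=len(ev_ids))
                nz = np.nonzero(n)[0]
                if len(nz) == 0:
                    continue
                inc = rng.binomial(n[nz], theta[nz])
                count_frames.append(
                    pd.DataFrame(
                        {
                            "event_id": [ev_ids[k] for k in nz],
                            "cell_id": cell_id,
                            "inc_count": inc,
                            "skip_count": n[nz] - inc,
                        }
                    )
                )

    cells = pd.DataFrame(cell_rows, columns=["cell_id", "patient", "state"])
    counts = (
        pd.concat(count_frames, ignore_index=True)
        if count_frames
        else pd.DataFrame(columns=["event_id", "cell_id", "inc_count", "skip_count"])
    )
    pb_true = pd.DataFrame(pb_psi, index=ev_ids)
    return ScSim(counts, cells, pb_true, state_scores)


def simulate_rbp(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """RBP expression table (RBPs x samples) with planted score coupling.

    Coupled RBPs reach the target Spearman rho by mixing the normal scores of
    the latent s_i with Gaussian noise at the bivariate-normal weight
    r = 2*sin(pi*rho/6); half of the couplings are positive
    (ceil(n_coupled/2)), half negative. Uncoupled RBPs are independent
    log-normal noise. Coupled ids and signs are recorded in ``truth``.
    """
    rng = np.random.default_rng(config.seed + 2)
    n_s = len(truth.sample_ids)
    s_norm = norm.ppf((rankdata(truth.latent_score) - 0.5) / n_s)
    s_norm = (s_norm - s_norm.mean()) / max(s_norm.std(), 1e-12)

    rho = config.rbp_rho
    r = 2.0 * math.sin(math.pi * rho / 6.0)
    n_pos = math.ceil(config.n_rbp_coupled / 2)

    rbp_ids = [f"RBP{k:04d}" for k in range(config.n_rbp_total)]
    expr = np.empty((config.n_rbp_total, n_s))
    truth.coupled_rbp = {}
    for k in range(config.n_rbp_total):
        if k < config.n_rbp_coupled:
            sign = 1 if k < n_pos else -1
            z = sign * r * s_norm + math.sqrt(max(1 - r * r, 0.0)) * rng.normal(size=n_s)
            truth.coupled_rbp[rbp_ids[k]] = sign
        else:
            z = rng.normal(size=n_s)
        expr[k] = np.exp(3.0 + z)  # log-normal expression scale

    return pd.DataFrame(expr, index=pd.Index(rbp_ids, name="rbp"),
                        columns=truth.sample_ids)


@dataclass
class SeqSim:
    records: pd.DataFrame  # event_id, region, role, sequence
    planted: pd.DataFrame  # event_id, region, motif, position


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(np.array(list("ACGT")), size=length, p=p)


def _realize_motif(rng: np.random.Generator, pattern: str) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in normalize_seq(pattern))


def simulate_sequences(
    config: SimConfig, event_roles: Mapping[str, str]
) -> SeqSim:
    """Flank sequences (upstream intron / exon / downstream intron) per event.

    ``event_roles`` maps event id -> "included" or "excluded". Background is
    i.i.d. at ``background_gc``. For excluded events, one concrete realization
    of the upstream (and downstream) motif is planted per flank with
    probability ``motif_plant_rate``; the exonic motif is planted in included
    exons at the same rate. The GC of the 3'SS-upstream window of included
    events is offset by ``gc_offset``. Planted positions are recorded.
    """
    for spec in (config.motif_upstream, config.motif_downstream, config.motif_exon):
        MotifSpec(spec)  # validates IUPAC letters
    rng = np.random.default_rng(config.seed + 3)
    rows, planted = [], []
    for event_id, role in event_roles.items():
        if role not in ("included", "excluded"):
            raise ValueError(f"role must be included/excluded, got {role!r}")
        up = _random_seq(rng, config.flank_len, config.background_gc)
        if role == "included" and config.gc_offset != 0:
            w = min(config.gc_window, config.flank_len)
            gc = float(np.clip(config.background_gc + config.gc_offset, 0, 1))
            up[-w:] = _random_seq(rng, w, gc)
        ex = _random_seq(rng, config.exon_len, config.background_gc)
        dn = _random_seq(rng, config.flank_len, config.background_gc)

        plant_specs = (
            [("upstream_intron", config.motif_upstream, up),
             ("downstream_intron", config.motif_downstream, dn)]
            if role == "excluded"
            else [("exon", config.motif_exon, ex)]
        )
        for region, pattern, arr in plant_specs:
            if rng.random() < config.motif_plant_rate:
                real = _realize_motif(rng, pattern)
                pos = int(rng.integers(0, len(arr) - len(real) + 1))
                arr[pos : pos + len(real)] = list(real)
                planted.append((event_id, region, pattern, pos))

        rows.append((event_id, "upstream_intron", role, "".join(up)))
        rows.append((event_id, "exon", role, "".join(ex)))
        rows.append((event_id, "downstream_intron", role, "".join(dn)))

    return SeqSim(
        records=pd.DataFrame(rows, columns=["event_id", "region", "role", "sequence"]),
        planted=pd.DataFrame(planted, columns=["event_id", "region", "motif", "position"]),
    )


def roles_from_truth(truth: SimTruth, included_role: str = "group1") -> dict[str, str]:
    """Map informative events to included/excluded sequence roles."""
    out = {}
    for ev, role in zip(truth.event_ids, truth.event_role):
        if role == "noise":
            continue
        out[ev] = "included" if role == included_role else "excluded"
    return out
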