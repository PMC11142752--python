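import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import spearmanr

from splicescape.psi import build_psi_matrix
from splicescape.seqfeat import iupac_match, motif_enrichment
from splicescape.synthetic import (
    SimConfig,
    simulate_bulk,
    simulate_rbp,
    simulate_sc,
    simulate_sequences,
    true_as_score,
)


class TestSimConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_informative=10, n_events=5)
        with pytest.raises(ValueError):
            SimConfig(psi_concentration=0.0)
        with pytest.raises(ValueError):
            SimConfig(latent_modes=(0.5, 0.5))
        with pytest.raises(ValueError):
            SimConfig(rbp_rho=1.0)
        with pytest.raises(ValueError):
            SimConfig(censor_rate=1.5)


class TestSimulateBulk:
    def test_same_seed_identical(self):
        cfg = SimConfig(n_samples=20, n_events=30, n_informative=10, seed=3)
        s1 = simulate_bulk(cfg)
        s2 = simulate_bulk(cfg)
        pd.testing.assert_frame_equal(s1.counts, s2.counts)
        pd.testing.assert_frame_equal(s1.samples, s2.samples)
        np.testing.assert_array_equal(s1.truth.true_psi, s2.truth.true_psi)

    def test_zero_effect_limit(self):
        cfg = SimConfig(n_samples=200, n_events=20, n_informative=0,
                        coupling_strength=0.0, psi_concentration=1e6,
                        reads_per_event=5000.0, seed=4)
        sim = simulate_bulk(cfg)
        m = build_psi_matrix(sim.counts, sim.events)
        expected = expit(sim.truth.event_a)
        col_means = np.nanmean(m.psi, axis=1)
        col_sds = np.nanstd(m.psi, axis=1)
        np.testing.assert_allclose(col_means, expected, atol=0.02)
        assert col_sds.max() < 0.02

    def test_mean_psi_matches_closed_form_at_mode(self):
        # samples pinned at the upper mixture mode m2: E[psi] = logistic(a + b*m2)
        m2 = 0.75
        cfg = SimConfig(n_samples=10_000, n_events=4, n_informative=4,
                        frac_group1=1.0, latent_modes=(m2, 0.7499999),
                        latent_concentration=1e9, psi_concentration=50.0,
                        reads_per_event=50.0, seed=5)
        sim = simulate_bulk(cfg)
        expected = expit(sim.truth.event_a + sim.truth.event_b * m2)
        mc_mean = sim.truth.true_psi.mean(axis=1)  # 10,000 replicate draws
        np.testing.assert_allclose(mc_mean, expected, atol=0.01)

    def test_truth_invariants(self, small_bulk):
        t = small_bulk.truth
        assert ((t.true_psi >= 0) & (t.true_psi <= 1)).all()
        assert (t.event_b[t.event_role == "group1"] > 0).all()
        assert (t.event_b[t.event_role == "group2"] < 0).all()
        assert (t.event_b[t.event_role == "noise"] == 0).all()
        assert set(t.cluster_label) == {1, 2}

    def test_as_true_tracks_latent_score(self):
        cfg = SimConfig(n_samples=150, n_events=60, n_informative=40,
                        psi_concentration=200.0, coupling_strength=3.0, seed=6)
        sim = simulate_bulk(cfg)
        rho = spearmanr(sim.truth.as_true, sim.truth.latent_score)[0]
        assert rho >= 0.99

    def test_censor_rate_approximate(self):
        cfg = SimConfig(n_samples=400, n_events=10, n_informative=0,
                        censor_rate=0.3, seed=7)
        sim = simulate_bulk(cfg)
        frac = 1.0 - sim.samples["status"].mean()
        assert frac == pytest.approx(0.3, abs=0.08)

    def test_shared_events_across_cohorts(self):
        cfg1 = SimConfig(n_samples=30, n_events=40, n_informative=10, seed=8)
        sim1 = simulate_bulk(cfg1)
        cfg2 = SimConfig(n_samples=30, n_events=40, n_informative=10, seed=9)
        sim2 = simulate_bulk(cfg2, share_events_from=sim1.truth)
        np.testing.assert_array_equal(sim1.truth.event_a, sim2.truth.event_a)
        assert not np.array_equal(sim1.truth.latent_score, sim2.truth.latent_score)


class TestSimulateSc:
    def _cfg(self, **kw):
        base = dict(n_samples=10, n_events=30, n_informative=20,
                    sc_n_patients=2, sc_states=("A", "B"),
                    sc_cells_per_state=50, sc_reads_per_cell_event=2.0, seed=10)
        base.update(kw)
        return SimConfig(**base)

    def test_zero_coverage_degenerate(self):
        cfg = self._cfg(sc_reads_per_cell_event=0.0)
        sim = simulate_bulk(cfg)
        sc = simulate_sc(cfg, sim.truth)
        assert sc.counts.empty
        assert len(sc.cells) == 2 * 2 * 50

    def test_poisson_sum_totals(self):
        lam, n_cells = 2.0, 100
        cfg = self._cfg(sc_n_patients=1, sc_states=("A",),
                        sc_cells_per_state=n_cells, sc_reads_per_cell_event=lam)
        sim = simulate_bulk(cfg)
        sc = simulate_sc(cfg, sim.truth)
        totals = (
            sc.counts.assign(total=sc.counts["inc_count"] + sc.counts["skip_count"])
            .groupby("event_id")["total"].sum()
        )
        expected = lam * n_cells
        sd = math.sqrt(expected)
        assert ((totals - expected).abs() <= 3 * sd).mean() >= 0.95

    def test_extreme_states_separate_in_pseudobulk(self):
        from splicescape.pseudobulk import aggregate

        cfg = self._cfg(sc_n_patients=1, sc_states=("lo", "hi"),
                        sc_state_scores=(0.0, 1.0), coupling_strength=9.0,
                        sc_reads_per_cell_event=10.0, sc_patient_jitter=0.0,
                        sc_cells_per_state=80)
        sim = simulate_bulk(cfg)
        sc = simulate_sc(cfg, sim.truth)
        agg, _ = aggregate(sc.counts, sc.cells)
        m = build_psi_matrix(agg, sim.events)
        g1 = [i for i, r in enumerate(sim.truth.event_role) if r == "group1"]
        hi = m.sample_ids.index("P00|hi")
        lo = m.sample_ids.index("P00|lo")
        sep = np.nanmean(m.psi[g1, hi] - m.psi[g1, lo])
        assert sep > 0.6

    def test_zero_states_rejected(self):
        cfg = self._cfg()
        sim = simulate_bulk(cfg)
        bad = SimConfig(n_samples=10, n_events=30, n_informative=20,
                        sc_n_patients=0, seed=1)
        with pytest.raises(ValueError):
            simulate_sc(bad, sim.truth)

    def test_deterministic(self):
        cfg = self._cfg()
        sim = simulate_bulk(cfg)
        sc1 = simulate_sc(cfg, sim.truth)
        sc2 = simulate_sc(cfg, sim.truth)
        pd.testing.assert_frame_equal(sc1.counts, sc2.counts)


class TestSimulateRbp:
    def test_null_rho_indistinguishable(self):
        cfg = SimConfig(n_samples=200, n_events=10, n_informative=4,
                        n_rbp_total=60, n_rbp_coupled=20, rbp_rho=0.0, seed=12)
        sim = simulate_bulk(cfg)
        expr = simulate_rbp(cfg, sim.truth)
        from scipy.stats import spearmanr as sp

        rhos = np.array([
            sp(expr.loc[r], sim.truth.latent_score)[0] for r in expr.index
        ])
        coupled = rhos[:20]
        # null band: +-2.58/sqrt(n) covers ~99%; require 95% inside
        band = 2.58 / math.sqrt(200)
        assert (np.abs(coupled) < band).mean() >= 0.95

    def test_target_rho_calibration(self):
        cfg = SimConfig(n_samples=500, n_events=10, n_informative=4,
                        n_rbp_total=40, n_rbp_coupled=29, rbp_rho=0.8, seed=13)
        sim = simulate_bulk(cfg)
        expr = simulate_rbp(cfg, sim.truth)
        from scipy.stats import spearmanr as sp

        ok = 0
        for rbp, sign in sim.truth.coupled_rbp.items():
            rho = sp(expr.loc[rbp], sim.truth.latent_score)[0]
            ok += abs(rho - sign * 0.8) <= 0.07
        assert ok / len(sim.truth.coupled_rbp) >= 0.95

    def test_sign_bookkeeping(self):
        cfg = SimConfig(n_samples=50, n_events=10, n_informative=4,
                        n_rbp_total=40, n_rbp_coupled=29, seed=14)
        sim = simulate_bulk(cfg)
        simulate_rbp(cfg, sim.truth)
        signs = list(sim.truth.coupled_rbp.values())
        assert sum(s == 1 for s in signs) == math.ceil(29 / 2)
        assert len(signs) == 29


class TestSimulateSequences:
    def _roles(self, n_inc=50, n_exc=50):
        roles = {f"I{i}": "included" for i in range(n_inc)}
        roles.update({f"X{i}": "excluded" for i in range(n_exc)})
        return roles

    def test_plant_rate_zero_null(self):
        cfg = SimConfig(n_events=10, n_informative=4, motif_plant_rate=0.0,
                        gc_offset=0.0, seed=15)
        seqs = simulate_sequences(cfg, self._roles(500, 500))
        up = seqs.records[seqs.records["region"] == "upstream_intron"]
        inc = list(up.loc[up["role"] == "included", "sequence"])
        exc = list(up.loc[up["role"] == "excluded", "sequence"])
        res = motif_enrichment(exc, inc, cfg.motif_upstream)
        assert res["p_value"] > 0.01
        assert seqs.planted.empty

    def test_plant_rate_one_all_match(self):
        cfg = SimConfig(n_events=10, n_informative=4, motif_plant_rate=1.0, seed=16)
        seqs = simulate_sequences(cfg, self._roles(5, 60))
        up = seqs.records[
            (seqs.records["region"] == "upstream_intron")
            & (seqs.records["role"] == "excluded")
        ]
        assert all(iupac_match(cfg.motif_upstream, s) for s in up["sequence"])

    def test_planted_positions_recorded(self):
        cfg = SimConfig(n_events=10, n_informative=4, motif_plant_rate=1.0, seed=17)
        seqs = simulate_sequences(cfg, {"X0": "excluded"})
        planted = seqs.planted
        up = planted[planted["region"] == "upstream_intron"].iloc[0]
        seq = seqs.records.loc[
            (seqs.records["event_id"] == "X0")
            & (seqs.records["region"] == "upstream_intron"), "sequence"
        ].iloc[0]
        window = seq[up["position"]: up["position"] + len(up["motif"])]
        assert iupac_match(up["motif"], window)

    def test_invalid_role_rejected(self):
        cfg = SimConfig(seed=18)
        with pytest.raises(ValueError, match="role"):
            simulate_sequences(cfg, {"E1": "banana"})

    def test_deterministic(self):
        cfg = SimConfig(n_events=10, n_informative=4, seed=19)
        s1 = simulate_sequences(cfg, self._roles(10, 10))
        s2 = simulate_sequences(cfg, self._roles(10, 10))
        pd.testing.assert_frame_equal(s1.records, s2.records)


def test_true_as_score_definition():
    psi = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.5, 0.5]])
    roles = np.array(["group1", "group1", "group2", "noise"], dtype=object)
    out = true_as_score(psi, roles)
    np.testing.assert_allclose(out, [0.85 - 0.1, 0.15 - 0.9])
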