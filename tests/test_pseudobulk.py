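import numpy as np
import pandas as pd
import pytest

from splicescape.pseudobulk import (
    aggregate,
    filter_pseudobulks,
    hcluster_cluster3,
    uncentered_correlation,
)
from splicescape.psi import build_psi_matrix, psi_point_estimate
from splicescape.types import PsiMatrix, SpliceEvent


def _cells(n, patient="P1", state="A"):
    return pd.DataFrame({
        "cell_id": [f"{patient}_{state}_{i}" for i in range(n)],
        "patient": patient,
        "state": state,
    })


class TestAggregate:
    def test_summation(self):
        ann = _cells(3)
        counts = pd.DataFrame({
            "event_id": ["E1"] * 3,
            "cell_id": ann["cell_id"],
            "inc_count": [1, 2, 0],
            "skip_count": [0, 1, 3],
        })
        agg, n_cells = aggregate(counts, ann)
        assert agg.loc[0, "inc_count"] == 3
        assert agg.loc[0, "skip_count"] == 4
        assert n_cells["P1|A"] == 3

    def test_single_cell_identity(self):
        ann = _cells(1)
        counts = pd.DataFrame({
            "event_id": ["E1"], "cell_id": ann["cell_id"],
            "inc_count": [7], "skip_count": [3],
        })
        agg, _ = aggregate(counts, ann)
        ev = SpliceEvent("E1", "G", "SE", inc_eff_len=1.0, skip_eff_len=1.0)
        m = build_psi_matrix(agg, [ev], min_reads=1)
        assert m.psi[0, 0] == pytest.approx(0.7)

    def test_unannotated_cell_raises(self):
        counts = pd.DataFrame({
            "event_id": ["E1"], "cell_id": ["ghost"],
            "inc_count": [1], "skip_count": [1],
        })
        with pytest.raises(ValueError, match="unannotated"):
            aggregate(counts, _cells(2))

    def test_pseudobulk_psi_equals_summed_counts(self):
        rng = np.random.default_rng(0)
        ann = _cells(20)
        frames = []
        for c in ann["cell_id"]:
            frames.append(pd.DataFrame({
                "event_id": [f"E{k}" for k in range(5)],
                "cell_id": c,
                "inc_count": rng.poisson(2, 5),
                "skip_count": rng.poisson(2, 5),
            }))
        counts = pd.concat(frames, ignore_index=True)
        agg, _ = aggregate(counts, ann)
        events = [SpliceEvent(f"E{k}", "G", "SE") for k in range(5)]
        m = build_psi_matrix(agg, events, min_reads=1)
        # oracle: PSI of summed counts, summed independently
        sums = counts.groupby("event_id")[["inc_count", "skip_count"]].sum()
        for k, ev in enumerate(m.event_ids):
            I, S = sums.loc[ev]
            assert m.psi[k, 0] == pytest.approx(
                psi_point_estimate(I, S, 2.0, 1.0)
            )


class TestFilterPseudobulks:
    def _matrix(self, det):
        det = np.asarray(det, dtype=bool)
        psi = np.where(det, 0.5, np.nan)
        return PsiMatrix(
            [f"E{i}" for i in range(det.shape[0])],
            [f"PB{j}" for j in range(det.shape[1])],
            psi, psi.copy(), det,
        )

    def test_threshold_49_of_200(self):
        det = np.zeros((200, 2), dtype=bool)
        det[:49, 0] = True
        det[:50, 1] = True
        m = self._matrix(det)
        kept_pbs, _ = filter_pseudobulks(m, list(m.event_ids),
                                         min_events=50, min_pseudobulks=1)
        assert kept_pbs == ["PB1"]

    def test_nothing_dropped_when_fully_detected(self):
        det = np.ones((10, 4), dtype=bool)
        m = self._matrix(det)
        kept_pbs, kept_events = filter_pseudobulks(m, list(m.event_ids),
                                                   min_events=5, min_pseudobulks=2)
        assert kept_pbs == m.sample_ids and kept_events == m.event_ids

    def test_matches_brute_force_on_fixture(self):
        rng = np.random.default_rng(1)
        det = rng.random((40, 30)) < 0.5
        m = self._matrix(det)
        min_events, min_pbs = 18, 12
        kept_pbs, kept_events = filter_pseudobulks(
            m, list(m.event_ids), min_events=min_events, min_pseudobulks=min_pbs
        )
        # brute force
        pbs = [j for j in range(30) if det[:, j].sum() >= min_events]
        evs = [i for i in range(40) if det[np.ix_([i], pbs)].sum() >= min_pbs]
        assert kept_pbs == [f"PB{j}" for j in pbs]
        assert kept_events == [f"E{i}" for i in evs]

    def test_fractional_min_pseudobulks(self):
        det = np.ones((10, 10), dtype=bool)
        det[0, :4] = False  # E0 detected in 6/10
        m = self._matrix(det)
        _, kept_events = filter_pseudobulks(m, list(m.event_ids),
                                            min_events=1, min_pseudobulks=0.7)
        assert "E0" not in kept_events and "E1" in kept_events


class TestUncenteredCorrelation:
    def test_positive_scaling_gives_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert uncentered_correlation(x, 2 * x) == pytest.approx(1.0)

    def test_orthogonal_gives_zero(self):
        x = np.array([1.0, 0.0, -1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        assert uncentered_correlation(x, y) == pytest.approx(0.0)

    def test_pairwise_complete(self):
        x = np.array([1.0, np.nan, 3.0])
        y = np.array([2.0, 5.0, 6.0])
        expected = (1 * 2 + 3 * 6) / np.sqrt((1 + 9) * (4 + 36))
        assert uncentered_correlation(x, y) == pytest.approx(expected)


def naive_centroid_oracle(X):
    """Independent O(n^3) centroid linkage; recomputes everything each step.

    Clusters are member-index lists; the centroid is the element-wise
    available mean of member rows; distance is 1 - uncentered correlation.
    Same node-id scheme as the implementation (new node = n + step).
    """
    n = X.shape[0]
    members = {i: [i] for i in range(n)}
    merges = []
    step = 0
    while len(members) > 1:
        ids = sorted(members)
        best, best_d = None, np.inf
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                ca = np.nanmean(X[members[a]], axis=0)
                cb = np.nanmean(X[members[b]], axis=0)
                ok = np.isfinite(ca) & np.isfinite(cb)
                num = (ca[ok] * cb[ok]).sum()
                den = np.sqrt((ca[ok] ** 2).sum() * (cb[ok] ** 2).sum())
                d = np.inf if den == 0 else 1 - num / den
                if d < best_d - 1e-15 or (
                    abs(d - best_d) <= 1e-15 and (best is None or (a, b) < best)
                ):
                    best_d, best = d, (a, b)
        a, b = best
        new = n + step
        members[new] = members.pop(a) + members.pop(b)
        merges.append((a, b, best_d))
        step += 1
    return merges


class TestHclusterCluster3:
    def test_matches_naive_oracle_random(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X = rng.random((10, 10)) + 0.1
            res = hcluster_cluster3(pd.DataFrame(X))
            oracle = naive_centroid_oracle(X)
            assert len(res.merges) == len(oracle)
            for (i1, j1, d1, _), (i2, j2, d2) in zip(res.merges, oracle):
                assert (i1, j1) == (i2, j2)
                assert d1 == pytest.approx(d2, abs=1e-9)

    def test_all_zero_row_dropped(self):
        X = pd.DataFrame([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0], [2.0, 4.0, 6.5]],
                         index=["z", "a", "b"])
        res = hcluster_cluster3(X)
        assert res.dropped == ["z"]
        assert set(res.leaf_order) == {"a", "b"}

    def test_newick_contains_all_leaves(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.random((5, 6)) + 0.1,
                         index=[f"pb{i}" for i in range(5)])
        res = hcluster_cluster3(X)
        assert res.newick.endswith(";")
        for name in X.index:
            assert name in res.newick

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.random((8, 5)) + 0.1)
        r1 = hcluster_cluster3(X)
        r2 = hcluster_cluster3(X)
        assert r1.merges == r2.merges and r1.newick == r2.newick

    def test_detection_monotone_in_cells(self):
        from splicescape.synthetic import SimConfig, simulate_bulk, simulate_sc

        cfg = SimConfig(n_samples=10, n_events=60, n_informative=20,
                        sc_n_patients=1, sc_states=("A",),
                        sc_cells_per_state=40, sc_reads_per_cell_event=1.0, seed=6)
        sim = simulate_bulk(cfg)
        sc = simulate_sc(cfg, sim.truth)
        events = sim.events
        detections = []
        for n_cells in (5, 10, 20, 40):
            cells = sc.cells.iloc[:n_cells]
            sub = sc.counts[sc.counts["cell_id"].isin(cells["cell_id"])]
            agg, _ = aggregate(sub, cells)
            m = build_psi_matrix(agg, events)
            detections.append(int(m.detected.sum()))
        assert detections == sorted(detections)
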