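"""LEiDA core: phases, phase-locking, eigenvectors, clustering, state metrics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from leidakit.containers import RoiTimeseries
from leidakit.leida import (
    LeadingEigSeries,
    cluster_states,
    dunn_index,
    eigenvector_series,
    hilbert_phase,
    leading_eigenvector,
    phase_locking,
    pool_eigenvectors,
    select_k,
    state_metrics,
)


def _cosine_run(freqs, tr=1.0, t=200, phases=None):
    ts = np.arange(t) * tr
    phases = phases or [0.0] * len(freqs)
    data = np.array([np.cos(2 * np.pi * f * ts + p) for f, p in zip(freqs, phases)])
    return RoiTimeseries(data, tr=tr, subject="s1", session="v1", modality="m")


class TestHilbertPhase:
    def test_phase_ramp_of_pure_cosine(self):
        f, tr, t = 0.04, 1.0, 400
        run = _cosine_run([f], tr=tr, t=t)
        theta = np.unwrap(hilbert_phase(run).theta[0])
        inc = np.diff(theta)
        interior = inc[int(0.1 * t) : int(0.9 * t)]
        assert np.max(np.abs(interior - 2 * np.pi * f * tr)) < 0.05

    def test_amplitude_scales_phase_does_not(self):
        run = _cosine_run([0.03, 0.03])
        run.data[1] *= 3.0
        ps = hilbert_phase(run)
        np.testing.assert_allclose(ps.theta[0], ps.theta[1], atol=1e-10)
        np.testing.assert_allclose(3.0 * ps.amplitude[0], ps.amplitude[1], atol=1e-8)

    def test_half_period_delay_gives_pi_difference(self):
        f = 0.025  # period 40 samples
        run = _cosine_run([f, f], phases=[0.0, np.pi])
        ps = hilbert_phase(run)
        diff = np.angle(np.exp(1j * (ps.theta[0] - ps.theta[1])))
        interior = diff[40:160]
        assert np.max(np.abs(np.abs(interior) - np.pi)) < 0.1

    def test_constant_roi_rejected(self):
        data = np.vstack([np.cos(np.linspace(0, 6, 50)), np.ones(50)])
        with pytest.raises(ValueError, match="constant"):
            hilbert_phase(RoiTimeseries(data, tr=1.0))

    def test_short_run_rejected(self):
        with pytest.raises(ValueError, match="8 volumes"):
            hilbert_phase(RoiTimeseries(np.random.default_rng(0).normal(size=(2, 5)), tr=1.0))


class TestPhaseLocking:
    def test_full_synchrony_is_one(self):
        dpl = phase_locking(np.full(5, 1.3))
        np.testing.assert_allclose(dpl, 1.0)

    def test_antiphase_is_minus_one(self):
        dpl = phase_locking(np.array([0.0, np.pi]))
        assert dpl[0, 1] == pytest.approx(-1.0)

    def test_quarter_cycle_is_zero(self):
        dpl = phase_locking(np.array([0.0, np.pi / 2]))
        assert dpl[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_symmetric_unit_diagonal(self, rng):
        dpl = phase_locking(rng.uniform(-np.pi, np.pi, size=8))
        np.testing.assert_array_equal(dpl, dpl.T)
        np.testing.assert_allclose(np.diag(dpl), 1.0)
        assert np.all(np.abs(dpl) <= 1.0)


class TestLeadingEigenvector:
    def test_all_ones_matrix(self):
        v, lam = leading_eigenvector(np.ones((4, 4)), return_eigenvalue=True)
        assert lam == pytest.approx(4.0)
        np.testing.assert_allclose(v, -0.5 * np.ones(4), atol=1e-12)

    def test_two_community_structure(self):
        # ideal two-community matrix, sizes 2 and 4: minority community positive
        s = np.array([1.0, 1.0, -1.0, -1.0, -1.0, -1.0])
        dpl = np.outer(s, s)
        v = leading_eigenvector(dpl)
        np.testing.assert_allclose(v[:2], 1 / np.sqrt(6), atol=1e-12)
        np.testing.assert_allclose(v[2:], -1 / np.sqrt(6), atol=1e-12)

    def test_eigenpair_identity(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=12)
        dpl = phase_locking(theta)
        v, lam = leading_eigenvector(dpl, return_eigenvalue=True)
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(dpl @ v, lam * v, atol=1e-8)

    def test_sign_convention_majority_nonpositive(self, rng):
        for _ in range(20):
            v = leading_eigenvector(phase_locking(rng.uniform(-np.pi, np.pi, 11)))
            assert (v > 0).sum() <= 11 / 2


class TestPooling:
    @staticmethod
    def _series(n, modality="m", subject="s1"):
        vecs = np.random.default_rng(len(modality) + n).normal(size=(n, 6))
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        idx = pd.DataFrame(
            {"subject": subject, "session": "v1", "modality": modality, "volume": range(n)}
        )
        return LeadingEigSeries(vecs, idx)

    def test_row_counts_concatenate(self):
        pooled = pool_eigenvectors([self._series(10), self._series(12, subject="s2")])
        assert len(pooled) == 22

    def test_index_round_trip(self):
        a, b = self._series(5), self._series(7, subject="s2")
        pooled = pool_eigenvectors([a, b])
        mask = (pooled.index["subject"] == "s2").to_numpy()
        np.testing.assert_array_equal(pooled.vectors[mask], b.vectors)

    def test_mixed_modalities_rejected(self):
        with pytest.raises(ValueError, match="modalities"):
            pool_eigenvectors([self._series(5, "a"), self._series(5, "bb")])

    def test_mixed_roi_counts_rejected(self):
        a = self._series(5)
        bad = LeadingEigSeries(np.ones((3, 4)), a.index.iloc[:3])
        with pytest.raises(ValueError, match="same number"):
            pool_eigenvectors([a, bad])


def _clouds(rng, centers, n_per=40, scale=0.05):
    pts = np.vstack([c + scale * rng.normal(size=(n_per, len(c))) for c in centers])
    labels = np.repeat(np.arange(1, len(centers) + 1), n_per)
    idx = pd.DataFrame(
        {"subject": "s1", "session": "v1", "modality": "m", "volume": range(len(pts))}
    )
    return LeadingEigSeries(pts, idx), labels


class TestClustering:
    def test_separable_clouds_recovered(self, rng):
        eigs, truth = _clouds(rng, [(0, 0), (5, 0), (0, 5)])
        sols = cluster_states(eigs, k_range=[3], replicates=10, seed=0)
        assert adjusted_rand_score(truth, sols[3].labels) == 1.0

    def test_replicate_count_irrelevant_for_unique_optimum(self, rng):
        eigs, _ = _clouds(rng, [(0, 0), (5, 0), (0, 5)])
        a = cluster_states(eigs, k_range=[3], replicates=1, seed=1)[3]
        b = cluster_states(eigs, k_range=[3], replicates=50, seed=2)[3]
        order = np.argsort(a.centroids[:, 0] + 100 * a.centroids[:, 1])
        order_b = np.argsort(b.centroids[:, 0] + 100 * b.centroids[:, 1])
        np.testing.assert_allclose(a.centroids[order], b.centroids[order_b], atol=1e-8)

    def test_duplicating_rows_keeps_centroids(self, rng):
        eigs, _ = _clouds(rng, [(0, 0), (5, 0)])
        doubled = LeadingEigSeries(
            np.vstack([eigs.vectors, eigs.vectors]),
            pd.concat([eigs.index, eigs.index], ignore_index=True),
        )
        a = cluster_states(eigs, k_range=[2], replicates=10, seed=0)[2]
        b = cluster_states(doubled, k_range=[2], replicates=10, seed=0)[2]
        oa = np.argsort(a.centroids[:, 0])
        ob = np.argsort(b.centroids[:, 0])
        np.testing.assert_allclose(a.centroids[oa], b.centroids[ob], atol=1e-8)


class TestDunnIndex:
    def test_hand_computed_two_clusters(self):
        x = np.array([[0.0], [0.1], [10.0], [10.1]])
        labels = np.array([1, 1, 2, 2])
        assert dunn_index(x, labels) == pytest.approx(9.9 / 0.1)

    def test_random_split_of_one_cloud_is_poor(self, rng):
        x = rng.normal(size=(60, 3))
        labels = rng.integers(1, 3, size=60)
        assert dunn_index(x, labels) <= 1.0

    @pytest.mark.parametrize("scale", [0.5, 3.0, 100.0])
    def test_scale_invariance(self, rng, scale):
        x = rng.normal(size=(40, 4))
        labels = np.repeat([1, 2], 20)
        assert dunn_index(scale * x, labels) == pytest.approx(dunn_index(x, labels))

    def test_singletons_give_infinity(self):
        x = np.array([[0.0], [1.0]])
        assert dunn_index(x, np.array([1, 2])) == np.inf

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            dunn_index(np.zeros((4, 2)), np.ones(4, dtype=int))


class TestSelectK:
    @staticmethod
    def _fake(k, dunn):
        from leidakit.leida import StateSolution

        idx = pd.DataFrame({"subject": [], "session": [], "modality": [], "volume": []})
        return StateSolution(
            k=k, centroids=np.zeros((k, 2)), labels=np.ones(1, dtype=int),
            index=idx, inertia=0.0, dunn=dunn,
        )

    def test_argmax_selected(self):
        best = select_k({5: self._fake(5, 0.8), 6: self._fake(6, 0.3)})
        assert best.k == 5

    def test_tie_goes_to_smaller_k(self):
        best = select_k({6: self._fake(6, 0.5), 5: self._fake(5, 0.5)})
        assert best.k == 5


class TestStateMetrics:
    def test_hand_counted_example(self):
        m = state_metrics(np.array([1, 1, 2, 2, 2]), n_states=2, tr=2.0)
        np.testing.assert_allclose(m.occurrence, [0.4, 0.6])
        np.testing.assert_allclose(m.lifetime_tp, [2.0, 3.0])
        np.testing.assert_allclose(m.lifetime_s, [4.0, 6.0])
        np.testing.assert_allclose(m.switching[0], [0.5, 0.5])
        np.testing.assert_allclose(m.switching[1], [0.0, 1.0])

    def test_constant_labels(self):
        m = state_metrics(np.array([1, 1, 1, 1]), n_states=2, tr=1.0)
        np.testing.assert_allclose(m.occurrence, [1.0, 0.0])
        assert m.lifetime_tp[0] == 4.0
        assert np.isnan(m.lifetime_tp[1])
        np.testing.assert_allclose(m.switching[0], [1.0, 0.0])
        assert np.all(np.isnan(m.switching[1]))

    def test_long_chain_recovers_transition_rates(self):
        p = np.array([[0.8, 0.2], [0.4, 0.6]])
        rng = np.random.default_rng(0)
        cdf = np.cumsum(p, axis=1)
        labels = np.empty(20000, dtype=int)
        labels[0] = 0
        u = rng.random(labels.size - 1)
        for t in range(1, labels.size):
            labels[t] = np.searchsorted(cdf[labels[t - 1]], u[t - 1])
        m = state_metrics(labels + 1, n_states=2, tr=1.0)
        for a in range(2):
            n_a = (labels[:-1] == a).sum()
            for b in range(2):
                se = np.sqrt(p[a, b] * (1 - p[a, b]) / n_a)
                assert abs(m.switching[a, b] - p[a, b]) < 3 * se

    def test_occurrence_sums_to_one_switching_rows_too(self, rng):
        labels = rng.integers(1, 5, size=200)
        m = state_metrics(labels, n_states=4, tr=0.5)
        assert m.occurrence.sum() == pytest.approx(1.0, abs=1e-12)
        for row in m.switching:
            if not np.any(np.isnan(row)):
                assert row.sum() == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            state_metrics(np.array([1, 3]), n_states=2, tr=1.0)


class TestPipelineEquivariance:
    def test_roi_permutation_permutes_centroids(self, small_cohort):
        key = next(iter(small_cohort.timeseries))
        ts = small_cohort.timeseries[key]
        perm = np.random.default_rng(4).permutation(ts.n_roi)
        es = eigenvector_series(ts)
        ts_perm = RoiTimeseries(
            ts.data[perm], tr=ts.tr, subject=ts.subject, session=ts.session,
            modality=ts.modality,
        )
        es_perm = eigenvector_series(ts_perm)
        np.testing.assert_allclose(es.vectors[:, perm], es_perm.vectors, atol=1e-8)

    def test_stored_vectors_obey_sign_convention(self, small_cohort):
        key = next(iter(small_cohort.timeseries))
        es = eigenvector_series(small_cohort.timeseries[key])
        n = es.n_roi
        assert np.all((es.vectors > 0).sum(axis=1) <= n / 2)
        np.testing.assert_allclose(np.linalg.norm(es.vectors, axis=1), 1.0, atol=1e-10)
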