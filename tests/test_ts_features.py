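"""Fuzzy recurrence plots, their axioms and the two entropies."""

import numpy as np
import pytest

from tfts_lstm import (
    FRPMatrix,
    SignalSeries,
    build_frp,
    embed_phase_space,
    fre,
    frie,
    fuzzy_c_means,
    ts_sequence,
)
from tfts_lstm.ts_features import (
    FuzzyPartition,
    frp_of_segment,
    segment_bounds,
    transitive_closure,
)


class TestEmbedding:
    @pytest.mark.parametrize(
        "series, m, tau, expected",
        [
            ([5, 6, 7], 1, 1, [[5], [6], [7]]),
            ([1, 2, 3, 4], 2, 1, [[1, 2], [2, 3], [3, 4]]),
            ([1, 2, 3, 4, 5], 2, 2, [[1, 3], [2, 4], [3, 5]]),
        ],
    )
    def test_delay_coordinates(self, series, m, tau, expected):
        ps = embed_phase_space(np.array(series, dtype=float), m=m, tau=tau)
        np.testing.assert_array_equal(ps.X, expected)

    def test_point_count_formula(self, rng):
        ps = embed_phase_space(rng.normal(size=100), m=3, tau=2)
        assert ps.n_points == 96

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            embed_phase_space(np.array([1.0, 2.0]), m=4, tau=1)


class TestFuzzyCMeans:
    def test_separated_clusters_recovered(self):
        x = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])
        part = fuzzy_c_means(embed_phase_space(x), c=2)
        np.testing.assert_allclose(sorted(part.centroids.ravel()), [0, 10], atol=1e-3)
        low = part.U[:3, part.centroids.ravel().argmin()]
        assert np.all(low >= 0.99)

    def test_membership_rows_sum_to_one(self, rng):
        part = fuzzy_c_means(embed_phase_space(rng.normal(size=60)), c=3)
        np.testing.assert_allclose(part.U.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((part.U >= 0) & (part.U <= 1))

    def test_point_on_centroid_is_crisp(self):
        # after convergence on symmetric data the middle point sits on a centroid
        x = np.array([0.0, 0.0, 5.0, 10.0, 10.0])
        part = fuzzy_c_means(embed_phase_space(x), c=2)
        d = np.abs(part.centroids.ravel()[None, :] - x[:, None])
        on_centroid = np.isclose(d, 0).any(axis=1)
        for i in np.where(on_centroid)[0]:
            assert part.U[i].max() == pytest.approx(1.0)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fuzzy_c_means(embed_phase_space(np.array([1.0, 1.0, 2.0, 2.0])), c=3)


class TestBuildFRP:
    def test_crisp_two_cluster_blocks(self):
        ps = embed_phase_space(np.array([0.0, 0.0, 1.0, 1.0]))
        R = build_frp(fuzzy_c_means(ps, c=2)).R
        expected = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], dtype=float
        )
        np.testing.assert_allclose(R, expected, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, c = int(rng.integers(5, 50)), int(rng.integers(2, 5))
        U = rng.dirichlet(np.ones(c), size=n)
        R = build_frp(FuzzyPartition(centroids=np.zeros((c, 1)), U=U, fuzzifier=2, n_iter=1)).R
        for i in range(n):
            for j in range(n):
                expected = 1.0 if i == j else max(
                    min(U[i, q], U[j, q]) for q in range(c)
                )
                assert abs(R[i, j] - expected) <= 1e-12

    def test_cluster_order_invariance(self, rng):
        U = rng.dirichlet(np.ones(3), size=20)
        part = lambda u: FuzzyPartition(
            centroids=np.zeros((3, 1)), U=u, fuzzifier=2, n_iter=1
        )
        R1 = build_frp(part(U)).R
        R2 = build_frp(part(U[:, [2, 0, 1]])).R
        np.testing.assert_array_equal(R1, R2)

    def test_axioms_on_random_series(self, rng):
        for _ in range(10):
            series = SignalSeries(values=rng.normal(size=80), fs=300)
            R = build_frp(fuzzy_c_means(embed_phase_space(series), c=3)).R
            np.testing.assert_array_equal(np.diag(R), 1.0)
            assert np.abs(R - R.T).max() <= 1e-12
            assert R.min() >= 0 and R.max() <= 1

    def test_closure_dominates_single_composition(self, rng):
        R = build_frp(fuzzy_c_means(embed_phase_space(rng.normal(size=40)), c=3))
        C = transitive_closure(R).R
        assert np.all(C >= R.R - 1e-12)
        np.testing.assert_array_equal(np.diag(C), 1.0)
        assert np.abs(C - C.T).max() <= 1e-12


class TestEntropies:
    def test_all_ones_frp_has_zero_entropies(self):
        R = FRPMatrix(R=np.ones((6, 6)))
        assert frie(R) == 0.0
        assert fre(R) == 0.0

    def test_half_zero_half_one_is_one_bit(self):
        R = np.zeros((4, 4))
        R[:2, :] = 1.0
        assert frie(FRPMatrix(R=R)) == pytest.approx(1.0)

    def test_all_half_fre_is_n_squared(self):
        R = FRPMatrix(R=np.full((4, 4), 0.5))
        assert fre(R) == pytest.approx(16.0)

    def test_crisp_fre_is_zero(self, rng):
        R = FRPMatrix(R=(rng.uniform(size=(8, 8)) > 0.5).astype(float))
        assert fre(R) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_frie_matches_histogram_oracle(self, seed):
        rng = np.random.default_rng(seed)
        R = FRPMatrix(R=rng.uniform(size=(30, 30)))
        L = 256
        levels = [round(mu * (L - 1)) for mu in R.R.ravel()]
        counts = {}
        for l in levels:
            counts[l] = counts.get(l, 0) + 1
        expected = -sum(
            (c / len(levels)) * np.log2(c / len(levels)) for c in counts.values()
        )
        assert abs(frie(R, L=L) - expected) <= 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_fre_matches_elementwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        R = FRPMatrix(R=rng.uniform(size=(25, 25)))
        expected = 0.0
        for mu in R.R.ravel():
            if 0 < mu < 1:
                expected += -mu * np.log2(mu) - (1 - mu) * np.log2(1 - mu)
        assert abs(fre(R) - expected) <= 1e-10

    def test_ranges(self, rng):
        R = FRPMatrix(R=rng.uniform(size=(20, 20)))
        assert 0 <= frie(R) <= np.log2(256)
        assert 0 <= fre(R) <= 400


class TestTSSequence:
    def test_segment_bounds_partition(self):
        bounds = segment_bounds(100, 7)
        assert bounds[0][0] == 0 and bounds[-1][1] == 100
        lens = [b - a for a, b in bounds]
        assert max(lens) - min(lens) <= 1
        for (_, b1), (a2, _) in zip(bounds, bounds[1:]):
            assert b1 == a2

    def test_sequence_lengths_match_target(self, rng):
        series = SignalSeries(values=rng.normal(size=4096), fs=300)
        ts = ts_sequence(series, T=63)
        assert len(ts.frie) == len(ts.fre) == len(ts.segment_bounds) == 63

    def test_constant_series_fully_recurrent(self):
        series = SignalSeries(values=np.zeros(160), fs=300)
        ts = ts_sequence(series, T=10)
        np.testing.assert_array_equal(ts.frie, 0.0)
        np.testing.assert_array_equal(ts.fre, 0.0)

    def test_degenerate_segment_gives_all_ones_frp(self):
        R = frp_of_segment(np.full(20, 3.0))
        np.testing.assert_array_equal(R.R, 1.0)

    def test_regime_change_separates_fre(self, rng):
        # FCM memberships are scale-invariant, so the regimes must differ in
        # correlation structure, not just variance: a smooth oscillation
        # clusters tightly, white noise does not. Direction recorded from the
        # oracle run: the noisy half carries the higher fuzzy entropy.
        smooth = 0.5 * np.sin(2 * np.pi * np.arange(800) / 200)
        noise = rng.normal(0, 0.5, size=800)
        series = SignalSeries(values=np.concatenate([smooth, noise]), fs=300)
        ts = ts_sequence(series, T=20)
        assert ts.fre[10:].mean() > ts.fre[:10].mean() * 1.1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            ts_sequence(SignalSeries(values=np.zeros(70), fs=300), T=10)
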