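"""Covariance segmentation/cleaning, shrinkage, and the GED solver."""

import numpy as np
import pytest

from gednet.ged import (build_covariance_pair, clean_covariance_pool,
                        ged_decompose, project_components, segment_covariances,
                        segment_slices, shrink_regularize)


def random_spd(m, rng, scale=1.0):
    A = rng.standard_normal((m, 4 * m))
    return scale * A @ A.T / (4 * m)


class TestSegmentation:
    def test_even_odd_split_counts_for_280s(self):
        # 280 s of retained data in 2-s segments -> 70 per pool
        fs = 100.0
        n = int(280 * fs)
        slices = segment_slices(n, fs, 2.0)
        assert len(slices) == 140
        assert len(slices[1::2]) == 70 and len(slices[0::2]) == 70

    def test_build_pair_bookkeeping(self, rng):
        fs = 100.0
        X = rng.standard_normal((4, int(40 * fs)))
        pair = build_covariance_pair(X, X, fs)
        assert pair.n_segments_S == 10 and pair.n_segments_R == 10
        assert np.allclose(pair.S, pair.S.T)

    def test_too_few_segments_raises(self, rng):
        X = rng.standard_normal((3, 500))
        with pytest.raises(ValueError, match="segments"):
            build_covariance_pair(X, X, 100.0)

    def test_amplified_segment_excluded(self, rng):
        fs = 100.0
        X = rng.standard_normal((4, int(60 * fs)))
        X[:, 1200:1400] *= 100.0         # corrupt one 2-s segment (index 6)
        covs, _ = segment_covariances(X, segment_slices(X.shape[1], fs, 2.0))
        _, n_excl, keep = clean_covariance_pool(covs, 3.0)
        assert n_excl == 1
        assert not keep[6]

    def test_stationary_exclusion_fraction_is_small(self, rng):
        fs = 100.0
        X = rng.standard_normal((6, int(300 * fs)))
        pair = build_covariance_pair(X, X, fs)
        frac = pair.n_excluded / (pair.n_segments_S + pair.n_segments_R)
        assert frac <= 0.05

    def test_masked_samples_dropped_listwise(self, rng):
        fs = 100.0
        X = rng.standard_normal((3, 2000))
        valid = np.ones_like(X, dtype=bool)
        X[0, 100] = 1e6                  # huge outlier, masked out
        valid[0, 100] = False
        covs, kept = segment_covariances(X, segment_slices(2000, fs, 2.0), valid)
        assert covs.shape[0] == 10
        assert np.abs(covs).max() < 10.0

    def test_mostly_masked_segment_discarded(self, rng):
        fs = 100.0
        X = rng.standard_normal((2, 1000))
        valid = np.ones_like(X, dtype=bool)
        valid[0, 200:400] = False        # whole second segment invalid
        covs, kept = segment_covariances(X, segment_slices(1000, fs, 2.0), valid)
        assert covs.shape[0] == 4
        assert 1 not in kept


class TestShrinkage:
    def test_identity_is_fixed_point(self):
        assert np.allclose(shrink_regularize(np.eye(5), 0.3), np.eye(5))

    def test_worked_2x2_example(self):
        # alpha = 2.5; diag(4,1) -> diag(3.985, 1.015) at 1% shrinkage
        out = shrink_regularize(np.diag([4.0, 1.0]), 0.01)
        assert np.allclose(np.diag(out), [3.985, 1.015])

    def test_trace_preserved_exactly(self, rng):
        R = random_spd(7, rng)
        out = shrink_regularize(R, 0.01)
        assert np.trace(out) == pytest.approx(np.trace(R), abs=1e-12)

    def test_bad_gamma_raises(self):
        with pytest.raises(ValueError):
            shrink_regularize(np.eye(3), 1.0)
        with pytest.raises(ValueError):
            shrink_regularize(np.eye(3), -0.1)


class TestGedDecompose:
    def test_equal_matrices_give_unit_eigenvalues(self, rng):
        S = random_spd(10, rng)
        cs = ged_decompose(S, S)
        assert np.allclose(cs.lambdas, 1.0, atol=1e-8)

    def test_diagonal_case(self):
        cs = ged_decompose(np.diag([2.0, 1.0]), np.eye(2))
        assert np.allclose(cs.lambdas, [2.0, 1.0])
        assert np.allclose(np.abs(cs.W[:, 0]), [1.0, 0.0])

    def test_eigenvalues_equal_rayleigh_quotients(self, rng):
        S, R = random_spd(6, rng), random_spd(6, rng)
        cs = ged_decompose(S, R)
        for j in range(6):
            w = cs.W[:, j]
            assert cs.lambdas[j] == pytest.approx((w @ S @ w) / (w @ R @ w),
                                                  abs=1e-8)

    def test_eigenvalues_sorted_descending_and_R_orthogonal(self, rng):
        S, R = random_spd(6, rng), random_spd(6, rng)
        cs = ged_decompose(S, R)
        assert np.all(np.diff(cs.lambdas) <= 1e-12)
        G = cs.W.T @ R @ cs.W
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_scale_invariance_of_directions(self, rng):
        S, R = random_spd(5, rng), random_spd(5, rng)
        a = ged_decompose(S, R)
        b = ged_decompose(9.0 * S, 9.0 * R)
        assert np.allclose(a.lambdas, b.lambdas)
        assert np.allclose(np.abs(a.W), np.abs(b.W), atol=1e-8)

    def test_sign_convention(self, rng):
        S, R = random_spd(5, rng), random_spd(5, rng)
        W = ged_decompose(S, R).W
        idx = np.argmax(np.abs(W), axis=0)
        assert np.all(W[idx, np.arange(5)] > 0)

    def test_singular_R_raises_with_hint(self):
        S = np.eye(3)
        R = np.zeros((3, 3))
        with pytest.raises(Exception, match="shrink"):
            ged_decompose(S, R)


class TestProjection:
    def test_identity_projection(self, rng):
        X = rng.standard_normal((4, 100))
        maps, ts, _ = project_components(np.eye(4), np.eye(4), X)
        assert np.allclose(maps, np.eye(4))
        assert np.allclose(ts, X)

    def test_maps_are_S_times_w(self, rng):
        S = random_spd(5, rng)
        W = rng.standard_normal((5, 5))
        maps, _, _ = project_components(W, S, rng.standard_normal((5, 50)))
        assert np.allclose(maps, S @ W)

    def test_extreme_timeseries_values_masked(self, rng):
        X = rng.standard_normal((1, 5000))
        X[0, 42] = 50.0
        _, _, valid = project_components(np.eye(1), np.eye(1), X, z_outlier=4.0)
        assert not valid[0, 42]
        assert valid.mean() > 0.99

    def test_zero_weight_on_channel_ignores_it(self, rng):
        X = rng.standard_normal((3, 200))
        w = np.array([[1.0], [1.0], [0.0]])
        _, ts, _ = project_components(w, np.eye(3), X)
        X2 = X.copy()
        X2[2] = 99.0
        _, ts2, _ = project_components(w, np.eye(3), X2)
        assert np.allclose(ts, ts2)
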