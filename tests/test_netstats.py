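"""Derived network statistics: region bias, modality dominance, entropy,
kurtosis, wPLI, reproducibility, and the permutation dimensionality test."""

import numpy as np
import pytest

from gednet import netstats

REGIONS3 = np.array(["PFC"] * 4 + ["PAR"] * 4 + ["HIP"] * 4)


class TestRegionBias:
    def test_equal_regions_score_zero(self):
        w = np.ones(12)
        assert netstats.region_bias_score(w, REGIONS3) == pytest.approx(0.0)

    def test_single_region_scores_one(self):
        w = np.zeros(12)
        w[:4] = [1.0, -2.0, 0.5, 1.5]
        assert netstats.region_bias_score(w, REGIONS3) == pytest.approx(1.0)

    def test_worked_example_06_03_01(self):
        # per-region RMS profile (0.6, 0.3, 0.1): distance 0.3559 to the
        # shared profile, 0.4359 after max-distance normalization
        w = np.concatenate([np.full(4, 0.6), np.full(4, 0.3), np.full(4, 0.1)])
        assert netstats.region_bias_score(w, REGIONS3) == pytest.approx(
            0.3559 / 0.8165, abs=1e-3)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            netstats.region_bias_score(np.zeros(12), REGIONS3)

    def test_sign_invariance(self, rng):
        w = rng.standard_normal(12)
        a = netstats.region_bias_score(w, REGIONS3)
        b = netstats.region_bias_score(-w, REGIONS3)
        assert a == pytest.approx(b)


class TestRegionFractions:
    def test_uniform_magnitude_gives_thirds(self):
        f = netstats.region_energy_fractions(np.ones(12), REGIONS3)
        assert np.allclose(f, 1 / 3)

    def test_single_region_gives_unit_fraction(self):
        w = np.zeros(12)
        w[4:8] = 2.0
        f = netstats.region_energy_fractions(w, REGIONS3)
        assert np.allclose(f, [0.0, 1.0, 0.0])

    def test_fractions_sum_to_one(self, rng):
        f = netstats.region_energy_fractions(rng.standard_normal(12), REGIONS3)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)


class TestModalityDominance:
    MODS = np.array(["LFP"] * 6 + ["MU"] * 3)

    def test_pure_lfp_is_plus_one(self):
        w = np.concatenate([np.ones(6), np.zeros(3)])
        assert netstats.modality_dominance(w, self.MODS) == 1.0

    def test_pure_mu_is_minus_one(self):
        w = np.concatenate([np.zeros(6), np.ones(3)])
        assert netstats.modality_dominance(w, self.MODS) == -1.0

    def test_equal_rms_is_zero(self):
        w = np.concatenate([np.full(6, 0.5), np.full(3, -0.5)])
        assert netstats.modality_dominance(w, self.MODS) == pytest.approx(0.0)

    def test_missing_modality_rejected(self):
        with pytest.raises(ValueError):
            netstats.modality_dominance(np.ones(4), np.array(["LFP"] * 4))


class TestEntropy:
    def test_uniform_over_40_bins(self):
        x = np.repeat(np.arange(40), 100) + 0.5
        assert netstats.channel_entropy(x, k=40) == pytest.approx(
            np.log2(40), abs=1e-9)

    def test_two_equal_bins_one_bit(self):
        x = np.array([0.0] * 50 + [1.0] * 50)
        assert netstats.channel_entropy(x, k=40) == pytest.approx(1.0)

    def test_bounds(self, rng):
        h = netstats.channel_entropy(rng.standard_normal(10_000), k=40)
        assert 0.0 <= h <= np.log2(40)

    def test_constant_series_zero(self):
        assert netstats.channel_entropy(np.full(100, 3.3)) == 0.0


class TestKurtosis:
    def test_gaussian_real_part_is_three(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal(1_000_000) + 0j
        k = netstats.distribution_kurtosis(z)
        assert k["kurt_real"] == pytest.approx(3.0, abs=0.05)

    def test_uniform_is_nine_fifths(self):
        rng = np.random.default_rng(6)
        z = rng.uniform(-1, 1, 500_000) + 0j
        assert netstats.distribution_kurtosis(z)["kurt_real"] == pytest.approx(
            1.8, abs=0.05)

    def test_laplace_is_six(self):
        rng = np.random.default_rng(7)
        z = rng.laplace(size=1_000_000) + 0j
        assert netstats.distribution_kurtosis(z)["kurt_real"] == pytest.approx(
            6.0, abs=0.25)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            netstats.distribution_kurtosis(np.ones(10) + 0j)


class TestWpli:
    def test_quarter_cycle_lag_gives_one(self):
        t = np.arange(20_000) / 1000.0
        z1 = np.exp(2j * np.pi * 10 * t)
        z2 = z1 * np.exp(-1j * np.pi / 2)
        assert netstats.wpli(z1, z2, 1000.0) == pytest.approx(1.0)

    def test_zero_lag_gives_zero(self):
        t = np.arange(20_000) / 1000.0
        z1 = np.exp(2j * np.pi * 10 * t) * (1 + 0.3 * np.sin(2 * np.pi * 0.3 * t))
        assert netstats.wpli(z1, z1, 1000.0) == 0.0

    def test_independent_phases_tend_to_zero(self, rng):
        n = 400_000
        z1 = np.exp(1j * rng.uniform(-np.pi, np.pi, n))
        z2 = np.exp(1j * rng.uniform(-np.pi, np.pi, n))
        assert netstats.wpli(z1, z2, 1000.0) < 0.1

    def test_common_zero_lag_component_does_not_create_coupling(self, rng):
        # volume-conduction robustness: a shared real signal adds only
        # zero-imaginary cross-terms
        t = np.arange(100_000) / 1000.0
        common = np.cos(2 * np.pi * 9 * t)
        z1 = common + 0.01 * rng.standard_normal(t.size)
        z2 = common + 0.01 * rng.standard_normal(t.size)
        assert netstats.wpli(z1 + 0j, z2 + 0j, 1000.0) < 0.25


class TestReproducibility:
    def test_identical_maps(self, rng):
        maps = rng.standard_normal((10, 2))
        out = netstats.map_reproducibility(maps, maps)
        assert out["r2_top"] == pytest.approx(1.0)
        assert out["r2_max"] == pytest.approx(1.0)

    def test_rank_swapped_components(self, rng):
        maps = rng.standard_normal((10, 2))
        out = netstats.map_reproducibility(maps, maps[:, ::-1])
        assert out["r2_max"] == pytest.approx(1.0)
        assert out["r2_top"] < 0.9

    def test_max_at_least_top(self, rng):
        a, b = rng.standard_normal((2, 10, 2))
        out = netstats.map_reproducibility(a, b)
        assert out["r2_max"] >= out["r2_top"]


class TestPermutationDimensionality:
    def _noise_pools(self, rng, n_seg=30, m=6, dof=40):
        def pool():
            covs = []
            for _ in range(n_seg):
                X = rng.standard_normal((m, dof))
                X -= X.mean(1, keepdims=True)
                covs.append(X @ X.T / (dof - 1))
            return np.stack(covs)
        return pool(), pool()

    def test_same_process_pools_give_zero_dimensionality(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a, b = self._noise_pools(rng)
            out = netstats.permutation_dimensionality(a, b, n_perm=100, rng=seed)
            hits += out["dimensionality"] == 0
        assert hits >= 9

    def test_planted_contrast_detected(self, rng):
        m, n_seg, dof = 6, 40, 60
        direction = np.zeros(m)
        direction[0] = 1.0
        a, b = [], []
        for _ in range(n_seg):
            X = rng.standard_normal((m, dof))
            Xs = X + 4.0 * np.outer(direction, rng.standard_normal(dof))
            a.append(np.cov(Xs))
            b.append(np.cov(rng.standard_normal((m, dof))))
        out = netstats.permutation_dimensionality(np.stack(a), np.stack(b),
                                                  n_perm=100, rng=0)
        assert out["dimensionality"] == 1

    def test_dimensionality_bounded_by_channels(self, rng):
        a, b = self._noise_pools(rng, m=4)
        out = netstats.permutation_dimensionality(a, b, n_perm=50, rng=0)
        assert 0 <= out["dimensionality"] <= 4

    def test_misaligned_pools_rejected(self, rng):
        a, b = self._noise_pools(rng)
        with pytest.raises(ValueError):
            netstats.permutation_dimensionality(a, b[:-1], n_perm=10)

    def test_threshold_shrinks_with_more_segments(self):
        thr = []
        for n_seg in (10, 80):
            rng = np.random.default_rng(3)
            a, b = self._noise_pools(rng, n_seg=n_seg)
            thr.append(netstats.permutation_dimensionality(
                a, b, n_perm=100, rng=1)["threshold"])
        assert thr[1] < thr[0]
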