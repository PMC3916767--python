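"""Odor panel generation, distance distribution and stimulus variants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from olfnet import odor_space as osp


class TestDescriptorSpace:
    def test_reference_scale_shape(self):
        space = osp.synthetic_descriptor_space(447, 32, 20, seed=1)
        assert space.matrix.shape == (447, 32)

    def test_seed_determinism(self):
        a = osp.synthetic_descriptor_space(10, 2, 1, seed=1)
        b = osp.synthetic_descriptor_space(10, 2, 1, seed=1)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    @pytest.mark.parametrize("args", [(5, 2, 6), (0, 2, 1), (5, 1, 1)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            osp.synthetic_descriptor_space(*args, seed=0)


class TestTrimodalDistribution:
    def test_expected_value_is_weighted_mean(self, default_dist):
        w, m = default_dist.weights, default_dist.means
        assert default_dist.expected_value == pytest.approx(
            sum(wi * mi for wi, mi in zip(w, m)), abs=1e-9)
        assert default_dist.expected_value == pytest.approx(7.7)

    def test_single_effective_component(self):
        d = osp.TrimodalDistribution((7.7, 1.0, 2.0), (1.0, 1.0, 1.0),
                                     (1.0, 0.0, 0.0))
        assert d.expected_value == pytest.approx(7.7)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            osp.TrimodalDistribution((1, 2, 3), (1, 0, 1), (0.4, 0.3, 0.3))
        with pytest.raises(ValueError):
            osp.TrimodalDistribution((1, 2, 3), (1, 1, 1), (0.5, 0.2, 0.2))

    def test_samples_nonnegative(self, default_dist):
        d = default_dist.sample(5000, np.random.default_rng(0))
        assert d.min() >= 0


class TestDistanceFitting:
    def test_parameter_recovery(self, default_dist):
        """Refitting samples from a known mixture recovers component means."""
        samples = default_dist.sample(10_000, np.random.default_rng(42))
        fit = osp.fit_trimodal(samples, seed=0)
        for m_true, m_fit in zip(default_dist.means, fit.means):
            assert abs(m_fit - m_true) / m_true < 0.10

    def test_fit_on_synthetic_space(self):
        space = osp.synthetic_descriptor_space(60, 4, 5, seed=2)
        fit = osp.fit_distance_distribution(space, range(3, 6), n_trials=3,
                                            seed=0)
        assert all(np.isfinite(fit.sds)) and all(s > 0 for s in fit.sds)
        assert np.isfinite(fit.expected_value)

    def test_trimodal_beats_single_gaussian(self):
        """KS distance of the mixture fit is below a single-Gaussian fit."""
        space = osp.synthetic_descriptor_space(80, 3, 4, seed=3)
        d, w = osp.pooled_centroid_distances(space, [4, 5], n_trials=5, seed=0)
        rng = np.random.default_rng(0)
        sample = d[rng.choice(d.size, size=5000, p=w / w.sum())]
        fit = osp.fit_trimodal(sample, seed=0)

        def mix_cdf(x):
            return sum(wi * stats.norm.cdf(x, mi, si) for wi, mi, si
                       in zip(fit.weights, fit.means, fit.sds))

        ks_mix = stats.kstest(sample, mix_cdf).statistic
        ks_gauss = stats.kstest(sample, "norm",
                                args=(sample.mean(), sample.std())).statistic
        assert ks_mix < ks_gauss


class TestDistanceToAffinity:
    def test_zero_distance_gives_one(self):
        assert osp.distance_to_affinity(0.0) == pytest.approx(1.0)

    def test_strictly_decreasing(self):
        d = np.linspace(0, 20, 200)
        a = osp.distance_to_affinity(d)
        assert np.all(np.diff(a) < 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            osp.distance_to_affinity(-0.1)

    def test_sampled_affinities_cover_full_range(self, default_dist):
        """10,000 sampled distances span affinities from <=0.01 to >=0.99."""
        d = default_dist.sample(10_000, np.random.default_rng(7))
        a = osp.distance_to_affinity(d, default_dist)
        assert a.min() <= 0.01 and a.max() >= 0.99


class TestGeneratePatternSet:
    def test_reference_panel_activation_counts(self, panel50):
        assert panel50.values.shape == (50, 40)
        nz = (panel50.values > 0).sum(axis=1)
        assert nz.min() >= 12 and nz.max() <= 20  # 30-50% of 40 ORs

    def test_full_activation_range(self):
        panel = osp.generate_pattern_set(5, 10, activation_range=(1.0, 1.0),
                                         seed=0)
        assert np.all(panel.values > 0)

    def test_seed_determinism(self, default_dist):
        a = osp.generate_pattern_set(5, 20, default_dist, seed=9)
        b = osp.generate_pattern_set(5, 20, default_dist, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_empty_activation_range_rejected(self):
        with pytest.raises(ValueError):
            osp.generate_pattern_set(5, 40, activation_range=(0.0, 0.01))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_active_fraction_always_in_range(self, seed):
        panel = osp.generate_pattern_set(8, 25, seed=seed)
        frac = panel.n_activated / panel.n_or
        assert np.all(frac >= 0.3 - 1e-12) and np.all(frac <= 0.5 + 1e-12)


class TestApplyNoise:
    def test_zero_sigma_identity(self, panel50):
        noisy = osp.apply_noise(panel50, 0.0, seed=1)
        np.testing.assert_array_equal(noisy.values, panel50.values)

    def test_bounds_at_reference_sigma(self, panel50):
        noisy = osp.apply_noise(panel50, 0.05, seed=1)
        assert np.max(np.abs(noisy.values - panel50.values)) <= 0.05
        assert noisy.values.min() >= 0 and noisy.values.max() <= 1

    def test_clipping_at_one(self):
        panel = osp.AffinityMatrix(np.array([[0.9]]), np.array([[True]]))
        noisy = osp.apply_noise(panel, 0.3, seed=0)
        assert noisy.values[0, 0] <= 1.0

    def test_inactive_entries_can_become_nonzero(self, panel50):
        noisy = osp.apply_noise(panel50, 0.05, seed=1)
        assert (noisy.values[~panel50.active] > 0).any()


class TestConcentrationVariants:
    OFFSETS = (-0.2, -0.1, 0.0, 0.1, 0.2)

    def test_ten_odors_five_offsets_give_fifty(self, panel50):
        var = osp.concentration_variants(panel50, range(10), self.OFFSETS)
        assert var.n_patterns == 50

    def test_zero_offset_identity(self, panel50):
        var = osp.concentration_variants(panel50, [3], [0.0])
        np.testing.assert_array_equal(var.values[0], panel50.values[3])

    def test_negative_offset_clips_to_zero(self):
        panel = osp.AffinityMatrix(np.array([[0.15, 0.0]]),
                                   np.array([[True, False]]))
        var = osp.concentration_variants(panel, [0], [-0.2])
        assert var.values[0, 0] == 0.0

    def test_offsets_touch_active_ors_only(self, panel50):
        var = osp.concentration_variants(panel50, [0], [0.1])
        inactive = ~panel50.active[0]
        np.testing.assert_array_equal(var.values[0][inactive],
                                      panel50.values[0][inactive])

    def test_unknown_pattern_id(self, panel50):
        with pytest.raises(ValueError):
            osp.concentration_variants(panel50, [999], [0.0])


class TestMakeIncomplete:
    def test_full_completeness_identity(self, panel50):
        row = osp.make_incomplete(panel50, 0, 1.0, seed=0)
        np.testing.assert_array_equal(row, panel50.values[0])

    def test_half_completeness_halves_active_count(self):
        values = np.zeros((1, 32))
        values[0, :16] = 0.5
        panel = osp.AffinityMatrix(values, values > 0)
        row = osp.make_incomplete(panel, 0, 0.5, seed=0)
        assert (row > 0).sum() == 8

    def test_monotone_along_completeness_grid(self, panel50):
        counts = [(osp.make_incomplete(panel50, 2, c, seed=5) > 0).sum()
                  for c in (0.8, 0.7, 0.6, 0.5, 0.4, 0.3)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_pattern_rejected(self):
        panel = osp.AffinityMatrix(np.zeros((1, 4)), np.zeros((1, 4), bool))
        with pytest.raises(ValueError):
            osp.make_incomplete(panel, 0, 0.5)


class TestMixtureSeries:
    FRACTIONS = (0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2)

    def test_seven_mixtures_per_pair(self, panel50):
        rows = osp.make_mixture_series(panel50, 0, 1, self.FRACTIONS, seed=0)
        assert rows.shape == (7, panel50.n_or)

    def test_fifty_pairs_give_350(self, panel50):
        total = sum(
            osp.make_mixture_series(panel50, 2 * p % 50, (2 * p + 1) % 50,
                                    self.FRACTIONS, seed=p).shape[0]
            for p in range(50))
        assert total == 350

    def test_degenerate_pure_pattern(self, panel50):
        rows = osp.make_mixture_series(panel50, 4, 9, (1.0,), seed=0)
        np.testing.assert_array_equal(rows[0], panel50.values[4])

    def test_nesting_of_parent_contributions(self, panel50):
        """Active-OR subsets form monotone chains along the fraction grid."""
        id_b, id_r = 7, 31
        rows = osp.make_mixture_series(panel50, id_b, id_r, self.FRACTIONS,
                                       seed=3)
        b_active = set(np.flatnonzero(panel50.active[id_b]))
        r_active = set(np.flatnonzero(panel50.active[id_r]))
        only_b = [set(np.flatnonzero(r)) & (b_active - r_active) for r in rows]
        only_r = [set(np.flatnonzero(r)) & (r_active - b_active) for r in rows]
        for t in range(len(rows) - 1):
            assert only_b[t] >= only_b[t + 1]  # B subset shrinks
            assert only_r[t] <= only_r[t + 1]  # R subset grows

    def test_identical_parents_rejected(self, panel50):
        with pytest.raises(ValueError):
            osp.make_mixture_series(panel50, 3, 3)


def test_panel_roundtrip(tmp_path, panel50):
    osp.save_panel(panel50, tmp_path / "panel.csv", metadata={"seed": 1})
    loaded = osp.load_panel(tmp_path / "panel.csv")
    np.testing.assert_allclose(loaded.values, panel50.values)
    np.testing.assert_array_equal(loaded.active, panel50.active)
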