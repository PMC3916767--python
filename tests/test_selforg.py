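"""Normalizations, MI distance, MDS, vector quantization and BCPNN rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from olfnet import selforg


class TestNormalizeResponses:
    def test_direct_evaluation(self):
        out = selforg.normalize_responses(np.array([[10.0, 30.0, 0.0]]))
        np.testing.assert_allclose(out, [[0.25, 0.75, 0.0]])

    def test_silent_cell_convention(self):
        out = selforg.normalize_responses(np.zeros((1, 3)))
        np.testing.assert_array_equal(out, np.zeros((1, 3)))

    def test_nonzero_rows_sum_to_one(self):
        f = np.random.default_rng(0).uniform(0, 5, size=(20, 7))
        out = selforg.normalize_responses(f)
        np.testing.assert_allclose(out.sum(axis=1), 1.0)


class TestHalfNormalize:
    def test_rescaled_group(self):
        out = selforg.half_normalize(np.array([0.8, 0.6]), np.array([0, 0]))
        np.testing.assert_allclose(out, [0.8 / 1.4, 0.6 / 1.4])

    def test_untouched_group(self):
        vals = np.array([0.3, 0.4])
        out = selforg.half_normalize(vals, np.array([0, 0]))
        np.testing.assert_array_equal(out, vals)

    @given(hnp.arrays(float, (6, 4), elements=st.floats(0, 3)))
    @settings(max_examples=50, deadline=None)
    def test_group_sums_never_exceed_one(self, vals):
        groups = np.array([0, 0, 1, 1, 2, 2])
        out = selforg.half_normalize(vals, groups)
        for g in range(3):
            assert np.all(out[groups == g].sum(axis=0) <= 1 + 1e-9)


class TestActivationProbabilities:
    def test_mean_over_patterns(self):
        xi = np.array([[1.0, 0.0, 0.0, 0.0]])
        p, _ = selforg.activation_probabilities(xi)
        assert p[0] == pytest.approx(0.25)

    def test_self_joint_is_mean_square(self):
        xi = np.random.default_rng(1).uniform(0, 1, size=(3, 10))
        _, pj = selforg.activation_probabilities(xi)
        np.testing.assert_allclose(np.diag(pj), (xi**2).mean(axis=1))

    def test_silent_unit(self):
        p, pj = selforg.activation_probabilities(np.zeros((2, 5)))
        assert p[0] == 0 and pj[0, 1] == 0


class TestMIDistance:
    def test_identical_units_distance_zero(self):
        p = np.array([0.5, 0.5])
        pj = np.full((2, 2), 0.5)
        stats = selforg.mi_distance(p, pj)
        expected = 0.5 * math.log(2)
        assert stats.mutual_information[0, 1] == pytest.approx(expected)
        assert stats.joint_entropy[0, 1] == pytest.approx(expected)
        assert stats.distance[0, 1] == pytest.approx(0.0)

    def test_independent_units_distance_one(self):
        p = np.array([0.5, 0.4])
        pj = np.outer(p, p)
        stats = selforg.mi_distance(p, pj)
        assert stats.distance[0, 1] == pytest.approx(1.0)

    def test_zero_joint_distance_one(self):
        stats = selforg.mi_distance(np.array([0.3, 0.3]), np.zeros((2, 2)))
        assert stats.distance[0, 1] == 1.0

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(4)
        xi = rng.uniform(0, 1, size=(12, 30))
        p, pj = selforg.activation_probabilities(xi)
        d = selforg.mi_distance(p, pj).distance
        np.testing.assert_allclose(d, d.T)
        assert d.min() >= 0 and d.max() <= 1
        np.testing.assert_allclose(np.diag(d), 0.0)


class TestEmbedMDS:
    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(15, 3))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        coords = selforg.embed_mds(d, dims=3, seed=0)
        d_hat = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        stress = ((d - d_hat) ** 2).sum()
        assert stress < 1e-6

    def test_two_points(self):
        coords = selforg.embed_mds(np.array([[0.0, 1.0], [1.0, 0.0]]), seed=0)
        assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(1.0, abs=1e-6)

    def test_identical_rows_coincide(self):
        d = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0.0]])
        coords = selforg.embed_mds(d, seed=0)
        assert np.linalg.norm(coords[0] - coords[1]) < 1e-6

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            selforg.embed_mds(np.zeros((3, 4)))


@pytest.fixture(scope="module")
def coords():
    return np.random.default_rng(6).normal(size=(320, 3))


class TestVQMTtoHC:
    def test_every_hc_nonempty_at_reference_scale(self, coords):
        _, mt_of_hc, _ = selforg.vq_mt_to_hc(coords, 12, m=4, seed=0)
        assert all(len(mt) >= 1 for mt in mt_of_hc)

    def test_each_mt_gets_m_assignments(self, coords):
        hc_of_mt, _, _ = selforg.vq_mt_to_hc(coords, 12, m=4, seed=0)
        assert all(h.size == 4 for h in hc_of_mt)

    def test_m1_equals_nearest_centroid(self, coords):
        hc_of_mt, _, centroids = selforg.vq_mt_to_hc(coords, 6, m=1, seed=1)
        dist = np.linalg.norm(coords[:, None] - centroids[None], axis=2)
        np.testing.assert_array_equal(
            np.array([h[0] for h in hc_of_mt]), dist.argmin(axis=1))

    def test_silent_cells_excluded(self, coords):
        silent = np.zeros(320, bool)
        silent[:50] = True
        hc_of_mt, mt_of_hc, _ = selforg.vq_mt_to_hc(coords, 8, m=2,
                                                    silent_mask=silent, seed=0)
        assert all(hc_of_mt[i].size == 0 for i in range(50))
        assert not any(np.isin(np.arange(50), mt).any() for mt in mt_of_hc)

    def test_too_many_hcs_rejected(self):
        with pytest.raises(ValueError):
            selforg.vq_mt_to_hc(np.zeros((5, 3)), 6, seed=0)


class TestVQPatternsToMC:
    def test_one_active_mc_per_hc_per_pattern(self):
        rng = np.random.default_rng(7)
        xi = rng.uniform(0, 0.5, size=(40, 50))
        mt_of_hc = [np.arange(0, 20), np.arange(20, 40)]
        zeta = selforg.vq_patterns_to_mc(xi, mt_of_hc, 30, seed=0)
        assert zeta.shape == (50, 60)
        for h in range(2):
            block = zeta[:, h * 30:(h + 1) * 30]
            np.testing.assert_array_equal(block.sum(axis=1), 1.0)
            assert block.sum() == 50  # one per pattern

    def test_identical_patterns_share_mc(self):
        xi = np.zeros((4, 6))
        xi[:, 0] = xi[:, 1] = [0.5, 0.1, 0.3, 0.2]  # patterns 0,1 identical
        xi[:, 2:] = np.random.default_rng(8).uniform(0, 1, size=(4, 4))
        zeta = selforg.vq_patterns_to_mc(xi, [np.arange(4)], 6, seed=0)
        np.testing.assert_array_equal(zeta[0], zeta[1])

    def test_surplus_mcs_stay_unused(self):
        xi = np.tile(np.array([[0.2], [0.4]]), (1, 5))  # 5 identical patterns
        zeta = selforg.vq_patterns_to_mc(xi, [np.arange(2)], 4, seed=0)
        assert (zeta.sum(axis=0) > 0).sum() == 1  # a single MC used


def _bcpnn_oracle(xi_pre, xi_post):
    """Brute-force per-pair probability accumulation and case analysis."""
    n_p = xi_pre.shape[1]
    w = np.zeros((xi_pre.shape[0], xi_post.shape[0]))
    for i in range(xi_pre.shape[0]):
        p_i = sum(xi_pre[i, k] for k in range(n_p)) / n_p
        for j in range(xi_post.shape[0]):
            p_j = sum(xi_post[j, k] for k in range(n_p)) / n_p
            p_ij = sum(xi_pre[i, k] * xi_post[j, k] for k in range(n_p)) / n_p
            if p_i == 0 or p_j == 0:
                w[i, j] = 0.0
            elif p_ij == 0:
                w[i, j] = math.log(1 / n_p)
            else:
                w[i, j] = math.log(p_ij / (p_i * p_j))
    return w


class TestBCPNN:
    def test_independence_gives_zero(self):
        w = selforg.bcpnn_weights(np.array([0.5]), np.array([0.4]),
                                  np.array([[0.2]]), 10)
        assert w[0, 0] == pytest.approx(0.0)

    def test_never_coactive_gives_log_inverse_np(self):
        w = selforg.bcpnn_weights(np.array([0.3]), np.array([0.3]),
                                  np.array([[0.0]]), 50)
        assert w[0, 0] == pytest.approx(math.log(1 / 50))

    def test_silent_pre_gives_zero_even_with_zero_joint(self):
        w = selforg.bcpnn_weights(np.array([0.0]), np.array([0.3]),
                                  np.array([[0.0]]), 50)
        assert w[0, 0] == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        xi = rng.uniform(0, 1, size=(6, 8)) * (rng.random((6, 8)) < 0.6)
        xi[5] = 0.0  # one silent unit
        p, pj = selforg.activation_probabilities(xi)
        w = selforg.bcpnn_weights(p, p, pj, 8)
        np.testing.assert_allclose(w, _bcpnn_oracle(xi, xi), atol=1e-12)

    def test_bias_cases(self):
        assert selforg.bcpnn_bias(0.1, 50) == pytest.approx(math.log(0.1))
        assert selforg.bcpnn_bias(0.0, 50) == pytest.approx(math.log(1 / 2500))
        assert selforg.bcpnn_bias(1.0, 50) == pytest.approx(0.0)
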