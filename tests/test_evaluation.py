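"""Evaluation metrics: dyadic coherence, sigma_FA, NMI, Jacobians, stats."""

import numpy as np
import pytest

from istg.evaluation import (
    compare_methods,
    dyadic_coherence,
    ecdf,
    jacobian_summary,
    nmi,
    sigma_fa,
)
from istg.volumes import Mask, ScalarVolume


def full_mask(shape=(2, 2, 2)):
    return Mask(np.ones(shape, dtype=bool), np.eye(4))


def vector_field(v, shape=(2, 2, 2)):
    f = np.zeros(shape + (3,))
    f[...] = v
    return f


class TestDyadicCoherence:
    def test_perfect_alignment_is_one(self):
        fields = [vector_field([1, 0, 0]) for _ in range(6)]
        kappa = dyadic_coherence(fields, full_mask())
        np.testing.assert_allclose(kappa.values, 1.0, atol=1e-12)

    def test_half_x_half_y_closed_form(self):
        # mean dyadic diag(1/2, 1/2, 0): kappa = 1 - sqrt(1/2)
        fields = [vector_field([1, 0, 0])] * 3 + [vector_field([0, 1, 0])] * 3
        kappa = dyadic_coherence(fields, full_mask())
        np.testing.assert_allclose(kappa.values, 1 - np.sqrt(0.5), atol=1e-12)

    def test_random_directions_approach_zero(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((1000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        fields = [vector_field(vi, shape=(1, 1, 1)) for vi in v]
        kappa = dyadic_coherence(fields, full_mask((1, 1, 1)))
        assert kappa.values[0, 0, 0] <= 0.05

    def test_sign_blind(self):
        fields = [vector_field([1, 0, 0]), vector_field([-1, 0, 0])]
        kappa = dyadic_coherence(fields, full_mask())
        np.testing.assert_allclose(kappa.values, 1.0, atol=1e-12)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        fields = [vector_field(rng.standard_normal(3)) for _ in range(5)]
        fields = [f / np.linalg.norm(f[0, 0, 0]) for f in fields]
        k1 = dyadic_coherence(fields, full_mask()).values
        k2 = dyadic_coherence(fields[::-1], full_mask()).values
        np.testing.assert_allclose(k1, k2, atol=1e-12)

    def test_all_zero_vectors_masked_out(self):
        fields = [vector_field([0, 0, 0]) for _ in range(3)]
        kappa = dyadic_coherence(fields, full_mask())
        assert np.all(kappa.values == 0.0)


class TestSigmaFa:
    def maps(self, rows):
        return [ScalarVolume(np.full((2, 2, 2), r, dtype=float), np.eye(4))
                if np.isscalar(r) else ScalarVolume(np.asarray(r), np.eye(4))
                for r in rows]

    def test_identical_maps_give_zero(self):
        out = sigma_fa(self.maps([0.4, 0.4, 0.4]), full_mask())
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_two_value_closed_form(self):
        # sd({0.4, 0.6}, ddof=1) / mean = 0.141421 / 0.5
        out = sigma_fa(self.maps([0.4, 0.6]), full_mask())
        np.testing.assert_allclose(out.values, np.sqrt(0.02) / 0.5, atol=1e-9)

    def test_scale_invariant(self):
        rng = np.random.default_rng(2)
        rows = rng.uniform(0.2, 0.8, size=(4, 2, 2, 2))
        a = sigma_fa(self.maps(list(rows)), full_mask()).values
        b = sigma_fa(self.maps(list(rows * 3.0)), full_mask()).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_near_zero_mean_masked_out(self):
        out = sigma_fa(self.maps([0.0, 0.0]), full_mask())
        np.testing.assert_allclose(out.values, 0.0)

    def test_needs_two_maps(self):
        with pytest.raises(ValueError, match="at least 2"):
            sigma_fa(self.maps([0.4]), full_mask())


class TestNmi:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(3)
        a = ScalarVolume(rng.uniform(0, 1, (8, 8, 8)), np.eye(4))
        assert nmi(a, a, full_mask((8, 8, 8))) == pytest.approx(1.0, abs=1e-12)

    def test_independent_images_near_zero(self):
        rng = np.random.default_rng(4)
        shape = (64, 64, 64)
        a = ScalarVolume(rng.uniform(0, 1, shape), np.eye(4))
        b = ScalarVolume(rng.uniform(0, 1, shape), np.eye(4))
        assert nmi(a, b, full_mask(shape)) <= 0.05

    def test_invariant_under_common_bin_relabeling(self):
        rng = np.random.default_rng(5)
        bins = 16
        vals_a = rng.integers(0, bins, (10, 10, 10)).astype(float)
        vals_b = rng.integers(0, bins, (10, 10, 10)).astype(float)
        # ensure the full label range is present so histogram ranges agree
        vals_a.flat[:bins] = np.arange(bins)
        vals_b.flat[:bins] = np.arange(bins)
        perm = rng.permutation(bins).astype(float)
        m = full_mask((10, 10, 10))
        orig = nmi(ScalarVolume(vals_a, np.eye(4)), ScalarVolume(vals_b, np.eye(4)),
                   m, bins=bins)
        relab = nmi(ScalarVolume(perm[vals_a.astype(int)], np.eye(4)),
                    ScalarVolume(perm[vals_b.astype(int)], np.eye(4)), m, bins=bins)
        assert relab == pytest.approx(orig, abs=1e-10)

    def test_constant_image_rejected(self):
        a = ScalarVolume(np.zeros((4, 4, 4)), np.eye(4))
        b = ScalarVolume(np.random.default_rng(0).uniform(0, 1, (4, 4, 4)), np.eye(4))
        with pytest.raises(ValueError, match="constant"):
            nmi(a, b, full_mask((4, 4, 4)))

    def test_entropy_ratio_variant_is_antitone(self):
        rng = np.random.default_rng(6)
        shape = (16, 16, 16)
        a = ScalarVolume(rng.uniform(0, 1, shape), np.eye(4))
        noisy = ScalarVolume(a.values + rng.normal(0, 0.05, shape), np.eye(4))
        b = ScalarVolume(rng.uniform(0, 1, shape), np.eye(4))
        m = full_mask(shape)
        r_similar = nmi(a, noisy, m, variant="entropy_ratio")
        r_dissimilar = nmi(a, b, m, variant="entropy_ratio")
        assert r_similar < r_dissimilar  # the literal ratio shrinks with similarity
        assert 0.5 <= r_similar <= 1.0 and 0.5 <= r_dissimilar <= 1.0


class TestJacobianSummary:
    def test_identity_deformations(self):
        maps = [ScalarVolume(np.ones((3, 3, 3)), np.eye(4)) for _ in range(3)]
        mean_map, sd_map, devs = jacobian_summary(maps, full_mask((3, 3, 3)))
        np.testing.assert_allclose(mean_map.values, 1.0)
        np.testing.assert_allclose(sd_map.values, 0.0)
        assert all(v == 0.0 for v in devs.values())

    def test_constant_expansion_deviation(self):
        maps = [ScalarVolume(np.full((3, 3, 3), 1.2), np.eye(4))]
        _, _, devs = jacobian_summary(maps, full_mask((3, 3, 3)))
        assert devs["0"] == pytest.approx(0.2)

    def test_voxel_order_invariant(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0.8, 1.2, (3, 3, 3))
        m1 = [ScalarVolume(vals, np.eye(4))]
        m2 = [ScalarVolume(vals.transpose(2, 1, 0).copy(), np.eye(4))]
        _, _, d1 = jacobian_summary(m1, full_mask((3, 3, 3)))
        _, _, d2 = jacobian_summary(m2, full_mask((3, 3, 3)))
        assert d1["0"] == pytest.approx(d2["0"], abs=1e-12)


class TestEcdf:
    def test_fractions(self):
        pts = ecdf([1.0, 2.0, 3.0])
        assert dict(zip(pts[:, 0], pts[:, 1]))[2.0] == pytest.approx(2 / 3)
        assert pts[0, 1] == pytest.approx(1 / 3)
        assert pts[-1, 1] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecdf([])


class TestCompareMethods:
    def test_equal_groups_give_zero_effect(self):
        r = compare_methods([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], seed=0, n_boot=200)
        assert r.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert r.cohens_d == pytest.approx(0.0, abs=1e-12)

    def test_textbook_values(self):
        r = compare_methods([1, 2, 3], [4, 5, 6], seed=0, n_boot=200)
        assert r.t_statistic == pytest.approx(-3.674, abs=1e-3)
        assert r.cohens_d == pytest.approx(-3.0, abs=1e-9)
        assert r.p_bonferroni == pytest.approx(min(1.0, 3 * r.p_value), abs=1e-12)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1, 20)
        r = compare_methods(a, b, seed=1, n_boot=2000)
        assert r.d_ci[0] <= r.cohens_d <= r.d_ci[1]

    def test_seeded_bootstrap_reproducible(self):
        a, b = [1, 2, 3, 4.0], [2, 3, 4, 5.0]
        r1 = compare_methods(a, b, seed=5, n_boot=500)
        r2 = compare_methods(a, b, seed=5, n_boot=500)
        assert r1.d_ci == r2.d_ci

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="pooled variance"):
            compare_methods([1.0, 1.0], [1.0, 1.0], seed=0, n_boot=10)
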