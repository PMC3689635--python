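"""Circular sampling, LBP patterns and the global texture-variance score."""

import numpy as np
import pytest

from chromoscore import (
    NeighborhoodSpec,
    global_texture_variance,
    lbp_pattern,
    local_variance,
    multi_radius_score,
    sample_neighbors,
)

from conftest import oracle_global_variance, oracle_neighbors


SPEC_R1N4 = NeighborhoodSpec(R=1, N=4)


class TestNeighborhoodSpec:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            NeighborhoodSpec(R=0, N=8)
        with pytest.raises(ValueError):
            NeighborhoodSpec(R=1, N=1)

    def test_margin_covers_radius(self):
        assert NeighborhoodSpec(R=1, N=4).margin() == 1
        assert NeighborhoodSpec(R=2.5, N=8).margin() == 3
        assert NeighborhoodSpec(R=10, N=8).margin() == 10


class TestSampleNeighbors:
    def test_constant_image(self):
        img = np.full((5, 5), 42.0)
        assert np.allclose(sample_neighbors(img, (2, 2), NeighborhoodSpec(2, 8)), 42.0)

    def test_hand_derived_cross_samples(self, ramp_3x3):
        # i = 1..4 at angles 90/180/270/360 deg with y pointing down:
        # below (8), left (4), above (2), right (6) of the center value 5
        got = sample_neighbors(ramp_3x3, (1, 1), SPEC_R1N4)
        assert np.allclose(got, [8, 4, 2, 6])

    def test_diagonal_samples_are_bilinear_blends(self, ramp_3x3):
        got = sample_neighbors(ramp_3x3, (1, 1), NeighborhoodSpec(R=1, N=8))
        expected = oracle_neighbors(ramp_3x3, 1, 1, 1.0, 8)
        assert np.allclose(got, expected)
        # 45 deg sample sits at (1 + 1/sqrt(2), 1 + 1/sqrt(2)): a blend of 5, 6, 8, 9
        s = 1 / np.sqrt(2)
        hand = (1 - s) * (1 - s) * 5 + s * (1 - s) * 6 + (1 - s) * s * 8 + s * s * 9
        assert got[0] == pytest.approx(hand)

    def test_circle_exiting_bounds_rejected(self, ramp_3x3):
        with pytest.raises(ValueError, match="bounds"):
            sample_neighbors(ramp_3x3, (0, 1), SPEC_R1N4)


class TestLbpPattern:
    def test_constant_image_all_bits_one(self):
        # the threshold b(0) = 1, so equality counts as "at least as bright"
        img = np.full((5, 5), 9.0)
        pat = lbp_pattern(img, (2, 2), NeighborhoodSpec(2, 8))
        assert pat.bits == (1,) * 8

    def test_hand_derived_bits(self, ramp_3x3):
        pat = lbp_pattern(ramp_3x3, (1, 1), SPEC_R1N4)
        assert pat.bits == (1, 0, 0, 1)
        assert pat.code == 0b1001

    def test_negation_flips_strict_bits(self, rng):
        img = rng.integers(0, 256, (8, 8)).astype(float)
        spec = NeighborhoodSpec(R=2, N=8)
        for center in [(3, 3), (4, 4), (2, 5)]:
            bits = lbp_pattern(img, center, spec).bits
            neg_bits = lbp_pattern(255.0 - img, center, spec).bits
            diffs = sample_neighbors(img, center, spec) - img[center[1], center[0]]
            for b, nb, d in zip(bits, neg_bits, diffs):
                if d != 0:  # strict inequalities flip; ties stay 1 by b(0)=1
                    assert nb == 1 - b


class TestLocalVariance:
    def test_constant_image_zero(self):
        assert local_variance(np.full((5, 5), 3.0), (2, 2), NeighborhoodSpec(2, 8)) == 0.0

    def test_hand_derived_value(self, ramp_3x3):
        # neighbors (8, 4, 2, 6): mean 5, population variance 5.0
        assert local_variance(ramp_3x3, (1, 1), SPEC_R1N4) == pytest.approx(5.0)

    def test_shift_invariance(self, ramp_3x3):
        base = local_variance(ramp_3x3, (1, 1), SPEC_R1N4)
        assert local_variance(ramp_3x3 + 11.0, (1, 1), SPEC_R1N4) == pytest.approx(base)

    def test_population_divisor(self):
        # neighbors (0, 0, 10, 10): population variance 25, sample variance 100/3
        img = np.zeros((3, 3))
        img[2, 1] = 10.0
        img[1, 2] = 10.0
        assert local_variance(img, (1, 1), SPEC_R1N4) == pytest.approx(25.0)


class TestGlobalTextureVariance:
    def test_constant_image_zero(self):
        # round-off in the bilinear weights leaves residuals of order 1e-31
        got = global_texture_variance(np.full((16, 16), 7.0), NeighborhoodSpec(3, 8))
        assert got == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed,N", [(0, 4), (1, 8), (2, 8)])
    def test_matches_brute_force_oracle(self, seed, N):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (32, 32)).astype(float)
        spec = NeighborhoodSpec(R=3, N=N)
        got = global_texture_variance(img, spec)
        expected = oracle_global_variance(img, 3, N)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_non_integer_radius_matches_oracle(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (24, 24)).astype(float)
        got = global_texture_variance(img, NeighborhoodSpec(R=2.5, N=8))
        assert got == pytest.approx(oracle_global_variance(img, 2.5, 8), rel=1e-9)

    def test_step_edge_exceeds_blurred_edge(self):
        from scipy.ndimage import gaussian_filter

        img = np.zeros((32, 32))
        img[:, 16:] = 255.0
        spec = NeighborhoodSpec(R=2, N=8)
        sharp = global_texture_variance(img, spec)
        blurred = global_texture_variance(gaussian_filter(img, 3.0), spec)
        assert sharp > blurred > 0

    def test_image_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            global_texture_variance(np.zeros((8, 8)), NeighborhoodSpec(R=4, N=8))

    def test_shift_and_quadratic_scale_response(self, rng):
        img = rng.integers(40, 90, (32, 32)).astype(float)
        spec = NeighborhoodSpec(R=3, N=8)
        base = global_texture_variance(img, spec)
        assert global_texture_variance(img + 25.0, spec) == pytest.approx(base, rel=1e-12)
        assert global_texture_variance(2.0 * img, spec) == pytest.approx(4.0 * base, rel=1e-12)

    def test_approximate_rotation_invariance(self):
        # radially symmetric ring pattern: a 90 deg rotation changes the
        # score only through interpolation error
        v = h = 65
        ys, xs = np.mgrid[0:v, 0:h]
        r = np.hypot(xs - h // 2, ys - v // 2)
        img = 120.0 + 60.0 * np.sin(r / 2.0)
        spec = NeighborhoodSpec(R=4, N=8)
        a = global_texture_variance(img, spec)
        b = global_texture_variance(np.rot90(img), spec)
        assert abs(a - b) / a < 0.01


class TestMultiRadiusScore:
    def test_constant_image_all_zero(self):
        res = multi_radius_score(np.full((128, 128), 50.0), radii=(10, 20, 30), N=8)
        assert all(v == 0.0 for v in res.per_radius.values())
        assert res.averaged == 0.0

    def test_averaged_is_mean_of_per_radius(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(float)
        res = multi_radius_score(img, radii=(4, 8, 12), N=8)
        assert res.averaged == pytest.approx(np.mean(list(res.per_radius.values())))
        assert res.N == 8
        assert res.valid_center_count[4.0] == (64 - 8) ** 2

    def test_matches_per_radius_calls(self, rng):
        img = rng.integers(0, 256, (48, 48)).astype(float)
        radii = (3.0, 5.0)
        res = multi_radius_score(img, radii=radii, N=8)
        for r in radii:
            direct = global_texture_variance(img, NeighborhoodSpec(R=r, N=8))
            assert res.per_radius[r] == pytest.approx(direct, rel=1e-12)

    def test_too_small_image_names_offending_radius(self):
        with pytest.raises(ValueError, match="radius 30"):
            multi_radius_score(np.zeros((40, 40)), radii=(10, 30), N=8)

    def test_texture_amplitude_ordering(self):
        # identical mean intensity, increasing planted amplitude ->
        # monotone increasing score
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(5)
        base_field = gaussian_filter(rng.standard_normal((96, 96)), 2.0)
        base_field /= base_field.std()
        scores = []
        for amp in [2, 5, 10, 20, 40]:
            img = np.clip(128.0 + amp * base_field, 0, 255)
            scores.append(multi_radius_score(img, radii=(5, 10, 15), N=8).averaged)
        assert all(a < b for a, b in zip(scores, scores[1:]))


def test_matches_skimage_var_reference_on_interior():
    """Cross-check local variances against scikit-image's LBP 'var' map."""
    skimage_feature = pytest.importorskip("skimage.feature")
    rng = np.random.default_rng(11)
    img = rng.integers(0, 256, (32, 32)).astype(float)
    ref = skimage_feature.local_binary_pattern(img, P=8, R=3, method="var")
    # scikit-image truncates its sampling coordinates to 8 decimals, so
    # agreement is limited to ~1e-4 relative
    for cy in range(5, 27):
        for cx in range(5, 27):
            ours = local_variance(img, (cx, cy), NeighborhoodSpec(R=3, N=8))
            assert ours == pytest.approx(ref[cy, cx], rel=1e-4)
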