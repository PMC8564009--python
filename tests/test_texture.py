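import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glcm_oracle import brute_force_glcm, brute_force_statistics
from msibeef.cube import MultispectralCube, RoiMask
from msibeef.texture import (
    GLCM,
    IGNORE,
    GlcmConfig,
    compute_glcm,
    extract_texture,
    glcm_statistics,
    quantize,
    texture_feature_names,
)

WORKED_IMAGE = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [0, 2, 2, 2], [2, 2, 3, 3]])
ASYM_H1 = GlcmConfig(n_levels=4, distance=1, angles_deg=(0,), symmetric=False,
                     average_over_angles=False)


def full_mask(shape):
    return RoiMask(np.ones(shape, dtype=bool))


class TestQuantize:
    def test_uniform_binning(self):
        roi = full_mask((2, 2))
        assert (quantize(np.full((2, 2), 0.5), roi, 4) == 2).all()
        levels = quantize(np.array([[0.0, 0.999], [0.0, 0.999]]), roi, 2)
        assert set(levels.ravel()) == {0, 1}

    def test_top_of_range_maps_to_last_level(self):
        levels = quantize(np.full((2, 2), 1.0), full_mask((2, 2)), 8)
        assert (levels == 7).all()

    def test_background_marked_ignore(self):
        mask = np.array([[True, False], [True, True]])
        levels = quantize(np.full((2, 2), 0.5), RoiMask(mask), 4)
        assert levels[0, 1] == IGNORE and levels[1, 1] == 2

    def test_empty_roi_rejected(self):
        mask = np.zeros((3, 3), dtype=bool)
        roi = RoiMask.__new__(RoiMask)
        roi.mask = mask
        with pytest.raises(ValueError, match="empty ROI"):
            quantize(np.full((3, 3), 0.5), roi, 4)


class TestComputeGlcm:
    def test_two_horizontal_pairs(self):
        g = compute_glcm(np.array([[0, 0], [1, 1]]), GlcmConfig(
            n_levels=2, angles_deg=(0,), symmetric=False, average_over_angles=False))
        np.testing.assert_allclose(g.g, [[0.5, 0.0], [0.0, 0.5]])

    def test_worked_example_pair_counts(self):
        g = compute_glcm(WORKED_IMAGE, ASYM_H1)
        counts = g.g * 12  # 12 horizontal pairs in a 4x4 image
        expected = {(0, 0): 2, (0, 1): 2, (1, 1): 2, (0, 2): 1, (2, 2): 3, (2, 3): 1, (3, 3): 1}
        for (i, j), n in expected.items():
            assert counts[i, j] == pytest.approx(n)
        assert counts.sum() == pytest.approx(12)

    def test_symmetric_equals_half_sum_with_transpose(self, rng):
        levels = rng.integers(0, 5, size=(12, 12))
        asym = compute_glcm(levels, GlcmConfig(n_levels=5, angles_deg=(0,), symmetric=False,
                                               average_over_angles=False))
        sym = compute_glcm(levels, GlcmConfig(n_levels=5, angles_deg=(0,), symmetric=True,
                                              average_over_angles=False))
        np.testing.assert_allclose(sym.g, (asym.g + asym.g.T) / 2, atol=1e-15)

    def test_ignored_pixels_excluded_from_pairs(self, rng):
        levels = rng.integers(0, 4, size=(10, 10))
        levels[rng.random((10, 10)) < 0.3] = IGNORE
        cfg = GlcmConfig(n_levels=4, distance=1, angles_deg=(0, 90), symmetric=True)
        got = compute_glcm(levels, cfg)
        want = brute_force_glcm(levels, 4, 1, (0, 90), symmetric=True, average_over_angles=True)
        np.testing.assert_allclose(got.g, want, atol=1e-14)

    def test_roi_with_no_pairs_fails(self):
        levels = np.full((4, 4), IGNORE)
        levels[0, 0] = 1
        with pytest.raises(ValueError, match="no valid pixel pairs"):
            compute_glcm(levels, GlcmConfig(n_levels=2, angles_deg=(0,), symmetric=False,
                                            average_over_angles=False))

    def test_matches_skimage_counting(self, rng):
        from skimage.feature import graycomatrix

        img = rng.integers(0, 8, size=(20, 20))
        # skimage steps down-right at pi/4 where this library steps up-right,
        # so the diagonal angles swap; symmetrization absorbs the direction flip
        for angle_deg, angle_rad in [(0, 0.0), (45, 3 * np.pi / 4), (90, np.pi / 2),
                                     (135, np.pi / 4)]:
            ours = compute_glcm(img, GlcmConfig(n_levels=8, angles_deg=(angle_deg,),
                                                symmetric=True, average_over_angles=False))
            ref = graycomatrix(img.astype(np.uint8), [1], [angle_rad], levels=8,
                               symmetric=True, normed=True)[:, :, 0, 0]
            np.testing.assert_allclose(ours.g, ref, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        data=st.data(),
        h=st.integers(3, 16),
        w=st.integers(3, 16),
        n_levels=st.integers(2, 6),
        distance=st.integers(1, 2),
        symmetric=st.booleans(),
    )
    def test_oracle_equivalence_property(self, data, h, w, n_levels, distance, symmetric):
        """The vectorized GLCM equals brute-force pair enumeration."""
        levels = np.array(
            data.draw(st.lists(st.lists(st.integers(0, n_levels - 1), min_size=w, max_size=w),
                               min_size=h, max_size=h))
        )
        angles = tuple(data.draw(st.sets(st.sampled_from([0, 45, 90, 135]), min_size=1)))
        if distance >= min(h, w):
            return
        cfg = GlcmConfig(n_levels=n_levels, distance=distance, angles_deg=angles,
                         symmetric=symmetric, average_over_angles=True)
        got = compute_glcm(levels, cfg)
        want = brute_force_glcm(levels, n_levels, distance, angles, symmetric, True)
        np.testing.assert_allclose(got.g, want, atol=1e-13)


class TestStatistics:
    def test_worked_example_statistics(self):
        stats = glcm_statistics(compute_glcm(WORKED_IMAGE, ASYM_H1))
        assert stats.contrast == pytest.approx(7 / 12, abs=1e-12)
        assert stats.homogeneity == pytest.approx(9.7 / 12, abs=1e-12)
        assert stats.energy == pytest.approx(1 / 6, abs=1e-12)

    def test_constant_image_is_degenerate_point_mass(self):
        g = compute_glcm(np.zeros((6, 6), dtype=int), GlcmConfig(
            n_levels=2, angles_deg=(0,), symmetric=False, average_over_angles=False))
        stats = glcm_statistics(g)
        assert stats.homogeneity == pytest.approx(1.0)
        assert stats.contrast == pytest.approx(0.0)
        assert stats.energy == pytest.approx(1.0)
        assert stats.correlation == 0.0  # zero marginal variance

    def test_checkerboard_is_perfectly_anticorrelated(self):
        rows, cols = np.mgrid[0:8, 0:8]
        board = (rows + cols) % 2
        g = compute_glcm(board, GlcmConfig(n_levels=2, angles_deg=(0,), symmetric=False,
                                           average_over_angles=False))
        assert glcm_statistics(g).correlation == pytest.approx(-1.0)

    def test_agrees_with_brute_force_definitions(self, rng):
        levels = rng.integers(0, 6, size=(14, 14))
        g = compute_glcm(levels, GlcmConfig(n_levels=6, symmetric=True))
        got = glcm_statistics(g)
        want = brute_force_statistics(g.g)
        np.testing.assert_allclose(tuple(got), want, atol=1e-12)

    def test_contrast_invariant_under_level_reversal(self, rng):
        levels = rng.integers(0, 5, size=(10, 10))
        cfg = GlcmConfig(n_levels=5, symmetric=True)
        a = glcm_statistics(compute_glcm(levels, cfg))
        b = glcm_statistics(compute_glcm(4 - levels, cfg))
        assert a.contrast == pytest.approx(b.contrast, abs=1e-12)

    def test_invariant_to_offset_within_quantization_bins(self, rng):
        # bins of width 1/50: values on bin centers shifted by < half a bin
        base = (rng.integers(0, 50, size=(8, 8)) + 0.5) / 50
        roi = full_mask((8, 8))
        cfg = GlcmConfig(n_levels=50, symmetric=True)
        a = glcm_statistics(compute_glcm(quantize(base, roi, 50), cfg))
        b = glcm_statistics(compute_glcm(quantize(base + 0.004, roi, 50), cfg))
        assert tuple(a) == pytest.approx(tuple(b), abs=1e-14)

    def test_energy_maximal_only_for_point_mass(self, rng):
        levels = rng.integers(0, 4, size=(10, 10))
        g = compute_glcm(levels, GlcmConfig(n_levels=4, symmetric=True))
        assert glcm_statistics(g).energy < 1.0
        point = GLCM(np.eye(4)[:1].T @ np.eye(4)[:1], GlcmConfig(n_levels=4))
        assert glcm_statistics(point).energy == pytest.approx(1.0)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GLCM(np.ones((3, 3)), GlcmConfig(n_levels=3))


class TestExtractTexture:
    def test_six_band_cube_yields_24_features(self, calibrated_cube, full_roi):
        vec = extract_texture(calibrated_cube, full_roi)
        assert vec.shape == (24,)
        assert len(texture_feature_names(calibrated_cube.band_centers_nm)) == 24

    def test_single_band_cube_yields_4_features(self, rng):
        cube = MultispectralCube(rng.uniform(0, 1, (16, 16, 1)), band_centers_nm=(680,),
                                 is_calibrated=True)
        assert extract_texture(cube, full_mask((16, 16))).shape == (4,)

    def test_stripes_raise_contrast_perpendicular_to_orientation(self):
        # vertical stripes: variation along rows' columns -> angle 0 sees it
        img = np.tile((np.arange(32) // 4 % 2) * 0.5 + 0.25, (32, 1))
        cube = MultispectralCube(img[:, :, None], band_centers_nm=(680,), is_calibrated=True)
        roi = full_mask((32, 32))
        levels = quantize(cube.band(0), roi, 16)
        horiz = glcm_statistics(compute_glcm(levels, GlcmConfig(
            n_levels=16, angles_deg=(0,), symmetric=True, average_over_angles=False)))
        vert = glcm_statistics(compute_glcm(levels, GlcmConfig(
            n_levels=16, angles_deg=(90,), symmetric=True, average_over_angles=False)))
        assert horiz.contrast > vert.contrast

    def test_requires_calibrated_cube(self, rng):
        raw = MultispectralCube(rng.integers(0, 100, (8, 8, 6)).astype(float))
        with pytest.raises(ValueError, match="calibrated"):
            extract_texture(raw, full_mask((8, 8)))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_levels=1), dict(distance=0), dict(angles_deg=()), dict(angles_deg=(30,))],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GlcmConfig(**kwargs)
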