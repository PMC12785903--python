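"""Spectral and surface descriptors: FTIR order ratio, XRD crystallinity,
roughness, GLCM texture and box-counting dimension."""

import numpy as np
import pytest
from scipy.stats import norm

import starchkin as sk
from starchkin.datatypes import HeightMap, Spectrum

FTIR_GRID = np.linspace(780.0, 1260.0, 2400)
XRD_GRID = np.linspace(4.0, 40.0, 1800)


class TestShortRangeOrder:
    def test_equal_peaks_give_unity(self):
        spec = sk.gen_spectrum([(1047.0, 1.0, 8.0), (1022.0, 1.0, 8.0)], x_grid=FTIR_GRID)
        assert sk.short_range_order(spec) == pytest.approx(1.0, abs=0.01)

    def test_scaled_peak_scales_ratio(self):
        base = sk.gen_spectrum([(1047.0, 1.0, 6.0), (1022.0, 1.0, 6.0)], x_grid=FTIR_GRID)
        up = sk.gen_spectrum([(1047.0, 1.10, 6.0), (1022.0, 1.0, 6.0)], x_grid=FTIR_GRID)
        assert sk.short_range_order(up) / sk.short_range_order(base) == pytest.approx(1.10, abs=0.01)

    def test_known_ratio_encoded(self):
        # generator built to carry a corrected-intensity ratio of 0.72, the
        # value reported for gelatinized waxy maize amylopectin paste
        spec = sk.gen_spectrum([(1047.0, 0.72, 6.0), (1022.0, 1.0, 6.0)],
                               baseline=(0.001, 0.5), x_grid=FTIR_GRID)
        assert sk.short_range_order(spec) == pytest.approx(0.72, abs=0.02)

    def test_baseline_offset_invariant(self):
        flat = sk.gen_spectrum([(1047.0, 0.9, 6.0), (1022.0, 1.0, 6.0)], x_grid=FTIR_GRID)
        offset = Spectrum(x=flat.x, y=flat.y + 0.7)
        assert sk.short_range_order(offset) == pytest.approx(sk.short_range_order(flat), rel=1e-6)

    def test_window_not_covered(self):
        spec = sk.gen_spectrum([(1047.0, 1.0, 6.0)], x_grid=np.linspace(900, 1100, 300))
        with pytest.raises(ValueError, match="cover"):
            sk.short_range_order(spec)


class TestRelativeCrystallinity:
    def test_pure_halo_near_zero(self):
        halo = sk.gen_spectrum([(20.0, 1.0, 8.0)], x_grid=XRD_GRID)
        assert sk.relative_crystallinity(halo) <= 2.0

    def test_known_crystalline_fraction(self):
        # sharp Gaussian reflections placed to contribute exactly 23.7% of
        # the total area over a broad amorphous halo
        halo_area = 8.0 * np.sqrt(2 * np.pi) * (norm.cdf(20 / 8) - norm.cdf(-16 / 8))
        cryst_area = 0.237 / (1 - 0.237) * halo_area
        w = 0.25
        h_each = cryst_area / 4 / (w * np.sqrt(2 * np.pi))
        peaks = [(20.0, 1.0, 8.0)] + [(c, h_each, w) for c in (12.0, 17.1, 19.8, 26.5)]
        spec = sk.gen_spectrum(peaks, x_grid=XRD_GRID)
        assert sk.relative_crystallinity(spec) == pytest.approx(23.7, abs=1.0)

    def test_scale_invariant(self):
        peaks = [(20.0, 1.0, 8.0), (17.0, 1.5, 0.3)]
        spec = sk.gen_spectrum(peaks, x_grid=XRD_GRID)
        rc1 = sk.relative_crystallinity(spec)
        rc2 = sk.relative_crystallinity(Spectrum(x=spec.x, y=spec.y * 2.0))
        assert rc1 == pytest.approx(rc2, rel=1e-9)


class TestRoughness:
    def test_constant_map_zero(self):
        assert sk.rms_roughness(HeightMap(np.full((32, 32), 3.5))) == 0.0

    def test_checkerboard_unit(self):
        cb = (np.indices((64, 64)).sum(axis=0) % 2) * 2.0 - 1.0
        assert sk.rms_roughness(HeightMap(cb)) == pytest.approx(1.0)

    def test_generator_target(self):
        hmap = sk.gen_height_map(sk.HeightMapSpec(n_pixels=128, target_rq=8.01, seed=9))
        assert sk.rms_roughness(hmap) == pytest.approx(8.01, rel=1e-12)


class TestGLCM:
    def test_constant_map_limits(self):
        energy, contrast, homogeneity, entropy = sk.glcm_features(HeightMap(np.zeros((32, 32))))
        assert energy == 1.0 and contrast == 0.0
        assert homogeneity == 1.0 and entropy == pytest.approx(0.0, abs=1e-12)

    def test_checkerboard_hand_enumeration(self):
        # 2-level checkerboard, offset (0,1) only: every horizontal pair is
        # (0,1) or (1,0) -> P is 0.5/0.5 off-diagonal
        cb = (np.indices((64, 64)).sum(axis=0) % 2).astype(float)
        energy, contrast, homogeneity, entropy = sk.glcm_features(
            HeightMap(cb), levels=2, offsets=((0, 1),))
        assert contrast == pytest.approx(1.0)
        assert energy == pytest.approx(0.5)
        assert homogeneity == pytest.approx(0.5)
        assert entropy == pytest.approx(np.log(2.0))

    def test_probabilities_bounds(self):
        rng = np.random.default_rng(4)
        hmap = HeightMap(rng.normal(size=(64, 64)))
        energy, contrast, homogeneity, entropy = sk.glcm_features(hmap)
        assert 0.0 < energy <= 1.0
        assert 0.0 < homogeneity <= 1.0
        assert contrast >= 0.0 and entropy >= 0.0

    def test_entropy_maximal_for_uniform_cooccurrence(self):
        # any map's GLCM entropy is bounded by ln(levels²), attained only
        # by the uniform distribution
        rng = np.random.default_rng(5)
        hmap = HeightMap(rng.normal(size=(64, 64)))
        levels = 8
        _, _, _, entropy = sk.glcm_features(hmap, levels=levels)
        assert entropy < np.log(levels**2)

    def test_cross_check_against_skimage(self):
        # independent route: skimage's co-occurrence counts for one offset
        from skimage.feature import graycomatrix
        rng = np.random.default_rng(6)
        hmap = HeightMap(rng.normal(size=(48, 48)))
        levels = 8
        energy, contrast, homogeneity, entropy = sk.glcm_features(
            hmap, levels=levels, offsets=((0, 1),))
        quant = np.floor((hmap.heights - hmap.heights.min())
                         / np.ptp(hmap.heights) * levels).astype(np.uint8)
        quant = np.clip(quant, 0, levels - 1)
        glcm = graycomatrix(quant, [1], [0], levels=levels, symmetric=True, normed=True)
        P = glcm[:, :, 0, 0]
        i, j = np.indices((levels, levels))
        assert energy == pytest.approx(np.sum(P**2), rel=1e-9)
        assert contrast == pytest.approx(np.sum((i - j) ** 2 * P), rel=1e-9)

    def test_jitter_monotonicity(self):
        # rougher surfaces (shorter correlation length) must raise entropy
        # and contrast and lower energy and homogeneity
        smooth = sk.gen_height_map(sk.HeightMapSpec(n_pixels=128, target_rq=8.0,
                                                    corr_length=80.0, seed=2))
        rough = sk.gen_height_map(sk.HeightMapSpec(n_pixels=128, target_rq=8.0,
                                                   corr_length=10.0, seed=2))
        e_s, c_s, h_s, s_s = sk.glcm_features(smooth)
        e_r, c_r, h_r, s_r = sk.glcm_features(rough)
        assert c_r > c_s and s_r > s_s
        assert e_r < e_s and h_r < h_s


class TestBoxDimension:
    def test_tilted_plane_is_two(self):
        x = np.arange(256.0)
        plane = HeightMap(np.add.outer(0.3 * x, 0.1 * x))
        assert sk.box_fractal_dimension(plane) == pytest.approx(2.0, abs=0.05)

    def test_fbm_half_hurst(self):
        surface = sk.gen_fbm_surface(n_pixels=1024, hurst=0.5, seed=0)
        assert sk.box_fractal_dimension(surface) == pytest.approx(2.5, abs=0.15)

    def test_offset_invariant(self):
        surface = sk.gen_fbm_surface(n_pixels=256, hurst=0.5, seed=3)
        d1 = sk.box_fractal_dimension(surface)
        d2 = sk.box_fractal_dimension(HeightMap(surface.heights + 100.0))
        assert d1 == pytest.approx(d2, rel=1e-9)

    def test_flat_map_convention(self):
        with pytest.warns(UserWarning, match="flat"):
            assert sk.box_fractal_dimension(HeightMap(np.zeros((128, 128)))) == 2.0


class TestTextureSuite:
    def test_constant_map_all_limits(self):
        res = sk.texture_suite(HeightMap(np.zeros((64, 64))))
        assert (res.energy, res.contrast, res.homogeneity) == (1.0, 0.0, 1.0)
        assert res.entropy == pytest.approx(0.0, abs=1e-12)
        assert res.Rq == 0.0
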