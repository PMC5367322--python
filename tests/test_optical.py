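"""Spectral indices, tasseled cap, GLCM textures and terrain layers."""

import numpy as np
import pytest

from firecarb.optical import (BAND_NAMES, TASSELED_CAP_OLI, block_mean,
                              build_feature_stack, glcm_textures, quantize,
                              tasseled_cap, terrain_features,
                              vegetation_indices)


def stack_from(values):
    return {name: np.full((2, 2), v) for name, v in zip(BAND_NAMES, values)}


class TestVegetationIndices:
    def test_ndvi_formula(self):
        s = stack_from([0.05, 0.08, 0.1, 0.4, 0.2, 0.15])
        idx = vegetation_indices(s)
        assert idx["NDVI"][0, 0] == pytest.approx((0.4 - 0.1) / (0.4 + 0.1))

    def test_ndii_zero_when_nir_equals_swir(self):
        s = stack_from([0.05, 0.08, 0.1, 0.2, 0.2, 0.15])
        assert vegetation_indices(s)["NDII"][0, 0] == pytest.approx(0.0)

    def test_zero_denominator_is_nodata(self):
        s = stack_from([0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        assert np.isnan(vegetation_indices(s)["NDVI"][0, 0])

    def test_bounded_on_random_stacks(self, rng):
        s = {n: rng.random((8, 8)) for n in BAND_NAMES}
        ndvi = vegetation_indices(s)["NDVI"]
        assert np.nanmin(ndvi) >= -1.0 - 1e-12
        assert np.nanmax(ndvi) <= 1.0 + 1e-12


class TestTasseledCap:
    def test_zero_reflectance_gives_zero_components(self):
        s = stack_from([0.0] * 6)
        tc = tasseled_cap(s)
        for k in tc:
            assert np.all(tc[k][np.isfinite(tc[k])] == 0.0) or k == "TC_angle"
        assert tc["TC_distance"][0, 0] == 0.0

    def test_scaling_bands_scales_components_but_not_angle(self, rng):
        vals = rng.random(6) * 0.4 + 0.05
        a = tasseled_cap(stack_from(vals))
        b = tasseled_cap(stack_from(3.0 * vals))
        for k in ("TC_brightness", "TC_greenness", "TC_wetness"):
            assert b[k][0, 0] == pytest.approx(3.0 * a[k][0, 0])
        assert b["TC_angle"][0, 0] == pytest.approx(a["TC_angle"][0, 0])

    def test_basis_vectors_reproduce_coefficient_table(self):
        for j in range(6):
            vals = np.zeros(6)
            vals[j] = 1.0
            tc = tasseled_cap(stack_from(vals))
            assert tc["TC_brightness"][0, 0] == pytest.approx(TASSELED_CAP_OLI[0, j])
            assert tc["TC_greenness"][0, 0] == pytest.approx(TASSELED_CAP_OLI[1, j])
            assert tc["TC_wetness"][0, 0] == pytest.approx(TASSELED_CAP_OLI[2, j])


def oracle_glcm(win, levels):
    """Hand-counted symmetric isotropic co-occurrence matrix of one window."""
    P = np.zeros((levels, levels))
    rows, cols = win.shape
    offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]  # E, NE, N, NW at dist 1
    for dr, dc in offsets:
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    P[win[r, c], win[r2, c2]] += 1
                    P[win[r2, c2], win[r, c]] += 1
    return P / P.sum()


class TestGLCM:
    def test_constant_window_degenerate_values(self):
        band = np.ones((5, 5))
        tex = glcm_textures(band, window=3, levels=8)
        assert np.allclose(tex["contrast"], 0.0)
        assert np.allclose(tex["asm"], 1.0)
        assert np.allclose(tex["entropy"], 0.0)
        assert np.allclose(tex["homogeneity"], 1.0)
        assert np.allclose(tex["correlation"], 0.0)

    def test_stripes_maximize_isotropic_contrast_among_two_level_patterns(
            self, rng):
        # under the isotropic (four-offset) co-occurrence average the
        # striped pattern beats every other two-level window, including the
        # checkerboard, whose diagonal neighbors are equal
        levels = 2
        i, j = np.meshgrid(range(levels), range(levels), indexing="ij")

        def contrast(win):
            return float((oracle_glcm(win, levels) * (i - j) ** 2).sum())

        stripes = (np.indices((5, 5))[0]) % 2
        checker = np.indices((5, 5)).sum(axis=0) % 2
        best_random = max(contrast(rng.integers(0, 2, size=(5, 5)))
                          for _ in range(300))
        assert contrast(stripes) >= max(best_random, contrast(checker))
        assert contrast(stripes) > contrast(checker)

    def test_matches_bruteforce_oracle_on_toy_raster(self, rng):
        band = rng.random((12, 12))
        levels = 8
        window = 5
        tex = glcm_textures(band, window=window, levels=levels)
        q = quantize(band, levels)
        pad = window // 2
        qp = np.pad(q, pad, mode="reflect")
        for r, c in [(0, 0), (3, 7), (11, 11), (6, 2)]:
            win = qp[r:r + window, c:c + window].astype(int)
            P = oracle_glcm(win, levels)
            i, j = np.meshgrid(range(levels), range(levels), indexing="ij")
            assert tex["contrast"][r, c] == pytest.approx(
                float((P * (i - j) ** 2).sum()))
            assert tex["asm"][r, c] == pytest.approx(float((P**2).sum()))
            nz = P[P > 0]
            assert tex["entropy"][r, c] == pytest.approx(
                float(-(nz * np.log(nz)).sum()))
            assert tex["homogeneity"][r, c] == pytest.approx(
                float((P / (1 + (i - j) ** 2)).sum()))


class TestTerrain:
    def test_flat_dem_zero_slope_nodata_aspect(self):
        t = terrain_features(np.full((6, 6), 500.0))
        assert np.allclose(t["slope"], 0.0)
        assert np.all(np.isnan(t["aspect"]))

    def test_planar_ramp_constant_analytic_slope(self):
        cell = 30.0
        rows, cols = np.indices((8, 8))
        dem = 1000.0 + 3.0 * cols * cell  # dz/dx = 3
        t = terrain_features(dem, cell_size_m=cell)
        inner = t["slope"][1:-1, 1:-1]
        assert np.allclose(inner, np.degrees(np.arctan(3.0)), atol=1e-9)
        # ramp rises eastward -> downslope aspect is west
        assert np.allclose(t["aspect"][1:-1, 1:-1], 270.0)

    def test_block_mean_of_constant_blocks(self):
        fine = np.kron(np.array([[1.0, 2.0], [3.0, 4.0]]), np.ones((30, 30)))
        out = block_mean(fine, 30)
        np.testing.assert_allclose(out, [[1.0, 2.0], [3.0, 4.0]])


def test_feature_stack_names_complete(rng):
    refl = rng.random((6, 5, 5)) * 0.5
    dem = rng.random((5, 5)) * 1000
    stack = build_feature_stack(refl, dem)
    for name in ("B2", "B7", "NDVI", "NDII", "EVI", "VARI", "TC_wetness",
                 "TC_angle", "TC_distance", "elevation", "slope", "aspect"):
        assert name in stack
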