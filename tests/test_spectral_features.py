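"""Topographic correction, band math, GLCM textures, PCA, plot sampling."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from forestagb import spectral_features as sf
from forestagb.spectral_features import (RasterStack, TopoIllumination,
                                         band_combinations, estimate_c,
                                         extract_plot_features, glcm_stats,
                                         glcm_texture, pca_transform,
                                         quantize, read_ascii_grid,
                                         scs_c_correction,
                                         vegetation_indices, window_glcm,
                                         write_ascii_grid)


def stack_from(values: dict, cell=30.0):
    shape = next(iter(values.values())).shape
    return RasterStack({k: np.asarray(v, float) for k, v in values.items()},
                       0.0, shape[0] * cell, cell)


def full_stack(rng, shape=(8, 8)):
    return stack_from({b: rng.uniform(0.01, 0.6, shape) for b in sf.BAND_NAMES})


class TestScsC:
    def test_flat_terrain_is_identity(self, rng):
        stack = full_stack(rng)
        topo = TopoIllumination(np.zeros((8, 8)), solar_zenith=0.6)
        out = scs_c_correction(stack, topo)
        for b in sf.BAND_NAMES:
            np.testing.assert_allclose(out.bands[b], stack.bands[b],
                                       rtol=1e-12)

    def test_c_recovered_from_synthetic_linear_band(self, rng):
        # L = 0.4 cos(i) + 0.1  =>  C = b/m = 0.25 exactly
        slope = rng.uniform(0, 0.5, (10, 10))
        aspect = rng.uniform(0, 2 * np.pi, (10, 10))
        topo = TopoIllumination(slope, solar_zenith=0.78, solar_azimuth=2.7,
                                aspect=aspect)
        band = 0.4 * topo.cos_i + 0.1
        assert estimate_c(band, topo.cos_i) == pytest.approx(0.25, rel=1e-9)

    def test_large_c_limit_is_identity(self, rng):
        slope = rng.uniform(0, 0.4, (6, 6))
        stack = full_stack(rng, (6, 6))
        topo = TopoIllumination(slope, solar_zenith=0.7,
                                c={b: 1e9 for b in sf.BAND_NAMES})
        out = scs_c_correction(stack, topo)
        for b in sf.BAND_NAMES:
            np.testing.assert_allclose(out.bands[b], stack.bands[b],
                                       rtol=1e-6)

    def test_flat_terrain_preserves_band_mean(self, rng):
        stack = full_stack(rng)
        topo = TopoIllumination(np.zeros((8, 8)), solar_zenith=0.5)
        out = scs_c_correction(stack, topo)
        for b in sf.BAND_NAMES:
            assert out.bands[b].mean() == pytest.approx(
                stack.bands[b].mean(), rel=1e-12)


class TestBandMath:
    def test_combination_identities(self, rng):
        base = {b: rng.uniform(0.1, 0.5, (4, 4)) for b in sf.BAND_NAMES}
        base["B2"] = np.zeros((4, 4))
        base["B7"] = base["B5"]
        base["B3"] = base["B5"] + base["B6"]
        combos = band_combinations(stack_from(base))
        np.testing.assert_allclose(combos["MVI5"], 1.0)  # B2 = 0
        np.testing.assert_allclose(combos["MVI7"], 0.0)  # B5 = B7
        np.testing.assert_allclose(combos["ND563"], 0.0)  # B5+B6 = B3

    def test_nd563_product_variant(self, rng):
        base = {b: rng.uniform(0.1, 0.5, (3, 3)) for b in sf.BAND_NAMES}
        combos = band_combinations(stack_from(base), nd563_product=True)
        expected = ((base["B5"] + base["B6"] - base["B3"])
                    * (base["B5"] + base["B6"] + base["B3"]))
        np.testing.assert_allclose(combos["ND563"], expected, rtol=1e-12)

    def test_ten_combinations_and_bounded_nd(self, rng):
        combos = band_combinations(full_stack(rng))
        assert len(combos) == 10
        for name in ("MVI5", "MVI7", "ND67"):
            v = combos[name]
            assert np.nanmax(np.abs(v)) <= 1.0 + 1e-12

    def test_vegetation_index_cases(self, rng):
        base = {b: rng.uniform(0.1, 0.5, (4, 4)) for b in sf.BAND_NAMES}
        base["B4"] = base["B5"].copy()
        vi = vegetation_indices(stack_from(base))
        assert len(vi) == 15
        np.testing.assert_allclose(vi["NDVI"], 0.0, atol=1e-12)  # B5 = B4
        base["B4"] = np.zeros((4, 4))
        vi = vegetation_indices(stack_from(base))
        np.testing.assert_allclose(vi["NDVI"], 1.0)  # B4 = 0, B5 > 0

    def test_evi_scalar_oracle(self, rng):
        base = {b: rng.uniform(0.05, 0.5, (3, 3)) for b in sf.BAND_NAMES}
        vi = vegetation_indices(stack_from(base))
        nir, red, blue = base["B5"][1, 1], base["B4"][1, 1], base["B2"][1, 1]
        expected = 2.5 * (nir - red) / (nir + 6 * red - 7.5 * blue + 1)
        assert vi["EVI"][1, 1] == pytest.approx(expected, rel=1e-12)


def brute_force_glcm(patch, levels):
    """Enumerate all symmetric pixel pairs over the four unit offsets."""
    m = np.zeros((levels, levels))
    nr, nc = patch.shape
    for dr, dc in [(0, 1), (1, 1), (1, 0), (1, -1)]:
        for r in range(nr):
            for c in range(nc):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nr and 0 <= c2 < nc:
                    m[patch[r, c], patch[r2, c2]] += 1
                    m[patch[r2, c2], patch[r, c]] += 1
    return m / m.sum()


class TestGlcm:
    def test_constant_window(self):
        tex = glcm_texture(np.full((5, 5), 3.14), window=3, levels=8)
        np.testing.assert_allclose(tex["Entr"], 0.0, atol=1e-12)
        np.testing.assert_allclose(tex["Homo"], 1.0)
        np.testing.assert_allclose(tex["Cont"], 0.0)

    def test_checkerboard_entropy_all_directions(self):
        """2-level checkerboard: brute-force pair enumeration oracle."""
        patch = (np.indices((5, 5)).sum(axis=0) % 2).astype(np.uint16)
        p_mine = window_glcm(patch, levels=2)
        p_oracle = brute_force_glcm(patch, 2)
        np.testing.assert_allclose(p_mine, p_oracle, atol=1e-12)
        ent = glcm_stats(p_mine)["Entr"]
        nz = p_oracle[p_oracle > 0]
        assert ent == pytest.approx(float(-(nz * np.log(nz)).sum()), rel=1e-12)

    def test_checkerboard_horizontal_entropy_is_log2(self):
        # restricted to the horizontal direction every pair is (0,1)/(1,0)
        patch = (np.indices((4, 4)).sum(axis=0) % 2)
        m = np.zeros((2, 2))
        for r in range(4):
            for c in range(3):
                m[patch[r, c], patch[r, c + 1]] += 1
                m[patch[r, c + 1], patch[r, c]] += 1
        p = m / m.sum()
        assert glcm_stats(p)["Entr"] == pytest.approx(math.log(2), rel=1e-12)

    def test_random_windows_match_bruteforce(self, rng):
        for _ in range(20):
            patch = rng.integers(0, 8, size=(3, 3)).astype(np.uint16)
            np.testing.assert_allclose(window_glcm(patch, 8),
                                       brute_force_glcm(patch, 8), atol=1e-12)

    def test_entropy_invariant_under_level_relabeling(self, rng):
        patch = rng.integers(0, 6, size=(4, 4)).astype(np.uint16)
        perm = rng.permutation(6).astype(np.uint16)
        e1 = glcm_stats(window_glcm(patch, 6))["Entr"]
        e2 = glcm_stats(window_glcm(perm[patch], 6))["Entr"]
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_window_exceeding_raster_rejected(self):
        with pytest.raises(ValueError, match="window"):
            glcm_texture(np.zeros((2, 2)), window=3)


class TestPca:
    def test_single_varying_band(self, rng):
        sig = rng.normal(size=(6, 6))
        bands = {b: np.full((6, 6), 0.2) for b in sf.BAND_NAMES}
        bands["B5"] = 0.2 + sig
        with pytest.warns(UserWarning, match="rank"):
            pcs, evr = pca_transform(stack_from(bands), 3)
        assert len(pcs) == 1
        assert evr[0] == pytest.approx(1.0)
        # PC1 is B5 up to centering, positive orientation
        r = np.corrcoef(pcs["PC1"].ravel(), sig.ravel())[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_explained_variance_nonincreasing(self, rng):
        _, evr = pca_transform(full_stack(rng, (10, 10)), 3)
        assert (np.diff(evr) <= 1e-12).all()

    def test_two_band_eigenvalues_closed_form(self, rng):
        a = rng.normal(size=400)
        b = 0.6 * a + rng.normal(scale=0.5, size=400)
        bands = {"B1": a.reshape(20, 20), "B2": b.reshape(20, 20)}
        _, evr = pca_transform(stack_from(bands), 2)
        cov = np.cov(np.stack([a, b]), ddof=1)
        tr, det = cov.trace(), np.linalg.det(cov)
        lam1 = (tr + math.sqrt(tr**2 - 4 * det)) / 2
        lam2 = (tr - math.sqrt(tr**2 - 4 * det)) / 2
        np.testing.assert_allclose(evr, [lam1 / tr, lam2 / tr], rtol=1e-9)


class TestPlotSampling:
    def test_constant_raster_both_modes(self):
        grid = np.full((4, 4), 5.5)
        stack = stack_from({"F": grid})
        plots = pd.DataFrame({"plot_id": ["p1"], "x": [45.0], "y": [61.0]})
        for mode in ("center", "area"):
            t = extract_plot_features({"F": grid}, stack, plots, mode=mode)
            assert t["F"][0] == pytest.approx(5.5)

    def test_area_weights_on_straddle(self):
        # 20x30 plot centered on the boundary x=30 between two columns:
        # half the area in each column
        grid = np.array([[1.0, 3.0]])
        stack = RasterStack({"F": grid}, 0.0, 30.0, 30.0)
        plots = pd.DataFrame({"plot_id": ["p"], "x": [30.0], "y": [15.0]})
        t = extract_plot_features({"F": grid}, stack, plots, mode="area")
        assert t["F"][0] == pytest.approx(0.5 * 1.0 + 0.5 * 3.0)

    def test_plot_outside_extent_names_plot(self):
        stack = stack_from({"F": np.zeros((2, 2))})
        plots = pd.DataFrame({"plot_id": ["lost"], "x": [1e6], "y": [0.0]})
        with pytest.raises(ValueError, match="lost"):
            extract_plot_features({"F": stack.bands["F"]}, stack, plots)


def test_ascii_grid_roundtrip(tmp_path, rng):
    grid = rng.normal(size=(5, 7))
    grid[0, 0] = np.nan
    path = tmp_path / "g.asc"
    write_ascii_grid(path, grid, 10.0, 20.0, 30.0)
    back, x_min, y_min, cell = read_ascii_grid(path)
    assert (x_min, y_min, cell) == (10.0, 20.0, 30.0)
    np.testing.assert_allclose(back[1:], grid[1:], rtol=1e-6)
    assert np.isnan(back[0, 0])
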