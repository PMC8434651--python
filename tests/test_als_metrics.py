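"""Point-cloud preprocessing and the ALS metric families against
brute-force oracles."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import random_cloud
from forestagb import als_metrics as am
from forestagb.als_metrics import (DtmGrid, clip_plot, density_metrics,
                                   elevation_metrics, extract_all_metrics,
                                   forest_metrics, intensity_metrics,
                                   interpolate_dtm_idw, normalize_heights,
                                   remove_noise)


def make_cloud(x, y, z, intensity=None, rn=None, cls=None):
    n = len(x)
    return pd.DataFrame({
        "x": np.asarray(x, float), "y": np.asarray(y, float),
        "z": np.asarray(z, float),
        "intensity": np.ones(n) if intensity is None else np.asarray(intensity, float),
        "return_number": np.ones(n, int) if rn is None else np.asarray(rn, int),
        "classification": np.ones(n, int) if cls is None else np.asarray(cls, int),
    })


class TestRemoveNoise:
    def test_coplanar_points_all_kept(self, rng):
        x = rng.uniform(0, 2, 200)
        y = rng.uniform(0, 2, 200)
        cloud = make_cloud(x, y, 0.3 * x + 0.1 * y + 5.0)
        out = remove_noise(cloud)
        assert (out["classification"] != am.CLASS_NOISE).all()

    def test_air_point_removed(self, rng):
        # dense planar cloud + a single return 100 m above it
        x = rng.uniform(0, 2, 300)
        y = rng.uniform(0, 2, 300)
        z = 0.05 * x + 0.02 * y
        cloud = make_cloud(np.append(x, 1.0), np.append(y, 1.0),
                           np.append(z, 100.0))
        out = remove_noise(cloud)
        assert out["classification"].iloc[-1] == am.CLASS_NOISE
        assert (out["classification"].iloc[:-1] != am.CLASS_NOISE).all()

    def test_isolated_point_kept_with_warning(self):
        cloud = make_cloud([0, 50], [0, 50], [0, 10])
        with pytest.warns(UserWarning, match="neighbours"):
            out = remove_noise(cloud)
        assert (out["classification"] != am.CLASS_NOISE).all()

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            remove_noise(make_cloud([], [], []))


class TestIdwDtm:
    def test_constant_elevation(self, rng):
        g = make_cloud(rng.uniform(0, 10, 50), rng.uniform(0, 10, 50),
                       np.full(50, 7.0))
        dtm = interpolate_dtm_idw(g)
        assert np.allclose(dtm.values, 7.0)

    def test_cell_center_on_ground_point_exact(self):
        # single cell with center (0.25, 0.25); one point exactly there
        g = make_cloud([0.25, 0.4], [0.25, 0.1], [3.0, 9.0])
        dtm = interpolate_dtm_idw(g, cell=0.5, k=2,
                                  bounds=(0.0, 0.0, 0.5, 0.5))
        assert dtm.values[0, 0] == 3.0

    def test_three_point_hand_computed_idw(self):
        # one cell with center at (0.25, 0.25); three ground points with
        # known distances
        pts_x = [0.25 + 1.0, 0.25, 0.25 - 2.0]
        pts_y = [0.25, 0.25 + 2.0, 0.25]
        z = [10.0, 20.0, 40.0]
        g = make_cloud(pts_x, pts_y, z)
        dtm = interpolate_dtm_idw(g, cell=0.5, k=3,
                                  bounds=(0.0, 0.0, 0.5, 0.5))
        w = np.array([1.0 ** -2, 2.0 ** -2, 2.0 ** -2])  # distances 1, 2, 2
        expected = (w * np.array(z)).sum() / w.sum()
        assert dtm.values[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_no_ground_points(self):
        with pytest.raises(ValueError, match="ground"):
            interpolate_dtm_idw(make_cloud([], [], []))


class TestNormalize:
    def test_flat_dtm_subtraction(self):
        dtm = DtmGrid(np.full((4, 4), 7.0), 0.0, 0.0, 1.0)
        cloud = make_cloud([2.0], [2.0], [10.0])
        out = normalize_heights(cloud, dtm)
        assert out["z"][0] == pytest.approx(3.0)

    def test_ground_returns_near_zero_after_normalization(self, rng):
        x = rng.uniform(0, 10, 400)
        y = rng.uniform(0, 10, 400)
        z = 5.0 + 0.2 * x  # sloped ground
        g = make_cloud(x, y, z, cls=np.full(400, 2))
        dtm = interpolate_dtm_idw(g, cell=0.5, bounds=(0, 0, 10, 10))
        out = normalize_heights(g, dtm)
        assert np.abs(out["z"]).max() < 0.25  # cell-scale tolerance

    def test_bilinear_matches_bruteforce(self, rng):
        vals = rng.normal(size=(6, 5))
        dtm = DtmGrid(vals, 0.0, 0.0, 2.0)
        xs = rng.uniform(1.0, 8.9, 40)  # interior of the cell-center lattice
        ys = rng.uniform(1.0, 10.9, 40)
        got = dtm.sample_bilinear(xs, ys)
        for x, y, g in zip(xs, ys, got):
            fx = x / 2.0 - 0.5
            fy = y / 2.0 - 0.5
            j0, i0 = int(math.floor(fx)), int(math.floor(fy))
            tx, ty = fx - j0, fy - i0
            exp = ((1 - tx) * (1 - ty) * vals[i0, j0]
                   + tx * (1 - ty) * vals[i0, j0 + 1]
                   + (1 - tx) * ty * vals[i0 + 1, j0]
                   + tx * ty * vals[i0 + 1, j0 + 1])
            assert g == pytest.approx(exp, rel=1e-12)

    def test_outside_extent_rejected(self):
        dtm = DtmGrid(np.zeros((2, 2)), 0.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="outside"):
            normalize_heights(make_cloud([5.0], [0.5], [1.0]), dtm)


class TestElevationMetrics:
    def test_simple_mean(self):
        m = elevation_metrics(make_cloud([0] * 3, [0] * 3, [3, 4, 5]))
        assert m["elev_mean"] == pytest.approx(4.0)

    def test_constant_heights_zero_cv(self):
        m = elevation_metrics(make_cloud([0] * 5, [0] * 5, [6] * 5))
        assert m["elev_cv"] == 0.0

    def test_percentile_matches_sort_oracle(self, rng):
        z = rng.uniform(2, 30, 1000)
        m = elevation_metrics(make_cloud(np.zeros(1000), np.zeros(1000), z))
        # linear interpolation between closest ranks
        zs = np.sort(z)
        h = (z.size - 1) * 0.60
        lo = int(math.floor(h))
        expected = zs[lo] + (h - lo) * (zs[lo + 1] - zs[lo])
        assert m["elev_p60"] == pytest.approx(expected, rel=1e-12)

    def test_no_returns_above_threshold_warns_nan(self):
        with pytest.warns(UserWarning, match="threshold"):
            m = elevation_metrics(make_cloud([0], [0], [1.0]))
        assert math.isnan(m["elev_mean"])


class TestDensityMetrics:
    def test_partition_sums_to_one(self, rng):
        cloud = random_cloud(rng, 500)
        d = density_metrics(cloud)
        assert sum(d.values()) == pytest.approx(1.0)

    def test_degenerate_span(self):
        d = density_metrics(make_cloud([0] * 4, [0] * 4, [2.0] * 4))
        assert d["density_1"] == 1.0
        assert sum(d.values()) == 1.0

    def test_uniform_heights_hit_each_decile(self, rng):
        # pin the span so the slice boundaries are deterministic
        z = np.append(rng.uniform(2, 22, 9999), 22.0)
        d = density_metrics(make_cloud(np.zeros(z.size), np.zeros(z.size), z))
        se = math.sqrt(0.1 * 0.9 / z.size)
        for i in range(1, 11):
            assert abs(d[f"density_{i}"] - 0.1) < 3 * se + 1e-4


class TestIntensityMetrics:
    def test_max_and_half_mass(self):
        m = intensity_metrics(make_cloud([0, 0], [0, 0], [3, 4], [10, 20]))
        assert m["int_max"] == 20.0
        m2 = intensity_metrics(make_cloud([0, 0], [0, 0], [3, 4], [5, 5]))
        assert m2["int_AII_50th"] == pytest.approx(0.5)

    def test_aii_matches_sort_oracle(self, rng):
        cloud = random_cloud(rng, 700, ground_frac=0.0)
        m = intensity_metrics(cloud)
        z = cloud["z"].to_numpy()
        inten = cloud["intensity"].to_numpy()
        keep = z >= 2.0
        z, inten = z[keep], inten[keep]
        order = np.argsort(z, kind="stable")
        k = 40
        mcount = math.ceil(k * z.size / 100)
        expected = inten[order][:mcount].sum() / inten.sum()
        assert m["int_AII_40th"] == pytest.approx(expected, rel=1e-12)
        assert m["int_AII_100th"] == pytest.approx(1.0)

    def test_aii_monotone_in_k(self, rng):
        cloud = random_cloud(rng, 300)
        m = intensity_metrics(cloud)
        ks = list(am.PERCENTILE_KS) + [100]
        vals = [m[f"int_AII_{k}th"] for k in ks]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_zero_total_intensity(self):
        with pytest.warns(UserWarning, match="intensity"):
            m = intensity_metrics(make_cloud([0, 0], [0, 0], [3, 4], [0, 0]))
        assert math.isnan(m["int_AII_50th"])


class TestForestMetrics:
    def test_gap_fraction_ratio(self):
        z = np.concatenate([np.full(30, 0.5), np.full(70, 10.0)])
        m = forest_metrics(make_cloud(np.zeros(100), np.zeros(100), z))
        assert m["gap_fraction"] == pytest.approx(0.3)
        # exact complement identity
        assert m["gap_fraction"] + 0.7 == pytest.approx(1.0)

    def test_full_canopy_cover(self):
        m = forest_metrics(make_cloud([0] * 4, [0] * 4, [5.0] * 4,
                                      rn=[1, 1, 2, 1]))
        assert m["canopy_cover"] == 1.0

    def test_no_canopy_lai_zero(self):
        m = forest_metrics(make_cloud([0] * 4, [0] * 4, [0.1] * 4))
        assert m["gap_fraction"] == 1.0
        assert m["lai"] == pytest.approx(0.0)

    def test_zero_gap_lai_nan(self):
        with pytest.warns(UserWarning, match="gap"):
            m = forest_metrics(make_cloud([0] * 4, [0] * 4, [5.0] * 4))
        assert math.isnan(m["lai"])


class TestExtractAll:
    def test_row_per_plot_and_order_invariance(self, rng):
        clouds = {f"p{i}": random_cloud(rng, 200) for i in range(5)}
        t1 = extract_all_metrics(clouds)
        t2 = extract_all_metrics(dict(reversed(list(clouds.items()))))
        assert len(t1) == 5
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_plot_set(self):
        t = extract_all_metrics({})
        assert len(t) == 0
        assert list(t.columns) == ["plot_id"] + am.metric_names()

    def test_translation_invariance(self, rng):
        """Shifting raw z and the DTM by a constant leaves metrics
        unchanged."""
        cloud = random_cloud(rng, 400)
        dtm0 = DtmGrid(np.zeros((40, 60)), 0.0, 0.0, 1.0)
        dtm1 = DtmGrid(np.full((40, 60), 123.0), 0.0, 0.0, 1.0)
        shifted = cloud.copy()
        shifted["z"] = cloud["z"] + 123.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m0 = am.all_metrics(normalize_heights(cloud, dtm0))
            m1 = am.all_metrics(normalize_heights(shifted, dtm1))
        for k in m0:
            assert m0[k] == pytest.approx(m1[k], rel=1e-9, nan_ok=True), k


def test_clip_plot_half_open_edges():
    cloud = make_cloud([-10.0, 9.999, 10.0, 0.0], [0.0, 0.0, 0.0, 15.0],
                       [1, 2, 3, 4])
    out = clip_plot(cloud, 0.0, 0.0, 20.0, 30.0)
    # x = -10 kept (min edge closed), x = 10 dropped, y = 15 dropped
    assert list(out["z"]) == [1.0, 2.0]
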