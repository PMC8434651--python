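"""Point-cloud preprocessing and area-based ALS plot metrics.

Pipeline order: noise removal (plane-fit outlier test), ground-point DTM by
inverse-distance-weighted interpolation (0.5 m cells, power 2, 12 nearest
points), height normalization (z minus bilinear DTM), then the four plot
metric families over normalized returns at or above a 2 m height threshold:

* elevation metrics — mean, dispersion, shape and height percentiles;
* density metrics — the proportion of above-threshold returns in each of ten
  equal height slices between the threshold and the maximum height;
* intensity metrics — order statistics of return intensity plus the AII
  family, the cumulative intensity share of the lowest k % of returns by
  height;
* forest metrics — gap fraction (returns below threshold / all returns),
  canopy cover (first returns at/above threshold / all first returns) and a
  Beer-Lambert leaf area index, LAI = -cos(scan angle) ln(gap)/k.

Percentiles use linear interpolation between closest ranks throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.spatial import cKDTree

from .synthetic_scene import CLASS_DEFAULT, CLASS_GROUND, CLASS_NOISE

__all__ = [
    "DtmGrid",
    "remove_noise",
    "classify_ground_simple",
    "interpolate_dtm_idw",
    "normalize_heights",
    "clip_plot",
    "elevation_metrics",
    "density_metrics",
    "intensity_metrics",
    "forest_metrics",
    "all_metrics",
    "extract_all_metrics",
    "metric_names",
    "PERCENTILE_KS",
]

#: percentile levels used for elevation/intensity order statistics and for
#: the cumulative-intensity (AII) family
PERCENTILE_KS = (1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50,
                 55, 60, 65, 70, 75, 80, 85, 90, 95, 99)

HEIGHT_THRESHOLD_M = 2.0


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def remove_noise(cloud: pd.DataFrame, radius: float = 0.5,
                 sd_multiplier: float = 1.0) -> pd.DataFrame:
    """Plane-fit outlier removal.

    For each point, a least-squares plane is fitted to its neighbours within
    ``radius`` (horizontal distance).  The point is kept iff its vertical
    distance to that plane is at most ``max(sd_multiplier * SD, eps)`` where
    SD is the standard deviation of the neighbours' distances to the plane
    (the epsilon keeps exactly coplanar neighbourhoods, whose SD is zero).
    Points with fewer than three neighbours are kept.  Flagged points get
    classification 7 (noise); downstream metrics exclude them.
    """
    if len(cloud) == 0:
        raise ValueError("empty point cloud")
    xy = cloud[["x", "y"]].to_numpy()
    z = cloud["z"].to_numpy()
    tree = cKDTree(xy)
    cls = cloud["classification"].to_numpy().copy()
    eps = 1e-9
    n_kept_isolated = 0
    for i in range(len(cloud)):
        idx = tree.query_ball_point(xy[i], radius)
        idx = [j for j in idx if j != i]
        if len(idx) < 3:
            n_kept_isolated += 1
            continue
        A = np.column_stack([xy[idx], np.ones(len(idx))])
        coef, *_ = np.linalg.lstsq(A, z[idx], rcond=None)
        resid = z[idx] - A @ coef
        sd = float(resid.std())
        dist = abs(z[i] - (coef[0] * xy[i, 0] + coef[1] * xy[i, 1] + coef[2]))
        if dist > max(sd_multiplier * sd, eps):
            cls[i] = CLASS_NOISE
    if n_kept_isolated:
        warnings.warn(
            f"noise filter: {n_kept_isolated} points kept with <3 neighbours"
            " (insufficient plane support)", stacklevel=2,
        )
    out = cloud.copy()
    out["classification"] = cls
    return out


def classify_ground_simple(cloud: pd.DataFrame, grid_m: float = 2.0,
                           height_tol_m: float = 0.3) -> pd.DataFrame:
    """Simple lowest-point ground labelling for unlabelled clouds.

    Marks as ground every non-noise point within ``height_tol_m`` of the
    lowest point of its ``grid_m`` cell.  A coarse fallback, not a
    progressive-densification filter; synthetic clouds arrive pre-labelled.
    """
    out = cloud.copy()
    live = out["classification"].to_numpy() != CLASS_NOISE
    gx = np.floor(out["x"].to_numpy() / grid_m).astype(int)
    gy = np.floor(out["y"].to_numpy() / grid_m).astype(int)
    z = out["z"].to_numpy()
    lowest: dict[tuple[int, int], float] = {}
    for i in np.flatnonzero(live):
        key = (gx[i], gy[i])
        if key not in lowest or z[i] < lowest[key]:
            lowest[key] = z[i]
    cls = out["classification"].to_numpy().copy()
    for i in np.flatnonzero(live):
        cls[i] = (CLASS_GROUND if z[i] - lowest[(gx[i], gy[i])] <= height_tol_m
                  else CLASS_DEFAULT)
    out["classification"] = cls
    return out


@dataclass
class DtmGrid:
    """Regular ground-elevation grid; cell (i, j) center at
    (x_min + (j+0.5) cell, y_min + (i+0.5) cell), row 0 southernmost."""

    values: np.ndarray
    x_min: float
    y_min: float
    cell: float

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def x_max(self) -> float:
        return self.x_min + self.values.shape[1] * self.cell

    @property
    def y_max(self) -> float:
        return self.y_min + self.values.shape[0] * self.cell

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return ((x >= self.x_min) & (x <= self.x_max)
                & (y >= self.y_min) & (y <= self.y_max))

    def sample_bilinear(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear interpolation between cell centers, clamped at borders."""
        v = self.values
        nrow, ncol = v.shape
        fx = (np.asarray(x) - self.x_min) / self.cell - 0.5
        fy = (np.asarray(y) - self.y_min) / self.cell - 0.5
        fx = np.clip(fx, 0, ncol - 1)
        fy = np.clip(fy, 0, nrow - 1)
        j0 = np.clip(np.floor(fx).astype(int), 0, ncol - 1)
        i0 = np.clip(np.floor(fy).astype(int), 0, nrow - 1)
        j1 = np.minimum(j0 + 1, ncol - 1)
        i1 = np.minimum(i0 + 1, nrow - 1)
        tx = fx - j0
        ty = fy - i0
        return ((1 - tx) * (1 - ty) * v[i0, j0] + tx * (1 - ty) * v[i0, j1]
                + (1 - tx) * ty * v[i1, j0] + tx * ty * v[i1, j1])


def interpolate_dtm_idw(ground: pd.DataFrame, cell: float = 0.5,
                        power: float = 2.0, k: int = 12,
                        bounds: tuple[float, float, float, float] | None = None
                        ) -> DtmGrid:
    """IDW interpolation of ground returns onto a regular grid.

    Each cell takes the inverse-distance-power weighted mean of its ``k``
    nearest ground points; a cell center coinciding with a ground point
    (d < 1e-9) takes that point's elevation exactly.  ``bounds`` (x_min,
    y_min, x_max, y_max) overrides the default extent (the ground bbox).
    """
    if len(ground) == 0:
        raise ValueError("no ground returns: cannot interpolate a DTM")
    xy = ground[["x", "y"]].to_numpy(dtype=float)
    z = ground["z"].to_numpy(dtype=float)
    if bounds is not None:
        x_min, y_min, x_max, y_max = bounds
    else:
        x_min, y_min = xy.min(axis=0)
        x_max, y_max = xy.max(axis=0)
    ncol = max(1, math.ceil((x_max - x_min) / cell))
    nrow = max(1, math.ceil((y_max - y_min) / cell))
    cx = x_min + (np.arange(ncol) + 0.5) * cell
    cy = y_min + (np.arange(nrow) + 0.5) * cell
    gx, gy = np.meshgrid(cx, cy)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    kk = min(k, len(ground))
    tree = cKDTree(xy)
    d, idx = tree.query(centers, k=kk)
    d = np.atleast_2d(d.reshape(len(centers), kk))
    idx = np.atleast_2d(idx.reshape(len(centers), kk))
    exact = d[:, 0] < 1e-9
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[~np.isfinite(w)] = 0.0
    vals = (w * z[idx]).sum(axis=1) / w.sum(axis=1)
    vals[exact] = z[idx[exact, 0]]
    return DtmGrid(vals.reshape(nrow, ncol), x_min, y_min, cell)


def normalize_heights(cloud: pd.DataFrame, dtm: DtmGrid) -> pd.DataFrame:
    """Replace z by height above the DTM (bilinear sampling).

    Points outside the DTM extent raise with the offending count.
    """
    x = cloud["x"].to_numpy(dtype=float)
    y = cloud["y"].to_numpy(dtype=float)
    inside = dtm.contains(x, y)
    if not inside.all():
        raise ValueError(
            f"{int((~inside).sum())} points fall outside the DTM extent"
        )
    out = cloud.copy()
    out["z"] = cloud["z"].to_numpy() - dtm.sample_bilinear(x, y)
    return out


def clip_plot(cloud: pd.DataFrame, center_x: float, center_y: float,
              width_m: float = 20.0, height_m: float = 30.0) -> pd.DataFrame:
    """Returns within the axis-aligned plot rectangle, half-open edges
    [min, max)."""
    x = cloud["x"].to_numpy()
    y = cloud["y"].to_numpy()
    keep = ((x >= center_x - width_m / 2) & (x < center_x + width_m / 2)
            & (y >= center_y - height_m / 2) & (y < center_y + height_m / 2))
    return cloud.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Metric families
# ---------------------------------------------------------------------------


def _live(cloud: pd.DataFrame) -> pd.DataFrame:
    return cloud.loc[cloud["classification"] != CLASS_NOISE]


def _above(cloud: pd.DataFrame, threshold: float) -> pd.DataFrame:
    live = _live(cloud)
    return live.loc[live["z"].to_numpy() >= threshold]


def elevation_metrics(cloud: pd.DataFrame,
                      height_threshold: float = HEIGHT_THRESHOLD_M
                      ) -> dict[str, float]:
    """Elevation family over normalized returns >= the height threshold."""
    z = _above(cloud, height_threshold)["z"].to_numpy(dtype=float)
    names = metric_names("elevation")
    if z.size == 0:
        warnings.warn("no returns above the height threshold; elevation"
                      " metrics are NaN (plot likely non-forest)", stacklevel=2)
        return {n: float("nan") for n in names}
    mean = float(z.mean())
    sd = float(z.std(ddof=0))
    out = {
        "elev_mean": mean,
        "elev_sd": sd,
        "elev_var": sd**2,
        "elev_cv": sd / mean if mean != 0 else float("nan"),
        "elev_skew": float(sstats.skew(z)) if z.size > 1 else 0.0,
        "elev_kurt": float(sstats.kurtosis(z)) if z.size > 1 else 0.0,
        "elev_min": float(z.min()),
        "elev_max": float(z.max()),
        "elev_median": float(np.median(z)),
        "elev_aad": float(np.abs(z - mean).mean()),
        "elev_sqmean": float(np.sqrt(np.mean(z**2))),
        "elev_cumean": float(np.cbrt(np.mean(z**3))),
        "elev_crr": (float((mean - z.min()) / (z.max() - z.min()))
                     if z.max() > z.min() else float("nan")),
    }
    for kk in PERCENTILE_KS:
        out[f"elev_p{kk:02d}"] = float(np.percentile(z, kk))
    return out


def density_metrics(cloud: pd.DataFrame, n_intervals: int = 10,
                    height_threshold: float = HEIGHT_THRESHOLD_M
                    ) -> dict[str, float]:
    """Proportion of above-threshold returns in each of ``n_intervals`` equal
    height slices spanning [threshold, max z]; the top slice is closed."""
    z = _above(cloud, height_threshold)["z"].to_numpy(dtype=float)
    names = [f"density_{i}" for i in range(1, n_intervals + 1)]
    if z.size == 0:
        return {n: float("nan") for n in names}
    zmax = z.max()
    out = dict.fromkeys(names, 0.0)
    if zmax <= height_threshold:
        out["density_1"] = 1.0
        return out
    edges = np.linspace(height_threshold, zmax, n_intervals + 1)
    counts, _ = np.histogram(z, bins=edges)  # numpy closes the top bin
    for i, c in enumerate(counts, start=1):
        out[f"density_{i}"] = float(c) / z.size
    return out


def intensity_metrics(cloud: pd.DataFrame,
                      height_threshold: float = HEIGHT_THRESHOLD_M,
                      aii_by_height: bool = True) -> dict[str, float]:
    """Intensity family over above-threshold returns.

    ``int_AII_k`` is the cumulative intensity of the lowest k % of returns
    ordered by height (the default reading), divided by the total intensity;
    ``aii_by_height=False`` orders by intensity instead.
    """
    sub = _above(cloud, height_threshold)
    names = metric_names("intensity")
    if len(sub) == 0:
        return {n: float("nan") for n in names}
    inten = sub["intensity"].to_numpy(dtype=float)
    z = sub["z"].to_numpy(dtype=float)
    mean = float(inten.mean())
    sd = float(inten.std(ddof=0))
    out = {
        "int_max": float(inten.max()),
        "int_min": float(inten.min()),
        "int_mean": mean,
        "int_sd": sd,
        "int_cv": sd / mean if mean != 0 else float("nan"),
        "int_skew": float(sstats.skew(inten)) if inten.size > 1 else 0.0,
        "int_kurt": float(sstats.kurtosis(inten)) if inten.size > 1 else 0.0,
    }
    for kk in PERCENTILE_KS:
        out[f"int_per_{kk}th"] = float(np.percentile(inten, kk))
    total = inten.sum()
    if total <= 0:
        warnings.warn("zero total intensity; AII metrics are NaN", stacklevel=2)
        for kk in PERCENTILE_KS + (100,):
            out[f"int_AII_{kk}th"] = float("nan")
        return out
    order = np.argsort(z, kind="stable") if aii_by_height else np.argsort(
        inten, kind="stable")
    csum = np.cumsum(inten[order])
    n = inten.size
    for kk in PERCENTILE_KS + (100,):
        m = math.ceil(kk * n / 100)
        out[f"int_AII_{kk}th"] = float(csum[m - 1] / total) if m >= 1 else 0.0
    return out


def forest_metrics(cloud: pd.DataFrame,
                   height_threshold: float = HEIGHT_THRESHOLD_M,
                   extinction_k: float = 0.5,
                   scan_angle_rad: float = 0.0) -> dict[str, float]:
    """Gap fraction, canopy cover and Beer-Lambert LAI."""
    live = _live(cloud)
    names = ["gap_fraction", "canopy_cover", "lai"]
    if len(live) == 0:
        return dict.fromkeys(names, float("nan"))
    z = live["z"].to_numpy(dtype=float)
    gap = float((z < height_threshold).sum()) / len(live)
    first = live.loc[live["return_number"].to_numpy() == 1]
    if len(first) == 0:
        warnings.warn("no first returns; canopy cover is NaN", stacklevel=2)
        cover = float("nan")
    else:
        cover = float((first["z"].to_numpy() >= height_threshold).sum()) / len(first)
    if gap == 0.0:
        warnings.warn("gap fraction 0; LAI undefined (reported NaN)",
                      stacklevel=2)
        lai = float("nan")
    else:
        lai = -math.cos(scan_angle_rad) * math.log(gap) / extinction_k
    return {"gap_fraction": gap, "canopy_cover": cover, "lai": lai}


def all_metrics(cloud: pd.DataFrame,
                height_threshold: float = HEIGHT_THRESHOLD_M,
                **kw) -> dict[str, float]:
    """All four families for one normalized plot cloud."""
    out: dict[str, float] = {}
    out.update(elevation_metrics(cloud, height_threshold))
    out.update(density_metrics(cloud, height_threshold=height_threshold))
    out.update(intensity_metrics(cloud, height_threshold, **kw))
    out.update(forest_metrics(cloud, height_threshold))
    return out


def metric_names(family: str = "all") -> list[str]:
    """Stable column order of the metric vector."""
    elev = ["elev_mean", "elev_sd", "elev_var", "elev_cv", "elev_skew",
            "elev_kurt", "elev_min", "elev_max", "elev_median", "elev_aad",
            "elev_sqmean", "elev_cumean", "elev_crr"]
    elev += [f"elev_p{k:02d}" for k in PERCENTILE_KS]
    dens = [f"density_{i}" for i in range(1, 11)]
    inten = ["int_max", "int_min", "int_mean", "int_sd", "int_cv",
             "int_skew", "int_kurt"]
    inten += [f"int_per_{k}th" for k in PERCENTILE_KS]
    inten += [f"int_AII_{k}th" for k in PERCENTILE_KS + (100,)]
    forest = ["gap_fraction", "canopy_cover", "lai"]
    table = {"elevation": elev, "density": dens, "intensity": inten,
             "forest": forest}
    if family != "all":
        return table[family]
    return elev + dens + inten + forest


def extract_all_metrics(clouds: Mapping[str, pd.DataFrame],
                        height_threshold: float = HEIGHT_THRESHOLD_M
                        ) -> pd.DataFrame:
    """One metric row per plot, sorted by plot id with a stable column order.

    A failing plot yields a NaN row and a warning, not a crash.
    """
    cols = metric_names()
    rows = []
    for pid in sorted(clouds):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = all_metrics(clouds[pid], height_threshold)
            rows.append([pid] + [m[c] for c in cols])
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"plot {pid}: metric extraction failed ({exc});"
                          " emitting NaN row", stacklevel=2)
            rows.append([pid] + [float("nan")] * len(cols))
    return pd.DataFrame(rows, columns=["plot_id"] + cols)


def normalize_plot_clouds(clouds: Mapping[str, pd.DataFrame],
                          cell: float = 0.5) -> dict[str, pd.DataFrame]:
    """Convenience: per-plot DTM + normalization for pre-labelled clouds."""
    out = {}
    for pid, cloud in clouds.items():
        ground = cloud.loc[cloud["classification"] == CLASS_GROUND]
        bounds = (cloud["x"].min(), cloud["y"].min(),
                  cloud["x"].max(), cloud["y"].max())
        dtm = interpolate_dtm_idw(ground, cell=cell, bounds=bounds)
        out[pid] = normalize_heights(cloud, dtm)
    return out
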