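"""Optical feature derivation from a 7-band surface-reflectance raster.

Covers the optical side of the area-based biomass workflow: SCS+C topographic
correction of reflectance over sloped terrain, band combinations, vegetation
indices, per-pixel GLCM (Haralick) textures, principal components, and sampling
of any derived layer at field-plot locations.

Rasters are plain numpy grids wrapped in :class:`RasterStack` with a north-up
affine grid (``x_min``, ``y_max``, square ``cell``); text I/O uses the ESRI
ASCII grid format, one file per band.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix
from sklearn.decomposition import PCA

__all__ = [
    "RasterStack",
    "TopoIllumination",
    "read_ascii_grid",
    "write_ascii_grid",
    "scs_c_correction",
    "estimate_c",
    "band_combinations",
    "vegetation_indices",
    "glcm_texture",
    "glcm_stats",
    "pca_transform",
    "extract_plot_features",
    "BAND_NAMES",
    "GLCM_STAT_NAMES",
]

BAND_NAMES = tuple(f"B{i}" for i in range(1, 8))

GLCM_STAT_NAMES = (
    "Mean",
    "Var",
    "Homo",
    "Cont",
    "Diss",
    "Entr",
    "SM",
    "Corr",
)


# ---------------------------------------------------------------------------
# Raster container and ASCII-grid text I/O
# ---------------------------------------------------------------------------


@dataclass
class RasterStack:
    """Co-registered named 2-D grids on a north-up square-cell raster.

    Row 0 is the northernmost row; cell (row, col) has its center at
    ``(x_min + (col + 0.5) * cell, y_max - (row + 0.5) * cell)``.
    NaN marks nodata.
    """

    bands: dict[str, np.ndarray]
    x_min: float
    y_max: float
    cell: float

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) > 1:
            raise ValueError(f"bands have mismatched shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.bands.values()))
        return first.shape

    @property
    def x_max(self) -> float:
        return self.x_min + self.shape[1] * self.cell

    @property
    def y_min(self) -> float:
        return self.y_max - self.shape[0] * self.cell

    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing (x, y); raises if outside."""
        col = int(math.floor((x - self.x_min) / self.cell))
        row = int(math.floor((self.y_max - y) / self.cell))
        nrow, ncol = self.shape
        if not (0 <= row < nrow and 0 <= col < ncol):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def sample(self, band: str, x: float, y: float) -> float:
        row, col = self.rowcol(x, y)
        return float(self.bands[band][row, col])

    def with_bands(self, bands: dict[str, np.ndarray]) -> "RasterStack":
        return RasterStack(bands, self.x_min, self.y_max, self.cell)


def write_ascii_grid(path, grid: np.ndarray, x_min: float, y_min: float,
                     cell: float, nodata: float = -9999.0) -> None:
    """Write one grid as an ESRI ASCII raster (row 0 = north)."""
    nrow, ncol = grid.shape
    out = np.where(np.isfinite(grid), grid, nodata)
    header = (
        f"NCOLS {ncol}\nNROWS {nrow}\nXLLCORNER {x_min!r}\n"
        f"YLLCORNER {y_min!r}\nCELLSIZE {cell!r}\nNODATA_VALUE {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path) -> tuple[np.ndarray, float, float, float]:
    """Read an ESRI ASCII raster; returns (grid, x_min, y_min, cell)."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.upper()] = float(val)
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)
    nodata = meta.get("NODATA_VALUE", -9999.0)
    grid = np.where(grid == nodata, np.nan, grid)
    return grid, meta["XLLCORNER"], meta["YLLCORNER"], meta["CELLSIZE"]


# ---------------------------------------------------------------------------
# SCS+C topographic correction
# ---------------------------------------------------------------------------


@dataclass
class TopoIllumination:
    """Terrain/sun geometry for topographic correction (angles in radians).

    ``cos_i`` is the cosine of the local solar incidence angle,

        cos i = cos(theta) cos(alpha)
                + sin(theta) sin(alpha) cos(phi_sun - aspect)

    with ``theta`` the solar zenith, ``alpha`` the slope, ``phi_sun`` the
    solar azimuth, and ``aspect`` the downslope azimuth grid.
    """

    slope: np.ndarray
    solar_zenith: float
    solar_azimuth: float = 0.0
    aspect: np.ndarray | None = None
    c: Mapping[str, float] | None = None
    cos_i: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        aspect = self.aspect if self.aspect is not None else np.zeros_like(self.slope)
        theta = self.solar_zenith
        self.cos_i = (
            np.cos(theta) * np.cos(self.slope)
            + np.sin(theta) * np.sin(self.slope) * np.cos(self.solar_azimuth - aspect)
        )


def estimate_c(band: np.ndarray, cos_i: np.ndarray) -> float:
    """Semi-empirical C for one band: intercept/slope of L = m*cos(i) + b.

    Degenerate geometry (constant cos i, e.g. flat terrain) returns C = 0;
    the correction factor is then exactly 1 so the choice is inert.
    """
    ok = np.isfinite(band) & np.isfinite(cos_i)
    x = cos_i[ok].ravel()
    y = band[ok].ravel()
    if x.size < 2 or np.ptp(x) < 1e-12:
        return 0.0
    m, b = np.polyfit(x, y, 1)
    if abs(m) < 1e-15:
        return 0.0
    return float(b / m)


def scs_c_correction(stack: RasterStack, topo: TopoIllumination) -> RasterStack:
    """Sun-Canopy-Sensor + C correction of every band.

    Lt = L * (cos(theta) * cos(alpha) + C) / (cos(i) + C); pixels where the
    denominator vanishes are masked NaN with a warning.
    """
    theta = topo.solar_zenith
    numer_geom = np.cos(theta) * np.cos(topo.slope)
    out: dict[str, np.ndarray] = {}
    n_masked = 0
    for name, band in stack.bands.items():
        c = topo.c[name] if topo.c is not None else estimate_c(band, topo.cos_i)
        denom = topo.cos_i + c
        bad = np.abs(denom) < 1e-9
        n_masked += int(bad.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            corrected = band * (numer_geom + c) / np.where(bad, np.nan, denom)
        out[name] = corrected
    if n_masked:
        warnings.warn(
            f"SCS+C: masked {n_masked} pixels with vanishing cos(i)+C",
            stacklevel=2,
        )
    return stack.with_bands(out)


# ---------------------------------------------------------------------------
# Band combinations and vegetation indices
# ---------------------------------------------------------------------------


def _nd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Normalized difference (a - b) / (a + b), NaN where the sum is 0."""
    return _ratio(a - b, a + b)


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(den) < 1e-12, np.nan, num / den)
    return out


def band_combinations(stack: RasterStack, *, nd563_product: bool = False
                      ) -> dict[str, np.ndarray]:
    """The ten band-combination layers.

    The headline combinations are MVI5 = (B5+B4-B2)/(B5+B4+B2), the simple
    ratios B76, B65, B53, the normalized difference MVI7 = (B5-B7)/(B5+B7),
    and ND563 = (B5+B6-B3)/(B5+B6+B3); four further ratios round out the set.
    ``nd563_product=True`` switches ND563 to the literal product form
    (B5+B6-B3)*(B5+B6+B3).
    """
    b = stack.bands
    nd563_num = b["B5"] + b["B6"] - b["B3"]
    nd563_den = b["B5"] + b["B6"] + b["B3"]
    nd563 = nd563_num * nd563_den if nd563_product else _ratio(nd563_num, nd563_den)
    return {
        "MVI5": _ratio(b["B5"] + b["B4"] - b["B2"], b["B5"] + b["B4"] + b["B2"]),
        "B76": _ratio(b["B7"], b["B6"]),
        "B65": _ratio(b["B6"], b["B5"]),
        "B53": _ratio(b["B5"], b["B3"]),
        "MVI7": _nd(b["B5"], b["B7"]),
        "ND563": nd563,
        "B54": _ratio(b["B5"], b["B4"]),
        "B74": _ratio(b["B7"], b["B4"]),
        "B43": _ratio(b["B4"], b["B3"]),
        "ND67": _nd(b["B6"], b["B7"]),
    }


def vegetation_indices(stack: RasterStack) -> dict[str, np.ndarray]:
    """Fifteen standard vegetation indices (Landsat 8 band roles:
    B2 blue, B3 green, B4 red, B5 NIR, B6/B7 SWIR).

    Coefficient constants follow the canonical literature values:
    EVI G=2.5, C1=6, C2=7.5, L=1; SAVI L=0.5; OSAVI L=0.16.
    """
    b = stack.bands
    blue, green, red, nir = b["B2"], b["B3"], b["B4"], b["B5"]
    swir1, swir2 = b["B6"], b["B7"]
    with np.errstate(divide="ignore", invalid="ignore"):
        msavi = 0.5 * (
            2 * nir + 1 - np.sqrt(np.maximum((2 * nir + 1) ** 2 - 8 * (nir - red), 0.0))
        )
    return {
        "NDVI": _nd(nir, red),
        "EVI": _ratio(2.5 * (nir - red), nir + 6 * red - 7.5 * blue + 1),
        "ARVI": _nd(nir - (red - (blue - red)), nir + (red - (blue - red))),
        "SAVI": _ratio(1.5 * (nir - red), nir + red + 0.5),
        "MSAVI": msavi,
        "OSAVI": _ratio(1.16 * (nir - red), nir + red + 0.16),
        "DVI": nir - red,
        "RVI": _ratio(nir, red),
        "GNDVI": _nd(nir, green),
        "NDMI": _nd(nir, swir1),
        "NBR": _nd(nir, swir2),
        "NDWI": _nd(green, nir),
        "GCI": _ratio(nir, green) - 1.0,
        "VARI": _ratio(green - red, green + red - blue),
        "EVI2": _ratio(2.5 * (nir - red), nir + 2.4 * red + 1),
    }


# ---------------------------------------------------------------------------
# GLCM textures
# ---------------------------------------------------------------------------


def glcm_stats(p: np.ndarray) -> dict[str, float]:
    """Eight Haralick statistics of a normalized symmetric co-occurrence
    matrix ``p`` (levels x levels, sums to 1).

    Entropy uses the natural log with 0*log(0) := 0; correlation is defined
    as 1 for a zero-variance matrix (single occupied level).
    """
    levels = p.shape[0]
    i = np.arange(levels, dtype=float)[:, None]
    j = np.arange(levels, dtype=float)[None, :]
    mu = float((i * p).sum())  # symmetric: row and column means coincide
    var = float(((i - mu) ** 2 * p).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    corr = 1.0 if var < 1e-15 else float((((i - mu) * (j - mu)) * p).sum() / var)
    return {
        "Mean": mu,
        "Var": var,
        "Homo": float((p / (1.0 + (i - j) ** 2)).sum()),
        "Cont": float((p * (i - j) ** 2).sum()),
        "Diss": float((p * np.abs(i - j)).sum()),
        "Entr": entropy,
        "SM": float((p**2).sum()),
        "Corr": corr,
    }


def quantize(band: np.ndarray, levels: int) -> np.ndarray:
    """Quantize a grid to integer gray levels 0..levels-1 over its finite
    range (constant grids map to level 0)."""
    finite = np.isfinite(band)
    lo = np.nanmin(band) if finite.any() else 0.0
    hi = np.nanmax(band) if finite.any() else 1.0
    if hi - lo < 1e-15:
        q = np.zeros(band.shape, dtype=np.uint16)
    else:
        q = np.clip(((band - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
        q = q.astype(np.uint16)
    return q


_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def window_glcm(patch: np.ndarray, levels: int, distance: int = 1) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix of one integer patch,
    accumulated over the four offset directions at the given distance."""
    m = graycomatrix(
        patch, [distance], list(_GLCM_ANGLES), levels=levels,
        symmetric=True, normed=False,
    )[:, :, 0, :].sum(axis=2).astype(float)
    total = m.sum()
    if total == 0:
        # degenerate 1x1 patch: treat the single pixel as self-co-occurring
        m[patch[0, 0], patch[0, 0]] = 1.0
        total = 1.0
    return m / total


def glcm_texture(band: np.ndarray, *, window: int = 3, levels: int = 32,
                 distance: int = 1,
                 stats: Sequence[str] = GLCM_STAT_NAMES) -> dict[str, np.ndarray]:
    """Per-pixel Haralick textures of one band over a sliding window.

    Gray levels are quantized over the band's finite range; at raster edges
    the window is clipped to the grid.  Returns one grid per statistic keyed
    by the short statistic name (Mean, Var, Homo, Cont, Diss, Entr, SM, Corr).
    """
    nrow, ncol = band.shape
    if window > nrow or window > ncol:
        raise ValueError(
            f"GLCM window {window} exceeds raster shape {band.shape}"
        )
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    q = quantize(band, levels)
    half = window // 2
    out = {s: np.full(band.shape, np.nan) for s in stats}
    for r in range(nrow):
        r0, r1 = max(0, r - half), min(nrow, r + half + 1)
        for c in range(ncol):
            c0, c1 = max(0, c - half), min(ncol, c + half + 1)
            p = window_glcm(q[r0:r1, c0:c1], levels, distance)
            vals = glcm_stats(p)
            for s in stats:
                out[s][r, c] = vals[s]
    return out


def glcm_features(stack: RasterStack, *, window: int = 3, levels: int = 32,
                  distance: int = 1) -> dict[str, np.ndarray]:
    """All 56 GLCM layers: eight Haralick statistics per band, named
    ``<Stat>_<Band>`` (e.g. Entr_B5)."""
    out: dict[str, np.ndarray] = {}
    for name, band in stack.bands.items():
        tex = glcm_texture(band, window=window, levels=levels, distance=distance)
        for stat, grid in tex.items():
            out[f"{stat}_{name}"] = grid
    return out


# ---------------------------------------------------------------------------
# Principal components
# ---------------------------------------------------------------------------


def pca_transform(stack: RasterStack, n_components: int = 3
                  ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Principal components of the pixel x band matrix.

    Components are ordered by decreasing explained variance with a
    deterministic sign convention (the largest-|loading| element of each
    component is positive).  Returns (PC grids keyed PC1..PCn, explained
    variance ratios).  Rank deficiency yields fewer components + a warning.
    """
    names = list(stack.bands)
    mat = np.stack([stack.bands[n].ravel() for n in names], axis=1)
    ok = np.isfinite(mat).all(axis=1)
    X = mat[ok]
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"requested {n_components} components but data rank is {rank};"
            f" returning {k}", stacklevel=2,
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    # sign convention: largest-|loading| element positive
    for ci in range(k):
        load = pca.components_[ci]
        j = int(np.argmax(np.abs(load)))
        if load[j] < 0:
            pca.components_[ci] = -load
            scores[:, ci] = -scores[:, ci]
    out: dict[str, np.ndarray] = {}
    for ci in range(k):
        grid = np.full(mat.shape[0], np.nan)
        grid[ok] = scores[:, ci]
        out[f"PC{ci + 1}"] = grid.reshape(stack.shape)
    return out, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# Plot sampling
# ---------------------------------------------------------------------------


def extract_plot_features(
    features: Mapping[str, np.ndarray],
    stack: RasterStack,
    plots: pd.DataFrame,
    *,
    mode: str = "center",
    plot_width_m: float = 20.0,
    plot_height_m: float = 30.0,
) -> pd.DataFrame:
    """Sample derived layers at plot locations.

    ``plots`` needs columns ``plot_id``, ``x``, ``y`` (plot centers, projected
    meters).  ``mode="center"`` takes the pixel containing the center;
    ``mode="area"`` takes the area-weighted mean over the plot rectangle.
    """
    if mode not in ("center", "area"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    rows = []
    names = list(features)
    cell = stack.cell
    for _, p in plots.iterrows():
        x, y = float(p["x"]), float(p["y"])
        try:
            stack.rowcol(x, y)
        except ValueError:
            raise ValueError(
                f"plot {p['plot_id']!r} at ({x}, {y}) outside raster extent"
            ) from None
        if mode == "center":
            r, c = stack.rowcol(x, y)
            rows.append([p["plot_id"]] + [float(features[n][r, c]) for n in names])
        else:
            x0, x1 = x - plot_width_m / 2, x + plot_width_m / 2
            y0, y1 = y - plot_height_m / 2, y + plot_height_m / 2
            vals = []
            # overlap of the plot rectangle with each intersecting cell
            c0 = int(math.floor((x0 - stack.x_min) / cell))
            c1 = int(math.ceil((x1 - stack.x_min) / cell))
            r0 = int(math.floor((stack.y_max - y1) / cell))
            r1 = int(math.ceil((stack.y_max - y0) / cell))
            weights, cells = [], []
            nrow, ncol = stack.shape
            for r in range(max(r0, 0), min(r1, nrow)):
                cy1 = stack.y_max - r * cell
                cy0 = cy1 - cell
                for c in range(max(c0, 0), min(c1, ncol)):
                    cx0 = stack.x_min + c * cell
                    cx1 = cx0 + cell
                    w = max(0.0, min(x1, cx1) - max(x0, cx0)) * max(
                        0.0, min(y1, cy1) - max(y0, cy0)
                    )
                    if w > 0:
                        weights.append(w)
                        cells.append((r, c))
            w = np.asarray(weights)
            w = w / w.sum()
            for n in names:
                v = np.asarray([features[n][r, c] for r, c in cells])
                vals.append(float(np.sum(w * v)))
            rows.append([p["plot_id"]] + vals)
    return pd.DataFrame(rows, columns=["plot_id"] + names)
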