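"""Synthetic forest scenes with known ground truth.

Generates the three inputs of the area-based biomass workflow — field plots
with per-tree species/DBH lists, discrete-return point clouds, and a 7-band
reflectance raster — from a small set of generative parameters, so every
downstream stage can be tested against a known truth.

The generative model, plot by plot:

* stem count ~ Poisson(lambda); species drawn from a mixing table; DBH from a
  species-specific Weibull truncated at the 5 cm census threshold;
* true AGB is the allometric plot aggregate of the tree list (exactly the
  equations of :mod:`forestagb.allometry` — conservation is testable);
* the canopy top height follows H = h0 * AGB**gamma; non-ground return
  heights are Beta(2, 1.2)-distributed up to H, a configured fraction of
  returns is ground, and return intensity decays with depth into the canopy:
  I = I0 * exp(-k_i (H - z)) + noise;
* reflectance saturates with biomass: band b = r0_b + r1_b * exp(-AGB/s_b)
  + noise, clipped to [0, 1] — emulating the insensitivity of optical data
  to high biomass;
* terrain is an optional uniform planar slope (exercises topographic
  correction and DTM normalization, nothing more).

All randomness flows through per-plot named substreams of one seed, so adding
plots never perturbs earlier ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import allometry
from .allometry import TreeRecord
from .spectral_features import BAND_NAMES, RasterStack, write_ascii_grid

__all__ = [
    "SceneConfig",
    "SyntheticPlot",
    "Scene",
    "generate_tree_list",
    "simulate_point_cloud",
    "simulate_reflectance",
    "build_scene",
    "write_scene",
]

# LAS-style classification codes used throughout the package
CLASS_DEFAULT = 1
CLASS_GROUND = 2
CLASS_NOISE = 7

# substream tags (mixed into the per-plot RNG seed material)
_STREAM_TREES = 1
_STREAM_CLOUD = 2
_STREAM_REFLECTANCE = 3
_STREAM_RASTER = 4

#: default per-band saturation parameters (r0, r1, s): reflectance
#: r0 + r1*exp(-AGB/s).  Visible bands darken with biomass, NIR (B5)
#: brightens, SWIR bands darken; saturation constants s sit at 60-110 Mg/ha,
#: in the range reported for temperate/subtropical forests.
DEFAULT_BAND_SATURATION: Mapping[str, tuple[float, float, float]] = {
    "B1": (0.020, 0.050, 80.0),
    "B2": (0.025, 0.060, 80.0),
    "B3": (0.045, 0.070, 90.0),
    "B4": (0.030, 0.100, 70.0),
    "B5": (0.420, -0.240, 100.0),
    "B6": (0.120, 0.140, 110.0),
    "B7": (0.060, 0.120, 90.0),
}

#: default species mix: a broadleaf-dominated natural secondary forest with
#: birch/oak/poplar and a conifer admixture (placeholder composition; the
#: field census composition of any real site will differ).
DEFAULT_SPECIES_MIX: Mapping[str, float] = {
    "Betula platyphylla": 0.30,
    "Quercus mongolica": 0.25,
    "Populus davidiana": 0.15,
    "Larix olgensis": 0.15,
    "Pinus koraiensis": 0.10,
    "Acer mono": 0.05,
}

#: default per-species DBH Weibull (shape, scale in cm), truncated at 5 cm
DEFAULT_DBH_WEIBULL: Mapping[str, tuple[float, float]] = {
    "Betula platyphylla": (2.0, 14.0),
    "Quercus mongolica": (1.9, 15.0),
    "Populus davidiana": (2.2, 16.0),
    "Larix olgensis": (2.1, 17.0),
    "Pinus koraiensis": (1.8, 15.0),
    "Acer mono": (2.0, 12.0),
}


@dataclass(frozen=True)
class SceneConfig:
    """Generative parameters of a synthetic scene (see module docstring)."""

    n_plots: int = 195
    plot_width_m: float = 20.0
    plot_height_m: float = 30.0
    point_density: float = 3.6  # points per m^2
    stem_density_mean: float = 60.0  # Poisson mean stems per plot
    species_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_MIX)
    )
    dbh_weibull: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DBH_WEIBULL)
    )
    # mean canopy top height H = h0 * AGB**gamma  (H in m, AGB in Mg/ha)
    height_gamma: float = 0.5
    height_h0: float = 1.8
    ground_fraction: float = 0.25
    intensity_i0: float = 1.0
    intensity_k: float = 0.15
    band_saturation: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_SATURATION)
    )
    # channel noise (standard deviations)
    noise_sd_reflectance: float = 0.01
    noise_sd_intensity: float = 0.05
    noise_sd_ground_z: float = 0.03
    # terrain: uniform planar slope (deg) dipping toward `slope_aspect_deg`
    slope_deg: float = 0.0
    slope_aspect_deg: float = 180.0
    base_elevation_m: float = 300.0
    # raster layout
    raster_cell_m: float = 30.0
    plot_spacing_m: float = 90.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_plots < 0:
            raise ValueError("n_plots must be non-negative")
        if self.plot_width_m <= 0 or self.plot_height_m <= 0:
            raise ValueError("plot dimensions must be positive")
        if self.point_density <= 0:
            raise ValueError(f"point density must be positive, got {self.point_density}")
        total = sum(self.species_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"species mixing proportions sum to {total}, not 1")
        for sp in self.species_mix:
            allometry.species_params(sp)  # raises for unknown species
            if sp not in self.dbh_weibull:
                raise ValueError(f"species {sp!r} has no DBH Weibull parameters")
        for b, (_, _, s) in self.band_saturation.items():
            if s <= 0:
                raise ValueError(f"saturation constant for {b} must be positive")


@dataclass
class SyntheticPlot:
    plot_id: str
    x: float  # center, projected meters
    y: float
    trees: list[TreeRecord]
    agb_mg_ha: float
    top_height_m: float
    cloud: pd.DataFrame | None = None
    reflectance: np.ndarray | None = None  # 7 bands


@dataclass
class Scene:
    config: SceneConfig
    plots: list[SyntheticPlot]
    raster: RasterStack  # 7 bands + "slope" + "aspect" (radians)
    truth: pd.DataFrame  # plot_id, agb_mg_ha, top_height_m, n_trees

    @property
    def plot_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.plot_id, p.x, p.y) for p in self.plots],
            columns=["plot_id", "x", "y"],
        )

    @property
    def clouds(self) -> dict[str, pd.DataFrame]:
        return {p.plot_id: p.cloud for p in self.plots}


def _rng(cfg: SceneConfig, stream: int, index: int = 0) -> np.random.Generator:
    """Named RNG substream: independent of how many plots exist."""
    return np.random.default_rng([cfg.seed, stream, index])


def _truncated_weibull(rng: np.random.Generator, shape: float, scale: float,
                       lower: float, size: int) -> np.ndarray:
    """Inverse-CDF sampling of a Weibull truncated below at `lower`."""
    p0 = 1.0 - math.exp(-((lower / scale) ** shape))
    u = rng.uniform(p0, 1.0, size=size)
    return scale * (-np.log1p(-u)) ** (1.0 / shape)


def generate_tree_list(cfg: SceneConfig, plot_id: str, plot_index: int = 0,
                       rng: np.random.Generator | None = None
                       ) -> list[TreeRecord]:
    """Draw the tree list of one plot: Poisson stem count, species from the
    mixing table, DBH from the species Weibull truncated at 5 cm."""
    cfg.validate()
    if rng is None:
        rng = _rng(cfg, _STREAM_TREES, plot_index)
    n = int(rng.poisson(cfg.stem_density_mean))
    if n == 0:
        return []
    names = list(cfg.species_mix)
    probs = np.asarray([cfg.species_mix[s] for s in names])
    species_idx = rng.choice(len(names), size=n, p=probs / probs.sum())
    trees: list[TreeRecord] = []
    for idx in species_idx:
        sp = names[idx]
        shape, scale = cfg.dbh_weibull[sp]
        dbh = float(_truncated_weibull(rng, shape, scale, allometry.MIN_DBH_CM, 1)[0])
        trees.append(TreeRecord(plot_id, sp, dbh))
    return trees


def _plot_agb(cfg: SceneConfig, trees: Sequence[TreeRecord]) -> float:
    area_ha = cfg.plot_width_m * cfg.plot_height_m / 1e4
    return allometry.plot_agb_density(trees, area_ha).agb_density_mg_ha


def top_height(cfg: SceneConfig, agb: float) -> float:
    """Canopy top height H = h0 * AGB**gamma (m)."""
    return cfg.height_h0 * agb**cfg.height_gamma


def _terrain_z(cfg: SceneConfig, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Planar terrain elevation at (x, y)."""
    slope = math.radians(cfg.slope_deg)
    aspect = math.radians(cfg.slope_aspect_deg)
    # downslope direction = aspect; elevation decreases along it
    dx, dy = math.sin(aspect), math.cos(aspect)
    return cfg.base_elevation_m - math.tan(slope) * (x * dx + y * dy)


def simulate_point_cloud(plot: SyntheticPlot, cfg: SceneConfig,
                         plot_index: int = 0,
                         rng: np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Simulate the discrete-return cloud of one plot.

    Returns a DataFrame with columns x, y, z, intensity, return_number,
    classification (LAS codes: 1 canopy/unclassified, 2 ground).  z carries
    the terrain elevation, so the cloud must be DTM-normalized downstream.
    """
    if cfg.point_density <= 0:
        raise ValueError(f"point density must be positive, got {cfg.point_density}")
    if rng is None:
        rng = _rng(cfg, _STREAM_CLOUD, plot_index)
    area = cfg.plot_width_m * cfg.plot_height_m
    n = int(rng.poisson(cfg.point_density * area))
    x = rng.uniform(plot.x - cfg.plot_width_m / 2, plot.x + cfg.plot_width_m / 2, n)
    y = rng.uniform(plot.y - cfg.plot_height_m / 2, plot.y + cfg.plot_height_m / 2, n)
    h_top = plot.top_height_m
    if h_top <= 0 or not plot.trees:
        is_ground = np.ones(n, dtype=bool)
    else:
        is_ground = rng.uniform(size=n) < cfg.ground_fraction
    height = np.zeros(n)
    n_canopy = int((~is_ground).sum())
    height[~is_ground] = h_top * rng.beta(2.0, 1.2, size=n_canopy)
    height[is_ground] = rng.normal(0.0, cfg.noise_sd_ground_z, size=int(is_ground.sum()))
    intensity = cfg.intensity_i0 * np.exp(
        -cfg.intensity_k * np.maximum(h_top - height, 0.0)
    ) + rng.normal(0.0, cfg.noise_sd_intensity, size=n)
    intensity = np.maximum(intensity, 0.0)
    return_number = rng.choice([1, 2, 3], size=n, p=[0.7, 0.2, 0.1])
    # ground returns are the last of their pulse more often than not
    return_number[is_ground] = rng.choice([1, 2, 3], size=int(is_ground.sum()),
                                          p=[0.4, 0.3, 0.3])
    z = _terrain_z(cfg, x, y) + height
    cls = np.where(is_ground, CLASS_GROUND, CLASS_DEFAULT)
    return pd.DataFrame({
        "x": x, "y": y, "z": z,
        "intensity": intensity,
        "return_number": return_number,
        "classification": cls,
    })


def simulate_reflectance(agb: np.ndarray, cfg: SceneConfig,
                         rng: np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Saturating per-band reflectance of an AGB vector:
    r = r0 + r1*exp(-AGB/s) + noise, clipped to [0, 1]."""
    agb = np.asarray(agb, dtype=float)
    if (agb < 0).any():
        raise ValueError("AGB must be non-negative")
    if rng is None:
        rng = _rng(cfg, _STREAM_REFLECTANCE)
    out = {}
    for b in BAND_NAMES:
        r0, r1, s = cfg.band_saturation[b]
        if s <= 0:
            raise ValueError(f"saturation constant for {b} must be positive")
        vals = r0 + r1 * np.exp(-agb / s)
        if cfg.noise_sd_reflectance > 0:
            vals = vals + rng.normal(0.0, cfg.noise_sd_reflectance, size=agb.shape)
        out[b] = np.clip(vals, 0.0, 1.0)
    return pd.DataFrame(out)


def build_scene(cfg: SceneConfig) -> Scene:
    """Generate the full scene: plots on a non-overlapping grid, per-plot tree
    lists / clouds / reflectance, a raster stack covering all plots, and the
    ground-truth table.  Deterministic given the config (including seed)."""
    cfg.validate()
    ncols = max(1, math.ceil(math.sqrt(cfg.n_plots)))
    nrows = max(1, math.ceil(cfg.n_plots / ncols)) if cfg.n_plots else 1
    spacing = cfg.plot_spacing_m
    if spacing < max(cfg.plot_width_m, cfg.plot_height_m):
        raise ValueError("plot spacing smaller than plot size: plots overlap")

    plots: list[SyntheticPlot] = []
    for i in range(cfg.n_plots):
        r, c = divmod(i, ncols)
        # offset by half a spacing so centers are interior to the raster
        x = (c + 0.5) * spacing
        y = (r + 0.5) * spacing
        pid = f"P{i + 1:04d}"
        trees = generate_tree_list(cfg, pid, i)
        agb = _plot_agb(cfg, trees)
        plot = SyntheticPlot(pid, x, y, trees, agb, top_height(cfg, agb))
        plot.cloud = simulate_point_cloud(plot, cfg, i)
        plots.append(plot)

    agb_vec = np.asarray([p.agb_mg_ha for p in plots])
    refl = simulate_reflectance(agb_vec, cfg) if plots else pd.DataFrame(
        columns=list(BAND_NAMES))
    for p, (_, row) in zip(plots, refl.iterrows()):
        p.reflectance = row.to_numpy()

    raster = _build_raster(cfg, plots)
    truth = pd.DataFrame(
        [(p.plot_id, p.agb_mg_ha, p.top_height_m, len(p.trees)) for p in plots],
        columns=["plot_id", "agb_mg_ha", "top_height_m", "n_trees"],
    )
    return Scene(cfg, plots, raster, truth)


def _build_raster(cfg: SceneConfig, plots: Sequence[SyntheticPlot]) -> RasterStack:
    """Reflectance + terrain raster covering every plot with a margin.

    A latent AGB surface (smoothed noise rescaled to the plot AGB range) fills
    cells between plots; the cell containing each plot center carries that
    plot's true AGB, so center-pixel sampling is consistent with the plot's
    own reflectance draw up to noise.
    """
    cell = cfg.raster_cell_m
    rng = _rng(cfg, _STREAM_RASTER)
    if plots:
        x_max = max(p.x for p in plots) + cfg.plot_spacing_m / 2
        y_top = max(p.y for p in plots) + cfg.plot_spacing_m / 2
    else:
        x_max = y_top = cfg.plot_spacing_m
    ncol = max(3, math.ceil(x_max / cell))
    nrow = max(3, math.ceil(y_top / cell))
    x_min, y_max = 0.0, nrow * cell

    agb_vals = np.asarray([p.agb_mg_ha for p in plots]) if plots else np.asarray([50.0])
    lo, hi = float(agb_vals.min()), float(agb_vals.max())
    latent = ndimage.gaussian_filter(rng.normal(size=(nrow, ncol)), sigma=2.0)
    lr = np.ptp(latent)
    latent = lo + (latent - latent.min()) / (lr if lr > 0 else 1.0) * (hi - lo)
    for p in plots:
        r = int((y_max - p.y) // cell)
        c = int((p.x - x_min) // cell)
        latent[r, c] = p.agb_mg_ha

    bands: dict[str, np.ndarray] = {}
    for b in BAND_NAMES:
        r0, r1, s = cfg.band_saturation[b]
        vals = r0 + r1 * np.exp(-latent / s)
        if cfg.noise_sd_reflectance > 0:
            vals = vals + rng.normal(0.0, cfg.noise_sd_reflectance, size=latent.shape)
        bands[b] = np.clip(vals, 0.0, 1.0)
    bands["slope"] = np.full((nrow, ncol), math.radians(cfg.slope_deg))
    bands["aspect"] = np.full((nrow, ncol), math.radians(cfg.slope_aspect_deg))
    bands["agb_latent"] = latent
    return RasterStack(bands, x_min, y_max, cell)


def write_scene(scene: Scene, outdir: str | Path) -> None:
    """Write the scene as text fixtures: per-plot cloud CSVs, one ASCII grid
    per raster layer, plots/trees/truth CSVs.  Byte-deterministic for a fixed
    config (no timestamps)."""
    out = Path(outdir)
    (out / "clouds").mkdir(parents=True, exist_ok=True)
    for p in scene.plots:
        p.cloud.to_csv(out / "clouds" / f"{p.plot_id}.csv", index=False,
                       float_format="%.6f")
    for name, grid in scene.raster.bands.items():
        write_ascii_grid(out / f"{name}.asc", grid, scene.raster.x_min,
                         scene.raster.y_min, scene.raster.cell)
    scene.plot_table.to_csv(out / "plots.csv", index=False, float_format="%.3f")
    trees = pd.DataFrame(
        [(t.plot_id, t.species, t.dbh_cm) for p in scene.plots for t in p.trees],
        columns=["plot_id", "species", "dbh_cm"],
    )
    trees.to_csv(out / "trees.csv", index=False, float_format="%.4f")
    scene.truth.to_csv(out / "truth.csv", index=False, float_format="%.6f")
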