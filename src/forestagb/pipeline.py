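"""End-to-end plumbing: synthetic scene -> feature tables -> experiments.

Convenience composition of the per-stage modules for scripted runs; every
step is the public API of the stage it wraps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import als_metrics as am
from . import spectral_features as sf
from .feature_engineering import (FusionSpec, assemble_experiment,
                                  best_lidar_variable, compute_coli1,
                                  compute_coli2, select_features,
                                  EXPERIMENT_IDS)
from .synthetic_scene import Scene

__all__ = ["FeatureBundle", "scene_feature_tables", "build_feature_sets"]


@dataclass
class FeatureBundle:
    als: pd.DataFrame          # plot_id + ALS metric columns + agb
    optical: pd.DataFrame      # plot_id + optical feature columns + agb
    y: np.ndarray              # true AGB, aligned to rows
    optical_layers: dict[str, np.ndarray]  # wall-to-wall feature grids
    raster: sf.RasterStack


def scene_feature_tables(scene: Scene, *, glcm_levels: int = 32,
                         sun_zenith_deg: float = 44.72,
                         sun_azimuth_deg: float = 154.91) -> FeatureBundle:
    """ALS metric and optical feature tables of a synthetic scene.

    ALS side: per-plot DTM + normalization + the full metric vector.
    Optical side: SCS+C correction, band combinations, vegetation indices,
    GLCM textures and principal components, sampled at plot centers.
    """
    norm = am.normalize_plot_clouds(scene.clouds)
    als = am.extract_all_metrics(norm)

    stack = scene.raster
    refl = stack.with_bands({b: stack.bands[b] for b in sf.BAND_NAMES})
    topo = sf.TopoIllumination(
        stack.bands["slope"], solar_zenith=np.radians(sun_zenith_deg),
        solar_azimuth=np.radians(sun_azimuth_deg),
        aspect=stack.bands["aspect"])
    corrected = sf.scs_c_correction(refl, topo)
    layers: dict[str, np.ndarray] = dict(corrected.bands)
    layers.update(sf.band_combinations(corrected))
    layers.update(sf.vegetation_indices(corrected))
    layers.update(sf.glcm_features(corrected, levels=glcm_levels))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pcs, _ = sf.pca_transform(corrected)
    layers.update(pcs)
    optical = sf.extract_plot_features(layers, corrected, scene.plot_table)

    truth = scene.truth.set_index("plot_id")["agb_mg_ha"]
    als = als.sort_values("plot_id").reset_index(drop=True)
    optical = optical.sort_values("plot_id").reset_index(drop=True)
    y = truth.loc[als["plot_id"]].to_numpy(dtype=float)
    als["agb"] = y
    optical["agb"] = y
    return FeatureBundle(als, optical, y, layers, corrected)


def build_feature_sets(bundle: FeatureBundle, *, k: int = 9,
                       n_runs: int = 10, rf_trees: int = 1000,
                       experiments: tuple[str, ...] = EXPERIMENT_IDS
                       ) -> dict:
    """Two-step selection per source, BLV, COLI fusion and the experiment
    feature sets.  Returns a dict with keys ``sets`` (id -> feature table),
    ``y``, ``als_selection``, ``optical_selection``, ``fusion`` and
    ``blv_report``."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        als_sel = select_features(bundle.als, k=k, n_runs=n_runs,
                                  n_estimators=rf_trees)
        opt_sel = select_features(bundle.optical, k=k, n_runs=n_runs,
                                  n_estimators=rf_trees)
        blv, blv_report = best_lidar_variable(bundle.als, als_sel.selected)

    merged = pd.concat(
        [bundle.als[["plot_id"] + als_sel.selected],
         bundle.optical[opt_sel.selected]], axis=1)
    fusion = FusionSpec(blv, tuple(opt_sel.selected))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coli1 = compute_coli1(merged, fusion)
        coli2 = compute_coli2(merged, fusion)

    sets = {}
    for eid in experiments:
        sets[eid] = assemble_experiment(
            eid, merged[als_sel.selected], merged[opt_sel.selected],
            merged[blv].rename(f"BLV_{blv}"), coli1, coli2)
    return {"sets": sets, "y": bundle.y, "als_selection": als_sel,
            "optical_selection": opt_sel, "fusion": fusion,
            "blv_report": blv_report}
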