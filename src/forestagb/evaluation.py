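"""Leave-one-out evaluation, the six accuracy indices, experiment runner,
wall-to-wall prediction and distribution comparison.

The six indices over actual/predicted plot AGB pairs (y, ŷ), with ȳ the mean
of the actuals:

    R²    squared Pearson correlation of y and ŷ
    RMSE  sqrt(Σ(y-ŷ)²/n)                (Mg/ha)
    rRMSE RMSE / ȳ
    MAE   Σ|y-ŷ|/n                       (Mg/ha)
    MAPE  100 Σ(|y-ŷ|/y)/n               (%)
    PM    Σ(y-ŷ)² / Σ(y-ȳ)²

A regression-sum-of-squares variant, eq5_r2 = Σ(ŷ-ȳ)²/Σ(y-ȳ)², is reported
alongside R²; unlike the squared correlation it is not bounded by 1 for
biased predictions.

LOOCV trains on n-1 plots and predicts the held-out plot, n times; per-fold
seeds are derived deterministically from the master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ModelSpec, TrainedModel, apply_budget, fit_model
from .stacking import StackModel, StackSpec, fit_stack

__all__ = [
    "EvalReport",
    "PredictionMap",
    "metrics_suite",
    "loocv_evaluate",
    "run_experiments",
    "wall_to_wall_predict",
    "histogram_compare",
]


@dataclass
class EvalReport:
    r2: float
    eq5_r2: float
    rmse: float
    rrmse: float
    mae: float
    mape: float
    pm: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {"r2": self.r2, "eq5_r2": self.eq5_r2, "rmse": self.rmse,
                "rrmse": self.rrmse, "mae": self.mae, "mape": self.mape,
                "pm": self.pm, "n": self.n}


def metrics_suite(y: np.ndarray, yhat: np.ndarray) -> EvalReport:
    """The six indices (plus eq5_r2) from aligned prediction pairs.

    Any y_i = 0 makes MAPE NaN (with a warning); zero variance in y makes
    PM, R² and eq5_r2 NaN.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("pair length mismatch")
    n = y.size
    if n < 2:
        raise ValueError("need at least two pairs")
    ybar = y.mean()
    resid = y - yhat
    rmse = float(np.sqrt((resid**2).mean()))
    mae = float(np.abs(resid).mean())
    rrmse = rmse / ybar if ybar != 0 else float("nan")
    if (y == 0).any():
        warnings.warn("zero actual AGB: MAPE undefined (NaN)", stacklevel=2)
        mape = float("nan")
    else:
        mape = float(100.0 * np.abs(resid / y).mean())
    sst = float(((y - ybar) ** 2).sum())
    if sst < 1e-300 or np.std(yhat) < 1e-300:
        if sst < 1e-300:
            warnings.warn("zero variance in actual AGB: PM/R² undefined",
                          stacklevel=2)
        pm = float((resid**2).sum() / sst) if sst > 0 else float("nan")
        r2 = float("nan") if (sst < 1e-300 or np.std(yhat) < 1e-300) else 0.0
        eq5 = float(((yhat - ybar) ** 2).sum() / sst) if sst > 0 else float("nan")
        if rmse == 0 and sst < 1e-300:
            pm = float("nan")
        return EvalReport(r2, eq5, rmse, rrmse, mae, mape, pm, n)
    pm = float((resid**2).sum() / sst)
    r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    eq5 = float(((yhat - ybar) ** 2).sum() / sst)
    return EvalReport(r2, eq5, rmse, rrmse, mae, mape, pm, n)


def _fit_predict(spec: ModelSpec | StackSpec, X_tr, y_tr, X_te) -> np.ndarray:
    if isinstance(spec, StackSpec):
        return fit_stack(spec, X_tr, y_tr).predict(X_te)
    return fit_model(spec, X_tr, y_tr).predict(X_te)


def loocv_evaluate(spec: ModelSpec | StackSpec, X: pd.DataFrame,
                   y: np.ndarray, master_seed: int = 0
                   ) -> tuple[pd.DataFrame, EvalReport]:
    """Leave-one-out cross-validation of a base model or a stack.

    Each plot is predicted by a model trained on the other n-1; the per-fold
    seed is ``master_seed + fold`` so reruns are bit-identical.  A failing
    fold records a NaN prediction and is excluded from the metrics (the
    returned pairs table carries an ``ok`` coverage flag).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least three plots")
    X = X.reset_index(drop=True)
    preds = np.full(n, np.nan)
    for i in range(n):
        tr = np.arange(n) != i
        fold_spec = spec.with_seed(master_seed + i)
        # KNN cannot use more neighbours than training rows
        if isinstance(fold_spec, ModelSpec) and fold_spec.algorithm == "KNN":
            k = fold_spec.resolved()["n_neighbors"]
            if n - 1 < k:
                params = dict(fold_spec.params)
                params["n_neighbors"] = n - 1
                fold_spec = ModelSpec("KNN", params, fold_spec.seed)
        try:
            preds[i] = _fit_predict(fold_spec, X.loc[tr], y[tr],
                                    X.loc[[i]])[0]
        except Exception as exc:
            warnings.warn(f"LOOCV fold {i} failed: {exc}", stacklevel=2)
    ok = np.isfinite(preds)
    pairs = pd.DataFrame({"y": y, "yhat": preds, "ok": ok})
    if ok.sum() < 2:
        raise ValueError("too few completed LOOCV folds")
    report = metrics_suite(y[ok], preds[ok])
    return pairs, report


def run_experiments(feature_sets: dict[str, pd.DataFrame], y: np.ndarray,
                    specs: dict[str, ModelSpec | StackSpec],
                    master_seed: int = 0) -> pd.DataFrame:
    """LOOCV over the cross product {feature set} x {algorithm}.

    Returns a tidy table (features, algorithm, r2, eq5_r2, rmse, rrmse, mae,
    mape, pm, n); failed cells carry NaN metrics.
    """
    rows = []
    for fid, table in feature_sets.items():
        for aid, spec in specs.items():
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, rep = loocv_evaluate(spec, table, y, master_seed)
                cell = rep.as_dict()
            except Exception as exc:
                warnings.warn(f"cell ({fid}, {aid}) failed: {exc}",
                              stacklevel=2)
                cell = dict.fromkeys(
                    ["r2", "eq5_r2", "rmse", "rrmse", "mae", "mape", "pm"],
                    float("nan"))
                cell["n"] = len(y)
            rows.append({"features": fid, "algorithm": aid, **cell})
    return pd.DataFrame(rows)


@dataclass
class PredictionMap:
    values: np.ndarray  # Mg/ha, NaN = nodata
    x_min: float
    y_max: float
    cell: float

    @property
    def summary(self) -> dict[str, float]:
        ok = np.isfinite(self.values)
        if not ok.any():
            return dict.fromkeys(("min", "max", "mean", "sd"), float("nan"))
        v = self.values[ok]
        return {"min": float(v.min()), "max": float(v.max()),
                "mean": float(v.mean()), "sd": float(v.std())}


def wall_to_wall_predict(model: TrainedModel | StackModel,
                         layers: dict[str, np.ndarray],
                         x_min: float = 0.0, y_max: float = 0.0,
                         cell: float = 30.0) -> PredictionMap:
    """Per-pixel AGB prediction from co-registered feature layers.

    Every model feature must be present as a layer; pixels with any NaN
    feature become nodata; negative predictions are clipped to 0.
    """
    if isinstance(model, StackModel):
        names = model.base_models[0].feature_names
    else:
        names = model.feature_names
    missing = [nm for nm in names if nm not in layers]
    if missing:
        raise KeyError(f"missing feature layers: {missing}")
    shape = layers[names[0]].shape
    mat = np.stack([layers[nm].ravel() for nm in names], axis=1)
    ok = np.isfinite(mat).all(axis=1)
    out = np.full(mat.shape[0], np.nan)
    if ok.any():
        X = pd.DataFrame(mat[ok], columns=list(names))
        out[ok] = np.maximum(model.predict(X), 0.0)
    return PredictionMap(out.reshape(shape), x_min, y_max, cell)


def histogram_compare(map_values: np.ndarray, plot_agb: np.ndarray,
                      bin_width: float = 50.0) -> pd.DataFrame:
    """Aligned relative-frequency histograms of map pixels vs plot actuals.

    Bins are half-open [lo, hi) of the given width from 0 to the common
    maximum (the last bin is closed at the top by construction of the edge).
    """
    mv = np.asarray(map_values, dtype=float).ravel()
    mv = mv[np.isfinite(mv)]
    pv = np.asarray(plot_agb, dtype=float).ravel()
    pv = pv[np.isfinite(pv)]
    if mv.size == 0 or pv.size == 0:
        raise ValueError("empty inputs")
    top = max(mv.max(), pv.max())
    n_bins = max(1, int(np.ceil((top + 1e-9) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    f_map = np.histogram(mv, bins=edges)[0] / mv.size
    f_plot = np.histogram(pv, bins=edges)[0] / pv.size
    return pd.DataFrame({
        "bin_lo": edges[:-1], "bin_hi": edges[1:],
        "freq_map": f_map, "freq_plots": f_plot,
        "difference": f_map - f_plot,
    })
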