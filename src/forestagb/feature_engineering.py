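"""Feature selection and optical-LiDAR fusion.

Two-step selection: (1) a Pearson filter keeps features whose correlation
with plot AGB is significant at alpha = 0.05 (two-sided p from the
t-transform of r with n-2 df); (2) the surviving features are ranked by
random-forest impurity importance, repeated over 10 seeded runs, and the most
stable high-ranking set (lowest mean rank; ties by |r| then name) is kept —
nine features per source by default.

The best LiDAR variable (BLV) is the single ALS metric whose univariate OLS
against AGB has the highest R².  Fusion features combine the BLV with each
selected optical feature SF_i:

    COLI1_i = SF_i * BLV
    COLI2_i = (BLV - SF_i) / (BLV + SF_i)

Experiment feature sets (by id): F1 optimal ALS (9), F2 optimal optical (9),
F1+2 (18), F4 all COLI1 (9), F5 all COLI2 (9), F2+3 optical + BLV (10),
F1+2+4 (27), F1+2+5 (27).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.ensemble import RandomForestRegressor

from .evaluation import metrics_suite

__all__ = [
    "SelectionResult",
    "FusionSpec",
    "pearson_filter",
    "rf_importance_ranking",
    "select_stable_top",
    "select_features",
    "best_lidar_variable",
    "compute_coli1",
    "compute_coli2",
    "assemble_experiment",
    "EXPERIMENT_IDS",
]

EXPERIMENT_IDS = ("F1", "F2", "F1+2", "F4", "F5", "F2+3", "F1+2+4", "F1+2+5")


@dataclass
class SelectionResult:
    """Pearson filter + repeated RF-importance ranking bookkeeping."""

    pearson_r: pd.Series = field(default_factory=pd.Series)
    pearson_p: pd.Series = field(default_factory=pd.Series)
    passing: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)  # undefined r
    ranks: pd.DataFrame | None = None  # features x runs
    mean_rank: pd.Series | None = None
    selected: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class FusionSpec:
    blv: str
    sf: tuple[str, ...]

    @property
    def coli1_names(self) -> tuple[str, ...]:
        return tuple(f"COLI1_{s}" for s in self.sf)

    @property
    def coli2_names(self) -> tuple[str, ...]:
        return tuple(f"COLI2_{s}" for s in self.sf)


def _feature_columns(table: pd.DataFrame, response: str) -> list[str]:
    return [c for c in table.columns if c not in ("plot_id", response)]


def pearson_filter(table: pd.DataFrame, response: str = "agb",
                   alpha: float = 0.05) -> SelectionResult:
    """Keep features significantly correlated with the response.

    Features with undefined correlation (zero variance, or fewer than three
    complete observations) are excluded with a log entry.
    """
    y = table[response].to_numpy(dtype=float)
    res = SelectionResult()
    rs, ps = {}, {}
    for col in _feature_columns(table, response):
        x = table[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) < 1e-15 or np.std(y[ok]) < 1e-15:
            res.excluded.append(col)
            continue
        r, p = sstats.pearsonr(x[ok], y[ok])
        rs[col], ps[col] = float(r), float(p)
        if p < alpha:
            res.passing.append(col)
    if res.excluded:
        warnings.warn(f"Pearson filter excluded {len(res.excluded)} features"
                      " with undefined correlation", stacklevel=2)
    res.pearson_r = pd.Series(rs, dtype=float)
    res.pearson_p = pd.Series(ps, dtype=float)
    return res


def rf_importance_ranking(table: pd.DataFrame, features: list[str],
                          response: str = "agb", n_runs: int = 10,
                          seeds: list[int] | None = None,
                          n_estimators: int = 1000,
                          result: SelectionResult | None = None
                          ) -> SelectionResult:
    """Repeated random-forest importance ranking of the passing features.

    Per run, impurity importances are converted to ranks (1 = most
    important); the mean rank across runs is the stability score.
    """
    if len(features) < 1:
        raise ValueError("no features to rank")
    y = table[response].to_numpy(dtype=float)
    if np.std(y) < 1e-15:
        raise ValueError("degenerate response: constant AGB")
    if seeds is None:
        seeds = list(range(n_runs))
    X = table[features].to_numpy(dtype=float)
    ranks = {}
    for run, seed in enumerate(seeds):
        rf = RandomForestRegressor(n_estimators=n_estimators,
                                   random_state=seed, n_jobs=1).fit(X, y)
        imp = rf.feature_importances_
        # descending importance -> ascending rank
        ranks[f"run{run}"] = sstats.rankdata(-imp, method="average")
    res = result if result is not None else SelectionResult()
    res.ranks = pd.DataFrame(ranks, index=features)
    res.mean_rank = res.ranks.mean(axis=1)
    return res


def select_stable_top(result: SelectionResult, k: int = 9) -> list[str]:
    """Top-k features by mean rank; ties by |r| descending, then name."""
    if result.mean_rank is None:
        raise ValueError("run rf_importance_ranking first")
    pool = list(result.mean_rank.index)
    if len(pool) < k:
        warnings.warn(f"only {len(pool)} features available for k={k};"
                      " returning the whole pool", stacklevel=2)
        k = len(pool)
    abs_r = result.pearson_r.abs()

    def key(name: str):
        return (float(result.mean_rank[name]),
                -float(abs_r.get(name, 0.0)), name)

    ordered = sorted(pool, key=key)
    result.selected = ordered[:k]
    return result.selected


def select_features(table: pd.DataFrame, response: str = "agb", k: int = 9,
                    alpha: float = 0.05, n_runs: int = 10,
                    n_estimators: int = 1000,
                    seeds: list[int] | None = None) -> SelectionResult:
    """Full two-step pipeline for one feature source."""
    res = pearson_filter(table, response, alpha)
    if not res.passing:
        raise ValueError("no feature passed the Pearson filter")
    rf_importance_ranking(table, res.passing, response, n_runs, seeds,
                          n_estimators, result=res)
    select_stable_top(res, k)
    return res


def best_lidar_variable(table: pd.DataFrame, features: list[str] | None = None,
                        response: str = "agb"
                        ) -> tuple[str, pd.DataFrame]:
    """Univariate OLS of AGB on each ALS feature; the winner is the feature
    with the highest R² (ties to 1e-12 broken by column order, logged).

    Returns (name, report) where the report carries the six evaluation
    metrics of the in-sample univariate fit per candidate.
    """
    if features is None:
        features = _feature_columns(table, response)
    if not features:
        raise ValueError("no ALS features supplied")
    y = table[response].to_numpy(dtype=float)
    rows = []
    for col in features:
        x = table[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) < 1e-15:
            continue
        slope, intercept = np.polyfit(x[ok], y[ok], 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = metrics_suite(y[ok], slope * x[ok] + intercept)
        rows.append({"feature": col, "r2": rep.r2, "rmse": rep.rmse,
                     "rrmse": rep.rrmse, "mae": rep.mae, "mape": rep.mape,
                     "pm": rep.pm})
    if not rows:
        raise ValueError("all univariate fits degenerate")
    report = pd.DataFrame(rows).set_index("feature")
    best_r2 = report["r2"].max()
    winners = [f for f in report.index if report.loc[f, "r2"] >= best_r2 - 1e-12]
    if len(winners) > 1:
        warnings.warn(f"R² tie among {winners}; keeping the first by column"
                      " order", stacklevel=2)
    return winners[0], report


def _require_columns(table: pd.DataFrame, names) -> None:
    missing = [n for n in names if n not in table.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")


def compute_coli1(table: pd.DataFrame, spec: FusionSpec) -> pd.DataFrame:
    """COLI1_i = SF_i * BLV, one new column per selected optical feature."""
    _require_columns(table, (spec.blv, *spec.sf))
    out = {}
    blv = table[spec.blv].to_numpy(dtype=float)
    for s, name in zip(spec.sf, spec.coli1_names):
        out[name] = table[s].to_numpy(dtype=float) * blv
    return pd.DataFrame(out, index=table.index)


def compute_coli2(table: pd.DataFrame, spec: FusionSpec) -> pd.DataFrame:
    """COLI2_i = (BLV - SF_i) / (BLV + SF_i); vanishing denominators
    (|BLV + SF_i| < 1e-12) yield NaN with a warning."""
    _require_columns(table, (spec.blv, *spec.sf))
    out = {}
    blv = table[spec.blv].to_numpy(dtype=float)
    n_bad = 0
    for s, name in zip(spec.sf, spec.coli2_names):
        sf = table[s].to_numpy(dtype=float)
        den = blv + sf
        bad = np.abs(den) < 1e-12
        n_bad += int(bad.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            out[name] = np.where(bad, np.nan, (blv - sf) / den)
    if n_bad:
        warnings.warn(f"COLI2: {n_bad} vanishing denominators set to NaN",
                      stacklevel=2)
    return pd.DataFrame(out, index=table.index)


def assemble_experiment(experiment_id: str, als_selected: pd.DataFrame,
                        optical_selected: pd.DataFrame, blv: pd.Series,
                        coli1: pd.DataFrame, coli2: pd.DataFrame
                        ) -> pd.DataFrame:
    """Assemble one of the eight experiment feature sets.

    All inputs must be row-aligned (same plot order).  ``blv`` is the single
    best-LiDAR-variable column.  Column counts are asserted against the
    design (9 / 9 / 18 / 9 / 9 / 10 / 27 / 27).
    """
    parts = {
        "F1": [als_selected],
        "F2": [optical_selected],
        "F1+2": [als_selected, optical_selected],
        "F4": [coli1],
        "F5": [coli2],
        "F2+3": [optical_selected, blv.to_frame()],
        "F1+2+4": [als_selected, optical_selected, coli1],
        "F1+2+5": [als_selected, optical_selected, coli2],
    }
    expected = {"F1": 9, "F2": 9, "F1+2": 18, "F4": 9, "F5": 9, "F2+3": 10,
                "F1+2+4": 27, "F1+2+5": 27}
    if experiment_id not in parts:
        raise ValueError(f"unknown experiment id {experiment_id!r};"
                         f" valid ids: {list(parts)}")
    out = pd.concat(parts[experiment_id], axis=1)
    if out.columns.duplicated().any():
        dup = list(out.columns[out.columns.duplicated()])
        raise ValueError(f"duplicate feature columns in {experiment_id}: {dup}")
    n_sel = als_selected.shape[1]  # tolerate pools smaller than 9
    if n_sel == 9 and optical_selected.shape[1] == 9:
        assert out.shape[1] == expected[experiment_id], (
            experiment_id, out.shape[1])
    return out
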