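"""Two-layer stacked generalization (SG).

Base models (default RF, SVR, KNN, CNN) are trained on the original feature
table; the meta model (any of the four) is trained on the base models'
predictions.  Meta-training predictions are produced out-of-fold by default:
a seeded inner K-fold (K = 5) partition, each base model trained on the
complement of a fold and predicting it, so no base prediction for row i ever
saw y_i.  The known-to-leak in-sample variant is available as
``inner="naive"`` for comparison.  For deployment, base models are refit on
the full training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .models import ModelSpec, TrainedModel, apply_budget, fit_model

__all__ = ["StackSpec", "MetaTrainingSet", "StackModel", "build_meta_features",
           "fit_stack", "default_stack_spec"]


@dataclass(frozen=True)
class StackSpec:
    base: tuple[ModelSpec, ...]
    meta: ModelSpec
    inner_k: int = 5
    inner: str = "oof"  # "oof" | "naive"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.base) < 2:
            raise ValueError("need at least two base models")
        if self.inner not in ("oof", "naive"):
            raise ValueError(f"unknown inner mode {self.inner!r}")

    def with_seed(self, seed: int) -> "StackSpec":
        return replace(
            self, seed=seed,
            base=tuple(b.with_seed(seed + i) for i, b in enumerate(self.base)),
            meta=self.meta.with_seed(seed + len(self.base)),
        )


def default_stack_spec(meta_algorithm: str = "RF", inner_k: int = 5,
                       seed: int = 0, budget: str = "full") -> StackSpec:
    """The canonical four-base stack: bases RF, SVR, KNN, CNN."""
    bases = tuple(
        apply_budget(ModelSpec(a, seed=seed + i), budget)
        for i, a in enumerate(("RF", "SVR", "KNN", "CNN"))
    )
    meta = apply_budget(ModelSpec(meta_algorithm, seed=seed + 10), budget)
    k = inner_k if budget == "full" else min(inner_k, 3)
    return StackSpec(bases, meta, inner_k=k, seed=seed)


@dataclass
class MetaTrainingSet:
    features: np.ndarray  # n x n_base, out-of-fold base predictions
    y: np.ndarray
    fold_of: np.ndarray  # fold index per row (-1 for naive mode)
    base_names: tuple[str, ...]


@dataclass
class StackModel:
    spec: StackSpec
    base_models: tuple[TrainedModel, ...]
    meta_model: TrainedModel
    meta_training: MetaTrainingSet = field(repr=False, default=None)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        base_preds = np.column_stack([m.predict(X) for m in self.base_models])
        return self.meta_model.predict(base_preds)


def build_meta_features(spec: StackSpec, X: pd.DataFrame | np.ndarray,
                        y: np.ndarray) -> MetaTrainingSet:
    """Out-of-fold base predictions as the meta-training matrix.

    Column j of row i comes from base model j trained with row i's fold held
    out, so perturbing y_i cannot move row i's own meta features.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if isinstance(X, pd.DataFrame):
        X = X.reset_index(drop=True)
    names = tuple(b.algorithm for b in spec.base)
    if spec.inner == "naive":
        cols = []
        for b in spec.base:
            cols.append(fit_model(b, X, y).predict(X))
        return MetaTrainingSet(np.column_stack(cols), y,
                               np.full(n, -1), names)
    k = spec.inner_k
    if k > n:
        raise ValueError(f"inner K={k} exceeds n={n}")
    if k < 2:
        raise ValueError("inner K must be >= 2")
    folds = KFold(n_splits=k, shuffle=True, random_state=spec.seed)
    feats = np.full((n, len(spec.base)), np.nan)
    fold_of = np.full(n, -1)
    for fold_idx, (tr, te) in enumerate(folds.split(np.arange(n))):
        fold_of[te] = fold_idx
        X_tr = X.iloc[tr] if isinstance(X, pd.DataFrame) else X[tr]
        X_te = X.iloc[te] if isinstance(X, pd.DataFrame) else X[te]
        for j, b in enumerate(spec.base):
            model = fit_model(b, X_tr, y[tr])
            feats[te, j] = model.predict(X_te)
    return MetaTrainingSet(feats, y, fold_of, names)


def fit_stack(spec: StackSpec, X: pd.DataFrame | np.ndarray,
              y: np.ndarray) -> StackModel:
    """Fit the two-layer stack: meta model on out-of-fold base predictions,
    base models refit on the full training set for deployment."""
    meta_set = build_meta_features(spec, X, y)
    meta_model = fit_model(spec.meta, meta_set.features, meta_set.y)
    bases = tuple(fit_model(b, X, meta_set.y) for b in spec.base)
    return StackModel(spec, bases, meta_model, meta_set)
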