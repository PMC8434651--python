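"""The eight base regression algorithms behind one fit/predict contract.

Algorithms: MLR (exact least squares), ELM (extreme learning machine, random
frozen hidden layer + least-squares readout, implemented from first
principles), BP (one-hidden-layer backprop network), RegT (regression tree),
RF (random forest, 1000 trees, random state 10), SVR (linear kernel, C = 1),
KNN (k = 5, uniform weights), CNN (1-D convolution over the feature vector:
32 filters of width 3, ReLU, flattened map, dense output; Adam, MSE loss,
1000 epochs, batch 30 — implemented in NumPy).

Features are standardized internally (training-set mean/SD) for the
scale-sensitive algorithms (ELM, BP, SVR, KNN, CNN); targets are standardized
for ELM/BP/SVR/CNN and predictions returned on the original scale.  Every
stochastic algorithm is fully seeded, so (spec, seed, data) determines the
fit exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR as SkSVR
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ALGORITHMS",
    "ModelSpec",
    "TrainedModel",
    "default_params",
    "fit_model",
    "elm_train",
    "apply_budget",
]

ALGORITHMS = ("MLR", "ELM", "BP", "RegT", "RF", "SVR", "KNN", "CNN")

_SCALE_X = {"ELM", "BP", "SVR", "KNN", "CNN"}
_SCALE_Y = {"ELM", "BP", "SVR", "CNN"}

_DEFAULTS: Mapping[str, dict[str, Any]] = {
    "MLR": {},
    "ELM": {"hidden_units": 64, "activation": "sigmoid"},
    "BP": {"hidden_units": 32, "epochs": 1000, "learning_rate": 0.01,
           "momentum": 0.9},
    "RegT": {},
    "RF": {"n_estimators": 1000, "random_state": 10},
    "SVR": {"kernel": "linear", "C": 1.0, "epsilon": 0.1},
    "KNN": {"n_neighbors": 5, "weights": "uniform"},
    "CNN": {"epochs": 1000, "batch_size": 30, "n_filters": 32, "kernel": 3,
            "learning_rate": 1e-3},
}


def default_params(algorithm: str) -> dict[str, Any]:
    if algorithm not in _DEFAULTS:
        raise ValueError(f"unknown algorithm {algorithm!r};"
                         f" choose one of {ALGORITHMS}")
    return dict(_DEFAULTS[algorithm])


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm identity + hyperparameters + seed."""

    algorithm: str
    params: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r};"
                             f" choose one of {ALGORITHMS}")

    def resolved(self) -> dict[str, Any]:
        out = default_params(self.algorithm)
        out.update(self.params)
        return out

    def with_seed(self, seed: int) -> "ModelSpec":
        return replace(self, seed=seed)


def apply_budget(spec: ModelSpec, budget: str = "full") -> ModelSpec:
    """Desk-scale profile: shrink the expensive fits without touching the
    algorithm identity.  ``small``: CNN 100 epochs, BP 200 epochs, RF 200
    trees.  ``full`` leaves the headline settings."""
    if budget == "full":
        return spec
    if budget != "small":
        raise ValueError(f"unknown budget {budget!r}")
    overrides = {"CNN": {"epochs": 100}, "BP": {"epochs": 200},
                 "RF": {"n_estimators": 200}}.get(spec.algorithm)
    if not overrides:
        return spec
    params = dict(spec.params)
    for key, val in overrides.items():
        params.setdefault(key, val)
        params[key] = min(params.get(key, val), val)
    return replace(spec, params=params)


# ---------------------------------------------------------------------------
# ELM
# ---------------------------------------------------------------------------

_ACTIVATIONS: Mapping[str, Callable[[np.ndarray], np.ndarray]] = {
    "sigmoid": lambda a: 1.0 / (1.0 + np.exp(-a)),
    "tanh": np.tanh,
    "linear": lambda a: a,
    "relu": lambda a: np.maximum(a, 0.0),
}


def elm_train(X: np.ndarray, y: np.ndarray, hidden_units: int,
              activation: str = "sigmoid", seed: int = 0
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Train an extreme learning machine on (standardized) data.

    Hidden weights/biases are drawn once from a seeded uniform(-1, 1) and
    frozen; the readout is the least-squares (minimum-norm pseudo-inverse)
    solution on the hidden activations with a bias column.  Returns
    (W_hidden, b_hidden, readout).
    """
    if hidden_units < 1:
        raise ValueError("hidden_units must be >= 1")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    rng = np.random.default_rng(seed)
    n, f = X.shape
    W = rng.uniform(-1.0, 1.0, size=(f, hidden_units))
    b = rng.uniform(-1.0, 1.0, size=hidden_units)
    H = _ACTIVATIONS[activation](X @ W + b)
    A = np.column_stack([H, np.ones(n)])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn("ELM activation matrix is rank deficient; using the"
                      " minimum-norm readout", stacklevel=2)
    return W, b, beta


def _elm_predict(X: np.ndarray, W: np.ndarray, b: np.ndarray,
                 beta: np.ndarray, activation: str) -> np.ndarray:
    H = _ACTIVATIONS[activation](X @ W + b)
    return np.column_stack([H, np.ones(len(X))]) @ beta


# ---------------------------------------------------------------------------
# CNN (NumPy, 1-D conv -> ReLU -> global average pooling -> dense)
# ---------------------------------------------------------------------------


class Conv1DNet:
    """Minimal 1-D convolutional regressor over a feature vector.

    Same-padded convolution (width ``kernel``, ``n_filters`` filters), ReLU,
    flattened feature map, dense scalar output.  Trained with Adam on MSE;
    fully deterministic given the seed.
    """

    def __init__(self, n_features: int, n_filters: int = 32, kernel: int = 3,
                 learning_rate: float = 1e-3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.kernel = kernel
        self.n_features = n_features
        scale = np.sqrt(2.0 / kernel)
        self.Wc = rng.normal(0.0, scale, size=(kernel, n_filters))
        self.bc = np.zeros(n_filters)
        n_flat = n_features * n_filters
        self.Wd = rng.normal(0.0, np.sqrt(1.0 / n_flat), size=n_flat)
        self.bd = 0.0
        self.lr = learning_rate
        self._adam = {k: [np.zeros_like(v), np.zeros_like(v)]
                      for k, v in self._params().items()}
        self._t = 0

    def _params(self) -> dict[str, np.ndarray]:
        return {"Wc": self.Wc, "bc": self.bc, "Wd": self.Wd,
                "bd": np.atleast_1d(np.asarray(self.bd, dtype=float))}

    def _windows(self, X: np.ndarray) -> np.ndarray:
        pad = self.kernel // 2
        Xp = np.pad(X, ((0, 0), (pad, pad)))
        return np.lib.stride_tricks.sliding_window_view(Xp, self.kernel, axis=1)

    def forward(self, X: np.ndarray):
        Xs = self._windows(X)               # (B, P, K)
        Z = Xs @ self.Wc + self.bc          # (B, P, F)
        A = np.maximum(Z, 0.0)
        G = A.reshape(A.shape[0], -1)       # (B, P*F)
        out = G @ self.Wd + self.bd
        return out, (Xs, Z, A, G)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def _step(self, X: np.ndarray, y: np.ndarray) -> float:
        out, (Xs, Z, A, G) = self.forward(X)
        B, P, _ = Z.shape
        err = out - y
        loss = float((err**2).mean())
        dout = 2.0 * err / B
        grads = {
            "Wd": G.T @ dout,
            "bd": np.atleast_1d(dout.sum()),
        }
        dG = np.outer(dout, self.Wd)                    # (B, P*F)
        dZ = dG.reshape(Z.shape) * (Z > 0)              # (B, P, F)
        grads["Wc"] = np.einsum("bpk,bpf->kf", Xs, dZ)
        grads["bc"] = dZ.sum(axis=(0, 1))
        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for name, g in grads.items():
            m, v = self._adam[name]
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g**2
            mh = m / (1 - b1**self._t)
            vh = v / (1 - b2**self._t)
            upd = self.lr * mh / (np.sqrt(vh) + eps)
            if name == "Wc":
                self.Wc -= upd
            elif name == "bc":
                self.bc -= upd
            elif name == "Wd":
                self.Wd -= upd
            else:
                self.bd -= float(upd[0])
        return loss

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int, batch_size: int,
            seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        n = len(X)
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                self._step(X[idx], y[idx])


# ---------------------------------------------------------------------------
# Uniform fit/predict contract
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    spec: ModelSpec
    feature_names: tuple[str, ...]
    x_mean: np.ndarray | None
    x_sd: np.ndarray | None
    y_mean: float
    y_sd: float
    state: Any

    def _prepare(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            have = list(X.columns)
            missing = [c for c in self.feature_names if c not in have]
            extra = [c for c in have if c not in self.feature_names]
            if missing or extra:
                raise ValueError(
                    f"feature columns mismatch training set:"
                    f" missing={missing}, extra={extra}"
                )
            mat = X[list(self.feature_names)].to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            if mat.ndim == 1:
                mat = mat[None, :]
            if mat.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected {len(self.feature_names)} features,"
                    f" got {mat.shape[1]}"
                )
        if self.x_mean is not None:
            mat = (mat - self.x_mean) / self.x_sd
        return mat

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        mat = self._prepare(X)
        alg = self.spec.algorithm
        if alg == "ELM":
            W, b, beta, activation = self.state
            raw = _elm_predict(mat, W, b, beta, activation)
        elif alg == "CNN":
            raw = self.state.predict(mat)
        else:
            raw = self.state.predict(mat)
        raw = np.asarray(raw, dtype=float).ravel()
        if alg in _SCALE_Y:
            raw = raw * self.y_sd + self.y_mean
        return raw


def _as_matrix(X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        cols = tuple(str(c) for c in X.columns)
        return X.to_numpy(dtype=float), cols
    mat = np.asarray(X, dtype=float)
    return mat, tuple(f"x{i}" for i in range(mat.shape[1]))


def fit_model(spec: ModelSpec, X: pd.DataFrame | np.ndarray,
              y: np.ndarray | pd.Series) -> TrainedModel:
    """Fit one base model under the uniform contract (see module docstring)."""
    mat, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    if mat.shape[0] != yv.shape[0]:
        raise ValueError("X and y length mismatch")
    if not np.isfinite(mat).all() or not np.isfinite(yv).all():
        raise ValueError("NaN/inf in training data")
    params = spec.resolved()
    alg = spec.algorithm

    x_mean = x_sd = None
    if alg in _SCALE_X:
        x_mean = mat.mean(axis=0)
        x_sd = mat.std(axis=0)
        x_sd = np.where(x_sd < 1e-12, 1.0, x_sd)
        mat = (mat - x_mean) / x_sd
    y_mean, y_sd = 0.0, 1.0
    yt = yv
    if alg in _SCALE_Y:
        y_mean = float(yv.mean())
        y_sd = float(yv.std())
        if y_sd < 1e-12:
            y_sd = 1.0
        yt = (yv - y_mean) / y_sd

    if alg == "MLR":
        state = LinearRegression().fit(mat, yt)
    elif alg == "ELM":
        W, b, beta = elm_train(mat, yt, params["hidden_units"],
                               params["activation"], spec.seed)
        state = (W, b, beta, params["activation"])
    elif alg == "BP":
        state = MLPRegressor(
            hidden_layer_sizes=(params["hidden_units"],),
            activation="logistic", solver="sgd",
            learning_rate_init=params["learning_rate"],
            momentum=params["momentum"], max_iter=params["epochs"],
            random_state=spec.seed, tol=0.0, n_iter_no_change=params["epochs"],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state.fit(mat, yt)
    elif alg == "RegT":
        state = DecisionTreeRegressor(random_state=spec.seed).fit(mat, yt)
    elif alg == "RF":
        state = RandomForestRegressor(
            n_estimators=params["n_estimators"],
            random_state=params["random_state"], n_jobs=1,
        ).fit(mat, yt)
    elif alg == "SVR":
        state = SkSVR(kernel=params["kernel"], C=params["C"],
                      epsilon=params["epsilon"]).fit(mat, yt)
    elif alg == "KNN":
        k = params["n_neighbors"]
        if mat.shape[0] < k:
            raise ValueError(f"KNN needs at least k={k} training rows,"
                             f" got {mat.shape[0]}")
        state = KNeighborsRegressor(n_neighbors=k,
                                    weights=params["weights"]).fit(mat, yt)
    elif alg == "CNN":
        net = Conv1DNet(mat.shape[1], params["n_filters"], params["kernel"],
                        params["learning_rate"], seed=spec.seed)
        net.fit(mat, yt, params["epochs"], params["batch_size"],
                seed=spec.seed + 1)
        state = net
    else:  # pragma: no cover
        raise AssertionError(alg)

    return TrainedModel(spec, names, x_mean, x_sd, y_mean, y_sd, state)
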