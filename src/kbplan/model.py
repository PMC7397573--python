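"""Shallow neural-network regression of dose objectives from geometry.

A fully connected 3-layer network (default 275 inputs, 184 hidden
logistic units, 21 linear outputs) maps the normalised OVH/TVH feature
vector to the 21 normalised dose objectives.  Training is plain
full-batch gradient descent on the mean squared error — learning rate
0.02 for 2500 iterations by default.  Five models are trained under a
chronological 5-fold cross-validation split of the knowledge library;
the deployed predictor is the arithmetic mean (in cGy, after each
fold's own denormalisation) of the five fold predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .features import (
    FeatureScaler,
    FeatureVector,
    LayoutEntry,
    LibraryMatrix,
    apply_scaler,
    fit_scaler,
    inverse_scaler,
    layout_column_names,
    layout_from_column_names,
    scaler_from_dict,
    scaler_to_dict,
)

DEFAULT_DIMS = (275, 184, 21)
MODEL_SCHEMA = "kbplan-ensemble-v1"


@dataclass
class NNParams:
    """Weights and biases of one 3-layer network.

    ``W1`` is input_dim x hidden_dim, ``W2`` hidden_dim x output_dim;
    the hidden activation is the logistic sigmoid, the output layer is
    linear (targets are min-max normalised to [0, 1]).
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    activation: str = "logistic"

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        d_in, d_hid = self.W1.shape
        if self.b1.shape != (d_hid,):
            raise ValueError("b1 shape inconsistent with W1")
        if self.W2.shape[0] != d_hid:
            raise ValueError("W2 rows inconsistent with hidden dim")
        if self.b2.shape != (self.W2.shape[1],):
            raise ValueError("b2 shape inconsistent with W2")
        if self.activation != "logistic":
            raise ValueError(f"unsupported activation {self.activation!r}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return (self.W1.shape[0], self.W1.shape[1], self.W2.shape[1])


@dataclass(frozen=True)
class TrainConfig:
    """Gradient-descent settings; the defaults are the reference setup."""

    learning_rate: float = 0.02
    iterations: int = 2500
    seed: int = 2016
    init_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def init_network(
    dims: tuple[int, int, int] = DEFAULT_DIMS,
    seed: int = 2016,
    init_scale: float = 1.0,
) -> NNParams:
    """Glorot-style scaled-uniform initialisation, deterministic per seed.

    Weights are drawn uniformly from [-r, r] with
    r = init_scale * sqrt(6 / (fan_in + fan_out)); biases start at zero.
    """
    if any(d < 1 for d in dims):
        raise ValueError("all dims must be positive")
    d_in, d_hid, d_out = dims
    rng = np.random.default_rng(seed)
    r1 = init_scale * np.sqrt(6.0 / (d_in + d_hid))
    r2 = init_scale * np.sqrt(6.0 / (d_hid + d_out))
    return NNParams(
        W1=rng.uniform(-r1, r1, size=(d_in, d_hid)),
        b1=np.zeros(d_hid),
        W2=rng.uniform(-r2, r2, size=(d_hid, d_out)),
        b2=np.zeros(d_out),
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward(params: NNParams, x: np.ndarray) -> np.ndarray:
    """Network output for one vector or a batch (rows = samples)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != params.dims[0]:
        raise ValueError(
            f"input has {X.shape[1]} features, network expects {params.dims[0]}"
        )
    h = _sigmoid(X @ params.W1 + params.b1)
    out = h @ params.W2 + params.b2
    return out[0] if single else out


def loss(params: NNParams, X: np.ndarray, Y: np.ndarray) -> float:
    """Mean squared error over all samples and output nodes."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty training batch")
    pred = forward(params, X)
    return float(np.mean((pred - Y) ** 2))


def gradient(params: NNParams, X: np.ndarray, Y: np.ndarray) -> NNParams:
    """Exact gradient of :func:`loss` by backpropagation.

    Returned as a parameter-shaped :class:`NNParams` container.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != params.dims[0]:
        raise ValueError("input dimension mismatch")
    n, m = Y.shape
    h = _sigmoid(X @ params.W1 + params.b1)
    pred = h @ params.W2 + params.b2
    # dL/dpred for L = mean over n*m squared errors
    delta_out = 2.0 * (pred - Y) / (n * m)
    gW2 = h.T @ delta_out
    gb2 = delta_out.sum(axis=0)
    delta_hid = (delta_out @ params.W2.T) * h * (1.0 - h)
    gW1 = X.T @ delta_hid
    gb1 = delta_hid.sum(axis=0)
    return NNParams(gW1, gb1, gW2, gb2)


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, iteration: int, fold: int | None = None) -> None:
        msg = f"diverged at iteration {iteration}"
        if fold is not None:
            msg += f" in fold {fold}"
        super().__init__(msg)
        self.iteration = iteration
        self.fold = fold


def train(
    X: np.ndarray,
    Y: np.ndarray,
    config: TrainConfig = TrainConfig(),
    dims: tuple[int, int, int] | None = None,
) -> tuple[NNParams, np.ndarray]:
    """Full-batch gradient descent for exactly ``config.iterations`` steps.

    ``X`` and ``Y`` are expected normalised to [0, 1].  The training
    cost is the per-node mean squared error summed over the output
    nodes and averaged over samples (i.e. 21x the :func:`loss` metric
    for the default output width); descent steps use its exact
    gradient.  Returns the final parameters and the per-iteration
    :func:`loss` trace (evaluated before each update).  Deterministic
    given the seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("at least one training sample required")
    if dims is None:
        dims = (X.shape[1], DEFAULT_DIMS[1], Y.shape[1])
    params = init_network(dims, seed=config.seed, init_scale=config.init_scale)
    trace = np.empty(config.iterations)
    lr = config.learning_rate
    for it in range(config.iterations):
        h = _sigmoid(X @ params.W1 + params.b1)
        pred = h @ params.W2 + params.b2
        err = pred - Y
        current = float(np.mean(err**2))
        if not np.isfinite(current):
            raise DivergenceError(it)
        trace[it] = current
        n = Y.shape[0]
        # training cost: sum over output nodes of per-node MSE
        delta_out = 2.0 * err / n
        delta_hid = (delta_out @ params.W2.T) * h * (1.0 - h)
        params.W2 -= lr * (h.T @ delta_out)
        params.b2 -= lr * delta_out.sum(axis=0)
        params.W1 -= lr * (X.T @ delta_hid)
        params.b1 -= lr * delta_hid.sum(axis=0)
    return params, trace


def chronological_folds(n: int, k: int) -> np.ndarray:
    """Contiguous chronological fold assignment for n patients, k folds.

    Fold sizes differ by at most one, with larger folds first
    (n=7, k=5 gives sizes 2, 2, 1, 1, 1).  Returns an integer array of
    fold indices per patient, in chronological order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} patients into {k} folds")
    assignment = np.empty(n, dtype=int)
    base, extra = divmod(n, k)
    start = 0
    for fold in range(k):
        size = base + (1 if fold < extra else 0)
        assignment[start : start + size] = fold
        start += size
    return assignment


@dataclass
class FoldModel:
    """One cross-validation fold: its network and its own scalers."""

    params: NNParams
    feature_scaler: FeatureScaler
    objective_scaler: FeatureScaler
    validation_loss: float


@dataclass
class EnsembleModel:
    """The k fold models whose mean (cGy) prediction is deployed."""

    folds: list[FoldModel]
    layout: list[LayoutEntry]
    fold_assignments: np.ndarray
    train_config: TrainConfig = field(default_factory=TrainConfig)

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def cross_validate(
    library: LibraryMatrix,
    config: TrainConfig = TrainConfig(),
    k: int = 5,
    hidden_dim: int = DEFAULT_DIMS[1],
) -> EnsembleModel:
    """Chronological k-fold cross-validation over a knowledge library.

    For each fold, min-max scalers for features and objectives are
    fitted on the k-1 training folds only (no leakage), one network is
    trained on the normalised training rows, and the normalised MSE on
    the held-out fold is recorded.  Per-fold training seeds are derived
    as ``config.seed + fold_index``.
    """
    assignment = chronological_folds(library.n_patients, k)
    folds: list[FoldModel] = []
    for fold in range(k):
        train_rows = assignment != fold
        val_rows = assignment == fold
        fscaler = fit_scaler(library.X[train_rows])
        oscaler = fit_scaler(library.Y[train_rows])
        Xn = apply_scaler(fscaler, library.X[train_rows])
        Yn = apply_scaler(oscaler, library.Y[train_rows])
        fold_config = replace(config, seed=config.seed + fold)
        try:
            params, _ = train(
                Xn, Yn, fold_config, dims=(Xn.shape[1], hidden_dim, Yn.shape[1])
            )
        except DivergenceError as exc:
            raise DivergenceError(exc.iteration, fold=fold) from exc
        Xv = apply_scaler(fscaler, library.X[val_rows], clip=True)
        Yv = apply_scaler(oscaler, library.Y[val_rows])
        val_loss = loss(params, Xv, Yv)
        folds.append(FoldModel(params, fscaler, oscaler, val_loss))
    return EnsembleModel(folds, library.layout, assignment, config)


def predict(ensemble: EnsembleModel, features: FeatureVector) -> np.ndarray:
    """Ensemble-mean dose objectives (cGy) for one patient.

    Each fold normalises the features with its own scaler (clipping to
    the trained domain), predicts, denormalises to cGy; the final
    output is the arithmetic mean of the fold predictions.
    """
    if features.layout != ensemble.layout:
        raise ValueError("feature layout does not match the model layout")
    preds = []
    for fm in ensemble.folds:
        xn = apply_scaler(fm.feature_scaler, features.values, clip=True)
        yn = forward(fm.params, xn)
        preds.append(inverse_scaler(fm.objective_scaler, yn))
    return np.mean(preds, axis=0)


# ---------------------------------------------------------------------------
# Model persistence (JSON)


def _params_to_dict(p: NNParams) -> dict:
    return {
        "W1": p.W1.tolist(),
        "b1": p.b1.tolist(),
        "W2": p.W2.tolist(),
        "b2": p.b2.tolist(),
        "activation": p.activation,
    }


def _params_from_dict(d: dict) -> NNParams:
    return NNParams(
        np.array(d["W1"]), np.array(d["b1"]),
        np.array(d["W2"]), np.array(d["b2"]),
        d.get("activation", "logistic"),
    )


def save_ensemble(ensemble: EnsembleModel, path: str) -> None:
    payload = {
        "schema": MODEL_SCHEMA,
        "dims": list(ensemble.folds[0].params.dims),
        "layout": layout_column_names(ensemble.layout),
        "train_config": {
            "learning_rate": ensemble.train_config.learning_rate,
            "iterations": ensemble.train_config.iterations,
            "seed": ensemble.train_config.seed,
            "init_scale": ensemble.train_config.init_scale,
        },
        "fold_assignments": ensemble.fold_assignments.tolist(),
        "folds": [
            {
                "params": _params_to_dict(fm.params),
                "feature_scaler": scaler_to_dict(fm.feature_scaler),
                "objective_scaler": scaler_to_dict(fm.objective_scaler),
                "validation_loss": fm.validation_loss,
            }
            for fm in ensemble.folds
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_ensemble(path: str) -> EnsembleModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema") != MODEL_SCHEMA:
        raise ValueError(f"unknown model schema {payload.get('schema')!r}")
    tc = payload["train_config"]
    return EnsembleModel(
        folds=[
            FoldModel(
                _params_from_dict(f["params"]),
                scaler_from_dict(f["feature_scaler"]),
                scaler_from_dict(f["objective_scaler"]),
                float(f["validation_loss"]),
            )
            for f in payload["folds"]
        ],
        layout=layout_from_column_names(payload["layout"]),
        fold_assignments=np.array(payload["fold_assignments"], dtype=int),
        train_config=TrainConfig(
            tc["learning_rate"], tc["iterations"], tc["seed"], tc["init_scale"]
        ),
    )
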