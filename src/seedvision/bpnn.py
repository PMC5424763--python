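"""A from-scratch three-layer back-propagation neural network.

Architecture: ``ni`` inputs, ``nh = ceil(0.5 * (ni + no))`` hidden units and
``no = 2`` outputs (good / NG), logistic sigmoid throughout, one-hot targets
and mean-squared-error loss.  Training is plain online (per-sample) gradient
descent: samples are visited in a freshly shuffled order each epoch and the
weights updated after every sample.  Training stops once the epoch-mean MSE
drops below the tolerance (default 0.01 at learning rate 0.01) or the epoch
budget runs out, in which case the model is flagged non-converged but still
returned.  All randomness (weight init, shuffling) comes from one seed, so
training is bit-reproducible.

Two trained networks — one on shape features, one on color-texture features —
grade a seed jointly: it is good only if both say good (AND rule).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

GOOD, NG = "good", "ng"
_LABELS = (GOOD, NG)


def hidden_nodes(ni: int, no: int) -> int:
    """Hidden-layer size: ceil(0.5 * (ni + no))."""
    if ni < 1 or no < 1:
        raise ValueError("ni and no must be >= 1")
    return math.ceil(0.5 * (ni + no))


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    mse_tolerance: float = 0.01
    max_epochs: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate > 0 required")
        if self.mse_tolerance <= 0:
            raise ValueError("mse_tolerance > 0 required")
        if self.max_epochs < 1:
            raise ValueError("max_epochs >= 1 required")


@dataclass
class BPNNModel:
    """Weights, normalization bounds and training metadata of one network."""

    n_input: int
    n_hidden: int
    n_output: int
    w1: np.ndarray  # (nh, ni)
    b1: np.ndarray  # (nh,)
    w2: np.ndarray  # (no, nh)
    b2: np.ndarray  # (no,)
    bounds: np.ndarray | None  # (2, ni) min/max per feature, or None
    rng_seed: int
    final_mse: float
    n_epochs: int
    converged: bool
    feature_columns: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_input": self.n_input, "n_hidden": self.n_hidden, "n_output": self.n_output,
            "w1": self.w1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2.tolist(),
            "bounds": None if self.bounds is None else self.bounds.tolist(),
            "rng_seed": self.rng_seed, "final_mse": self.final_mse,
            "n_epochs": self.n_epochs, "converged": self.converged,
            "feature_columns": self.feature_columns,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BPNNModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            n_input=d["n_input"], n_hidden=d["n_hidden"], n_output=d["n_output"],
            w1=np.array(d["w1"]), b1=np.array(d["b1"]),
            w2=np.array(d["w2"]), b2=np.array(d["b2"]),
            bounds=None if d["bounds"] is None else np.array(d["bounds"]),
            rng_seed=d["rng_seed"], final_mse=d["final_mse"],
            n_epochs=d["n_epochs"], converged=d["converged"],
            feature_columns=list(d.get("feature_columns", [])),
        )


def normalize_fit(features: np.ndarray) -> np.ndarray:
    """Per-feature (min, max) bounds from a training matrix.

    Raises if any feature is constant (naming its column index): a constant
    feature carries no information and would divide by zero.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    lo, hi = X.min(axis=0), X.max(axis=0)
    const = np.nonzero(hi <= lo)[0]
    if const.size:
        raise ValueError(f"constant feature(s) at column(s) {const.tolist()}: "
                         "min == max, cannot scale")
    return np.vstack([lo, hi])


def normalize_apply(bounds: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Min-max scale rows into [0, 1]; out-of-range values are clipped."""
    bounds = np.asarray(bounds, dtype=np.float64)
    rows = np.asarray(rows, dtype=np.float64)
    scaled = (rows - bounds[0]) / (bounds[1] - bounds[0])
    return np.clip(scaled, 0.0, 1.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def forward(w1, b1, w2, b2, x):
    """One forward pass; returns (hidden, output) activations."""
    h = _sigmoid(w1 @ x + b1)
    o = _sigmoid(w2 @ h + b2)
    return h, o


def gradients(w1, b1, w2, b2, x, t):
    """Analytic MSE gradients for a single sample.

    Loss is mean((t - o)^2) over output nodes; returns (gw1, gb1, gw2, gb2).
    """
    h, o = forward(w1, b1, w2, b2, x)
    no = o.shape[0]
    delta_o = (2.0 / no) * (o - t) * o * (1.0 - o)
    gw2 = np.outer(delta_o, h)
    gb2 = delta_o
    delta_h = (w2.T @ delta_o) * h * (1.0 - h)
    gw1 = np.outer(delta_h, x)
    gb1 = delta_h
    return gw1, gb1, gw2, gb2


@njit(cache=True)
def _train_epoch(w1, b1, w2, b2, X, T, order, lr):  # pragma: no cover - numba kernel
    n = order.shape[0]
    nh = w1.shape[0]
    no = w2.shape[0]
    ni = w1.shape[1]
    sse = 0.0
    for idx in range(n):
        s = order[idx]
        x = X[s]
        t = T[s]
        h = np.empty(nh)
        for j in range(nh):
            z = b1[j]
            for i in range(ni):
                z += w1[j, i] * x[i]
            h[j] = 1.0 / (1.0 + np.exp(-z))
        o = np.empty(no)
        for k in range(no):
            z = b2[k]
            for j in range(nh):
                z += w2[k, j] * h[j]
            o[k] = 1.0 / (1.0 + np.exp(-z))
        delta_o = np.empty(no)
        for k in range(no):
            err = o[k] - t[k]
            sse += err * err
            delta_o[k] = (2.0 / no) * err * o[k] * (1.0 - o[k])
        delta_h = np.empty(nh)
        for j in range(nh):
            acc = 0.0
            for k in range(no):
                acc += w2[k, j] * delta_o[k]
            delta_h[j] = acc * h[j] * (1.0 - h[j])
        for k in range(no):
            for j in range(nh):
                w2[k, j] -= lr * delta_o[k] * h[j]
            b2[k] -= lr * delta_o[k]
        for j in range(nh):
            for i in range(ni):
                w1[j, i] -= lr * delta_h[j] * x[i]
            b1[j] -= lr * delta_h[j]
    return sse / (n * no)


def train(samples: np.ndarray, targets: np.ndarray, cfg: TrainConfig | None = None,
          bounds: np.ndarray | None = None,
          feature_columns: list[str] | None = None) -> BPNNModel:
    """Train a network on normalized samples with one-hot targets.

    ``samples`` is (n, ni) in [0, 1]; ``targets`` is (n, 2) one-hot with
    column 0 = good, column 1 = NG.  Both classes must be present.
    """
    cfg = cfg or TrainConfig()
    X = np.ascontiguousarray(samples, dtype=np.float64)
    T = np.ascontiguousarray(targets, dtype=np.float64)
    if np.isnan(X).any() or np.isnan(T).any():
        raise ValueError("NaN in training inputs")
    if X.ndim != 2 or T.shape != (X.shape[0], 2):
        raise ValueError("samples must be (n, ni) and targets (n, 2)")
    if T[:, 0].sum() == 0 or T[:, 1].sum() == 0:
        raise ValueError("need at least one sample per class")
    n, ni = X.shape
    no = 2
    nh = hidden_nodes(ni, no)
    rng = np.random.default_rng(cfg.rng_seed)
    w1 = rng.uniform(-0.5, 0.5, size=(nh, ni))
    b1 = rng.uniform(-0.5, 0.5, size=nh)
    w2 = rng.uniform(-0.5, 0.5, size=(no, nh))
    b2 = rng.uniform(-0.5, 0.5, size=no)
    mse = math.inf
    epoch = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        mse = float(_train_epoch(w1, b1, w2, b2, X, T, order, cfg.learning_rate))
        if mse < cfg.mse_tolerance:
            break
    converged = mse < cfg.mse_tolerance
    if not converged:
        warnings.warn(f"BPNN did not reach MSE < {cfg.mse_tolerance} "
                      f"within {cfg.max_epochs} epochs (final MSE {mse:.4f})")
    return BPNNModel(
        n_input=ni, n_hidden=nh, n_output=no,
        w1=w1, b1=b1, w2=w2, b2=b2,
        bounds=None if bounds is None else np.asarray(bounds, dtype=np.float64),
        rng_seed=cfg.rng_seed, final_mse=mse, n_epochs=epoch, converged=converged,
        feature_columns=list(feature_columns or []),
    )


def train_classifier(features: np.ndarray, labels, cfg: TrainConfig | None = None,
                     feature_columns: list[str] | None = None) -> BPNNModel:
    """Fit normalization bounds on raw features, then train on scaled data."""
    features = np.asarray(features, dtype=np.float64)
    bounds = normalize_fit(features)
    X = normalize_apply(bounds, features)
    T = one_hot(labels)
    return train(X, T, cfg, bounds=bounds, feature_columns=feature_columns)


def one_hot(labels) -> np.ndarray:
    """Map good/ng labels to one-hot rows (good, ng)."""
    out = np.zeros((len(labels), 2), dtype=np.float64)
    for i, lab in enumerate(labels):
        if lab not in _LABELS:
            raise ValueError(f"unknown label {lab!r}")
        out[i, 0 if lab == GOOD else 1] = 1.0
    return out


def predict(model: BPNNModel, row: np.ndarray) -> tuple[str, np.ndarray]:
    """Classify one raw feature row; ties go to NG (conservative)."""
    row = np.asarray(row, dtype=np.float64)
    if row.shape != (model.n_input,):
        raise ValueError(f"row length {row.shape} != n_input {model.n_input}")
    if model.bounds is not None:
        row = normalize_apply(model.bounds, row)
    _, o = forward(model.w1, model.b1, model.w2, model.b2, row)
    label = GOOD if o[0] > o[1] else NG
    return label, o


def predict_batch(model: BPNNModel, rows: np.ndarray) -> list[str]:
    rows = np.asarray(rows, dtype=np.float64)
    if model.bounds is not None:
        rows = normalize_apply(model.bounds, rows)
    h = _sigmoid(rows @ model.w1.T + model.b1)
    o = _sigmoid(h @ model.w2.T + model.b2)
    return [GOOD if row[0] > row[1] else NG for row in o]


def combine(shape_label: str, colortex_label: str) -> str:
    """AND rule: a seed is good only if both networks say good."""
    for lab in (shape_label, colortex_label):
        if lab not in _LABELS:
            raise ValueError(f"unknown label {lab!r}")
    return GOOD if shape_label == GOOD and colortex_label == GOOD else NG
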