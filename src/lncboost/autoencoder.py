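"""Single-hidden-layer sigmoid autoencoder trained on per-element cross-entropy.

Inputs are min-max scaled to [0, 1] (the cross-entropy reconstruction loss
requires it); the scaler is fitted on training data only and stored with the
model. Optimization is plain seeded mini-batch gradient descent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_EPS = 1e-12


@dataclass
class AeTrainConfig:
    epochs: int = 100
    batch_size: int = 128
    latent_dim: int = 128
    seed: int = 0
    step_size: float = 0.5

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


@dataclass
class MinMaxScaler:
    """Per-column min-max scaling to [0, 1]; constant columns map to 0."""

    data_min: np.ndarray
    data_range: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaler":
        lo = X.min(axis=0)
        rng = X.max(axis=0) - lo
        rng[rng == 0] = 1.0
        return cls(data_min=lo, data_range=rng)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.clip((X - self.data_min) / self.data_range, 0.0, 1.0)


@dataclass
class EncoderModel:
    """Encoder/decoder weights and thresholds plus the training-loss trace."""

    w: np.ndarray       # encoder weights, (input_dim, latent_dim)
    b: np.ndarray       # encoder threshold
    beta: np.ndarray    # decoder weights, (latent_dim, input_dim)
    gamma: np.ndarray   # decoder threshold
    scaler: MinMaxScaler
    loss_trace: list[float] = field(default_factory=list)

    @property
    def latent_dim(self) -> int:
        return self.w.shape[1]

    @property
    def input_dim(self) -> int:
        return self.w.shape[0]

    def save(self, path: str | Path) -> None:
        payload = {
            "w": self.w.tolist(),
            "b": self.b.tolist(),
            "beta": self.beta.tolist(),
            "gamma": self.gamma.tolist(),
            "data_min": self.scaler.data_min.tolist(),
            "data_range": self.scaler.data_range.tolist(),
            "loss_trace": self.loss_trace,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "EncoderModel":
        d = json.loads(Path(path).read_text())
        return cls(
            w=np.array(d["w"]),
            b=np.array(d["b"]),
            beta=np.array(d["beta"]),
            gamma=np.array(d["gamma"]),
            scaler=MinMaxScaler(np.array(d["data_min"]), np.array(d["data_range"])),
            loss_trace=list(d["loss_trace"]),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _cross_entropy(x: np.ndarray, xhat: np.ndarray) -> float:
    xhat = np.clip(xhat, _EPS, 1.0 - _EPS)
    return float(-np.mean(x * np.log(xhat) + (1.0 - x) * np.log(1.0 - xhat)))


def train_autoencoder(X: np.ndarray, config: AeTrainConfig | None = None) -> EncoderModel:
    """Fit the autoencoder by seeded mini-batch gradient descent.

    Records the full-data reconstruction loss once per epoch (trace length =
    epochs). Deterministic for a fixed seed.
    """
    config = config or AeTrainConfig()
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite inputs")
    n, d = X.shape
    if config.latent_dim > d:
        raise ValueError("latent_dim exceeds input dimension")
    scaler = MinMaxScaler.fit(X)
    Xs = scaler.transform(X)

    rng = np.random.default_rng(config.seed)
    h = config.latent_dim
    w = rng.uniform(-0.05, 0.05, size=(d, h))
    b = rng.uniform(-0.05, 0.05, size=h)
    beta = rng.uniform(-0.05, 0.05, size=(h, d))
    gamma = rng.uniform(-0.05, 0.05, size=d)

    lr = config.step_size
    trace: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = Xs[idx]
            z = _sigmoid(xb @ w + b)
            xhat = _sigmoid(z @ beta + gamma)
            # cross-entropy + sigmoid output: d(loss)/d(pre-activation) = xhat - x
            d2 = (xhat - xb) / len(idx)
            d1 = (d2 @ beta.T) * z * (1.0 - z)
            beta -= lr * (z.T @ d2)
            gamma -= lr * d2.sum(axis=0)
            w -= lr * (xb.T @ d1)
            b -= lr * d1.sum(axis=0)
        z = _sigmoid(Xs @ w + b)
        trace.append(_cross_entropy(Xs, _sigmoid(z @ beta + gamma)))
    return EncoderModel(w=w, b=b, beta=beta, gamma=gamma, scaler=scaler, loss_trace=trace)


def encode(model: EncoderModel, X: np.ndarray) -> np.ndarray:
    """Latent representation of ``X`` (rows of length latent_dim, in (0, 1))."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.input_dim:
        raise ValueError(f"expected {model.input_dim} columns, got {X.shape[1]}")
    return _sigmoid(model.scaler.transform(X) @ model.w + model.b)


def reconstruct(model: EncoderModel, X: np.ndarray) -> np.ndarray:
    """Decoder output on the scaled inputs (for reconstruction-error checks)."""
    return _sigmoid(encode(model, X) @ model.beta + model.gamma)
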