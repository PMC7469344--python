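"""Gradient boosting of regression trees on the binomial log-loss.

The additive model is F_m(x) = F_{m-1}(x) + eta * rho_m * h_m(x): the base
score F_0 is the training log-odds, each regression tree h_m is fit by least
squares to the negative gradient of the log-loss (the residual y - p), and
the step rho_m is either the per-terminal-region Newton step (default) or a
single global line-search step. Raw scores live on the log-odds scale and
are mapped through the logistic link for probabilities.

The CART least-squares tree fitting itself is delegated to
sklearn.tree.DecisionTreeRegressor; the boosting procedure is implemented
here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.tree import DecisionTreeRegressor

_EPS = 1e-12


@dataclass
class GbmConfig:
    max_depth: int = 3
    n_trees: int = 1200
    learning_rate: float = 0.1
    seed: int = 0
    step_rule: str = "newton_per_leaf"  # or "global_line_search"

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        # learning_rate 0 is a legal edge case (no updates; base-rate model)
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError("learning_rate must be in [0, 1]")


@dataclass
class _TreeRecord:
    """Flattened split records of one fitted regression tree."""

    feature: np.ndarray          # split feature per node (-2 for leaves)
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray            # leaf contribution (rho already folded in)

    def apply(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(len(X), dtype=np.int64)
        while True:
            internal = self.feature[node] >= 0
            if not internal.any():
                return self.value[node]
            feat = self.feature[node].clip(min=0)
            go_left = X[np.arange(len(X)), feat] <= self.threshold[node]
            nxt = np.where(go_left, self.left[node], self.right[node])
            node = np.where(internal, nxt, node)


@dataclass
class BoostedModel:
    f0: float
    trees: list[_TreeRecord]
    learning_rate: float
    loss_trace: list[float] = field(default_factory=list)
    config: GbmConfig | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def raw_score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.full(len(X), self.f0)
        for t in self.trees:
            out += self.learning_rate * t.apply(X)
        return out

    def save(self, path: str | Path) -> None:
        payload = {
            "f0": self.f0,
            "learning_rate": self.learning_rate,
            "loss_trace": self.loss_trace,
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "value": t.value.tolist(),
                }
                for t in self.trees
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "BoostedModel":
        d = json.loads(Path(path).read_text())
        trees = [
            _TreeRecord(
                feature=np.array(t["feature"], dtype=np.int64),
                threshold=np.array(t["threshold"]),
                left=np.array(t["left"], dtype=np.int64),
                right=np.array(t["right"], dtype=np.int64),
                value=np.array(t["value"]),
            )
            for t in d["trees"]
        ]
        return cls(f0=d["f0"], trees=trees, learning_rate=d["learning_rate"],
                   loss_trace=list(d["loss_trace"]))


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def log_loss(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _record_from_sklearn(tree: DecisionTreeRegressor, leaf_values: dict[int, float]) -> _TreeRecord:
    t = tree.tree_
    value = np.zeros(t.node_count)
    for leaf, v in leaf_values.items():
        value[leaf] = v
    return _TreeRecord(
        feature=t.feature.astype(np.int64).copy(),
        threshold=t.threshold.copy(),
        left=t.children_left.astype(np.int64).copy(),
        right=t.children_right.astype(np.int64).copy(),
        value=value,
    )


def train_gbm(X: np.ndarray, y: np.ndarray, config: GbmConfig | None = None) -> BoostedModel:
    """Fit the boosted-tree classifier; deterministic for a fixed seed.

    Each round fits a depth-limited least-squares tree to the residual
    y - p, then replaces leaf outputs with the Newton step
    sum(residual) / sum(p(1-p)) over the leaf (default) or scales the raw
    tree output by one global line-searched rho. The binomial log-loss after
    every round is recorded.
    """
    config = config or GbmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("non-finite features")
    pos_rate = y.mean()
    if pos_rate in (0.0, 1.0):
        raise ValueError("both classes must be present")

    f0 = float(np.log(pos_rate / (1.0 - pos_rate)))
    F = np.full(len(X), f0)
    trees: list[_TreeRecord] = []
    trace: list[float] = []
    for _ in range(config.n_trees):
        p = _logistic(F)
        residual = y - p
        tree = DecisionTreeRegressor(max_depth=config.max_depth, random_state=config.seed)
        tree.fit(X, residual)
        leaves = tree.apply(X)
        leaf_values: dict[int, float] = {}
        if config.step_rule == "newton_per_leaf":
            for leaf in np.unique(leaves):
                mask = leaves == leaf
                denom = np.sum(p[mask] * (1.0 - p[mask]))
                leaf_values[int(leaf)] = float(residual[mask].sum() / max(denom, _EPS))
        elif config.step_rule == "global_line_search":
            h = tree.predict(X)
            res = minimize_scalar(
                lambda rho: log_loss(y, _logistic(F + rho * h)),
                bounds=(0.0, 1e4), method="bounded",
            )
            rho = float(res.x)
            for leaf in np.unique(leaves):
                leaf_values[int(leaf)] = rho * float(tree.tree_.value[leaf].ravel()[0])
        else:
            raise ValueError(f"unknown step_rule {config.step_rule!r}")
        rec = _record_from_sklearn(tree, leaf_values)
        trees.append(rec)
        F = F + config.learning_rate * rec.apply(X)
        trace.append(log_loss(y, _logistic(F)))
    return BoostedModel(f0=f0, trees=trees, learning_rate=config.learning_rate,
                        loss_trace=trace, config=config)


def predict_score(model: BoostedModel, X: np.ndarray) -> np.ndarray:
    """Association probability per row, logistic of the additive raw score."""
    X = np.asarray(X, dtype=float)
    if model.trees and X.shape[1] <= model.trees[0].feature.max(initial=-1):
        raise ValueError("feature dimension smaller than training dimension")
    return _logistic(model.raw_score(X))


def staged_training_loss(model: BoostedModel) -> list[float]:
    """Binomial log-loss after each boosting round (length = trees fitted)."""
    if not model.trees:
        raise ValueError("untrained model")
    return list(model.loss_trace)
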