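"""Classifiers for the two feature representations.

* **Session features** (the 269-entry vectors) are classified with a shallow
  multilayer perceptron: two hidden ReLU layers of 20–40 units, softmax
  output, trained full batch with Adam (beta1 = 0.95, beta2 = 0.99) under an
  inverse-scaling learning-rate schedule ``lr_t = lr / t^0.5``.  The network
  is implemented here directly because training must honour per-class
  weights and the stated optimiser schedule, and be bit-deterministic under
  a seed.
* **Per-movement profiles** are classified with a gradient-boosting machine
  (scikit-learn): 500–1000 shallow trees (depth 2), learning rate 0.1,
  subsample 0.8, log2(feature count) features per split.  A session's
  prediction is the arithmetic mean of its movements' probability vectors.

Group imbalance is offset with balanced inverse-frequency class weights
``w_c = N / (K * N_c)``: larger groups get weights below 1.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier


class LeakageError(RuntimeError):
    """A subject's movements appear on both sides of a train/test split."""


def compute_class_weights(labels) -> dict:
    """Balanced inverse-frequency weights ``w_c = N_total / (K * N_c)``.

    Strictly decreasing in class size, and ``sum_c w_c * N_c = N_total``.
    """
    counts = Counter(labels)
    if len(counts) < 2:
        raise ValueError("need at least two classes to weight")
    if min(counts.values()) == 0:
        raise ValueError("empty class")
    n_total = sum(counts.values())
    k = len(counts)
    return {c: n_total / (k * n) for c, n in counts.items()}


def check_no_subject_overlap(train_subjects, test_subjects) -> None:
    """Leakage guard: raise if any subject sits on both sides of a split."""
    overlap = set(train_subjects) & set(test_subjects)
    if overlap:
        raise LeakageError(
            f"subjects present in both train and test: {sorted(overlap)[:5]}"
        )


# ---------------------------------------------------------------------------
# shallow network on session features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetConfig:
    """Shallow-network hyperparameters (two hidden ReLU layers)."""

    units: int = 30  # 20–40 per hidden layer
    learning_rate: float = 0.003  # 0.001–0.01
    lr_power: float = 0.5  # inverse-scaling schedule exponent
    adam_beta1: float = 0.95
    adam_beta2: float = 0.99
    max_epochs: int = 500
    plateau_tol: float = 1e-7
    plateau_patience: int = 25
    seed: int = 0


@dataclass(frozen=True)
class GBMConfig:
    """Gradient-boosting hyperparameters."""

    n_trees: int = 500  # 500–1000
    learning_rate: float = 0.1
    subsample: float = 0.8
    max_depth: int = 2
    max_features: str = "log2"
    seed: int = 0


class SessionNet:
    """Two-hidden-layer softmax MLP trained full batch with Adam.

    Deterministic under ``config.seed``; supports per-sample weights (class
    weights) in the cross-entropy loss.  API mirrors scikit-learn:
    ``fit(X, y, sample_weight)``, ``predict_proba``, ``predict``,
    ``classes_``.
    """

    def __init__(self, config: NetConfig = NetConfig()):
        self.config = config
        self.classes_: np.ndarray | None = None

    def fit(self, X, y, sample_weight=None) -> "SessionNet":
        X = np.asarray(X, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError(
                "non-finite feature values; impute or drop missing-value "
                "sentinels before training"
            )
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, d = X.shape
        k = len(self.classes_)
        if k < 2:
            raise ValueError("need at least two classes")
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        w = w / w.sum()
        Y = np.zeros((n, k))
        Y[np.arange(n), y_idx] = 1.0

        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        sizes = [d, cfg.units, cfg.units, k]
        params = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            params.append(rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
            params.append(np.zeros(fan_out))
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = cfg.adam_beta1, cfg.adam_beta2, 1e-8

        prev_loss, stall = np.inf, 0
        for epoch in range(1, cfg.max_epochs + 1):
            # forward
            W1, c1, W2, c2, W3, c3 = params
            h1 = np.maximum(X @ W1 + c1, 0.0)
            h2 = np.maximum(h1 @ W2 + c2, 0.0)
            logits = h2 @ W3 + c3
            logits -= logits.max(axis=1, keepdims=True)
            expz = np.exp(logits)
            proba = expz / expz.sum(axis=1, keepdims=True)
            loss = float(-(w * np.log((proba * Y).sum(axis=1) + 1e-12)).sum())

            # backward (weighted cross-entropy)
            delta3 = (proba - Y) * w[:, None]
            g = [
                h2.T @ delta3 + 0.0,
                delta3.sum(axis=0),
            ]
            delta2 = (delta3 @ W3.T) * (h2 > 0)
            g = [h1.T @ delta2, delta2.sum(axis=0)] + g
            delta1 = (delta2 @ W2.T) * (h1 > 0)
            g = [X.T @ delta1, delta1.sum(axis=0)] + g

            lr = cfg.learning_rate / epoch**cfg.lr_power
            for i in range(len(params)):
                m[i] = b1 * m[i] + (1 - b1) * g[i]
                v[i] = b2 * v[i] + (1 - b2) * g[i] ** 2
                mhat = m[i] / (1 - b1**epoch)
                vhat = v[i] / (1 - b2**epoch)
                params[i] = params[i] - lr * mhat / (np.sqrt(vhat) + eps)

            if abs(prev_loss - loss) < cfg.plateau_tol:
                stall += 1
                if stall >= cfg.plateau_patience:
                    break
            else:
                stall = 0
            prev_loss = loss

        self._params = params
        return self

    def predict_proba(self, X) -> np.ndarray:
        W1, c1, W2, c2, W3, c3 = self._params
        h1 = np.maximum(np.asarray(X, float) @ W1 + c1, 0.0)
        h2 = np.maximum(h1 @ W2 + c2, 0.0)
        logits = h2 @ W3 + c3
        logits -= logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        return expz / expz.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def fit_session_net(
    X,
    y,
    config: NetConfig = NetConfig(),
    class_weights: dict | None = None,
) -> SessionNet:
    """Train the shallow network on (already normalized) session features."""
    y = np.asarray(y)
    if class_weights is None:
        class_weights = compute_class_weights(y)
    sw = np.array([class_weights[c] for c in y])
    return SessionNet(config).fit(X, y, sample_weight=sw)


# ---------------------------------------------------------------------------
# gradient boosting on per-movement profiles
# ---------------------------------------------------------------------------

def fit_profile_gbm(
    X,
    y,
    config: GBMConfig = GBMConfig(),
    class_weights: dict | None = None,
) -> GradientBoostingClassifier:
    """Train the boosted-tree model on per-movement profile rows.

    ``y`` holds each movement's inherited session label; the caller is
    responsible for keeping all of a session's movements on one side of any
    split (see :func:`check_no_subject_overlap`).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("profile training set contains a single class")
    if class_weights is None:
        class_weights = compute_class_weights(y)
    sw = np.array([class_weights[c] for c in y])
    model = GradientBoostingClassifier(
        n_estimators=config.n_trees,
        learning_rate=config.learning_rate,
        subsample=config.subsample,
        max_depth=config.max_depth,
        max_features=config.max_features,
        random_state=config.seed,
    )
    model.fit(np.asarray(X, float), y, sample_weight=sw)
    return model


def predict_session_average(model, profile_rows) -> np.ndarray:
    """Session prediction: mean of the per-movement probability vectors.

    Components sum to 1; the argmax is the session's predicted class.
    """
    X = np.asarray(profile_rows, float)
    if len(X) == 0:
        raise ValueError("no movements to average over")
    return model.predict_proba(X).mean(axis=0)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

#: Default grids spanning the configured hyperparameter ranges.
NET_GRID = {"units": (20, 30, 40), "learning_rate": (0.01, 0.003, 0.001)}
GBM_GRID = {"n_trees": (500, 1000)}


@dataclass
class GridSearchResult:
    best_config: object
    best_score: float
    table: pd.DataFrame = field(repr=False)


def grid_search(
    evaluate_config,
    base_config,
    grid: dict,
) -> GridSearchResult:
    """Exhaustive grid search over ``grid`` applied to ``base_config``.

    ``evaluate_config(config)`` must return a sequence of per-fold accuracy
    records ``(fold_id, repeat_id, accuracy)``.  The best configuration has
    the highest mean accuracy; ties go to the smaller model (fewer units or
    trees), then the lower learning rate.  The full score table (one row per
    config x fold x repeat) is returned alongside.
    """
    keys = list(grid)
    points = list(itertools.product(*(grid[k] for k in keys)))
    if not points:
        raise ValueError("empty parameter grid")
    rows, summary = [], []
    from dataclasses import replace

    for values in points:
        overrides = dict(zip(keys, values))
        config = replace(base_config, **overrides)
        scores = list(evaluate_config(config))
        for fold_id, repeat_id, acc in scores:
            rows.append({**overrides, "fold": fold_id, "repeat": repeat_id,
                         "accuracy": acc})
        mean_acc = float(np.mean([s[2] for s in scores])) if scores else np.nan
        size = overrides.get("units", overrides.get("n_trees", 0))
        lr = overrides.get("learning_rate", getattr(config, "learning_rate", 0.0))
        summary.append((mean_acc, -size, -lr, config))
    summary.sort(key=lambda s: (s[0], s[1], s[2]), reverse=True)
    best = summary[0]
    return GridSearchResult(
        best_config=best[3], best_score=best[0], table=pd.DataFrame(rows)
    )
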