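"""Subject-level cross-validation with leakage-safe normalization, and
classification metrics.

Splits are always over *subjects*: a session's feature vector and all of its
per-movement profiles stay on one side of every split (a hard error guards
this).  Feature-wise standardization is fitted on the training fold only and
applied to the held-out fold, so no test statistics leak into training.
Schemes: leave-one-out, repeated stratified k-fold (data reshuffled before
each repeat), and nested k-fold where an inner loop tunes the model grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .models import (
    GBMConfig,
    NetConfig,
    check_no_subject_overlap,
    compute_class_weights,
    fit_profile_gbm,
    fit_session_net,
    grid_search,
    predict_session_average,
)
from .session import GROUPS

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation scheme over subjects."""

    kind: str = "repeated_kfold"  # leave_one_out | repeated_kfold | nested_kfold
    n_folds: int = 4  # tuned hyperparameter; 4 by default
    n_repeats: int = 10
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("leave_one_out", "repeated_kfold", "nested_kfold"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


class NormParams(NamedTuple):
    mean: np.ndarray
    scale: np.ndarray  # zero-SD columns carry scale 0 and map to 0


def normalize_fit(train: np.ndarray) -> NormParams:
    """Per-feature center/scale from the training data only.

    NaN entries (missing-value sentinels) are ignored when estimating the
    parameters; zero-SD features are flagged and will map to 0.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("empty training set")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(train, axis=0)
        sd = np.nanstd(train, axis=0)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    n_const = int((sd == 0).sum()) + int((~np.isfinite(sd)).sum())
    if n_const:
        warnings.warn(f"{n_const} constant feature(s); mapped to 0 after scaling")
    sd = np.where(np.isfinite(sd), sd, 0.0)
    return NormParams(mean=mean, scale=sd)


def normalize_apply(params: NormParams, X: np.ndarray) -> np.ndarray:
    """Standardize with train-fold parameters; sentinel NaNs become 0 (the
    training mean), zero-SD columns become 0."""
    X = np.asarray(X, dtype=float)
    scale = np.where(params.scale == 0, 1.0, params.scale)
    out = (X - params.mean) / scale
    out[:, params.scale == 0] = 0.0
    return np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)


@dataclass
class EvalReport:
    """Pooled cross-validation result.

    ``confusion`` rows are true groups, columns predicted groups, in
    ``labels`` order; entries are counts pooled over folds (and repeats, so
    each subject contributes ``n_repeats`` predictions under k-fold).
    """

    labels: tuple
    confusion: np.ndarray
    n_repeats: int = 1
    per_fold: list = field(default_factory=list)
    positive: str | None = None

    @property
    def metrics(self) -> dict:
        chance = 1.0 / len(self.labels)
        pos = self.positive
        if pos is None and len(self.labels) == 2:
            pos = self.labels[1]
        return confusion_metrics(self.confusion, self.labels, pos, chance)

    def to_json(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion": self.confusion.astype(int).tolist(),
            "n_repeats": self.n_repeats,
            "metrics": self.metrics,
            "per_fold": self.per_fold,
        }


def confusion_metrics(
    confusion, labels=None, positive=None, chance: float | None = None
) -> dict:
    """Accuracy, sensitivity/specificity (two-class) and above-chance gain.

    ``above_chance`` = (accuracy - chance) / chance with chance = 1/K.  Two
    conventions are reported: ``above_chance_pct`` from the exact accuracy,
    and ``above_chance_pct_rounded`` where accuracy and chance are first
    rounded to whole percentage points (the convention that matches rounded
    headline figures).
    """
    mat = np.asarray(confusion, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (mat < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    total = mat.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    k = mat.shape[0]
    if chance is None:
        chance = 1.0 / k
    accuracy = float(np.trace(mat) / total)
    out = {
        "accuracy": accuracy,
        "accuracy_pct": 100.0 * accuracy,
        "chance": chance,
        "above_chance": (accuracy - chance) / chance,
        "above_chance_pct": 100.0 * (accuracy - chance) / chance,
    }
    acc_pct_r = round(100.0 * accuracy)
    chance_pct_r = round(100.0 * chance)
    out["above_chance_pct_rounded"] = 100.0 * (acc_pct_r - chance_pct_r) / chance_pct_r
    if k == 2 and positive is not None:
        if labels is None:
            labels = tuple(range(k))
        p = list(labels).index(positive)
        n = 1 - p
        tp, fn = mat[p, p], mat[p, n]
        tn, fp = mat[n, n], mat[n, p]
        out["sensitivity"] = float(tp / (tp + fn)) if tp + fn else np.nan
        out["specificity"] = float(tn / (tn + fp)) if tn + fp else np.nan
        out["positive"] = positive
    return out


# ---------------------------------------------------------------------------
# the CV driver
# ---------------------------------------------------------------------------

def _fold_iterator(labels: np.ndarray, scheme: CVScheme):
    """Yield (repeat, fold, train_idx, test_idx) over subjects."""
    n = len(labels)
    if scheme.kind == "leave_one_out":
        for fold, (tr, te) in enumerate(LeaveOneOut().split(np.zeros(n))):
            yield 0, fold, tr, te
        return
    for repeat in range(scheme.n_repeats):
        # reshuffle before each repeat
        skf = StratifiedKFold(
            n_splits=scheme.n_folds,
            shuffle=scheme.shuffle,
            random_state=scheme.seed + 1000 * repeat,
        )
        for fold, (tr, te) in enumerate(skf.split(np.zeros(n), labels)):
            yield repeat, fold, tr, te


def run_cv(
    features: pd.DataFrame,
    scheme: CVScheme,
    pair=None,
    model: str = "net",
    profiles: pd.DataFrame | None = None,
    net_config: NetConfig = NetConfig(),
    gbm_config: GBMConfig = GBMConfig(),
    param_grid: dict | None = None,
    positive: str | None = None,
) -> EvalReport:
    """Cross-validate a classifier at the subject level.

    Parameters
    ----------
    features
        Wide feature table (subject_id, group, feature columns).
    pair
        Two group labels for a pairwise problem, or ``None`` for all groups
        present (e.g. the 3-way problem).
    model
        ``"net"`` — shallow network on session features; ``"gbm"`` —
        gradient boosting on per-movement ``profiles`` with session-average
        prediction.
    param_grid
        Only for ``nested_kfold``: the grid tuned in the inner loop.
    """
    if pair is not None:
        features = features[features["group"].isin(pair)].reset_index(drop=True)
        labels_order = tuple(pair)
    else:
        labels_order = tuple(g for g in GROUPS if g in set(features["group"]))
    subjects = features["subject_id"].to_numpy()
    if len(np.unique(subjects)) != len(subjects):
        raise ValueError("duplicate subject_id in feature table")
    y = features["group"].to_numpy()
    feat_cols = [c for c in features.columns if c not in ("subject_id", "group")]
    X = features[feat_cols].to_numpy(dtype=float)

    if model == "gbm":
        if profiles is None:
            raise ValueError("profile model requires the profiles frame")
        profiles = profiles[profiles["subject_id"].isin(subjects)]
        prof_cols = [
            c for c in profiles.columns
            if c not in ("subject_id", "group", "gesture_index")
        ]

    label_index = {g: i for i, g in enumerate(labels_order)}
    k = len(labels_order)
    confusion = np.zeros((k, k), dtype=int)
    per_fold = []
    n_repeats = 1 if scheme.kind == "leave_one_out" else scheme.n_repeats

    for repeat, fold, tr, te in _fold_iterator(y, scheme):
        if len(set(y[tr])) < k:
            log.warning("repeat %d fold %d: missing class in training; skipped",
                        repeat, fold)
            continue
        check_no_subject_overlap(subjects[tr], subjects[te])
        weights = compute_class_weights(y[tr])
        fold_seed = scheme.seed + 7919 * repeat + fold

        if model == "net":
            cfg = replace(net_config, seed=fold_seed)
            if scheme.kind == "nested_kfold" and param_grid:
                cfg = _tune_inner(
                    X[tr], y[tr], subjects[tr], cfg, param_grid, scheme, fold_seed
                )
            params = normalize_fit(X[tr])
            net = fit_session_net(
                normalize_apply(params, X[tr]), y[tr], cfg, weights
            )
            pred = net.predict(normalize_apply(params, X[te]))
        elif model == "gbm":
            tr_subj, te_subj = set(subjects[tr]), set(subjects[te])
            prof_tr = profiles[profiles["subject_id"].isin(tr_subj)]
            Xp = prof_tr[prof_cols].to_numpy(dtype=float)
            yp = prof_tr["group"].to_numpy()
            params = normalize_fit(Xp)
            cfg = replace(gbm_config, seed=fold_seed)
            gbm = fit_profile_gbm(
                normalize_apply(params, Xp), yp, cfg,
                compute_class_weights(yp),
            )
            pred = []
            for s in subjects[te]:
                rows = profiles[profiles["subject_id"] == s][prof_cols]
                proba = predict_session_average(
                    gbm, normalize_apply(params, rows.to_numpy(dtype=float))
                )
                pred.append(gbm.classes_[int(np.argmax(proba))])
            pred = np.array(pred)
        else:
            raise ValueError(f"unknown model family {model!r}")

        for true, hat in zip(y[te], pred):
            confusion[label_index[true], label_index[hat]] += 1
        acc = float(np.mean(pred == y[te]))
        per_fold.append(
            {"repeat": repeat, "fold": fold, "n_test": int(len(te)), "accuracy": acc}
        )

    return EvalReport(
        labels=labels_order,
        confusion=confusion,
        n_repeats=n_repeats,
        per_fold=per_fold,
        positive=positive,
    )


def _tune_inner(X, y, subjects, base_config, grid, scheme: CVScheme, seed: int):
    """Inner-loop grid tuning on the training subjects only."""
    min_class = int(np.min(np.bincount(pd.factorize(y)[0])))
    if min_class < 2:
        return base_config  # too few subjects per class to tune
    inner = CVScheme(
        kind="repeated_kfold",
        n_folds=max(2, min(scheme.n_folds, min_class)),
        n_repeats=1,
        seed=seed,
    )

    def evaluate(config):
        records = []
        for repeat, fold, tr, te in _fold_iterator(y, inner):
            if len(set(y[tr])) < len(set(y)):
                continue
            check_no_subject_overlap(subjects[tr], subjects[te])
            params = normalize_fit(X[tr])
            net = fit_session_net(
                normalize_apply(params, X[tr]), y[tr],
                replace(config, seed=seed), compute_class_weights(y[tr]),
            )
            pred = net.predict(normalize_apply(params, X[te]))
            records.append((fold, repeat, float(np.mean(pred == y[te]))))
        return records

    return grid_search(evaluate, base_config, grid).best_config
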