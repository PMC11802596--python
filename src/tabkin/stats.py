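"""Feature-level group statistics.

Each feature is screened with a per-group normality check — by default a
Kolmogorov–Smirnov test against a normal with sample-estimated mean/SD
(Lilliefors) at alpha = 0.05.  Features normal in every group are compared
with one-way ANOVA (three groups) and independent t-tests (pairs); all
others use Kruskal–Wallis and Mann–Whitney U.  Raw p-values are reported by
default; Benjamini–Hochberg adjustment is available behind a flag.

Feature–covariate association uses Kendall's tau-b (tie-corrected), chosen
for robustness to extreme values, computed across all subjects and within
each group.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .session import GROUPS

NORMALITY_ALPHA = 0.05


def _is_normal(values: np.ndarray, method: str, alpha: float) -> bool:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 4 or np.ptp(v) == 0:
        return False
    if method == "lilliefors":
        _, p = lilliefors(v, dist="norm")
    elif method == "shapiro":
        _, p = sps.shapiro(v)
    else:
        raise ValueError(f"unknown normality method {method!r}")
    return bool(p > alpha)


def _safe_p(func, *groups) -> float:
    try:
        with np.errstate(all="ignore"):
            return float(func(*groups).pvalue)
    except ValueError:
        return np.nan


def feature_group_tests(
    features: pd.DataFrame,
    feature_cols=None,
    group_col: str = "group",
    normality: str = "lilliefors",
    normality_alpha: float = NORMALITY_ALPHA,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-feature group-difference tests with a normality-gated router.

    Returns one row per feature: the test family used, the overall
    (all-groups) p-value and every pairwise p-value, mirroring the layout of
    a group-comparison table.  All-constant features are skipped and
    flagged.  ``correction="bh"`` adds Benjamini–Hochberg adjusted columns.
    """
    groups = [g for g in GROUPS if g in set(features[group_col])]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if (features[group_col] == g).sum() < 3:
            raise ValueError(f"group {g} has fewer than 3 subjects")
    if feature_cols is None:
        feature_cols = [
            c for c in features.columns
            if c not in ("subject_id", group_col)
            and pd.api.types.is_numeric_dtype(features[c])
        ]

    rows = []
    for feat in feature_cols:
        samples = {
            g: features.loc[features[group_col] == g, feat].to_numpy(dtype=float)
            for g in groups
        }
        samples = {g: v[np.isfinite(v)] for g, v in samples.items()}
        pooled = np.concatenate(list(samples.values()))
        row: dict = {"feature": feat, "skipped": False}
        if len(pooled) == 0 or np.ptp(pooled) == 0 or any(
            len(v) < 3 for v in samples.values()
        ):
            row.update(
                {"normal": False, "test": None, "p_overall": np.nan,
                 "skipped": True}
            )
            for a, b in combinations(groups, 2):
                row[f"p_{a}_{b}"] = np.nan
            rows.append(row)
            continue
        normal = all(
            _is_normal(v, normality, normality_alpha) for v in samples.values()
        )
        row["normal"] = normal
        if normal:
            row["test"] = "anova/t"
            if len(groups) > 2:
                row["p_overall"] = _safe_p(sps.f_oneway, *samples.values())
            for a, b in combinations(groups, 2):
                row[f"p_{a}_{b}"] = _safe_p(sps.ttest_ind, samples[a], samples[b])
        else:
            row["test"] = "kruskal/mannwhitney"
            if len(groups) > 2:
                row["p_overall"] = _safe_p(sps.kruskal, *samples.values())
            for a, b in combinations(groups, 2):
                row[f"p_{a}_{b}"] = _safe_p(
                    sps.mannwhitneyu, samples[a], samples[b]
                )
        if len(groups) == 2:
            a, b = groups
            row["p_overall"] = row[f"p_{a}_{b}"]
        rows.append(row)

    out = pd.DataFrame(rows)
    if correction == "bh":
        for col in [c for c in out.columns if c.startswith("p_")]:
            mask = out[col].notna()
            adj = np.full(len(out), np.nan)
            if mask.any():
                adj[mask.to_numpy()] = multipletests(
                    out.loc[mask, col], method="fdr_bh"
                )[1]
            out[col + "_bh"] = adj
    return out


def feature_covariate_correlations(
    features: pd.DataFrame,
    covariate_cols,
    feature_cols=None,
    group_col: str = "group",
    by_group: bool = True,
) -> pd.DataFrame:
    """Kendall tau-b between features and covariates.

    One row per (feature, covariate, scope) where scope is ``"all"`` or a
    group label.  Pairs with fewer than 3 complete observations or a
    constant vector are flagged (tau undefined → NaN).
    """
    if feature_cols is None:
        feature_cols = [
            c for c in features.columns
            if c not in ("subject_id", group_col) and c not in covariate_cols
            and pd.api.types.is_numeric_dtype(features[c])
        ]
    scopes = [("all", features)]
    if by_group:
        scopes += [
            (g, features[features[group_col] == g])
            for g in GROUPS
            if g in set(features[group_col])
        ]
    rows = []
    for scope, df in scopes:
        for feat in feature_cols:
            for cov in covariate_cols:
                x = df[feat].to_numpy(dtype=float)
                z = df[cov].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(z)
                x, z = x[ok], z[ok]
                flagged = len(x) < 3 or np.ptp(x) == 0 or np.ptp(z) == 0
                if flagged:
                    tau, p = np.nan, np.nan
                else:
                    res = sps.kendalltau(x, z)  # tau-b, tie-corrected
                    tau, p = float(res.statistic), float(res.pvalue)
                rows.append(
                    {"scope": scope, "feature": feat, "covariate": cov,
                     "n": int(len(x)), "tau": tau, "p": p, "flagged": flagged}
                )
    return pd.DataFrame(rows)
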