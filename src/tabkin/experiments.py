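"""End-to-end experiments: worked example, parameter recovery, null
calibration and pipeline determinism.

These drive the whole pipeline (simulate → segment → extract → classify →
test) at fixed seeds and are shared by the test suite and the acceptance
script.  Problem sizes follow the reference study conditions: three groups,
20 subjects per group, five-minute sessions.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .evaluate import CVScheme, confusion_metrics, run_cv
from .features import extract_features, extract_profiles, profiles_to_frame
from .models import NetConfig
from .session import GROUPS, feature_table
from .stats import feature_group_tests
from .synth import (
    DESIGNED_DIFFERENCES,
    CohortSpec,
    generate_cohort,
    null_archetypes,
    study_archetypes,
)

#: The published 3-way confusion matrix (rows: clinical TD/ASD/DCD, columns:
#: predicted TD/ASD/DCD) — the worked example for the metric definitions.
REFERENCE_CONFUSION = ((14, 2, 4), (5, 11, 2), (5, 5, 6))


def reference_confusion_metrics() -> dict:
    """Metrics of the published 3-way confusion matrix (31/54 correct)."""
    return confusion_metrics(np.asarray(REFERENCE_CONFUSION), labels=GROUPS)


def cohort_features(
    seed: int,
    effect: str = "large",
    n_per_group: int = 20,
    duration: float = 300.0,
    with_profiles: bool = False,
):
    """Generate a cohort and extract the session feature table (and
    optionally the per-movement profile frame)."""
    archetypes = (
        null_archetypes() if effect == "none" else study_archetypes(effect)
    )
    spec = CohortSpec(
        archetypes=archetypes, n_per_group=n_per_group, duration=duration,
        seed=seed,
    )
    sessions = generate_cohort(spec)
    vectors = [extract_features(s) for s in sessions]
    features = feature_table(vectors)
    if not with_profiles:
        return features
    profiles = profiles_to_frame(
        [p for s in sessions for p in extract_profiles(s)]
    )
    return features, profiles


def recovery_experiment(
    seed: int = 1, n_per_group: int = 20, duration: float = 300.0
) -> dict:
    """Parameter recovery on the study preset (large effects).

    Checks that (a) each designed group-difference feature is significant
    (p < 0.05) for its designed pair under the normality-gated test router,
    and (b) each pairwise leave-one-out CV accuracy of the session-feature
    network is high.
    """
    features = cohort_features(seed, "large", n_per_group, duration)
    tests = feature_group_tests(features).set_index("feature")
    designed_p = {}
    for feat, (a, b) in DESIGNED_DIFFERENCES.items():
        key = f"p_{a}_{b}" if f"p_{a}_{b}" in tests.columns else f"p_{b}_{a}"
        designed_p[feat] = float(tests.loc[feat, key])

    scheme = CVScheme(kind="leave_one_out", seed=seed)
    pair_acc = {}
    for pair in (("TD", "ASD"), ("TD", "DCD"), ("ASD", "DCD")):
        report = run_cv(features, scheme, pair=pair, model="net",
                        net_config=NetConfig(seed=seed))
        pair_acc["_".join(pair)] = report.metrics["accuracy"]
    return {
        "designed_p": designed_p,
        "pairwise_accuracy": pair_acc,
        "n_per_group": n_per_group,
    }


def null_accuracy_experiment(
    seed: int = 1,
    n_seeds: int = 10,
    n_per_group: int = 20,
    duration: float = 300.0,
) -> dict:
    """3-way CV accuracy on exchangeable (identical-archetype) cohorts.

    Pools predictions over ``n_seeds`` independent cohorts and reports the
    pooled accuracy with its 95% binomial band around chance (1/3).
    """
    total, correct = 0, 0
    per_seed = []
    for i in range(n_seeds):
        features = cohort_features(seed + i, "none", n_per_group, duration)
        report = run_cv(
            features,
            CVScheme(kind="repeated_kfold", n_folds=4, n_repeats=1, seed=seed + i),
            pair=None,
            model="net",
            net_config=NetConfig(seed=seed + i),
        )
        n = int(report.confusion.sum())
        c = int(np.trace(report.confusion))
        total += n
        correct += c
        per_seed.append(c / n)
    acc = correct / total
    chance = 1.0 / 3.0
    half = 1.96 * np.sqrt(chance * (1 - chance) / total)
    return {
        "accuracy": acc,
        "per_seed": per_seed,
        "n_predictions": total,
        "band": (chance - half, chance + half),
    }


def null_type_i_experiment(
    seed: int = 1, n_features: int = 1000, n_per_group: int = 20
) -> dict:
    """Type-I error rate of the feature test router on exchangeable data.

    Simulates ``n_features`` independent standard-normal features across
    three equal groups and counts overall-test rejections at alpha = 0.05,
    against the 95% binomial band.
    """
    rng = np.random.default_rng(seed)
    n = 3 * n_per_group
    df = pd.DataFrame(
        rng.normal(size=(n, n_features)),
        columns=[f"f{i:04d}" for i in range(n_features)],
    )
    df.insert(0, "group", np.repeat(GROUPS, n_per_group))
    df.insert(0, "subject_id", [f"S{i:03d}" for i in range(n)])
    tests = feature_group_tests(df)
    rejected = int((tests["p_overall"] < 0.05).sum())
    rate = rejected / n_features
    half = 1.96 * np.sqrt(0.05 * 0.95 / n_features)
    return {
        "rate": rate,
        "n_features": n_features,
        "rejected": rejected,
        "band": (0.05 - half, 0.05 + half),
    }


def pipeline_report(
    seed: int, n_per_group: int = 3, duration: float = 60.0
) -> str:
    """Run the full pipeline (simulate → extract → train → evaluate) and
    serialize the evaluation report to canonical JSON.  Used to check that a
    fixed master seed reproduces the report bit for bit."""
    features, profiles = cohort_features(
        seed, "large", n_per_group, duration, with_profiles=True
    )
    scheme = CVScheme(kind="repeated_kfold", n_folds=3, n_repeats=2, seed=seed)
    report = run_cv(features, scheme, pair=None, model="net",
                    net_config=NetConfig(seed=seed))
    payload = {
        "seed": seed,
        "n_subjects": int(len(features)),
        "n_profiles": int(len(profiles)),
        "feature_checksum": float(
            np.nansum(features.drop(columns=["subject_id", "group"]).to_numpy())
        ),
        "report": report.to_json(),
    }
    return json.dumps(payload, sort_keys=True)
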