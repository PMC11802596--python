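"""Frozen inventory of the 269 session-level gameplay features.

The feature set is a grid of {per-gesture or per-channel base quantity} x
{session statistic}, trimmed to exactly 105 touch-derived and 164 IMU-derived
entries.  The registry is the single source of truth for feature names and
their order: feature vectors, feature tables and downstream statistics all
follow it.  Seven features that drive the group comparisons keep their
canonical field names instead of the systematic ``touch_*`` / ``imu_*`` ones:

* ``gesture_area_variance``          (touch: hull area, variance)
* ``minimum_gesture_acceleration``   (touch: per-gesture min tangential accel, mean)
* ``gesture_directness_variance``    (touch: terminal directness, variance)
* ``attitude_variance_x`` / ``attitude_variance_y``
* ``rotation_variance_x``
* ``accel_direction_change_rate_y``
"""

from __future__ import annotations

import json
from typing import NamedTuple


class FeatureDef(NamedTuple):
    """One registry entry: a stable name, its sensor source and definition id."""

    name: str
    source: str  # "touch" | "imu"
    definition: str  # e.g. "area:var", "attitude:x:var"


#: Session statistics applied to per-gesture quantities (full grid).
STATS_FULL = ("mean", "var", "sd", "min", "max", "median", "q1", "q3")
#: Reduced statistic set for quantities whose extremes matter most.
STATS_REDUCED = ("mean", "var", "min", "max")
#: Statistics applied to each IMU channel.
STATS_IMU = ("mean", "sd", "var", "min", "max", "range", "median", "q1", "q3", "iqr")

#: Per-gesture (swipe) quantities aggregated with the full statistic grid.
TOUCH_QUANTITIES_FULL = (
    "duration",
    "path_length",
    "displacement",
    "area",
    "directness",
    "line_deviation",
    "mean_speed",
    "max_speed",
    "intergesture_interval",
)
#: Per-gesture quantities aggregated with the reduced grid.
TOUCH_QUANTITIES_REDUCED = ("min_speed", "mean_accel", "max_accel", "min_accel")
#: Stroke endpoint coordinates (location on screen), mean and SD only.
TOUCH_COORDS = ("start_x", "start_y", "end_x", "end_y")
#: Tap- and count-based session features (not per-gesture aggregates).
TOUCH_TAP_FEATURES = (
    "tap_count",
    "tap_rate",
    "tap_fraction",
    "gesture_count",
    "intertap_interval_mean",
    "intertap_interval_sd",
    "intertap_interval_min",
    "intertap_interval_max",
    "intertap_interval_median",
)

#: IMU signals and axes; "mag" is the Euclidean norm of the three axes.
IMU_SIGNALS = ("accel", "rot", "attitude", "jerk")
IMU_AXES = ("x", "y", "z", "mag")

# Canonical names for the features reported in the group comparisons.
_CANONICAL_TOUCH = {
    ("area", "var"): "gesture_area_variance",
    ("min_accel", "mean"): "minimum_gesture_acceleration",
    ("directness", "var"): "gesture_directness_variance",
}
_CANONICAL_IMU = {
    ("attitude", "x", "var"): "attitude_variance_x",
    ("attitude", "y", "var"): "attitude_variance_y",
    ("rot", "x", "var"): "rotation_variance_x",
}

TABLE_FEATURES = (
    "attitude_variance_x",
    "gesture_area_variance",
    "minimum_gesture_acceleration",
    "accel_direction_change_rate_y",
    "rotation_variance_x",
    "attitude_variance_y",
    "gesture_directness_variance",
)


def _build_touch() -> list[FeatureDef]:
    defs: list[FeatureDef] = []
    for q in TOUCH_QUANTITIES_FULL:
        for s in STATS_FULL:
            name = _CANONICAL_TOUCH.get((q, s), f"touch_{q}_{s}")
            defs.append(FeatureDef(name, "touch", f"{q}:{s}"))
    for q in TOUCH_QUANTITIES_REDUCED:
        for s in STATS_REDUCED:
            name = _CANONICAL_TOUCH.get((q, s), f"touch_{q}_{s}")
            defs.append(FeatureDef(name, "touch", f"{q}:{s}"))
    for q in TOUCH_COORDS:
        for s in ("mean", "sd"):
            defs.append(FeatureDef(f"touch_{q}_{s}", "touch", f"{q}:{s}"))
    for q in TOUCH_TAP_FEATURES:
        defs.append(FeatureDef(f"touch_{q}", "touch", f"tap:{q}"))
    return defs


def _build_imu() -> list[FeatureDef]:
    defs: list[FeatureDef] = []
    for sig in IMU_SIGNALS:
        for ax in IMU_AXES:
            for s in STATS_IMU:
                name = _CANONICAL_IMU.get((sig, ax, s), f"imu_{sig}_{ax}_{s}")
                defs.append(FeatureDef(name, "imu", f"{sig}:{ax}:{s}"))
    for ax in ("x", "y", "z", "3d"):
        defs.append(
            FeatureDef(
                f"accel_direction_change_rate_{ax}", "imu", f"adcr:{ax}"
            )
        )
    return defs


TOUCH_FEATURES: tuple[FeatureDef, ...] = tuple(_build_touch())
IMU_FEATURES: tuple[FeatureDef, ...] = tuple(_build_imu())
REGISTRY: tuple[FeatureDef, ...] = TOUCH_FEATURES + IMU_FEATURES

TOUCH_NAMES: tuple[str, ...] = tuple(f.name for f in TOUCH_FEATURES)
IMU_NAMES: tuple[str, ...] = tuple(f.name for f in IMU_FEATURES)
FEATURE_NAMES: tuple[str, ...] = TOUCH_NAMES + IMU_NAMES

N_TOUCH = len(TOUCH_NAMES)
N_IMU = len(IMU_NAMES)
N_FEATURES = len(FEATURE_NAMES)

assert N_TOUCH == 105 and N_IMU == 164 and N_FEATURES == 269
assert len(set(FEATURE_NAMES)) == N_FEATURES
assert set(TABLE_FEATURES) <= set(FEATURE_NAMES)


def registry_to_json(path) -> None:
    """Serialize the registry (name, source, definition triples) to JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([f._asdict() for f in REGISTRY], fh, indent=1)


def feature_order(names) -> list[str]:
    """Return ``names`` sorted into registry order; unknown names raise."""
    index = {n: i for i, n in enumerate(FEATURE_NAMES)}
    unknown = [n for n in names if n not in index]
    if unknown:
        raise KeyError(f"names not in feature registry: {unknown[:5]}")
    return sorted(names, key=index.__getitem__)
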