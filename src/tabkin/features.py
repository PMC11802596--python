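"""Feature extraction: the 269-entry session vector and per-movement
time-normalized bin profiles.

Two representations are computed from a segmented session:

1. **Session features** — per-gesture base quantities (duration, path
   length, hull area, terminal directness, speed/acceleration extremes, …)
   reduced to session statistics, plus tap/count features and IMU channel
   statistics, following the frozen registry (105 touch + 164 IMU = 269).
2. **Per-movement profiles** — each swipe's speed and tangential
   acceleration series time-normalized to [0, 1] and split into ``n_bins``
   bins, with mean / median / SD / Q1 / Q3 per bin.  Each movement is a
   separate sample carrying its session's subject id and label.

Conventions: variances are population variances (divide by N); quartiles
use linear interpolation between order statistics; empty aggregates are NaN
(an explicit missing-value sentinel, never silent zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from . import registry as reg
from .gestures import (
    TAP_DISPLACEMENT_PT,
    TAP_DURATION_S,
    Gesture,
    segment_and_derive,
)
from .session import FeatureVector, GameplaySession

PROFILE_STATS = ("mean", "median", "sd", "q1", "q3")


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable extraction parameters.

    ``adcr_definition`` selects how the acceleration direction-change rate is
    measured per axis: ``"sign_change"`` (zero crossings per second, default)
    or ``"angle"`` (mean absolute angular velocity of the projected
    acceleration vector is used for the 3d variant regardless).
    """

    pointer: str = "first"
    tap_duration: float = TAP_DURATION_S
    tap_displacement: float = TAP_DISPLACEMENT_PT
    smooth: bool = False
    tail_fraction: float = 0.25
    n_bins: int = 10
    adcr_definition: str = "sign_change"


DEFAULT_CONFIG = ExtractionConfig()


# ---------------------------------------------------------------------------
# per-gesture geometry
# ---------------------------------------------------------------------------

def gesture_area(g: Gesture) -> float:
    """Area of the minimal convex polygon (convex hull) around the gesture's
    touch points; 0 for fewer than three distinct non-collinear points."""
    pts = np.column_stack([g.x, g.y])
    pts = np.unique(pts, axis=0)
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is the area
    except QhullError:  # collinear / degenerate input
        return 0.0


def gesture_directness(g: Gesture, tail_fraction: float = 0.25) -> float:
    """Straightness of the stroke's ending: displacement over path length of
    the terminal ``tail_fraction`` of samples.  1 for a straight (or
    stationary) tail; always in [0, 1] by the triangle inequality."""
    n = g.n_samples
    k = max(2, int(np.ceil(tail_fraction * n)))
    xs, ys = g.x[-k:], g.y[-k:]
    path = float(np.hypot(np.diff(xs), np.diff(ys)).sum())
    if path == 0.0:
        return 1.0
    disp = float(np.hypot(xs[-1] - xs[0], ys[-1] - ys[0]))
    return disp / path


def line_deviation(g: Gesture) -> float:
    """Maximum perpendicular distance of the stroke from its start→end chord
    (distance from the start point if the chord has zero length)."""
    dx, dy = g.x[-1] - g.x[0], g.y[-1] - g.y[0]
    chord = np.hypot(dx, dy)
    if chord == 0.0:
        return float(np.hypot(g.x - g.x[0], g.y - g.y[0]).max())
    return float(
        np.abs(dx * (g.y - g.y[0]) - dy * (g.x - g.x[0])).max() / chord
    )


def min_gesture_acceleration(g: Gesture) -> float:
    """Most negative tangential acceleration of the stroke (its deepest
    deceleration)."""
    if len(g.tangential_accel) == 0:
        raise ValueError(f"gesture {g.index}: no acceleration series")
    return float(g.tangential_accel.min())


# ---------------------------------------------------------------------------
# session statistics
# ---------------------------------------------------------------------------

def _stat(values: np.ndarray, stat: str) -> float:
    if len(values) == 0:
        return np.nan
    v = np.asarray(values, dtype=float)
    if stat == "mean":
        return float(v.mean())
    if stat == "var":
        return float(v.var())  # population
    if stat == "sd":
        return float(v.std())
    if stat == "min":
        return float(v.min())
    if stat == "max":
        return float(v.max())
    if stat == "range":
        return float(v.max() - v.min())
    if stat == "median":
        return float(np.median(v))
    if stat == "q1":
        return float(np.percentile(v, 25))
    if stat == "q3":
        return float(np.percentile(v, 75))
    if stat == "iqr":
        return float(np.percentile(v, 75) - np.percentile(v, 25))
    raise KeyError(f"unknown statistic {stat!r}")


def extract_touch_features(
    session: GameplaySession, config: ExtractionConfig = DEFAULT_CONFIG
) -> dict:
    """The 105 touch-derived session features, in registry order.

    Kinematic aggregates are computed over *swipes* (non-tap, non-degenerate
    gestures); taps enter the tap/count features.  A session with no swipes
    yields NaN aggregates and zero counts.
    """
    gestures = segment_and_derive(
        session.touch,
        pointer=config.pointer,
        tap_duration=config.tap_duration,
        tap_displacement=config.tap_displacement,
        smooth=config.smooth,
    )
    swipes = [g for g in gestures if not g.is_tap and not g.degenerate]
    taps = [g for g in gestures if g.is_tap]

    q: dict[str, np.ndarray] = {}
    q["duration"] = np.array([g.duration for g in swipes])
    q["path_length"] = np.array([g.path_length for g in swipes])
    q["displacement"] = np.array([g.displacement for g in swipes])
    q["area"] = np.array([gesture_area(g) for g in swipes])
    q["directness"] = np.array(
        [gesture_directness(g, config.tail_fraction) for g in swipes]
    )
    q["line_deviation"] = np.array([line_deviation(g) for g in swipes])
    q["mean_speed"] = np.array([g.speed.mean() for g in swipes])
    q["max_speed"] = np.array([g.speed.max() for g in swipes])
    q["min_speed"] = np.array([g.speed.min() for g in swipes])
    q["mean_accel"] = np.array([g.tangential_accel.mean() for g in swipes])
    q["max_accel"] = np.array([g.tangential_accel.max() for g in swipes])
    q["min_accel"] = np.array([min_gesture_acceleration(g) for g in swipes])
    q["start_x"] = np.array([g.start[0] for g in swipes])
    q["start_y"] = np.array([g.start[1] for g in swipes])
    q["end_x"] = np.array([g.end[0] for g in swipes])
    q["end_y"] = np.array([g.end[1] for g in swipes])
    # pauses between consecutive gestures (all gestures, taps included)
    if len(gestures) >= 2:
        ends = np.array([g.t[-1] for g in gestures[:-1]])
        starts = np.array([g.t[0] for g in gestures[1:]])
        q["intergesture_interval"] = starts - ends
    else:
        q["intergesture_interval"] = np.empty(0)

    tap_starts = np.array([g.t[0] for g in taps])
    intertap = np.diff(tap_starts) if len(taps) >= 2 else np.empty(0)
    tap_vals = {
        "tap_count": float(len(taps)),
        "tap_rate": len(taps) / session.duration,
        "tap_fraction": (len(taps) / len(gestures)) if gestures else np.nan,
        "gesture_count": float(len(gestures)),
        "intertap_interval_mean": _stat(intertap, "mean"),
        "intertap_interval_sd": _stat(intertap, "sd"),
        "intertap_interval_min": _stat(intertap, "min"),
        "intertap_interval_max": _stat(intertap, "max"),
        "intertap_interval_median": _stat(intertap, "median"),
    }

    out: dict[str, float] = {}
    for f in reg.TOUCH_FEATURES:
        kind, _, spec = f.definition.partition(":")
        if kind == "tap":
            out[f.name] = tap_vals[spec]
        else:
            out[f.name] = _stat(q[kind], spec)
    return out


def extract_imu_features(
    session: GameplaySession, config: ExtractionConfig = DEFAULT_CONFIG
) -> dict:
    """The 164 IMU-derived session features, computed across the whole
    session irrespective of the touch data."""
    imu = session.imu
    if len(imu) == 0:
        warnings.warn("empty IMU stream: IMU features set to NaN")
        return {f.name: np.nan for f in reg.IMU_FEATURES}

    t = imu["t"].to_numpy()
    sig: dict[str, dict[str, np.ndarray]] = {}
    for base, prefix in (("accel", "accel"), ("rot", "rot"), ("attitude", "attitude")):
        axes = {ax: imu[f"{prefix}_{ax}"].to_numpy() for ax in ("x", "y", "z")}
        axes["mag"] = np.sqrt(sum(v**2 for v in axes.values()))
        sig[base] = axes
    if len(imu) >= 2:
        dt = np.diff(t)
        jerk = {
            ax: np.diff(sig["accel"][ax]) / dt for ax in ("x", "y", "z")
        }
        jerk["mag"] = np.sqrt(sum(jerk[ax] ** 2 for ax in ("x", "y", "z")))
    else:
        jerk = {ax: np.empty(0) for ax in ("x", "y", "z", "mag")}
    sig["jerk"] = jerk

    out: dict[str, float] = {}
    for f in reg.IMU_FEATURES:
        parts = f.definition.split(":")
        if parts[0] == "adcr":
            out[f.name] = _accel_direction_change_rate(
                sig["accel"], t, parts[1], config.adcr_definition
            )
        else:
            s, ax, stat = parts
            out[f.name] = _stat(sig[s][ax], stat)
    return out


def _accel_direction_change_rate(
    accel: dict, t: np.ndarray, axis: str, definition: str
) -> float:
    span = t[-1] - t[0] if len(t) >= 2 else 0.0
    if span <= 0:
        return np.nan
    if axis == "3d":
        # mean angular change rate of the 3-D acceleration direction
        vec = np.column_stack([accel["x"], accel["y"], accel["z"]])
        norms = np.linalg.norm(vec, axis=1)
        ok = (norms[:-1] > 0) & (norms[1:] > 0)
        dots = np.einsum("ij,ij->i", vec[:-1], vec[1:])[ok]
        cosang = np.clip(dots / (norms[:-1] * norms[1:])[ok], -1.0, 1.0)
        return float(np.arccos(cosang).sum() / span)
    v = accel[axis]
    if definition == "angle":
        ang = np.abs(np.diff(np.sign(v))) / 2  # fall back to crossings per axis
        return float(ang.sum() / span)
    s = np.sign(v)
    crossings = int(np.count_nonzero(s[:-1] * s[1:] < 0))
    return float(crossings / span)


def extract_features(
    session: GameplaySession, config: ExtractionConfig = DEFAULT_CONFIG
) -> FeatureVector:
    """Full 269-entry session feature vector (105 touch + 164 IMU)."""
    values = extract_touch_features(session, config)
    values.update(extract_imu_features(session, config))
    return FeatureVector(
        subject_id=session.subject_id, group=session.group, values=values
    )


# ---------------------------------------------------------------------------
# per-movement time-normalized profiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileSample:
    """One movement's binned kinematic profile, labelled with its session.

    ``values`` holds ``n_bins x 5 statistics x {speed, accel}`` numbers;
    ``occupancy`` maps series name to per-bin sample counts (summing to the
    series length); bins with no samples are imputed with the gesture-level
    statistic and recorded in ``imputed``.
    """

    subject_id: str
    group: str
    gesture_index: int
    n_bins: int
    values: dict
    occupancy: dict = field(default_factory=dict)
    imputed: dict = field(default_factory=dict)


def profile_feature_names(n_bins: int) -> list[str]:
    return [
        f"{series}_b{b:02d}_{stat}"
        for series in ("speed", "accel")
        for b in range(n_bins)
        for stat in PROFILE_STATS
    ]


def _bin_series(
    values: np.ndarray,
    times: np.ndarray,
    t0: float,
    t1: float,
    n_bins: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign series samples to left-closed bins of normalized time and
    compute the 5 statistics per bin; empty bins get the series-level
    statistics (imputation, flagged)."""
    u = (times - t0) / (t1 - t0)
    idx = np.minimum((u * n_bins).astype(int), n_bins - 1)
    stats = np.empty((n_bins, len(PROFILE_STATS)))
    occupancy = np.zeros(n_bins, dtype=int)
    imputed = np.zeros(n_bins, dtype=bool)
    fallback = [_stat(values, s) for s in PROFILE_STATS]
    for b in range(n_bins):
        sel = values[idx == b]
        occupancy[b] = len(sel)
        if len(sel) == 0:
            stats[b] = fallback
            imputed[b] = True
        else:
            stats[b] = [_stat(sel, s) for s in PROFILE_STATS]
    return stats, occupancy, imputed


def extract_profiles(
    session: GameplaySession,
    n_bins: int | None = None,
    config: ExtractionConfig = DEFAULT_CONFIG,
) -> list[ProfileSample]:
    """Per-movement time-normalized bin profiles for every swipe.

    Each swipe's speed and tangential-acceleration series are normalized to
    [0, 1] over the gesture's duration, split into ``n_bins`` left-closed
    bins (last bin closed), and summarized per bin by mean, median, SD, Q1
    and Q3.
    """
    if n_bins is None:
        n_bins = config.n_bins
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    gestures = segment_and_derive(
        session.touch,
        pointer=config.pointer,
        tap_duration=config.tap_duration,
        tap_displacement=config.tap_displacement,
        smooth=config.smooth,
    )
    samples: list[ProfileSample] = []
    for g in gestures:
        if g.is_tap or g.degenerate:
            continue
        t0, t1 = g.t[0], g.t[-1]
        values: dict[str, float] = {}
        occ: dict[str, np.ndarray] = {}
        imp: dict[str, np.ndarray] = {}
        for series, vals, times in (
            ("speed", g.speed, g.speed_t),
            ("accel", g.tangential_accel, g.accel_t),
        ):
            stats, occupancy, imputed = _bin_series(vals, times, t0, t1, n_bins)
            occ[series] = occupancy
            imp[series] = imputed
            for b in range(n_bins):
                for si, stat in enumerate(PROFILE_STATS):
                    values[f"{series}_b{b:02d}_{stat}"] = float(stats[b, si])
        samples.append(
            ProfileSample(
                subject_id=session.subject_id,
                group=session.group,
                gesture_index=g.index,
                n_bins=n_bins,
                values=values,
                occupancy=occ,
                imputed=imp,
            )
        )
    return samples


def profiles_to_frame(samples: list[ProfileSample]) -> pd.DataFrame:
    """Stack profile samples into a long frame: one row per movement."""
    if not samples:
        return pd.DataFrame(columns=["subject_id", "group", "gesture_index"])
    n_bins = samples[0].n_bins
    cols = profile_feature_names(n_bins)
    rows = []
    for s in samples:
        if s.n_bins != n_bins:
            raise ValueError("mixed n_bins among profile samples")
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "gesture_index": s.gesture_index,
        }
        row.update(s.values)
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "group", "gesture_index", *cols])
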