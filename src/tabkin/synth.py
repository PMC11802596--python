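"""Synthetic gameplay cohorts with controllable group structure.

The generator emulates five-minute coloring-game sessions: a variable-rate
(~60 Hz) touch stream of taps and swipes, and a regular 20 Hz IMU stream of
user acceleration, rotation rate and device attitude.  It exists so the full
pipeline — segmentation, the 269-feature extraction, per-movement profiles,
class-weighted cross-validated classification and group statistics — can be
exercised end to end, including parameter-recovery experiments, without any
recorded cohort.

Movement model
--------------
Swipes follow a minimum-jerk arc-length profile ``s(u) = L(10u^3 - 15u^4 +
6u^5)``, whose tangential acceleration attains its minimum ``-(10/sqrt(3))
L/T^2`` at ``u = (3+sqrt(3))/6``.  Each swipe draws a deceleration floor
``a`` from the archetype and solves for the duration ``T`` that realizes it,
so the archetype knob maps directly onto the extracted minimum tangential
acceleration.  A perpendicular lognormal bow gives strokes a convex-hull
area whose session-level dispersion is set by ``area_log_sd``; a tapered
sinusoidal perturbation of the final quarter of the stroke controls terminal
directness.  Taps are sub-0.1 s gestures with near-zero displacement.

The IMU channels are stationary AR(1) noise with archetype-set standard
deviations, plus small gesture-locked exponential-decay perturbations.  The
y-axis acceleration's AR(1) coefficient is chosen as ``rho = cos(pi * r /
f_s)`` so its zero-crossing (direction-change) rate equals the archetype's
``accel_dir_change_rate_y`` target ``r``.

Every session is a pure function of its seed: cohorts are bit-reproducible,
and per-subject seeds are derived from the master seed with a counter-based
spawn key, so resizing a cohort does not change existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .session import GROUPS, IMU_COLUMNS, TOUCH_COLUMNS, GameplaySession

SCREEN_W = 768.0  # abstract points, tablet portrait
SCREEN_H = 1024.0
TOUCH_HZ = 60.0
IMU_HZ = 20.0
#: |min tangential acceleration| of a minimum-jerk stroke = this * L / T^2.
MINJERK_DECEL = 10.0 / np.sqrt(3.0)

# fixed baseline IMU noise (channels without a dedicated archetype knob)
_ATTITUDE_SD_Z = 0.01  # rad
_ROT_SD_YZ = 0.05  # rad/s
_ACCEL_SD = 0.05  # m/s^2
_AR_ATTITUDE = 0.95
_AR_ROT = 0.80
_AR_ACCEL = 0.60


@dataclass(frozen=True)
class GroupArchetype:
    """Generative knobs for one group's gameplay style.

    Each group-comparison feature has at least one controlling knob:
    ``area_log_sd`` → gesture area variance; ``decel_floor_mean/sd`` →
    minimum gesture acceleration; ``directness_tail_sd`` → gesture
    directness variance; ``attitude_sd_x/y`` → attitude variance;
    ``rot_sd_x`` → rotation variance; ``accel_dir_change_rate_y`` → rate of
    change of acceleration direction (y-axis).
    """

    name: str
    gesture_rate: float = 0.5  # gestures / s
    tap_fraction: float = 0.15
    stroke_length_mean: float = 120.0  # points
    stroke_length_sd: float = 40.0
    area_log_sd: float = 0.4  # lognormal sigma of the per-stroke bow width
    decel_floor_mean: float = -1200.0  # points / s^2
    decel_floor_sd: float = 250.0
    directness_tail_sd: float = 1.5  # points, terminal perturbation scale
    attitude_sd_x: float = 0.02  # rad
    attitude_sd_y: float = 0.02
    rot_sd_x: float = 0.05  # rad/s
    accel_dir_change_rate_y: float = 6.5  # sign changes / s
    noise_sd: float = 0.5  # points, touch sensor noise scale

    def __post_init__(self) -> None:
        if not 0.0 <= self.tap_fraction <= 1.0:
            raise ValueError("tap_fraction must be in [0, 1]")
        if self.gesture_rate <= 0:
            raise ValueError("gesture_rate must be positive")
        for f in (
            "stroke_length_sd", "area_log_sd", "decel_floor_sd",
            "directness_tail_sd", "attitude_sd_x", "attitude_sd_y",
            "rot_sd_x", "noise_sd",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if not 0 < self.accel_dir_change_rate_y < IMU_HZ:
            raise ValueError(
                f"accel_dir_change_rate_y must be in (0, {IMU_HZ})"
            )

    @property
    def mean_swipe_duration(self) -> float:
        return float(
            np.sqrt(
                MINJERK_DECEL * self.stroke_length_mean / abs(self.decel_floor_mean)
            )
        )


@dataclass(frozen=True)
class CohortSpec:
    """A full synthetic cohort: archetype per group, size, duration, seed."""

    archetypes: dict
    n_per_group: int = 20
    duration: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


# ---------------------------------------------------------------------------
# archetype presets
# ---------------------------------------------------------------------------

#: For each group-comparison feature, the group pair the presets are designed
#: to separate (matching the reported pairwise significance pattern).
DESIGNED_DIFFERENCES = {
    "attitude_variance_x": ("TD", "ASD"),
    "gesture_area_variance": ("ASD", "DCD"),
    "minimum_gesture_acceleration": ("TD", "ASD"),
    "accel_direction_change_rate_y": ("ASD", "DCD"),
    "rotation_variance_x": ("TD", "ASD"),
    "attitude_variance_y": ("TD", "ASD"),
    "gesture_directness_variance": ("TD", "DCD"),
}

_EFFECT_SCALE = {"large": 1.0, "medium": 0.5, "none": 0.0}


def study_archetypes(effect: str = "large") -> dict:
    """Three-group presets reproducing the reported significance pattern.

    TD is the baseline.  ASD has elevated device-motion dispersion (attitude
    x/y, rotation x), deeper stroke deceleration and higher gesture-area
    dispersion; DCD has noisier stroke endings (directness) and a lower
    y-acceleration direction-change rate.  ``effect`` scales all group
    offsets: "large" (default), "medium", or "none" (an exchangeable null
    cohort — every group is a TD clone).
    """
    try:
        e = _EFFECT_SCALE[effect]
    except KeyError:
        raise ValueError(f"unknown effect preset {effect!r}") from None
    td = GroupArchetype(name="TD")
    asd = replace(
        td,
        name="ASD",
        attitude_sd_x=td.attitude_sd_x * (1 + e),
        attitude_sd_y=td.attitude_sd_y * (1 + e),
        rot_sd_x=td.rot_sd_x * (1 + e),
        decel_floor_mean=td.decel_floor_mean * (1 + 0.7 * e),
        area_log_sd=td.area_log_sd * (1 + e),
        accel_dir_change_rate_y=td.accel_dir_change_rate_y + 2.5 * e,
    )
    dcd = replace(
        td,
        name="DCD",
        directness_tail_sd=td.directness_tail_sd * (1 + 2 * e),
        accel_dir_change_rate_y=td.accel_dir_change_rate_y - 1.5 * e,
    )
    return {"TD": td, "ASD": asd, "DCD": dcd}


def null_archetypes() -> dict:
    """Identical archetypes for all three groups (exchangeable null)."""
    return study_archetypes(effect="none")


# Table-like covariate models used for the synthetic subject table:
# motor-battery total standard score (TD higher) and age in years.
_COVARIATE_MODEL = {
    "TD": {"mabc2_total": (10.4, 1.67), "age": (12.1, 2.6)},
    "ASD": {"mabc2_total": (4.7, 2.45), "age": (12.4, 2.0)},
    "DCD": {"mabc2_total": (4.4, 1.79), "age": (12.0, 2.3)},
}


# ---------------------------------------------------------------------------
# gesture generation
# ---------------------------------------------------------------------------

def _minjerk_s(u: np.ndarray) -> np.ndarray:
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _sample_times(total: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered ~60 Hz timestamps over [0, total], rescaled to end exactly
    at ``total`` so the nominal stroke duration is preserved."""
    n = max(2, int(round(total * TOUCH_HZ)))
    dt = (1.0 / TOUCH_HZ) * rng.uniform(0.8, 1.2, size=n)
    t = np.concatenate([[0.0], np.cumsum(dt)])
    return t * (total / t[-1])


def generate_gesture(
    archetype: GroupArchetype, rng: np.random.Generator
) -> pd.DataFrame:
    """Generate one atomic gesture (tap or swipe) starting at t = 0.

    Returns a touch-stream frame (down…move…up).  With probability
    ``tap_fraction`` the gesture is a tap; otherwise a minimum-jerk swipe
    whose deceleration floor, bow width and terminal perturbation are drawn
    from the archetype.
    """
    if rng.uniform() < archetype.tap_fraction:
        return _generate_tap(archetype, rng)
    return _generate_swipe(archetype, rng)


def _generate_tap(a: GroupArchetype, rng: np.random.Generator) -> pd.DataFrame:
    dur = rng.uniform(0.04, 0.10)
    t = _sample_times(dur, rng)
    cx = rng.uniform(40.0, SCREEN_W - 40.0)
    cy = rng.uniform(40.0, SCREEN_H - 40.0)
    x = cx + np.clip(rng.normal(0.0, 1.0, size=len(t)), -3, 3)
    y = cy + np.clip(rng.normal(0.0, 1.0, size=len(t)), -3, 3)
    return _as_touch(t, x, y)


def _generate_swipe(a: GroupArchetype, rng: np.random.Generator) -> pd.DataFrame:
    L = float(np.clip(rng.normal(a.stroke_length_mean, a.stroke_length_sd), 20, 400))
    floor = rng.normal(a.decel_floor_mean, a.decel_floor_sd)
    floor = min(floor, -100.0)
    T = float(np.sqrt(MINJERK_DECEL * L / abs(floor)))
    t = _sample_times(T, rng)
    u = t / T
    s = L * _minjerk_s(u)

    theta = rng.uniform(0, 2 * np.pi)
    ux, uy = np.cos(theta), np.sin(theta)
    margin = 30.0
    half = L / 2 + margin
    cx = rng.uniform(half, SCREEN_W - half)
    cy = rng.uniform(half, SCREEN_H - half)
    sx, sy = cx - ux * L / 2, cy - uy * L / 2

    # perpendicular bow: lognormal width scaled by the touch noise scale
    w = 10.0 * a.noise_sd * rng.lognormal(0.0, a.area_log_sd)
    perp = w * np.sin(np.pi * u)
    # terminal perturbation over the last quarter of the stroke
    if a.directness_tail_sd > 0:
        amp = abs(rng.normal(0.0, a.directness_tail_sd))
        freq = rng.uniform(0.5, 1.5)
        phase = rng.uniform(0, 2 * np.pi)
        r = np.clip((u - 0.75) / 0.25, 0.0, 1.0)
        perp = perp + np.where(
            r > 0, amp * np.sin(2 * np.pi * freq * r + phase) * np.sin(np.pi * r), 0.0
        )
    x = sx + ux * s - uy * perp
    y = sy + uy * s + ux * perp
    if a.noise_sd > 0:
        # smoothed sensor noise: correlated jitter, gentle on derivatives
        kernel = np.ones(5) / 5.0
        x = x + np.convolve(rng.normal(0, a.noise_sd, len(t)), kernel, "same")
        y = y + np.convolve(rng.normal(0, a.noise_sd, len(t)), kernel, "same")
    return _as_touch(t, x, y)


def _as_touch(t: np.ndarray, x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    phase = np.full(len(t), "move", dtype=object)
    phase[0] = "down"
    phase[-1] = "up"
    return pd.DataFrame(
        {"t": t, "x": x, "y": y, "phase": phase, "pointer_id": 0},
        columns=TOUCH_COLUMNS,
    )


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

def _ar1(n: int, rho: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    burn = 100
    eps = rng.normal(0.0, sd * np.sqrt(1 - rho**2), size=n + burn)
    out = lfilter([1.0], [1.0, -rho], eps)
    return out[burn:]


def generate_session(
    archetype: GroupArchetype,
    subject_id: str,
    group: str,
    duration: float = 300.0,
    seed=0,
    covariates: dict | None = None,
) -> GameplaySession:
    """Generate one full gameplay session (touch + IMU streams).

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`; the same
    seed reproduces the session exactly.
    """
    rng = np.random.default_rng(seed)
    mean_pause = max(
        0.05,
        1.0 / archetype.gesture_rate
        - (
            archetype.tap_fraction * 0.07
            + (1 - archetype.tap_fraction) * archetype.mean_swipe_duration
        ),
    )

    pieces = []
    cursor = rng.exponential(mean_pause)
    while True:
        g = generate_gesture(archetype, rng)
        if cursor + g["t"].iloc[-1] > duration:
            break
        g = g.copy()
        g["t"] = g["t"] + cursor
        pieces.append(g)
        cursor = g["t"].iloc[-1] + rng.exponential(mean_pause)
    touch = (
        pd.concat(pieces, ignore_index=True)
        if pieces
        else pd.DataFrame(columns=TOUCH_COLUMNS)
    )

    imu = _generate_imu(
        archetype,
        duration,
        gesture_starts=[p["t"].iloc[0] for p in pieces],
        rng=rng,
    )
    if covariates is None:
        model = _COVARIATE_MODEL.get(group, _COVARIATE_MODEL["TD"])
        covariates = {
            k: float(np.round(rng.normal(m, s), 2)) for k, (m, s) in model.items()
        }
    return GameplaySession(
        subject_id=subject_id,
        group=group,
        duration=duration,
        touch=touch,
        imu=imu,
        covariates=covariates,
    )


def _generate_imu(
    a: GroupArchetype,
    duration: float,
    gesture_starts: list,
    rng: np.random.Generator,
) -> pd.DataFrame:
    t = np.arange(0.0, duration, 1.0 / IMU_HZ)
    n = len(t)
    rho_y = float(np.cos(np.pi * a.accel_dir_change_rate_y / IMU_HZ))
    cols = {
        "accel_x": _ar1(n, _AR_ACCEL, _ACCEL_SD, rng),
        "accel_y": _ar1(n, rho_y, _ACCEL_SD, rng),
        "accel_z": _ar1(n, _AR_ACCEL, _ACCEL_SD, rng),
        "rot_x": _ar1(n, _AR_ROT, a.rot_sd_x, rng),
        "rot_y": _ar1(n, _AR_ROT, _ROT_SD_YZ, rng),
        "rot_z": _ar1(n, _AR_ROT, _ROT_SD_YZ, rng),
        "attitude_x": _ar1(n, _AR_ATTITUDE, a.attitude_sd_x, rng),
        "attitude_y": _ar1(n, _AR_ATTITUDE, a.attitude_sd_y, rng),
        "attitude_z": _ar1(n, _AR_ATTITUDE, _ATTITUDE_SD_Z, rng),
    }
    # gesture-locked perturbations: the finger impact imparts a small
    # exponentially decaying kick to acceleration/rotation and a damped
    # oscillatory attitude response
    for t0 in gesture_starts:
        i0 = int(np.searchsorted(t, t0))
        i1 = min(n, i0 + int(1.0 * IMU_HZ))
        if i1 <= i0:
            continue
        dt = t[i0:i1] - t0
        kick = np.exp(-dt / 0.15)
        for ax, scale in (("accel_x", 0.02), ("accel_z", 0.02), ("accel_y", 0.01)):
            cols[ax][i0:i1] += rng.normal(0, scale) * kick
        cols["rot_x"][i0:i1] += rng.normal(0, 0.3 * a.rot_sd_x) * np.exp(-dt / 0.2)
        damped = np.exp(-dt / 0.4) * np.sin(2 * np.pi * 1.5 * dt)
        cols["attitude_x"][i0:i1] += rng.normal(0, 0.2 * a.attitude_sd_x) * damped
        cols["attitude_y"][i0:i1] += rng.normal(0, 0.2 * a.attitude_sd_y) * damped
    return pd.DataFrame({"t": t, **cols}, columns=IMU_COLUMNS)


def generate_cohort(spec: CohortSpec) -> list[GameplaySession]:
    """Generate ``n_per_group`` sessions per group from a cohort spec.

    Per-subject seeds are ``SeedSequence(spec.seed, spawn_key=(group_index,
    subject_index))``, so the cohort is a pure function of the spec and
    adding subjects never changes existing ones.
    """
    sessions = []
    for gi, group in enumerate(g for g in GROUPS if g in spec.archetypes):
        arch = spec.archetypes[group]
        for si in range(spec.n_per_group):
            ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(gi, si))
            sessions.append(
                generate_session(
                    arch,
                    subject_id=f"{group}{si + 1:02d}",
                    group=group,
                    duration=spec.duration,
                    seed=ss,
                )
            )
    return sessions
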