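"""Segmentation of the touch stream into atomic gestures and per-gesture
kinematic series.

An *atomic gesture* is one touch-down → move… → touch-up run by a single
pointer; it is the unit of all touch-side analysis.  Because the touch
sampling rate is variable, derivatives use actual timestamp differences — no
resampling:

* ``speed_i   = ||p_{i+1} - p_i|| / (t_{i+1} - t_i)`` at midpoint times,
* ``tangential_accel_j = (speed_{j+1} - speed_j) / dt_mid`` at interior times.

Acceleration is the *signed* derivative of speed along the path, so its
minimum captures the deepest deceleration of a stroke.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import Phase

log = logging.getLogger(__name__)

#: Default tap definition: shorter than 0.15 s and moving less than 10 points.
TAP_DURATION_S = 0.15
TAP_DISPLACEMENT_PT = 10.0


@dataclass
class Gesture:
    """One down…up touch run with derived kinematics.

    ``speed`` has ``n_samples - 1`` entries (at midpoint timestamps
    ``speed_t``); ``tangential_accel`` has ``n_samples - 2`` entries (at
    ``accel_t``).  Gestures with fewer than three samples are *degenerate*:
    they still count as gestures (and may be taps) but carry no usable
    kinematic series.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    index: int = 0
    speed: np.ndarray = field(default_factory=lambda: np.empty(0))
    speed_t: np.ndarray = field(default_factory=lambda: np.empty(0))
    tangential_accel: np.ndarray = field(default_factory=lambda: np.empty(0))
    accel_t: np.ndarray = field(default_factory=lambda: np.empty(0))
    is_tap: bool = False

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def degenerate(self) -> bool:
        return self.n_samples < 3

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def displacement(self) -> float:
        return float(np.hypot(self.x[-1] - self.x[0], self.y[-1] - self.y[0]))

    @property
    def path_length(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())

    @property
    def start(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.y[0])

    @property
    def end(self) -> tuple[float, float]:
        return float(self.x[-1]), float(self.y[-1])


def segment_gestures(
    touch: pd.DataFrame, pointer: str | int = "first"
) -> list[Gesture]:
    """Split a touch stream into atomic gestures.

    Parameters
    ----------
    touch
        Touch stream frame (columns t, x, y, phase, pointer_id).
    pointer
        ``"first"`` keeps only the first pointer id seen (dominant-hand
        single-finger default), ``"all"`` segments every pointer, or pass an
        explicit pointer id.

    A down without a matching up at stream end closes the gesture at the last
    sample with a warning.  Samples are partitioned: each belongs to exactly
    one gesture of its pointer.
    """
    if len(touch) == 0:
        return []
    if pointer == "first":
        pids = [int(touch["pointer_id"].iloc[0])]
    elif pointer == "all":
        pids = list(pd.unique(touch["pointer_id"]))
    else:
        pids = [int(pointer)]

    gestures: list[Gesture] = []
    for pid in pids:
        sub = touch[touch["pointer_id"] == pid]
        t = sub["t"].to_numpy()
        x = sub["x"].to_numpy()
        y = sub["y"].to_numpy()
        phases = sub["phase"].to_numpy()
        start = None
        for i, ph in enumerate(phases):
            if ph == Phase.DOWN.value:
                if start is not None:
                    raise ValueError(
                        f"nested 'down' at sample {i} of pointer {pid}"
                    )
                start = i
            elif ph in (Phase.MOVE.value, Phase.UP.value):
                if start is None:
                    raise ValueError(
                        f"'{ph}' before any 'down' at sample {i} of pointer {pid}"
                    )
                if ph == Phase.UP.value:
                    gestures.append(
                        Gesture(t[start : i + 1], x[start : i + 1], y[start : i + 1])
                    )
                    start = None
        if start is not None:
            log.warning(
                "pointer %s: unmatched 'down' at stream end; closing gesture "
                "at last sample",
                pid,
            )
            gestures.append(Gesture(t[start:], x[start:], y[start:]))

    gestures.sort(key=lambda g: g.t[0])
    for k, g in enumerate(gestures):
        g.index = k
    return gestures


def classify_tap(
    g: Gesture,
    dur_thresh: float = TAP_DURATION_S,
    disp_thresh: float = TAP_DISPLACEMENT_PT,
) -> bool:
    """A tap is a gesture both shorter than ``dur_thresh`` seconds and
    displacing less than ``disp_thresh`` points."""
    return g.duration < dur_thresh and g.displacement < disp_thresh


def kinematic_series(g: Gesture, smooth: bool = False) -> Gesture:
    """Populate ``speed`` and ``tangential_accel`` from actual timestamps.

    With ``smooth=True`` a 3-point moving average is applied to the
    coordinates before differencing (default off; the raw variable-rate
    samples are used as recorded).  Degenerate gestures get empty series.
    """
    n = g.n_samples
    if n < 2:
        return g
    t, x, y = g.t, g.x, g.y
    dt = np.diff(t)
    if (dt <= 0).any():
        raise ValueError(
            f"gesture {g.index}: duplicate or non-increasing timestamps"
        )
    if smooth and n >= 3:
        kernel = np.ones(3) / 3.0
        xs, ys = x.copy(), y.copy()
        xs[1:-1] = np.convolve(x, kernel, mode="valid")
        ys[1:-1] = np.convolve(y, kernel, mode="valid")
        x, y = xs, ys
    g.speed = np.hypot(np.diff(x), np.diff(y)) / dt
    g.speed_t = 0.5 * (t[:-1] + t[1:])
    if n >= 3:
        dt_mid = np.diff(g.speed_t)
        g.tangential_accel = np.diff(g.speed) / dt_mid
        g.accel_t = t[1:-1]
    else:
        g.tangential_accel = np.empty(0)
        g.accel_t = np.empty(0)
    return g


def segment_and_derive(
    touch: pd.DataFrame,
    pointer: str | int = "first",
    tap_duration: float = TAP_DURATION_S,
    tap_displacement: float = TAP_DISPLACEMENT_PT,
    smooth: bool = False,
) -> list[Gesture]:
    """Segment, compute kinematics and flag taps in one pass."""
    gestures = segment_gestures(touch, pointer=pointer)
    for g in gestures:
        kinematic_series(g, smooth=smooth)
        g.is_tap = classify_tap(g, tap_duration, tap_displacement)
    return gestures
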