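"""Gameplay-session data model and on-disk formats.

A recording session couples two sensor streams captured while a child colors
on a tablet with the dominant hand for a nominal five minutes:

* a **touch stream** — timestamped screen coordinates with down/move/up
  phases, sampled at a variable rate of roughly 60 Hz while the finger moves;
* an **IMU stream** — triaxial user acceleration, rotation rate and device
  attitude (roll/pitch/yaw) at a regular ~20 Hz.

On disk a session is a *bundle*: a directory holding ``manifest.json``
(subject id, group, duration, covariates, stream filenames) plus
``touch.csv`` and ``imu.csv``.  Timestamps are seconds since session start;
screen coordinates are abstract points with the origin at the top-left and y
increasing downward.  All numeric fields are written with six decimal places,
so ``read_session(write_session(s))`` round-trips bit-exactly at that
precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .registry import FEATURE_NAMES, N_FEATURES

GROUPS = ("TD", "ASD", "DCD")

TOUCH_COLUMNS = ["t", "x", "y", "phase", "pointer_id"]
IMU_COLUMNS = [
    "t",
    "accel_x", "accel_y", "accel_z",
    "rot_x", "rot_y", "rot_z",
    "attitude_x", "attitude_y", "attitude_z",
]

_FLOAT_FMT = "%.6f"


class Phase(str, Enum):
    DOWN = "down"
    MOVE = "move"
    UP = "up"


class TouchSample(NamedTuple):
    t: float
    x: float
    y: float
    phase: str
    pointer_id: int = 0


class IMUSample(NamedTuple):
    t: float
    accel: tuple[float, float, float]
    rot: tuple[float, float, float]
    attitude: tuple[float, float, float]


class SessionFormatError(ValueError):
    """Bundle files are missing, malformed, or have wrong columns."""


class SessionValidationError(ValueError):
    """Stream contents violate a session invariant."""


@dataclass
class GameplaySession:
    """One subject's gameplay recording plus label and covariates.

    ``touch`` and ``imu`` are pandas DataFrames with :data:`TOUCH_COLUMNS`
    and :data:`IMU_COLUMNS` respectively; either may be empty.
    """

    subject_id: str
    group: str
    duration: float = 300.0
    touch: pd.DataFrame = field(default_factory=lambda: _empty_touch())
    imu: pd.DataFrame = field(default_factory=lambda: _empty_imu())
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.touch = _coerce_frame(self.touch, TOUCH_COLUMNS, "touch")
        self.imu = _coerce_frame(self.imu, IMU_COLUMNS, "imu")

    # -- convenience iterators over typed records -------------------------
    def iter_touch(self):
        for row in self.touch.itertuples(index=False):
            yield TouchSample(row.t, row.x, row.y, row.phase, int(row.pointer_id))

    def iter_imu(self):
        for row in self.imu.itertuples(index=False):
            yield IMUSample(
                row.t,
                (row.accel_x, row.accel_y, row.accel_z),
                (row.rot_x, row.rot_y, row.rot_z),
                (row.attitude_x, row.attitude_y, row.attitude_z),
            )

    def validate(self) -> None:
        """Raise :class:`SessionValidationError` on any invariant violation."""
        if self.group not in GROUPS:
            raise SessionValidationError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if not (self.duration > 0):
            raise SessionValidationError("duration must be positive")
        validate_touch_stream(self.touch, self.duration)
        validate_imu_stream(self.imu, self.duration)

    def __eq__(self, other) -> bool:
        """Value equality at the declared on-disk precision (6 decimals on
        numeric stream fields), used by the round-trip contract."""
        if not isinstance(other, GameplaySession):
            return NotImplemented
        if not (
            self.subject_id == other.subject_id
            and self.group == other.group
            and math.isclose(self.duration, other.duration, abs_tol=1e-9)
            and self.covariates == other.covariates
            and len(self.touch) == len(other.touch)
            and len(self.imu) == len(other.imu)
        ):
            return False
        for a, b, cols in (
            (self.touch, other.touch, TOUCH_COLUMNS),
            (self.imu, other.imu, IMU_COLUMNS),
        ):
            for c in cols:
                if c in ("phase", "pointer_id"):
                    if not a[c].equals(b[c]):
                        return False
                elif not np.allclose(
                    a[c].to_numpy(), b[c].to_numpy(), atol=5.000001e-7, rtol=0.0
                ):
                    return False
        return True


def _empty_touch() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t": pd.Series(dtype=float),
            "x": pd.Series(dtype=float),
            "y": pd.Series(dtype=float),
            "phase": pd.Series(dtype=object),
            "pointer_id": pd.Series(dtype=int),
        }
    )


def _empty_imu() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in IMU_COLUMNS})


def _coerce_frame(df: pd.DataFrame, columns: list[str], what: str) -> pd.DataFrame:
    if not isinstance(df, pd.DataFrame):
        df = pd.DataFrame(df, columns=columns)
    missing = [c for c in columns if c not in df.columns]
    extra = [c for c in df.columns if c not in columns]
    if missing or extra:
        raise SessionFormatError(
            f"{what} stream columns mismatch: missing={missing} extra={extra}"
        )
    df = df[columns].reset_index(drop=True)
    for c in columns:
        if c == "phase":
            df[c] = df[c].astype(str)
        elif c == "pointer_id":
            df[c] = df[c].astype(int)
        else:
            df[c] = df[c].astype(float)
    return df


def validate_touch_stream(touch: pd.DataFrame, duration: float) -> None:
    if len(touch) == 0:
        return
    t = touch["t"].to_numpy()
    if (t < 0).any() or (t > duration + 1e-9).any():
        bad = int(np.flatnonzero((t < 0) | (t > duration + 1e-9))[0])
        raise SessionValidationError(
            f"touch timestamp out of [0, duration] at row {bad}"
        )
    bad_phase = ~touch["phase"].isin([p.value for p in Phase])
    if bad_phase.any():
        raise SessionValidationError(
            f"invalid touch phase at row {int(np.flatnonzero(bad_phase)[0])}"
        )
    for pid, sub in touch.groupby("pointer_id", sort=False):
        ts = sub["t"].to_numpy()
        if (np.diff(ts) < 0).any():
            row = int(sub.index[int(np.flatnonzero(np.diff(ts) < 0)[0]) + 1])
            raise SessionValidationError(
                f"non-monotone touch timestamps for pointer {pid} at row {row}"
            )
        # every down must be matched by a later up; no touch activity while up
        open_down = False
        for row_idx, phase in zip(sub.index, sub["phase"]):
            if phase == Phase.DOWN.value:
                if open_down:
                    raise SessionValidationError(
                        f"nested down without up (pointer {pid}, row {row_idx})"
                    )
                open_down = True
            elif phase in (Phase.MOVE.value, Phase.UP.value):
                if not open_down:
                    raise SessionValidationError(
                        f"'{phase}' sample before any down "
                        f"(pointer {pid}, row {row_idx})"
                    )
                if phase == Phase.UP.value:
                    open_down = False


def validate_imu_stream(imu: pd.DataFrame, duration: float) -> None:
    if len(imu) == 0:
        return
    t = imu["t"].to_numpy()
    if (t < 0).any() or (t > duration + 1e-9).any():
        bad = int(np.flatnonzero((t < 0) | (t > duration + 1e-9))[0])
        raise SessionValidationError(f"IMU timestamp out of range at row {bad}")
    if (np.diff(t) <= 0).any():
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise SessionValidationError(
            f"IMU timestamps not strictly increasing at row {row}"
        )


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

def write_session(session: GameplaySession, path) -> Path:
    """Write ``session`` as a bundle directory; returns the bundle path.

    Numeric stream values are rounded to six decimals on write, which defines
    the round-trip precision of the format.
    """
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subject_id": session.subject_id,
        "group": session.group,
        "duration": session.duration,
        "covariates": session.covariates,
        "touch_file": "touch.csv",
        "imu_file": "imu.csv",
    }
    with open(path / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    session.touch.to_csv(
        path / "touch.csv", index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )
    session.imu.to_csv(
        path / "imu.csv", index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )
    return path


def read_session(path) -> GameplaySession:
    """Read a session bundle written by :func:`write_session` and validate it."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise SessionFormatError(f"no manifest.json under {path}")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    for key in ("subject_id", "group", "duration"):
        if key not in manifest:
            raise SessionFormatError(f"manifest missing field {key!r}")
    touch = pd.read_csv(path / manifest.get("touch_file", "touch.csv"))
    imu = pd.read_csv(path / manifest.get("imu_file", "imu.csv"))
    try:
        session = GameplaySession(
            subject_id=str(manifest["subject_id"]),
            group=str(manifest["group"]),
            duration=float(manifest["duration"]),
            touch=touch,
            imu=imu,
            covariates=dict(manifest.get("covariates", {})),
        )
    except SessionFormatError:
        raise
    session.validate()
    return session


# ---------------------------------------------------------------------------
# feature vectors and the feature table
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """The named 269-entry session representation (105 touch + 164 IMU).

    ``values`` maps feature name to number; missing values (e.g. touch
    aggregates of a gesture-free session) are ``NaN``, written as empty cells
    in the feature table.
    """

    subject_id: str
    group: str
    values: dict

    def __post_init__(self) -> None:
        names = set(self.values)
        if names != set(FEATURE_NAMES):
            missing = set(FEATURE_NAMES) - names
            extra = names - set(FEATURE_NAMES)
            raise ValueError(
                f"feature vector must contain exactly the {N_FEATURES} registry "
                f"names; missing={sorted(missing)[:5]} extra={sorted(extra)[:5]}"
            )
        # normalize insertion order to registry order
        self.values = {n: float(self.values[n]) for n in FEATURE_NAMES}


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack vectors into a wide table: subject_id, group, 269 registry columns."""
    rows = []
    for v in vectors:
        row = {"subject_id": v.subject_id, "group": v.group}
        row.update(v.values)
        rows.append(row)
    cols = ["subject_id", "group", *FEATURE_NAMES]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


def write_feature_table(vectors: list[FeatureVector], path) -> Path:
    """Write the wide feature CSV; column order comes from the registry only."""
    path = Path(path)
    df = feature_table(vectors)
    df.to_csv(path, index=False, float_format="%.9g", lineterminator="\n")
    return path


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["subject_id", "group", *FEATURE_NAMES]
    if list(df.columns) != expected:
        raise SessionFormatError(
            "feature table columns do not match the registry layout"
        )
    return df
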