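import numpy as np
import pandas as pd
import pytest

from tabkin.session import GameplaySession
from tabkin.synth import generate_session, study_archetypes


def touch_frame(rows):
    """Build a touch-stream frame from (t, x, y, phase[, pointer]) tuples."""
    recs = []
    for r in rows:
        t, x, y, phase = r[:4]
        pid = r[4] if len(r) > 4 else 0
        recs.append({"t": t, "x": x, "y": y, "phase": phase, "pointer_id": pid})
    return pd.DataFrame(recs, columns=["t", "x", "y", "phase", "pointer_id"])


def imu_frame(t, **channels):
    cols = {
        "t": np.asarray(t, dtype=float),
        **{
            f"{sig}_{ax}": np.zeros(len(t))
            for sig in ("accel", "rot", "attitude")
            for ax in ("x", "y", "z")
        },
    }
    for name, values in channels.items():
        cols[name] = np.asarray(values, dtype=float)
    return pd.DataFrame(cols)


@pytest.fixture(scope="session")
def td_archetype():
    return study_archetypes()["TD"]


@pytest.fixture(scope="session")
def short_session(td_archetype):
    """A 60 s synthetic session used by structural tests."""
    return generate_session(td_archetype, "TD01", "TD", duration=60.0, seed=11)


@pytest.fixture()
def two_stroke_session():
    """Hand-built session: two move runs and regular IMU samples."""
    rows = []
    for k, t0 in enumerate((0.0, 2.0)):
        for i in range(6):
            phase = "down" if i == 0 else ("up" if i == 5 else "move")
            rows.append((t0 + 0.02 * i, 100.0 + 10 * i + 50 * k, 200.0 + 5 * i, phase))
    t = np.arange(0.0, 3.0, 0.05)
    imu = imu_frame(t, accel_x=np.sin(t), attitude_y=0.01 * np.cos(t))
    return GameplaySession(
        subject_id="S1", group="TD", duration=3.0,
        touch=touch_frame(rows), imu=imu, covariates={"age": 12.0},
    )
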