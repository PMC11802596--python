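import numpy as np
import pytest

from tabkin.features import (
    ExtractionConfig,
    extract_features,
    extract_imu_features,
    extract_profiles,
    extract_touch_features,
    gesture_area,
    gesture_directness,
    line_deviation,
    min_gesture_acceleration,
    profiles_to_frame,
)
from tabkin.gestures import segment_and_derive
from tabkin.registry import FEATURE_NAMES, IMU_NAMES, TOUCH_NAMES
from tabkin.session import GameplaySession
from tabkin.synth import generate_session

from conftest import imu_frame, touch_frame
from test_gestures import make_gesture


# --------------------------------------------------------------------------
# convex-hull area
# --------------------------------------------------------------------------

def hull_area_oracle(points: np.ndarray) -> float:
    """Brute force: find extreme points by exhaustive edge testing, order
    them around the centroid, and sum signed triangle (shoelace) areas."""
    pts = np.unique(points, axis=0)
    n = len(pts)
    if n < 3:
        return 0.0
    hull = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts - pts[i]
            cross = (pts[j, 0] - pts[i, 0]) * d[:, 1] - (pts[j, 1] - pts[i, 1]) * d[:, 0]
            if (cross >= -1e-12).all() or (cross <= 1e-12).all():
                hull.append(i)
                break
    verts = pts[sorted(set(hull))]
    c = verts.mean(axis=0)
    order = np.argsort(np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0]))
    v = verts[order]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestGestureArea:
    def test_rectangle(self):
        g = make_gesture(np.arange(4) * 0.1, [0, 4, 4, 0], [0, 0, 3, 3], derive=False)
        assert gesture_area(g) == pytest.approx(12.0)

    def test_collinear_points_have_zero_area(self):
        g = make_gesture(np.arange(5) * 0.1, np.arange(5.0), 2 * np.arange(5.0),
                         derive=False)
        assert gesture_area(g) == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = rng.integers(1, 13)
            pts = rng.uniform(0, 100, size=(n, 2))
            g = make_gesture(np.arange(n) * 0.02, pts[:, 0], pts[:, 1], derive=False)
            assert gesture_area(g) == pytest.approx(
                hull_area_oracle(pts), rel=1e-9, abs=1e-9
            )

    def test_monotone_under_point_appending(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 100, size=(12, 2))
        areas = [
            gesture_area(
                make_gesture(np.arange(k) * 0.02, pts[:k, 0], pts[:k, 1], derive=False)
            )
            for k in range(1, 13)
        ]
        assert all(a2 >= a1 - 1e-12 for a1, a2 in zip(areas, areas[1:]))


class TestDirectnessAndDeviation:
    def test_straight_line_is_perfectly_direct(self):
        g = make_gesture(np.arange(8) * 0.1, np.arange(8.0), np.zeros(8))
        assert gesture_directness(g) == pytest.approx(1.0)
        assert line_deviation(g) == pytest.approx(0.0)

    def test_hand_computed_tail(self):
        # tail = last 3 of 12 samples: (0,0),(1,0),(1,1): sqrt(2)/2
        x = np.concatenate([np.linspace(-9, -1, 9), [0, 1, 1]])
        y = np.concatenate([np.zeros(9), [0, 0, 1]])
        g = make_gesture(np.arange(12) * 0.05, x, y)
        assert gesture_directness(g, tail_fraction=0.25) == pytest.approx(
            np.sqrt(2) / 2
        )

    def test_stationary_tail_defined_as_one(self):
        g = make_gesture(np.arange(4) * 0.1, [0, 5, 5, 5], [0, 0, 0, 0])
        assert gesture_directness(g, tail_fraction=0.5) == 1.0

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = rng.integers(4, 20)
            g = make_gesture(
                np.arange(n) * 0.02, rng.uniform(0, 50, n), rng.uniform(0, 50, n)
            )
            assert 0.0 <= gesture_directness(g) <= 1.0


class TestMinAcceleration:
    def test_constant_speed_gesture(self):
        g = make_gesture(np.arange(5) * 0.1, 2.0 * np.arange(5), np.zeros(5))
        assert min_gesture_acceleration(g) == pytest.approx(0.0)

    def test_hand_computed(self):
        g = make_gesture([0.0, 0.1, 0.2, 0.3], [0.0, 0.0, 1.0, 1.0], np.zeros(4))
        assert min_gesture_acceleration(g) == pytest.approx(-100.0)
        assert min_gesture_acceleration(g) <= g.tangential_accel.mean()


# --------------------------------------------------------------------------
# session feature extraction
# --------------------------------------------------------------------------

class TestSessionFeatures:
    def test_exactly_269_named_values(self, short_session):
        fv = extract_features(short_session)
        assert list(fv.values) == list(FEATURE_NAMES)
        touch = extract_touch_features(short_session)
        imu = extract_imu_features(short_session)
        assert set(touch) == set(TOUCH_NAMES) and len(touch) == 105
        assert set(imu) == set(IMU_NAMES) and len(imu) == 164

    def test_identical_gestures_zero_variance(self):
        rows = []
        for t0 in (0.0, 2.0):
            for i in range(5):
                phase = "down" if i == 0 else ("up" if i == 4 else "move")
                rows.append((t0 + 0.05 * i, 10.0 * i, 5.0 * i, phase))
        s = GameplaySession("S", "TD", duration=4.0, touch=touch_frame(rows))
        feats = extract_touch_features(s)
        for name in ("gesture_area_variance", "gesture_directness_variance",
                     "touch_duration_var", "touch_path_length_var"):
            assert feats[name] == pytest.approx(0.0)

    def test_population_variance_convention(self):
        # per-gesture areas {0.5, 1.0, 1.5}: population variance = 1/6
        areas = np.array([0.5, 1.0, 1.5])
        assert np.isclose(areas.var(), 1 / 6)
        rows = []
        for k, side in enumerate(np.sqrt(areas)):
            t0 = 2.0 * k
            pts = [(0, 0), (side, 0), (side, side), (0, side)]
            for i, (px, py) in enumerate(pts):
                phase = "down" if i == 0 else ("up" if i == 3 else "move")
                rows.append((t0 + 0.1 * i, 100 * k + px, py, phase))
        s = GameplaySession("S", "TD", duration=7.0, touch=touch_frame(rows))
        feats = extract_touch_features(s)
        assert feats["gesture_area_variance"] == pytest.approx(1 / 6)

    def test_translation_invariance(self, short_session):
        base = extract_touch_features(short_session)
        shifted = short_session.touch.copy()
        shifted["x"] += 37.0
        shifted["y"] -= 11.0
        moved = GameplaySession(
            "S", "TD", duration=short_session.duration, touch=shifted,
            imu=short_session.imu,
        )
        other = extract_touch_features(moved)
        coord_feats = {
            n for n in TOUCH_NAMES
            if any(c in n for c in ("start_x", "start_y", "end_x", "end_y"))
        }
        for name in TOUCH_NAMES:
            if name in coord_feats:
                continue
            assert other[name] == pytest.approx(base[name], rel=1e-9, abs=1e-9), name

    def test_constant_attitude_has_zero_variance(self):
        t = np.arange(0.0, 2.0, 0.05)
        s = GameplaySession("S", "TD", duration=2.0,
                            imu=imu_frame(t, attitude_x=np.full(len(t), 0.3)))
        feats = extract_imu_features(s)
        assert feats["attitude_variance_x"] == pytest.approx(0.0)

    def test_alternating_sign_direction_change_rate(self):
        t = np.arange(0.0, 2.0, 0.05)  # 20 Hz
        s = GameplaySession(
            "S", "TD", duration=2.0,
            imu=imu_frame(t, accel_y=0.1 * (-1.0) ** np.arange(len(t))),
        )
        feats = extract_imu_features(s)
        assert feats["accel_direction_change_rate_y"] == pytest.approx(20.0)

    def test_empty_imu_yields_sentinels_with_warning(self):
        s = GameplaySession("S", "TD", duration=1.0)
        with pytest.warns(UserWarning, match="empty IMU"):
            feats = extract_imu_features(s)
        assert all(np.isnan(v) for v in feats.values())


# --------------------------------------------------------------------------
# per-movement profiles
# --------------------------------------------------------------------------

class TestProfiles:
    def test_constant_speed_profile(self):
        n = 21
        rows = [
            (0.05 * i, 3.0 * i, 0.0,
             "down" if i == 0 else ("up" if i == n - 1 else "move"))
            for i in range(n)
        ]
        s = GameplaySession("S", "TD", duration=2.0, touch=touch_frame(rows))
        (p,) = extract_profiles(s, n_bins=5)
        means = [p.values[f"speed_b{b:02d}_mean"] for b in range(5)]
        sds = [p.values[f"speed_b{b:02d}_sd"] for b in range(5)]
        assert np.allclose(means, means[0])
        assert np.allclose(sds, 0.0)

    def test_occupancy_of_uniformly_timed_samples(self):
        # 10 samples at dt=1: speed midpoints 0.5..8.5 → bins [2,2,1,2,2];
        # acceleration at interior samples 1..8 → bins [1,2,2,2,1]
        rows = [
            (float(i), 20.0 * i, 0.0,
             "down" if i == 0 else ("up" if i == 9 else "move"))
            for i in range(10)
        ]
        s = GameplaySession("S", "TD", duration=10.0, touch=touch_frame(rows))
        (p,) = extract_profiles(s, n_bins=5)
        assert p.occupancy["speed"].tolist() == [2, 2, 1, 2, 2]
        assert p.occupancy["accel"].tolist() == [1, 2, 2, 2, 1]

    def test_occupancy_conservation_random_gestures(self, td_archetype):
        s = generate_session(td_archetype, "S", "TD", duration=120.0, seed=13)
        profiles = extract_profiles(s, n_bins=10)
        gestures = [
            g for g in segment_and_derive(s.touch) if not g.is_tap and not g.degenerate
        ]
        assert len(profiles) == len(gestures)
        for p, g in zip(profiles, gestures):
            assert p.occupancy["speed"].sum() == len(g.speed)
            assert p.occupancy["accel"].sum() == len(g.tangential_accel)

    def test_empty_bins_imputed_and_flagged(self):
        rows = [
            (t, 30.0 * t, 0.0, phase)
            for t, phase in [(0.0, "down"), (0.05, "move"), (0.1, "move"),
                             (2.0, "up")]
        ]
        s = GameplaySession("S", "TD", duration=3.0, touch=touch_frame(rows))
        (p,) = extract_profiles(s, n_bins=10)
        assert p.imputed["speed"].any()
        (g,) = segment_and_derive(s.touch)
        for b in np.flatnonzero(p.imputed["speed"]):
            # imputed bins carry the gesture-level statistic
            assert p.values[f"speed_b{b:02d}_mean"] == pytest.approx(g.speed.mean())
            assert p.values[f"speed_b{b:02d}_sd"] == pytest.approx(g.speed.std())

    def test_invalid_bin_count(self, short_session):
        with pytest.raises(ValueError, match="n_bins"):
            extract_profiles(short_session, n_bins=0)

    def test_frame_layout(self, short_session):
        frame = profiles_to_frame(extract_profiles(short_session, n_bins=4))
        assert list(frame.columns[:3]) == ["subject_id", "group", "gesture_index"]
        assert frame.shape[1] == 3 + 4 * 5 * 2
        assert (frame["subject_id"] == "TD01").all()
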