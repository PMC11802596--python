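import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from tabkin.models import (
    GBMConfig,
    NET_GRID,
    NetConfig,
    LeakageError,
    check_no_subject_overlap,
    compute_class_weights,
    fit_profile_gbm,
    fit_session_net,
    grid_search,
    predict_session_average,
)


class TestClassWeights:
    @pytest.mark.parametrize(
        "sizes,expected",
        [
            ({"A": 10, "B": 10}, {"A": 1.0, "B": 1.0}),
            ({"A": 20, "B": 16}, {"A": 0.9, "B": 1.125}),
            ({"TD": 20, "ASD": 18, "DCD": 16}, None),
        ],
    )
    def test_balanced_inverse_frequency(self, sizes, expected):
        labels = [c for c, n in sizes.items() for _ in range(n)]
        w = compute_class_weights(labels)
        if expected is not None:
            assert w == pytest.approx(expected)
        # algebraic identity and monotonicity in class size
        assert sum(w[c] * n for c, n in sizes.items()) == pytest.approx(len(labels))
        ordered = sorted(sizes, key=sizes.get)
        assert all(
            w[a] >= w[b] - 1e-12 for a, b in zip(ordered, ordered[1:])
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights(["A"] * 5)


def blobs(n_per, d=5, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(0.0, 1.0, (n_per, d)),
        rng.normal(sep, 1.0, (n_per, d)),
    ])
    y = np.array(["A"] * n_per + ["B"] * n_per)
    return X, y


class TestSessionNet:
    def test_separable_blobs_fit_perfectly(self):
        X, y = blobs(20)
        net = fit_session_net(X, y, NetConfig(seed=0))
        assert (net.predict(X) == y).mean() == 1.0
        proba = net.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_deterministic_under_seed(self):
        X, y = blobs(15, sep=1.0)
        p1 = fit_session_net(X, y, NetConfig(seed=3)).predict_proba(X)
        p2 = fit_session_net(X, y, NetConfig(seed=3)).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_nonfinite_features_rejected(self):
        X, y = blobs(5)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_session_net(X, y)

    def test_shuffled_labels_near_chance(self):
        # null experiment: random labels → accuracy on an independent test
        # set within the 95% binomial band around 0.5
        rng = np.random.default_rng(5)
        correct, total = 0, 0
        for seed in range(5):
            X = rng.normal(size=(40, 10))
            y = np.array(["A", "B"] * 20)
            net = fit_session_net(X, y, NetConfig(seed=seed, max_epochs=200))
            X_new = rng.normal(size=(200, 10))
            y_new = rng.choice(["A", "B"], size=200)
            correct += int((net.predict(X_new) == y_new).sum())
            total += 200
        acc = correct / total
        half = 1.96 * np.sqrt(0.25 / total)
        assert 0.5 - half <= acc <= 0.5 + half

    def test_class_weighting_matches_minority_duplication(self):
        # training with weight 2 on the minority ≈ training on duplicated
        # minority rows (loose tolerance on the predicted probabilities)
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(0, 1, (20, 4)), rng.normal(2, 1, (10, 4))])
        y = np.array(["A"] * 20 + ["B"] * 10)
        sw = np.where(y == "B", 2.0, 1.0)
        from tabkin.models import SessionNet

        net_w = SessionNet(NetConfig(seed=1)).fit(X, y, sample_weight=sw)
        X_dup = np.vstack([X, X[y == "B"]])
        y_dup = np.concatenate([y, y[y == "B"]])
        net_d = SessionNet(NetConfig(seed=1)).fit(X_dup, y_dup)
        grid = rng.normal(1, 1.5, (40, 4))
        assert np.allclose(
            net_w.predict_proba(grid), net_d.predict_proba(grid), atol=0.12
        )


class TestProfileGBM:
    def test_disjoint_profiles_classified_perfectly(self):
        rng = np.random.default_rng(2)
        rows, labels, subjects = [], [], []
        for s in range(8):
            group = "A" if s < 4 else "B"
            base = 10.0 if group == "A" else 50.0
            for _ in range(6):
                rows.append(base + rng.uniform(-2, 2, size=5))
                labels.append(group)
                subjects.append(f"S{s}")
        X = np.array(rows)
        y = np.array(labels)
        subjects = np.array(subjects)
        train = ~np.isin(subjects, ["S0", "S7"])
        check_no_subject_overlap(subjects[train], subjects[~train])
        gbm = fit_profile_gbm(X[train], y[train], GBMConfig(n_trees=100, seed=0))
        for sid, truth in (("S0", "A"), ("S7", "B")):
            proba = predict_session_average(gbm, X[subjects == sid])
            assert gbm.classes_[np.argmax(proba)] == truth
            assert proba.sum() == pytest.approx(1.0)

    def test_single_class_input_rejected(self):
        X = np.zeros((4, 3))
        with pytest.raises(ValueError, match="single class"):
            fit_profile_gbm(X, np.array(["A"] * 4))

    def test_leakage_guard_raises(self):
        with pytest.raises(LeakageError, match="S1"):
            check_no_subject_overlap(["S1", "S2"], ["S1", "S3"])


class TestPredictionAveraging:
    def test_mean_arithmetic_and_permutation_invariance(self):
        class Stub:
            def predict_proba(self, X):
                return np.asarray(X)

        probs = np.array([[0.8, 0.2], [0.6, 0.4]])
        avg = predict_session_average(Stub(), probs)
        assert avg == pytest.approx([0.7, 0.3])
        assert predict_session_average(Stub(), probs[::-1]) == pytest.approx(avg)
        same = np.tile([[0.25, 0.75]], (5, 1))
        assert predict_session_average(Stub(), same) == pytest.approx([0.25, 0.75])

    def test_empty_movement_list_rejected(self):
        class Stub:
            def predict_proba(self, X):
                return np.asarray(X)

        with pytest.raises(ValueError, match="no movements"):
            predict_session_average(Stub(), np.empty((0, 2)))


class TestGridSearch:
    def test_single_point_grid(self):
        res = grid_search(lambda cfg: [(0, 0, 0.5)], NetConfig(), {"units": (20,)})
        assert res.best_config.units == 20
        assert res.best_score == 0.5

    def test_dominant_config_selected_and_table_shape(self):
        def evaluate(cfg):
            acc = 0.9 if (cfg.units, cfg.learning_rate) == (30, 0.003) else 0.5
            return [(f, r, acc) for r in range(2) for f in range(3)]

        res = grid_search(evaluate, NetConfig(), NET_GRID)
        assert (res.best_config.units, res.best_config.learning_rate) == (30, 0.003)
        assert len(res.table) == 9 * 3 * 2  # grid size x folds x repeats

    def test_ties_prefer_smaller_model_then_lower_lr(self):
        res = grid_search(lambda cfg: [(0, 0, 0.7)], NetConfig(), NET_GRID)
        assert res.best_config.units == 20
        assert res.best_config.learning_rate == 0.001

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            grid_search(lambda cfg: [], NetConfig(), {"units": ()})
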