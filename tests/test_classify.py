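"""Splits, L0 training, decision-level fusion and feature-level fusion."""

import numpy as np
import pandas as pd
import pytest

import omicstack as om
from omicstack.classify import SplitPlan, StackedProbabilities, FusionWeights

from conftest import LIGHT_GRIDS


def _separable(n=300, k=3, p=10, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.resize(np.arange(k), n)
    rng.shuffle(labels)
    centers = rng.normal(0, 6, size=(k, p))
    X = centers[labels] + rng.normal(size=(n, p))
    return X, labels


def _stacked(p_svm, p_rf, p_ffnn, classes=None):
    n, k = np.asarray(p_svm).shape
    return StackedProbabilities(
        sample_ids=[f"s{i}" for i in range(n)],
        p_svm=np.asarray(p_svm, float),
        p_rf=np.asarray(p_rf, float),
        p_ffnn=np.asarray(p_ffnn, float),
        classes=np.asarray(classes if classes is not None else np.arange(k)),
    )


class TestMakeSplits:
    def test_split_sizes_match_protocol(self):
        labels = np.resize(np.arange(4), 1000)
        s = om.make_splits(labels, SplitPlan(seed=0))
        assert len(s.test) == 100
        assert len(s.val) == 90
        assert len(s.train) == 810

    def test_holdout_partition_sizes_and_disjointness(self):
        labels = np.resize(np.arange(3), 1000)
        s = om.make_splits(labels, SplitPlan(holdout=True, seed=1))
        assert len(s.l0_train) == 486
        assert len(s.l1_train) == 324
        assert set(s.l0_train).isdisjoint(s.l1_train)
        assert set(s.l0_train) | set(s.l1_train) == set(s.train)
        assert set(s.train) | set(s.val) | set(s.test) == set(range(1000))

    def test_stratification_within_one_sample(self):
        rng = np.random.default_rng(2)
        labels = rng.choice([0, 1, 2], size=600, p=[0.5, 0.3, 0.2])
        s = om.make_splits(labels, SplitPlan(seed=2))
        global_props = np.bincount(labels) / len(labels)
        for idx in (s.test, s.val, s.train):
            counts = np.bincount(labels[idx], minlength=3)
            expected = global_props * len(idx)
            assert np.all(np.abs(counts - expected) <= 1.0 + 1e-9)

    def test_tiny_class_raises_with_name(self):
        labels = np.array([0] * 50 + [1] * 2)
        with pytest.raises(ValueError, match="class 1"):
            om.make_splits(labels, SplitPlan())


class TestTrainL0:
    @pytest.mark.parametrize("kind", ["SVM", "RF", "FFNN"])
    def test_separable_data_high_accuracy_and_valid_probs(self, kind):
        X, y = _separable(seed=3)
        clf = om.train_l0(X, y, kind, seed=0, cv_folds=3, cv_repeats=1,
                          param_grid=LIGHT_GRIDS[kind])
        assert (clf.predict(X) == y).mean() > 0.95
        proba = clf.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert proba.min() >= 0.0

    def test_hyperparameter_choice_is_deterministic(self):
        X, y = _separable(n=120, seed=4)
        grid = {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01]}
        a = om.train_l0(X, y, "SVM", seed=5, cv_folds=3, cv_repeats=2, param_grid=grid)
        b = om.train_l0(X, y, "SVM", seed=5, cv_folds=3, cv_repeats=2, param_grid=grid)
        assert a.best_params == b.best_params

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError, match="single class"):
            om.train_l0(X, np.zeros(20, dtype=int), "RF")


class TestFusedPredict:
    def test_corner_weight_reproduces_l0(self):
        rng = np.random.default_rng(6)
        raw = rng.random((10, 3))
        p = raw / raw.sum(axis=1, keepdims=True)
        other = np.full((10, 3), 1 / 3)
        probs = _stacked(p, other, other)
        fused, labels = om.fused_predict(probs, FusionWeights(1.0, 0.0, 0.0))
        np.testing.assert_array_equal(fused, p)
        np.testing.assert_array_equal(labels, p.argmax(axis=1))

    def test_worked_example(self):
        probs = _stacked(
            [[0.6, 0.4]], [[0.2, 0.8]], [[0.5, 0.5]], classes=np.array([1, 2])
        )
        fused, labels = om.fused_predict(probs, FusionWeights(0.5, 0.3, 0.2))
        np.testing.assert_allclose(fused, [[0.46, 0.54]], atol=1e-12)
        assert labels[0] == 2

    def test_rows_remain_stochastic(self):
        rng = np.random.default_rng(7)
        mats = []
        for _ in range(3):
            raw = rng.random((20, 4))
            mats.append(raw / raw.sum(axis=1, keepdims=True))
        probs = _stacked(*mats)
        fused, _ = om.fused_predict(probs, FusionWeights(0.17, 0.33, 0.5))
        np.testing.assert_allclose(fused.sum(axis=1), 1.0, atol=1e-12)
        assert fused.min() >= 0.0

    def test_argmax_tie_goes_to_lowest_class(self):
        probs = _stacked([[0.5, 0.5]], [[0.5, 0.5]], [[0.5, 0.5]],
                         classes=np.array([3, 7]))
        _, labels = om.fused_predict(probs, FusionWeights(1 / 5 * 0 + 0.2, 0.3, 0.5))
        assert labels[0] == 3

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            FusionWeights(0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            FusionWeights(0.333, 0.333, 0.334)  # off the hundredths grid
        with pytest.raises(ValueError):
            FusionWeights(-0.1, 0.6, 0.5)


class TestLinearFusionSearch:
    def test_grid_has_5151_triples_summing_to_one(self):
        grid = om.weight_grid(0.01)
        assert grid.shape == (5151, 3)
        np.testing.assert_allclose(grid.sum(axis=1), 1.0, atol=1e-12)
        assert (grid >= 0).all()
        # ascending lexicographic order
        assert tuple(grid[0]) == (0.0, 0.0, 1.0)
        assert tuple(grid[-1]) == (1.0, 0.0, 0.0)

    def test_selected_at_least_as_good_as_corners(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 3, size=60)
        mats = []
        for noise in (0.3, 0.6, 1.0):
            raw = np.eye(3)[y] + noise * rng.random((60, 3))
            mats.append(raw / raw.sum(axis=1, keepdims=True))
        probs = _stacked(*mats)
        w, acc = om.linear_fusion_search(probs, y)
        for corner in (FusionWeights(1, 0, 0), FusionWeights(0, 1, 0), FusionWeights(0, 0, 1)):
            _, labels = om.fused_predict(probs, corner)
            assert acc >= (labels == y).mean()

    def test_perfect_classifier_gets_all_the_mass(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, size=80)
        perfect = np.eye(2)[y] * 0.98 + 0.01
        noise = rng.random((80, 2))
        noise = noise / noise.sum(axis=1, keepdims=True)
        probs = _stacked(noise, perfect, noise[::-1])
        w, acc = om.linear_fusion_search(probs, y)
        assert acc == 1.0
        _, labels = om.fused_predict(probs, w)
        assert (labels == y).all()


class TestNonlinearStacker:
    def test_input_dimension_is_three_k(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 4, size=100)
        raw = np.eye(4)[y] + 0.2 * rng.random((100, 4))
        p = raw / raw.sum(axis=1, keepdims=True)
        probs = _stacked(p, p, p)
        assert probs.stack().shape == (100, 12)
        st = om.train_nonlinear_stacker(probs, y, kind="LR", seed=0)
        assert st.model.coef_.shape[1] == 12
        assert (st.predict(probs) == y).mean() > 0.95

    def test_unknown_kind_rejected(self):
        probs = _stacked([[1.0, 0.0]], [[1.0, 0.0]], [[1.0, 0.0]])
        with pytest.raises(ValueError):
            om.train_nonlinear_stacker(probs, np.array([0, 1])[:1], kind="GBM")


class TestFeatureLevelFuse:
    def test_widths_add(self):
        idx = [f"s{i}" for i in range(4)]
        f3 = pd.DataFrame(np.ones((4, 5)), index=idx,
                          columns=[f"p{j}" for j in range(5)])
        f4 = pd.DataFrame(np.zeros((4, 3)), index=idx,
                          columns=[f"q{j}" for j in range(3)])
        fused = om.feature_level_fuse({"F3": f3, "F4": f4}, "F3", "F4")
        assert fused.shape == (4, 8)

    def test_sample_mismatch_is_error(self):
        f3 = pd.DataFrame(np.ones((3, 2)), index=["a", "b", "c"])
        f4 = pd.DataFrame(np.ones((3, 2)), index=["a", "b", "d"])
        with pytest.raises(ValueError, match="sample"):
            om.feature_level_fuse({"F3": f3, "F4": f4}, "F3", "F4")

    def test_self_fusion_rejected(self):
        f3 = pd.DataFrame(np.ones((2, 2)))
        with pytest.raises(ValueError, match="itself"):
            om.feature_level_fuse({"F3": f3}, "F3", "F3")
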