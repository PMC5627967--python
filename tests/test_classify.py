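"""Windowing arithmetic and the online classification protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fabricsense.apparatus import ApparatusConfig, MotionSignal
from fabricsense.classify import (ClassifierSpec, WindowSpec,
                                  accuracy_summary, online_run,
                                  segment_windows, tune_hyperparameters,
                                  window_sweep)
from fabricsense.dynamics import Dataset, Trial


def _toy_dataset(class_means, n_trials=4, P=240, noise=0.05, seed=0,
                 rate=600.0):
    """Synthetic two-class dataset of constant-mean noisy signals."""
    rng = np.random.default_rng(seed)
    cfg = ApparatusConfig(duration=P / rate)
    ds = Dataset(master_seed=seed)
    for label, mean in class_means.items():
        for i in range(n_trials):
            samples = mean + rng.normal(scale=noise, size=P)
            sig = MotionSignal("S", rate, samples)
            ds.trials.append(Trial(label=label, signals={"S": sig},
                                   config=cfg, seed=i))
    return ds


class TestWindowing:
    def test_enumeration_small(self):
        w = segment_windows(np.array([1.0, 2.0, 3.0, 4.0]), WindowSpec(2))
        np.testing.assert_array_equal(w, [[1, 2], [2, 3], [3, 4]])

    def test_study_window_count(self):
        # 250 ms at 600 Hz over a 6000-sample record: 79 windows
        spec = WindowSpec(150)
        assert spec.stride == 75
        assert spec.count(6000) == 79
        assert segment_windows(np.zeros(6000), spec).shape == (79, 150)

    def test_full_signal_single_window(self):
        assert WindowSpec(6000).count(6000) == 1

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            segment_windows(np.zeros(10), WindowSpec(12))

    def test_odd_size_rounded_down_with_warning(self):
        with pytest.warns(UserWarning, match="rounded"):
            spec = WindowSpec(9)
        assert spec.n == 8

    def test_millisecond_grid_conversion(self):
        with pytest.warns(UserWarning):
            assert WindowSpec.from_ms(15, 600).n == 8
        assert WindowSpec.from_ms(1500, 600).n == 900
        assert WindowSpec.from_ms(250, 600).n == 150

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(2, 40), st.integers(1, 12))
    def test_contents_match_direct_enumeration(self, P, half_n):
        n = 2 * half_n
        if n > P:
            return
        x = np.arange(P, dtype=float)
        got = segment_windows(x, WindowSpec(n))
        offsets = range(0, P - n + 1, n // 2)
        expected = [x[o:o + n] for o in offsets]
        assert got.shape == (len(expected), n)
        np.testing.assert_array_equal(got, expected)

    def test_even_windows_reconstruct_signal_prefix(self):
        x = np.arange(100, dtype=float)
        w = segment_windows(x, WindowSpec(10))
        recon = np.concatenate([w[i] for i in range(0, len(w), 2)])
        np.testing.assert_array_equal(recon, x[:len(recon)])


class TestTuning:
    def _separable(self, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(-2, 0.1, size=(12, 4)),
                       rng.normal(2, 0.1, size=(12, 4))])
        y = np.array(["a"] * 12 + ["b"] * 12)
        return X, y

    def test_separable_toy_reaches_perfect_cv(self):
        X, y = self._separable()
        spec = tune_hyperparameters(X, y, ClassifierSpec(kernel="linear"))
        clf = spec.build().fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_deterministic_given_fold_seed(self):
        X, y = self._separable(3)
        a = tune_hyperparameters(X, y, seed=11)
        b = tune_hyperparameters(X, y, seed=11)
        assert a == b

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            tune_hyperparameters(np.zeros((6, 3)), np.array(["a"] * 6))

    def test_uninformative_data_falls_back_to_neutral_spec(self):
        # identical feature vectors for both classes: nothing can beat the
        # majority baseline, so the tuner must return the neutral setting
        X = np.ones((20, 6))
        y = np.array(["a", "b"] * 10)
        spec = tune_hyperparameters(X, y, ClassifierSpec(kernel="gaussian"))
        assert spec.box_constraint == 1.0
        assert spec.kernel_scale == 1.0  # degenerate median falls back to 1


class TestOnlineRun:
    def test_separable_classes_perfect_at_every_window(self):
        ds = _toy_dataset({"up": 1.0, "down": -1.0}, n_trials=4, noise=0.05)
        res = online_run(ds, "S", WindowSpec(60), seed=0)
        assert res.mean_accuracy == 1.0
        assert np.all(res.per_window_accuracy == 1.0)
        summary = accuracy_summary(res)
        assert summary["mean"] == 1.0 and summary["sd"] == 0.0

    def test_identical_generators_near_chance(self):
        ds = _toy_dataset({"a": 0.0, "b": 0.0}, n_trials=8, P=400, noise=1.0,
                          seed=5)
        res = online_run(ds, "S", WindowSpec(40), seed=0)
        n_pred = res.predictions.size
        se = 0.5 / np.sqrt(n_pred)
        assert abs(res.mean_accuracy - 0.5) < 3 * se + 0.05

    def test_missing_sensor_raises_lookup_error(self):
        ds = _toy_dataset({"a": 1.0, "b": -1.0})
        with pytest.raises(KeyError, match="absent"):
            online_run(ds, "nope", WindowSpec(60))

    def test_repeats_cover_every_trial_once(self):
        ds = _toy_dataset({"a": 1.0, "b": -1.0}, n_trials=3)
        res = online_run(ds, "S", WindowSpec(120), seed=0)
        assert len(res.true_labels) == 6
        assert sorted(res.true_labels) == ["a"] * 3 + ["b"] * 3

    def test_trial_order_within_class_irrelevant(self):
        ds = _toy_dataset({"a": 0.4, "b": -0.4}, n_trials=4, seed=9)
        res1 = online_run(ds, "S", WindowSpec(80), seed=7)
        ds.trials[0:4] = ds.trials[0:4][::-1]
        res2 = online_run(ds, "S", WindowSpec(80), seed=7)
        assert res1.mean_accuracy == pytest.approx(res2.mean_accuracy)

    def test_linear_kernel_scale_equivariance(self):
        ds = _toy_dataset({"a": 0.3, "b": -0.3}, n_trials=4, noise=0.3,
                          seed=2)
        lin = ClassifierSpec(kernel="linear", box_constraint=1.0)
        res1 = online_run(ds, "S", WindowSpec(60), lin, tune=False)
        for t in ds.trials:
            t.signals["S"].samples = t.signals["S"].samples * 10.0
        lin2 = ClassifierSpec(kernel="linear", box_constraint=1.0 / 100.0)
        res2 = online_run(ds, "S", WindowSpec(60), lin2, tune=False)
        np.testing.assert_array_equal(res1.predictions, res2.predictions)


class TestAccuracySummary:
    def test_hand_computed_mean_and_sd(self):
        preds = np.array([["a", "a", "b", "b"],
                          ["a", "b", "b", "b"]], dtype=object)
        res_true = ["a", "b"]
        from fabricsense.classify import OnlineRunResult
        res = OnlineRunResult("S", WindowSpec(2), ("a", "b"), res_true, preds)
        # repeat accuracies: 0.5 and 0.75
        assert res.mean_accuracy == pytest.approx(0.625)
        assert res.sd_accuracy == pytest.approx(np.std([0.5, 0.75], ddof=1))
        np.testing.assert_allclose(res.per_window_accuracy,
                                   [0.5, 1.0, 0.5, 0.5])

    def test_half_correct_every_repeat(self):
        preds = np.array([["a", "b"], ["a", "b"]], dtype=object)
        from fabricsense.classify import OnlineRunResult
        res = OnlineRunResult("S", WindowSpec(2), ("a", "b"), ["a", "a"],
                              preds)
        assert res.mean_accuracy == 0.5 and res.sd_accuracy == 0.0


def test_window_sweep_table_shape():
    ds = _toy_dataset({"a": 1.0, "b": -1.0}, n_trials=3, P=240)
    table = window_sweep(ds, ["S"], [100, 200], seed=0)
    assert list(table.sensor.unique()) == ["S"]
    assert len(table) == 2
    assert table.mean_accuracy.between(0, 1).all()
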