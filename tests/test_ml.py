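import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from twomst.errors import DataError, GroupingError, LeakageError, SchemaError
from twomst.ml import (
    FeatureWindowSpec,
    SplitPlan,
    calibrate_isotonic,
    extract_features,
    fit_tail_correction,
    predict_peaks,
    train_stacked,
)
from twomst.peaks import cycle_set_from_peaks
from twomst.preprocess import TriaxialSignal, UniformSignal


def _tri(x, y=None, z=None, rate=60.0):
    x = np.asarray(x, dtype=float)
    y = x * 0.5 if y is None else np.asarray(y, dtype=float)
    z = x * 0.2 if z is None else np.asarray(z, dtype=float)
    mk = lambda v: UniformSignal(rate, 0.0, v)
    return TriaxialSignal(mk(x), mk(y), mk(z))


class TestExtractFeatures:
    def test_constant_window_features(self):
        x = np.full(600, 10.0)
        anchors = cycle_set_from_peaks([3.0, 5.0], [10.0, 10.0])
        df = extract_features(_tri(x, x, x), anchors, prefiltered=True)
        row = df.iloc[0]
        assert row["x_mean"] == 10.0
        assert row["x_sd"] == 0.0
        assert row["x_rms"] == 10.0
        assert row["x_zero_crossings"] == 0
        for p in (10, 25, 50, 75, 90):
            assert row[f"x_p{p}"] == 10.0

    def test_full_period_sine_rms(self):
        rate = 60.0
        # ±7 samples = 15-sample window covering one period at f = rate/15
        n = 15
        t = np.arange(600) / rate
        f = rate / n
        x = 100.0 * np.sin(2 * np.pi * f * t)
        anchor_t = 5.0
        anchors = cycle_set_from_peaks([anchor_t], [100.0])
        df = extract_features(_tri(x, x, x), anchors, prefiltered=True)
        assert df.iloc[0]["x_rms"] == pytest.approx(100.0 / np.sqrt(2), rel=0.02)

    def test_edge_anchor_dropped_and_counted(self):
        x = np.ones(600)
        anchors = cycle_set_from_peaks([0.05, 5.0], [1.0, 1.0])
        df = extract_features(_tri(x), anchors, prefiltered=True)
        assert len(df) == 1
        assert df.attrs["n_dropped"] == 1

    def test_no_anchors_rejected(self):
        with pytest.raises(DataError):
            extract_features(_tri(np.ones(600)), cycle_set_from_peaks([], []))

    def test_energy_definition(self):
        x = np.full(600, 2.0)
        anchors = cycle_set_from_peaks([5.0], [2.0])
        df = extract_features(_tri(x, x, x), anchors, prefiltered=True)
        assert df.iloc[0]["x_energy"] == pytest.approx(15 * 4.0 / 60.0)


def _feature_table(n_subjects=6, cycles_per_subject=60, seed=0, compress=0.0):
    """Synthetic feature rows whose x parabolic peak is (a distortion of)
    the target, for learnability tests."""
    rng = np.random.default_rng(seed)
    rows = []
    from twomst.ml import feature_columns_for

    cols = feature_columns_for()
    for s in range(n_subjects):
        for c in range(cycles_per_subject):
            target = rng.uniform(150, 450)
            observed = target / (1 + compress * target / 300.0)
            row = {col: rng.normal() for col in cols}
            row.update(
                {
                    "subject": f"s{s}",
                    "cycle": c,
                    "peak_time": c * 0.9,
                    "duration": 0.9,
                    "x_parabolic_peak": observed,
                    "target": target,
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)


class TestSplitPlan:
    def test_partition_is_deterministic_and_roughly_70_30(self):
        plan = SplitPlan(seed=5)
        df = _feature_table(n_subjects=8, cycles_per_subject=100)
        train, test = plan.split(df)
        train2, _ = plan.split(df)
        assert list(train["cycle"]) == list(train2["cycle"])
        frac = len(train) / len(df)
        assert 0.65 < frac < 0.75

    def test_different_seed_changes_partition(self):
        df = _feature_table(n_subjects=4)
        a, _ = SplitPlan(seed=1).split(df)
        b, _ = SplitPlan(seed=2).split(df)
        assert set(map(tuple, a[["subject", "cycle"]].values)) != set(
            map(tuple, b[["subject", "cycle"]].values)
        )


class TestTrainStacked:
    def test_identity_mapping_is_learnable(self):
        plan = SplitPlan(seed=3)
        df = _feature_table(seed=3)
        train, test = plan.split(df)
        model = train_stacked(train, plan)
        pred = model.predict(test)
        rmse = np.sqrt(np.mean((pred - test["target"]) ** 2))
        assert rmse < 1.0

    def test_single_subject_rejected(self):
        plan = SplitPlan(seed=3)
        df = _feature_table(n_subjects=1, seed=3)
        train, _ = plan.split(df)
        with pytest.raises(GroupingError):
            train_stacked(train, plan)

    def test_test_partition_row_rejected(self):
        plan = SplitPlan(seed=3)
        df = _feature_table(seed=3)
        with pytest.raises(LeakageError):
            train_stacked(df, plan)  # full table includes test rows

    def test_stacked_corrects_compression_better_than_linear(self):
        """With a saturating phone channel, the stacked model's held-out mean
        bias is smaller in magnitude than a purely linear fit's."""
        from sklearn.linear_model import LinearRegression

        plan = SplitPlan(seed=4)
        df = _feature_table(seed=4, compress=0.6)
        train, test = plan.split(df)
        model = train_stacked(train, plan)
        stacked_bias = np.mean(model.predict(test) - test["target"])
        cols = model.feature_columns
        lin = LinearRegression().fit(train[cols], train["target"])
        linear_bias = np.mean(lin.predict(test[cols]) - test["target"])
        assert abs(stacked_bias) < abs(linear_bias)

    def test_prediction_is_deterministic(self):
        plan = SplitPlan(seed=3)
        df = _feature_table(seed=3)
        train, test = plan.split(df)
        model = train_stacked(train, plan)
        assert np.array_equal(model.predict(test), model.predict(test))

    def test_schema_mismatch_rejected(self):
        plan = SplitPlan(seed=3)
        df = _feature_table(seed=3)
        train, test = plan.split(df)
        model = train_stacked(train, plan)
        with pytest.raises(SchemaError):
            model.predict(test.drop(columns=["x_rms"]))


class TestIsotonic:
    def test_identity_at_knots_when_already_calibrated(self, rng):
        y = np.sort(rng.uniform(100, 400, size=50))
        iso = calibrate_isotonic(y, y)
        assert np.allclose(iso.predict(y), y, atol=1e-9)

    def test_recovers_halved_scale(self, rng):
        targets = np.sort(rng.uniform(100, 400, size=200))
        predictions = 2.0 * targets
        iso = calibrate_isotonic(predictions, targets)
        assert np.allclose(iso.predict(predictions), targets, rtol=0.01)

    def test_clips_below_training_range(self, rng):
        targets = np.sort(rng.uniform(100, 400, size=50))
        iso = calibrate_isotonic(targets, targets)
        assert iso.predict([0.0])[0] == pytest.approx(iso.predict([targets.min()])[0])

    @given(st.lists(st.floats(0, 500), min_size=2, max_size=30))
    def test_monotone_on_arbitrary_queries(self, queries):
        rng = np.random.default_rng(0)
        preds = np.sort(rng.uniform(0, 500, size=100))
        iso = calibrate_isotonic(preds, preds + rng.normal(0, 20, 100))
        out = iso.predict(np.sort(np.asarray(queries)))
        assert np.all(np.diff(out) >= -1e-9)


class TestTailCorrection:
    def test_unbiased_tail_near_identity(self, rng):
        calibrated = rng.uniform(100, 400, size=2000)
        targets = calibrated + rng.normal(0, 1.0, size=2000)
        tail = fit_tail_correction(calibrated, targets)
        assert tail.slope == pytest.approx(1.0, abs=0.05)
        assert tail.intercept == pytest.approx(0.0, abs=20.0)

    def test_compressed_tail_slope_recovered(self):
        # monotone compression of the upper range: c = 300 + 0.9·(t − 300)
        targets = np.linspace(100, 400, 500)
        calibrated = np.where(targets > 300, 300 + 0.9 * (targets - 300), targets)
        tail = fit_tail_correction(calibrated, targets)
        assert tail.enabled
        assert tail.slope == pytest.approx(1 / 0.9, rel=0.05)

    def test_too_few_pairs_disables_correction(self, rng):
        tail = fit_tail_correction(rng.uniform(size=10), rng.uniform(size=10))
        assert not tail.enabled
        x = rng.uniform(size=5)
        assert np.array_equal(tail.apply(x), x)

    def test_applies_only_above_threshold(self):
        from twomst.ml import TailCorrection

        tail = TailCorrection(threshold=10.0, slope=2.0, intercept=0.0)
        out = tail.apply(np.array([5.0, 20.0]))
        assert out.tolist() == [5.0, 40.0]


class TestPredictPeaks:
    def test_counts_and_durations_pass_through(self):
        plan = SplitPlan(seed=3)
        df = _feature_table(seed=3)
        train, test = plan.split(df)
        model = train_stacked(train, plan)
        subj = test[test["subject"] == "s1"].sort_values("peak_time")
        cycles = predict_peaks(model, subj)
        assert len(cycles) == len(subj)
        assert np.allclose(
            cycles.durations, np.diff(subj["peak_time"].to_numpy()), atol=1e-12
        )
        assert np.all(cycles.omega_peaks > 0)
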