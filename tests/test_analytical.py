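import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from twomst.analytical import (
    CutoffMap,
    WindowingSpec,
    adaptive_filter,
    cutoff_map_from_table,
    dominant_frequency,
    fit_cutoff_map,
    optimal_cutoff_table,
    run_analytical,
    synchronize,
)
from twomst.errors import (
    InsufficientDataError,
    LeakageError,
    UndefinedFrequencyError,
)
from twomst.mocap import FilterSpec, butterworth_lowpass
from twomst.peaks import PeakDetectorSpec
from twomst.preprocess import TriaxialSignal, UniformSignal


def _signal(values, rate=60.0, start=0.0):
    return UniformSignal(rate, start, np.asarray(values, dtype=float))


def _tri(x, rate=60.0):
    x = np.asarray(x, dtype=float)
    return TriaxialSignal(
        _signal(x, rate), _signal(np.zeros_like(x), rate), _signal(np.zeros_like(x), rate)
    )


class TestDominantFrequency:
    def test_on_bin_sine(self):
        t = np.arange(600) / 60.0  # 10 s → 0.1 Hz bins
        assert dominant_frequency(np.sin(2 * np.pi * 1.2 * t), 60.0) == pytest.approx(1.2)

    def test_larger_amplitude_wins(self):
        t = np.arange(600) / 60.0
        seg = 2 * np.sin(2 * np.pi * 1.0 * t) + 1 * np.sin(2 * np.pi * 3.0 * t)
        assert dominant_frequency(seg, 60.0) == pytest.approx(1.0)

    def test_constant_segment_rejected(self):
        with pytest.raises(UndefinedFrequencyError):
            dominant_frequency(np.full(600, 7.0), 60.0)

    def test_mean_offset_does_not_create_dc_peak(self):
        t = np.arange(600) / 60.0
        seg = 1000.0 + 0.5 * np.sin(2 * np.pi * 2.0 * t)
        assert dominant_frequency(seg, 60.0) == pytest.approx(2.0)


class TestCutoffMap:
    def test_identical_signals_select_high_flat_region(self):
        t = np.arange(60 * 30) / 60.0  # 30 s → 3 windows
        sig = _signal(100 * np.sin(2 * np.pi * 1.2 * t))
        table = optimal_cutoff_table(sig, sig, WindowingSpec())
        assert len(table) == 3
        # with phone == ref, less attenuation is always at least as good:
        # every selected cutoff sits in the flat upper region of the grid
        assert all(c >= 6.0 for _, c in table)

    def test_noisy_cadence_sweep_yields_positive_slope(self, rng):
        table = []
        for cadence in (0.8, 1.0, 1.2, 1.4):
            t = np.arange(60 * 30) / 60.0
            clean = 300 * np.sin(2 * np.pi * cadence * t)
            noisy = clean + 40 * np.sin(2 * np.pi * 15.0 * t) + rng.normal(0, 5, t.size)
            table.extend(
                optimal_cutoff_table(_signal(noisy), _signal(clean), WindowingSpec())
            )
        cmap = cutoff_map_from_table(table)
        assert cmap.slope > 0

    def test_single_window_insufficient(self):
        t = np.arange(600) / 60.0
        sig = _signal(np.sin(2 * np.pi * t))
        with pytest.raises(InsufficientDataError):
            fit_cutoff_map(sig, sig, WindowingSpec())

    def test_degenerate_single_frequency_gives_constant_map(self):
        table = [(1.0, 4.0), (1.0, 5.0), (1.0, 4.5)]
        cmap = cutoff_map_from_table(table)
        assert cmap.slope == 0.0
        assert cmap.intercept == 4.5

    @given(st.floats(-100, 100, allow_nan=False))
    def test_cutoff_always_clamped(self, fd):
        cmap = CutoffMap(slope=3.0, intercept=1.0)
        assert 1.0 <= cmap.cutoff_for(fd) <= 12.0


class TestAdaptiveFilter:
    def test_constant_map_matches_global_filter(self, rng):
        t = np.arange(60 * 120) / 60.0
        values = 300 * np.sin(2 * np.pi * 1.2 * t) + rng.normal(0, 10, t.size)
        sig = _signal(values)
        piecewise = adaptive_filter(sig, CutoffMap(slope=0.0, intercept=6.0))
        global_ = butterworth_lowpass(sig, FilterSpec(cutoff_hz=6.0))
        rms_diff = np.sqrt(np.mean((piecewise.values - global_.values) ** 2))
        assert rms_diff < 0.01 * np.sqrt(np.mean(values**2))

    def test_dc_component_passes(self):
        t = np.arange(60 * 30) / 60.0
        values = 50.0 + 10 * np.sin(2 * np.pi * 1.0 * t)
        out = adaptive_filter(_signal(values), CutoffMap(slope=0.0, intercept=6.0))
        assert np.mean(out.values) == pytest.approx(50.0, abs=0.5)

    def test_high_frequency_noise_suppressed(self, rng):
        t = np.arange(60 * 60) / 60.0
        clean = 300 * np.sin(2 * np.pi * 1.0 * t)
        noise = 50 * np.sin(2 * np.pi * 20.0 * t + rng.uniform(0, np.pi))
        out = adaptive_filter(
            _signal(clean + noise), CutoffMap(slope=0.0, intercept=5.0)
        )
        resid_rms = np.sqrt(np.mean((out.values - clean) ** 2))
        assert resid_rms < 0.10 * np.sqrt(np.mean(noise**2))

    def test_output_length_equals_input_length(self, rng):
        n = 60 * 47 + 13  # forces a trailing partial window
        sig = _signal(100 * np.sin(2 * np.pi * np.arange(n) / 60.0) + rng.normal(0, 5, n))
        out = adaptive_filter(sig, CutoffMap(slope=2.0, intercept=2.0))
        assert len(out) == n


class TestSynchronize:
    def test_identical_series(self):
        t = np.arange(60 * 20) / 60.0
        sig = _signal(np.sin(2 * np.pi * 1.1 * t) * (1 + 0.2 * np.sin(0.1 * t)))
        res = synchronize(sig, sig)
        assert res.lag_s == 0.0
        assert res.peak_correlation == pytest.approx(1.0)
        assert not res.low_confidence

    def test_constructed_quarter_second_delay(self, rng):
        rate = 60.0
        t = np.arange(int(rate * 40)) / rate
        envelope = 1 + 0.3 * np.sin(2 * np.pi * 0.05 * t)
        ref_values = envelope * np.sin(2 * np.pi * 1.1 * t) + rng.normal(0, 0.05, t.size)
        delay = 0.25
        phone_values = np.interp(t - delay, t, ref_values, left=0.0)
        res = synchronize(_signal(phone_values), _signal(ref_values))
        assert abs(res.lag_s - delay) <= 1.0 / rate + 1e-9

    def test_unrelated_noise_flagged_low_confidence(self, rng):
        a = _signal(rng.normal(size=60 * 20))
        b = _signal(rng.normal(size=60 * 20))
        res = synchronize(a, b)
        assert res.low_confidence

    def test_apply_shift_aligns_events(self):
        values = np.zeros(1200)
        values[300] = 1.0
        shifted = np.zeros(1200)
        shifted[330] = 1.0  # delayed by 30 samples
        res = synchronize(_signal(shifted), _signal(values), max_lag_s=1.0)
        aligned = res.apply(_signal(shifted))
        assert np.argmax(aligned.values) == 300


class TestRunAnalytical:
    def test_empty_signal_yields_empty_cycles(self):
        tri = _tri(np.array([]))
        out = run_analytical(tri, CutoffMap(slope=0.0, intercept=6.0))
        assert len(out) == 0

    def test_leakage_check_rejects_overlapping_cycles(self):
        cmap = CutoffMap(slope=0.0, intercept=6.0, fit_cycle_ids=frozenset({("s0", 3)}))
        tri = _tri(np.sin(2 * np.pi * np.arange(60 * 30) / 60.0))
        with pytest.raises(LeakageError):
            run_analytical(tri, cmap, eval_cycle_ids=frozenset({("s0", 3), ("s0", 9)}))

    def test_disjoint_cycles_accepted(self):
        cmap = CutoffMap(slope=0.0, intercept=6.0, fit_cycle_ids=frozenset({("s0", 3)}))
        t = np.arange(60 * 30) / 60.0
        tri = _tri(300 * np.sin(2 * np.pi * t))
        out = run_analytical(
            tri, cmap, PeakDetectorSpec(), eval_cycle_ids=frozenset({("s1", 3)})
        )
        assert len(out) == 30
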