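"""Analytical approach (AA): adaptive Butterworth filtering of the phone's
x-axis with a cutoff that tracks the signal's dominant cycle frequency.

The signal is processed in 10-s windows advancing by 9 s (1-s overlap).  Per
window, the dominant cycle frequency f_d is the maximum-magnitude bin of the
mean-centered real FFT (0 Hz excluded).  During calibration, each window is
filtered at every cutoff on a fine 1–12 Hz grid and compared to the
motion-capture reference by RMS error; the argmin cutoff c* is the window's
optimum.  A line c = a·f_d + b fitted over (f_d, c*) pairs is then the cutoff
map, applied window-by-window at deployment with the output clamped to
[1, 12] Hz and overlapping filtered segments merged by linear crossfade.
Phone and reference are time-synchronized by normalized cross-correlation
before any RMS comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import (
    InsufficientDataError,
    LeakageError,
    UndefinedFrequencyError,
)
from .peaks import CycleSet, PeakDetectorSpec, detect_cycle_peaks
from .preprocess import TriaxialSignal, UniformSignal


@dataclass(frozen=True)
class WindowingSpec:
    window_s: float = 10.0
    overlap_s: float = 1.0
    cutoff_grid_hz: tuple = tuple(np.round(np.arange(1.0, 12.0 + 1e-9, 0.1), 10))

    def __post_init__(self):
        if not 0 < self.overlap_s < self.window_s:
            raise ValueError("need 0 < overlap < window length")

    @property
    def hop_s(self) -> float:
        return self.window_s - self.overlap_s


@dataclass
class CutoffMap:
    """Linear dominant-frequency → cutoff-frequency mapping, clamped to [1, 12] Hz."""

    slope: float
    intercept: float
    clamp: tuple[float, float] = (1.0, 12.0)
    n_windows: int = 0
    residual_rms: float = float("nan")
    fit_cycle_ids: frozenset = field(default_factory=frozenset)

    def cutoff_for(self, f_dominant: float) -> float:
        c = self.slope * f_dominant + self.intercept
        return float(min(max(c, self.clamp[0]), self.clamp[1]))


@dataclass
class SyncResult:
    """Inter-device lag estimate: positive lag = phone delayed w.r.t. reference."""

    lag_s: float
    peak_correlation: float
    shift_samples: int
    low_confidence: bool = False

    def apply(self, signal: UniformSignal) -> UniformSignal:
        """Shift the phone signal by −lag so its events align with the reference."""
        k = self.shift_samples
        v = signal.values
        if k > 0:
            out = v[k:]
        elif k < 0:
            out = np.concatenate([np.full(-k, v[0]), v])
        else:
            out = v
        return signal.replace(out)

    def apply_triaxial(self, signal: TriaxialSignal) -> TriaxialSignal:
        return signal.map_channels(self.apply)


def dominant_frequency(segment: np.ndarray, rate: float) -> float:
    """Frequency of the maximum-magnitude rFFT bin, 0 Hz excluded.

    The segment is mean-centered first; ties break toward the lower
    frequency.  A constant segment has no spectral content and raises.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < rate:
        raise InsufficientDataError("dominant_frequency needs >= 1 s of samples")
    centered = segment - segment.mean()
    if np.allclose(centered, 0.0):
        raise UndefinedFrequencyError("constant segment has no dominant frequency")
    mag = np.abs(np.fft.rfft(centered))
    freqs = np.fft.rfftfreq(segment.size, d=1.0 / rate)
    k = 1 + int(np.argmax(mag[1:]))  # argmax returns the first (lowest-f) maximum
    return float(freqs[k])


@lru_cache(maxsize=512)
def _design_lowpass(cutoff_hz: float, rate: float):
    return butter(2, cutoff_hz, btype="low", fs=rate, output="sos")


def _lowpass_segment(seg: np.ndarray, cutoff_hz: float, rate: float) -> np.ndarray:
    sos = _design_lowpass(float(cutoff_hz), float(rate))
    default_pad = 3 * (2 * sos.shape[0] + 1)
    return sosfiltfilt(sos, seg, padlen=min(default_pad, seg.size - 1))


def _window_starts(n: int, win: int, hop: int) -> list[int]:
    if n < win:
        raise InsufficientDataError("signal shorter than one analysis window")
    starts = list(range(0, n - win + 1, hop))
    return starts


def optimal_cutoff_table(
    phone: UniformSignal,
    ref: UniformSignal,
    spec: WindowingSpec = WindowingSpec(),
    window_mask: np.ndarray | None = None,
) -> list[tuple[float, float]]:
    """Per-window (dominant frequency, RMS-optimal cutoff) pairs.

    For every analysis window: compute f_d on the phone, filter the phone
    window at each grid cutoff, record the cutoff minimizing RMS error
    against the reference window.  Grid ties break toward the lower cutoff.
    ``window_mask`` restricts which windows contribute (train/test
    discipline).
    """
    rate = phone.rate
    n = min(len(phone), len(ref))
    win = int(round(spec.window_s * rate))
    hop = int(round(spec.hop_s * rate))
    starts = _window_starts(n, win, hop)
    if window_mask is not None and len(window_mask) != len(starts):
        raise ValueError("window_mask length must equal the number of windows")
    table = []
    for w, s in enumerate(starts):
        if window_mask is not None and not window_mask[w]:
            continue
        pseg = phone.values[s : s + win]
        rseg = ref.values[s : s + win]
        fd = dominant_frequency(pseg, rate)
        errors = np.array(
            [
                np.sqrt(np.mean((_lowpass_segment(pseg, c, rate) - rseg) ** 2))
                for c in spec.cutoff_grid_hz
            ]
        )
        best = int(np.argmin(errors))  # first minimum = lowest cutoff on ties
        table.append((fd, float(spec.cutoff_grid_hz[best])))
    return table


def cutoff_map_from_table(
    table: list[tuple[float, float]],
    clamp: tuple[float, float] = (1.0, 12.0),
    fit_cycle_ids: frozenset = frozenset(),
) -> CutoffMap:
    """Least-squares line through (f_d, c*) pairs; degenerates to a constant
    map (slope 0, intercept = median c*) when every window shares one f_d."""
    if len(table) < 2:
        raise InsufficientDataError("cutoff-map fitting needs >= 2 windows")
    fd = np.array([p[0] for p in table])
    copt = np.array([p[1] for p in table])
    if np.allclose(fd, fd[0]):
        return CutoffMap(
            slope=0.0,
            intercept=float(np.median(copt)),
            clamp=clamp,
            n_windows=len(table),
            residual_rms=float(np.sqrt(np.mean((copt - np.median(copt)) ** 2))),
            fit_cycle_ids=fit_cycle_ids,
        )
    slope, intercept = np.polyfit(fd, copt, 1)
    resid = copt - (slope * fd + intercept)
    return CutoffMap(
        slope=float(slope),
        intercept=float(intercept),
        clamp=clamp,
        n_windows=len(table),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        fit_cycle_ids=fit_cycle_ids,
    )


def fit_cutoff_map(
    phone: UniformSignal,
    ref: UniformSignal,
    spec: WindowingSpec = WindowingSpec(),
    window_mask: np.ndarray | None = None,
) -> CutoffMap:
    """Fit the dominant-frequency → cutoff map on one synchronized pair."""
    return cutoff_map_from_table(optimal_cutoff_table(phone, ref, spec, window_mask))


def adaptive_filter(
    phone: UniformSignal, cmap: CutoffMap, spec: WindowingSpec = WindowingSpec()
) -> UniformSignal:
    """Piecewise window-by-window filtering with linear crossfade merging.

    Each window is zero-lag low-passed at ``clamp(a·f_d + b)``.  The final
    window extends to the end of the signal; its trailing partial segment is
    filtered at the last full window's cutoff (short segments have too little
    frequency resolution for their own f_d).  Output length equals input
    length, and where neighboring windows produce identical samples in the
    1-s overlap the merge is exact.
    """
    v = phone.values
    rate = phone.rate
    win = int(round(spec.window_s * rate))
    hop = int(round(spec.hop_s * rate))
    ov = win - hop
    starts = _window_starts(v.size, win, hop)
    out = np.zeros_like(v)
    ramp = (np.arange(ov) + 0.5) / ov  # complementary up/down ramps sum to 1
    for k, s in enumerate(starts):
        last = k == len(starts) - 1
        e = v.size if last else s + win
        fd = dominant_frequency(v[s : s + win], rate)
        seg = _lowpass_segment(v[s:e], cmap.cutoff_for(fd), rate)
        w = np.ones(e - s)
        if k > 0:
            w[:ov] = ramp
        if not last:
            w[-ov:] = ramp[::-1]
        out[s:e] += w * seg
    return phone.replace(out, label="phone-AA")


def synchronize(
    phone: UniformSignal, ref: UniformSignal, max_lag_s: float = 2.0
) -> SyncResult:
    """Estimate the inter-device lag by normalized cross-correlation.

    Lag is phone relative to reference (positive = phone delayed); peak
    correlation below 0.2 flags the result as low confidence.
    """
    if phone.rate != ref.rate:
        raise ValueError("synchronize requires equal sampling rates")
    rate = phone.rate
    p = phone.values - phone.values.mean()
    r = ref.values - ref.values.mean()
    max_shift = int(round(max_lag_s * rate))
    clock_offset = phone.start_time - ref.start_time
    best_corr, best_k = -np.inf, 0
    for k in range(-max_shift, max_shift + 1):
        # lag k: phone[n] aligns with ref[n - k]
        if k >= 0:
            m = min(p.size - k, r.size)
            a, b = p[k : k + m], r[:m]
        else:
            a = p[: min(p.size, r.size + k)]
            b = r[-k : -k + a.size]
        if a.size < int(10 * rate):
            continue
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        corr = float(np.dot(a, b) / denom) if denom > 0 else 0.0
        if corr > best_corr:
            best_corr, best_k = corr, k
    if not np.isfinite(best_corr):
        raise InsufficientDataError("overlap after shifting is shorter than 10 s")
    lag = best_k / rate + clock_offset
    return SyncResult(
        lag_s=float(lag),
        peak_correlation=best_corr,
        shift_samples=best_k,
        low_confidence=best_corr < 0.2,
    )


def run_analytical(
    phone: TriaxialSignal,
    cmap: CutoffMap,
    detector: PeakDetectorSpec = PeakDetectorSpec(),
    sync: SyncResult | None = None,
    spec: WindowingSpec = WindowingSpec(),
    eval_cycle_ids: frozenset | None = None,
    test_duration: float = 120.0,
) -> CycleSet:
    """Full AA chain on the phone x-axis: align → adaptive filter → peaks.

    When ``eval_cycle_ids`` is given (train/test evaluation mode), the map's
    recorded training cycles must be disjoint from them, otherwise the
    reference signal used during map fitting overlapped the cycles now being
    scored and a ``LeakageError`` is raised.
    """
    if eval_cycle_ids is not None and cmap.fit_cycle_ids & frozenset(eval_cycle_ids):
        overlap = sorted(cmap.fit_cycle_ids & frozenset(eval_cycle_ids))[:5]
        raise LeakageError(f"cutoff map was fitted on evaluation cycles, e.g. {overlap}")
    x = phone.x
    if len(x) == 0:
        return CycleSet(cycles=[], source="phone-AA", test_duration=test_duration)
    if sync is not None:
        x = sync.apply(x)
    filtered = adaptive_filter(x, cmap, spec)
    return detect_cycle_peaks(
        filtered, detector, source="phone-AA", test_duration=test_duration
    )
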