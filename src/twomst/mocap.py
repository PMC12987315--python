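"""Motion-capture reference path: marker pair → thigh angle → angular velocity.

The two reflective markers (hip = greater trochanter, knee = lateral condyle)
define a 2D thigh segment in the sagittal plane.  The thigh angle is measured
from the downward vertical: 0° = thigh vertical (knee straight below the hip),
90° = thigh horizontal with the knee anterior.  The reference angular-velocity
series — the study's ground truth — is the first derivative of that angle
after zero-lag 2nd-order Butterworth smoothing at 6 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfilt, sosfiltfilt

from .errors import DataError, InsufficientDataError, ParameterError
from .io_formats import LONG_GAP_FRAMES, MarkerTrajectory
from .preprocess import UniformSignal


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth specification (default: 2nd order, 6 Hz, zero-lag).

    Zero-lag means forward–backward application: squared magnitude response
    and no phase shift, so peak timing is unbiased.
    """

    order: int = 2
    cutoff_hz: float = 6.0
    zero_lag: bool = True

    def __post_init__(self):
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ParameterError("cutoff must be positive")


def butterworth_lowpass(signal: UniformSignal, spec: FilterSpec = FilterSpec()) -> UniformSignal:
    """Apply the spec'd low-pass; output length equals input length."""
    nyquist = signal.rate / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ParameterError(
            f"cutoff {spec.cutoff_hz} Hz >= Nyquist {nyquist} Hz at rate {signal.rate}"
        )
    sos = butter(spec.order, spec.cutoff_hz, btype="low", fs=signal.rate, output="sos")
    if spec.zero_lag:
        default_pad = 3 * (2 * sos.shape[0] + 1)
        out = sosfiltfilt(sos, signal.values, padlen=min(default_pad, len(signal) - 1))
    else:
        out = sosfilt(sos, signal.values)
    return signal.replace(out)


def _fill_gaps(values: np.ndarray, gap_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spline-fill short gaps (<= LONG_GAP_FRAMES); flag longer runs.

    Long gaps are still interpolated (the series must stay uniform) but the
    returned flag array marks them as untrusted.
    """
    filled = values.copy()
    flagged = np.zeros(values.size, dtype=bool)
    if not gap_mask.any():
        return filled, flagged
    valid = ~gap_mask
    if valid.sum() < 4:
        raise InsufficientDataError("too few valid frames to interpolate marker gaps")
    idx = np.arange(values.size)
    spline = CubicSpline(idx[valid], values[valid])
    filled[gap_mask] = spline(idx[gap_mask])
    # mark frames belonging to runs longer than the trusted gap length
    run_start = None
    for i, g in enumerate(np.append(gap_mask, False)):
        if g and run_start is None:
            run_start = i
        elif not g and run_start is not None:
            if i - run_start > LONG_GAP_FRAMES:
                flagged[run_start:i] = True
            run_start = None
    return filled, flagged


def thigh_angle(traj: MarkerTrajectory) -> UniformSignal:
    """Thigh angle from vertical, degrees; positive when the knee is raised
    anterior to the hip.

    Invariant to uniform translation of both markers and to segment-length
    scaling.  Short marker gaps are spline-filled; longer runs are filled but
    flagged in ``meta['long_gap_flagged']``.
    """
    d = traj.knee - traj.hip
    seg_len = np.hypot(d[:, 0], d[:, 1])
    degenerate = (seg_len < 1e-9) & ~traj.gap_mask
    if degenerate.any():
        raise DataError(
            f"hip and knee markers coincide at frame {int(np.argmax(degenerate))}"
        )
    # angle from downward vertical: atan2(anterior component, downward component)
    angle = np.degrees(np.arctan2(d[:, 0], -d[:, 1]))
    angle, flagged = _fill_gaps(angle, traj.gap_mask)
    sig = UniformSignal(
        rate=traj.frame_rate, start_time=0.0, values=angle, label="thigh_angle"
    )
    sig.meta["long_gap_flagged"] = flagged
    return sig


def differentiate(angle: UniformSignal, label: str = "reference") -> UniformSignal:
    """First derivative, °·s⁻¹: central differences interior, one-sided ends."""
    if len(angle) < 3:
        raise InsufficientDataError("differentiation needs >= 3 samples")
    vel = np.gradient(angle.values, 1.0 / angle.rate)
    return angle.replace(vel, label=label)


def reference_velocity(
    traj: MarkerTrajectory, filter_spec: FilterSpec = FilterSpec()
) -> UniformSignal:
    """Marker trajectory → filtered thigh angle → angular velocity (ground truth)."""
    return differentiate(butterworth_lowpass(thigh_angle(traj), filter_spec))
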