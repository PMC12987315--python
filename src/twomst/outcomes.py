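"""2MST outcome variables computed from a CycleSet.

STP (step-cycle count), DUR statistics, cadence, the coefficients of
variation of ω_peak and DUR, and the rate of performance change (RPC): the
difference between the mean ω_peak of cycles peaking in the final 20 s of
the test and the mean in the initial 20 s.  RPC classifies the performance
strategy as steady (|RPC| ≤ 11.5 °·s⁻¹, boundary inclusive), ascending
(> +11.5) or descending (< −11.5).  The cutoff band is configurable — it was
set pragmatically for healthy adults and may not transfer to clinical groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, InsufficientDataError
from .peaks import CycleSet

STEADY, ASCENDING, DESCENDING = "steady", "ascending", "descending"


@dataclass(frozen=True)
class RpcConfig:
    edge_window_s: float = 20.0
    steady_band: float = 11.5  # °·s⁻¹, boundary inclusive

    def __post_init__(self):
        if self.edge_window_s <= 0:
            raise ValueError("edge window must be positive")


@dataclass
class OutcomeSummary:
    source: str
    stp: int
    mean_dur: float
    sd_dur: float
    cv_dur: float  # %
    cadence: float  # cycles·min⁻¹
    mean_omega_peak: float
    sd_omega_peak: float
    cv_omega_peak: float  # %
    rpc: float  # °·s⁻¹ (edge-mean difference)
    rpc_slope_per_s: float  # auxiliary per-second slope
    rpc_class: str
    initial_window: tuple
    final_window: tuple


def classify_rpc(rpc: float, cfg: RpcConfig = RpcConfig()) -> str:
    """Partition of the real line: exactly one label for any finite RPC."""
    if not np.isfinite(rpc):
        raise DataError("RPC must be finite to classify")
    if abs(rpc) <= cfg.steady_band:
        return STEADY
    return ASCENDING if rpc > 0 else DESCENDING


def summarize(cycles: CycleSet, cfg: RpcConfig = RpcConfig()) -> OutcomeSummary:
    """All outcome variables for one test.

    Cadence uses the nominal test duration (cycles per minute of test), and
    edge-window membership is decided by each cycle's peak time.
    """
    if len(cycles) < 2:
        raise InsufficientDataError("outcome summary needs >= 2 cycles")
    if 2 * cfg.edge_window_s > cycles.test_duration:
        raise DataError("edge windows overlap: edge window > half the test duration")
    omega = cycles.omega_peaks
    durs = cycles.durations
    t = cycles.peak_times
    t0 = cycles.test_start
    initial = (t0, t0 + cfg.edge_window_s)
    final = (t0 + cycles.test_duration - cfg.edge_window_s, t0 + cycles.test_duration)
    in_initial = (t >= initial[0]) & (t <= initial[1])
    in_final = (t >= final[0]) & (t <= final[1])
    if not in_initial.any() or not in_final.any():
        raise InsufficientDataError("no cycle peaks inside an RPC edge window")

    mean_dur = float(durs.mean())
    sd_dur = float(durs.std(ddof=1)) if durs.size > 1 else 0.0
    mean_om = float(omega.mean())
    sd_om = float(omega.std(ddof=1)) if omega.size > 1 else 0.0
    if mean_dur == 0 or mean_om == 0:
        raise DataError("zero mean makes the coefficient of variation undefined")
    rpc = float(omega[in_final].mean() - omega[in_initial].mean())
    center_gap = (final[0] + final[1]) / 2 - (initial[0] + initial[1]) / 2
    return OutcomeSummary(
        source=cycles.source,
        stp=len(cycles),
        mean_dur=mean_dur,
        sd_dur=sd_dur,
        cv_dur=100.0 * sd_dur / mean_dur,
        cadence=len(cycles) / (cycles.test_duration / 60.0),
        mean_omega_peak=mean_om,
        sd_omega_peak=sd_om,
        cv_omega_peak=100.0 * sd_om / mean_om,
        rpc=rpc,
        rpc_slope_per_s=rpc / center_gap,
        rpc_class=classify_rpc(rpc, cfg),
        initial_window=initial,
        final_window=final,
    )
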