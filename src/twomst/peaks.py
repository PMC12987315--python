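"""Step-cycle peak detection shared by the reference and both phone pipelines.

One step cycle contributes one positive (elevation-phase) angular-velocity
peak, ω_peak.  The cycle count STP is the number of detected peaks and the
cycle duration DUR is the time between successive peaks.  Detection keeps
strict local maxima that clear a height floor and a prominence floor, then
enforces a minimum separation greedily by descending height — when two
candidates are too close, the larger survives.  The defaults derive from
stepping physiology: cadence below ~150 cycles·min⁻¹ per leg implies at least
0.4 s between same-leg peaks.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

from .errors import ContractError
from .preprocess import UniformSignal


@dataclass(frozen=True)
class PeakDetectorSpec:
    """Detector parameters; ``None`` height/prominence use the adaptive rule
    (height = 30% of the series' 95th percentile, prominence = height / 2)."""

    min_separation_s: float = 0.40
    min_height: float | None = None
    min_prominence: float | None = None
    height_fraction: float = 0.30
    height_percentile: float = 95.0

    def __post_init__(self):
        if self.min_separation_s <= 0:
            raise ValueError("min_separation_s must be positive")

    def resolve(self, values: np.ndarray) -> tuple[float, float]:
        height = self.min_height
        if height is None:
            height = self.height_fraction * float(
                np.percentile(values, self.height_percentile)
            )
        height = max(height, 1e-12)  # only positive peaks are cycle events
        prominence = self.min_prominence
        if prominence is None:
            prominence = height / 2.0
        return float(height), float(prominence)


@dataclass(frozen=True)
class StepCycle:
    index: int
    peak_time: float
    omega_peak: float
    duration: float | None  # time to next peak; None for the last cycle


@dataclass
class CycleSet:
    """Ordered step cycles from one source (reference | phone-AA | phone-ML)."""

    cycles: list[StepCycle]
    source: str = ""
    test_duration: float = 120.0
    test_start: float = 0.0

    def __post_init__(self):
        times = self.peak_times
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("cycle peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.cycles)

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([c.peak_time for c in self.cycles], dtype=float)

    @property
    def omega_peaks(self) -> np.ndarray:
        return np.array([c.omega_peak for c in self.cycles], dtype=float)

    @property
    def durations(self) -> np.ndarray:
        """The n−1 defined durations (the last cycle has none)."""
        return np.array(
            [c.duration for c in self.cycles if c.duration is not None], dtype=float
        )


def cycle_set_from_peaks(
    times: np.ndarray,
    omegas: np.ndarray,
    source: str = "",
    test_duration: float = 120.0,
    test_start: float = 0.0,
) -> CycleSet:
    times = np.asarray(times, dtype=float)
    omegas = np.asarray(omegas, dtype=float)
    cycles = []
    for i in range(times.size):
        dur = float(times[i + 1] - times[i]) if i + 1 < times.size else None
        cycles.append(
            StepCycle(index=i, peak_time=float(times[i]), omega_peak=float(omegas[i]), duration=dur)
        )
    return CycleSet(
        cycles=cycles, source=source, test_duration=test_duration, test_start=test_start
    )


def _greedy_separation(idx: np.ndarray, heights: np.ndarray, min_gap: int) -> np.ndarray:
    """Keep candidates by descending height subject to index separation.

    Ties break toward the lower index for determinism.  Two peaks exactly
    ``min_gap`` apart are both allowed; closer is a violation.  A kept-peak
    list maintained in index order makes each check a two-neighbour lookup.
    """
    order = np.lexsort((idx, -heights))
    kept: list[int] = []
    for k in order:
        i = int(idx[k])
        pos = bisect.bisect_left(kept, i)
        left_ok = pos == 0 or i - kept[pos - 1] >= min_gap
        right_ok = pos == len(kept) or kept[pos] - i >= min_gap
        if left_ok and right_ok:
            kept.insert(pos, i)
    return np.array(kept, dtype=int)


def detect_cycle_peaks(
    v: UniformSignal,
    spec: PeakDetectorSpec = PeakDetectorSpec(),
    source: str = "",
    test_duration: float = 120.0,
) -> CycleSet:
    """Detect one ω_peak per step cycle; an empty series yields an empty set."""
    values = v.values
    if values.size == 0 or not np.any(values > 0):
        return CycleSet(cycles=[], source=source, test_duration=test_duration,
                        test_start=v.start_time if values.size else 0.0)
    height, prominence = spec.resolve(values)
    candidates, _ = find_peaks(values, height=height)
    if candidates.size:
        proms = peak_prominences(values, candidates)[0]
        candidates = candidates[proms >= prominence]
    if candidates.size == 0:
        return CycleSet(cycles=[], source=source, test_duration=test_duration,
                        test_start=v.start_time)
    min_gap = max(1, int(round(spec.min_separation_s * v.rate)))
    kept = _greedy_separation(candidates, values[candidates], min_gap)
    times = v.start_time + kept / v.rate
    return cycle_set_from_peaks(
        times, values[kept], source=source, test_duration=test_duration,
        test_start=v.start_time,
    )


def parabolic_peak(y_prev: float, y0: float, y_next: float, dt: float) -> tuple[float, float]:
    """Refine a sample-level maximum by the vertex of the parabola through
    three consecutive samples.

    Returns ``(time_offset_s, refined_value)``.  The refined value is always
    >= y0 (vertex of a downward-opening parabola through a maximum); a flat
    triple returns ``(0, y0)``.
    """
    if y0 < y_prev or y0 < y_next:
        raise ContractError("parabolic_peak requires y0 to be a sample-level maximum")
    denom = y_prev - 2.0 * y0 + y_next
    if denom == 0:
        return 0.0, float(y0)
    p = 0.5 * (y_prev - y_next) / denom
    value = y0 - 0.25 * (y_prev - y_next) * p
    return float(p * dt), float(value)


def refine_cycle_peaks(cycles: CycleSet, v: UniformSignal) -> CycleSet:
    """Parabolically refine every peak of a CycleSet against its source signal."""
    times, omegas = [], []
    for c in cycles.cycles:
        i = int(round((c.peak_time - v.start_time) * v.rate))
        if 0 < i < len(v) - 1:
            off, val = parabolic_peak(v.values[i - 1], v.values[i], v.values[i + 1], 1.0 / v.rate)
            times.append(c.peak_time + off)
            omegas.append(val)
        else:
            times.append(c.peak_time)
            omegas.append(c.omega_peak)
    return cycle_set_from_peaks(
        np.array(times), np.array(omegas), source=cycles.source,
        test_duration=cycles.test_duration, test_start=cycles.test_start,
    )


def write_cycles_csv(cycles: CycleSet, path) -> None:
    """Serialize a CycleSet as a delimited table (index, peak_time, omega_peak,
    duration, source, test_duration)."""
    df = pd.DataFrame(
        {
            "index": [c.index for c in cycles.cycles],
            "peak_time": [c.peak_time for c in cycles.cycles],
            "omega_peak": [c.omega_peak for c in cycles.cycles],
            "duration": [c.duration for c in cycles.cycles],
        }
    )
    df.attrs = {}
    header = f"# source={cycles.source} test_duration={cycles.test_duration}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_cycles_csv(path) -> CycleSet:
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh)
    source, test_duration = "", 120.0
    if header.startswith("#"):
        for token in header[1:].split():
            key, _, val = token.partition("=")
            if key == "source":
                source = val
            elif key == "test_duration":
                test_duration = float(val)
    return cycle_set_from_peaks(
        df["peak_time"].to_numpy(dtype=float),
        df["omega_peak"].to_numpy(dtype=float),
        source=source,
        test_duration=test_duration,
    )


def match_cycles(a: CycleSet, b: CycleSet, tolerance_s: float = 0.30) -> list[tuple[int, int]]:
    """Pair cycles of two sets by nearest peak time within a tolerance.

    Greedy one-to-one matching by ascending time distance; unmatched cycles
    are dropped.  Used to pair phone-derived cycles with reference cycles.
    """
    ta, tb = a.peak_times, b.peak_times
    if ta.size == 0 or tb.size == 0:
        return []
    pairs = []
    for i, t in enumerate(ta):
        j = int(np.argmin(np.abs(tb - t)))
        dist = abs(tb[j] - t)
        if dist <= tolerance_s:
            pairs.append((dist, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for _, i, j in pairs:
        if i not in used_a and j not in used_b:
            matched.append((i, j))
            used_a.add(i)
            used_b.add(j)
    matched.sort()
    return matched
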