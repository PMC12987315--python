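"""Synthetic paired-session generator: phone gyroscope + motion-capture
markers for a 2-Minute Step Test, with closed-form ground truth.

The thigh elevation of each step cycle is a raised-cosine pulse
``θ(τ) = θ_max/2 · (1 − cos(2πτ/T))`` over the cycle duration T, chosen
because it is smooth, band-limited, and has a closed-form peak angular
velocity ``ω_peak = π·θ_max/T`` at τ = T/4.  Per-cycle ground-truth peaks
therefore come from pulse calculus, never from peak-picking on sampled data,
which makes the generator a valid oracle for every downstream pipeline.

The phone channel model layers the defects seen in real smartphone logs on
top of the true angular velocity: gain and saturating amplitude compression
``v → v / (1 + κ·|v|/300)`` (the 300 °·s⁻¹ scale sits inside the observed
ω_peak range), crosstalk into the y/z axes from sensor–segment misalignment,
additive Gaussian noise, slow bias drift, a jittered 58–62 Hz sampling clock
with occasional duplicate timestamps, and a constant inter-device lag.  The
marker channel adds Gaussian position noise and optional occlusion gaps.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .io_formats import (
    AxisMap,
    MarkerTrajectory,
    RawGyroStream,
    read_gyro_csv,
    read_marker_csv,
    write_gyro_csv,
    write_marker_csv,
)
from .peaks import CycleSet, cycle_set_from_peaks

NOMINAL_RATE = 60.0
COMPRESSION_SCALE = 300.0  # °·s⁻¹
MIN_CYCLE_DURATION = 0.40  # s, truncation floor of the duration draw


@dataclass(frozen=True)
class SyntheticSessionSpec:
    """All knobs of one simulated test; defaults emulate the study conditions."""

    duration_s: float = 120.0
    mean_cycle_duration_s: float = 0.84
    cycle_duration_sd_s: float = 0.05
    mean_peak_angle_deg: float = 81.0
    peak_angle_sd_deg: float = 4.0
    omega_trend: float = 0.0  # °·s⁻¹ difference, first cycle → last cycle
    thigh_length_m: float = 0.45
    # phone channel model
    gain: float = 1.0
    compression: float = 0.08  # κ in v / (1 + κ|v|/300)
    crosstalk_y: float = 0.15
    crosstalk_z: float = 0.10
    noise_sd: float = 8.0  # °·s⁻¹
    drift_rate: float = 3.0  # °·s⁻¹ per minute
    jitter_sd_s: float = 0.0005
    duplicate_prob: float = 0.01
    lag_s: float = 0.35  # phone delayed w.r.t. motion capture
    # marker channel model
    marker_noise_m: float = 0.001
    marker_gap_prob: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.duration_s <= 0 or self.mean_cycle_duration_s <= 0:
            raise DataError("durations must be positive")
        if self.mean_cycle_duration_s > self.duration_s:
            raise DataError("mean cycle duration exceeds test duration")
        if self.compression < 0 or self.cycle_duration_sd_s < 0:
            raise DataError("spread/compression parameters must be non-negative")


@dataclass
class SyntheticSession:
    ground_truth: CycleSet
    phone: RawGyroStream
    markers: MarkerTrajectory
    spec: SyntheticSessionSpec
    seed: int
    subject_id: str = "s0"
    intended_class: str = ""

    # closed-form pulse parameters kept for oracle use
    cycle_starts: np.ndarray = field(default_factory=lambda: np.array([]))
    cycle_durations: np.ndarray = field(default_factory=lambda: np.array([]))
    peak_angles_deg: np.ndarray = field(default_factory=lambda: np.array([]))

    def true_velocity(self, t: np.ndarray) -> np.ndarray:
        """Analytic thigh angular velocity (°·s⁻¹) at arbitrary times."""
        return _pulse_velocity(t, self.cycle_starts, self.cycle_durations, self.peak_angles_deg)

    def true_angle(self, t: np.ndarray) -> np.ndarray:
        return _pulse_angle(t, self.cycle_starts, self.cycle_durations, self.peak_angles_deg)


def _pulse_locate(t, starts, durations):
    t = np.asarray(t, dtype=float)
    idx = np.searchsorted(starts, t, side="right") - 1
    idx_c = np.clip(idx, 0, starts.size - 1)
    tau = t - starts[idx_c]
    inside = (idx >= 0) & (tau >= 0) & (tau < durations[idx_c])
    return idx_c, tau, inside


def _pulse_velocity(t, starts, durations, thetas):
    idx, tau, inside = _pulse_locate(t, starts, durations)
    T = durations[idx]
    v = np.pi * thetas[idx] / T * np.sin(2 * np.pi * tau / T)
    return np.where(inside, v, 0.0)


def _pulse_angle(t, starts, durations, thetas):
    idx, tau, inside = _pulse_locate(t, starts, durations)
    T = durations[idx]
    a = thetas[idx] / 2.0 * (1 - np.cos(2 * np.pi * tau / T))
    return np.where(inside, a, 0.0)


def compress(v: np.ndarray, kappa: float, scale: float = COMPRESSION_SCALE) -> np.ndarray:
    """Saturating amplitude compression of the phone channel."""
    return v / (1.0 + kappa * np.abs(v) / scale)


def _draw_cycles(spec: SyntheticSessionSpec, rng: np.random.Generator):
    durations = []
    total = 0.0
    while True:
        d = rng.normal(spec.mean_cycle_duration_s, spec.cycle_duration_sd_s)
        while d < MIN_CYCLE_DURATION:
            d = rng.normal(spec.mean_cycle_duration_s, spec.cycle_duration_sd_s)
        if total + d > spec.duration_s:
            break
        durations.append(d)
        total += d
    durations = np.array(durations)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return starts, durations


def simulate_session(
    spec: SyntheticSessionSpec, seed: int | None = None, subject_id: str = "s0"
) -> SyntheticSession:
    """Generate one paired session; identical spec + seed is bit-identical."""
    if seed is None:
        seed = spec.seed if spec.seed is not None else 0
    rng = np.random.default_rng(seed)

    starts, durations = _draw_cycles(spec, rng)
    n_cycles = durations.size
    if n_cycles < 2:
        raise DataError("spec produces fewer than 2 cycles")
    centers = (starts + durations / 4.0) / spec.duration_s
    omega_base = np.pi * spec.mean_peak_angle_deg / spec.mean_cycle_duration_s
    omega_sd = np.pi * spec.peak_angle_sd_deg / spec.mean_cycle_duration_s
    omega = (
        omega_base
        + spec.omega_trend * (centers - 0.5)
        + rng.normal(0.0, omega_sd, size=n_cycles)
    )
    omega = np.maximum(omega, 30.0)
    thetas = omega * durations / np.pi  # θ_max giving exactly ω_peak = omega

    peak_times = starts + durations / 4.0
    truth = cycle_set_from_peaks(
        peak_times, omega, source="truth", test_duration=spec.duration_s
    )

    phone = _simulate_phone(spec, rng, starts, durations, thetas)
    markers = _simulate_markers(spec, rng, starts, durations, thetas)

    return SyntheticSession(
        ground_truth=truth,
        phone=phone,
        markers=markers,
        spec=spec,
        seed=seed,
        subject_id=subject_id,
        cycle_starts=starts,
        cycle_durations=durations,
        peak_angles_deg=thetas,
    )


def _simulate_phone(spec, rng, starts, durations, thetas) -> RawGyroStream:
    dt_nominal = 1.0 / NOMINAL_RATE
    span = spec.duration_s + spec.lag_s + 0.5
    # draw jittered increments (58–62 Hz instantaneous rate, occasional
    # duplicate stamps) until the recording actually covers the target span
    chunks = [np.array([0.0])]
    total = 0.0
    while total < span:
        m = max(64, int(np.ceil((span - total) / dt_nominal)))
        inc = dt_nominal + rng.normal(0.0, spec.jitter_sd_s, size=m)
        inc = np.clip(inc, 1.0 / 62.0, 1.0 / 58.0)
        inc[rng.random(m) < spec.duplicate_prob] = 0.0
        chunks.append(total + np.cumsum(inc))
        total = chunks[-1][-1]
    t = np.concatenate(chunks)
    t = t[t <= span + dt_nominal]
    n = t.size

    v_true = _pulse_velocity(t - spec.lag_s, starts, durations, thetas)
    vx_clean = compress(spec.gain * v_true, spec.compression)
    drift = spec.drift_rate * t / 60.0
    noise = rng.normal(0.0, spec.noise_sd, size=(3, n))
    x = vx_clean + drift + noise[0]
    y = spec.crosstalk_y * vx_clean + noise[1]
    z = spec.crosstalk_z * vx_clean + noise[2]
    return RawGyroStream(timestamps=t, x=x, y=y, z=z, axis_map=AxisMap())


def _simulate_markers(spec, rng, starts, durations, thetas) -> MarkerTrajectory:
    n = int(np.ceil((spec.duration_s + 0.5) * NOMINAL_RATE)) + 1
    t = np.arange(n) / NOMINAL_RATE
    angle = np.radians(_pulse_angle(t, starts, durations, thetas))
    hip_true = np.column_stack([np.zeros(n), np.full(n, 0.9)])
    knee_true = hip_true + spec.thigh_length_m * np.column_stack(
        [np.sin(angle), -np.cos(angle)]
    )
    hip = hip_true + rng.normal(0.0, spec.marker_noise_m, size=(n, 2))
    knee = knee_true + rng.normal(0.0, spec.marker_noise_m, size=(n, 2))
    gaps = rng.random(n) < spec.marker_gap_prob
    hip[gaps] = np.nan
    knee[gaps] = np.nan
    return MarkerTrajectory(frame_rate=NOMINAL_RATE, hip=hip, knee=knee, gap_mask=gaps)


# population distributions loosely matched to the study cohort
POP_OMEGA_MEAN, POP_OMEGA_SD = 303.0, 39.0  # °·s⁻¹
POP_DUR_MEAN, POP_DUR_SD = 0.84, 0.11  # s
STRATEGY_MIX = {"steady": 0.40, "descending": 0.40, "ascending": 0.20}


def default_cohort(
    n_subjects: int, seed: int, duration_s: float = 120.0, **spec_overrides
) -> list[SyntheticSession]:
    """Per-subject sessions drawn from the population distributions.

    Subject mean ω_peak ~ N(303, 39) °·s⁻¹ and mean cycle duration
    ~ N(0.84, 0.11) s; the ω_peak trend is a steady/descending/ascending
    mixture (≈40/40/20%).  The intended strategy class is recorded on each
    session for oracle use.
    """
    if n_subjects < 2:
        raise DataError("a cohort needs >= 2 subjects")
    rng = np.random.default_rng(seed)
    sessions = []
    classes = list(STRATEGY_MIX)
    probs = np.array([STRATEGY_MIX[c] for c in classes])
    for i in range(n_subjects):
        omega_subj = float(np.clip(rng.normal(POP_OMEGA_MEAN, POP_OMEGA_SD), 150.0, None))
        dur_subj = float(np.clip(rng.normal(POP_DUR_MEAN, POP_DUR_SD), 0.55, 1.20))
        cls = classes[int(rng.choice(len(classes), p=probs))]
        if cls == "steady":
            trend = float(np.clip(rng.normal(0.0, 4.0), -9.0, 9.0))
        elif cls == "descending":
            trend = float(min(rng.normal(-32.0, 8.0), -22.0))
        else:
            trend = float(max(rng.normal(32.0, 8.0), 22.0))
        spec = SyntheticSessionSpec(
            duration_s=duration_s,
            mean_cycle_duration_s=dur_subj,
            mean_peak_angle_deg=omega_subj * dur_subj / np.pi,
            omega_trend=trend,
            **spec_overrides,
        )
        session_seed = int(rng.integers(0, 2**31 - 1))
        sessions.append(
            simulate_session(spec, seed=session_seed, subject_id=f"s{i:02d}")
        )
        sessions[-1].intended_class = cls
    return sessions


def write_session(session: SyntheticSession, directory) -> None:
    """Persist one session through the package's own writers (end-to-end I/O)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_gyro_csv(session.phone, directory / "phone.csv")
    write_marker_csv(session.markers, directory / "markers.csv")
    truth = pd.DataFrame(
        {
            "index": [c.index for c in session.ground_truth.cycles],
            "peak_time": [c.peak_time for c in session.ground_truth.cycles],
            "omega_peak": [c.omega_peak for c in session.ground_truth.cycles],
        }
    )
    truth.to_csv(directory / "truth.csv", index=False)
    meta = {
        "subject_id": session.subject_id,
        "seed": session.seed,
        "intended_class": session.intended_class,
        "spec": asdict(session.spec),
    }
    (directory / "session.json").write_text(json.dumps(meta, sort_keys=True, indent=2) + "\n")


def read_session(directory):
    """Load the phone stream, markers, truth table and metadata back."""
    directory = Path(directory)
    phone = read_gyro_csv(directory / "phone.csv")
    markers = read_marker_csv(directory / "markers.csv")
    truth_df = pd.read_csv(directory / "truth.csv", float_precision="round_trip")
    meta = json.loads((directory / "session.json").read_text())
    truth = cycle_set_from_peaks(
        truth_df["peak_time"].to_numpy(),
        truth_df["omega_peak"].to_numpy(),
        source="truth",
        test_duration=meta["spec"]["duration_s"],
    )
    return phone, markers, truth, meta


def load_session(directory) -> SyntheticSession:
    """Reconstruct a session object from a written session directory."""
    phone, markers, truth, meta = read_session(directory)
    return SyntheticSession(
        ground_truth=truth,
        phone=phone,
        markers=markers,
        spec=SyntheticSessionSpec(**meta["spec"]),
        seed=meta["seed"],
        subject_id=meta["subject_id"],
        intended_class=meta.get("intended_class", ""),
    )
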