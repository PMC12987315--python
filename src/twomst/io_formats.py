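"""Readers and writers for the external file dialects.

Canonical internal units everywhere past this boundary: seconds, degrees,
degrees per second (°·s⁻¹), meters.  Readers convert at read time; writers
emit full-precision decimal text so a write→read round trip is bit-exact.

Gyroscope logs are SensorLog-style CSV: a header row, a timestamp column and
three axis columns, comma or semicolon delimited.  Marker files carry the
sagittal-plane projection of the hip (greater trochanter) and knee (lateral
condyle) markers; a blank cell marks an occluded (gap) frame.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

DEG_PER_RAD = 180.0 / math.pi

#: Longest marker drop-out (frames) that gap-filling is trusted to bridge.
LONG_GAP_FRAMES = 10


@dataclass(frozen=True)
class GyroDialect:
    """Column-name profile of a gyroscope CSV file."""

    time: str = "time"
    x: str = "x"
    y: str = "y"
    z: str = "z"

    @property
    def columns(self) -> tuple[str, str, str, str]:
        return (self.time, self.x, self.y, self.z)


@dataclass(frozen=True)
class AxisMap:
    """Mapping of device axes onto anatomical axes, as a ±1 sign per axis.

    Positive angular velocity = thigh elevation (upward movement), matching
    the motion-capture convention.
    """

    x: int = 1
    y: int = 1
    z: int = 1

    def __post_init__(self):
        for name in ("x", "y", "z"):
            if getattr(self, name) not in (-1, 1):
                raise ValueError(f"axis sign for {name!r} must be ±1")

    @property
    def signs(self) -> dict[str, int]:
        return {"x": self.x, "y": self.y, "z": self.z}


@dataclass
class RawGyroStream:
    """Unresampled tri-axial angular-velocity stream in °·s⁻¹.

    Timestamps are seconds since session start (rebased to 0 by the reader),
    non-decreasing; duplicate timestamps are retained — the resampler
    collapses them to their mean.
    """

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    axis_map: AxisMap = field(default_factory=AxisMap)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        for name in ("x", "y", "z"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.timestamps.shape:
                raise DataError(f"axis {name!r} length != timestamps length")
        if self.timestamps.size < 2:
            raise DataError("a gyroscope stream needs at least 2 samples")
        if np.any(np.diff(self.timestamps) < 0):
            row = int(np.argmax(np.diff(self.timestamps) < 0)) + 1
            raise DataError(f"timestamps decrease at row {row}")

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass
class MarkerTrajectory:
    """Per-frame planar (sagittal) hip and knee marker coordinates, meters.

    Coordinate convention: column 0 = anterior/horizontal, column 1 = vertical
    (up positive).  ``gap_mask`` flags frames where either marker is missing.
    """

    frame_rate: float
    hip: np.ndarray  # (n, 2)
    knee: np.ndarray  # (n, 2)
    gap_mask: np.ndarray  # (n,) bool, True = gap

    def __post_init__(self):
        self.hip = np.asarray(self.hip, dtype=float)
        self.knee = np.asarray(self.knee, dtype=float)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.frame_rate <= 0:
            raise DataError("frame_rate must be positive")
        if self.hip.shape != self.knee.shape or self.hip.ndim != 2:
            raise DataError("hip and knee arrays must have identical (n, 2) shape")
        if self.gap_mask.shape[0] != self.hip.shape[0]:
            raise DataError("gap_mask length mismatch")

    def __len__(self) -> int:
        return self.hip.shape[0]


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return ";" if header.count(";") > header.count(",") else ","


def read_gyro_csv(
    path,
    dialect: GyroDialect = GyroDialect(),
    unit: str = "deg",
    axis_map: AxisMap | None = None,
    monotone_tolerance: float = 1e-9,
) -> RawGyroStream:
    """Read a gyroscope log; rebase time to start at 0 and convert to °·s⁻¹.

    ``unit`` is the source angular unit, ``"deg"`` (°·s⁻¹) or ``"rad"``
    (rad·s⁻¹).  Rows are preserved in file order, duplicates included.
    """
    path = Path(path)
    if unit not in ("deg", "rad"):
        raise FormatError(f"unknown angular unit {unit!r}")
    df = pd.read_csv(path, sep=_sniff_delimiter(path), float_precision="round_trip")
    missing = [c for c in dialect.columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    t = df[dialect.time].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        bad = dt < -monotone_tolerance
        if np.any(bad):
            raise DataError(
                f"{path}: timestamps not non-decreasing at row {int(np.argmax(bad)) + 1}"
            )
        t = np.maximum.accumulate(t)  # absorb sub-tolerance jitter
    scale = DEG_PER_RAD if unit == "rad" else 1.0
    return RawGyroStream(
        timestamps=t - t[0],
        x=df[dialect.x].to_numpy(dtype=float) * scale,
        y=df[dialect.y].to_numpy(dtype=float) * scale,
        z=df[dialect.z].to_numpy(dtype=float) * scale,
        axis_map=axis_map or AxisMap(),
    )


def write_gyro_csv(stream: RawGyroStream, path, dialect: GyroDialect = GyroDialect()) -> None:
    """Write a stream with full float precision (repr round-trip)."""
    df = pd.DataFrame(
        {
            dialect.time: stream.timestamps,
            dialect.x: stream.x,
            dialect.y: stream.y,
            dialect.z: stream.z,
        }
    )
    df.to_csv(path, index=False)


MARKER_COLUMNS = ("frame", "hip_a", "hip_b", "knee_a", "knee_b")


def read_marker_csv(path, frame_rate: float = 60.0, plane=("a", "b")) -> MarkerTrajectory:
    """Read a two-marker planar trajectory; blank cells become gap frames.

    ``plane`` names the two stored coordinates (suffixes of the ``hip_*`` /
    ``knee_*`` columns); the default ``("a", "b")`` matches the canonical
    header ``frame,hip_a,hip_b,knee_a,knee_b``.  Runs of more than
    ``LONG_GAP_FRAMES`` consecutive gaps are kept but logged as a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), float_precision="round_trip")
    cols = [f"hip_{plane[0]}", f"hip_{plane[1]}", f"knee_{plane[0]}", f"knee_{plane[1]}"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    hip = df[cols[:2]].to_numpy(dtype=float)
    knee = df[cols[2:]].to_numpy(dtype=float)
    gap = np.isnan(hip).any(axis=1) | np.isnan(knee).any(axis=1)
    longest = _longest_run(gap)
    if longest > LONG_GAP_FRAMES:
        logger.warning(
            "%s: %d consecutive gap frames (> %d); gap-filling may be unreliable",
            path,
            longest,
            LONG_GAP_FRAMES,
        )
    return MarkerTrajectory(frame_rate=frame_rate, hip=hip, knee=knee, gap_mask=gap)


def write_marker_csv(traj: MarkerTrajectory, path) -> None:
    hip = traj.hip.copy()
    knee = traj.knee.copy()
    hip[traj.gap_mask] = np.nan
    knee[traj.gap_mask] = np.nan
    df = pd.DataFrame(
        {
            "frame": np.arange(len(traj)),
            "hip_a": hip[:, 0],
            "hip_b": hip[:, 1],
            "knee_a": knee[:, 0],
            "knee_b": knee[:, 1],
        }
    )
    df.to_csv(path, index=False)


def _longest_run(mask: np.ndarray) -> int:
    longest = run = 0
    for flag in mask:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    return longest


def write_report(summary, path, format: str = "csv") -> None:
    """Serialize an OutcomeSummary or AgreementReport.

    ``csv`` emits a two-column ``metric,value`` table (flat fields only);
    ``json`` emits the full nested structure.  Both use repr-precision floats
    so a round trip reproduces every numeric field exactly, and both are
    byte-deterministic for a given object.
    """
    if not is_dataclass(summary):
        raise DataError("write_report expects a report dataclass")
    fields = asdict(summary)
    if fields.get("n_pairs") == 0:
        raise DataError("refusing to write an agreement report with zero pairs")
    missing = [k for k, v in fields.items() if v is None]
    if missing:
        raise DataError(f"report not fully populated: {missing}")
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(fields, fh, sort_keys=True, indent=2, default=_jsonable)
            fh.write("\n")
    elif format == "csv":
        lines = ["metric,value"]
        for key in sorted(fields):
            lines.append(f"{key},{_scalar_repr(fields[key])}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise FormatError(f"unknown report format {format!r}")


def read_report(path, format: str = "csv") -> dict:
    """Read a report back into a plain dict of field -> value."""
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    if format == "csv":
        out: dict = {}
        for line in path.read_text().splitlines()[1:]:
            key, _, raw = line.partition(",")
            out[key] = _parse_scalar(raw)
        return out
    raise FormatError(f"unknown report format {format!r}")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)!r}")


def _scalar_repr(value) -> str:
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, (np.floating, np.integer)):
        return repr(value.item())
    return str(value)


def _parse_scalar(raw: str):
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    if raw in ("True", "False"):
        return raw == "True"
    return raw
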