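"""Machine-learning approach: per-cycle feature extraction and stacked regression.

Each reference-anchored ±0.12 s window (15 samples at 60 Hz) of the 6-Hz
pre-filtered phone signal yields a row of time-domain features per axis —
window peak, 10/25/50/75/90th percentiles, mean, SD, RMS, signal energy
(Σv²·Δt), high-amplitude width (time above 50% of the window peak), zero
crossings, and the parabolically interpolated peak — plus the cycle duration.
A stacked regressor maps those features to the motion-capture ω_peak: an
ElasticNet behind median imputation / standardization / variance filtering,
a histogram gradient-boosted tree model, and a Ridge meta-learner fitted on
subject-wise out-of-fold base predictions.  The stacked output is calibrated
by isotonic regression (out-of-range inputs clipped to the training range)
and the top 5% of calibrated predictions receive an extra linear tail
correction, sharpening high-magnitude peaks where filtering losses bite
hardest.

Train/test discipline: cycles are split 70/30 at the cycle level; grouped
(leave-one-subject-out style) folds within the training partition keep
subjects disjoint between base-learner fitting and out-of-fold prediction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.feature_selection import VarianceThreshold
from sklearn.impute import SimpleImputer
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import ElasticNetCV, RidgeCV
from sklearn.model_selection import GroupKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import DataError, GroupingError, LeakageError, SchemaError
from .mocap import FilterSpec, butterworth_lowpass
from .peaks import CycleSet, cycle_set_from_peaks, parabolic_peak
from .preprocess import TriaxialSignal

META_COLUMNS = ("subject", "cycle", "peak_time", "target")

PERCENTILES = (10, 25, 50, 75, 90)


@dataclass(frozen=True)
class FeatureWindowSpec:
    """±half-width analysis window around each reference peak.

    0.12 s at 60 Hz rounds down to 7 samples per side so the window lies
    fully inside ±0.12 s.
    """

    half_width_s: float = 0.12
    prefilter: FilterSpec = FilterSpec(order=2, cutoff_hz=6.0, zero_lag=True)

    def half_width_samples(self, rate: float) -> int:
        return max(1, int(np.floor(self.half_width_s * rate)))


@dataclass(frozen=True)
class SplitPlan:
    """Cycle-level 70/30 partition plus grouped folds over subjects.

    Membership is a deterministic hash of (seed, subject, cycle) against the
    train fraction, so any row's partition is computable in isolation.  Folds
    within training are subject-disjoint: pure leave-one-subject-out when
    there are at most ``max_folds`` subjects, grouped K-fold otherwise.
    """

    train_fraction: float = 0.70
    seed: int = 0
    max_folds: int = 10

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")

    def _unit(self, subject, cycle) -> float:
        digest = hashlib.sha256(f"{self.seed}:{subject}:{cycle}".encode()).digest()
        return int.from_bytes(digest[:8], "big") / 2**64

    def is_train(self, subjects, cycles) -> np.ndarray:
        return np.array(
            [self._unit(s, c) < self.train_fraction for s, c in zip(subjects, cycles)]
        )

    def split(self, rows: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        mask = self.is_train(rows["subject"], rows["cycle"])
        return rows[mask].reset_index(drop=True), rows[~mask].reset_index(drop=True)

    def n_folds(self, n_subjects: int) -> int:
        return min(n_subjects, self.max_folds)


@dataclass(frozen=True)
class TailCorrection:
    """Linear correction applied only above the calibrated-prediction threshold."""

    threshold: float
    slope: float = 1.0
    intercept: float = 0.0
    enabled: bool = True

    def apply(self, values: np.ndarray) -> np.ndarray:
        if not self.enabled:
            return values
        out = values.copy()
        tail = out > self.threshold
        out[tail] = self.slope * out[tail] + self.intercept
        return out


@dataclass
class StackedModel:
    base_linear: object
    base_trees: object
    meta: object
    calibration: IsotonicRegression
    tail: TailCorrection
    feature_columns: list[str]
    provenance: dict = field(default_factory=dict)

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_columns if c not in rows.columns]
        if missing:
            raise SchemaError(f"feature table is missing columns {missing}")
        X = rows[self.feature_columns].to_numpy(dtype=float)
        stacked = np.column_stack(
            [self.base_linear.predict(X), self.base_trees.predict(X)]
        )
        combined = self.meta.predict(stacked)
        calibrated = self.calibration.predict(combined)
        return self.tail.apply(np.asarray(calibrated, dtype=float))


def _axis_features(window: np.ndarray, dt: float, prefix: str) -> dict[str, float]:
    peak = float(window.max())
    feats = {
        f"{prefix}_peak": peak,
        f"{prefix}_mean": float(window.mean()),
        f"{prefix}_sd": float(window.std(ddof=0)),
        f"{prefix}_rms": float(np.sqrt(np.mean(window**2))),
        f"{prefix}_energy": float(np.sum(window**2) * dt),
        f"{prefix}_zero_crossings": int(np.sum(window[:-1] * window[1:] < 0)),
    }
    for p in PERCENTILES:
        feats[f"{prefix}_p{p}"] = float(np.percentile(window, p))
    # high-amplitude width: duration spent above half of the window peak
    feats[f"{prefix}_half_width"] = float(np.sum(window > 0.5 * peak) * dt) if peak > 0 else 0.0
    # parabolic refinement of the window's own maximum
    i = int(np.argmax(window))
    if 0 < i < window.size - 1:
        _, refined = parabolic_peak(window[i - 1], window[i], window[i + 1], dt)
    else:
        refined = peak
    feats[f"{prefix}_parabolic_peak"] = float(refined)
    return feats


def feature_columns_for(rate: float = 60.0) -> list[str]:
    """Deterministic feature-column ordering shared by training and deployment."""
    cols = []
    for axis in ("x", "y", "z"):
        cols.extend(_axis_features(np.array([0.0, 1.0, 0.0]), 1.0 / rate, axis).keys())
    cols.append("duration")
    return cols


def extract_features(
    phone: TriaxialSignal,
    anchors: CycleSet,
    spec: FeatureWindowSpec = FeatureWindowSpec(),
    subject="s0",
    with_target: bool = True,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """One feature row per anchor whose full ±half-width window fits the signal.

    Anchors are the reference peaks (detection on the x-axis anchors all
    three axes).  Rows whose window would be clipped at the signal edge are
    dropped; the count is recorded in ``df.attrs['n_dropped']``.
    """
    if len(anchors) == 0:
        raise DataError("no anchors to extract features at")
    tri = phone if prefiltered else phone.map_channels(
        lambda ch: butterworth_lowpass(ch, spec.prefilter)
    )
    rate = tri.rate
    half = spec.half_width_samples(rate)
    dt = 1.0 / rate
    median_dur = float(np.median(anchors.durations)) if len(anchors) > 1 else np.nan
    rows, dropped = [], 0
    for c in anchors.cycles:
        center = int(round((c.peak_time - tri.start_time) * rate))
        lo, hi = center - half, center + half + 1
        if lo < 0 or hi > len(tri):
            dropped += 1
            continue
        row: dict = {
            "subject": subject,
            "cycle": c.index,
            "peak_time": c.peak_time,
            "duration": c.duration if c.duration is not None else median_dur,
        }
        for axis in ("x", "y", "z"):
            window = getattr(tri, axis).values[lo:hi]
            row.update(_axis_features(window, dt, axis))
        if with_target:
            row["target"] = c.omega_peak
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        raise DataError("every anchor window was clipped by the signal edges")
    df.attrs["n_dropped"] = dropped
    return df


def _make_base_learners(seed: int):
    linear = make_pipeline(
        SimpleImputer(strategy="median"),
        StandardScaler(),
        VarianceThreshold(0.0),
        ElasticNetCV(l1_ratio=[0.2, 0.5, 0.8], alphas=30, cv=3, max_iter=5000),
    )
    trees = HistGradientBoostingRegressor(random_state=seed, max_iter=150)
    return linear, trees


def train_stacked(rows: pd.DataFrame, plan: SplitPlan = SplitPlan()) -> StackedModel:
    """Fit the stacked model on training-partition feature rows.

    Raises ``LeakageError`` if any row belongs to the plan's test partition,
    and ``GroupingError`` with fewer than two subjects (grouped folds need
    held-out subjects).
    """
    if "target" not in rows.columns:
        raise DataError("training rows must carry the reference target")
    in_train = plan.is_train(rows["subject"], rows["cycle"])
    if not in_train.all():
        bad = rows.loc[~in_train, ["subject", "cycle"]].iloc[0]
        raise LeakageError(
            f"test-partition row passed to training: subject={bad['subject']} cycle={bad['cycle']}"
        )
    subjects = rows["subject"].to_numpy()
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise GroupingError("subject-wise folding needs >= 2 distinct subjects")
    feature_cols = [c for c in rows.columns if c not in META_COLUMNS and c != "duration"]
    feature_cols = feature_cols + ["duration"]
    X = rows[feature_cols].to_numpy(dtype=float)
    y = rows["target"].to_numpy(dtype=float)

    k = plan.n_folds(uniq.size)
    cv = GroupKFold(n_splits=k)
    linear, trees = _make_base_learners(plan.seed)
    oof = np.column_stack(
        [
            cross_val_predict(linear, X, y, cv=cv, groups=subjects),
            cross_val_predict(trees, X, y, cv=cv, groups=subjects),
        ]
    )
    meta = RidgeCV(alphas=np.logspace(-3, 3, 13)).fit(oof, y)
    # refit bases on the full training partition for deployment
    linear.fit(X, y)
    trees.fit(X, y)

    stacked_oof = meta.predict(oof)
    calibration = calibrate_isotonic(stacked_oof, y)
    calibrated = np.asarray(calibration.predict(stacked_oof), dtype=float)
    tail = fit_tail_correction(calibrated, y)

    return StackedModel(
        base_linear=linear,
        base_trees=trees,
        meta=meta,
        calibration=calibration,
        tail=tail,
        feature_columns=feature_cols,
        provenance={
            "n_rows": int(len(rows)),
            "subjects": [str(s) for s in uniq],
            "n_folds": k,
            "split_seed": plan.seed,
            "train_fraction": plan.train_fraction,
        },
    )


def calibrate_isotonic(predictions: np.ndarray, targets: np.ndarray) -> IsotonicRegression:
    """Non-decreasing least-squares map from stacked predictions to targets,
    clipping queries outside the training prediction range to its endpoints."""
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if predictions.size < 2:
        raise DataError("isotonic calibration needs >= 2 pairs")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(predictions, targets)
    return iso


def fit_tail_correction(
    calibrated: np.ndarray, targets: np.ndarray, quantile: float = 0.95
) -> TailCorrection:
    """Least-squares line target ~ calibrated on the top-(1−q) tail.

    Disabled (identity) when there are fewer than 20 pairs overall or fewer
    than 2 pairs strictly above the threshold.
    """
    calibrated = np.asarray(calibrated, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if calibrated.size < 20:
        return TailCorrection(threshold=float("inf"), enabled=False)
    threshold = float(np.quantile(calibrated, quantile))
    tail = calibrated > threshold
    if tail.sum() < 2 or np.ptp(calibrated[tail]) == 0:
        return TailCorrection(threshold=threshold, enabled=False)
    slope, intercept = np.polyfit(calibrated[tail], targets[tail], 1)
    return TailCorrection(
        threshold=threshold, slope=float(slope), intercept=float(intercept)
    )


def predict_peaks(model: StackedModel, rows: pd.DataFrame) -> CycleSet:
    """Predicted per-cycle ω_peak; anchor times and durations pass through."""
    preds = model.predict(rows)
    order = np.argsort(rows["peak_time"].to_numpy())
    times = rows["peak_time"].to_numpy(dtype=float)[order]
    return cycle_set_from_peaks(times, preds[order], source="phone-ML")
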