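"""Study-level orchestration: the full replication recipe on a cohort.

For every session: condition the phone stream (resample to 60 Hz, sign
convention, drift removal), build the motion-capture reference velocity,
detect reference cycles, and synchronize phone to reference by
cross-correlation.  Cycles are then partitioned 70/30 at the cycle level;
the AA cutoff map is fitted on train-majority windows pooled across
sessions, the ML stacked model on training-partition feature rows; both are
evaluated on test cycles only, and agreement with the reference is
summarized by Bland–Altman (differences oriented reference − estimate, so a
positive bias is a phone underestimate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agreement import AgreementReport, bland_altman
from .analytical import (
    CutoffMap,
    WindowingSpec,
    _window_starts,
    adaptive_filter,
    cutoff_map_from_table,
    optimal_cutoff_table,
    synchronize,
)
from .errors import InsufficientDataError
from .ml import (
    FeatureWindowSpec,
    SplitPlan,
    StackedModel,
    extract_features,
    train_stacked,
)
from .mocap import FilterSpec, reference_velocity
from .outcomes import OutcomeSummary, RpcConfig, summarize
from .peaks import CycleSet, PeakDetectorSpec, detect_cycle_peaks, match_cycles
from .preprocess import TriaxialSignal, UniformSignal, preprocess_stream
from .synth import SyntheticSession


@dataclass
class ProcessedSession:
    subject: str
    phone: TriaxialSignal  # conditioned and synchronized to the reference
    reference: UniformSignal
    ref_cycles: CycleSet
    aa_cycles: CycleSet | None = None
    lag_s: float = 0.0
    sync_correlation: float = 1.0
    outcome: OutcomeSummary | None = None


@dataclass
class StudyResult:
    sessions: list[ProcessedSession]
    cutoff_map: CutoffMap
    model: StackedModel
    cycle_table: pd.DataFrame
    aa_agreement: AgreementReport
    ml_agreement: AgreementReport
    config: dict = field(default_factory=dict)

    def descriptives(self) -> dict:
        """Cohort-level descriptive statistics (per-subject means averaged)."""
        tbl = self.cycle_table
        per_subj = tbl.groupby("subject")
        stp = per_subj.size()
        ref_mean = per_subj["ref_omega"].mean()
        aa_mean = tbl.dropna(subset=["aa_omega"]).groupby("subject")["aa_omega"].mean()
        ml_mean = tbl.dropna(subset=["ml_omega"]).groupby("subject")["ml_omega"].mean()
        out = {
            "n_subjects": int(stp.size),
            "n_cycles_total": int(len(tbl)),
            "n_test_cycles": int((~tbl["is_train"]).sum()),
            "stp_mean": float(stp.mean()),
            "stp_sd": float(stp.std(ddof=1)),
            "omega_peak_ref_mean": float(ref_mean.mean()),
            "omega_peak_ref_sd": float(ref_mean.std(ddof=1)),
            "omega_peak_aa_mean": float(aa_mean.mean()),
            "omega_peak_ml_mean": float(ml_mean.mean()),
        }
        outcomes = [s.outcome for s in self.sessions if s.outcome is not None]
        if outcomes:
            out["dur_mean_s"] = float(np.mean([o.mean_dur for o in outcomes]))
            out["cadence_mean"] = float(np.mean([o.cadence for o in outcomes]))
            out["cv_dur_mean_pct"] = float(np.mean([o.cv_dur for o in outcomes]))
            out["cv_omega_mean_pct"] = float(np.mean([o.cv_omega_peak for o in outcomes]))
            classes = [o.rpc_class for o in outcomes]
            for name in ("steady", "descending", "ascending"):
                out[f"pct_{name}"] = 100.0 * classes.count(name) / len(classes)
        return out


def process_session(
    session: SyntheticSession,
    detector: PeakDetectorSpec = PeakDetectorSpec(),
    filter_spec: FilterSpec = FilterSpec(),
    rpc_cfg: RpcConfig = RpcConfig(),
) -> ProcessedSession:
    """Condition, reference, detect and synchronize one session."""
    tri = preprocess_stream(session.phone)
    ref = reference_velocity(session.markers, filter_spec)
    duration = session.spec.duration_s
    ref_cycles = detect_cycle_peaks(
        ref, detector, source="reference", test_duration=duration
    )
    sync = synchronize(tri.x, ref)
    aligned = sync.apply_triaxial(tri)
    n = min(len(aligned), len(ref))
    aligned = aligned.map_channels(lambda ch: ch.replace(ch.values[:n]))
    outcome = summarize(ref_cycles, rpc_cfg) if len(ref_cycles) >= 2 else None
    return ProcessedSession(
        subject=session.subject_id,
        phone=aligned,
        reference=ref.replace(ref.values[:n]),
        ref_cycles=ref_cycles,
        lag_s=sync.lag_s,
        sync_correlation=sync.peak_correlation,
        outcome=outcome,
    )


def _train_window_mask(
    proc: ProcessedSession, plan: SplitPlan, spec: WindowingSpec
) -> tuple[np.ndarray, frozenset]:
    """Assign each analysis window to train/test by majority vote of the
    reference-cycle peaks it contains; returns the mask and the training
    cycle ids covered by fitted windows."""
    rate = proc.phone.rate
    n = min(len(proc.phone), len(proc.reference))
    win = int(round(spec.window_s * rate))
    hop = int(round(spec.hop_s * rate))
    starts = _window_starts(n, win, hop)
    times = proc.ref_cycles.peak_times
    ids = [(proc.subject, c.index) for c in proc.ref_cycles.cycles]
    is_train = plan.is_train([proc.subject] * len(ids), [c.index for c in proc.ref_cycles.cycles])
    mask = np.zeros(len(starts), dtype=bool)
    covered: set = set()
    t0 = proc.phone.start_time
    for w, s in enumerate(starts):
        lo, hi = t0 + s / rate, t0 + (s + win) / rate
        inside = (times >= lo) & (times < hi)
        if not inside.any():
            continue
        n_train = int(is_train[inside].sum())
        if n_train * 2 >= inside.sum():
            mask[w] = True
            covered.update(
                cid for cid, tr, ins in zip(ids, is_train, inside) if ins and tr
            )
    return mask, frozenset(covered)


def fit_cohort_cutoff_map(
    processed: list[ProcessedSession],
    plan: SplitPlan,
    spec: WindowingSpec = WindowingSpec(),
) -> CutoffMap:
    """Pool train-window (f_d, c*) pairs across sessions into one linear map."""
    table = []
    covered: set = set()
    for proc in processed:
        mask, ids = _train_window_mask(proc, plan, spec)
        if not mask.any():
            continue
        table.extend(optimal_cutoff_table(proc.phone.x, proc.reference, spec, mask))
        covered.update(ids)
    if len(table) < 2:
        raise InsufficientDataError("fewer than 2 training windows across the cohort")
    return cutoff_map_from_table(table, fit_cycle_ids=frozenset(covered))


def run_study(
    sessions: list[SyntheticSession],
    plan: SplitPlan = SplitPlan(),
    detector: PeakDetectorSpec = PeakDetectorSpec(),
    windowing: WindowingSpec = WindowingSpec(),
    feature_spec: FeatureWindowSpec = FeatureWindowSpec(),
    filter_spec: FilterSpec = FilterSpec(),
    rpc_cfg: RpcConfig = RpcConfig(),
) -> StudyResult:
    """The full AA-vs-ML comparison on a cohort of paired sessions."""
    processed = [
        process_session(s, detector=detector, filter_spec=filter_spec, rpc_cfg=rpc_cfg)
        for s in sessions
    ]
    cmap = fit_cohort_cutoff_map(processed, plan, windowing)

    session_by_subject = {s.subject_id: s for s in sessions}
    feature_frames = []
    records = []
    for proc in processed:
        # AA: adaptive filtering of the aligned x-axis, then peak detection
        filtered = adaptive_filter(proc.phone.x, cmap, windowing)
        proc.aa_cycles = detect_cycle_peaks(
            filtered, detector, source="phone-AA",
            test_duration=proc.ref_cycles.test_duration,
        )
        aa_by_ref = {
            j: proc.aa_cycles.cycles[i].omega_peak
            for i, j in match_cycles(proc.aa_cycles, proc.ref_cycles)
        }
        truth = session_by_subject[proc.subject].ground_truth
        truth_by_ref = {
            j: truth.cycles[i].omega_peak
            for i, j in match_cycles(truth, proc.ref_cycles)
        }
        is_train = plan.is_train(
            [proc.subject] * len(proc.ref_cycles),
            [c.index for c in proc.ref_cycles.cycles],
        )
        for c, tr in zip(proc.ref_cycles.cycles, is_train):
            records.append(
                {
                    "subject": proc.subject,
                    "cycle": c.index,
                    "peak_time": c.peak_time,
                    "ref_omega": c.omega_peak,
                    "truth_omega": truth_by_ref.get(c.index, np.nan),
                    "aa_omega": aa_by_ref.get(c.index, np.nan),
                    "is_train": bool(tr),
                }
            )
        feature_frames.append(
            extract_features(
                proc.phone, proc.ref_cycles, feature_spec, subject=proc.subject
            )
        )

    cycle_table = pd.DataFrame(records)
    features = pd.concat(feature_frames, ignore_index=True)
    train_rows, test_rows = plan.split(features)
    model = train_stacked(train_rows, plan)
    ml_pred = model.predict(test_rows)
    ml_map = {
        (s, c): p
        for s, c, p in zip(test_rows["subject"], test_rows["cycle"], ml_pred)
    }
    cycle_table["ml_omega"] = [
        ml_map.get((s, c), np.nan)
        for s, c in zip(cycle_table["subject"], cycle_table["cycle"])
    ]

    test_tbl = cycle_table[~cycle_table["is_train"]]
    aa_pairs = test_tbl.dropna(subset=["aa_omega"])
    ml_pairs = test_tbl.dropna(subset=["ml_omega"])
    aa_agreement = bland_altman(
        aa_pairs["ref_omega"], aa_pairs["aa_omega"], labels=("reference", "phone-AA")
    )
    ml_agreement = bland_altman(
        ml_pairs["ref_omega"], ml_pairs["ml_omega"], labels=("reference", "phone-ML")
    )
    return StudyResult(
        sessions=processed,
        cutoff_map=cmap,
        model=model,
        cycle_table=cycle_table,
        aa_agreement=aa_agreement,
        ml_agreement=ml_agreement,
        config={
            "split_seed": plan.seed,
            "train_fraction": plan.train_fraction,
            "n_sessions": len(sessions),
        },
    )
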