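# Methods

## Signal model and conventions

All processing uses canonical units — seconds, degrees, °·s⁻¹, meters — and
the sign convention that thigh elevation (upward movement) is positive. The
thigh angle is measured from the downward vertical of the hip→knee marker
segment: 0° = thigh vertical, 90° = thigh horizontal with the knee anterior.
Angular velocity is the first derivative of that angle (central differences
in the interior, one-sided at the ends). The motion-capture chain (marker
pair → 6-Hz zero-lag 2nd-order Butterworth on the angle → differentiation)
is treated as ground truth for training and validation.

Phone logs arrive with a jittered clock (nominally 60 Hz, 58–62 Hz observed)
and occasional duplicate timestamps. Conditioning is: collapse co-timestamped
samples to their mean (unbiased under symmetric noise), cubic-spline resample
onto an exact 60 Hz grid anchored at the first raw timestamp (no
extrapolation past the raw span — cubic splines extrapolate badly), apply the
per-axis sign map, and subtract a zero-lag 2nd-order Butterworth low-pass
baseline at 0.1 Hz. The 0.1 Hz drift cutoff sits at least a decade below any
plausible stepping frequency (~0.9–1.5 Hz), so bias drift is removed without
touching stepping content.

All filtering is zero-lag (forward–backward), including the mocap angle
filter: phase distortion would bias peak timing, and the squared magnitude
response |H(f)|² = 1/(1 + (f/f_c)⁴) of the forward–backward 2nd-order
Butterworth is what the filter tests check against.

## Peak detection

One step cycle contributes one positive ω_peak. The detector keeps strict
local maxima above a height floor (default 30% of the series' 95th
percentile) and a prominence floor (half the height floor), then enforces a
minimum separation of 0.40 s greedily by descending height (ties to the
lower index). The separation derives from physiology: per-leg cadence below
~150 cycles·min⁻¹ implies ≥ 0.4 s between same-leg peaks. Negative
(lowering-phase) extrema are never cycle events. The detector is verified
exactly against an independently coded enumerate → filter → greedy oracle.
Parabolic refinement of a sample-level maximum uses the vertex of the
parabola through the three samples; a flat triple degenerates to the centre
sample.

## Analytical pipeline (AA)

Windows are 10 s advancing by 9 s (1 s overlap). Per window the dominant
cycle frequency f_d is the maximum-magnitude bin of the mean-centred rFFT,
0 Hz excluded, ties toward the lower frequency. During calibration each
window is filtered at every cutoff of a 0.1 Hz grid over [1, 12] Hz and the
cutoff minimizing RMS error against the synchronized reference is that
window's optimum (grid ties toward the lower cutoff — the smoother
estimate). A least-squares line through the pooled (f_d, c*) pairs is the
cutoff map; if every window shares one f_d the map degenerates to a constant
(slope 0, intercept = median c*). At deployment each window is filtered at
the clamped mapped cutoff and overlapping filtered segments are merged by a
linear crossfade over the 1-s overlap (continuous output, no amplitude
doubling; exact wherever neighbouring windows agree). The final window
extends to the signal end, so a trailing partial segment is filtered at the
last full window's cutoff rather than computing f_d on a short segment with
poor frequency resolution.

Synchronization maximizes the normalized cross-correlation between the
conditioned phone x-axis and the reference velocity over ±2 s; a peak
correlation below 0.2 flags the result as low confidence. Synchronization
precedes map fitting, since an uncorrected lag inflates the RMS criterion.

## ML pipeline

Anchored at each reference peak (detection on the x-axis anchors all three
axes), ±0.12 s windows — 7 samples per side at 60 Hz, rounding down so the
window lies fully inside the nominal half-width — are cut from the 6-Hz
pre-filtered phone axes. Features per axis: window peak, 10/25/50/75/90th
percentiles (a standard five-number spread; the percentile set is
config-exposed), mean, SD, RMS, signal energy Σv²·Δt (discretization-stable),
high-amplitude width (time above 50% of the window peak — the
duration-at-half-maximum convention), zero-crossing count, and the
parabolically refined window peak; plus the cycle duration. Windows clipped
by the signal edge are dropped and counted.

The stack: an ElasticNet (behind median imputation, standardization and
variance filtering) and a histogram gradient-boosted tree regressor produce
out-of-fold predictions under subject-disjoint folds — pure
leave-one-subject-out up to 10 training subjects, grouped K-fold (K = 10)
beyond, so the scheme scales while preserving subject independence. A Ridge
meta-learner is fitted on the out-of-fold predictions only; the bases are
then refitted on the full training partition for deployment. Isotonic
regression (non-decreasing, out-of-range queries clipped to the training
range) calibrates the stacked output, and a linear correction fitted to the
top 5% of calibrated training predictions is applied only above that
threshold, sharpening the high-magnitude peaks where filtering losses are
largest. Calibration and tail correction are fitted on the out-of-fold
stacked predictions — the standard stacking practice, avoiding the optimism
of in-sample refit predictions.

### Train/test discipline

Cycles are partitioned 70/30 at the cycle level. Membership is a
deterministic hash of (seed, subject, cycle-id) against the train fraction,
so any row's partition is computable in isolation; the realized fraction is
binomial around 0.70. The AA cutoff map is fitted only on analysis windows
whose contained reference peaks are majority-training (the window-to-
partition assignment is this package's choice; windows usually contain a mix
of both partitions under a random cycle split). The fitted map records the
training cycle ids it saw and evaluating it on any of them raises a leakage
error; similarly, passing a test-partition feature row to model training
raises immediately. Both agreement analyses use held-out cycles only.

## Agreement

Bland–Altman with normal-theory 95% limits (bias ± 1.96·SD of differences),
proportional bias as the slope (with p-value) of differences regressed on
pair means, and the correlation of |residuals| with pair means reported as a
heteroscedasticity indicator (the visual inspection such analyses usually
start from is out of scope for automated tests). Differences are oriented
reference − estimate and the orientation is recorded in the report, keeping
signs auditable: a positive bias is a phone underestimate.

## Synthetic generator

Each cycle's thigh elevation is a raised-cosine pulse
θ(τ) = θ_max/2·(1 − cos 2πτ/T): smooth, band-limited, and with the
closed-form peak velocity ω_peak = π·θ_max/T at τ = T/4. Ground-truth
per-cycle peaks come from this closed form, never from peak-picking on
sampled data, so the generator is a valid oracle for every pipeline. Cycle
durations are truncated-normal draws (floor 0.4 s) filling the 120-s test;
per-cycle peak angles carry a linear first-to-last velocity trend (the RPC
control) plus Gaussian spread.

Default session conditions (per-subject populations in parentheses): mean
cycle duration 0.84 s, SD 0.05 s within session (between subjects
N(0.84, 0.11) s); session mean ω_peak from the peak-angle amplitude
(between subjects N(303, 39) °·s⁻¹); strategy mixture ≈ 40% steady /
40% descending / 20% ascending, with steady trends within ±9 °·s⁻¹ and
ascending/descending trends beyond ±22 °·s⁻¹ so intended classes are
realizable under edge-mean noise.

The phone channel layers, in order: gain 1.0; saturating compression
v → v/(1 + κ|v|/300) with κ = 0.08, placing an ≈ 8% underestimate at the
population-mean velocity — the error size an uncorrected phone estimate
exhibits — with the 300 °·s⁻¹ scale inside the observed ω_peak range;
crosstalk fractions 0.15/0.10 into y/z (sensor–segment misalignment);
additive noise SD 8 °·s⁻¹; bias drift 3 °·s⁻¹·min⁻¹; timestamp jitter
SD 0.5 ms with increments clipped to the 58–62 Hz band; duplicate-stamp
probability 0.01; inter-device lag 0.35 s (under half a typical cycle, so
cross-correlation is unambiguous). Markers get Gaussian position noise
(SD 1 mm) and optional occlusion gaps. Recordings extend slightly past the
test (and past the lag on the phone side) so edge cycles are never clipped.

What the generator does **not** emulate: soft-tissue artifact and
hand-holding micro-slips, posture-dependent axis rotation drift,
non-stationary noise, marker mislabeling, and true 3-D out-of-plane motion.
Passing tests therefore demonstrate the pipelines' correctness and their
relative behaviour under the modelled defects — not field accuracy on real
recordings.

## Problem sizes and numerical choices

The evaluation cohort is 20 subjects (~3000 cycles, ~900 held out) and the
statistical-calibration checks use 50–200 subjects; these sizes give stable
Bland–Altman estimates while keeping the full suite fast. Tolerances: spline
resampling is exact at knots to 1e-9; filter gains are checked to 1%
absolute; the reference chain recovers closed-form peaks to 1% on
defect-free sessions; detector/oracle agreement is exact. Degenerate inputs
are defined, not undefined: constant signals have no dominant frequency
(error), an all-zero series yields an empty cycle set, a flat parabolic
triple returns its centre, a singular cutoff fit degrades to a constant map,
and a tail with under 2 points (or under 20 pairs total) disables the tail
correction.

## Known limitations

- The AA window-to-partition majority rule is one of several defensible
  readings of a cycle-level split for window-based calibration; results are
  insensitive to it on synthetic data but the choice matters for exact
  replication on real data.
- ML deployment without a motion-capture reference needs anchors from the
  phone itself (e.g. AA-filtered x-axis peaks); that extension mode is
  supported by the API (`extract_features` accepts any anchor CycleSet) but
  is not part of the validated protocol, which anchors at reference peaks.
- RPC classification uses the pragmatic ±11.5 °·s⁻¹ band; it is
  config-exposed (`RpcConfig`) because the appropriate band likely differs
  for clinical populations.
- Bland–Altman limits use the normal-theory 1.96 multiplier without
  repeated-measures correction for within-subject clustering of cycles.
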