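# Methods

This note records the models, conventions and numerical choices behind
`emgcycle`, and what the synthetic-data tests do and do not establish about
real recordings.

## Processing chain

Raw sEMG (nominally 1,024 Hz, arbitrary units) passes through five stages,
each of which tags the envelope with its stage so out-of-order application
is rejected:

1. **Band-pass filter.** 4th-order Butterworth, 20–450 Hz, applied
   forward–backward (`sosfiltfilt`). Zero-phase application is chosen
   because per-phase integrals require the envelope and the angle trace to
   share a time base; the effective magnitude response is the square of the
   designed one, which is irrelevant inside the passband and only deepens
   the stop band.
2. **Block RMS.** Non-overlapping 0.25-s windows; hop = window is what makes
   a 0.25-s window produce exactly a 4-Hz envelope from 1,024-Hz input. A
   trailing partial window is dropped. Envelope samples are timestamped at
   window centers.
3. **Oversampling.** Linear interpolation onto the 20-Hz angle grid
   (zero-order hold available via configuration); values beyond the first or
   last window center are held at the edge values, and the output length can
   be pinned to the angle trace's.
4. **Baseline correction.** A 30-sample window (1.5 s at 20 Hz) estimates
   the quiet-period statistics; the offset is its mean − 3·SD, subtracted
   with negatives clamped to zero. The window is placed where the 30-point
   running mean is minimal — the quietest stretch of the record — rather
   than centered on the single lowest sample. On noisy envelopes the
   pointwise minimum regularly falls at a burst edge mid-movement; a window
   centered there straddles burst flanks, its SD explodes, and mean − 3·SD
   turns negative, which would *raise* the whole envelope. The quietest-
   window placement implements the same rule robustly and reduces to the
   same answer whenever a genuine quiet stretch exists. Note the rule
   deliberately undershoots: the corrected envelope retains a floor of about
   3·SD of the quiet noise, by design.
   Correction is applied to the 20-Hz stream (the stream every metric
   consumes); 30 samples at 20 Hz require only 1.5 s of quiet data, which a
   recording's lead-in provides.
5. **Normalization.** Division by the recording's per-muscle maximum after
   baseline correction. The result is dimensionless in [0, 1] and invariant
   to any positive rescaling of the raw channel (gain, electrode impedance),
   which is the property that makes between-subject CC comparisons
   meaningful without an MVC reference. All-zero envelopes pass through.

## Kinematics and segmentation

Angular velocity uses central differences (one-sided at the record edges).
Flexion peaks are local maxima with prominence ≥ 20% of the trace's range;
when the metronome rate is known, peaks closer than half the nominal cycle
period are suppressed. Both thresholds are configurable. Because the
protocol starts at maximum flexion, the record's opening is accepted as a
peak when it dominates the first stretch; it is placed at movement onset
(the end of any initial resting plateau). The trailing edge is never
counted, so the final return to flexion opens a partial cycle that is
discarded — ten metronome repetitions yield nine complete analyzed cycles.
Plateau peaks resolve to their first sample; ties at extrema to the earliest
sample (determinism).

Within a peak-to-peak cycle the extension trough is the angle minimum; each
half-cycle splits at its angular-speed extremum into an acceleration phase
(angle extremum → speed extremum) and a deceleration phase (speed extremum →
next angle extremum), giving the order Acc_Ext → Dec_Ext → Acc_Flex →
Dec_Flex. The four half-open intervals partition the cycle exactly; a
half-cycle without an interior speed extremum excludes its cycle with a
warning. ROM summaries average the per-cycle landmark angles (each cycle's
own flexion peak and extension trough, so consecutive cycles do not share a
boundary sample); dispersion is the mean pointwise SD over 100-point
time-normalized cycles.

## Metrics

Integrals use the trapezoidal rule on the 20-Hz grid. A phase interval
[start, end) is integrated over the closed panel span start..end, so the
four phase integrals sum exactly to the cycle integral and CC computed from
concatenated phases equals the full-cycle CC. The common area is the
integral of the pointwise minimum of the two envelopes. Segments where both
areas are zero define CC = 0 rather than NaN so quiet phases do not poison
aggregates; results are clamped to [0, 100]. CC is symmetric in its
arguments; the agonist label (biceps in flexion, triceps in extension)
affects only reporting.

Synergy uses the per-muscle denominator by default — each muscle's flexion
and extension areas as percentages of that muscle's total cycle area, so
the two shares sum to 100 — because it isolates *when* a muscle is active
independently of between-muscle scaling. The complementary between-muscle
share (biceps % of the two-muscle area within each half-movement) is also
emitted. A muscle silent over a whole cycle yields missing values.

## Factorial model

The observational unit is the mean CC per subject × speed × phase cell
(20 × 3 × 4 = 240 cells for the default study). The model
`cc ~ C(phase) + C(speed) + C(phase):C(speed)` is fitted by OLS with type-II
sums of squares — identical to type I/III on a balanced design and robust to
the mild imbalance left by discarded cycles. Tukey HSD controls the FWER at
α = 0.05 with group sizes taken from the data. Cohen's f defaults to the
partial-η² form f = √(SS_effect/SS_error); an η²-based variant is available
and every result records which variant produced it, because published
effect sizes do not always state theirs and the two differ whenever other
effects absorb variance. Degenerate data (all observations equal) define
F = 0, p = 1 instead of a 0/0 ratio. A null-simulation helper
(`null_rejection_rate`) audits the type-I error calibration; with iid
Gaussian cells the phase test rejects at the nominal 5%.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
muscle physiology:

- **Angle.** Raised-cosine half-cycles between +75° and −60°, one metronome
  beat per half-cycle (a full cycle lasts 2·60/bpm s — plausible angular
  velocities of roughly ±150–300 deg/s across 42–78 bpm), multiplicative
  half-cycle jitter (CV 0.05 by default), and a 2-s rest hold at maximum
  flexion before and after the movement. The rest hold mirrors a real
  session's lead-in/lead-out and gives the baseline rule the quiet stretch
  it presupposes.
- **Activation.** One smooth (Hann) agonist burst per half-cycle — biceps in
  flexion, triceps in extension — with burst width equal to the half-cycle;
  antagonist activity is a per-phase fraction r of the agonist profile, plus
  a constant tonic triceps component (0.05 of peak) standing in for gravity
  compensation, plus an additive band-limited sensor-noise floor (RMS 0.03
  of peak) in the raw signal. Because antagonist = r·agonist within a phase,
  the analytic per-phase CC is 200r/(1+r); the default fractions invert that
  relation at the pooled per-phase CC levels reported for healthy adults
  (Dec_Flex 36.66 > Acc_Flex 28.07 > Dec_Ext 27.9 > Acc_Ext 19.54 %), so the
  default cohort reproduces that phase ordering. Sharp fraction steps at
  phase boundaries are a deliberate simplification.
- **Raw sEMG.** Unit-RMS Gaussian noise band-passed to 20–450 Hz, amplitude-
  modulated by the activation envelope upsampled to 1,024 Hz; the analysis
  filter is then near-transparent. Deterministic given (protocol, model,
  seed) via spawned generator streams.
- **Cohort.** Each subject receives one log-normal multiplier (σ = 0.25) on
  all antagonist fractions — subjects differ in overall coactivation level —
  plus small per-phase perturbations (SD 0.015); no speed effect is
  injected, matching the healthy-adult finding that coactivation depends on
  phase but not on pace.

**Ground truth** is computed from the noise-free activation envelopes with
the pipeline's own conventions (quiet-window baseline — which removes the
tonic component exactly in the noiseless limit — peak normalization,
trapezoidal integrals, the same phase spans), making it the analytic target
the noisy pipeline estimates.

## What the synthetic tests show — and their known biases

Passing recovery tests show that conditioning, segmentation and the metric
conventions are mutually consistent and that noise alone costs little
accuracy. They do not validate electrode placement, motion artifacts,
fatigue, trunk compensation, or real activation waveforms (the generator's
bursts are stylized and its antagonist ratios piecewise constant).

The measurement chain carries reproducible biases that an analytic ground
truth cannot absorb, quantified by ablation on the default conditions:

- The baseline rule's designed 3·SD floor, the quadrature composition of
  activation with the sensor floor in an RMS reading, and Jensen-type
  inflation of small envelopes under block RMS together read the flexion-
  phase antagonist ≈ +0.015 normalized units above the analytic truth.
  Because a phase CC divides a small antagonist area by a large agonist
  area, this maps to roughly +5 CC points in Acc_Flex (+2.5 in Dec_Flex);
  with the tonic component removed from the generator the bias collapses to
  under one point.
- A 0.25-s RMS window covers a growing fraction of the quarter-phase as
  pace increases (≈ 1.5 windows per quarter-phase at 78 bpm), smearing
  adjacent agonist bursts across movement turnarounds. The net bias
  therefore grows with metronome rate (≈ 3 CC points between 42 and 78
  bpm), which in a clean 240-cell synthetic study makes the *speed* factor
  statistically significant even though no speed effect is generated. Real
  between-subject variability (published SDs of 10–16 CC points) dwarfs
  this; interpret synthetic speed contrasts accordingly.
- Phase ordering and between-phase contrasts are recovered robustly at
  every seed examined; absolute per-phase levels in flexion should be read
  with the above offsets in mind.

## Problem sizes and defaults

The default study (20 subjects × 3 speeds × 10 cycles ≈ 60 trials of ~24–31
s each) runs the full pipeline in well under a minute on one core; the
type-I calibration uses 1,000 replicates of the 240-cell design. All
tunables live in `PipelineConfig` (YAML-serializable, validated at load
time); every module constant above is its default there or in the generator
dataclasses.

## Limitations

Single-joint, two-muscle analysis only; no notch filtering or artifact
rejection; no repeated-measures or mixed-effects modeling (cells are
treated as independent, as in a plain two-way ANOVA); the export format of
the original acquisition device is unknown, so only the documented CSV
interchange format is read and `io.load_study_export` is an explicit,
unimplemented hook.
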