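# Methods

## The measurement problem

Positional compression at the thoracic outlet can trap venous blood in
the upper limb while arterial inflow continues. If venous return
falls, cardiac preload falls, and heart rate is expected to rise to
compensate. The pipeline quantifies three things from a provocative
"surrender + prayer" manoeuvre: whether each limb's artery stays open
(arterial pulse amplitude), whether each forearm empties normally on
elevation (venous PPG), and how heart rate responds per manoeuvre
phase in patients with bilateral venous entrapment versus patients
with no vascular compression.

The phase timeline is fixed: Rest [−5, 0) s (arms down, calibration),
Su [0, 30) s (90° abduction), Pra [30, 45) s (arms raised in front —
elevation without costoclavicular compression, used as the arterial
normalization reference), End [45, 55) s (arms lowered). Time zero is
the start of arm elevation. Samples within ±2 s of each movement onset
are excluded from all phase statistics; movement artifacts occur
systematically at elevation and lowering, and the ±2 s halfwidth is a
package choice (the clinical convention marks the bands but not their
width).

## Synthetic cohort generator

The generator is first-class, tested code; it defines the study
conditions under which everything downstream is validated.

**Heart rate.** HR(t) = baseline + sustained phase offset +
exponentially decaying transients at each movement onset + white
jitter, floored at 1 bpm and sampled at 10 Hz. Default group
parameters are the study-population summaries: venous group baseline
81.5 (SD 10.1) bpm with sustained offsets Su +6.9 (7.1), Pra +7.2
(8.4), End +6.3 (6.9) bpm; control group baseline 84.9 (13.4) with
offsets +1.9 (4.2), +4.3 (5.8), +4.1 (6.1). The transient amplitude
defaults to 4.1 bpm in both groups: the observed transition peaks
(~11 bpm above baseline in the venous group, ~6 in controls) are the
sustained Su offset *plus* the transient, so a common ~4 bpm surge
reproduces both. Transient and venous time constants default to 2 s.
Beat-to-beat jitter defaults to SD 1.5 bpm.

**Beats and arterial waveforms.** Beat onsets come from
integrate-and-fire on HR/60 (threshold 1, crossings refined on a 1 kHz
grid) — invertible at zero jitter, so beat-count conservation is
exact. Each cycle carries a two-Gaussian systolic/dicrotic template
(peak at 30% of the cycle, range-normalised to [0, 1]); any smooth
unimodal-per-beat shape would do, this one is conventional. The
fingertip amplitude envelope is phase-wise constant: rest amplitude ×
1.2 during Su and Pra for normal limbs (elevation physiologically
raises pulse amplitude), × ~0.05 during Su for the
arterial-compressed phenotype (with a normal Pra response — the Pra
position relieves the compression, which is why it serves as the
normalization reference). The earlobe amplitude is
positional-invariant. A slow 0.05 Hz drift plus a DC offset sits under
the pulsatile component, which is what the high-pass stage removes.

**Venous channels.** First-order exponential approach (τ = 2 s) to a
phase target: 0 at Rest, the subject's emptying plateau during Su and
Pra, back to 0 (refilling) at End, plus a constant device baseline.
First-order emptying is the standard plethysmographic assumption; no
kinetics are specified clinically. The full-emptying reference (20
a.u.) is carried per limb in the recording metadata, mirroring the
device calibration a clinic would provide — the 70%/87% thresholds are
only meaningful against a subject-specific full-emptying scale.

**Noise.** Additive Gaussian noise (arterial SD 0.02 at unit rest
amplitude ≈ 2%; venous SD 0.05 a.u.), a Hann-windowed motion-artifact
burst (duration 1.5 s, amplitude 4× rest amplitude) at every movement
onset, and 0.5% sample dropout. The "uninterpretable" phenotype has
zero arterial amplitude — a detached or pulseless sensor.

**Phenotype distributions.** Per-group truncated normal draws. The
venous group's emptying plateau centres at 55% (truncated ≤ 63.5), the
control group at 95% (≥ 92.5), the grey zone at 78% (76–81), the
arterial-compressed Su amplitude factor at 0.05 (0.02–0.08). The
truncations keep every measured limb metric ≥ 5 points from the
25/70/87 thresholds, which is what makes the classification-count
recovery a sharp test: the measured remaining pulsatility of a
collapsed pulse reads ~10–14 points above its generating factor,
because the trailing 10-point smoother inevitably drags rest-level
amplitudes into the early elevation window and additive noise inflates
tiny peak-to-trough readings. That bias is a property of the published
measurement procedure, not of this implementation, and the generating
distributions are placed so that phenotypes remain separated under it.

**What the generator does not emulate.** Respiratory modulation, HR
variability structure (the jitter is white), baroreflex dynamics,
SpO₂, pulse-wave morphology changes, unilateral/mixed phenotypes (the
classifier handles them; the default cohort contains none), and
pain-driven sympathetic activation. Passing tests therefore show that
the pipeline recovers what this signal model encodes — not that it is
robust to every failure mode of real optical recordings.

## Signal processing choices

* **High-pass filter**: order-2 Butterworth, 0.5 Hz cutoff, applied
  forward-backward (zero phase). 0.5 Hz separates venous/DC drift from
  the cardiac band down to 30 bpm; the cutoff is configurable.
* **Beat detection**: the filtered signal is divided by a rolling 3 s
  RMS estimate (so amplitude collapse does not starve the detector),
  then local maxima with minimum spacing 60/220 s and unit prominence
  on the normalised scale. Peak times are refined to sub-sample
  precision by a parabolic fit (the 8 ms grid would otherwise
  quantise inter-beat intervals by ~1 bpm). A channel with no
  autocorrelation peak in the 0.25–2 s lag band in any 10 s slice
  (threshold 0.25) is pulseless and raises an uninterpretability
  error; so does a detection whose inter-beat intervals are mostly
  outside 25–230 bpm. The first detected peak anchors the second
  beat's cycle and is not itself reported (its trough window would be
  truncated by the record edge, biasing its amplitude low).
* **A_pulse**: per-cycle peak minus the minimum between consecutive
  peaks, evaluated on the full 125 Hz grid; trailing 10-point moving
  average (the first nine values average the available points).
  Trailing rather than centered: causal and reproducible; the two
  differ only at window edges, outside every analysis window. Beats
  inside the transition exclusion windows are dropped *before*
  smoothing in the pipeline — artifact bursts otherwise masquerade as
  high-amplitude beats inside the trailing windows of valid beats.
* **Amplitude windows**: rest [−20, −5] s when the recording has the
  long pre-roll, else the [−5, 0) calibration tail (the canonical
  synthetic timeline starts at −5 s); Su [5, 20] s; Pra [35, 40] s.
* **Venous emptying**: rest-window mean subtracted (calibration is
  idempotent); a 0.5 s median prefilter suppresses single-sample
  spikes before the Su∪Pra maximum (the raw maximum is
  spike-sensitive); negative maxima clamp to 0.
* **HR export**: HR = 60/IBI assigned at beat-pair midpoints, sampled
  onto a 0.4 s grid (first point exactly −5.0 s) by previous-value
  hold — tachogram semantics; the difference from interpolation is
  negligible at 0.4 s. Samples outside the first/last midpoint are
  invalid.
* **HR repair**: a sample is invalid when missing, outside 30–220 bpm,
  or deviating > 20 bpm from a rolling 5 s median of the series.
  (A naive sample-to-sample step rule either cascades after a spike or
  locks onto a gradual artifact ramp; the rolling-median reference
  applies the same 20 bpm threshold without either failure mode.)
  Interior runs are linearly interpolated, edge runs take the nearest
  valid value; > 50% invalid samples make the recording
  uninterpretable. The repair is idempotent.
* **Normalization**: the rest median is computed over the same sample
  set the phase summaries use (valid, transition-excluded rest
  samples), which makes the Rest phase median exactly zero by
  construction. The 6 s display smoother is a centered moving median
  (robustness-consistent with the median-based normalization) and is
  never used for statistics.

## Classification

Strict inequalities exactly as the screening rules are stated:
arterial compression if remaining pulsatility < 25% (this rule
dominates, because an occluded artery invalidates the venous emptying
reading); else venous compression if emptying < 70%; else normal if
emptying > 87%; else grey zone. Boundary values (exactly 25, 70, 87)
therefore fall on the non-compressed / grey-zone sides. V-group
requires bilateral venous compression; C-group bilateral normal limbs;
any uninterpretable limb excludes the patient, as does any arterial or
grey-zone limb or a mixed venous/normal pattern.

## Statistics

Per-patient per-phase medians of normalized HR enter a linear mixed
model with group, phase and their interaction as fixed effects and a
random intercept per patient, fitted by REML (statsmodels MixedLM
behind the module surface). Rest rows (identically zero) are retained
so the Rest contrast appears in the output; their degenerate variance
is noted in the diagnostics. A singular or non-converging fit falls
back to OLS for the fixed effects — relevant only for noise-free
fixtures — and is flagged, never fatal. EMMs are fixed-effect design
rows times the coefficient vector; on complete balanced designs they
equal raw cell means (tested to 1e-6).

Contrasts: V−C within each of the 4 phases, and the 6 phase pairs
within each group. Holm step-down adjustment is applied within three
families (4, 6, 6) by default, matching the default behaviour of
pairwise-EMM machinery per comparison set; a single 16-contrast family
is available as an option. Degrees of freedom use the residual method
(n_obs − n_fixed = 156 for a 41-patient cohort); the study's
fractional df values imply a Satterthwaite-type approximation whose
exact reproduction is out of scope — estimates and standard errors,
not df, are the recovery targets. A zero-standard-error contrast
(possible only on degenerate fixtures and the Rest row) reports p = 1
when the estimate is 0 and p = 0 otherwise. Shapiro residual normality
and Levene cell-homogeneity statistics are reported, never used to
gate the fit.

## Problem sizes and runtime

The acceptance script simulates one 116-patient cohort for the
classification counts and 20 replicate 41-patient cohorts for the HR
effect recovery (about 2,500 s of five-channel signal per cohort);
the whole script runs in well under a minute on one core. The test
suite's heaviest case is the same 20-replicate recovery. Replicate
averages of the Su−Rest and between-group contrasts carry a small
positive residual (~0.2–0.4 bpm) from the decaying HR transient that
survives the ±2 s transition exclusion inside the Su phase — the same
contamination any median over the full phase would show.

## Known limitations

* Venous emptying percent is referenced to a device-style per-limb
  calibration value; if a clinic instead normalised to the subject's
  own observed maximum, absolute percentages would differ.
* The uninterpretability gates (autocorrelation threshold, IBI
  plausibility, > 50% invalid HR) are calibrated on the synthetic
  signal model; real-world failure modes are more varied.
* The mixed model assumes homoscedastic residuals across cells while
  the Rest column has zero variance by construction; this mirrors the
  analysis design but slightly deflates residual variance.
* Amplitude metrics inherit the trailing-smoother phase-boundary bias
  discussed above; comparisons between conditions are unaffected
  because the bias is shared, but absolute remaining-pulsatility
  values near a threshold should be read with that in mind.
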