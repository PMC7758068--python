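# Methods

This note documents the models, parameter choices, and numerical decisions
behind `nvsleep`, and what its synthetic-data tests do and do not establish
about real recordings.

## Signal conditioning

All filtering is zero-phase (forward–backward `sosfiltfilt`), so stated
Butterworth orders are one-pass orders and the effective attenuation is
doubled. Resampling is polyphase and anti-aliased; linear interpolation is
used only to fill dropped camera frames. Derived channels share a 30 Hz
analysis rate.

Band power: 3rd-order bandpass at the band edges, pointwise square, 3rd-order
lowpass < 10 Hz, resample to 30 Hz. Low bands are band-passed on an
anti-alias-decimated copy of the raw signal (decimation target ≥ 6× the
band's upper edge); the decimation filter removes only content the bandpass
rejects, so the output is unchanged while the cost becomes independent of the
20 kHz acquisition rate. The same argument licenses smoothing the squared EMG
at 300 Hz before the 0.5 s Gaussian kernel. EMG conditioning adds a
configurable floor (default 1e-12) before the log to keep silent stretches
finite.

Gamma band edges are 30–100 Hz throughout (the scoring feature uses the same
band; a 99 vs 100 Hz upper edge is immaterial at these spectral resolutions
and the 100 Hz value is used consistently).

Drift correction fits `a·exp(−t/τ₁) + b·exp(−t/τ₂) + c` to a reference
region without hemodynamic signal (cement), falling back to a single
exponential with a warning if the fit does not converge. The correction is
multiplicative — reflectance divided by the fit normalized to its
first-minute mean — matching a light-source/camera-gain mechanism and
preserving the input's initial level.

Beer-Lambert conversion: ∆[HbT] = −ln(1 + ∆R/R)/(ε·X) in µM, with defaults
ε = 39 036.4 M⁻¹cm⁻¹ (total hemoglobin at the 530 nm isosbestic point) and
X = 0.037 cm photon pathlength, both config-exposed. Their product
(≈ 1444 cm⁻¹·M⁻¹·cm) is what the data constrain; a −2.4 % reflectance change
maps to +16.8 µM. Only total hemoglobin is computed; 530 nm is isosbestic,
so no oxy/deoxy separation is attempted.

## Multitaper estimation

Slepian tapers with pairs written (TW, K), K ≤ 2TW−1 (violations are clipped
with a warning). `pad_level = p` pads FFTs to `2^(ceil(log2 N)+p)`; the
default analyses use (3, 5) tapers with pad 1, spectrograms use (5, 9) or
(1, 1) per their stated window/step. Coherence averages cross- and
auto-spectra over tapers and equal-length trials before forming MoC², giving
dof = 2·K·n_trials and the analytic 95 % null level
`1 − 0.05^(1/(dof/2−1))`. Heart rate is the per-frame argmax of spectral
power in 5–15 Hz (ties toward the lower frequency, for determinism) from a
3.33 s / 1 s multitaper spectrogram of each hemisphere's reflectance,
averaged across hemispheres, interpolated to 30 Hz, and lowpassed < 2 Hz.

## Image analysis

Whisker angle: frames are inverted (whiskers bright), Radon-projected over
0–179° in 1° steps with a ±1° refinement at 0.1°, and the projection angle
of maximal sinogram variance converted to a from-horizontal,
protraction-positive angle (the sign convention is ours; the tracker is
validated on rendered lines to ±1°). Dropped or uniform frames are filled by
linear interpolation; blank runs > 1 s are flagged and excluded from whisk
detection.

Whisking/movement binarization thresholds are "empirically chosen" in
practice; the reproducible default here is 10× the median absolute deviation
of the signed acceleration (or centered force) trace, ≈ 6.7 σ of quiet
noise. At 5× MAD a Gaussian quiet trace crosses threshold every ~20 s of
session, fragmenting rest detection; 10× produces no spurious crossings at
any session length while remaining far below genuine whisking acceleration.
Supra-threshold samples within 0.1 s are linked into one bout. Note that with
gap-linking the bout count is not globally monotone in the threshold
(raising it can split a linked bout); it is monotone for isolated events.

Vessel diameters: pial vessels by FWHM of the box-averaged cross profile
(half-max level `(max − baseline)/2 + baseline`, baseline = mean of the outer
10 % of the profile, linear interpolation at the crossings; scale-invariant
by construction). Penetrating vessels by thresholding in Radon space: median
background subtraction, Radon transform over 0–179°, per-projection threshold
at 0.5 of each projection's maximum, unfiltered backprojection, re-binarize
at 2/3 of the reconstruction maximum, equivalent diameter `2√(A/π)` of the
largest connected component. The 2/3 image threshold is exact for a uniform
circular lumen: half-maximum strips of a disk of diameter d are (√3/2)·d
wide, and the fraction of projection angles whose strip covers a point on
the true boundary is (2/π)·asin(√3/2) = 2/3. A ramp-filtered reconstruction
thresholded at 0.2 — sometimes quoted for this algorithm — underestimates
uniform-disk diameters by ~20 % because the projection half-max strips are
narrower than the lumen and edge ringing dominates the reconstruction
maximum; both thresholds are config-exposed. Diameter traces are smoothed
with a 10-sample median filter (even windows average the two central order
statistics; edges shrink the window).

## Sleep scoring

Seven features per non-overlapping 5 s bin: cortical delta, beta, and gamma
band power (each the larger of the two hemispheres' bin means), hippocampal
theta, EMG log-power, heart rate, and binarized whisk count. The classifier
is 128 bagged decision trees (bootstrap aggregation; tree hyperparameters at
the ensemble library's defaults) with out-of-bag error, compared against the
mean OOB error of 100 label-shuffled training sets. Under shuffling, bagged
voting is biased toward the majority class, so the shuffled error lies
between `1 − max(p)` and the matching-by-chance value `1 − Σp²`; the two
coincide for balanced mixes. Training mirrors the manual-scoring protocol:
alternating 15-minute blocks, train on one half, validate on the other.

Contiguity: REM gaps ≤ 2 bins (10 s) are bridged first — but never across a
run that itself qualifies as contiguous NREM — then runs of ≥ 6 NREM bins
(30 s) or ≥ 12 REM bins (60 s) become contiguous epochs; epochs overlapping
a whisker stimulus are excluded.

## Events and summaries

Event classes: awake rest (≥ 10 s, no whisking/movement/stimulation, inside
manually flagged true-awake periods, ≥ 5 s post-stimulus), whisking bouts by
duration (0.5–2, 2–5, > 5 s, same screening), stimulation, contiguous
NREM/REM, and non-overlapping 15-minute alert/asleep/all windows (≥ 80 % of
bins of the target class, no stimulation). Summaries use the < 1 Hz
4th-order zero-phase lowpassed signal; whisking summaries subtract the 2 s
pre-onset mean over an onset→+5 s window; stimulus summaries average
+1→+2 s. Baselines are daily scalars over qualifying rest; if less than 60 s
qualifies, the quietest decile of 5 s bins is used and flagged.

Probability curves: state probability vs session time (averaged across
sessions, single-exponential fit `a·exp(−t/τ) + c`, robust soft-L1 least
squares, initialization a = range, τ = duration/3, c = final value; flat
curves are flagged unidentifiable); probability of staying awake vs
quiescence duration (events binned by duration into 5 s bins — a 7.5 s event
falls in the 5–10 s bin — and marked asleep if any overlapped bin is
NREM/REM); state probability vs binned signal value (1 µM or 1 % bins,
10-point median smoothing, empty bins propagate as NaN).

## Coupling

Per event class, both signals are truncated to the class minimum duration
(10/30/60/900 s), mean-subtracted, and lowpassed < 1 Hz (4th order) before
cross-correlation (±5 s lags, normalized so a pure delay peaks at 1;
positive lag = hemodynamics follows neural activity), Pearson correlation,
or trial-averaged coherence. Frequency read-outs below the inverse event
duration are refused with the minimum resolvable frequency stated.
Aggregation is always within subject/hemisphere first, then across subjects,
with the unweighted mean.

## Mixed-effects comparisons

Gaussian linear mixed models (the responses are continuous; identity link)
with a fixed arousal-state effect and random intercepts for subject and
subject:unit (hemisphere or arteriole), REML-estimated; Wald z-tests against
the chosen reference state, labeled as such. A singular subject:unit variance
(boundary at zero) triggers a flagged fallback to the subject-only
intercept. No multiple-testing correction is applied by default (per-contrast
p-values are reported); a Holm option exists. Calibration: at a null with
14 subjects × 2 units × 5 events per state, the empirical type-I rate over
500 replicates falls within [0.03, 0.07] at α = 0.05.

## The synthetic session generator

The generator emulates the statistical structure the analysis assumes, not
the biophysics of cortex:

* **State sequence** — semi-Markov chain on 5 s bins: minimum dwell (AWAKE 1,
  NREM 6, REM 12 bins, mirroring the epoch definitions) then row-stochastic
  transitions. Direct AWAKE→REM is 0 by default. Default matrix rows
  (AWAKE, NREM, REM): [.92 .08 0], [.10 .88 .02], [.30 0 .70], giving
  stationary occupancy ≈ 44/47/9 % — a mouse that sleeps readily under
  head fixation. The analytic occupancy (jump-chain eigenvector weighted by
  expected dwell) is exposed for tests.
* **Slow drive** — per hemisphere, a unit-variance Gaussian process lowpassed
  < 1 Hz, mixed as `m_h = √s·m₀ + √(1−s)·u_h` with shared-variance fraction
  s (default 0.75 awake, 0.90 in sleep). Anything linear in the drive then
  has bilateral Pearson r ≈ s and squared coherence ≈ s².
* **Neural channels** — sums of unit-variance band-limited noise with a
  1/f-flavored base profile and per-state variance gains (NREM: delta ×4;
  REM: hippocampal theta ×4, cortical gamma ×2, delta ×0.5). The gamma and
  MUA amplitudes are modulated by the envelope `e_h = 1 + 2·depth·m_h`
  (depth 0.25) plus awake whisking/stimulus bumps, so measured gamma band
  power fluctuates with the drive.
* **Hemodynamics** — ∆[HbT]_h = state offset (0 / 32.2 / 77.1 µM) +
  5 µM × standardized HRF⊗m_h + 10 µM × 0.1 Hz sinusoid gated to NREM
  (common across hemispheres) + evoked responses (whisking ~4 µM,
  stimulation ~16.8 µM at full drive) + 1 µM white noise. The HRF is a
  gamma-shaped kernel parameterized by peak lag (1.2 s) and width (0.4 s
  SD); the narrow width keeps the cross-correlation peak — the kernel
  convolved with the drive autocorrelation — within ~0.05 s of the kernel
  mode, and matches the fast hemodynamic responses of awake mice. The HRF is
  driven by the latent gamma envelope (the expectation of the measured band
  power) rather than the measured trace, which would inject chi-square
  estimation noise into the hemodynamics and attenuate the shared-variance
  fraction; the measured trace still carries the same envelope, so the lag
  is recoverable from data the pipeline actually computes.
* **Reflectance** — `R = R₀·exp(−εX·∆[HbT])` × two-exponent drift
  (amplitudes 2 %/3 %, time constants 300/3000 s) × (1 + 1 % cardiac
  modulation at the state-dependent heart rate: 9.5/7.5/9.0 Hz) + noise. A
  cement reference ROI channel carries the drift alone, so drift correction
  and Beer-Lambert inversion recover the latent ∆[HbT] (exactly, with noise
  terms off).
* **Behavior** — whisking bouts as Poisson events per state (0.10/0.01/0.03
  bouts/s; declared, not fitted — no quantitative per-state bout statistics
  are available to fit) rendered as 8–14 Hz oscillations of ~12° on the
  whisker-angle channel; movement bouts (0.05/0.005/0.01 /s) as lowpassed
  bursts on the force channel; EMG variance gains 1/0.1/0.02 (atonia deepest
  in REM).

What the generator does **not** emulate: biophysically structured LFP
(waveforms, cross-frequency coupling, spindles), eye/pupil signals,
multi-day sleep pressure (a drift hook exists but is off), spatially
structured image noise, electrode artifacts, and state-transition dynamics
slower than the ~1–2 s smoothing applied to offsets. Passing recovery tests
therefore demonstrates that the pipeline's estimators are correct and
calibrated on data satisfying their assumptions — not that classification
accuracy or coupling strengths will match any particular animal.

Whisker camera frames are rendered at 30 × 350 px (dark lines on a bright
background) only for tracker validation; full sessions carry the angle trace
directly. Vessel fixtures (Gaussian/plateau profiles, disks, ellipses) are
synthetic stand-ins for two-photon frames.

## Problem sizes used in validation

Parameter-recovery tests run on a one-hour session at generator defaults
(20 kHz raw channels, fixed seed), conditioned end to end; classifier
validation uses alternating 15-minute train/test blocks within that hour and
100 shuffled baselines; the mixed-model calibration uses 500 null replicates
of a 14-subject × 2-unit design; image oracles use a 91-point angle grid and
disks of 20–60 px. These sizes were chosen so the full suite exercises every
stage at realistic signal-to-noise.

## Determinism

Every stochastic component takes an explicit seed (`numpy` Generator);
sessions are bit-identical for a fixed seed, and pipeline reruns write
byte-identical CSV/JSON outputs. Heart-rate argmax ties break toward the
lower frequency; the ROI tie-break on degenerate stacks is the lowest
row-major index, flagged low-confidence.
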