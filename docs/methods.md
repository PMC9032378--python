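# Methods

This note documents the models, signal-processing conventions, parameter
choices and known limitations of the `ecochg` package.

## Signal model

A monitoring stimulus (53 ms sinusoidal tone burst, 500 Hz, ~110 dB SPL) is
presented repeatedly with alternating polarity while the electrode array
advances over 1–2 minutes.  Each response buffer, digitised at 9,280 Hz in
electrode-referred microvolts, is modelled as

```
buffer = ± CM + nuisance + noise
```

* **CM** — the cochlear microphonic: a sinusoid at the stimulus frequency
  whose amplitude and phase follow a latent insertion trajectory, and whose
  sign flips with stimulus polarity.
* **nuisance** — a polarity-invariant transient standing in for neural and
  summating contributions; by default a damped 1 kHz onset burst at 20% of
  the local CM amplitude.  It is evaluated at the pair's emission time for
  *both* buffers of a pair, so polarity subtraction cancels it exactly; this
  is what makes the cancellation property assertable to machine precision on
  noiseless streams.
* **noise** — white Gaussian, per-sample SD `σ = floor · sqrt(2N/π)` with
  `N = 464` window samples, calibrated so the mean single-pair spectral
  noise-floor estimate equals the configured floor (the bin magnitude of
  white noise is Rayleigh with mean `σ_d·sqrt(π/N)`, and the difference of
  two independent buffers halved has per-sample SD `σ/√2`).

### Buffer geometry

Buffers are 512 samples (55.2 ms, containing the 53 ms burst); one buffer is
emitted every 62.5 ms, so an alternating pair takes 125 ms and a strong
response yields 8 monitoring points per second.  The analysis window is the
central 464 samples: at 9,280 Hz that is exactly 50 ms, giving 20 Hz bin
spacing with 500 Hz exactly on bin 25.  An on-bin stimulus leaks nothing, so
a rectangular window without zero padding is used and no tapering decisions
affect accuracy.  The dB SPL → µV transfer function of real hardware is
unknown and unneeded (only relative amplitudes matter); 110 dB SPL maps to
the configured CM amplitude.

## Extraction conventions

* **Difference average:** `(condensation − rarefaction)/2`, keeping CM
  amplitudes in physical microvolts.
* **Spectrum:** single-sided, normalised so a unit-amplitude on-bin sinusoid
  reads magnitude 1 (DC/Nyquist not doubled).
* **Phase:** argument of the stimulus bin in degrees in (−180, 180],
  relative to the analysis-window start; a quarter-period delay reads −90°.
  The synthesiser uses the same reference, so latent phase is recovered
  directly.
* **Noise floor:** mean magnitude of 3 bins on each side of the stimulus
  bin, skipping 1 guard bin ("a few surrounding bins" quantified as a
  configurable default), clamped to 1e−12 µV so SNR stays finite.
* **SNR:** amplitude-ratio dB, `20·log10(amplitude/floor)`; the dB
  convention is configurable in effect through the thresholds.
* **Stopping rule:** strict arithmetic running mean over pairs; stop at
  SNR ≥ 12 dB or 40 pairs, whichever first.  A point's time is the
  acquisition time of its first pair.  Since the floor of an `n`-pair
  average falls as `1/√n`, SNR grows ≈ `10·log10(n)` dB: a signal with 6 dB
  single-pair SNR stops near 4 averages.

## Detection margin for trace-level decisions

`EcochgPoint.above_floor` is the plain bookkeeping flag SNR > 0 dB.  It is
*not* used for classification decisions: for a noise-only bin the magnitude
is a Rayleigh draw that exceeds the mean-of-surrounding-bins floor with
probability `exp(−π/4) ≈ 0.46`, and because the stopping rule inspects the
running SNR after every pair, even a 12 dB margin is crossed by pure noise
at ~2% per point (the reported SNR is effectively maximised over up to 40
looks).  Classification therefore uses:

* a point is *detectable* at SNR ≥ `detect_snr_db` (default 12 dB, matching
  the stopping rule — any point that satisfied the stopping rule passes);
* a trace *has a response* only when `detect_run_points` (default 3)
  consecutive points are detectable (noise fakes this with probability
  ~1e−4 per trace);
* a trace *ends with a response* only when its final `detect_run_points`
  points are all detectable;
* phase is missing below the margin and at isolated detectable points
  (which, in silence, carry uniform random phase), and is never
  interpolated.

## Latent trajectories

Amplitude courses are built in dB on a 125 ms grid:

* **growth** — linear rise of 12 dB to the peak at the end of insertion,
  forced monotone non-decreasing after sub-dB jitter (SD 0.15 dB, clipped to
  ±0.45 dB).
* **fluctuating / total loss** — rise to the peak at 25% of the insertion
  (closest approach to the generator), then a gentle 2 dB decline; this
  makes the clinical min-after-max landmark sensitive to later dips, which a
  monotonically rising course cannot be.  Dips are Gaussian in dB (width
  parameter 3 s, σ = 1.5 s); the amplitude at a dip's centre is exactly
  `10^(−depth/20)` times the drop-free course.  Requested phase shifts ramp
  linearly across the falling flank of the dip, completing before the
  trough (where deep dips can fall below the detection margin) and holding
  afterwards.
* **total loss** — additionally decays from 72% of the insertion to 26 dB
  below the noise floor by 90%, staying there; **no response** sits 26 dB
  below the floor throughout.

Cohort defaults: peak amplitudes log-uniform over 30–150 µV (within the
clinically observed ~5–200 µV span; the lower bound keeps early-insertion
points far enough above the detection margin that measurement noise cannot
mimic a 5 dB drop), insertion durations uniform 90–120 s, 1–3 dips per
fluctuating trace with depths 8–20 dB, shifted dips at 135–215° and
unshifted at 0–15° — all at least 3 dB (amplitude) or 45° (phase) clear of
the 5 dB / 90° classification thresholds, so ground-truth recovery measures
pipeline error rather than threshold ambiguity.  Insertion angles are
truncated-normal, mean 375°, SD 45°, range [290°, 500°].

## Classification

* Drop detection runs on a 3-point median-smoothed dB series (a single
  noisy point cannot fake a 5 dB event); a drop starts when the series falls
  more than `drop_threshold_db` (5 dB) below the running maximum, ends after
  recovering `recovery_db` (default also 5 dB) above its trough, and the
  trough time/depth are refined on the raw series because median smoothing
  flattens dip bottoms.  Events are non-overlapping and ordered, and raising
  the threshold can never create an event.
* The growth/fluctuating boundary reuses the same 5 dB criterion for
  internal consistency; both are configurable.
* The concurrent-shift threshold is 90°: observed trauma-suspicious drops
  show near-zero shifts while generator-passing drops show large ones (up
  to ~180°), so the midpoint separates them; it is configurable and the
  single most judgement-laden default in the package.
* A trace with both shifted and unshifted drops is Type III — the
  damage-suspicious reading dominates — as is a drop whose phase could not
  be measured.
* "Fluctuating" requires only a detectable ending after a super-threshold
  excursion; no explicit recovery magnitude is demanded.

## Tonotopic map

Angle → fractional organ-of-Corti length uses piecewise-linear
interpolation through a control-point table shipped as editable CSV
(`src/ecochg/data/oc_angle_length.csv`), interpolated from published human
averages; fraction → CF uses the Greenwood organ-of-Corti function with
A = 165.4 Hz, α = 2.1, k = 0.88 (base ≈ 20.7 kHz, apex ≈ 19.8 Hz; the
500 Hz place sits at ≈ 0.718 of the length from the base).  The organ-of-
Corti rather than spiral-ganglion map is used, since the recording contact
lies along the duct.  Under this calibration the observed angle range
[290°, 500°] spans CFs ≈ 1370 → 448 Hz, bracketing the 500 Hz stimulus with
deep-insertion values in the few-hundred-Hz region, and the crossing angle
(≈ 472°) is unique.  A multiplicative CF offset is exposed for the
basal-ward map shift reported in substantially impaired cochleae
(default off).

## Outcome statistics

* LF PTA HL is the mean post−pre threshold change over 125, 250, 500, 1000
  and 1500 Hz; missing frequencies are skipped with a warning, never
  imputed; negative values (improvement) are kept.
* Group comparisons: Kruskal–Wallis omnibus; pairwise Dunn z-tests with tie
  correction, Holm-adjusted (the post-hoc procedure is not uniquely
  determined by common clinical reporting; Dunn/Holm is the standard
  rank-based choice and is configurable).  All-identical data yield the
  degenerate H = 0, p = 1.  Groups with n < 2 are reported but excluded
  from testing with a warning.
* Two-group tests are Welch by default (unequal variances are the norm in
  small clinical groups); the pooled-variance Student form is a flag.  Both
  zero-variance degeneracies have documented fallbacks.
* Correlations are Pearson with listwise NaN deletion; the
  `A_min/A_max`-type features correlate on linear ratios by default, with a
  dB alternative via `ratio_in_db`.
* Audiogram synthesis: pre-operative thresholds N(mean profile 40–75 dB HL,
  SD 12) per frequency, redrawn until at least one threshold ≤ 80 dB HL
  (the residual-hearing inclusion rule); post-operative thresholds add
  N(type mean, SD 8) independently per low frequency and N(0, SD 8) at 2
  and 4 kHz, clipped to the audiometer range [−10, 130] dB HL.  The
  pre-operative distribution is fabricated (no public per-subject data
  exists) and fully configurable; subjects without a measurable response
  draw their shift from the mean of the three type means and are excluded
  from the fitted analysis, mirroring clinical practice.

## What the synthetic cohort does and does not show

The generator reproduces the *structure* the analysis assumes: polarity
symmetry, calibrated noise floors, the three amplitude patterns, drops with
and without phase shifts, inclusion-rule audiograms and type-dependent
hearing loss.  It does not emulate surgeon feedback loops (real fluctuating
traces partly reflect intraoperative corrections), electrode-movement
artefacts, non-stationary noise, acoustic-coupling failures beyond the
no-response archetype, or any imaging.  Passing recovery tests therefore
demonstrates that the pipeline measures what the model generates — not that
the clinical thresholds themselves are optimal for real recordings.

## Problem sizes and numerical choices

Test and acceptance runs use 100 traces per archetype for classification
recovery, 100 seeds for stopping-rule statistics, 200 replicates for power
and 500 for Type-I error (three groups of 15 subjects, 10/10/25 dB means,
SD 8), and reduced cohorts (n ≈ 8–20, insertions 10–45 s) for end-to-end
pipeline checks; these sizes give stable rates while keeping a full run in
the order of a minute.  All randomness flows from explicit seeds;
identical config + seed reproduces byte-identical pipeline outputs.
Floating-point guards: noise floors clamped at 1e−12 µV, dB ratios clamp
zero amplitudes at the same epsilon, phase unwrap uses a 360° period.

## Known limitations

* The control-point angle→length table is an interpolation of published
  averages, not a subject-specific measurement; CF estimates inherit its
  uncertainty (the clinical source reports ±~10% between estimation
  methods).
* The 90° concurrent-shift threshold and the 3-point detection run length
  are heuristics with clear rationale but no external calibration data.
* Phase at sub-floor points is unrecoverable by design; deep Type II drops
  are classified from flank phase only.
* The outcome model treats subjects as independent and ignores the
  feedback-driven, non-observational nature of real intraoperative data.
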