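# Methods

## Scope and model of the data

`cardiomap` analyzes fluorescence recordings of spontaneously beating,
electrically coupled cardiomyocyte monolayers ("functional syncytia").
A recording is a T×H×W intensity stack with known frame rate (frames/s)
and pixel pitch (cm/pixel), in one of two modalities: membrane voltage
(fast upstroke, short transient) or cytosolic calcium (slow rise, long
return to baseline).  Intensities are arbitrary units and are never
rescaled on input: the absolute diastolic level is itself a biological
readout (a surrogate for diastolic calcium), so any conditioning is an
explicit, parameterized analysis step.

## Synthetic syncytia (the verification substrate)

No raw recordings accompany the study conditions this package targets,
so correctness is established by closure: a generator renders movies
with *exact* ground truth, and the analysis must recover the configured
parameters.  The generator is deliberately kinematic rather than
biophysical — a reaction–diffusion model would make "true APD" and
"true conduction velocity" estimated quantities and the recovery test
circular.

- **Waveform template.** F(before) = F₀; half-cosine rise to F₀ + A
  over t_up; repolarization F(τ) = F₀ + A(1 − (τ/τ_r)^p), clamped at F₀
  afterward.  Durations obey D_x = t_up + τ_r·x^(1/p); `solve_template`
  inverts two duration targets in closed form, and
  `solve_template_d80_tri` solves (D₈₀, D₉₀−D₃₀) pairs by bracketing
  root-finding on u = 1/p (the duration ratio is monotone in u).
  Template defaults used in the recovery cohorts: voltage t_up = 20 ms,
  calcium t_up = 100 ms.
- **Rhythm script.** Inter-beat intervals are Gamma distributed with
  mean 1/f and coefficient of variation `jitter_cv` (degenerate at 0):
  positive support and directly controllable irregularity.  Tachycardic
  segments override the local rate; quiescent episodes delete scripted
  beats; EADs are additive Gaussian bumps (σ = 30 ms) of height δ·A
  placed at a chosen recovery phase on individual beats — the simplest
  detectable embodiment, since no waveform for them is published.
- **Propagation.** Planar (arbitrary angle), target (radial from an
  origin) or rotating (Archimedean-spiral activation-time field)
  delay maps; `speed=inf` scripts simultaneous activation, the
  degenerate case the mapper must flag rather than quantify.
- **Composition.** Per pixel the trace replays the template at
  beat time + delay; a beat arriving before the previous repolarization
  finished truncates it and starts its upstroke from the instantaneous
  value, so composite traces are continuous.  Multiplicative
  monoexponential bleaching and additive white noise come last.
  `noise_sd=None` defaults to A/20 (peak SNR ≈ 20) — a plausible level
  for a high-NA sCMOS acquisition, chosen once as a default because the
  source recordings carry no published SNR; it is a config knob, not a
  claim.

What the generator does *not* emulate: ion-channel dynamics, cell-scale
heterogeneity, motion artifacts (source preparations are
contraction-arrested), dye photophysics beyond additive noise and
monoexponential bleach, and true re-entry (the rotating pattern only
exercises conduction-heterogeneity handling).  Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
noise model, not robustness to every optical artifact of real rigs.

## Beat detection and measurement

- **Detection** thresholds the Savitzky–Golay first derivative (window
  0.11 s, order 2 — shot noise differentiates badly, so detection uses
  a heavier smoother than measurement) at 20% of the recording maximum,
  one activation per suprathreshold excursion at the sub-frame
  (parabolically refined) derivative peak, with a 100-ms refractory
  merge.  A quiescence guard returns no beats when the smoothed
  peak-to-peak range is within 8× the high-frequency noise floor
  (robustly estimated from first differences).  Savitzky–Golay edge
  polynomials can spike, so detections inside the half-window margins
  are discarded.
- **Measurement** operates on the raw trace by default: every estimator
  is fit-based, and pre-smoothing would only distort sharp peaks.  Per
  beat: (1) a rough onset from derivative-threshold walk-back ends the
  50-ms pre-upstroke window whose median is the diastolic baseline;
  (2) the activation onset (the reference point for all durations) is
  the baseline intercept of the line through the interpolated 25% and
  75% rise crossings — stable under noise, late by ≈0.16·t_up for a
  half-cosine upstroke (≈3 ms voltage, ≈16 ms calcium), a bias
  documented rather than corrected because it is shape-dependent;
  (3) the peak is located on a lightly smoothed copy (so an isolated
  noise spike cannot win) and its value estimated by a quadratic fit
  over the early falling limb, removing the upward order-statistic bias
  of a noisy maximum; cusp-like peaks (steep early decay) are instead
  reconstructed as the intersection of the rise line and the early
  decay line, clamped to one frame's worth of decay above the sample
  maximum — sampling at 100 fps genuinely misses such peaks;
  (4) recovery crossings (peak − x·ΔF) are found by first passage with
  a 3-sample median confirmation (rejects transient noise dips), then
  refined by an iterated local linear regression whose window scales
  with the elapsed decay (15%), truncated in *time* where the smoothed
  signal reaches the diastolic floor — a pointwise value mask would
  selectively discard noise-low samples and bias the fit; near-vertical
  falls (≥25% of the amplitude within one frame) keep the interpolated
  crossing, which is sharper than any fitted line.  Crossings are
  clamped monotone in x, so D₃₀ ≤ D₈₀ ≤ D₉₀ holds by construction.
- **Censoring.** A beat whose x-crossing is not reached before the next
  activation or the end of the recording is censored; censored beats
  are excluded from duration means (truncated beats would bias APD
  downward at high rates) but still count toward frequency.
- **Frequency** is (N−1)/(t_N − t₁) for ≥2 beats; ≤1 beat reports 0 Hz
  with a quiescence flag.
- **Fridericia correction** divides each beat's D₈₀ by the cube root of
  its own preceding interval, then averages per recording; per-beat
  correction is the standard reading of rate-correction formulas and
  coincides with mean-rate correction for regular rhythms.  First beats
  (no RR) are excluded from the corrected mean.
- **Upstroke slope** is reported raw (a.u./s) and amplitude-normalized
  (1/s); published "a.u." values are scale-ambiguous, so comparisons
  should use the normalized form.

## Activation mapping and conduction velocity

Frames in a beat window (bounded by midpoints to neighboring beats) are
smoothed with a separable Gaussian: σ = 1 px spatially (the activation
field is locally planar, so this suppresses noise without biasing
gradients) and σ = 2 frames temporally.  The temporal smoothing matters
even without noise: a voltage upstroke spans ~2 frames at 100 fps, and
frame-quantized peak timing produces a periodic distortion of the
activation surface whose local slope errors do not average out of a
median.  Signals are then cubic-spline upsampled ×8 in time and each
pixel timed at its refined derivative maximum.  Pixels with
within-window amplitude below 20% of the global-trace amplitude are
masked out.

Conduction velocity uses the classic local-gradient construction: a
plane t(x, y) is least-squares fitted over each sliding 5×5
neighborhood (quality pixels only, ≥80% coverage required); local speed
is 1/‖∇t‖ via the pixel pitch; neighborhoods with R² < 0.9 or gradient
below 1% of the median are excluded.  The per-recording headline is the
**median** of local speeds (robust to collision/boundary outliers); the
mean is reported alongside.  If the whole field activates within one
frame the estimate is flagged "global activation" and no CV is
reported.  By default CV is computed on one fully captured spontaneous
beat (the second, when available); no pacing model is provided because
the analysis targets spontaneous activations only.

Measured accuracy on synthetic planar waves (64×64, 0.01 cm/px,
100 fps): ≤0.3% bias noiseless and ≤1.1% at SNR 20 across
5–20 cm/s, rotation-invariant to <1%.

## Rhythm classification

Per-recording labels from independent rules (any abnormal label removes
"normal"; a recording is *arrhythmic* iff its label set ≠ {normal}):
frequency > f_hi (default 2.0 Hz) → tachyarrhythmia; 0 < frequency <
f_lo (0.2 Hz) → bradyarrhythmia; any gap > max(5 s, 3× median IBI)
(including the margins to the recording edges), or ≤1 beat →
quiescence; IBI coefficient of variation > 0.20 with ≥5 beats →
irregular; any EAD event → EAD.  The published material names the
categories but no numeric criteria, so the defaults were chosen to
leave normal spontaneous rates (~0.5–1.5 Hz) comfortably inside the
normal band; all are configurable and every assessment records the
thresholds and the evidence numbers it used.  When a reference
(control) frequency is supplied, the tachycardia cut becomes 2.5× that
reference — "abnormal increase relative to control" semantics.
Premature/delayed release events are intentionally mapped to the
irregular label (they inflate interval CV) rather than to a bespoke
detector.

**EAD detection** screens each beat's 30–90% recovery segment (minus a
30-ms guard before the next activation): the segment is smoothed,
fitted with a robustly reweighted quadratic representing the monotone
decay, and an event requires a positive residual of ≥ δ·ΔF (default
δ = 0.10) and ≥4 robust residual SDs.  A plain min-to-max drawdown
would subtract the concurrent decay from the bump and fire on shot
noise.  The screen is tuned for voltage-like transients; on very
low-amplitude slow calcium signals at SNR 20 occasional false positives
remain (a known limitation).

## Statistics

The group-comparison tree mirrors standard applied practice for small-n
functional cohorts: per-group normality screening by Kolmogorov–Smirnov
with the Lilliefors correction (the plug-in mean/SD make plain KS
critical values badly conservative — plain KS would almost never detect
skewness at n = 50); variance homogeneity by an F-test on the extreme
(max vs min) variance pair, Bonferroni-corrected for k > 2; all
premises passing → one-way ANOVA with Tukey HSD, else Kruskal–Wallis
with pairwise Mann–Whitney at a Bonferroni-adjusted level.  Groups too
small (n < 4) or constant make the premises untestable and force the
nonparametric branch with a note.  Because the published methods name
both Tukey and Bonferroni without stating their composition, pairwise
results carry both the raw and the Bonferroni-adjusted p-value and no
intent is guessed.  Incidence tables use Pearson chi-square without
continuity correction (configurable; the choice is logged).  Measured
type-I error of the full tree on null Normal data (n = 20 per group,
2,000 replicates) is ≈0.048 at α = 0.05.

## Numerical and design notes

- Frame k is at time k/frame_rate (frame 0 at t = 0); pixels are
  (row, col), 0-based; durations in seconds, rates in Hz, speeds in
  cm/s, pitch in cm/pixel.
- HDF5 stores frames as float32 with metadata as attributes; TIFF uses
  a JSON sidecar (TIFF tag dialects are fragile).  Pixel pitch is never
  inferred from data — it is a required user input.
- Detrending subtracts a rolling 10th-percentile floor (5-s window,
  linearly extrapolated into the boundary half-windows) and re-adds its
  mean, preserving absolute a.u. levels.
- Cohort seeds are spawned per recording from a master
  `SeedSequence`, so cohorts are reproducible as a whole and
  recordings statistically independent; identical config + seed gives
  byte-identical CSV outputs.
- Recovery cohort sizes (10 recordings of 64×64×1000 frames for CV, 26
  30-s traces for frequency, 20/8 traces for duration and baseline
  recovery, 16/36/40 recordings for incidence counts) match the group
  sizes of the study conditions while keeping a full validation run in
  the low minutes on a single core.
- Known limitations: absolute calcium calibration, ratiometric dyes and
  motion correction are out of scope; the onset estimator carries the
  ≈0.16·t_up shape bias noted above; CaTD estimates on very slow,
  SNR-20 transients carry per-cohort sampling noise of a few percent
  (few beats per 30-s recording at 0.07 Hz); cusp-shaped peaks are
  undersampled at 100 fps and their amplitudes recovered to ~5%.
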