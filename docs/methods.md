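# Methods

`wakenet` analyzes how the brain's functional network reorganizes during
sleep inertia — the groggy transition following abrupt awakening from slow
wave sleep — and how short-wavelength-enriched light modulates that
reorganization.  The pipeline reproduces a sensor-space EEG analysis
design: per subject, condition (control dim red light vs. blue-enriched
light) and bout (pre-sleep baseline BL, post-awakening bouts T1–T4), it
derives standardized spectral band power, weighted phase lag index (wPLI)
connectivity, weighted small-world graph metrics, and a paired-design
inferential layer.  A synthetic-study generator with known ground truth
closes the loop: every stage can be verified against planted structure
without access to human recordings.

## Preprocessing

Recordings (channels × samples, µV) are band-passed 0.5–50 Hz with a
third-order Butterworth filter applied forward–backward (`sosfiltfilt`),
i.e. zero-phase with the squared magnitude response of the one-pass
design.  A *clean reference signal* is then built by concatenating maximal
runs of at least 1,000 ms during which **every** channel stays strictly
below 100 µV in absolute value.  The amplitude gate is applied jointly
across channels (a sample is disqualified if any channel exceeds the
threshold); a per-channel reading of the gate is also defensible, but the
joint rule yields a single consistent segmentation for the multichannel
covariance that follows.

Artifact suppression is a simplified subspace clamp in the spirit of
artifact subspace reconstruction (ASR): the reference covariance defines
principal axes and per-axis RMS; the recording is processed in
non-overlapping 500-ms windows (last partial window as-is), each window's
projection onto the reference axes is compared with 5 × the reference RMS
per axis, and components over threshold are attenuated down to it before
reconstruction.  Windows with no excursion pass through bit-identically,
and the clamp can only ever reduce per-axis RMS.  This is deliberately
*not* a re-implementation of any specific ASR tool (no sliding calibration
windows, no covariance cleaning of the reference); the fidelity target is
artifact suppression with a transparent, testable rule, not numerical
equivalence with a particular toolbox.

## Spectral power

Welch's average modified periodogram (4-s Hann windows, 50% overlap —
standard parameters giving sub-1-Hz resolution below the delta band's
lower edge) yields a PSD per channel on a grid from 0 to Nyquist.  PSDs
are log10-transformed and z-scored per channel across the *entire* grid
(population SD).  Band power is the mean standardized value over a band's
grid points (closed intervals; the gaps 3–4, 7–8 and 12–15 Hz are
unassigned), and *global power* is the scalp mean of the per-channel
values.  By default PSD is computed on the cleaned broadband (0.5–50 Hz)
signal; a config switch (`psd_source="bandpassed"`) instead estimates
each band's power from its band-filtered copy.  Standardization spans the
actual Nyquist rather than a hard-coded 250 Hz so the definition survives
other sampling rates.

## Connectivity (wPLI)

Band-limited copies of the cleaned recording (third-order zero-phase
Butterworth; delta 1–3, theta 4–7, alpha 8–12, beta 15–25 Hz) are turned
into analytic signals by Hilbert transform.  For each channel pair the
per-sample imaginary cross-spectrum `I_t = Im(z_i conj(z_j))` is
accumulated over the whole epoch:

    wPLI(i, j) = |Σ_t I_t| / Σ_t |I_t|

Two seconds are trimmed at each epoch edge before accumulation to suppress
filter and Hilbert edge effects.  The estimator is the whole-epoch
Hilbert form by default (no debiasing); an optional segmented variant
computes the index per non-overlapping segment and averages the segment
values.  Pairs whose denominator
vanishes — exact zero-lag copies — are assigned 0 with a warning, using a
relative tolerance of 1e-9 against the summed cross-amplitude because the
floating-point complex product leaves a nonzero residue even for
identical signals.

At 60-s epochs the estimator has a noise floor: for independent 1–3 Hz
signals the null wPLI is ≈0.1 (it shrinks as 1/√(bandwidth × duration)).
All calibration tests bound null behavior by Monte-Carlo rather than
assuming the floor is zero.

## Graph metrics

For a wPLI matrix W with weights in [0, 1], zero diagonal:

* degree `K_i = Σ_j w_ij`;
* clustering, default (`bct`) convention:
  `C_i = Σ_{j≠k} (w_ij w_jk w_ki)^{1/3} / (k_i (k_i − 1))` with `k_i` the
  *count* of nonzero edges at node i — the standard weighted formulation
  (geometric-mean triangle intensity), bounded by [0, 1] for weights in
  [0, 1];
* a `literal` convention that normalizes by the weighted degree,
  `C_i = 2 Σ_{j<k} (…)^{1/3} / (K_i (K_i − 1))`, is retained for
  transparency.  It can exceed 1 on dense weak graphs and its
  normalization is undefined for `K_i ≤ 1` (such nodes get 0).  The
  unordered-pair sum with the factor 2 equals the ordered-pair sum; both
  conventions therefore share the same triangle numerator.
* distances: edge length `1 − w` for `w > 0`; zero-weight edges are
  *absent* (non-traversable), not length-1 — assigning length 1 to a
  missing edge would reward disconnection.  Shortest paths come from a
  masked-array Dijkstra so that zero-length edges (w = 1) remain
  traversable.  The characteristic path length λ is the mean over ordered
  pairs; unreachable pairs are excluded with a warning and a reported
  count (wPLI matrices are generically complete, so this is a corner
  case, and an infinite λ would poison every downstream mean).

No thresholding or sparsification is applied before graph analysis.

## Statistics

Paired t tests compare baseline with each bout within condition and the
two conditions at matched bouts (`t = mean(d)/(sd(d)/√n)`, df = n − 1,
two-sided p from the central t distribution).  Hedges' g is the
*pooled-SD* standardized mean difference with the small-sample correction
`J = 1 − 3/(4(2n − 2) − 1)`; because the t statistic standardizes by the
SD of the paired differences and g by the pooled SD, g need not equal
t/√n, and both are always reported.  Electrode-level clustering contrasts
are corrected with Benjamini–Hochberg FDR at q = 0.05 within a band
(never pooled across bands); uncorrected p values are reported alongside
the flag.  Brain–behavior association uses Pearson correlation with
df = n − 2, computed on whatever subjects are present in the supplied
tables (n is never hard-coded).  PVT summaries: mean speed = mean of
1/RT (RT in seconds), lapse = RT strictly greater than 500 ms.

## Synthetic studies

The generator emulates the study's statistical structure, not its
biophysics (no forward modeling, no sleep architecture, no circadian
process):

* **Sources.**  Per band, latent narrowband signals are white noise
  filtered to slightly jittered sub-intervals spanning ~84% of the band
  (order-4 zero-phase Butterworth), amplitude-jittered around the band's
  nominal RMS (delta 30, theta 15, alpha 20, beta 8 µV).  At least 90% of
  each source's power lies inside its nominal band.
* **Coupling.**  Each subject gets a base coupling matrix with weights
  uniform in 0.55–0.85 (complete graph by default).  Edge (i, j) with
  weight w consumes a dedicated source: channel i receives it, channel j
  receives `w` parts of its π/4-phase-shifted copy plus `√(1 − w²)` parts
  of an independent partner source of equal power.  The weight thus sets
  the *coherent fraction* of the lagged common source at constant per-edge
  power, which makes the expected wPLI rise near-linearly with w; a pure
  amplitude-share encoding is almost invisible to wPLI because scaling
  all shares leaves the coherent-to-interference ratio unchanged.
  Zero-lag leakage is never used to encode coupling, so recovering the
  planted graph genuinely requires a lag-sensitive estimator.  The mixed
  band signal is normalized so a band's configured amplitude is
  approximately the per-channel band RMS (the coupling information lives
  in the shared/private ratio, not the absolute scale), which keeps
  channel RMS near physiological values (~30-40 µV total) and well under
  the 100 µV reference-signal gate.
* **Noise and artifacts.**  Independent 1/f noise (exponent 1, 3 µV RMS)
  per channel; artifact bursts are Hann-windowed 15–45 Hz oscillations
  (Poisson rate 1/min, 400 µV, 200 ms) added coherently across channels
  with random gains, polarity-aligned at the peak so the logged burst
  peak is at least the configured amplitude; burst spans are recorded as
  ground truth.
* **Planted effects.**  Effects are specified as target Hedges-g values
  for the *estimated* metrics, matching how effects are reported.  The
  wPLI estimator attenuates truth-space differences (its noise floor adds
  variance and compresses the response), so a target g maps to a larger
  truth-space drop: the coupling scale at an affected bout is
  `1 − delta_s`, with `delta_s` a Beta deviate (mean `g × drop_scale`,
  SD `subject_sd`, drawn by inverse CDF on a per-subject uniform so drops
  are strictly positive and monotone in g).  The response factor
  `drop_scale = 0.46` and `subject_sd = 0.15` were fixed once by power
  simulation against the full pipeline at the scaled-down replicate size
  (11 subjects, 8 channels, 60-s epochs) so that the baseline-vs-T1
  delta clustering contrast is detected in well over 80% of replicates
  and the realized effect size lands near the targeted g ≈ 1.2 scale;
  they are study conditions, not per-run knobs.  Defaults plant the
  reported effect structure: delta clustering g = 1.17 at T1 under
  control and 0.8 under light (recovery from T2 onward), and global-power
  reductions in beta (T1–T3), alpha (T1–T2) and theta (T1) under both
  conditions.  Band amplitudes carry the power effects through an
  analogous Beta mapping (`power_drop_scale = 0.2`).
* **Behavior.**  KSS and PVT reaction times are linear functions of the
  subject's ground-truth delta clustering drop plus Gaussian noise
  (KSS ≈ 3 + 80 × drop, mean RT ≈ 240 ms + 1500 ms × drop, lognormal
  trial jitter), so brain–behavior correlation stages have a planted
  target whose strength is configurable.
* **Determinism.**  One global integer seed; per-subject/condition/bout
  streams derive from fixed `SeedSequence` offsets.  Identical config +
  seed ⇒ bit-identical studies and, downstream, byte-identical analysis
  tables.

What the generator does *not* emulate: volume-conduction mixing with
realistic lead fields, non-stationarity within an epoch, heterogeneous
per-electrode noise, oculomotor/EMG artifact morphology, or any
dependence structure between bands.  Passing tests therefore demonstrate
that the estimators and inference recover the intended structure under
this model, not that the pipeline is robust to every failure mode of real
scalp EEG.

## Problem sizes in the test battery

Unit and pipeline tests run seconds-scale configurations (2–4 subjects,
6 channels, 8–10 s epochs at 200 Hz).  The recovery battery uses the
scaled replicate unit described above — 11 subjects, 8 channels, 250 Hz,
60-s epochs, delta band only, 200 replicates with effects planted and 200
with effects disabled — chosen so the complete battery runs on one CPU in
minutes while keeping the paired design at its full n = 11.  Full-scale
studies (32 channels, 500 Hz, 5-min bouts, four bands) use the same code
paths through a config switch.

## Known limitations

* The wPLI noise floor at 60-s epochs compresses small coupling
  differences; truth-space effects must be larger than the realized
  standardized effects they produce.  At full scale (5-min epochs, 32
  channels) the floor is ≈2.2× lower and the attenuation correspondingly
  smaller.
* The literal clustering convention is reported but not recommended; its
  normalization is not scale-free and can leave [0, 1].
* The subspace cleaner assumes artifacts are high-variance relative to
  the reference subspace; low-amplitude structured artifacts pass
  through.
* Brain–behavior correlations at n = 11 have wide sampling variability;
  the generator plants strong couplings so sign recovery, not precise R
  values, is the testable claim.
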