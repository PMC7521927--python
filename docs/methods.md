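# Methods

`vestcode` analyzes how resting-discharge variability shapes the coding
strategy of central vestibular neurons during naturalistic self-motion, and
provides a seeded synthetic cohort on which every analysis is exercised and
tested.  This note documents the models, the estimator conventions, the
defaults and why they were chosen, and what the synthetic cohort does and
does not establish about real recordings.

## Signals and containers

Head velocity S(t), eye velocity EV(t) and eye position are uniformly
sampled traces (1 kHz, deg/s or deg).  A spike train is a sorted list of
event times with a duration; analyses binarize it to a 1 kHz sequence R(t)
whose bins hold spike counts (bin t covers [t/fs, (t+1)/fs)).  Masked
epochs (quick phases, eye-position windows) are half-open second intervals;
after masking, retained segments are concatenated and their seam positions
carried along so that no spectral window ever straddles a seam.

## Spectral estimation

All spectra come from one multitaper Welch engine: windows of 2.048 s with
50% overlap, 5 DPSS tapers at NW = 3 (≈1.5 Hz analysis bandwidth,
≈0.49 Hz grid spacing), mean removed per window so the DC line never leaks
into the 0–20 Hz band of naturalistic head motion.  `n_tapers=0` selects a
boxcar window, in which case the engine reproduces `scipy.signal.welch`
bin-for-bin (a unit test asserts exact agreement).

Two output scalings exist and are recorded in the estimate metadata:

* **density** (traces): standard one-sided density; the integral over
  frequency recovers the variance (Parseval, tested at 2% on broadband
  noise).  Processes with substantial power below ~1/window_s lose that
  power to per-window demeaning; tests that need the spectral peak of the
  2 Hz-knee stimulus resolved use 8.192 s windows with 3 tapers at NW = 2.
* **rate** (spike trains): the point-process convention — the two-sided
  density reported on the one-sided grid — so a Poisson train is flat at
  its rate λ (in sp²/s) and a gamma renewal train approaches λ·CV² at low
  frequency, the renewal-theory limit.  This is the convention under which
  the resting spectrum P0 and the spectrum of a rate trace add (see the LN
  model below).

Ratios (transfer functions, Wiener kernels, coherence) use one consistent
internal scaling, so the convention cancels.

The Poisson surrogate confidence band follows the standard construction:
surrogate Poisson trains with the same duration and total spike count as
the neuron, each run through the same estimator; the band is the
per-frequency 95% percentile interval over 1000 surrogates (fewer in
tests, where only band coverage is asserted).

Trial-to-trial variability is the average spectrum of the residuals
ΔR_i = R_i − mean(R), multiplied by n/(n−1) so it estimates the
single-trial noise spectrum without the shrinkage caused by subtracting a
mean that contains the trial itself.  The signal spectrum is the spectrum
of the trial average, bias-corrected by subtracting noise/n; SNR is their
ratio, capped and flagged where the noise estimate vanishes.

## Whitening index

WI = ∫_band P df / (bandwidth · max_band P) on [0, 20] Hz, with the in-band
maximum taken after 3-point median smoothing so a single noisy bin cannot
set the white reference level.  WI is scale-invariant, 1 for a flat
spectrum, and matches closed forms (half-band 0.5; Lorentzian knee-2 Hz
2·atan(10)/20) to better than 1% on constructed spectra.  Because the
reference is an in-band *maximum* of a noisy estimate, even a truly white
input scores slightly below 1 at finite data length (≈0.92 for 300 s of a
Poisson train); comparisons across neurons use matched estimator settings
so this bias is common mode.

## Linear–nonlinear cascade

The linear stage is H(f) = P_SR(f)/P_SS(f); its magnitude G(f) is the
tuning curve and |H(1 Hz)| summarizes sensitivity.  Bins where the stimulus
has less than 1e−6 of its peak power are marked invalid.  Symmetry of the
head-velocity distribution about zero makes this estimator unbiased.

The static nonlinearity is the binned mean firing rate versus the linear
prediction (uniform bins over the observed drive range, sparse bins merged,
piecewise-linear between bin centers, clamped extrapolation).  For fitting
only, the binarized rate is smoothed with a 25 ms-SD Gaussian (~100 ms
support), and the drive is smoothed with the same kernel — smoothing only
one side would attenuate the fitted map by the fraction of drive power
above the smoother's cutoff (regression dilution).  Spectra are always
computed on unsmoothed sequences.

The predicted response spectrum is P0(f) + P_FR(f), where P0 is the resting
spectrum and P_FR the (rate-scaled) spectrum of the predicted firing rate.
The additivity rests on the empirical observation that trial-to-trial
variability during stimulation shares the resting-discharge spectrum; in
the generator this holds by construction up to the mild spectral smearing
that rate modulation inflicts on the renewal correlation structure.  On the
default cohort the predicted and measured whitening indices agree within
0.04 per neuron.

`whitening_vs_cv_curve` sweeps the resting CV with the fitted linear and
nonlinear stages frozen, regenerating a matched renewal P0 per CV — the
model-level statement that variability alone moves a neuron along the
whitening continuum.

## Wiener reconstruction and coding fraction

The decoder is the classical optimal linear filter: for one neuron
K~(f) = P_RS*(f)/P_RR(f); for a pair, the per-frequency 2×2 cross-spectral
matrix is inverted against the cross-spectra with the stimulus
(ill-conditioned bins get a flagged ridge of 1e−6·mean diagonal; identical
trains fall back to the single-neuron kernel with a warning).  Kernels are
inverse-transformed, truncated to ±300 ms by default, cosine-tapered over
their outer 10%, and restricted to 0–30 Hz.  Reconstruction convolves
mean-subtracted binarized trains with the kernels per contiguous segment;
samples within half a kernel width of a seam are excluded from scoring.

CF = 1 − RMSE/σ_S: 1 for perfect reconstruction, 0 when no better than
predicting the stimulus mean.  CF is scored on the fitting data by default
(comparability across neurons); nothing prevents scoring held-out segments
via the segment arguments.

The frequency-domain kernel is validated against an explicit least-squares
FIR fit (normal equations on lagged regressors).  For a single 60 s neuron
the kernels agree within 2% RMS.  For the pair, the two estimates share a
near-collinear weak direction (both neurons encode the same stimulus) in
which each method's estimation noise is amplified, leaving a ~2–3% RMS
coefficient-level floor at 60 s that no estimator setting removes; the
decoders' *outputs* are what the analysis uses, and the pair decoder's
coding fraction matches the least-squares oracle's to better than 0.1%.

## Coherence, information, optimality

C(f) = |P_RS|²/(P_RR·P_SS), clipped to [0, 1], NaN where an auto-spectrum
vanishes.  The information rate is the Gaussian-channel coherence lower
bound MI = −∫_band log2(1 − C) df (bits/s), capped just below C = 1.
Optimality divides MI by the water-filling Gaussian capacity over the band,
with the neuron's noise spectrum (resting discharge, per the additivity
above) as channel noise and a signal-power budget equal to the measured
stimulus-driven response power ∫ max(P_RR − P0, 0) df.  Water filling is
solved by bisection on the water level with trapezoid band integrals and is
verified against an exhaustive allocation search; a flat-allocation bound
is exposed behind a flag for sensitivity analysis.  These are documented
interpretations: the information estimator is the standard coherence bound,
not a histogram estimator, and carries its known biases (lower bound;
small-sample coherence bias of order 1/n_windows).

## VOR model

Four-stage cascade in s = 2πif (time constants in seconds): afferents
s·Tc·(1+sT1)/((1+sT2)(1+sTc)) with T1 = 0.0175, T2 = 0.0027, Tc = 5.7;
vestibular nucleus −g_VOR·(T_VOR/Tc)·(1+sTc)/(1+sT_VOR) with T_VOR = 16
(velocity storage); neural integrator (sTe1+1)/s with Te1 = 1; plant
s·e^(−sτ)/((sTe1+1)(sTe2+1)) with Te2 = 0.016 and delay τ = 0.008.  These
are canonical reconstructions of the standard model: the canal constant
cancels in afferents·VN (velocity storage replaces it), and NI·plant
collapses exactly to e^(−sτ)/(1+sTe2); both identities are unit-tested, and
FFT simulation matches the analytic gain/phase at probe frequencies to
numerical precision.  With g_VOR = 1 the naturalistic regression gain is
≈0.96 (R² ≈ 0.91): a robust compensatory reflex.

Spike-driven prediction removes the mean rate before NI filtering (the 1/s
pole would otherwise integrate it without bound), divides by the neuron's
rate gain in (sp/s)/(deg/s), and filters by NI·plant.  The matching index
between predicted and actual eye-velocity spectra is
mi = max(0, 1 − RMS_f(log P_pred − log P_act)/SD_f(log P_act)) on
(0, 20] Hz, natural log, zero-power bins floored at 1e−12 of the band
maximum.  This log-spectral RMS convention is the package's own: it is 1
iff the spectra coincide on the band, 0 for gross disagreement, and
invariant to common rescaling.  VOR gain is minus the slope of the
eye-versus-head ordinary least-squares regression on retained (non-saccade)
samples.

## Synthetic cohort

The generator emulates the study conditions rather than any particular
recording:

* **Stimulus** — white Gaussian noise, causal first-order shaping knee at
  2 Hz, zero-phase 20 Hz cutoff, rescaled to SD 30 deg/s.  Only the
  Gaussianity, symmetry and 0–20 Hz band of naturalistic head motion are
  constrained by the problem; the knee and SD are this package's defaults,
  chosen so that most power sits below a few Hz at a realistic intensity
  for active head movement.
* **Resting discharge** — gamma-interval renewal process, shape k = 1/CV²,
  so the target CV and the λ·CV² low-frequency limit hold exactly in
  expectation.  Rates default to 50 sp/s, the middle of the physiological
  range.
* **Driven responses** — LN cascade run generatively: rate =
  nonlinearity(kernel ⊛ stimulus) + base rate, floored at zero; spikes by
  time-rescaling the same gamma renewal process (operational time =
  integrated rate), so resting-segment CV matches the target and
  trial-to-trial variability inherits the resting spectrum.  Kernels:
  identity, first-order low-pass, band-pass, or the VOR sensory cascade
  (a model-consistent VOR neuron).  Sensitivity defaults to
  0.5 (sp/s)/(deg/s).
* **Eye movements** — the VOR cascade output, plus optional Poisson-timed
  40–80 ms half-sine quick-phase transients (alternating sign, 150 deg/s
  peak) reported in a mask; a pause mask can silence spiking during them.
* **Seeding** — one master seed fans out through named SHA-256 substreams;
  identical spec + seed gives bit-identical output.

The default cohort (8 CVs × 3 seeds, rate fixed at 50 sp/s, sensitivity
fixed, 200 s of stimulation, 100 s of rest, 6 repeat trials) reproduces the
qualitative structure of the real population: whitening index rising with
CV (Spearman ρ ≈ +0.98), coding fraction (ρ ≈ −0.98), information rate
(ρ ≈ −0.99) and VOR matching index (ρ ≈ −0.86) falling, optimality rising.
Problem sizes (60–300 s signals, 24 neurons) were chosen so every
documented check runs comfortably on one core while keeping estimator
error well inside the stated tolerances.

What passing these tests shows: the estimators implement their definitions
correctly (closed forms, independent least-squares and allocation-search
oracles, scipy cross-checks), and the pipeline end-to-end recovers injected
parameters and the direction of every variability trend.  What it does not
show: anything about real macaque data — the generator has no adaptation,
no nonlinear plant saturation, no bursting, a purely renewal noise model,
and stationary statistics; quick phases are stylized transients rather than
detected saccades.

## Degenerate inputs and numerical choices

Empty spike trains are rejected by the decoders and the eye predictor;
fewer than 3 spikes by the CV estimator; fewer than 2 trials by the
residual spectrum; all-zero spectra by the whitening index; constant
stimuli by the coding fraction; masks that retain nothing by the
concatenator.  Coherence is clipped to [0, 1] and capped below 1 inside the
information integral.  Band integrals use the trapezoid rule on the
estimator grid.  The 2×2 pair solve regularizes when the condition number
exceeds 1e8.  CV uses the unbiased (n−1) standard deviation, recorded in
the output metadata.
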