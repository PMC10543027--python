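# Methods

This note documents the models and procedures `infantspec` implements,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Spectral estimation

Per-channel power spectral densities are computed on pre-cleaned 2-s
segments with discrete prolate spheroidal sequence (DPSS) tapers. The
time-half-bandwidth product defaults to NW = 2, giving K = 2NW − 1 = 3
orthogonal tapers and a half-bandwidth W = NW/T = 1 Hz at 2-s segments;
both are configurable. Spectra are one-sided in linear power (µV²/Hz)
on the grid 0 … fs/2 with spacing 1/segment-length; equal-weight
averaging over tapers and then over segments commutes, and the integral
of the PSD equals the signal variance up to taper bias. The log10
transform happens downstream, never here. ROI spectra are arithmetic
means of linear power over member channels; a whole-brain ROI over all
channels is always available. The recording-level gate rejects iff
n_segments < 20, % good channels < 80, % ICs rejected > 80, mean
artifact probability > 0.3, or % variance retained < 25 — strict
inequalities, so a recording exactly on every threshold passes — and
reports every violated criterion.

## Spectral parameterization

The model, over 2.5–50 Hz in log10 power, is an aperiodic line in
log-log space, `L(f) = b − χ·log10 f` (fixed mode, no knee), plus up to
seven Gaussians `h·exp(−(f−c)²/2w²)` (w is the SD; bandwidth is 2w).
Because the model is linear in (b, χ), aperiodic fits use the exact
least-squares solution rather than an iterative optimizer.

The robust aperiodic stage fits an initial line, forms the flattened
spectrum (log power minus line), transforms it, retains the points at
or below its 2.5th percentile, and refits the line on the retained
points of the *original* log spectrum. The two variants differ only in
the transform:

* `original`: negative flattened values are set to 0. Clipping creates
  a large tie at zero, so the retained set is "every point at or below
  the initial line" — stable, but it discards the shape of any segment
  of the spectrum that dips below the line.
* `modified` (default): the flattened spectrum is shifted upward so its
  minimum is ≥ 0. Nothing is discarded; the retained set is the lower
  envelope of the flattened spectrum, which in young-infant spectra is
  the 10–20 Hz trough. The refit line consequently tracks the trough
  rather than riding above it.

After the robust stage the flattened spectrum is recomputed; the
`modified` variant clips its negative values to zero before peak
fitting (the classic algorithm does not). Peaks are extracted
iteratively — take the global maximum, stop when its height falls below
`peak_threshold × SD` of the input flattened spectrum (the threshold is
fixed from the input, not recomputed on the shrinking residual, which
would never terminate on noise-free spectra; 1e-8 log-units acts as a
numerical floor), estimate the Gaussian SD from the half-height extent
clamped to `peak_width_limits/2`, subtract, repeat up to
`max_n_peaks` — then all retained Gaussians are refit jointly by
bounded least squares (centers within ±1.5 guess-SD, heights ≥ 0, SDs
within limits); a non-convergent joint fit drops the smallest peak with
a logged warning and retries. Finally the aperiodic line is refit a
third time on the peak-removed spectrum; reported parameters, R², and
mean absolute error (log10 units) come from this final model. The
reported offset is the aperiodic log10 power at 2.5 Hz
(`b − χ·log10 2.5`), avoiding the noisy 0 Hz extrapolation; linear
power is `10**offset`.

Numerical notes. The fits are deterministic: fixed initializations, no
randomness. The bit-identity of the two variants when the initial
flattened spectrum is non-negative is exact, but such inputs only arise
for spectra whose residuals are non-negative everywhere (least-squares
residuals sum to zero, so in practice: exact power laws, or an injected
initial line); the test suite uses an injectable initial fit to probe
this branch. Known limitation: the `modified` variant's lower-envelope
refit loses slope identifiability when the lowest flattened points
cluster in a narrow frequency range (e.g. two strong low-frequency
peaks and no trough force the envelope points to the low edge); the
final peak-removed refit absorbs most of the error, but an exponent
bias of order 0.1 can remain in that configuration. The variant was
designed for smooth, segment-averaged spectra where the lower envelope
is well defined; on such spectra (and on trough-shaped spectra, its
target case) it matches or beats the clipping variant's 10–20 Hz error.

## Periodic features

The periodic spectrum is log10 power minus the fitted aperiodic curve —
the space in which the model is additive — computed at native
resolution and then linearly upsampled to a 0.1 Hz grid. The native
multitaper grid (0.5 Hz, ≈96 points over 2.5–50 Hz) cannot host the
101-point Savitzky–Golay window, so upsampling precedes smoothing; the
window (101) and polyorder (8) are retained as defaults and
configurable. At these settings the filter's coefficient solve is
ill-conditioned, so polynomial reproduction is exact only to ~1e-3 —
irrelevant at feature scale but visible in tests. Band peaks are the
highest *strict* interior local maxima of the smoothed curve in each
band (ties → lower frequency; absence is a value, not an error; no
amplitude floor by default since none is defined, with an optional
`min_peak_amplitude`). The trough is the global minimum of the smoothed
curve in 10–20 Hz; the dual-peak flag requires ≥ 2 strict local maxima
in 4–12 Hz — note that with no amplitude floor, small smoothed noise
wiggles can satisfy it. Band integrals are trapezoidal integrals of the
*unsmoothed* periodic curve and of the aperiodic curve (a switch
selects the smoothed curve); which curve the original analysis
integrated is not stated, and the unsmoothed curve is the less
processed choice.

## Developmental trajectories

Each feature is modeled as

    value ~ sex_c + study + NS(age, k=4) (+ sex_c : NS(age, k=4))
            + per-subject random intercept and age slope

where `sex_c` is an ordered ±0.5 contrast (F = +0.5), study dummies use
the first level as reference, and `NS` is a natural cubic spline with
four knots at the age quantiles {0, ⅓, ⅔, 1} — a fixed-df basis of
dimension 4 including the constant, i.e. three free columns. This is a
regression-spline mixed model: the penalized factor-smooth random
effects of a full GAMM are represented by the documented fallback of
random intercept + random linear age slope per subject (statsmodels
MixedLM, ML estimation), which accounts for the repeated-measures
correlation the contract requires and is testable for calibration; the
fallback is the package default. Degenerate inputs (zero residual
variance, singular random-effects covariance) fall back to the OLS
limit. The additive and interaction forms are compared by a
likelihood-ratio ANOVA (χ², df = number of interaction columns = 3);
the interaction model is kept iff p < 0.05, strictly. Measured type-I
rate of that selection on null cohorts is ~5–8% at n=200 (50-cohort
harness). Daily predictions are fixed-effects predictions per sex at
the reference study level from the minimum to maximum observed age.
FDR correction is Benjamini–Hochberg across measures within an ROI.
ROI contrasts add an ROI factor (posterior reference) to the additive
form; each non-reference coefficient is the adjusted offset vs.
posterior with a Wald statistic and BH q-value. Trajectory extrema are
points that strictly dominate all neighbors within ±100 days (scipy's
relative-extrema scan, clipped at the boundaries, endpoints excluded);
the standardized rate of change is the day-to-day difference divided by
the SD of the modeled values over the full range (population SD; a
constant series yields zeros with a warning). The extrema scan applies
to the modeled daily values; the rate series can be passed instead.

## Anesthesia coherence

The bipolar derivations F7−Fp1 and F8−Fp2 are band-passed 0.1–30 Hz
with a zero-phase (forward–backward) 4th-order Butterworth filter —
the response contract is the passband plus ≥20 dB attenuation at 0.01
and 60 Hz, which this meets with margin. Thirty-second epochs are
excluded when their SD exceeds k·median epoch SD (k = 3 by default; the
original analysis states SD-based exclusion without a threshold) or
when the preceding 120 s of end-tidal sevoflurane span more than 0.2%.
Retained epochs are concatenated and coherence is estimated with 6-s
non-overlapping windows, TW = 3, K = 5 tapers (spectral resolution
2W = 1 Hz): auto- and cross-spectra are averaged over all windows and
tapers, and coh = |Sxy|²/(SxxSyy) ∈ [0, 1]. The summary statistic is
the median coherence over the alpha band, 8–13 Hz by default (the
original bounds are unstated; configurable). With L = windows × tapers
averaged estimates, the null coherence bias is ≈ 1/L (≈ 0.04 for one
30-s epoch). The group comparison is an ANCOVA
`coherence ~ presence + sevoflurane`; the reported effect is the
adjusted group difference. A perfectly collinear design raises an
error naming the degeneracy.

## Synthetic data

The generators define the study conditions for all tests:

* **Spectra**: log10 P = b − χ·log10 f + Gaussians + N(0, σ), default
  σ = 0.02 log-units on a 0.5 Hz grid — emulating segment-averaged
  spectra with residual estimation noise. Real spectra have smoother,
  frequency-correlated deviations; independent per-bin noise is the
  harsher case for envelope-based fitting.
* **Time series**: per-segment circular complex Gaussian rFFT
  coefficients scaled to a target one-sided PSD, so the multitaper PSD
  is unbiased for the target; segments are independent.
* **Cohorts**: n = 200 subjects by default, nominal visits at 75, 180,
  270, 365, 550, 730 and 1095 days (±15 d jitter, 2–5 visits each,
  echoing the contributing studies' schedules), sex ≈ 46% female,
  three studies with N(0, 0.05) offsets, per-subject random intercept
  (SD 0.08) and slope (SD 0.05/yr), residual SD 0.08. Truth shapes:
  rise-then-plateau aperiodic offset (logistic, midpoint 180 d),
  theta→alpha peak-frequency drift 5.5→8 Hz, unimodal high-beta
  amplitude peaking at day 229 (height 0.5), and a low-beta presence
  probability rising 0.1→0.7 (logistic, midpoint 500 d). Noise scales
  were chosen once so that recovery at this cohort size has margin;
  they are recovery targets, not data.
* **Anesthesia**: a shared narrowband 8–12 Hz source injected into F7
  and F8 over independent broadband channel noise, so both bipolar
  derivations share exactly the source; with in-band source-to-noise
  ratio ρ the expected coherence is (ρ/(1+ρ))². Group SNRs 1.45 / 0.8
  target a ≈ 0.15 median-alpha-coherence difference at n = 11 vs 10.
  Sevoflurane is a plateau series with occasional 0.4% steps.

What passing tests show — and do not. Recovery and calibration results
demonstrate the pipeline's correctness under these generative
assumptions (Gaussian peaks, additive log-noise, linear mixed
structure, stationary segments). They do not certify behavior on real
EEG pathologies the generators omit: artifacts surviving preprocessing,
non-Gaussian peak shapes (the feature stage deliberately works on the
model residual rather than fitted peak parameters for this reason),
age-heteroscedastic noise, or missing-not-at-random visit patterns.

## Problem sizes

Test and acceptance harnesses use: 20 noise seeds per spectral
recovery condition (12 conditions), 20 recovery cohorts and 50 null
cohorts of n = 200 subjects for the trajectory stage, 100 simulated
record sets for ANCOVA calibration, 20 null-coherence seeds plus 5
four-minute common-signal runs, and a 200-segment (400 s) synthesis
round trip. These sizes give stable medians and rates while keeping
the full suite under a minute for the fast stages and a few minutes
end to end.
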