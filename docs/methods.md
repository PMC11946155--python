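# Methods

`pawnpipe` implements a within-task brain-dynamics analysis for the
equiprobable auditory Go/No-Go paradigm: estimate and remove pink (1/f) and
white noise from immediately-prestimulus EEG amplitude spectra under a
non-negativity constraint on the residual oscillations, decompose the
noise-free oscillation spectra by frequency PCA and the Go/No-Go ERPs by
temporal PCAs, and link the prestimulus measures to ERP components and
behaviour with stepwise regressions.  Because no public dataset accompanies
this analysis style, the package ships a synthetic-EEG generator with full
ground truth, and every claim the test suite makes is a recovery claim
against that ground truth.

## Signal model and synthetic data

A session is the sample-for-sample sum of four parts on `n_channels`
channels at 1000 Hz:

* **Band-limited oscillations.**  Each band is a Gaussian process with a
  Gaussian spectral envelope (centre, FWHM bandwidth, RMS amplitude in uV),
  synthesized by frequency-domain shaping with complex-Gaussian
  coefficients.  This produces the slowly varying random envelope of real
  EEG rhythms.  (A 4th-order band-pass driven by white noise gives an
  equivalent process; the spectral route is used because its expected
  spectrum is known in closed form and it is cheap at scale.)  The default
  bands peak at 2, 8, 10, 15 and 25 Hz — the delta/theta, theta/alpha,
  alpha, alpha/beta and beta components this literature reports — with
  RMS amplitudes 2.5, 2.0, 3.5, 1.8 and 1.5 uV and smooth per-channel
  topography weights (simple weight vectors, not head models).
* **Pink noise**, one-sided PSD `p/f` uV^2/Hz, default `p = 10` at the
  vertex, synthesized with amplitude ∝ f^(-1/2) and uniform random phases;
  independent per channel.
* **White noise**, flat PSD `w` (default 0.3 uV^2/Hz; time-domain variance
  `w * fs / 2`), independent per channel.
* **ERP templates**: Gaussian-windowed deflections per condition with
  latency, FWHM width, peak amplitude, polarity and topography.  Go:
  N1b (95 ms, −8 uV), N1c (160, −5), N2c (240, −6), P3b (350, +12),
  SW1 (460, +6).  No-Go: N1b, N1c, P2/N2b (215, −5), N2c/eP3a (290, +8),
  lP3a (380, +7), SW1 (470, +5).  Latencies and widths are generic values
  for this component sequence, chosen once so that adjacent components are
  separable by a temporal PCA.

Stimuli alternate at a fixed 1100 ms onset asynchrony; each block holds
75 Go and 75 No-Go tones in shuffled order (2 blocks by default).  Go
responses are draws from a normal RT distribution (mean 340 ms, SD 80 ms)
truncated to [100, 1000] ms; omissions (4%) and No-Go commissions (6%)
occur independently.  The truncated normal does not reproduce the heavy
slow-RT tail seen in real students; the behavioural error *rates* are the
emulated quantities.

**Couplings.**  A coupling (source band or pink noise → ERP component,
sign, strength) scales the target's template on trial k by
`1 + sign * polarity * strength * z_k`, where `z_k` is the standardized
prestimulus (−500..0 ms) amplitude of the source on that trial.  The
`polarity` factor makes `sign` the sign of the induced regression slope of
the *signed* component amplitude.  Standardization constants are computed
at cohort level (a seeded calibration of the within-trial RMS distribution,
combined analytically with the between-participant log-normal jitter), so a
participant with chronically high alpha has chronically larger P3 — which
is what across-participant regressions can detect.  The default pattern,
at strength 0.5: alpha→Go P3b (+), beta→Go N2c (−), beta→Go SW1 (−),
pink→No-Go N1b (−), pink→No-Go N1c (+).

**Cohorts.**  One participant = one session.  Between-participant
variability is log-normal jitter (σ = 0.2 on the log scale, median 1) on
every amplitude-like ground-truth quantity, applied independently per
parameter; powers are scaled by the squared factor.  The paradigm gives no
generative model for participant heterogeneity, so this is a deliberately
simple stand-in.  All randomness derives from one master seed through
`SeedSequence`-based derivation keyed by participant and stage, so runs are
bit-reproducible.

## Preprocessing

Zero-phase (forward–backward) Butterworth filtering, 0.1–30 Hz.  The two
edges are designed separately — a low-order high-pass (order 4) cascaded
with an order-8 low-pass — because a single band-pass design with a 0.1 Hz
edge at 1000 Hz is numerically ill-conditioned.  The forward–backward pass
doubles the attenuation; pad length is set to three high-pass time
constants so the slow edge transient cannot leak into the analysis.

Epochs are [−500, +500) ms around each onset (half-open, so exactly 1000
samples, and the prestimulus slice [−500, 0) has exactly 500).  Validity:
a Go trial needs a press inside the closed [100, 500] ms window; a No-Go
trial needs no press before the next stimulus; any press landing inside a
trial's 500 ms prestimulus window (a late press from the previous trial)
invalidates it.  Artifact rejection applies three rules per channel in
order — absolute amplitude > 125 uV, sample-to-sample jump > 50 uV,
max−min < 0.05 uV in any sliding 100 ms window — and records the first rule
triggered.  Accepted counts are matched between conditions by seeded
subsampling of the larger set; participants with fewer than `min_trials`
accepted trials in either condition are excluded (50 by default, 30 in the
single-block recovery studies).

## Spectral estimation

Each 500-sample prestimulus segment is de-meaned, tapered with a 10%
split-cosine-bell (cosine ramps over the first and last 25 samples, flat
in between; mean exactly 0.95), zero-padded to 1000 points and transformed;
bins are 1 Hz, retained 0–30 Hz.  Single-sided amplitudes are corrected for
the unpadded length and the taper.  Two calibration choices matter:

* **Image-term correction (default on).**  With the 5%-per-end ramps the
  taper transform at twice the bin frequency reaches 2.6% of its peak, so
  the negative-frequency image biases a 10 Hz tone by ±2.6% depending on
  phase.  A real tone at bin k satisfies
  `X[k] = (z W(0) + conj(z) W(2 f_k)) / 2`; inverting this R-linear map
  recovers `|z|` exactly for any phase.  For broadband noise the change is
  second order (<0.1%).  The plain coherent-gain formula is available via
  `image_correction=False`.
* **Noise-calibration constants.**  Spectra are averaged on the amplitude
  scale (as is conventional for these "magnitude" spectra).  For Gaussian
  noise, (mean amplitude)^2 underestimates mean power by π/4 (Rayleigh),
  and a bin integrates the PSD over the taper's equivalent noise bandwidth
  (≈2.08 Hz here).  `noise_psd_from_mean_amplitude` applies both factors;
  recovery studies use it to compare fitted noise levels with generator
  PSD ground truth.  Power-vs-amplitude averaging is switchable in
  principle; amplitude is the default and the tested path.

Condition means are averaged per channel; the pooled spectrum is the mean
of the Go-mean and No-Go-mean spectra (prestimulus activity cannot depend
on the upcoming, randomly ordered stimulus).

## Constrained pink + white noise fit

The model is `S(f) = p/f + w + osc(f)` with `osc(f) ≥ 0` on the 2–24 Hz
integer bins, fitted in the **power** domain (power is additive across
independent processes; amplitude plots are produced by square-rooting).
The fit maximizes the total extracted noise `Σ (p/f + w)` subject to
`p, w ≥ 0` and `p/f + w ≤ S(f)` at every bin — the maximal noise consistent
with non-negative oscillations everywhere in the range.  With `x = 1/f`
this is a two-variable linear program; the optimum is found by exact vertex
enumeration (every line through two spectrum points in `(x, S)` space plus
the axis candidates), with ties broken toward the larger white level.  The
pink exponent is fixed at exactly 1; the free-exponent log–log fit exists
only as `aperiodic_baseline_demo`, which exhibits the negative-oscillation
pathology the constraint prevents.  The fitted noise is extended over
1–30 Hz and subtracted in power; outside the fit range (1 Hz, 25–30 Hz)
clipping at zero may activate and clipped bins are counted.

Because the LP presses the noise line against the *lowest* fluctuating
bins, per-channel fits on few epochs are biased low by roughly 1–2 standard
errors of a spectrum bin; the parameter-recovery study therefore averages
over channels and uses longer sessions (6 channels with flat topography,
4 blocks, bumps confined to 6–20 Hz so the fit-range flanks are pure
noise), and compensates the spectra for the known analysis-filter gain.
Observed recovery at those sizes: pink within ~5%, white within ~8%
(median).

## Component PCAs

Both PCAs eigendecompose the variables' covariance matrix, keep **all**
components, and keep loadings on the microvolt scale (so the plotted
"scaled loadings" are simply the loadings).  Cases are participant ×
channel; f-PCA pools Go/No-Go into one solution (31 bins, Promax), t-PCA is
run per condition on the half-sampled mean ERPs (−100..498 ms at 2 ms, 300
variables, Kaiser-normalized Varimax).  Components with at least 1.5%
post-rotation variance are selected; each selected component's
per-participant amplitude is its standardized score times the loading at
the component's peak variable, averaged over channels (the "global mean",
deliberately avoiding region-of-interest choices).  Components are
sign-flipped so the peak loading is positive; negative deflections then
carry negative scores.

Varimax uses the standard SVD-based matrix algorithm with a criterion
tolerance of 1e-7 and an iteration cap (500 by default; 200 in the large
simulation studies, where the criterion has long since plateaued — the
best iterate is returned with a warning either way).  Promax (kappa = 3,
the ERP-PCA-toolkit convention; the source literature does not state
kappa) fits the Varimax solution to the element-wise |l|^κ·sign(l) target
by oblique Procrustes.  Two numerical decisions proved necessary when all
components of a full-rank extraction are rotated:

* factors whose powered target column carries less than 25% of the largest
  column norm are left at their Varimax orientation.  Obliquely fitting a
  near-zero target is numerically arbitrary and lets pure-noise factors
  rotate into genuine ones (factor correlations near 0.9 with junk factors,
  duplicated alpha components).
* post-Promax explained variance uses the pattern × structure product
  partition, which sums exactly to 100% of the total variance.  Structure
  sums of squares double-count the shared variance of correlated factors so
  badly here (sums near 280%) that a variance cutoff loses meaning.

## Behaviour and linkage regressions

Six behavioural measures per participant: omission %, slow-RT % (>500 ms),
fast-RT % (<100 ms), mean and SD of valid-window RTs, commission %.  Slow
presses are slow errors, not omissions, and are excluded from the RT
moments.

The predictor table holds the selected f-PCA component amplitudes plus the
pink amplitude at 1 Hz (√p, uV) and the white amplitude (√w), each a global
mean over channels.  Every behavioural measure and every Go/No-Go ERP
component amplitude is a dependent variable in a separate stepwise
regression (forward entry at p ≤ 0.05 on the best candidate, backward
removal at p > 0.10, iterated to a fixed point; thresholds are the common
statistical-package defaults — the procedure's source does not state them).
Betas are standardized; no multiple-testing correction is applied, matching
the exploratory framing.  A secondary suite regresses the behavioural
measures on the EEG-affected ERP components (those whose primary regression
selected at least one predictor).  Entry stops if the current model is
numerically perfect (R² within 1e-12 of 1), which otherwise produces
arbitrary entries on zero residuals.

## Study sizes and what the tests show

The recovery studies run at sizes chosen to keep a 20-cohort simulation on
one desktop core while leaving the statistics intact: linkage cohorts use
47 participants (the headline sample size), 10 channels, one block of
75+75 trials, a 4 ms ERP grid and `min_trials = 30`; the noise-recovery
study uses 6 channels and 4 blocks.  Configuration-arithmetic checks
(case/variable ratios 45.5 and 4.7) run at the full 30-channel, 300-variable
geometry.  Passing tests show that the pipeline recovers known parameters,
components and couplings from data obeying its own generative model — with
Gaussian noise, linear couplings, stationary spectra and no ocular or
movement artifacts.  They do not show that real EEG satisfies those
assumptions, and the EOG-correction, channel-interpolation and visual
inspection steps of a real laboratory chain are out of scope.

## Known limitations

* The maximal-valid-noise objective is one concrete realization of the
  "valid noise estimate" idea; other objectives (e.g. least squares under
  the same constraints) satisfy validity too and would give slightly
  different (p, w).
* The LP's min-type construction makes per-channel noise estimates biased
  low at realistic epoch counts (see above); the validity guarantee itself
  is unconditional.
* Amplitude-vs-power averaging, subtraction domain, and the formula behind
  per-participant component amplitudes follow the stated defaults; all are
  isolated behind switches or single functions.
* With all components rotated, Varimax on a 300-variable temporal PCA
  retains small noise components above the 1.5% cutoff when the ERP
  signal-to-background ratio is low; recovery tests therefore match
  components to planted latencies rather than asserting exact counts in
  the end-to-end study.
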