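# Methods

`netstates` characterises time-averaged and transient functional networks in
parcellated electrophysiological recordings (MEG/EEG-style data: a
parcels × samples array per subject at a common sampling rate, 250 Hz by
default) and tests how network features vary with subject covariates such as
age and cognitive performance. This note documents the models, the defaults
and why they were chosen, the synthetic cohort generator used for
validation, and known limitations.

## Time-averaged spectra and networks

Per subject, each parcel time course is z-scored and a multitaper estimate
of the power spectral density (PSD) and cross-spectral density (CSD) is
computed: 2 s windows, 0% overlap, dimensionless time-half-bandwidth
NW = 4, and 2·NW − 1 = 7 DPSS tapers (standard settings for resting-state
MEG). Frequency resolution is 1/2 s = 0.5 Hz; the axis is restricted to
1–45 Hz for time-averaged analyses. A trailing partial window is dropped
rather than zero-padded.

Normalisation is a one-sided density whose integral over frequency
approximates the signal variance; unit-variance white noise therefore sits
at a flat level of 2/fs (DC and Nyquist bins are not doubled). The
convention is chosen so the white-noise oracle is analytic; all group
statistics are invariant to a global PSD rescaling.

Coherence is

    C_xy(f) = |CSD_xy(f)| / sqrt(PSD_x(f) · PSD_y(f)),

bounded in [0, 1] with unit diagonal. Band power and band coherence are
simple means over bins whose centres fall in half-open canonical bands
δ [1, 4), θ [4, 8), α [8, 13), β [13, 24), γ [30, 45) Hz — half-open so
touching edges are not double-counted; the 24–30 Hz gap between β and γ is
deliberate (a range contaminated by site artefacts in the motivating
data). A coherence map is the per-parcel mean over off-diagonal edges of
the unreferenced, unthresholded band network.

For display only, band networks/maps can be referenced against the
weighted average across bands (weights proportional to each band's bin
count on the retained axis) and thresholded to the top 3% of edges by
absolute referenced value, with deterministic lexicographic tie-breaking.
Statistics always run on unreferenced values.

## Transient network states

### Data preparation

Each subject's parcel data are time-delay embedded with ±L lags (default
L = 7, a ±28 ms window at 250 Hz; 52 parcels give 780 embedded
channels), trimming 2L boundary samples rather than zero-padding so no
artificial covariance is introduced at the edges. A group-level PCA
(default 120 components) is fitted on the covariance pooled over subjects
— accumulated subject-by-subject with bounded memory and defined to equal
the PCA of the time-concatenated data — and each component's sign is
fixed (largest-magnitude loading positive) so runs are comparable. The
projected data are then temporally z-scored per channel, in that order
(embed → project → standardise).

### The hidden Markov model

States are modelled as a zero-mean multivariate Gaussian per state,
x_t | θ_t = k ~ N(0, D_k): forcing the mean to zero makes the states pure
covariance (and, through the embedding, spectral/connectivity) patterns.
Switching follows a first-order Markov chain with transition matrix A.
The default number of states is K = 10, matching common practice for
resting-state electrophysiology; validation experiments use K = 3 at
reduced channel counts.

Inference is full-batch Baum–Welch EM: framewise Gaussian log-likelihoods
via Cholesky factors, scaled forward–backward recursions (each row of the
likelihood matrix is max-shifted before exponentiation, which is exactly
log-space arithmetic and safe for sequences of 10^5+ samples), and
maximum-likelihood M-steps with a diagonal regularisation ε = 1e-5 times
the mean channel variance added to every D_k (guards against singular
accumulated covariances; an informative error suggests raising it if data
are degenerate). Subjects are independent sequences — no transitions
across subject boundaries — and the initial distribution is estimated
from the first-sample posteriors averaged over subjects. Initialisation
draws random responsibilities from the seed and applies one M-step, with
a sticky initial A (diagonal 0.8). Training restarts `n_runs` times
(default 5) from seeds spawned deterministically from `random_state`; the
run with the lowest free energy — in this exact-EM setting the negative
log-likelihood, lower is better — is selected, ties going to the lowest
run index. The EM log-likelihood trace is nondecreasing and asserted as
such in the tests. A stochastic mini-batch variational scheme is not
provided; exact EM shares the generative model, is deterministic given a
seed, and is the appropriate tool at the problem sizes this package
targets.

### Dynamics summaries

The MAP state time course takes the most probable state per sample (ties
to the lowest index); it is mutually exclusive by construction. Per
subject and state we compute fractional occupancy (FO), mean lifetime
(ms), mean interval (s) and switching rate (Hz). Conventions: a visit is
a maximal run; the first visit counts as an onset; intervals are measured
end-of-visit → start-of-next-visit (an onset-to-onset mode is available,
as the gap definition is genuinely open); censored first/last visits are
included in lifetime means by default (switchable). With censored visits
included, FO_k = switching-rate_k × mean-lifetime_k holds exactly.
Never-visited states carry FO 0, switching rate 0, and missing
lifetime/interval — NaN, never silent zeros — and missingness propagates
to the GLM stage where subjects are dropped per feature. Subject
transition matrices count all consecutive pairs including
self-transitions (the diagonal is the empirical stay probability), with
never-visited rows set uniform and flagged.

### Dual-estimated state spectra

Per subject and state, the standardised (pre-embedding) parcel data are
multiplied by the state's binary MAP indicator, the same multitaper is
applied (1–80 Hz for state spectra), coherence is computed from the
masked P/CSD, and the PSD is rescaled by 1/FO to undo the amplitude bias
of masking. Coherence self-normalises and is not rescaled. Windows
straddling state boundaries are retained (the mask inserts zeros); the
resulting leakage is accepted — the reconstruction property
Σ_k FO_k · PSD_k ≈ static PSD holds within 5% on stationary input with
visit durations around 1 s. When the state course comes from embedded
data it is 2L samples short; the recording is trimmed by L samples per
end to align, and this trim-and-align rule is the module's contract.
Broadband state maps average over the full retained range (each state has
its own characteristic spectrum, so no hand-chosen band); display
referencing subtracts the across-state mean.

## Group statistics

Cognitive task batteries are reduced to one performance score: tasks are
z-scored, PCA is applied across subjects, and the first component is kept
with its sign fixed so the mean loading is positive (the score then
increases with performance on all tasks).

The GLM y = Xβ + ε is fitted by OLS jointly across features, with a
constant, the standardised regressor of interest, and standardised
confounds (sex, total brain volume, relative grey/white-matter volume,
head size, x/y/z head position; for cognition analyses age joins the
confounds, and vice versa). Significance uses sign-flip max-statistic
permutations: each of n_perm (default 1000) permutations draws ±1 per
subject, refits the GLM once for all features, and records the maximum
absolute statistic across features, giving one null distribution that
controls family-wise error over everything tested together. The absolute
regression coefficient is the default statistic; the t-statistic is used
for the dynamics summaries, whose per-feature scales differ by orders of
magnitude.

Because confounds correlate with the regressor of interest, flips are
applied within the Freedman–Lane scheme: the data are residualised
against the confound submodel, residuals are rescaled by 1/sqrt(1 − h_ii)
(confound-model leverage) so their variance matches the error variance,
sign-flipped, and the full model is refitted. Naively flipping the
interest column itself destroys its correlation with the confounds and
produces a materially anti-conservative null; the leverage rescaling
removes the residual (n − k)/n variance deficit of plain Freedman–Lane.
Calibration is verified empirically: on fully null cohorts the
family-wise rejection rate lies inside the exact binomial 95% interval
around α = 0.05.

P-values use (1 + #{null ≥ observed}) / (1 + n_perm) — valid, never
zero, and the identity permutation need not be forced into the null.
Two-sidedness comes from absolute values. Feature blocks (band power,
band coherence edges, each dynamics statistic, state maps) are tested in
separate calls, mirroring per-figure analyses.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes:
K discrete hidden states with Markov switching, state-specific oscillatory
spectra and inter-parcel coherence, and covariates that modulate dynamics
and power.

* Oscillators are damped AR(2) resonators (pole radius 0.95, fixed)
  driven by white noise and standardised to unit variance before a
  per-parcel gain; frequency 0 means broadband noise. The resonance peak
  sits within one 0.5 Hz bin of the nominal frequency at these settings.
* Parcels in a coupling group share the driving noise source, giving
  coherence near 1 at the resonance in the noise-free limit; a mixing
  weight w (shared vs. independent source, w·shared + sqrt(1−w²)·own)
  sets the coupling strength while preserving unit variance.
* Each state's stationary process runs for the whole recording and the
  observation switches between them sample-wise — abrupt switching,
  matching the HMM's piecewise-stationary assumption.
* Covariate effects act on the logit of a state's stay probability (the
  row is renormalised proportionally, so it stays stochastic) and
  multiplicatively, exp(slope · z(covariate)), on gains (they stay
  nonnegative). Between-subject spectral heterogeneity — for which no
  canonical generative account exists — is emulated by log-normal gain
  jitter (log-sd 0.1 by default); this is one plausible choice among
  many.
* The covariate table draws age uniformly from 18–88 years, binary sex,
  anatomical/geometry confounds as Gaussians with fixed correlations to
  age (total brain volume −0.4, grey −0.35, white −0.2, head size 0.1,
  positions 0) so confound regression is exercised non-trivially, and
  cognitive scores from a single latent performance factor
  (latent = slope · z(age) + residual, positive loadings), default
  latent slope −0.5 with unit score noise.

What the generator does not emulate: source leakage and field spread,
sensor noise and head movement, non-sinusoidal waveform shape, 1/f
background slopes, vigilance drift, and non-Markovian dwell-time
distributions. Passing tests therefore demonstrate correctness of the
pipeline's estimators under its own assumptions, not robustness to real
MEG artefacts.

## Validation experiments and problem sizes

The validation suite (also re-run by `scripts/acceptance.py`) uses
desk-scale problem sizes chosen as the smallest that leave comfortable
statistical margins:

* HMM recovery: 5 channels, K = 3 states with distinct random
  covariances, sticky transitions, 10 subjects × 20 000 samples.
* Coherence oracle: y = a·x + noise, 20 random (a, σ_n) draws,
  60 000 samples each; the bin-averaged coherence (flat by construction)
  is compared with a·σ_x/sqrt(a²σ_x² + σ_n²).
* Power conservation: two-state masking of stationary oscillatory noise,
  10^5 samples, ~1 s dwell.
* FWE calibration: 200 fully null cohorts of 60 subjects × 20 features,
  500 flips each.
* End-to-end recovery: static — 20 cohorts of 60 subjects × 6 parcels ×
  60 s with a multiplicative age slope of 0.3 on two parcels' 10 Hz
  gain; transient — 20 cohorts of 40 subjects × 4 parcels × 48 s, K = 3,
  ±2 lags, 8 components, with a −1.0 logit age slope on one state's stay
  probability.

One caveat observed in the transient experiment: because FO sums to one,
the non-planted states' occupancies rise mechanically with age, and the
shared group-level transition matrix can let strongly age-modulated
switching bleed into other states' *estimated* lifetimes even though
their generating dwell dynamics are untouched (verified null on the
ground-truth sequences). Recovery is therefore scored on the planted
state's own FO and lifetime effects; clean null-feature control is
asserted in the static experiment and in the full-null calibration.

## Numerical choices and degenerate inputs

Ties in MAP states, run selection, and edge thresholding break towards
the lowest index. Transition rows that sum to 1 only within 1e-8 are
rejected. Constant channels raise with the channel named. Coherence from
a zero PSD bin raises naming parcel and frequency. Constant GLM targets
yield zero statistics and p = 1 (a 1e-12 tolerance in the null
comparison absorbs roundoff dust). Fits are bit-reproducible given a
seed; run restarts use seeds spawned from a `SeedSequence`.

## Limitations

* Exact EM finds local optima; multi-run restarts mitigate but do not
  eliminate this, and very similar states (near-identical covariances)
  may merge at desk scale.
* The max-statistic test controls family-wise error but is conservative
  for weak distributed effects; no cluster or TFCE-style statistics are
  provided.
* No sensor-space preprocessing, source reconstruction, parcellation,
  leakage correction, or spectral parameterisation — parcel time courses
  and a covariate table are the pipeline's contract.
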