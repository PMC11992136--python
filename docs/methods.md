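# Methods

This note documents the models, the synthetic data, the numerical
choices and the known limitations of `restingnorm`, in the spirit of a
package methods appendix. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model

All internal signal math is in microvolts; spectra are in
log₁₀(µV²/Hz). The resting spectrum of one channel is modeled as

log₁₀ P(f) = b − χ·log₁₀ f + Σₖ PWₖ · exp(−(f − CFₖ)² / (2 σₖ²)),

an aperiodic (1/f-like) component with offset *b* and exponent *χ*
("fixed" mode — no knee, adequate over 2.5–45 Hz) plus Gaussian
periodic peaks with center frequency CF (Hz), log-power above the
aperiodic fit PW, and bandwidth BW = 2σ (Hz).

## Preprocessing chain

Eight steps, applied in fixed order: (1) flat-channel removal,
(2) high-pass + comb notch, (3) bipolar EOG derivation (E8 − E9),
(4) 2-s epoching, (5) adaptive epoch rejection, (6) average reference,
(7) EOG-ICA removal, (8) per-epoch bad-channel interpolation. Choices
that the contract left open:

- **Flat channels** are defined on log-SD: a channel is flat when its
  log₁₀ SD lies more than 3 SDs below the across-channel mean of
  log-SDs (a threshold on raw SD is ill-posed for a strictly positive,
  right-skewed quantity); zero-variance channels are always flagged.
- **"Adaptive" epoch rejection** is median + 5·MAD on the per-epoch
  worst-channel peak-to-peak, computed per subject. It is parameter-
  light, robust, and reproducible; with MAD = 0 (identical epochs)
  nothing is rejected. The rejected fraction becomes the data-quality
  covariate of the normative model.
- **Filters**: zero-phase (forward-backward) application throughout;
  2nd-order Butterworth high-pass at 0.1 Hz; notches at 60 Hz and
  in-band harmonics with quality factor 30 (narrow line removal,
  < 1 dB ripple over 2.5–45 Hz). Harmonics at or above Nyquist are
  skipped.
- **ICA** runs on the kept epochs concatenated in time (FastICA,
  seeded, n−1 components because average-referenced data loses one
  rank). Components whose time course correlates with the bipolar EOG
  above |r| = 0.7 are zeroed, at most 2 of them; a non-converging
  decomposition passes the data through with a logged warning rather
  than failing the subject.
- **Step 8** rejects channels whose within-epoch peak-to-peak exceeds
  median + 8·MAD across channels and replaces them by spherical-spline
  interpolation from the remaining channels; an epoch with > 30 % bad
  channels is dropped instead. This keeps the reject-and-interpolate
  contract without re-implementing any particular published artifact
  package's internal cross-validation.

On artifact-free synthetic subjects the whole chain changes band
powers by < 0.05 log₁₀ units (asserted in the test suite).

## Current source density

Spherical-spline surface Laplacian with kernels

g(x) = 1/4π Σₙ (2n+1)/(n(n+1))ᵐ Pₙ(x),  h(x) = 1/4π Σₙ (2n+1)/(n(n+1))^(m−1) Pₙ(x)

truncated at 50 Legendre terms, m = 4, ridge λ = 10⁻⁵ on the diagonal
of G. The per-sample solve enforces the zero-sum constraint on the
spline coefficients, which makes the operator exactly invariant to the
recording reference; the head is a unit sphere, so the absolute CSD
scale is arbitrary but consistent (all downstream statistics are
scale-equivariant or normalized). The truncation order is the standard
free parameter of this construction — there is no iterative refinement
in the spline solution. Both spectra and connectivity consume
CSD-transformed epochs by default (config-switchable to
average-reference scalp data).

## Spectral estimation and parameterization

Welch: 2-s Hamming windows sliding with 50 % overlap across the
*concatenated kept epochs* (this reading maximizes segment count and
matches the estimator's standard use), median-averaged per channel with
the standard median bias correction, log-transformed, on the 0.5 Hz
grid 2.5–45 Hz.

Parameterization, per channel: (a) robust aperiodic line fit in
log-log space — ordinary fit, then two refits on the points whose
residual is below the 60th percentile, which drops peak regions;
(b) iterative peak detection on the flattened spectrum — take the
maximum, stop when its height is below max(0.1, 2 × SD of the current
flattened spectrum), estimate σ from the half-prominence width, subtract
the guess; at most 6 peaks; (c) joint bounded nonlinear least-squares
refit of all Gaussians (BW limited to [1, 8] Hz; peaks that fail the
refit fall back to their guesses; peaks ending below the minimum height
are dropped); (d) final aperiodic refit on the peak-removed spectrum;
(e) R² and MAE of the full model. Channels with R² < 0.9 or MAE > 0.1
are excluded from all channel averaging (boundary values retained).

Band features use half-open bins [low, high) on the grid (no bin is
counted twice by adjacent bands; the whole-spectrum band closes at
45 Hz) and the mean over bins (invariant to band width), then the mean
over valid channels. "Periodic" band power averages the flattened
spectrum itself, not Gaussian parameters. Peak frequencies are the
grid argmax of the channel-averaged periodic spectrum within the search
windows alpha 2.5–14.5 Hz and beta 15–37 Hz — the alpha window
deliberately reaches below 8 Hz to capture slowed alpha in children —
with ties broken toward the lower frequency and an all-nonpositive
window reported as missing.

## Connectivity

wPLI over the cross-term X_t = a_i(t)·conj(a_j(t)) of the band-limited
analytic signals: |mean Im X| / mean |Im X|, with 0 by convention when
the denominator vanishes (identical or exactly zero-lag signals — the
estimator's insensitivity to volume conduction). Imaginary cross-terms
are pooled over time within each 2-s epoch, per-epoch matrices are
arithmetically averaged, and arctanh (Fisher) is applied to the result,
clipped below 1. The subject-level summary is the mean transformed
value over all unordered channel pairs. Band-passing uses a zero-phase
4th-order Butterworth per epoch followed by the Hilbert transform, with
5 % of samples excluded at each epoch edge: a linear-phase FIR with the
nominally desirable 0.5 Hz transition would need several times more
taps than a 2-s epoch holds, so an IIR filter applied forward-backward
is the practical zero-phase choice at this epoch length. No debiasing
is applied (plain wPLI, not debiased wPLI²).

## Normative model

Per feature: outlier exclusion on the pooled sample (carriers and
controls) using Q15/Q85 percentiles (linear interpolation) ± 1.5 ×
(Q85 − Q15), inclusive bounds; then a Gaussian-process regression of
the feature on standardized covariates (age in years, sex F=0/M=1,
site 0/1, quality ratio) trained on controls only — passing a carrier
row to the trainer raises. Kernel: constant × anisotropic RBF + white
noise, hyperparameters by marginal-likelihood maximization with 3
seeded restarts; zero-variance covariates are dropped with a warning.
The predictive SD used in z = (y − μ(x))/σ(x) includes the learned
noise term, so z is calibrated against observations (held-out controls
should be ≈ N(0, 1)), not against latent means. Model quality is the
standardized mean squared error (MSE / population variance of the
targets; exactly 1 for a mean predictor) under seeded 5-fold
cross-validation on the controls.

## Group inference

One-way ANOVA from the between/within decomposition with
η²ₚ = SSB/(SSB+SSW) = F·df₁/(F·df₁+df₂); Tukey–Kramer studentized-range
post-hocs (unequal n) with simultaneous CIs; Cohen's d with
(n−1)-weighted pooled SD. Two OLS interaction models on z-scores:
Model 1 regresses on carrier status, sex, age, status×sex and
age×status; Model 2 replaces status by treatment-coded DEL/DUP
indicators (CTRL reference) and expands the interactions accordingly.
Sex is coded F=0/M=1 and age enters in raw years, uncentered; the
design condition number is reported alongside. p-values are two-sided;
no multiple-testing correction is applied across features (only the
within-feature Tukey adjustment). A rank-deficient design (e.g.
dosage model with an empty group) raises, naming the collinear terms.
Demographic-table utilities (`anova_from_summary`,
`chi_square_independence` without continuity correction) recompute
published test statistics from printed means/SDs/ns and counts.

## Synthetic cohorts

The generator's defaults are the study conditions: groups CTRL/DEL/DUP
with sizes configurable up to the study's 256/66/43; ages uniform on
[3, 17]; P(male) = 0.56; carriers recorded at site 0 and 87.5 % of
controls at site 1; 128-channel geodesic-style montage (golden-angle
spiral cap) with a 28-name face/neck exclusion ring leaving 100
analysis channels; 4-minute recordings at 500 Hz by default.

Per-subject generative parameters are Gaussian draws around linear age
trajectories — exponent 1.80 − 0.030/yr (SD 0.25), offset 0.80 −
0.020/yr (SD 0.25), alpha CF 9.0 + 0.20/yr (SD 0.8), alpha PW 0.50
(SD 0.12), plus a beta peak — values chosen as representative of
school-age resting EEG (aperiodic flattening and alpha acceleration
through childhood). Group effects are additive shifts in pooled-SD
units so the injected standardized effect size is known; the defaults
mirror carrier-like deviations (≈ −0.5 SD exponent, slowed alpha peak,
group-dependent alpha coupling).

Channels are realized by frequency-domain amplitude shaping of white
noise to the target one-sided PSD (E|X_k|² = S(f_k)·rate·N/2), so the
spectrum the estimator assumes is the spectrum the data has in
expectation and parameter recovery tests the estimator rather than
model mismatch. Coupled pairs share a band-limited (8–12 Hz) source
injected with a constant phase lag (frequency-domain rotation) and a
coupling coefficient c scaled so the coherent fraction of in-band power
is c². Artifacts: 400-ms raised-cosine blinks (150 µV) on frontal
sensors with mirrored polarity on the EOG pair, Poisson arrivals
(default 10/min); flat channels (×10⁻⁵, applied last so they stay
flat); high-amplitude low-frequency bursts in a configurable fraction
of 2-s segments (default 30 %, matching the study's retention rates).
Identical seed and config give bit-identical cohorts and recordings.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: volume-conduction mixing beyond the
explicit coupling construction (real scalp EEG is strongly spatially
correlated; here channels are independent apart from coupled pairs, so
CSD and interpolation face an easier field than in vivo), muscle and
electrode-drift artifacts, non-Gaussian or non-stationary background
dynamics, nonlinearity of developmental trajectories (linear by
default; curvature only via config), and heterogeneity of effect across
carriers of different genomic loci.

## Problem sizes

The committed tests and the acceptance script run reduced renditions of
the study conditions, chosen as the smallest sizes at which the checked
quantities are stable: 16–32-channel montages, 30–60-s recordings at
250 Hz, 50-subject recovery cohorts, 200 training / 200 held-out
controls for calibration, and 100 replicates at the study's 66/43/256
group sizes for detection power. The full-scale configuration
(128 channels, 240 s, 500 Hz) is the `RunConfig` default.

## Known limitations

- The spectral parameterization is a from-scratch implementation of the
  standard aperiodic + Gaussian-peaks scheme; it matches the published
  algorithm's settings and contract but not its code paths, so
  channel-level peak inventories can differ on noisy spectra even when
  aperiodic parameters agree.
- The Fisher transform applied to wPLI (a [0, 1] quantity that is not a
  correlation) is kept for fidelity to the analysis it reproduces, not
  because it is variance-stabilizing here.
- The per-epoch interpolation bound (30 %) and the ICA correlation
  threshold are config defaults, not estimated quantities.
- GP normative modeling assumes homoskedastic Gaussian residuals around
  the trajectory; no warped likelihoods or site harmonization beyond
  the site covariate.
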