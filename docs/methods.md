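# Methods

`megnets` re-implements, at desk scale, a resting-state MEG analysis chain
for comparing symptomatic ALS patients, asymptomatic C9orf72/SOD1 variant
carriers and healthy controls: static spectral and connectivity metrics,
dynamic network-mode summary statistics, permutation-based GLM group
inference, and a nested cross-validated classifier. Because the clinical
MEG cohort underlying such studies is not publicly available, the package
ships a synthetic cohort generator with full ground truth; every
quantitative claim the test suite and `scripts/acceptance.py` make is
computed on that generator or on analytically constructed inputs.

## Signal model of the simulator

Each simulated subject is a parcel-by-samples matrix (default 52 parcels,
250 Hz, 480 s) built as

    x_p(t) = s_per * sum_k alpha_k(t) m_kp s_k(t) + b_p(t)

* `alpha(t)` — K simplex-valued mixing coefficients (default K = 6),
  obtained as the softmax of temporally smoothed, cross-correlated Gaussian
  logits. The smoothing kernel width (`logit_smoothness`, default 1 s) sets
  the time scale of network switching; the logit correlation matrix sets
  how strongly modes co-activate. Because coactivation effects are injected
  on the logits rather than on `alpha` itself, the simplex constraint is
  never violated; the induced `alpha` correlation is verified against a
  long-run Monte-Carlo oracle in the tests.
* `s_k(t)` — unit-variance Gaussian sources with Gaussian spectral profiles
  (centre, bandwidth per mode). The default six modes mirror the kind of
  networks seen in resting MEG (two temporal, frontal, occipital, motor,
  plus one spatially diffuse broad-band "background" mode) with centres at
  8, 4, 6, 10, 14 and 21 Hz.
* `m_kp` — nonnegative spatial loadings; default block maps over five
  contiguous parcel sets standing in for lobes (frontal, sensorimotor,
  temporal, parietal, occipital). Doubling a loading quadruples that
  mode's contribution to the parcel's power.
* `b_p(t)` — independent aperiodic background with PSD proportional to
  `f**(-chi)` (default chi = 1, a typical source-level MEG value), flat
  below 0.5 Hz.

The periodic scale (`periodic_scale = 6`) and background scale (1.0) put
oscillatory peaks clearly above the 1/f floor at their centre frequencies
while the background dominates the broadband power, mimicking real parcel
spectra. Between-subject realism comes from lognormal per-mode amplitude
jitter (sd 0.1), Gaussian exponent jitter (sd 0.05) and lognormal
background jitter (sd 0.1); without these the cohort would be implausibly
homogeneous and every group test trivially powered.

Group effects are injected as:

* **band-power scaling** — an amplitude factor applied exactly in the
  frequency domain on a named band and parcel set (power scales as the
  square; a factor 0.8 gives the 0.64 power ratio used in the end-to-end
  recovery checks);
* **CoE shift** — all periodic peak centres move by a fixed Hz offset,
  which shifts the centre of energy, leaving the aperiodic component
  untouched;
* **exponent shift** — added to the background's chi;
* **coactivation offset** — added to the off-diagonal logit correlations
  (projected back to the nearest valid correlation matrix).

Default per-group effects follow the direction of the clinical findings
(symALS: sensorimotor beta power x0.8, slight slowing and flatter 1/f;
aC9: temporo-occipital beta reduction, 1 Hz slowing, steeper 1/f, +0.3
coactivation offset; aSOD: 1 Hz acceleration, mildly steeper 1/f). Group
sizes default to 84/61/16/12 (HC/symALS/aC9/aSOD) with ages drawn from
N(57,16), N(63,11), N(48,14), N(47,12) years, male fractions
0.52/0.69/0.31/0.08, riluzole only in symALS (52.4%), and missing-MRI
rates 2/84, 4/61, 3/16, 1/12. Recording length is fixed at 480 s
(configurable); the cohort master seed spawns one child seed per subject
via `numpy` seed sequences so cohorts are reproducible and subjects
independent. A positive beta-power-vs-age slope (0.004 log-amplitude per
year on the sensorimotor set) is on by default in HC and aC9 and off in
symALS and aSOD, reproducing the disrupted aging-trajectory scenario.

What the generator does **not** emulate: sensor-space artifacts, head
movement, beamformer leakage geometry, spatially correlated background
noise, non-Gaussian bursting, or any real anatomy. Passing tests therefore
demonstrate correctness of the metrics and inference machinery under a
known generative model, not clinical validity on real MEG.

## Preprocessing

Entry filter: zero-phase Butterworth band-pass (order 5, default 1-80 Hz;
forward-backward, so the effective order is doubled). The z-transform uses
the population (1/N) variance. Multivariate leakage correction finds the
closest set of mutually orthogonal time courses in the least-squares sense
(orthonormal factor times per-parcel positive scales) by alternating a
polar-decomposition step with the closed-form scale update; tolerance 1e-9,
at most 500 iterations. The input is demeaned first, which keeps the
orthogonalized outputs exactly uncorrelated rather than merely orthogonal.
Rank-deficient input (duplicated parcels) is rejected since no orthogonal
solution preserves all parcels. Cross-subject sign alignment flips parcel
signs greedily to match each subject's lagged covariance pattern (lags
0-5) to a template — the first subject's pattern, then one refinement pass
against the cohort mean; the procedure is deterministic given the input
order. Pipeline order is bandpass -> z-transform -> leakage correction ->
sign alignment.

## Static metrics

Welch PSDs use 2 s Hann windows, 50% overlap, per-segment constant
detrend, density scaling (the integral over frequency approximates the
variance). Band power is the *mean* density over the half-open band
`[low, high)`; the six canonical bands are delta 1-4, theta 4-7, alpha
7-13, beta 13-30, low-gamma 30-48 and high-gamma 52-80 Hz, leaving the
48-52 Hz mains gap unassigned. Mean density rather than the integral keeps
group contrasts identical up to band-width constants and makes the flat
spectrum a fixed point.

Spectral shape is fit between 1 and 70 Hz in log10-power space: a fixed
aperiodic model `offset - exponent*log10(f)` plus Gaussian peaks extracted
iteratively from the residuals. The aperiodic fit is made robust to peaks
by refitting on the lowest 40% of the flattened spectrum (twice), then
refit once more after peak removal. Peak extraction honours: width limits
0.5-12 Hz (on twice the Gaussian SD), minimum height 0.05, stopping
threshold 2.0 times the current residual SD, unlimited peaks (hard safety
cap 20); half-height widths are estimated with interpolated crossings and
overlapping guesses are pruned (centres within 0.75 joint SD) before a
bounded joint refinement. The periodic component is the log-power spectrum
minus the aperiodic fit. The centre of energy (CoE) is the frequency at
which the cumulative trapezoidal integral of the *rectified* periodic
component reaches half its total, located by linear interpolation;
rectification is needed because the subtraction can go negative, and an
all-zero periodic component yields NaN. A lower CoE means oscillatory
slowing.

## Static connectivity

Amplitude envelope correlation (AEC): band-pass per band (same Butterworth
family), analytic-signal magnitude via the Hilbert transform, 1 s trimmed
from each end to remove transients, then Pearson correlation across parcel
pairs. Envelopes are used raw (no log, no downsampling), and parcel
connectedness is the signed mean of a parcel's off-diagonal row. Leakage
correction is applied once, globally, before any band-wise filtering.

## Dynamic metrics

Data preparation follows the standard dynamic-network recipe: time-delay
embedding with 15 lags (-7..+7 samples) giving an embedded dimension of
`15 P` (780 at 52 parcels), row standardization, and PCA to 100
components.

The full deep generative network model used on real data is out of scope
here; mixing-coefficient inference is a transparent desk-scale surrogate:
sliding-window covariances (1 s windows, 0.5 s step) of the prepared
components are clustered by k-means (seeded restarts) into K covariance
templates, each window covariance is expressed as a convex combination of
the templates by simplex-constrained least squares (nonnegative least
squares on a sum-penalty augmented system), and window solutions are
mapped back to the sample grid by nearest-window assignment. Ground-truth
mode time courses from the simulator are the primary test surface; all
five summary metrics are model-agnostic functions of the mode time courses
and spectra, so they transfer unchanged between true and inferred modes.

Mode spectra are obtained by regressing short-time cross-spectra (2 s Hann
windows, 50% overlap) across windows onto the window-averaged mixing
coefficients, per frequency and parcel pair; with a single always-on mode
this reduces exactly to the Welch estimate. Mode PSDs are the rectified
diagonals; mode coherence is the normalized cross-spectral magnitude
clipped to [0, 1]. The five dynamic metrics are: strength (time mean of
alpha), variability (population SD), pattern concentration (excess Fisher
kurtosis, population convention), coactivation (Pearson correlation of
mode time courses; both the full pair matrix and per-mode off-diagonal
means are emitted, since group reports use both readings), and dynamic
parcel connectedness (mean coherence from a parcel to all others, averaged
over frequency, per mode). Inferred and true modes are matched by maximum
correlation with the Hungarian algorithm, as modes carry no canonical
order.

## Group inference

The design matrix has one 0/1 indicator per group plus z-scored confounds
(age, sex, riluzole, missing MRI); the four default contrasts are
symALS-HC, aC9-HC, aSOD-HC and aC9-aSOD. Contrasts are fit by OLS:
`cope = c'beta`, `t = cope / sqrt(sigma2 c'(X'X)^-1 c)`. Family-wise error
over features (parcels x bands, or modes) is controlled with the
max-statistic permutation method: per permutation the outcome rows are
shuffled among the subjects of the groups entering the contrast (the
exchangeability unit; other rows and the design stay fixed), the maximum t
over features forms the null, and

    p = (1 + #{max-t >= t_obs}) / (1 + n_perm)

one-sided per contrast direction (each direction is its own contrast).
With few subjects and a two-group contrast all distinct relabelings can be
enumerated exactly. Permuting rows of Y against a fixed design is the
simplest scheme consistent with permuting "the data"; confounds are not
re-orthogonalized per permutation (a Freedman-Lane scheme is not used),
which is a documented limitation.

The beta-power aging analysis selects parcels whose beta power rises
significantly with age within controls (p < 0.001, positive slope), takes
each subject's mean beta power over the selected parcels, fits per-group
linear regressions (Bonferroni over groups) and tests group-by-age
interactions against the control slope via a group x age design.
Age-beta linearity is assumed.

## Classifier

Binary problem: genetically at-risk (aC9 + aSOD) vs healthy controls.
Controls are age-matched by greedy nearest-age selection without
replacement (default 40 controls against 28 at-risk, reproducing the
published design sizes). Features concatenate band powers, spectral-shape
metrics (exponent, CoE), dynamic parcel connectedness, upper-triangle
coactivations and the three per-mode summary statistics — 767 features at
the default geometry — with namespaced, deterministically ordered columns
and a guard that label/id columns can never enter the matrix.

Nested CV: outer stratified 5-fold; within each training fold a randomized
search (inner stratified 5-fold, ROC-AUC scoring, balanced class weights)
tunes the random forest, impurity importances rank features, top-k subsets
(k in {8, 16, 32, 64, 128, all}) are scored by inner AUC and the best k
kept, and the tuned model predicts the held-out fold. Out-of-fold
probabilities are pooled for the ROC curve, PR curve and the 0.5-threshold
confusion matrix. The default search space (trees 50-300, depth
{None, 4-32}, feature fraction {sqrt, log2, 0.2, 0.5}, 15 sampled
configurations) is deliberately compact so a full nested run fits in
minutes on one core; the search breadth is a runtime knob, not part of the
protocol. ROC AUC is computed as the Mann-Whitney statistic with 0.5 tie
credit; its 95% CI uses DeLong's structural-components variance with a
normal approximation truncated to [0, 1]. No DeLong analogue exists for
the PR AUC, so its CI is a stratified bootstrap (2000 resamples). Training
index hashes are recorded per fold so leakage-freedom is auditable.

## Numerical and design choices

* Half-open band convention `[low, high)` disambiguates the shared edges
  at 4, 7, 13 and 30 Hz.
* Kurtosis is excess (Fisher) kurtosis with population normalization.
* The simplex solver renormalizes after NNLS; columns sum to 1 within
  1e-9 by construction.
* Constant mode time courses make coactivation undefined; NaN sentinels
  plus a warning are emitted rather than silent zeros.
* Degenerate inputs fail loudly with the offending parcel/subject named:
  zero-variance parcels, rank-deficient leakage input, missing metadata
  rows, non-finite outcomes.
* All randomness flows through explicit integer seeds; the pipeline
  manifest records one derived seed per stage, and rerunning with the same
  config and seed reproduces byte-identical CSV artifacts.

## Problem sizes used in tests and the acceptance script

Simulated checks run on reduced problem sizes chosen once: 60-120 s
recordings instead of 480 s, 200 null cohorts x 500 permutations for the
FWE calibration, n = 40 + 30 subjects for the end-to-end effect recovery,
and 40 matched controls + 28 carriers for the classifier power check.
These sizes keep a full run on one core in the minutes range while leaving
each check's statistical resolution far finer than the effects being
verified.

## Known limitations

* The surrogate mode inference assumes covariance-expressible modes and
  degrades when modes mix on time scales far below the window length.
* Permutation inference permutes outcomes only (no residual permutation),
  so strong confound-outcome correlation combined with confound-group
  imbalance can cost power (not validity under the global null).
* The PR-AUC bootstrap CI is approximate for very small positive classes.
* CoE is computed on the rectified periodic component; spectra whose
  periodic component is essentially zero give NaN and are excluded by
  downstream consumers.
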