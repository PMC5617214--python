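# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `fhrhdp`, and what the validation suite does
and does not establish.

## Signal model and preprocessing

Input is a 4 Hz FHR series in bpm with 0 encoding missing samples. Two
defect types are handled by one rule set: a sample is flagged when it is 0,
or when it departs from the last accepted sample by more than 25 bpm; the
flagged run then extends until the signal returns to within 25 bpm of that
last accepted value. Flagging the *later* sample of an offending pair and
anchoring on the last accepted value avoids flagging the recovery sample.
Flagged runs shorter than 15 s (60 samples) are refilled with
shape-preserving piecewise cubic Hermite interpolation (scipy's PCHIP,
fitted on all retained samples); runs of 15 s or more — and any run
touching a signal boundary, where Hermite interpolation has no second
endpoint — are excised, with their original index spans recorded. The
remaining signal is concatenated before segmentation, which keeps the
segment count `m = M·60/l` exact.

Every sample therefore has a provenance (measured, interpolated, or
dropped), and per-segment quality `u` is the measured fraction. Cohort
labels come from umbilical-cord pH: healthy above τ0 = 7.2, unhealthy at or
below τ1 (7.05 or 7.1); recordings in between are excluded, and an optional
seeded uniform subsample of the majority class balances the cohort.

## Features

Fourteen per-segment features in a fixed order: mean; sample SD; short-term
variability (mean |successive difference|); long-term variability (mean
per-minute range — for segments of at most one minute the whole segment is
the single block and the divisor is its duration in fractional minutes,
since 10–30 s segments admit no integer-minute blocks); short- and
long-term irregularity (IQRs of `arctan(s(k+1)/s(k))` and
`sqrt(s(k)²+s(k+1)²)`); Poincaré SD1, SD2 and CCM of the RR series
(RR = 60/FHR, seconds); and Welch band powers VLF [0, 0.06), LF [0.06,
0.3), MF [0.3, 1), HF [1, 2] Hz plus LF/(MF+HF).

Conventions worth stating:

- Successive-pair statistics run over the K−1 valid pairs with divisor K−1;
  IQR is Q3 − Q1 with linear interpolation between order statistics.
- The RR autocorrelation is non-centered and bias-corrected,
  `γ(k) = (1/(N−k)) Σ RR(i)·RR(i+k)`. This is the form under which
  SD1² = γ(0) − γ(1) and SD2² = γ(0) + γ(1) − 2·RR̄² are mutually
  consistent. On short, smooth segments the two estimates can cancel
  catastrophically, so negative squared descriptors are clipped to zero
  (with a warning) and a degenerate normalizer Cn = π·SD1·SD2 = 0 makes
  CCM 0 rather than undefined. CCM uses lag m = 1, N = the segment's RR
  length, and γ(−1) = γ(1) by symmetry.
- Spectral estimation is a single Hann-windowed Welch periodogram spanning
  the whole mean-removed segment (no averaging is possible at 40 samples);
  band powers integrate the PSD over half-open bands so they are additive.
  Frequency features are computed on the FHR signal in bpm, not on RR.

## Dimensionality reduction

Features are min-max scaled to (−1, 1) with training extrema (test rows may
exceed the interval and are not clipped; constant features map to 0), then
projected on the top-q principal axes of the scaled training table
(full-SVD PCA, q ∈ {2, 3, 4}). The component sign convention — largest
magnitude loading positive — makes the transform reproducible across runs
and platforms. Scaler and PCA are refitted inside every cross-validation
fold.

## HDP Gaussian mixture and collapsed Gibbs sampling

The base measure H is Normal–Inverse–Wishart; defaults are data-scaled and
weakly informative: μ0 = training mean, κ0 = 0.01, ν0 = q + 2, and scatter
matrix Λ0 = the empirical covariance of the (reduced) training features.
All are overridable. With H conjugate, component parameters are integrated
out and every likelihood term is a multivariate Student-t: for a component
with n observations, df = ν0 + n − q + 1, mean μn, scale
Λn(κn+1)/(κn·df). Component sufficient statistics (n, Σx, Σxxᵀ) support
O(1) add/remove, so leave-one-out and leave-block-out predictives are
exact. The block predictive of a table is the chain of one-point
predictives with earlier block members absorbed.

One Gibbs sweep resamples every customer's table (occupied tables weighted
by occupancy × dish predictive; a new table by α × the franchise-level
mixture of dish predictives and the γ-weighted prior predictive), then
every table's dish (existing dishes by global table count × block
predictive; a new dish by γ × prior block predictive), then the
concentrations. Emptied tables and dishes are garbage-collected
immediately. All weights are handled in the log domain with log-sum-exp,
and the categorical normalization is asserted before each draw.

Concentrations carry γ ~ Gamma(1, 1) and α ~ Gamma(10, 1) hyperpriors.
γ is updated by the Escobar–West beta-auxiliary step given (K, total
tables); α by the multi-group auxiliary scheme (per-restaurant Beta and
Bernoulli auxiliaries) given the per-restaurant customer counts and the
total table count. With no data both reduce to prior draws. A `frozen`
flag fixes them instead, which the exact-enumeration test uses.

Initialization is a sequential CRF pass — each customer seated by the
prior-times-likelihood rule — which is itself a draw from the model and
mixes faster than one-cluster starts. Default sampler budget is 1000
sweeps, 500 burn-in, thinning 5, all configurable, with a required integer
seed; the validation suites use much smaller budgets (tens of sweeps)
because their synthetic posteriors are sharply separated.

Held-out recordings are scored by treating each test segment as a new
table's first customer: per retained posterior snapshot the density is
`Σ_k m_k/(m_·+γ)·postpred_k(x) + γ/(m_·+γ)·priorpred(x)`, and snapshots are
averaged on the density scale. Per-recording log-likelihood is the sum over
segments.

## Finite-capacity franchise and real-time tracking

The CRFC caps each restaurant at N customers; a new segment arrives only
after the oldest leaves, and seating uses the post-removal counts with
denominator N − 1 + α. Since that denominator is common to all options,
the seating weights coincide with the CRF's on the starred counts, and
warm-up (below capacity) is exactly the CRF — which the equivalence tests
exploit. The tracker initializes both class models on the first 30-minute
window of their training recordings, then per 1-segment step evicts and
admits one segment per training restaurant, runs a small number of
refresher sweeps (default 5), and scores the test recording's most recent
window with both models to emit naive and weighted probabilities. Training
recordings keep their class for the whole duration; labels are never
re-assigned online.

## Classification and evaluation

Label = healthy iff l0 ≥ l1 (an exact tie is labelled healthy with a
warning, since the decision rule is a strict inequality). Naive and
weighted probabilities are computed with log-sum-exp; when all segment
qualities are equal the two coincide exactly (w_i = 1/m). Metrics use
"positive = unhealthy" (detecting the compromised fetus), switchable via
`positive_label`. WRA = 4·cost·(TPR − FPR)/(1+cost)², so TPR − FPR at
cost 1. Cross-validation is stratified (a balanced cohort with few
recordings makes unstratified folds degenerate), seeded, and refits the
entire pipeline per fold.

## Synthetic data

The grouped-mixture generator draws per-group component indices from known
weights and observations from shared Gaussian components — exactly the
model's generative assumption — and returns ground-truth labels. The
standard validation configuration uses K = 3 unit-variance components with
means 10 SDs apart, J = 6 groups of 100 observations.

The FHR simulator composes a 100–180 bpm baseline with two slow sinusoidal
drifts, AR(1) beat-scale variability (ρ = 0.9, ~2.5 bpm), sparse
raised-cosine accelerations/decelerations (~1/min, ~15 bpm), then injects
spike artifacts (+40 bpm, ~0.5/min) and zeroed gaps (~0.5/min, durations
4/8/25 s so both sides of the 15 s rule fire), keeping defects disjoint
and away from boundaries so each rule triggers unambiguously. It exercises
the preprocessing rules and provides class-separable recordings; it does
not attempt physiological fidelity (no contraction coupling, no
sinusoidal/saltatory patterns, no transducer-specific noise), so passing
tests demonstrate correctness of the pipeline's mechanics, not clinical
performance on real cardiotocograms.

## Validation problem sizes

The deeper suites run at deliberately desk-scale sizes: exact enumeration
on 1 group × 4 observations (q = 1, frozen α = γ = 1) against 10⁵ post
burn-in sweeps; quadrature checks of the NIW predictives at three 1-D
configurations; mixture recovery at J = 6 × 100 observations for 3 seeds
(60 sweeps); end-to-end cross-validation on 8 recordings per class × 12
segments of 14 features at 10-SD class shift for 5 seeds (30 sweeps); and
the preprocessing closed loop on 45-minute simulated traces.

## Known limitations

- SD1/SD2/CCM are noisy on 40-sample segments and frequently clipped; they
  survive in the feature vector for completeness but carry little signal at
  l = 10 s.
- The predictive for held-out recordings is a modelling choice (new-table
  first-customer form); other plug-in predictives are defensible.
- The CRFC tracker's per-step retraining budget trades accuracy for
  latency; sweeps_per_step = 0 (window advance only) up to large budgets
  are all supported.
- Recording input is plain CSV; clinical formats must be converted
  upstream.
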