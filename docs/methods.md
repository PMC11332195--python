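# Methods

This note documents the models behind `scenecue`, the defaults and why
they were chosen, the numerical decisions, and what a passing test suite
does and does not establish.

## Scene scores

A labeled corpus supplies, for every scene, its category, its object
list, and a per-occurrence anchor flag. From counts:

- diagnosticity(o, c) = #scenes of c containing o / #scenes containing o.
  By construction these sum to 1 over categories for each object, i.e.
  they estimate P(c | o) under the corpus's category base rates.
- anchor_freq(o, c) = #scenes of c where o is flagged anchor / #scenes of
  c containing o.

Two glosses of "anchor status frequency" circulate (probability of anchor
status within a category vs within a scene); we implement the
per-category conditional above and document it as one defensible reading
rather than the only one.

Per-image scores take the **maximum** table entry over the image's
predicted objects after filtering: predictions with probability strictly
greater than 0.3 are kept, and structural elements are removed. The
structural set defaults to exactly {window, wall, floor, door} and is
user-extensible — the source description ("such as") implies a
non-exhaustive list, so the default stays minimal and explicit. Pairs
never observed in the corpus are *skipped*, not scored 0: absent evidence
is not evidence of absence. Only when no object survives does the scene
get (0, 0) with an `empty` flag, so downstream regressions keep it.

Scores are conditioned on the image's nominal category (the GAN/LSUN
label), matching the category-specific probability assignment. The
z-transform used for regression predictors (sample mean 0, SD 1, ddof=1)
is computed within each analysis set; constant input raises an explicit
degenerate-input error.

## Signal detection observer and empirical ROC

The observer model is equal-variance Gaussian SDT. Evidence on one trial
is x ~ N(μ, 1) with

μ = d′(duration)·[condition = real] + β_anchor·z_anchor
    + β_diag(condition)·z_diag + participant intercept.

The response is "real" iff x exceeds the middle of 11 ordered criteria;
confidence is the position of x among them, giving a 12-bin ordinal
scale (1 = confident generated … 12 = confident real; the mapping is the
bijection implemented in `confidence_scale`). The empirical ROC evaluates
hit(k) = P(scale > k | real) and fa(k) = P(scale > k | generated) at the
11 interior cutoffs, appends (0,0) and (1,1), and integrates by
trapezoid. Under this model the true AUC is Φ(d′/√2).

Defaults and their rationale:

- d′ per duration is back-computed from the reported group AUCs,
  d′ = √2·Φ⁻¹(AUC) → 0.358 (50 ms), 1.987 (500 ms). These are stated as
  defaults, not ground truth about any observer.
- Criterion placement is unreported for human observers, so the default
  puts the 11 criteria at equal-mass quantiles of the observer's evidence
  mixture — observers spreading confidence categories roughly evenly, a
  standard convention in confidence-ROC work. A practical consequence:
  the 11-point trapezoid then underestimates the smooth binormal AUC by
  ≤ 0.0023 across the d′ range used here, comfortably inside the ±0.005
  tolerance the acceptance suite checks at 10⁵ trials. Wider, fixed
  criterion grids (e.g. ±2.5 evidence units) push that binning bias to
  ≈ 0.005–0.006 and were rejected for that reason — a property of the
  stated convention, verified before the tests were frozen.
- Participant heterogeneity is additive intercepts only (SD 0.3 by
  default); random slopes are out of scope.
- Group AUC is the unweighted mean of per-participant AUCs; pooled-trials
  AUC is available by flag. On homogeneous groups the two agree within
  0.01.
- d′ from a single (hit, FA) pair applies the log-linear correction
  (+0.5/+1) by default; 1/(2N) clipping is available; both are logged in
  the result.

The bootstrap AUC comparison resamples participants with replacement and
then trials within (participant, condition) — implemented as multinomial
resampling of per-participant 12-bin scale counts, which is *exactly*
equivalent for any statistic of the empirical ROC and orders of magnitude
faster. Flat trial resampling is available by flag. The two-sided p-value
is add-one smoothed, 2·(min tail + 1)/(N + 1), capped at 1; each input
table's resampling stream is derived from a digest of its own counts, so
swapping the two inputs exactly negates the difference distribution and
identical inputs give p = 1.

Per-image *realness* is the mean binary response (real = 1) per duration.
The pipeline presents every image at both durations (crossing durations
within participant), which emulates the counterbalanced design at the
group level and guarantees support in every image × duration cell; the
cost is that each simulated participant sees an image twice rather than
once.

## Fixed-effects regressions

A declared simplification of mixed-effects analyses: the inferential
claims here are about recovering *planted* fixed effects in synthetic
data, not reproducing mixed-model coefficients. Two-level factors are
sum-coded — the first sorted level gets +1 (so 50 ms → +1, "generated" →
+1) — making the intercept the grand mean and slopes half the difference
between levels. Continuous predictors are z-scored; interactions are
elementwise products of coded columns; factors with more than two levels
are rejected (none occur in these designs). Optional sum-coded
participant indicator columns absorb participant intercepts.

Families and fitting:

- linear: OLS; t statistics on n − p df; an exactly-collinear response
  yields a `degenerate` flag (zero residual variance, SEs meaningless).
- logistic / probit: binomial GLM (statsmodels IRLS, tolerance 1e-10,
  max 100 iterations); SEs from the inverse Fisher information; Wald z
  and p. Coefficients diverging past |β| > 30, or the library's own
  separation detection, raise an explicit separation error. A rank-
  deficient design is rejected up front.
- chance-corrected logistic: P(y=1) = γ + (1−γ)·σ(η) with known guess
  rate γ (0.2 for 5-AFC accuracy), fitted by damped Fisher scoring with a
  trust region (step capped at 2 per iteration). When the data sit at or
  below the guessing floor the likelihood is flat in the slopes and the
  intercept MLE is at −∞; the fitter stops on gradient stall or
  vanishing improvement and returns near-zero slopes with very wide SEs
  rather than an error — the scientifically useful answer for
  chance-level observers.

Why probit is in the family set: responses simulated by thresholding
Gaussian evidence follow a probit, not logistic, law. Refitting with a
logistic link recovers ≈ 1.6–1.8 times the evidence-scale coefficient, so
recovery of a planted evidence-scale β (e.g. 0.18) is checked with the
probit family — the correctly specified model — while logistic remains
the default reporting family. For the same reason 5-AFC accuracy
generated with a 0.2 guessing floor is recovered with the
chance-corrected likelihood, not plain logistic.

Wald 95% CIs are β ± 1.96·SE in every family. `linear_trend` converts a
continuous-by-factor interaction into per-level slopes b_cont ± b_int
with SEs from the coefficient covariance; their average equals the main
effect exactly under sum coding.

## Layer-wise encoding analysis

Feature matrices (images × features) per model instance and layer carry a
normalized depth l/(L−1) ∈ [0, 1] and a trained/random flag. The decoding
pipeline per matrix:

1. Sparse random projection to `srp_dim` when that is below the input
   dimensionality (density 1/√D entries in {−1, 0, +1}, variance-scaled;
   pass-through otherwise, logged).
2. Leave-one-out cross-validated ridge regression. For each held-out
   image, the penalty is selected on the training fold by closed-form GCV
   over a 13-point log grid 10⁻¹…10⁵ (SVD once per fold; GCV(α) =
   n·RSS/(n − edf)², edf = Σ s²/(s² + α)), and the held-out score is
   predicted from that training-fold fit. X standardization statistics
   come from the training fold only. y is centered once on the full
   sample: correlation scoring is location-invariant, and per-fold
   centering would make a fully shrunk null fit predict the leave-one-out
   mean, which is perfectly anti-correlated with the held-out values (the
   familiar constant-model LOO artifact, r → −1). Even so, per-fold GCV
   adaptivity leaves null decoding scores mildly dispersed and slightly
   negative on average (≈ −0.13 at n = 100) — a property of LOO
   correlation scoring, shared identically by trained and random
   instances and therefore harmless to their comparison.
3. Score r = Pearson correlation of predictions with actual values
   (Pearson, not rank, matching the predicted-vs-actual convention).

Layer scores are averaged within 10 depth bins, bin b covering
[(b−1)/10, b/10) with the last bin closed at 1; empty bins propagate as
missing and are excluded from inference. Trained vs random per bin:

- one-sided permutation test of mean(trained) − mean(random), relabeling
  the 14 model instances, p = (1 + #{perm ≥ obs})/(N + 1), N = 10 000 by
  default. One permutation matrix is reused across bins so per-bin nulls
  stay coupled the way the data are. The quoted "95.5%" significance
  cutoff in the source description is read as a typo for 95%; the
  default rejects at p ≤ 0.05 and the threshold is a parameter for
  anyone wanting literal fidelity (0.045).
- Benjamini–Hochberg FDR across the 10 bins (q-values monotone; missing
  bins excluded).
- bootstrap mean and percentile 95% CI of the paired per-model
  differences (N = 1000). Percentile intervals undercover somewhat at
  n = 7 pairs (~91–93% observed) — inherent to the estimator, documented
  rather than corrected.
- paired JZS Bayes factor: one-sample default-prior (Cauchy, r = 0.707 —
  the quoted "r = 707" is read as 0.707) Bayes factor on the differences,
  computed by adaptive quadrature of the standard g-mixture integral;
  cross-checked against an independent fine-grid oracle and pingouin to
  1e-6 relative error. Monotone in |t| at fixed n; BF₁₀ < 1 at t = 0.

Correlation scores are computed per model instance and then averaged
within bins (the per-model reading of the group comparison), never pooled
across models.

Real DNN feature extraction is out of scope; the `FeatureStore`
HDF5/CSV format is the interface an external extractor would write.

## Synthetic world

The generators plant every parameter the analyses try to recover.
Defaults encode the stated experimental world; where the sources fix no
value, one realistic value was chosen and is listed here:

| parameter | default | basis |
|---|---|---|
| categories × objects × corpus scenes | 5 × 40 × 200 | 5 LSUN categories; corpus is the score-table source, deliberately larger than the stimulus set |
| stimulus set | 30 real + 30 generated per category | stated image set |
| participants | 50 (Exp 1), 44 (Exp 2) | stated samples |
| d′ (50, 500 ms) | 0.358, 1.987 | √2·Φ⁻¹(AUC) from AUCs 0.6, 0.92 |
| β_anchor (evidence), β_diag by condition | 0.18; +0.08 real / −0.15 generated | reported estimates used as plausible effect sizes |
| rating model | α 3.5, β_anchor 0.15, β_diag −0.09, noise SD 1.0, participant SD 0.5 | β from reported estimates; α/noise chosen so the 1–6 scale is used without heavy clipping |
| 5-AFC model | b0 0.5, b_diag 0.53, b_realness 0.48, b_duration −1.07 | b0 chosen for mid-range accuracy; slopes from reported estimates |
| segmentation noise | miss 0.1, false label 0.1, prob noise SD 0.1 | plausible segmentation-quality regime |
| feature store | 12 layers × 256 dims (pipeline: 10 × 64), sigmoid depth-SNR (scale 6, midpoint 0.7), 7 trained + 7 random | "high-level features carry the signal" world; 7+7 matches the group comparison |

What the generator does *not* emulate: image content, confusion structure
among the four wrong 5-AFC categories (errors are uniform), random slopes
or item effects, reaction times, criterion variability across
participants, and any correlation between segmentation noise and scene
difficulty. A green suite therefore establishes that the *analysis chain*
is correct and calibrated on data satisfying its assumptions — not that
real observers satisfy those assumptions.

Determinism: every generator takes an explicit seed and derives
independent streams via seed sequences; the pipeline derives per-stage
seeds from the master seed by hashing the stage name, records them in a
run manifest together with the full configuration and its hash, and any
output table can be regenerated from the manifest alone. Identical seeds
give bit-identical outputs.

## Numerical notes and edge cases

- Probabilities at 0/1 in d′: rejected without a correction, corrected
  rates logged with the method used.
- Ridge GCV: constant feature columns get unit scale (they contribute
  nothing after centering); the alpha grid must be positive; fewer than
  10 images or constant y are rejected.
- `loo_ridge_fixed_alpha` exposes the exact hat-matrix LOO identity
  e_i/(1 − h_ii) (intercept unpenalized, no per-fold re-standardization)
  and is verified against explicit refits to 1e-8.
- Permutation p-values can never be 0 (add-one smoothing); with 7-vs-7
  groups only C(14,7) = 3432 labelings exist, so the attainable one-sided
  level is 171/3432 ≈ 4.98%.
- Tie-break in per-scene scoring: the first object in prediction order
  wins among equal scores (stable, order-preserving).
- 5-AFC wrong answers use a uniform draw over the other four categories
  implemented as a random cyclic offset, exactly uniform by construction.

## Known limitations

- Fixed-effects inference understates uncertainty relative to a
  mixed-effects treatment when participant slopes truly vary; the
  pipeline's claims are calibrated for the synthetic world, where they
  do not.
- The bootstrap AUC comparison treats resampled participants as new
  units; small participant counts make the percentile CI approximate.
- The encoding stage's null decoding scores are not exactly zero-mean
  (see above); all trained-vs-random conclusions are differential and
  unaffected, but absolute per-bin decoding scores should not be read as
  unbiased effect sizes.
- HDF5 feature stores hold everything in memory; the CSV fallback is for
  portability, not scale.
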