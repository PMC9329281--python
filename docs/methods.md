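# Methods

## Model and procedure

The pipeline estimates biological heart age from a tabular radiomics
feature matrix and profiles its correlates. Stages, in order:

1. **Screening/exclusions.** Participants with prevalent cardiovascular
   disease are removed (disease-driven remodelling would contaminate the
   normative aging signal), and the cohort is restricted to the ethnic
   group the normative model is built for. Filtering is idempotent and
   logs counts per criterion.
2. **Sex stratification.** All downstream models are fitted separately in
   women and men; cardiac geometry and its aging trajectories differ by
   sex, and a pooled model would mostly learn sex.
3. **Deconfounding.** Each feature is replaced by its residual from an
   OLS fit on height and weight (body size is the dominant nuisance
   source of variation in cardiac shape features), then standardized to
   zero mean / unit variance. The residualizer stores coefficients and
   moments at fit time and can be applied to unseen rows, which enables
   the leakage-free mode below. Residualization is exactly orthogonal to
   the confounds in-sample and invariant to affine confound rescaling, so
   units (cm vs m) are immaterial.
4. **Age model.** Bayesian linear regression with isotropic Gaussian
   weight prior and Gamma(10⁻⁶, 10⁻⁶) hyperpriors on both precisions,
   fitted by the closed-form evidence-approximation updates (posterior
   mean/covariance, effective degrees of freedom γ, then precision
   updates), iterated until the maximum weight change is below 10⁻³
   (cap 300 iterations; non-convergence is flagged, not raised). The
   eigendecomposition of XᵀX is computed once per fit. Initial noise
   precision 1/var(y), initial weight precision 1 — the standard
   reference defaults for this estimator. The intercept is handled by
   centring y. The log marginal likelihood is tracked and is monotone
   non-decreasing up to 10⁻⁶ per step.
5. **Cross-validation and bias correction.** Tenfold CV with seeded
   balanced folds (sizes differ by ≤ 1). Per fold, the bias line
   D = αΩ + β is fitted on training-set deltas and subtracted from the
   held-out predictions (CPHA = prediction − (αΩ + β)). Pooled
   out-of-fold CPHA over all folds gives exactly one estimate per
   participant; metrics (MAE, R², r(prediction, age), r(Δ, age)) are
   reported on the pooled vector, with per-fold values logged.
6. **Associations.** Pearson r with two-sided p from the t transform;
   Bonferroni correction min(1, p·m) per family; significance at
   corrected p < 0.05 (strict); ranking by ascending corrected p, ties by
   descending |r|. Feature profiling treats all features tested as one
   family; the exposure scan uses each of the 13 catalogue categories as
   its own family, with family sizes counted per sex (shared +
   sex-specific variables).

## Key design choices

**Training-delta estimation for the bias line (`bias_mode`).** In-sample
training predictions are systematically less attenuated than held-out
ones (optimism of order effective-dof/n), so a bias line fitted on them
under-corrects and leaves a residual negative Δ–age correlation in the
validation folds (measured ≈ −0.04 at n = 10,000 under default
conditions). The default `bias_mode="nested"` therefore estimates each
training participant's delta out-of-sample by reusing the remaining k−1
fold labels as an inner cross-validation inside the training set, which
restores the near-zero corrected correlation (measured +0.005 at
n = 10,000) that the correction exists to deliver, at the cost of k−1
extra fits per fold. `bias_mode="in_sample"` keeps the cheaper literal
variant for comparison.

**Full-sample vs per-fold deconfounding (`mode`).** The default
`mode="pooled"` residualizes and standardizes once on the whole stratum
before splitting. This leaks a small amount of held-out information into
the training folds through the confound coefficients and standardization
moments; `mode="strict"` refits the residualizer inside each training
fold. Both are first-class; the default replicates the reference
procedure, and the difference is small at cohort scale.

**Heart age used in profiling.** Feature profiling correlates against the
bias-corrected CPHA. Note the profile deconfounds features by age and
then correlates them with a quantity that is itself strongly age-related;
this mirrors the reference analysis and is kept as stated rather than
"fixed". p-values are floored at the smallest positive double before
−log10; corrected p capped at 1 renders as −log10 = 0.

**Missing exposure data.** Pairwise complete cases per variable, with a
minimum of 100 complete pairs; below that the variable is reported as
not-evaluable (NaN statistics, never significant, ranked last) rather
than dropped silently.

**Seed fan-out.** A single master seed spawns named per-stage seed
streams (generation, per-sex folds) via `numpy.random.SeedSequence`, so
any stage can be re-run in isolation and full reruns are byte-identical.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes:

* **Latent aging rate.** δᵢ ~ N(0, σ_δ²) with σ_δ = 5 years (the spread
  that places a regression-based age predictor's accuracy in the range
  reported for cardiac and brain age models); biological age
  Bᵢ = ageᵢ + δᵢ.
* **Demographics.** Ages truncated-normal within [45, 82] (women
  62.7 ± 7.3, men 63.8 ± 7.6); heights/weights sex-specific Gaussians
  (women 163.7 ± 6.3 cm, 68 ± 12.7 kg; men 177.4 ± 6.6 cm,
  83.1 ± 13.2 kg) — the baseline characteristics of the population the
  model targets.
* **Features.** xᵢⱼ = μⱼ(sex) + sⱼBᵢ + hⱼheightᵢ + wⱼweightᵢ + shared
  low-rank noise (rank 10, total sd 1.5) + iid noise (sd 0.8). Age
  loadings |sⱼ| ~ U(0.002, 0.008) with random signs. These defaults were
  set analytically, once: for the combined feature set to recover
  biological age with error variance ≈ 95 yr² — which puts
  tenfold-CV performance at the reported operating point (uncorrected
  MAE ≈ 4.8 y, R² ≈ 0.28, corrected r(prediction, age) ≈ 0.91) — the
  signal-to-noise ratio Σsⱼ²/σ² must be ≈ 1/95, and the dominant shared
  noise component reproduces the near-duplicate intercorrelation
  structure of real radiomics matrices.
* **Exposures.** Standardized at generation; a planted exposure with
  target correlation c is c·δᵢ/σ_δ + √(1−c²)·noise, so its population
  correlation with the latent aging rate is exactly c and it is
  independent of chronological age — the scan deconfounds age, so only
  age-orthogonal signal is detectable by construction. Null exposures
  are iid standard normal. Sex-specific variables are masked for the
  other sex; optional MCAR masking is available.

**What the generator does not emulate.** Real radiomics features have
heterogeneous per-feature effect sizes: a handful of shape features
correlate individually and strongly with age, while the generator spreads
the age signal thinly and near-uniformly across all 254 columns to match
the joint prediction performance. Consequently the per-feature profiling
stage finds few individually significant features on default synthetic
cohorts (≈ 2% vs the 70–76% reported on real data), and profiling power
is exercised instead through targeted fixtures with concentrated planted
loadings. Exposures are Gaussian and independent of each other (real
exposure batteries are mixed-type and correlated), there is no
measurement-error model for the confounds, and no non-White stratum is
modelled beyond the screening flag.

## Problem sizes

Unit and property tests run on cohorts of 10²–10³ participants with
10–60 features. The scale-sensitive checks use the sizes at which their
properties are stated: bias-correction removal at n = 10,000 (254
features), family-wise error control over 200 replicates of a 40-variable
null catalogue at n = 300, and planted-exposure ranking over 50
replicates at n = 5,000 with 60 features — 60 rather than 254 because
ranking power depends on the delta-recovery correlation, which is set by
the total signal-to-noise rather than the column count, and the smaller
matrix keeps the replicate loop economical. The acceptance script runs
the complete pipeline at full study scale (15,920 women, 14,076 men, 254
features, 701 exposures).

## Known limitations

* The regression-dilution correction assumes the bias is linear in age;
  curvature at the age-range edges is not modelled.
* Bonferroni control is exact for independent tests and conservative
  under positive dependence; no FDR alternative is provided.
* The Pearson-based scan detects linear associations only.
* `mode="pooled"` is knowingly not leakage-free (see above); use
  `mode="strict"` when that matters.
* Heart-age deltas have no per-participant uncertainty intervals.
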