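# Methods

## The clock model

`spermclock` predicts chronological age (years) from sperm
methylation-array beta values with a penalized linear regression on
region-level features. For sample *i* with feature vector *xᵢ* (one mean
beta per clock region) the fit minimizes

    (1/2n) Σᵢ (yᵢ − β₀ − xᵢᵀβ)²  +  λ [ α‖β‖₁ + (1−α)/2 ‖β‖₂² ]

the glmnet parameterization of the elastic net: `α ∈ [0, 1]` mixes the
lasso (sparsity) and ridge (shrinkage) penalties and `λ ≥ 0` scales the
whole penalty. Features are standardized to unit population variance
during optimization and coefficients are reported back on the beta
scale, so a stored coefficient reads as years per unit beta.
Optimization is cyclic coordinate descent (scikit-learn's
`ElasticNet`/`enet_path`, which minimize exactly this objective); the
unpenalized limit `λ = 0` is solved directly by least squares
(minimum-norm when rank deficient). The fit is deterministic for fixed
inputs.

Assumptions: age enters each region's methylation linearly over the
modelled range (~20–45 years), region means in [0, 1] are treated as
ordinary real covariates (no logit link), and age itself is regressed
untransformed — no log-linear age warp, since the cohort the clock
targets spans only adulthood.

### Key parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.5 | L1/L2 mix; 1.0 = pure lasso, 0.0 = ridge. A neutral mix is the default; the mix is recorded in the model file. |
| `lambda` | chosen by CV | penalty strength, selected on a log grid from λ_max (all coefficients zero) down 3 decades (30 values) by k-fold CV minimizing out-of-fold MSE (`lambda.min`); a one-standard-error rule (`1se`) is available by flag. Ties go to the larger (more parsimonious) λ. |
| `k` | 10 | folds for both λ selection and the outer CV protocol. |
| `min_probes` | 1 | minimum probes a region needs to yield a feature; the packaged regions are ~1 kb and sparse on arrays, so no silent floor is applied. |
| `stability threshold` | 0.80 | inclusion-frequency cutoff, boundary inclusive ("80% or more"). |
| `QC threshold` | 0.2 | beta-units a panel-locus mean must deviate beyond the expected sperm range, toward the somatic state, before the locus counts against a sample; a strict majority of covered loci flags the sample. |

### Cross-validation protocol

The outer protocol is k-fold CV repeated R times (10 × 10 by default) on
freshly shuffled partitions whose fold sizes differ by at most one.
Inside every fold, λ is re-selected by an inner CV on that fold's
training portion only — held-out samples never touch any modelling
choice. Per-repeat test R² is the squared Pearson correlation of the
repeat's pooled out-of-fold predictions against actual age (one value
per repeat, so design comparisons by two-sample t-test are
well-defined); per-repeat train R² is the mean of the fold models'
training correlations. "A feature is used by a model" means a nonzero
elastic-net coefficient; inclusion frequency divides by all k × R
fold-models.

The t-test engine is Student's pooled two-sample test, two-tailed
(Welch by flag); the same engine backs both the design comparison and
the smoking group comparison. Degenerate input (both groups constant
and equal) returns p = 1 by convention.

### Metrics

MAE = mean |predicted − actual| in years; MAPE = 100 · mean
(|predicted − actual| / actual), relative to chronological age; R² is
the squared Pearson correlation of predicted vs actual, identical to
the R² of the least-squares line of predicted on actual (that
regression's slope, intercept and slope-test p-value are also
reported). Replicate precision is the sample SD (n−1) of predicted age
within each individual's technical replicates; the summary value is the
unweighted mean of per-individual SDs (with equal replicate counts the
weighted alternatives coincide). Age acceleration is the signed percent
100 · (predicted − chronological)/chronological; the "< 35 years"
subgroup filter is strict.

## The synthetic-data generator

`simulate_cohort` emulates the statistical structure the clock assumes,
not array chemistry. Defaults are the study conditions:

- **Cohort**: 250 samples (330 where a 250/80 train/test split is
  needed), ages uniform on 20–45 years.
- **Signal**: 148 regions of ~1 kb, 8 gaining and 140 losing
  methylation with age; slopes uniform in magnitude on 0.002–0.006
  beta/year; hypomethylating baselines 0.55–0.90, hypermethylating
  0.10–0.40 (betas at the young reference age of 20).
- **Probes**: 3–8 probes per region with fixed per-probe offsets
  (SD 0.02), plus 2000 age-independent background probes with a bimodal
  baseline, plus the contamination-panel loci.
- **Noise**: truncated-Gaussian measurement noise on the beta scale,
  SD 0.03 per probe, clipped to [0, 1] (a logit-normal option exists);
  and a per-sample *biological age* offset, Gaussian SD 2.0 years,
  applied to every signal region. The shared offset is what puts a
  realistic floor (~1.6 years MAE, R² ≈ 0.93 at these settings) under
  any predictor: without it, averaging hundreds of probes would drive
  prediction error implausibly close to zero compared with what sperm
  clocks achieve on real cohorts.
- **Smoking**: effective-age inflation — a smoker's signal regions look
  `age · (1 + s/100)` years old — so the ground-truth group acceleration
  equals the configured percentage by construction.
- **Replicates**: per individual, the measured probe profile plus
  independent replicate noise (SD 0.02 default), clipped; 10 × 6 by
  default.
- **Contamination**: per-sample somatic admixture moves panel-locus
  betas toward the somatic state in proportion to the mixing fraction;
  blood positive controls sit fully at the somatic state. Admixture is
  modelled at panel loci only — its (second-order) effect on clock
  regions is not simulated, since the screen, not the clock, is what it
  exercises.

The truth object carries everything needed to recompute expected region
means analytically, plus two derived quantities used by tests: the
information-weighted age-equivalent variance of probe noise
(`1/Σ_r m_r s_r²/σ²`), and the implied MAE floor
`√(2/π) · √(σ_bio² + that variance)` and attainable R²
`Var(age)/(Var(age) + noise)`.

What passing tests do **not** show about real data: the generator has no
batch effects beyond an optional offset, no probe-type bias, no
cross-reactive probes, and exactly linear age effects — real cohorts
will be harder, and metric values obtained on simulations are
statements about the software, not about sperm.

## Numerical choices

- Coordinate-descent tolerance 1e−7 for reported fits (tight enough
  that the objective matches an independent convex solve to ~1e−13);
  the inner CV paths that only *rank* λ values use 1e−4 for speed.
  Maximum 10⁵ iterations.
- Constant feature columns get unit scale during standardization (their
  coefficients are irrelevant and remain zero under any penalty).
- Missing features at prediction time (absent columns or NaN entries)
  are imputed with the training-set feature means stored in the model.
- Fold assignment is a pure function of the seed
  (`numpy.random.default_rng`); inner-CV seeds derive deterministically
  from (seed, repeat, fold) so results are independent of iteration
  order. Region tables are 1-based inclusive internally; BED input is
  converted on read.
- Model files are JSON with a schema version; floats use shortest
  round-trip representation, so reloaded models reproduce predictions
  bit for bit. Delimited readers use round-trip float parsing for the
  same reason.

## Problem sizes

The repeated-CV runs in the test suite and in `scripts/acceptance.py`
use 3 repeats of 10-fold CV with 5-fold inner λ selection on the
250-sample training split; multi-seed recovery checks use 10 seeds
(training/evaluation) and 50 seeds (smoking-shift recovery). These sizes
give stable Monte-Carlo estimates while keeping a full run in minutes on
one CPU; the protocol defaults in the library remain 10 × 10 with
10-fold inner selection.

## Known limitations

- Stability selection on the default cohort retains roughly a third of
  the 148 signal regions in ≥ 80% of fold-models. This is expected, not
  a defect: all regions proxy the same latent age signal, so the
  sparsity-inducing penalty freely swaps redundant regions between fold
  models. Selection here identifies a *sufficient* predictive subset,
  not the complete causal set.
- The exact coefficients of any real-cohort clock are not reproducible
  from published summary numbers; this package reproduces the method,
  and its metric definitions, not a specific fitted model.
- The contamination screen flags; it does not estimate the admixture
  fraction.
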