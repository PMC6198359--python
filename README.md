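# spermclock

**Germ-line age prediction from sperm DNA methylation.**

Sperm age differently from somatic tissue: most of the ~1 kb genomic
regions whose methylation tracks age in the male germ line *lose*
methylation with age, and somatic-tissue epigenetic clocks fail on sperm
altogether. `spermclock` implements a sperm-specific "germ line age"
calculator for researchers working with methylation-array beta values
(fraction methylation per CpG probe, in [0, 1]):

- **Region-level features** — per-sample mean beta over a fixed set of
  clock regions (a packaged set of 50 named intervals ships with the
  package; any region list can be supplied as CSV or BED).
- **An elastic-net age regression** — minimize
  `(1/2n) Σᵢ (yᵢ − β₀ − xᵢᵀβ)² + λ[α‖β‖₁ + (1−α)/2 ‖β‖₂²]`
  of chronological age *y* (years) on region means *x*, with the penalty
  strength λ chosen by internal k-fold cross-validation (glmnet-style
  parameterization; α mixes lasso and ridge, default 0.5).
- **Repeated 10-fold cross-validation with stability selection** —
  regions with nonzero coefficients in ≥ 80% of fold-models form the
  "optimized" region list; feature designs (entire array, per-CpG,
  regional) are compared by two-tailed t-tests on per-repeat R².
- **Evaluation and inference** — MAE (years), MAPE (% of chronological
  age), R² (squared Pearson of predicted vs actual), technical-replicate
  precision (per-individual SD of predicted age), and smoking
  age-acceleration statistics (signed percent difference between
  predicted and chronological age, compared between exposure groups).
- **Contamination QC** — sperm and somatic tissue have opposite
  methylation states at discriminating loci such as DLK1; samples
  drifting toward the somatic state are flagged.
- **A synthetic-cohort generator** — probe-level cohorts with
  region-structured linear age effects (140 hypo- / 8 hypermethylating
  regions by default), biological and technical noise, technical
  replicates, smoking effects and somatic admixture, with full ground
  truth for end-to-end testing.

## Worked example

```python
import spermclock as sc

# a 330-man cohort, ages 20-45, with known ground truth
cohort = sc.simulate_cohort(sc.SimulationConfig(n_samples=330, seed=1))
feats  = sc.build_features(cohort.betas, cohort.manifest, cohort.regions)

X, ages = feats.values, cohort.truth.ages
X_train, y_train = X.iloc[:250], ages.iloc[:250]
X_test,  y_test  = X.iloc[250:], ages.iloc[250:]

lam, _ = sc.select_lambda_cv(X_train, y_train, k=10, seed=1)
model  = sc.fit_elastic_net(X_train, y_train, lam=lam)
report = sc.compute_metrics(sc.predict_age(model, X_test), y_test)
print(f"MAE {report.mae:.2f} y  MAPE {report.mape:.2f}%  r2 {report.r2:.3f}")
print(f"analytic floor {cohort.truth.mae_floor():.2f} y")
```

prints

```
MAE 1.68 y  MAPE 5.82%  r2 0.926
analytic floor 1.61 y
```

The held-out MAE of 1.68 years sits just above the 1.61-year analytic
floor implied by the generator's noise (2 years of per-sample biological
scatter plus probe noise averaged over each region), and R² = 0.926 is
close to the 0.928 attainable under those conditions — the clock
extracts essentially all the age information the data contain.

The same pipeline is available from the shell:

```sh
spermclock simulate --out cohort/ --seed 1 --n-samples 330
spermclock qc        --betas cohort/betas.tsv --manifest cohort/manifest.csv --out qc/
spermclock train     --betas cohort/betas.tsv --manifest cohort/manifest.csv \
                     --regions cohort/regions.csv --metadata cohort/metadata.csv \
                     --seed 1 --out fit/
spermclock predict   --betas cohort/betas.tsv --manifest cohort/manifest.csv \
                     --regions cohort/regions.csv --model fit/model.json --out pred/
spermclock evaluate  --predictions pred/predictions.tsv \
                     --metadata cohort/metadata.csv --out eval/
```

Every command writes a `run_manifest.json` (parameters, seed, input
hashes, version) so runs can be reproduced bit for bit.

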