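# epiresponse

Peripheral-blood DNA-methylation analysis for predicting therapy response in
rheumatoid arthritis, built as a tested, reusable pipeline.  The target
setting is an EWAS on whole blood of patients starting a TNFα-inhibitor
(adalimumab): beta values from an EPIC-style array, a clinical sample sheet
with DAS28 disease-activity scores, and the question of whether baseline
methylation can classify eventual responders from non-responders.

Because real cohorts of this kind are controlled-access, the package ships a
first-class synthetic-cohort generator with known ground truth (planted
response-associated CpGs, SNP-affected probes, leukocyte mixtures, covariate
effects, DAS28 trajectories), so every stage is testable end to end without
any download.

## What the pipeline does

1. **Preprocessing** (`epiresponse.preprocess`) — beta ↔ M-value transforms
   (`M = log2(β / (1 − β))`; M-values for statistics, betas for
   interpretation), allosome exclusion, and *gap hunting*: probes whose
   sorted betas split into ≥ 2 clusters at gaps > 0.3 carry the bi-/tri-modal
   signature of an underlying genetic variant and are flagged.
2. **Cell deconvolution** (`epiresponse.deconvolution`) — per sample, solve
   `min_w ‖R w − b‖²  s.t.  w ≥ 0` over reference profiles `R` of six
   leukocyte types (B, CD4T, CD8T, monocytes, neutrophils, NK) by
   non-negative least squares; compare compositions between response groups
   with a two-way ANOVA plus per-cell-type contrasts.
3. **Differential methylation** (`epiresponse.diffmeth`) — per-CpG OLS of
   M-values on intercept + response + covariates (age, sex, smoking,
   concomitant methotrexate), t-test on the response coefficient, and the
   group difference of mean betas (Δβ) for reporting.
4. **Gene-level aggregation** (`epiresponse.geneagg`) — probes annotated to
   the nearest gene within 20 kb; per-gene combination of correlated CpG
   p-values by Brown's method (Fisher's ψ = −2Σln pᵢ referred to a scaled
   χ² whose variance includes Kost–McDermott pairwise covariances); loess
   regional Δ-methylation profiles with pointwise standard errors.
5. **Response labeling** (`epiresponse.labels`) — the DAS28 decision rule
   (responder: follow-up < 3.2 or decrease ≥ 1.2; non-responder: follow-up
   > 5.1 or decrease < 0.6), with rule overlaps surfaced as `conflict`, plus
   a baseline-characteristics table with χ²/t/Mann–Whitney tests.
6. **Classifier** (`epiresponse.stability`) — stratified 70/30 split,
   stability-selected gradient boosting: 100 cross-validation resamples,
   each with a fresh random noise probe injected among the features;
   features whose gain importance beats the noise probe are marked selected;
   resamples aggregate into a consensus panel (Copeland ordering of the
   pairwise win matrix; membership by a stability screen plus a sign-flip
   permutation test with BH control); a final model retrained on the panel
   is scored by AUROC on the held-out test set.

## Worked example

```python
from epiresponse import synthetic, preprocess, stability

refs = synthetic.generate_reference_profiles(60, 10, seed=1)
cfg = synthetic.GeneratorConfig(
    n_samples=114, n_probes=2000, n_informative=10,
    delta_logit=0.8, responder_fraction=0.5, seed=5,
)
beta, sheet, manifest, truth = synthetic.generate_cohort(cfg, refs)

m = preprocess.beta_to_m(beta, offset=1e-6).T       # samples x probes
bc = stability.BoostConfig(seed=7)
X_tr, y_tr, X_te, y_te = stability.split_train_test(m, sheet["response"], 0.7, seed=2)
result = stability.run_stability_selection(X_tr, y_tr, bc)
panel = stability.aggregate_pairwise(result, bc)
model = stability.train_final(X_tr, y_tr, panel, bc)
perf = stability.evaluate(model, X_te, y_te, result, bc.cv_folds)
print(len(panel), sorted(panel.features))
print(round(perf.test_auroc, 3), round(perf.mean_cv_auroc, 3))
```

prints

```
5 ['cg00000000', 'cg00000001', 'cg00000002', 'cg00000003', 'cg00000004']
1.0 1.0
```

i.e. the consensus panel recovered 5 of the 10 planted CpGs (the remainder
fall below the 90% stability screen at this sample size) and the retrained
model separates the held-out samples perfectly — expected here, since a
planted logit shift of 0.8 against measurement noise of SD 0.15 is a strong
per-probe effect.  On a label-permuted null cohort the same pipeline returns
a near-empty panel and a held-out AUROC near 0.5.

The same analysis is available from the shell:

```
epiresponse run --outdir run1 --seed 5      # simulate + full pipeline
epiresponse report --outdir run1            # verify artifact checksums
```

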