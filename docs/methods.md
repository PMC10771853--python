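# Methods

This note documents the models, numerical choices and known limitations of
the package, in the spirit of a statistical methods appendix.

## Data model and scales

A methylation array reports, per CpG probe and sample, a beta value
β ∈ [0, 1] — the fraction of methylated copies.  Statistics are computed on
the M-value scale, M = log2(β / (1 − β)), which stabilizes variance and is
unbounded; betas are used for interpretation (a Δβ of 0.05–0.15 is a typical
reportable effect).  `beta_to_m` takes an offset that defaults to 0 with
strict validation: a beta of exactly 0 or 1 is rejected with advice to pass
a small offset (1e−6) rather than silently producing ±∞.  The inverse
transform is exact at offset 0; the round-trip error is at machine
precision.

## Synthetic cohorts: what they emulate, and what they do not

`synthetic.generate_cohort` draws, per sample:

* **Cell composition** — Dirichlet over six leukocyte types with
  neutrophil-dominant means (Neu 0.60, CD4T 0.15, CD8T 0.08, Mono 0.08,
  B 0.06, NK 0.03) and concentration 50, giving realistic between-donor
  spread.  Deconvolution-panel betas are the reference profiles mixed by
  the true proportions.
* **Response effects** — a constant shift of `delta_logit` (default 0.8 on
  the log2-odds scale) added to responders at the informative probes.
  Planting on the logit scale keeps betas in [0, 1] and makes the M-value
  regression model exactly correct, which keeps oracles closed-form.
* **SNP-affected probes** — tri-modal clusters at β ∈ {0.05, 0.5, 0.95}
  with Hardy–Weinberg genotype frequencies at allele frequency 0.5
  (25/50/25), the configuration that maximizes detectability.
* **Covariate effects** — smoking and concomitant-methotrexate carriers get
  a logit shift at dedicated probe blocks; covariate prevalences differ by
  response group (smoking 20.4% vs 42.9%, MTX 85.7% vs 65.1%, female 79.6%
  vs 74.4%, age means 52.7 vs 55.4), so confounding analyses have something
  real to find.
* **DAS28 trajectories** — baseline ~ N(4.8, 1.2²); the follow-up score is
  rejection-sampled from a group-specific proposal until the clinical
  decision rule reproduces the intended label exactly, so emitted labels
  are always unambiguous (conflicting draws are redrawn, never resolved
  silently).
* **Noise** — i.i.d. N(0, noise_sd²) on the logit scale, applied last;
  default SD 0.15.  This value represents technical plus residual
  biological variation and keeps the tri-modal SNP signature separable at
  the 0.3 gap threshold, as it is on real arrays.  At noise_sd = 0 the
  generator skips the transform entirely, so zero-noise mixtures are exact
  to the last bit.

Not emulated: batch/chip effects, probe cross-reactivity, detection
failures, cell-type-specific response effects, and any correlation
structure between probes beyond gene-block adjacency.  Passing tests on
these cohorts therefore demonstrate correctness and calibration of the
machinery, not field performance on real arrays.

With the default effect size (Δlogit 0.8 ≈ Δβ 0.04–0.16 depending on the
baseline) against noise SD 0.15, single planted probes are strongly
separable; recovery tests are deliberately run at these conditions, and
null behavior is tested separately on label-permuted cohorts.

## Gap hunting

Sorted betas are cut wherever consecutive values differ by more than the
threshold (default 0.3).  Clusters smaller than `min_group_fraction`
(default 0.01) of the samples are outliers and do not by themselves cause
flagging; a probe is flagged iff ≥ 2 non-outlier clusters remain.  Flags are
reported rather than probes dropped (a config switch enables removal): in
cohorts of this kind the characteristic multi-modal pattern is usually
absent after upstream QC, so the flag is a diagnostic.

## Deconvolution

Per sample we solve non-negative least squares against the six reference
profiles; the sum-to-one constraint is *not* imposed during optimization
(matching reference-based projection practice), and normalized proportions
are derived afterwards.  On noiseless mixtures the raw solution sums to one
to ~1e−7 without the constraint, which the tests check.  Group comparison
uses a two-way fixed-effects ANOVA (type-II sums of squares, appropriate
for unbalanced 49/43-style designs) of proportion on response × cell type.

**Caveat** — compositional proportions are heteroscedastic across cell
types (neutrophils vary far more than NK), so the pooled-variance omnibus
interaction test is anti-conservative on Dirichlet data (measured ≈ 0.19
at nominal 0.05), while the group main effect is structurally conservative
(compositions sum to one).  The per-cell-type two-sample contrasts, which
are the reported group comparisons, are correctly calibrated; tests assert
exactly this.

## Differential methylation

Plain per-CpG OLS with covariate adjustment; the response coefficient is
tested with a t-test on the residual degrees of freedom.  No empirical-Bayes
variance moderation is applied — with ≥ 80 samples the moderation effect is
small, and plain OLS admits exact closed-form oracles; the model slot is
config-reserved.  With no covariates the test reduces algebraically to the
pooled two-sample t-test (asserted to 1e−10).  Zero-variance probes are
reported with coefficient 0 and p = 1 and flagged.  No multiple-testing
correction is applied at the probe level (nominal p-values are the
deliverable); a Benjamini–Hochberg column is available but off by default.
`covariate_robustness` fits the response-only and fully adjusted designs on
a probe panel and reports both p-values — the count of probes significant
after adjustment measures robustness to smoking/MTX confounding.

## Brown's method

For a gene with k probe p-values, ψ = −2Σ ln pᵢ has E = 2k and, under
correlation, Var = 4k + 2Σᵢ<ⱼ cov(−2 ln pᵢ, −2 ln pⱼ).  Covariances use the
Kost–McDermott polynomial 3.263ρ + 0.710ρ² + 0.027ρ³ in the score
correlation ρ, clipped to [0, 4]; negative correlations are clipped at 0
from below.  The combined p-value is the upper tail of a scaled chi-square:
c = Var/(2E), f = 2E²/Var, p = P(χ²_f > ψ/c).  Limiting cases are exact:
ρ ≡ 0 reproduces Fisher's method to 1e−12, k = 1 is the identity, and
perfectly correlated identical p-values return the input p.  Correlations
are estimated as Pearson correlations of M-values across all samples
(Spearman available).  On nulls with within-gene correlation 0.6 the
combined test holds its size (≈ 0.04 at nominal 0.05 over 2000 replicates)
where naive Fisher exceeds 0.10.

## Regional profiles

Per-gene Δβ versus genomic position, smoothed by a degree-1 loess (tricube
weights; bandwidth = distance to the ⌈span·n⌉-th nearest point, span
default 0.75) evaluated on a 200-point grid within the probe range.  The
smoother is linear in the data, so pointwise standard errors are
σ̂‖l(x₀)‖ with σ̂² from the smoother's residuals on n − 2 degrees of
freedom.  This smoother is implemented in-package because the loess needed
here must expose both span-based grid evaluation and pointwise standard
errors.  Genes with < 3 probes return raw points with smoothing skipped.

## Response labeling

Boundary semantics follow the clinical wording exactly: "decrease of at
least 1.2" is ≥, "decrease of < 0.6" is strict, "< 3.2" and "> 5.1" are
strict.  The two clauses are not mutually exclusive; overlaps are surfaced
as `conflict` and gaps as `indeterminate`.  The decrease is rounded at the
9th decimal so scores recorded at clinical precision hit boundaries exactly
despite binary floating point.  The characteristics table uses χ² (no
continuity correction by default), pooled t, or Mann–Whitney (exact
distribution when the smaller group has ≤ 8 samples, otherwise the
tie-corrected normal approximation).

## Stability-selected gradient boosting

Design choices, in order of consequence:

* **Resampling** — each of `n_resamples` (default 100) resamples is one
  training fold of repeated stratified 5-fold CV (repeats derived as
  ⌈n_resamples/folds⌉).  Each resample appends one freshly drawn standard
  normal noise column, fits gradient-boosted trees (200 trees, depth 3,
  learning rate 0.1, row subsample 0.8, feature subsample 0.3 per tree),
  and reads total-gain importances.  The per-tree feature subsample
  diversifies the ensemble so chance-correlated features cannot monopolize
  every split; it measurably improves planted-probe recovery.
* **Selection bookkeeping** — a feature is "selected" in a resample iff its
  gain strictly exceeds the noise column's; the full importance vector
  also feeds a pairwise win matrix W (W[i,j] = resamples where i outranked
  j).
* **Panel membership** — candidates must beat the noise probe in more than
  90% of successful resamples.  A single fixed dataset induces chance
  feature–label correlations that persist across resamples, so features
  can beat a median-quality noise draw in well over half the resamples
  under a label-permuted null; the conservative end of the conventional
  stability-selection threshold range is required for null panels to stay
  near-empty, and our null simulations confirm it does (≤ 0.7% of features
  across permutation seeds).  Candidates are then confirmed by a paired
  one-sided sign-flip permutation test of their per-resample importance
  margin over the noise probe (10 000 sign flips; the resolution needed for
  BH across small candidate sets), with Benjamini–Hochberg control at
  α = 0.05 across candidates.  An empty panel is a valid outcome.
* **Consensus order** — Copeland score of W (number of features beaten in a
  majority of resamples), ties broken by mean importance then feature id.
* **Final model** — retrained from scratch on the full training set
  restricted to panel features; evaluated once on the held-out 30% split.
  Both the held-out AUROC and the mean per-repetition CV AUROC are
  reported.  When the panel is empty there is no model and the AUROC is
  undefined (for null-behavior experiments we evaluate an all-features
  model instead, which stays at chance).
* **Determinism** — every stochastic element (fold assignment, noise
  column, booster seed, sign flips) derives from the run seed via hashed
  child seeds, so identical seeds give bit-identical panels and AUROCs,
  and each resample is reproducible in isolation.
* **Leakage** — the test set enters nothing upstream of the final
  evaluation; tests corrupt all test labels and assert the selection
  output is unchanged.

AUROC is the Mann–Whitney pair statistic (ties earn half credit), computed
from ranks.

The 70/30 split allocates round-half-up(0.7·n_class) of each class to
training: 92 samples at 49/43 give 64 training (34/30) and 28 test samples.

## Pipeline and reproducibility

`pipeline.run_pipeline` executes the stages in a fixed order on shared
artifacts, recording per-stage elapsed time, input/output row counts, and
SHA-256 checksums of every written file into `run_report.json`;
`verify_report` re-hashes artifacts to detect tampering.  Identical
configurations reproduce byte-identical artifacts, including all stochastic
stages.  The default simulation sizes (92 samples × 2000 probes; 100
resamples) run the full pipeline in a few minutes on one CPU; calibration
experiments in the test suite use 1000–2000 probes/replicates, sizes at
which the binomial error of an estimated rate is a few per mille.

## Known limitations

* Reference-based deconvolution assumes the six-type reference covers the
  mixture; minor populations fold into the nearest major type.
* The Kost–McDermott covariance approximation degrades for strongly
  negative score correlations (clipped at 0 here).
* Stability selection on a single cohort cannot distinguish a true weak
  effect from a strong chance correlation; the 90% screen trades recall
  for a near-zero false-panel rate, and panel size is an outcome, not a
  parameter.
* The boosting hyperparameters are fixed for reproducibility, not tuned;
  no probability calibration is attempted.
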