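# Methods

This note documents the statistical model behind `ogttmet`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Data model

A cohort is `subjects × metabolites × timepoints` with timepoints
0/15/30/60/120 min of a 2-h oral glucose tolerance test, two intervention
arms (labels `almond`/`cracker` throughout), optional QC-replicate and blank
samples flagged by a `role` column, a metabolite annotation table (chemical
class, hex-encoded structural fingerprint, KEGG id) plus a reactant-pair
edge list, and a per-subject Matsuda Index. All intensities are
non-negative; `NaN` marks a missing measurement. Sample SD (n−1 denominator)
is used everywhere.

## Synthetic cohorts

The generator works on the log10 scale:

```
log10 x[i, t, j] = base_j + amplitude · shape_{a(j)}(t) + b[i, j] + group shift + ε[i, t, j]
```

- `base_j ~ N(4.5, 0.5²)` — typical untargeted peak-height magnitudes
  (10³–10⁶).
- `shape_a` is one of four unit-variance temporal archetypes (sustained
  decline; rise with flattening slope; V-shape; rise-then-fall), assigned
  with configurable weights; `amplitude` defaults to 0.15 log10 units, a
  moderate but clearly detectable oGTT excursion at the default noise.
- `b[i, j] ~ N(0, 0.1²)` is a subject random intercept, **independent across
  metabolites**. Real metabolomes are cross-correlated; independence is
  chosen deliberately so that per-metabolite tests are independent and
  null-calibration checks admit exact binomial error bands. The
  within-subject correlation magnitude across oGTT timepoints is not a
  published quantity, so it is an explicit parameter (`subject_sd`) rather
  than a constant.
- `ε ~ N(0, 0.2²)` log10-scale measurement noise (`noise_sd`).
- **Planted group effects.** For affected metabolites the almond arm's
  trajectory is shifted at all post-baseline timepoints by a constant δ
  calibrated in closed form so that the standardized mean difference of the
  full-window (0–120) log-AUC equals `planted_g` exactly:
  `δ = g · sd(AUC) / Σ_{t>0} w_t`, with `sd(AUC)² = subject_sd²(Σw)² +
  noise_sd²·Σw²` and `w` the trapezoid quadrature weights. The fasting value
  is left untouched, so baseline adjustment does not absorb the effect.
  Default `planted_g = 1.5` with 20 affected metabolites per 200.
- **Biphasic class.** Optionally one class is shifted up at 15/30 min and
  down at 60/120 min (each δ calibrated against its window's AUC SD), which
  reproduces an "elevated early, suppressed late" lipid-class pattern with
  opposite enrichment directions in windows 0–30 vs 60–120.
- **QC replicates** are constructed to hit their target RSD *exactly* (a
  root-solve on a multiplicative spread factor applied to a standardized
  Gaussian pattern): planted high-RSD metabolites sit at RSD 0.8, clean ones
  in [0.05, 0.20], so the 50% filter threshold separates them
  deterministically rather than by sampling luck.
- **Blanks** sit at 1% of the study median (clean metabolites); planted
  blank artifacts get blanks resampled from study values and scaled ×1.5,
  guaranteeing a median sample/blank ratio below 1.
- **Matsuda Index** is built per arm as `MI = 6 + 2(r·ã + √(1−r²)·ẽ)` where
  `ã` is the designated metabolite's standardized log-AUC and `ẽ` an
  orthogonalized standardized noise vector — the within-arm sample
  correlation equals the configured `r` exactly (defaults 0.45 almond /
  0.00 cracker).
- **Missingness** is MCAR at 2% (the mechanism in the motivating datasets is
  undocumented; MCAR is the neutral choice and is what the imputation
  assumes).
- All randomness flows from one seeded `default_rng([seed, stream])`;
  identical configs give byte-identical tables.

What the generator does **not** emulate: metabolite–metabolite correlation,
heteroscedastic (intensity-dependent) noise, batch/injection-order drift,
missingness that depends on abundance, and annotation ambiguity. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to those real-data features.

## Preprocessing

- **QC-RSD filter**: remove metabolites with QC `SD/mean > 0.5` (threshold
  configurable); zero or undefined QC mean counts as failing. Requires ≥ 2
  QC samples, otherwise the caller must skip explicitly.
- **Blank filter**: remove when the two-sided Wilcoxon rank-sum test of
  study vs blank intensities has p > 0.05 **or** the median study/blank
  ratio is < 1 (a disjunction: either criterion excludes; both statistics
  are recorded per metabolite for audit). Exact enumeration below 8 per
  side without ties, tie-corrected normal approximation otherwise. The
  one- vs two-sided choice is not documented in the motivating analysis;
  two-sided is used and noted here.
- **Imputation**: iterative chained regression (sklearn `IterativeImputer`,
  Bayesian ridge, ≤ 20 nearest predictor features, fixed seed), applied to
  the log10 matrix. Observed entries are never modified. A fully missing or
  ≥ 50%-missing metabolite is an error.
- **Transforms**: `log10_autoscale` (log10 then per-column z-scoring;
  constant columns excluded with a warning) and `timecourse_zscores`
  (across-subject mean per timepoint, then z-scoring that 5-vector per
  metabolite — the representation clustering uses).

Filters are order-independent by construction (each is computed on the full
dataset and removals are unioned).

## Two-step univariate selection

Step 1 tests each metabolite for any time effect with a linear mixed model
(5-level time factor, subject random intercept). For balanced complete data
the ML likelihood-ratio statistic has the closed form

```
LRT = n(T−1) · ln(1 + SS_time / SS_resid),   df = T − 1,
```

where `SS_time` is the between-timepoint and `SS_resid` the
subject-by-timepoint interaction sum of squares; the subject variance
component cancels from the ratio. This is algebraically identical to a
numerical ML mixed-model fit (verified against `statsmodels MixedLM` to
~1e-9 in the tests) and ~1000× faster, which is what makes the Monte-Carlo
calibration checks affordable. Unbalanced trajectories fall back to the
numerical fit, and non-convergence falls back to the repeated-measures
ANOVA F test; the method used is recorded per metabolite. P-values are BH
corrected; the FDR gate defaults to 0.05. The screen deliberately contains
no group term: it asks only "does this metabolite move during the oGTT".

Step 2 fits `AUC ~ group + time0` per metabolite and window (plain OLS; the
baseline covariate is the subject's fasting value on the same scale as the
AUC). Reported: group-coefficient p, Hedge's g on the raw AUCs, group means
± SD, and percent difference `(mean₁−mean₂)/mean₂·100`. AUC features in the
pipeline are computed on log10 trajectories — group contrasts are then on
the multiplicative scale, consistent with the log-scale multivariate
analyses; the trapezoid engine itself is scale-agnostic (`log10=False`
integrates raw intensities).

## PLS-DA

NIPALS PLS2 against centered one-hot class indicators on autoscaled
predictors. Determinism: deflation order is fixed, the starting `u` is the
highest-variance response column, and each weight vector is sign-fixed so
its largest-magnitude element is positive. Component count is chosen by
leave-one-out accuracy (folds re-center/re-scale internally) with a
one-standard-error parsimony tie-break — the selection rule in the
motivating analysis is unstated, so the most conventional one is used and
the full CV record is kept on the model. Class prediction is argmax over
the continuous class columns. VIP uses `SSY_a = (tᵀt)·‖q‖²` per component;
`Σ VIP² = p` holds to 1e-8 on every fit. The pruning loop refits on
variables with VIP > 0.8 until stable, returning the previous model if LOO
accuracy degrades ("optimized predictor variability" operationalized as a
CV-degradation stop; per-round history is attached for audit). Pairwise
latent-variable timepoint contrasts are unadjusted paired t-tests,
matching the exploratory reporting convention; the overall test is a
repeated-measures ANOVA.

## Temporal clustering

Euclidean fuzzy c-means on the metabolite × timepoint z-score matrix,
fuzzifier from the Schwämmle–Jensen dimension/size rule, `c = 4` by default
(the number of observed oGTT trajectory archetypes), tol 1e-6 on centroid
displacement, ≤ 500 iterations. Seeding is k-means++ (fixed seed) with
centers pulled 1% toward the grand mean: a centroid exactly coinciding with
a data point receives membership 1 there by the distance-zero limit, which
at large fuzzifiers freezes the iteration at its initialization — the
shrink removes the coincidence without affecting normal runs. `u^m`
underflow at extreme fuzzifiers is guarded (centroids fall back to the
grand mean, which is the correct m→∞ limit). The objective
`J = Σ u^m d²` is non-increasing across iterations; note that for finite m
on separated data the fixed-point memberships deviate from `1/c` by O(1/m),
so near-uniform memberships should only be expected at very large m.

## Enrichment, network, correlation

- Enrichment: per chemical class (≥ 3 mapped members), one-sample KS test of
  member p-values vs Uniform(0,1) — exact distribution below n = 10,
  asymptotic otherwise — BH across classes, altered members at raw p < 0.05,
  class direction = majority sign of altered members' g (ties → `mixed`).
  Class labels are an input annotation; no ontology lookups.
- Network: node inclusion is exactly `any-window p < alpha OR max |g| >
  g_floor` with **unadjusted** p-values — this stage is exploratory by
  design and documented as such. The display letter (A–G) is the window
  with the largest |g| among significant windows; node size attribute is
  the 0–120 g. Edges: curated reactant pairs, Tanimoto ≥ 0.7 on hex
  fingerprints (length-agnostic), optional manual edges; undirected,
  deduplicated, no self-loops. Dense glyceride classes can be excluded from
  the exported view via config without affecting statistics.
- Correlation: variables passing the ±1.5 SD LV1-loading rule from the
  group-discriminant PLS-DA are correlated with the Matsuda Index per arm
  (Pearson; Shapiro–Wilk normality is flagged, not an exclusion — the
  motivating analysis verified normality but prescribed no action), and
  arms are compared by Fisher's r-to-z with n ≥ 4 per arm.

## Pipeline

`run_pipeline` executes: load/simulate → filters + imputation → AUC
features → two-step univariate → timepoint PLS-DA → fuzzy clustering →
per-window enrichment → network export → group PLS-DA + MI correlations
(→ recovery report vs ground truth for synthetic runs). Every stage writes
TSV/JSON and the manifest records config, version, warnings, and SHA-256
checksums; a rerun with the same config is bit-identical.

## Problem sizes in the checks

The acceptance script and Monte-Carlo tests use cohorts of 20 subjects per
arm and 120–200 metabolites, with 10–50 replicates per property and
1000-draw nulls for the scalar statistics — sizes at which the binomial/MC
error of each assertion is comfortably below its tolerance.

## Known limitations

- The balanced-LRT screen assumes homoscedastic Gaussian log-intensities;
  heavy-tailed noise would need the F-statistic option or a rank screen.
- PLS-DA treats each subject × timepoint sample as an observation in
  timepoint-discriminant mode (no subject term), consistent with plotting
  all samples in latent space; the repeated-measures test on the scores is
  where within-subject structure is honored.
- The enrichment KS test treats member p-values as independent; correlated
  members (shared pathways) make it anti-conservative on real data.
- Fingerprint provenance (type, length) is the caller's responsibility; the
  Tanimoto threshold is not adjusted for fingerprint density.
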