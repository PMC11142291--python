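# ogttmet

Dynamic oGTT-response metabolomics analysis: a tested, reusable pipeline for
studying how the serum metabolome responds to an acute glucose challenge, and
how that response differs between two dietary intervention arms.

## The problem

An oral glucose tolerance test (oGTT) samples serum at 0, 15, 30, 60 and
120 min after a glucose bolus. Untargeted metabolomics on those samples
yields, per subject, a short intensity trajectory for each of hundreds of
metabolites. The scientific questions this package answers:

1. Which metabolites change during the glucose challenge at all, and in what
   temporal patterns (sustained decline, rise-plateau, V-shape, rise-fall)?
2. Which windowed responses differ between intervention arms (e.g. almond vs
   cracker snacking), after adjusting for the fasting baseline?
3. Which *chemical classes* (triglycerides, lysophosphatidylcholines, ...)
   are coherently shifted, in which time windows, and in which direction —
   including biphasic patterns (elevated early, suppressed late)?
4. Which metabolite responses correlate with insulin sensitivity (Matsuda
   Index), differentially by arm?

## The methods at its core

- **Windowed AUC features.** Each trajectory is summarized by trapezoid-rule
  areas `AUC = Σᵢ (tᵢ₊₁−tᵢ)(yᵢ+yᵢ₊₁)/2` over seven canonical windows
  (0–15, 0–30, 0–60, 0–120, 15–30, 30–60, 60–120 min; letter-coded A–G).
- **Two-step univariate selection.** Step 1: per metabolite, a linear mixed
  model with a 5-level time factor and subject random intercept; the overall
  time-effect likelihood-ratio p-values are Benjamini–Hochberg corrected and
  metabolites pass at FDR < 0.05. Step 2: for passing metabolites,
  `AUC ~ group + time0` per window, reporting the group p-value and Hedge's
  g = (x̄₁−x̄₂)/s_pooled · (1 − 3/(4n−9)).
- **PLS-DA.** NIPALS PLS2 against one-hot class labels on autoscaled
  log10 data, leave-one-out CV for the component count, VIP scores
  (Σⱼ VIPⱼ² = p), iterative pruning at VIP > 0.8, and a ±1.5 SD rule on LV1
  loadings for variable selection.
- **Fuzzy temporal clustering.** Fuzzy c-means (memberships
  u = 1/Σₖ(d_ic/d_ik)^{2/(m−1)}) on per-timepoint z-scored mean trajectories,
  fuzzifier m estimated from data dimensions (Schwämmle–Jensen rule).
- **Chemical enrichment.** Per class, a Kolmogorov–Smirnov test of member
  p-values against Uniform(0,1), BH-FDR across classes, with altered-member
  and direction summaries per AUC window.
- **Network export.** Metabolites with any-window p < 0.05 or |g| > 0.8,
  connected by KEGG reactant pairs and Tanimoto ≥ 0.7 fingerprint
  similarity, exported as SIF/GraphML.
- **Differential correlation.** Per-arm Pearson r of selected AUCs vs the
  Matsuda Index, compared via Fisher's
  z = (atanh r₁ − atanh r₂)/√(1/(n₁−3)+1/(n₂−3)).

Because the original clinical dataset is not bundled, the package ships a
first-class synthetic-cohort generator (`ogttmet.sim`) that reproduces the
statistical structure the analysis assumes — four temporal archetypes,
planted group effects of known Hedge's g, an enriched chemical class, QC
replicates with controlled RSD, blank artifacts, MCAR missingness, and exact
planted metabolite–Matsuda correlations — together with a machine-readable
ground truth, so every stage is testable end to end.

## Worked example

```python
from ogttmet import (SimConfig, generate_cohort, generate_blank_qc, filter_qc_rsd,
                     filter_blank, apply_filters, build_auc_table, group_effect_auc,
                     time_effect_screen, chemical_enrichment)

cfg = SimConfig(n_per_group=20, n_metabolites=200, planted_g=1.5, seed=1,
                missing_rate=0.0)
dataset, truth = generate_cohort(cfg)
dataset = generate_blank_qc(cfg, dataset)

qc, blank = filter_qc_rsd(dataset), filter_blank(dataset)
dataset = apply_filters(dataset, [qc, blank])

screen = time_effect_screen(dataset)
feats = build_auc_table(dataset, log10=True)
res = group_effect_auc(feats, "0-120")
table, _ = chemical_enrichment(res.reset_index(),
                               dataset.annotations["chem_class"].to_dict())
```

This prints (via the snippet in `scripts/` style reporting):

```
retained 194 metabolites (QC filter removed 3, blank filter removed 3)
time-effect screen: 194 of 194 metabolites at FDR < 0.05
top planted metabolite M0068: p = 6.41e-10, Hedge's g = 1.86
top enriched class: unsaturated_triglycerides (size 10, KS p = 4.2e-09, FDR = 4.2e-08, higher in almond)
```

Reading: the six planted QC/blank artifact metabolites are exactly the ones
the filters remove; every remaining metabolite shows a time effect (all have
a planted temporal archetype); the strongest planted group effect is
recovered with g ≈ 1.9 against a planted 1.5 (per-metabolite estimates
scatter around the truth); and the planted enriched class is the top — and
only — FDR-significant class, with the correct direction.

The same analysis runs from the shell:

```bash
ogttmet simulate --seed 1 --out cohort/
ogttmet run --input-dir cohort/ --out results_run/
ogttmet report results_run/
```

## Layout

| module | role |
| --- | --- |
| `ogttmet.sim` | synthetic cohorts + ground truth |
| `ogttmet.preprocessing` | QC-RSD / blank filters, imputation, transforms |
| `ogttmet.auc` | windowed trapezoid AUC features |
| `ogttmet.univariate` | two-step selection, BH, Hedge's g |
| `ogttmet.plsda` | NIPALS PLS-DA, VIP pruning, loading selection |
| `ogttmet.clustering` | fuzzy c-means temporal archetypes |
| `ogttmet.enrichment` | KS chemical-class enrichment |
| `ogttmet.network` | KEGG/Tanimoto network assembly + SIF/GraphML |
| `ogttmet.correlation` | group-wise Pearson + Fisher r-to-z |
| `ogttmet.pipeline`, `ogttmet.cli` | orchestration, manifest, CLI |

See `docs/methods.md` for modeling assumptions, parameter choices, and known
limitations.
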