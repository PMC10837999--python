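# microimmune

Statistical toolkit for longitudinal gut-microbiome / immune-phenotype
cohort studies, built around a two-timepoint, three-cohort HIV design:
people living with HIV who are ART-naive at baseline and start therapy,
people established on therapy, and healthy controls, each sampled at
week 0 and week 24 in a rural and an urban location.

It is aimed at analysts who have an ASV count table, a rooted phylogeny,
per-sample metadata and an immune-marker panel (T-cell activation
CD38+HLA-DR+, exhaustion PD-1+, trafficking CD103+ on CD4+/CD8+ cells,
plus IL-6 and CRP) and want the downstream statistics as tested,
reproducible library calls rather than a notebook of one-off snippets.

## What it computes

- **Cohort preparation** — viral-load-based exclusion cascade (strict
  thresholds: baseline naive VL < 20 copies/mL is inconsistent with
  untreated status; VL > 200 copies/mL defines viremia), cohort x week
  mean imputation of CD4-lineage markers, rarefaction, prevalence
  filtering, relative abundance.
- **Diversity** — Shannon entropy (bits); weighted UniFrac
  `d(A,B) = Σ_b L_b |p_A(b) − p_B(b)|`; PCoA of the Gower-centered matrix
  with deterministic axis orientation; abundance-weighted biplots;
  multi-term sequential PERMANOVA with permutations restricted to strata
  (participant) blocks.
- **Dysbiosis** — per-sample mean weighted-UniFrac distance to the
  same-week healthy controls, and per-stratum OLS of
  `Δvalue ~ baseline value` (the regression-to-the-mean design used for
  both Shannon entropy and dysbiosis).
- **Immune statistics** — Kruskal–Wallis + Dunn post hoc, paired Wilcoxon
  signed-rank, OLS of `marker ~ cohort * week` with participant-clustered
  sandwich standard errors, and backward-stepwise predictive models with
  forced-in covariates.
- **Association networks** — Spearman/complete-linkage module binning;
  per-pair models `marker ~ read count + feature * cohort` on
  non-rarefied relative abundances; a five-criterion cascade
  (BH-FDR < 0.2 on the overall F, adjusted R² > 0.25, significant
  reference-cohort slope, significant slope difference vs another cohort,
  max |DFFITS| < 2); bipartite network export as JSON/TSV.
- **Synthetic cohorts** — a generator producing the full data bundle
  (counts, tree, metadata, immune panel, ground truth) with planted
  microbe→immune effects, so every stage is testable end to end without
  external data.

## Worked example

`examples/01_cohort_exclusions.py` runs the participant-flow worked
example on the built-in enrolment roster:

```
enrolled:                      162
  excluded (inconsistent_naive_baseline): 14
  excluded (exp_viremic_baseline): 6
baseline analysis set:         142 individuals
  excluded (lost_to_follow_up): 14
  excluded (naive_week24_viremic): 15
longitudinal analysis set:     113 individuals, 226 samples
naive virologic failure rate:  22.4% (share of baseline naive cohort not suppressed at week 24)
experienced baseline viremia:  15.4% (share of enrolled experienced cohort viremic despite ART)
```

Of 162 enrolled participants, 20 are excluded at baseline by the
viral-load rules, 142 enter the cross-sectional analyses, and after
dropping participants missing a visit or failing to suppress on therapy,
226 samples from 113 participants form the longitudinal set.

`examples/05_association_network.py` plants five naive-cohort-only
microbe→immune effects and runs the full screen:

```
fitted 480 marker x feature models (0 correlation modules binned)
edges surviving the cascade: 5
  cd4_cd38_hladr_pct + feature_0038   (naive-slope p = 8e-32)
  ...
planted effects recovered: 5/5, false edges: 0
```

Every edge is an association present in untreated infection and absent
(or significantly different) under therapy or in healthy controls. The
other examples cover diversity/ordination/PERMANOVA, dysbiosis and delta
regressions, and the immune models.

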