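# Methods

`microimmune` implements the downstream statistical pipeline of a
two-timepoint (week 0 / week 24), three-cohort (ART-naive, ART-experienced,
healthy control), two-location (rural / urban) gut-microbiome and
immune-phenotype study, together with a synthetic-data generator that
reproduces the statistical structure those analyses assume. This note
documents the models, the defaults and why they were chosen, and what the
synthetic data does and does not emulate.

## Cohort preparation

**Viremia labeling and exclusions.** All thresholds are strict
inequalities on plasma HIV-1 RNA: an ART-naive participant with baseline
viral load < 20 copies/mL is inconsistent with declared untreated status;
a naive participant with > 200 copies/mL at week 24 has failed to reach
virologic control; an experienced participant with > 200 copies/mL at
baseline is viremic despite therapy. The baseline stage removes the first
and third groups; the longitudinal stage additionally removes anyone
missing a visit and the second group, leaving exactly two samples per
retained participant. Every `FilterReport` conserves counts
(`retained + excluded = input`) and the filters are idempotent.

**Imputation.** Missing CD4-lineage markers (CD4+CD38+HLA-DR+, CD4+PD-1+,
CD4+CD103+, which fail together when the CD4 easy-count assay fails) are
replaced by the mean of observed values in the same cohort x week stratum.
A global-mean variant exists for sensitivity checks; the stratified
default avoids leaking values across cohorts whose distributions differ by
an order of magnitude. Percentages are reported rounded half-up to one
decimal.

**Rarefaction** subsamples each sample to a fixed depth (the workflows
here use 16,645 reads) without replacement via the multivariate
hypergeometric distribution, consuming one RNG stream in sample-ID sort
order so results do not depend on input row order. Samples below the
depth are dropped and logged. The **prevalence filter** keeps features
with a nonzero count in strictly more than 20 % of samples (the boundary
case is dropped).

## Diversity and ordination

**Shannon entropy** is computed in log base 2 (bits) by default; the base
is an argument.

**Weighted UniFrac** is the raw (unnormalized) variant,
`d(A,B) = sum_b L_b |p_A(b) - p_B(b)|`, where `p_X(b)` is the fraction of
sample X's reads on leaves below branch `b`; computation is delegated to
scikit-bio and verified in the test suite against a brute-force
descendant-set enumeration written independently of it. The normalized
variant (bounded by 1) is available behind a flag.

**PCoA** eigendecomposes the Gower-centered matrix `-1/2 J D^2 J`.
Negative eigenvalues (non-Euclidean distances) are dropped from both the
coordinates and the proportion-explained denominator — no Lingoes or
Cailliez correction is applied, matching the common core-workflow default.
Axis reflections are pinned by orienting each axis so the
lexicographically smallest sample ID scores non-negative; this makes
ordinations byte-reproducible without changing any geometry. Biplot
feature coordinates are abundance-weighted means of the sample scores,
ranked by distance from the origin.

**PERMANOVA** partitions the Gower matrix sequentially (Type-I) over an
ordered term list using hat-matrix projections built term by term, so
categorical factors, continuous covariates (e.g. age) and interactions
(`location:week`) are all supported. The permutation p-value is
`(1 + #{F* >= F_obs}) / (1 + n_perm)`; with a strata variable (here the
participant ID) permutations shuffle samples only within blocks. Two
numerical conventions matter: residual sums of squares at cancellation-
noise level are treated as exact fits (F = infinity), and exceedances are
counted with a relative tie tolerance of 1e-9 so permutations that
reproduce the observed partition count as ties rather than falling on the
wrong side of float jitter. A caveat inherent to restricted permutations:
a factor constant within blocks (location, cohort) is never rearranged by
within-block shuffles, so its p-value is uninformative under strata even
though its F and R^2 are valid descriptions of the partition.

## Dysbiosis

A sample's dysbiosis score is its mean weighted-UniFrac distance to all
healthy-control samples collected at the same week. Scores are computed
for the HIV cohorts by default; the HC-side variant (used for
healthy-control correlates) excludes the scored sample from its own
reference set. Delta regressions fit per-stratum OLS of
`(value at week 24 - value at week 0)` on the baseline value, per cohort
and per cohort x location; strata with fewer than three complete pairs
are skipped. Under no true tracking this regression has slope -1
(pure regression to the mean); under perfect tracking plus noise it has
slope 0 — both limits are verified by simulation in the test suite.
Correlations with months of cotrimoxazole exposure are reported as both
Pearson and Spearman coefficients, since exposure has a point mass at
zero and neither coefficient is canonical for it.

## Immune statistics

Inter-cohort comparisons use Kruskal-Wallis with tie correction and a
Dunn post hoc (z from pooled mean ranks with tie-corrected variance);
Dunn p-values are Benjamini-Hochberg adjusted within each marker's
pairwise family by default, with an unadjusted option. Intra-cohort
week-0 vs week-24 comparisons use the Wilcoxon signed-rank test — the
standard paired rank test — with the exact null for n <= 25 without ties
and the tie-corrected normal approximation otherwise; zero differences
are dropped, and all-zero input is reported as degenerate (p = 1) rather
than an error.

The longitudinal linear model is OLS of
`marker ~ cohort + week + cohort:week` with healthy controls and week 0
as reference levels, fitted overall and per location, with cluster-robust
(sandwich) standard errors grouped by participant using the
`G/(G-1) x (n-1)/(n-k)` small-sample factor and t-tests on `G - 1`
degrees of freedom. The interaction coefficients are each cohort's change
over time beyond the change seen in healthy controls.

Backward-stepwise selection starts from the full candidate model and
removes, one candidate at a time, the term whose removal most improves
AIC (a p-threshold variant exists); forced-in covariates are never
removable, single-level categoricals are dropped with a warning, the full
trace is recorded for audit, and the final model is flagged "model NS"
when its overall F p-value is >= 0.05. The final model is locally
optimal: no single removal improves the criterion.

## Immune-microbe association networks

**Module binning.** Pairwise Spearman correlation of relative abundances,
complete-linkage clustering on `1 - r`, cut at `1 - min_r` so every
within-module pair satisfies `r >= min_r` (default 0.35; constant
features are left unbinned). Modules sum their members' counts; the
combined table is modules plus unbinned singles. These settings stand in
for the version-dependent defaults of co-occurrence binning tools and are
recorded in the output.

**Pair models.** For each immune marker and each (non-rarefied,
prevalence-filtered, module-binned) microbial feature:
`marker ~ total read count + feature + cohort + feature:cohort`, with the
naive cohort as reference (experienced, in the two-cohort
experienced-vs-control mode). Read count enters because the table is not
rarefied. Per-cohort slopes are the reference slope plus interaction
coefficients, with Wald tests from the same covariance (no refitting);
slopes are invariant to which cohort is coded as reference. The overall F
is tested against the intercept + read-count null, so depth alone cannot
make a model "significant". DFFITS is the externally studentized residual
times `sqrt(h/(1-h))`; perfect fits return zero by the limit convention
and exact-leverage points report infinity.

**Filter cascade.** An edge survives iff (1) Benjamini-Hochberg
FDR-adjusted overall-F p < 0.2, the family being all marker x feature
fits of one timepoint; (2) adjusted R^2 > 0.25; (3) the reference-cohort
slope has p < 0.05; (4) at least one interaction (slope-difference)
p < 0.05; (5) max |DFFITS| < 2. Edges carry the sign of the
reference-cohort slope and a width of `-log10(p_slope)`; the network is
exported as JSON and TSV and round-trips exactly.

## The synthetic cohort

The generator emulates the study design, not its raw sequence data:

- **Counts** are Dirichlet-multinomial (concentration 50 around a
  log-normal mean composition; negative-binomial depths, mean 25,000) with
  two designated 10 %-of-features blocks — "Prevotella-like" and
  "Bacteroides-like" — whose mass shifts between rural and urban samples
  by `gradient_strength` log-units, so the leading PCoA axis separates
  locations the way a Prevotella/Bacteroides axis does.
- **Viral loads** are log-normal per cohort with point masses at zero for
  suppressed participants; the three exclusion-relevant states are drawn
  at the per-cohort rates of the emulated design (14/81 inconsistent
  naive baselines, 15/67 naive week-24 failures, 6/39 viremic experienced
  baselines), with a 10 % loss-to-follow-up rate.
- **Immune markers** are marker baseline + cohort effect + a
  naive-cohort week-24 treatment response + planted microbe effects +
  participant random intercept (SD 0.5) + noise (SD 1.0), clipped to
  [0, 100] for percentages and to non-negative for IL-6/CRP. CD4-lineage
  markers go missing jointly, completely at random (7 % of samples).
- **Planted edges** add `slope x (relative abundance - its mean)` to one
  marker in one cohort. The centering is deliberate: an uncentered planted
  effect shifts the planted cohort's marker mean, which the pair model's
  cohort main effect then "explains" for every feature of that marker,
  lifting all adjusted R^2 values above threshold and gutting the
  cascade's specificity. Centering leaves the slope — the quantity the
  screen estimates — exactly recoverable while keeping cohort means
  honest. The default slope (80) and the abundance-ranked feature choice
  in `suggest_planted_features` size the planted effect so that a
  recoverable association has within-cohort R^2 well above the cascade's
  0.25 floor; planting on an arbitrary feature would make recovery hinge
  on the random base abundance (features with Dirichlet shape < 1 are
  mostly zeros and cannot carry a linear signal). Effect sizes for real
  microbe-immune associations are not reported anywhere we could anchor
  to, so these defaults are chosen for testability of the screen, not for
  biological realism.
- One master seed is split into fixed named substreams (tree, roster,
  counts, immune, missingness), so regeneration is byte-identical and
  changing, say, the planted edges does not reshuffle the count table.

What passing tests on this generator show: the pipeline's algebra and
calibration are correct (oracle equivalence, permutation-test type-I
error, planted-effect recovery with controlled false edges). What they do
not show: robustness to real-data features the generator omits —
taxonomic correlation structure beyond the two blocks and planted
modules, zero inflation beyond the Dirichlet-multinomial's own,
covariate confounding (age, BMI, diet), batch effects, or non-linear
microbe-immune relationships.

## Problem sizes

Simulation-backed checks use sizes chosen to make Monte-Carlo error small
relative to the tolerances tested: 100 random instances for the UniFrac
oracle, 500 null simulations at 99 permutations each for PERMANOVA
calibration, 200 seeds for the null-cascade bound, 200 strata for the
delta-regression limits, and a single n-per-cell-40 cohort (about 460
samples, 480 pair models) for planted-edge recovery.

## Known limitations

- The mixed-effects model for ordination axes (random intercept per
  participant) is not implemented; the exposed PC axes plus the
  cluster-robust OLS are the supported approximation, and the PERMANOVA
  strata caveat above applies to between-participant factors.
- Module counts from correlation binning are sensitive to `min_r` and the
  correlation estimator; they are reported with their settings and should
  not be compared across settings.
- BIOM output is not provided; tables are read and written as TSV.
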