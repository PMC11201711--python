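# Methods

This note records the models, conventions and design choices behind
`cfscreen`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, and
where the genuinely open choices were made.

## Screening setting and data model

A screened subject contributes baseline covariates (age, sex, pack-years,
smoking status, family history of lung cancer, emphysema), a baseline
plasma cell-free DNA concentration (cfDNA, ng DNA per mL plasma), the
nodules seen at the initial LDCT, and an outcome label: *benign* (the
nodules never evolved into cancer), *prevalent* lung cancer (diagnosed at
the first round), or *incident* lung cancer (diagnosed at rounds 2–4, with
the round recorded). Validation is strict and fails loudly: ages must lie
in [40, 90], cfDNA and pack-years must be non-negative, a perpendicular
diameter may not exceed the maximum diameter, a solid-component size is
only meaningful for part-solid nodules, and outcome labels must be
consistent with their diagnosis round. Missing optional fields are encoded
as empty strings in the CSV; required fields may not be missing —
explicit failure is preferred over silent imputation.

A subject's nodules are serialized into a single semicolon-joined CSV cell
with a fixed within-nodule field order, keeping the cohort one flat file.
The *main nodule* of a subject is the baseline nodule with the largest
mean diameter (ties broken by nodule id); the choice matters for the size,
Lung-RADS and Brock per-subject scores and is isolated in one function.
Subjects with a negative baseline exam (no nodules) are treated as size
0 mm, Lung-RADS category 1 and Brock probability 0 for ranking and
stratification purposes.

## Nodule scoring

**Lung-RADS 1.1, baseline exams only.** Solid nodules: category 2 below
6 mm mean diameter, 3 in [6, 8), 4A in [8, 15), 4B at ≥ 15 mm. Part-solid:
2 below 6 mm total diameter, 3 from 6 mm with solid component < 6 mm, 4A
with solid component in [6, 8), 4B at ≥ 8 mm. Non-solid (ground-glass): 2
below 30 mm, 3 from 30 mm. All size brackets are half-open [lo, hi),
matching the bracket style of the descriptive tables. A spiculated nodule
whose base category is 3 or higher is promoted to 4X (spiculation is the
suspicious feature recorded in this data model). The subject-level
category is the maximum over nodules; an empty exam is category 1. Growth
categories for follow-up exams and the v2022 revision are out of scope.

**Brock (PanCan) model.** The full logistic model *with* spiculation:
covariates are age (centered at 62), female sex, family history of lung
cancer, emphysema, the nonlinear size transform `(d/10)^-0.5` centered at
its 4 mm value (1.58113883), nodule density (part-solid +, non-solid −
relative to solid), upper-lobe location, nodule count (centered at 4) and
spiculation. Coefficients are transcribed into a versioned JSON constants
file with the source citation, so the variant in use is auditable and
swappable. The conventional decision threshold is a 5% probability; all
threshold comparisons in the package are closed on the left (score ≥
cutoff), consistent with the half-open category brackets. Because no
complete covariate vector with its published score was available to pin an
end-to-end test point, the model is verified against an independent
in-test evaluation of the published formula, plus monotonicity checks on
every covariate.

## Volume doubling time

Two serial exams with effective diameters `d0`, `d1` an interval `Δt`
apart give `VDT = Δt · ln 2 / (3 · ln(d1/d0))` days, assuming exponential
volume growth and spherical idealization `V = π/6 · d³`. The effective
diameter combines the measured maximum and perpendicular axial diameters
as their geometric mean `√(d_max · d_perp)`. The exact axis-combination
convention of the originating measurement scheme is not restated in the
modern literature consistently (geometric vs arithmetic mean); the
constant cancels in the `d1/d0` ratio as long as both timepoints use the
same convention, and the choice is isolated in `effective_diameter` so it
can be swapped. Shrinking nodules return a negative VDT rather than an
error — callers decide; equal effective diameters leave VDT undefined
(error). VDT is computed for solid nodules only, and when more than two
exams exist the first and last are used.

The estimator is heavy-tailed when true growth over the interval is
comparable to measurement noise: `1/ln(d1/d0)` blows up near zero growth.
This drives two choices documented below (growth-consistent diagnosis
rounds in the simulator; pooling across replicate cohorts when reporting a
mean VDT).

## Statistics

* **AUROC** is the Mann–Whitney concordance probability computed from
  ranks; tied cross-class pairs count one half. It is checked
  property-wise against brute-force pair counting.
* **Youden cut-point**: candidates are the observed marker values plus
  +∞ (never positive); the maximizer of J = sensitivity + specificity − 1
  is returned with ties (within float tolerance 1e-12) broken toward the
  smallest cutoff, which makes results reproducible on discrete
  reconstructed data. Exposed as a scikit-learn classifier
  (`fit`/`predict`, fitted attributes `cutoff_`, `performance_`).
* **Stratified predictive values**: per stratum, NPV = benign-below /
  all-below and PPV = cancer-above / all-above at the cfDNA cutoff; empty
  denominators report missing (None), not 0. Strata: main-nodule size
  (<6, 6–8, 8–15, ≥15 mm), merged Lung-RADS classes (1/2, 3, 4A, 4B/4X),
  Brock probability classes (<1, 1–5, 5–10, ≥10 %).
* **Chi-square** on 2×2 tables is Pearson's without continuity correction
  by default (the printed p-values of the source tables correspond to the
  uncorrected statistic); Yates' correction is available as a flag.
* **Correlation intervals** use the Fisher z transform with SE
  `1/√(n−3)`; the function also accepts a precomputed (r, n) pair so
  published correlations can be interval-checked without raw data.
* **Over-optimism correction of the AUROC**: the data are repeatedly
  (default 100×) split into two equally sized outcome-stratified halves —
  the odd subject goes to the training half — a logistic model is fitted
  on the first half, and the AUROC of its linear predictor is computed on
  the second. The corrected estimate is the mean of the replicate AUROCs;
  the 2.5/97.5 empirical percentiles form a 95% uncertainty interval.
  The model family applied to each predictor is logistic regression (the
  natural default for a binary outcome); for a single marker the fitted
  monotone model cannot change the test-half ranking, so the correction
  reduces to the raw-score test-half AUROC whenever the fitted slope is
  positive. Under complete separation the maximum-likelihood fit can fail;
  the fallback is a least-squares linear-probability fit, which preserves
  the linear-predictor ranking that the AUROC depends on and keeps the
  procedure deterministic. Subgroup analyses at very small case counts
  (e.g. 12 incident cancers) are supported but fragile by nature: each
  half holds only ~6 cases.

## Synthetic cohort generator

The generator emulates the group structure of the screening subset the
package targets, with defaults fixed at the published conditions:

* group sizes 108 benign / 17 prevalent / 12 incident;
* per-group cfDNA from a log-normal distribution. The published tables
  give each group's mean (3.3 / 18.8 / 4.8 ng/mL) and the fraction at or
  above the 3.15 ng/mL category boundary (37/108, 14/17, 9/12); the two
  parameters (μ, σ) are solved exactly from these two constraints
  (`calibrate_cfdna_lognormal`, a quadratic in σ after substituting the
  tail condition). A log-normal is the natural two-parameter family here:
  non-negative, right-skewed, and able to satisfy both printed moments.
  The dispersion is identified only through the category fraction — the
  source reports no group SDs — so this calibration is the package's
  choice, not a published fact;
* main-nodule size classes, nodule-count distribution, spiculation,
  emphysema, sex, smoking status and family-history frequencies per group
  at the printed frequencies; sizes uniform within their class bracket;
  ages normal around the printed group means (SD 3.8 y, clipped to the
  55–69 y eligibility window); pack-years log-normal around the printed
  group medians (log-SD 0.35, floored at the >20 pack-year eligibility
  criterion); densities 85/10/5 % solid/part-solid/non-solid;
* exactly 2 of the 12 incident subjects have no visible baseline nodule
  (they surface as new nodules at round 3); the other 10, and 4 of the 17
  prevalent subjects, carry a second solid-nodule timepoint so that
  doubling time is measurable — 14 serial-exam cancers per cohort;
* for those serial nodules, (ln cfDNA, VDT) follow a bivariate-Gaussian
  structure with correlation −0.77, VDT mean 172 days and SD 80 days,
  truncated below at 20 days. The SD is the package's choice (the source
  reports only the mean and the correlation) set to give a realistic
  spread of screening-detected doubling times (~50–400 days); truncation
  at this SD affects ~3% of draws and shifts the recovered correlation by
  well under 0.01;
* the diagnosis round of an incident cancer follows its growth rate
  (marginal-VDT quantile < 0.1 → round 2, < 0.4 → round 3, else round 4),
  so that fast growers surface early. Expected round counts reproduce the
  printed 1/5/6 split. Independent (round, VDT) draws would "diagnose"
  slow growers after one year with sub-resolution simulated growth,
  which the screening protocol's own repeat-positivity rule (≥ 1 mm
  growth) excludes and which makes the VDT estimator blow up;
* the second timepoint inverts the VDT formula exactly, then adds
  independent Gaussian measurement noise (SD 0.2 mm per diameter, a
  realistic careful-reader repeatability) to each timepoint.

Everything is driven by one `numpy` Generator seed: same seed, byte
identical cohort CSV.

**What the generator does not emulate.** Covariates are drawn
independently within group (no pack-years–emphysema correlation, no
size–spiculation interaction); benign nodules do not grow; cfDNA has no
measurement error of its own; and real screening data have inter-reader
measurement variability and nodule-level correlation structures that a
per-group categorical model cannot carry. Passing tests therefore show
that the *methods* recover what the simulation encodes under the
published marginal structure — not that the biological effect sizes are
re-established.

**Known limitation — Youden-cut spread.** With only 29 cancers, the
Youden cut-point's sampling distribution under the calibrated conditions
is bimodal: the main mode sits at the calibrated 3.15 ng/mL boundary, but
a secondary high-specificity mode near 5–7 ng/mL (supported by the
prevalent group's heavy tail) captures roughly one seed in six, so the
fraction of replicate cohorts whose estimated cut lands in [2.0, 4.5]
ng/mL plateaus around 0.84. Since every parameter that this quantity
depends on is pinned by the published tables, the spread is a property of
the design (small case numbers, mixed case severity), not a tunable of
the generator. The acceptance suite reports the measured fraction.

## Reconstructed published-count cohorts

The original subject-level data are available only on request, but the
published tables print exact counts. `cfscreen.reconstructed` synthesizes
minimal subject rows that reproduce, one table at a time: the cfDNA
category counts per outcome group (137 subjects; category representatives
2.0, 3.15 and 5.0 ng/mL sit exactly on the half-open boundaries so
threshold scans recover them), and the below/above-cutoff counts per
size, Lung-RADS and Brock stratum (nodule blueprints chosen so each
subject's derived stratum lands in the intended class). These cohorts are
synthetic reconstructions: only the counts each one encodes are
meaningful, and the full joint distribution across stratifiers was never
published, hence one fixture per stratification.

## Reporting conventions and problem sizes

Percentages are rounded half-up to integer percent when compared against
printed integer values; raw proportions are retained internally. The
analysis report is deterministic given the seed — its JSON carries the
seed, a config hash and the package version, and no wall-clock timestamp,
so same-seed runs are byte-identical.

The acceptance script's simulation-based quantities use: n = 5000 pairs
for correlation recovery; 200 replicate cohorts for the Youden-cut
recovery fraction; 50 replicate cohorts (700 serial nodules) for the mean
estimated VDT, pooled because the VDT estimator's heavy tails make a
single 14-nodule mean unstable; and 50 repeats of a 10-noise-feature,
n = 100 logistic simulation (100 split-half replications each) for the
resubstitution-optimism gap. These sizes keep every quantity's Monte
Carlo error well below the differences that matter while completing in
well under a minute each.
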