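# Methods

This note documents the statistical procedures implemented in
`methfidelity`, the generative model behind its synthetic cohorts, the
defaults and why they were chosen, and the limits of what the test
suite demonstrates.

## Input model and preprocessing

The universal input is a probes × samples matrix of beta values
β = M / (M + U) ∈ [0, 1] (the denominator is exactly M + U, with both
signals zero an error; no stabilizing offset is added). Missing values
are permitted (`""`, `NA`, `NaN` on input, written back as `NA`); how
missingness arose (e.g. detection-p filtering) is outside the model, so
every operation documents its own missing-value policy rather than
imposing a global one.

**Variable-probe selection** ranks probes by standard deviation across
samples — the n−1 denominator everywhere in this package — and keeps
the top ⌈fraction · P⌉, ties broken by probe id so results are
independent of sample order. The default fraction is 0.02; 0.01 is a
documented alternative because the two values are both in circulation
for this style of analysis, and the choice is exposed as
`variable_fraction` rather than hard-coded. Probes with fewer than two
non-missing values are excluded before ranking.

**Standardization** converts each probe row to z-scores using the
moments of the dataset being processed — never moments imported from a
training set — so that cohorts profiled on different scales remain
comparable after the transform. Zero-SD probes are dropped with a
warning (they carry no information and would divide by zero); an input
that loses every probe is an error.

## Hypermethylation score

A sample's score is the mean of its per-probe z-values over the
variable-probe subset used for clustering (the subset is an explicit
argument, so scoring and clustering provably share probes). On a
complete matrix the scores sum to zero because every z row does; a
positive score means globally elevated methylation relative to the
cohort. Samples with no non-missing values are flagged and left
unscored. Group comparisons of the score use a two-sided t-test — Welch
by default, the pooled variant available and always recorded in the
result, since the two can differ materially at unequal group sizes.
The statistic's sign convention is first group minus second, with
groups ordered descending by label so "positive" leads.

## Per-probe ANOVA and FDR signatures

`probe_anova` computes a one-way fixed-effects F per probe from the
between/within sum-of-squares decomposition, vectorized over probes
with per-probe missing-value removal; probes where any group drops
below 2 non-missing samples are excluded with a warning. A probe with
zero variance everywhere is reported as F = 0, p = 1 (no evidence, not
an error); zero within-group but positive between-group variance yields
F = ∞, p = 0. Benjamini–Hochberg adjustment (step-up with monotonicity
enforcement, via statsmodels) is applied across all tested probes, and
per-group mean betas accompany every row. Signature derivation keeps
probes with adjusted p strictly below the threshold (default 0.01);
"below" is read as strict inequality, with `strict=False` available
since the convention differs between toolchains.

## Signature transfer (nearest-prototype classification)

The three-step procedure: (1) standardize each cohort within itself;
(2) average the training cohort's z-profiles within each phenotype
class over the signature probes to form prototypes; (3) Spearman-
correlate each test sample with every prototype over the shared probes
and assign the best-correlated class. Rank correlation makes the
assignment invariant to any strictly increasing transform of a
sample's values, which is the property that lets signatures cross
cohorts and platforms with different intensity scales.

Probe mismatch between a signature and a cohort is handled by
intersection, with the coverage fraction logged and a hard floor
(default 0.8) below which the transfer refuses to run; imputing absent
probes was rejected as silently fabricating data. At least 3 shared
probes are required per sample; a sample constant across the signature
probes has no rank information and is an error. Class ties are broken
lexicographically and logged. Binary CIMP, binary ER and the 6-class
methylation taxonomy are all instances of this one operation with
different signature files. Prototype correlation uses all signature
probes jointly (no per-chromosome blocking).

## Fidelity scoring (nearest-reference distance)

Pairwise distances use d = 1 − ρ_Spearman by default; 1 − |ρ| is
available because correlation-distance utilities differ on this point,
and the convention used is recorded in every output. Ranks use average-
rank tie handling; ρ is the Pearson correlation of ranks. The probe
universe is the intersection of the two matrices' probes (the "all
probes on each array" policy) unless an explicit subset is supplied.
Complete matrices take a vectorized path (rank each profile once,
correlate rank matrices); missing values fall back to per-pair
pairwise-complete computation, warning when a pair shares fewer than
half the universe and failing below 3 shared values. Each query's
fidelity score is the minimum distance over references (ties broken by
reference id, logged), and scores are compared across the four
phenotype groups — ER−/HER2−/CIMP−, ER−/HER2−/CIMP+, ER−/HER2+/CIMP+,
ER+ — with the same one-way F-test, alongside per-group five-number
summaries and the overall median. The module contains no
methylation-specific logic, so expression matrices pass through it
unchanged.

## Ward clustering

Samples are clustered agglomeratively on Euclidean distances over the
variable probes with Ward's minimum-variance criterion in its
squared-distance formulation (the ward.D2-equivalent; heights are
√(2·ΔSSE), verified in tests against exhaustive minimization of the
variance increase for n ≤ 8). A legacy variant that feeds unsquared
distances through the same recurrence is switchable for comparison
with older pipelines. Euclidean distance is assumed because Ward's
criterion is classically defined only for it. Missing betas are
imputed by the probe mean before distance computation (the simplest
deterministic policy, logged) or rejected when imputation is disabled.
`cut_tree` renumbers clusters by first appearance so labels are
deterministic, and the heatmap export emits the leaf-ordered matrix
with ER/HER2/subtype annotation tracks plus an optional basic PNG
rendering.

## Synthetic cohort generator

Each probe j has a baseline logit-scale mean: a two-component mixture
(60% near β = 0.1, 40% near β = 0.8 — weights exposed in config) plus
Gaussian jitter with sd 1.0 on the logit scale. The jitter models the
continuum of per-probe mean methylation on real arrays; a much smaller
value leaves within-class rank noise dominating all class structure,
so that even samples from identical classes look mutually distant —
unlike any real cohort, where matched samples correlate strongly.

Class structure is additive on the logit scale (so effects vanish
smoothly at the boundaries of [0, 1]):

- a 200-probe **ER block** shifted +δ for ER+ classes;
- a 1440-probe **CIMP block** shifted +δ for CIMP+ classes;
- an optional **class block** whose per-probe shifts (+δ with
  probability ½) are derived from a stable hash of the class's
  methylation-class key, giving each class its own prototype — the
  mechanism that emulates a multi-class methylation taxonomy, and, in
  the paired default (300 probes), the coordinated in-vitro adaptation
  pattern that makes the anomalous cell lines unlike any tumor;
- a per-class **global shift** Δ on every probe (Δ = 0.5 for ER+
  classes by default), producing the ER+ global hypermethylation that
  the score detects. Note that a pure logit shift preserves the
  ranking of probe means, so this effect is visible to the z-score
  machinery but nearly invisible to rank correlation — matching the
  observation that global methylation level and profile shape are
  different axes of variation.

Observed betas are Beta(μκ, (1−μ)κ) draws — mean μ, concentration
κ = 50 by default (≈ 0.04 SD at μ = 0.1) — clipped to stay strictly
inside (0, 1). The Beta noise model was chosen over a logit-normal for
its closed-form mean on bounded support and its standing in the
beta-value literature. Everything is driven by two seeds: a probe seed
fixing the universe (ids, roles, baselines, class-block patterns) and
a sampling seed, so paired cohorts share probes while drawing
independent samples, and identical configs are bit-reproducible.

The default paired cohorts mirror the study design: 90 tumors
(ER+/CIMP+, ER+/CIMP−, ER−/CIMP−, 30 each) and 55 cell lines with no
ER+/CIMP− class and 11 anomalous ER−/CIMP+ lines (20%, split across
HER2− and HER2+ groups that share one methylation class). Effect sizes
δ = 1.5 and κ = 50 are the package's standard test conditions. 2000
probes stand in for a ~27k-probe array — the probe dimension enters
the statistics only through averaging, so block proportions, not
absolute counts, drive behaviour; the full scale is one config field
away.

`generate_probe_stats` feeds signature-derivation experiments: null
probes draw p ~ U(0, 1), CIMP-block probes draw p ~ Beta(a, 1). The
default a = 0.1108 was calibrated once, analytically, as the solution
of the BH fixed-point equation k = m₁(qk/m)^a + m₀(qk/m) with
m = 27578, m₁ = 3297, q = 0.01 and k = 1440 — i.e. the strength at
which FDR-0.01 selection from 3297 correlated probes yields a
1440-probe signature — and is not adjusted per run.

## What the synthetic tests do and do not show

Passing tests demonstrate that the machinery is correct (oracle
equivalence, conservation laws, invariances) and that the pipeline
recovers planted structure at realistic effect sizes: prototype
transfer recovers ≥ 95% of true classes, the ER+ score shift is
detected, the anomalous group is the farthest from tumors in every
seed, and BH selection controls the empirical FDR. They do not
demonstrate robustness to features real cohorts have and the generator
omits: batch effects between cohorts, probe-level genomic annotation
structure (CpG-island status, chromosome), correlated noise between
neighbouring probes, cohort-specific missingness patterns, or
mislabelled phenotypes. Results on real data additionally depend on
the unresolved conventions noted below.

## Numerical choices and degenerate inputs

- SD and variance use the n−1 denominator throughout.
- Standardization tolerances: probe rows reproduce mean 0 / SD 1 to
  1e-9; re-standardizing is the identity to the same tolerance.
- t = 0, p = 1 is returned for identical constant groups (scipy yields
  NaN); F = 0, p = 1 for probes with no variance at all.
- Ties: class assignment and nearest-reference break ties
  lexicographically and log the event; Ward merge ties follow scipy's
  deterministic nearest-neighbor-chain order; variable-probe SD ties
  break by probe id.
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers; no global state.

## Known limitations

- The accession-backed checks (reproducing the printed ER and HER2
  t-statistics on the deposited cell-line cohort) require downloading
  the public arrays and are not part of the desk-scale suite; the
  1%-vs-2% variable-fraction ambiguity would apply to them.
- `probe_anova` is one-way fixed-effects only — no covariates, no
  interaction terms.
- The distance module offers no batch-effect alignment; distances
  between cohorts with strong technical differences conflate biology
  and batch.
- Probe-mean imputation before clustering shrinks heavily-missing
  samples toward the centroid.
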