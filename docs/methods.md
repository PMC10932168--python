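# Methods

## Study design being modelled

The package reproduces a case–control analysis of DNA double-strand-break
(DSB) repair in rheumatoid arthritis: 45 patients and 45 healthy
controls, each characterised by (i) a comet-assay damage pair taken
immediately after an in-vitro bleomycin challenge and after 120 min of
recovery, (ii) genotypes at 17 SNPs in homologous-recombination and
non-homologous end-joining genes, and (iii) qPCR expression of seven
DSB-repair genes relative to RPLP1. Only arm-level summaries of that
study are public; they are stored in `dsbrepair.study_data` and serve
both as desk-scale inputs for reproduction tests and as the calibration
of the synthetic-cohort generator.

## Repair scoring

`RepEff = 100 · (1 − t₁₂₀/t₀)` treats the initial damage as 100%, so
only the damage *ratio* matters; the score is scale-invariant and may be
negative when damage increased during recovery (such subjects always
rank in the worst group). Ranks come from the control arm's quartiles
(25th/50th/75th percentiles, linear interpolation between order
statistics — the convention that reproduces the published group edges
within rounding). Intervals are half-open with each cut point on the
higher-efficiency side: group 4 = (−∞, c₁), 3 = [c₁, c₂), 2 = [c₂, c₃),
1 = [c₃, ∞).

Two numbering conventions coexist in the field's reports: the group
table (1 = highly efficient) and a quartile phrasing (quartile 4 =
best). The group table is treated as authoritative; the mapping
`quartile = 5 − group` is exposed for traceability. For the classifier
the rank is recoded 0–3 with 3 = no repair, so the printed decision rule
"if x1 = 3 then 1" reads literally.

Because the original analysis may have used either the cohort's own
control quartiles or the published fixed edges, both modes are provided
(`mode="quartile"` and `mode="fixed"`); the fixed edges are the
midpoints of the published rounded ranges (65.05, 78.65, 83.35), which
contain one-decimal rounding gaps.

## Association statistics

* **Odds ratios.** Cross-product `ad/bc` with the Woolf interval
  `exp(ln OR ± z·√(Σ 1/cell))`, z = 1.96 by default (this choice, not
  the exact quantile 1.959964, matches the reference tables'
  printed intervals; it is configurable). Zero cells follow an
  explicit policy: `na` flags the row undefined (as association tables
  print "NA"), `haldane` adds 0.5 to every cell.
* **Logistic regression.** The outcome is binary (RA vs control), so
  the model is binomial; categorical predictors enter as dummies
  against a declared reference (the first-listed genotype). Fitting is
  Newton/IRLS with tolerance 1e-10 on the coefficient change, at most
  100 iterations, Wald 95% intervals from the inverse observed
  information. Rank-deficient designs raise an error naming the
  collinear columns; non-convergence (e.g. perfect separation) is
  flagged with a diagnostic rather than silently reported. For a
  saturated single-binary-predictor model the MLE slope equals the log
  cross-product ratio exactly, which the tests exploit as an oracle.
* **Rank statistics.** Mann–Whitney U from midrank sums; the two-sided
  p uses the normal approximation with tie correction and a 0.5
  continuity correction. Against exact permutation enumeration the
  approximate p deviates by up to ~0.15 at n ≤ 7 per arm (the U
  statistic itself is exact); at the study's n = 45 per arm the
  approximation is accurate. The Hodges–Lehmann shift is the median of
  all pairwise differences, computed by brute force (n₁·n₂ ≤ ~2·10⁶ in
  any realistic use here).
* **Calibration.** Hosmer–Lemeshow deciles-of-risk (g = 10 default,
  ties never split across boundaries, zero-expected groups merged with
  a warning), χ² with g − 2 degrees of freedom (floor 1). Simulation
  tests confirm a ~5% rejection rate under a correctly specified model
  and high power against a quadratic misspecification.

The package follows an always-nonparametric policy for group
comparisons (no normality gating): with n = 45 per arm and skewed
fold-scale expression data the rank test is the defensible default.

## Expression

`ΔCt = Ct_target − Ct_reference`, `fold = 2^−ΔCt`, a single reference
gene (no multi-reference geometric mean, no efficiency-corrected
model). Technical replicates, when present, should be averaged on the
Ct scale before calling in. Arms are compared by median fold and the
Mann–Whitney test.

## CART classifier

Binary equality tests `x_j = v` (not multi-way or subset splits), split
quality = decrease in Gini impurity `1 − p₀² − p₁²`, growth in
breadth-first order with a budget of 20 internal nodes by default, no
pruning and no minimum leaf size. Determinism is total: split ties
break toward the lowest feature index then the smallest value (a 1e-12
tolerance makes mathematically tied candidates resolve identically
across float routes), and leaf-label ties break toward class 0
(healthy). After growth, subtrees whose leaves all share a label are
collapsed; this never changes a prediction and yields the minimal rule
set — on the reconstructed study data the tree is the single node
"if x1 = 3 then 1 else 0".

Greedy growth is *not* globally optimal: on a parity (XOR) instance no
single split reduces impurity, so growth stops at the majority stump
while a three-split tree would classify perfectly. The test suite
documents this counterexample explicitly; the exhaustive-search
comparison is therefore asserted as greedy ≤ optimal, with equality on
instances whose impurity landscape has no zero-gain plateau.

Evaluation is leave-one-out cross-validation pooled into one confusion
matrix with RA as the positive class. Note that the field's published
confusion tables sometimes swap the FP/FN columns relative to standard
definitions; accuracy and F1 are invariant under that swap and are the
quantities used for fixture comparisons.

## Feature selection

* **SFS** adds the feature maximising the wrapped LOOCV accuracy, ties
  to the lowest index, stopping when no addition strictly improves;
  **SBS** starts full and removes the feature whose removal maximises
  accuracy, ties to the highest index, continuing while accuracy does
  not decrease. Both can run to exhaustion and return the best subset
  seen. Every recorded accuracy is reproducible by re-evaluating the
  recorded subset.
* **Chi2**: per-feature Pearson test (no continuity correction),
  score = −ln p via the χ² log-survival function so tiny p-values do
  not underflow.
* **MRMR**: greedy difference scheme — first pick maximises I(f; y),
  later picks maximise I(f; y) − mean I(f; selected) — with plug-in
  mutual information in nats. When the first pick is a *perfect*
  predictor the criterion ties at zero for every remaining feature
  (redundancy with it equals relevance identically); this degeneracy
  is inherent to the difference scheme.
* **ReliefF**: k = 10 nearest hits/misses (k reduced with a warning for
  small classes), Hamming diff on categorical values, neighbour ties
  toward the lower index, all instances evaluated by default (m = n,
  deterministic). Weights lie in [−1, 1].

## Synthetic cohort generator

Each subject draws a repair group from the configured per-arm group
distribution (defaults: controls 12/11/11/11, cases 1/1/5/38 over
groups 1–4, i.e. the study's table), then a percent-repaired value
uniform inside that group's bin over the range [0, 100] (group 1's bin
is [83.35, 100]; damage never worsens under the default range — the
scoring still handles negative RepEff for real data). `damage_t0` is
uniform on [80, 120] arbitrary comet units and
`damage_t120 = t0·(1 − r/100)`, so the recomputed RepEff equals the
sampled r: only the ratio is identifiable, matching the 100%-baseline
convention. Genotypes are sampled independently per locus from the
per-arm frequencies implied by the published counts — no linkage
disequilibrium, no age/sex confounding, no treatment effects.
Expression folds are log2-normal around the per-arm median (σ = 1 log2
unit, a typical qPCR between-subject spread) with the Ct pair
back-derived as (Ct_ref + ΔCt, Ct_ref), Ct_ref uniform on [18, 25]; the
three genes without published medians (RAD51, ATM, PRKDC — reported
only as "no difference") use one plausible median for both arms (0.01,
0.02, 0.005).

`plant_association` rebuilds the case-arm genotype distribution from
the control arm by multiplying the variant category's weight by the
target odds ratio and renormalising; within-arm renormalisation leaves
the exposure-odds ratio untouched, so the planted population OR is
exact and all other categories stay at OR 1.

All randomness flows from one `numpy` generator seeded by the config;
identical config ⇒ byte-identical cohorts.

What the generator does *not* emulate — within-subject correlation of
assays, Hardy-Weinberg structure beyond the observed genotype
frequencies, LD between the RAD51 (or RAD51B) SNPs, measurement error
in comet scoring — bounds what passing tests show: they validate the
statistical machinery and its calibration to the published marginals,
not the biology of any real cohort.

One inconsistency in the public summaries is resolved in favour of the
count table: the panel lists a control minor-allele frequency of 0.33
for rs1801320 while the genotype counts imply 0.267; the generator uses
the counts as ground truth.

## Problem sizes and numerical choices

Simulation-based tests use deliberately chosen sizes: marginal-fidelity
checks at 10,000 per arm (2% absolute tolerance), planted-OR recovery
at 2,000–5,000 per arm (10–15%), study-scale power and coverage checks
at 45 per arm across 100–200 seeds, and calibration of the
Hosmer–Lemeshow test over 500 replicates of n = 300. Multi-seed checks
assert a success *fraction* (e.g. ≥ 90% CI coverage) rather than
all-seeds success, since individual 45-per-arm cohorts are legitimately
noisy. The adjusted-logistic recovery test averages estimates over
three seeds on the log scale: the data-generating process samples
covariates independently within arm, making the true model exactly
logistic with coefficients equal to the marginal log odds ratios, and
one seed's standard error (~0.085 on a log-OR) would otherwise dominate
a 15% check.

Printed-value comparisons round half-up to the printed decimals and
allow one unit in the last printed digit, because the reference tables
mix rounding and truncation in their final digit (e.g. they print 2.75
where the cross-product of their own counts gives 2.756).

## Known limitations

* Binomial (not multinomial) logistic regression; exact/conditional
  logistic and Firth correction are out of scope, so sparse tables rely
  on the zero-cell policy.
* The published multivariable (adjusted) odds ratios and the
  SFS/SBS-selected panels cannot be reproduced exactly without
  individual-level data; they are validated only by parameter recovery
  on synthetic cohorts. The published 30-feature panel itself is not
  fully reconstructible (it references SNPs absent from the public
  panel table), so the feature set is configurable.
* No multiple-testing adjustment is applied (none was used in the
  reference analysis).
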