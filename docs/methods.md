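# Methods

This note documents the statistical model behind `comorbnet`, the defaults
it ships with, what the synthetic cohort generator does and does not
emulate, and the numerical choices that matter for reproducing its results.

## Data model

A cohort is two tables. `dogs` carries one row per dog: age (years), weight
(lbs), sex/reproductive status (intact female, spayed female, intact male,
neutered male) and breed background (purebred vs mixed). `conditions` is
long-format: one row per (dog, condition) with the condition's body-system
category (20 categories) and an optional onset date at month resolution,
stored internally as an integer month index (year·12 + month − 1); all
spans and windows are computed in whole months.

**Inclusion filter.** Conditions with fewer than `min_cases = 60` dogs are
dropped (the one-in-ten heuristic: ≥10 outcome events per predictor, six
predictors), then dogs left with no retained condition are dropped. The
filter runs conditions-then-dogs exactly once. A second pass can never
change the result: a removed dog by construction carries no retained
condition, so retained case counts are unaffected by the dog step. The
filter log still records this check explicitly.

Note the dog step is a selection on "has ≥ 1 retained condition". For small
condition sets this conditioning induces visible negative dependence among
the indicators of the retained conditions (with only 3 conditions at ~17%
prevalence it removes over half the dogs and dominates moderate planted
effects); with many conditions, as in a realistic 160-condition survey, the
removed fraction and the induced dependence are small. Power/recovery
simulations in the test suite therefore use ≥ 6 conditions.

## Risk models

One maximum-likelihood logistic regression per retained condition:
indicator ~ intercept + age + weight + mixed-breed + three sex contrasts.
The reference sex category defaults to spayed female (the largest group) and
is configurable; fitted probabilities are invariant to this choice. Age and
weight enter untransformed (years, lbs); no interactions and no
regularization — the 60-case floor is the overfitting guard. Fits use
Newton-Raphson (statsmodels). A fit is flagged non-converged when the
optimizer reports failure or any |coefficient| exceeds 30 (quasi-separation,
which in practice arises when a rare sex cell — intact females are ~2.6% of
dogs — contains no cases). Flagged models are excluded from all pairwise
testing, with a logged warning; no remediation (penalization, cell merging)
is attempted.

Every converged fit satisfies calibration-in-the-large (Σ fitted
probabilities = case count, a score equation of the MLE), which the tests
verify to 1e-6 relative.

## Undirected Poisson-binomial test

For a pair (y, z), each included dog contributes a null joint probability
q_d = p̂_y(d) p̂_z(d). The co-occurrence count k over all included dogs (not
only dogs with either condition) is Poisson-binomial with
μ = Σ q_d, σ² = Σ q_d(1 − q_d).

**Tail evaluation.** The default P-value is the refined normal
approximation: evaluate the normal CDF at (k − ½ − μ)/σ and add the
Edgeworth skewness term γ(1 − x²)φ(x)/6 with γ = Σ q(1−q)(1−2q)/σ³.
Measured against the exact dynamic-programming convolution, the maximum
absolute error over random 15-dog instances with joint probabilities in
[0.05, 0.5] is ~0.006; the plain normal tail without continuity correction
errs by up to ~0.11 in the same regime (half the modal point mass) and is
retained only as an explicit option (`skew=0.0, continuity=False`), where
k = μ gives exactly 0.5. The exact convolution (O(n²), documented limit
n ≤ 5000) serves as the oracle in tests, never in the scan.

**Inclusion rule.** Bonferroni with m = C(K, 2) over all tested pairs
regardless of later filtering; an edge requires adjusted P < α (default
0.001), positive Pearson correlation of the observed indicators, and
observed > expected. The Pearson sign filter uses the binary indicators
rather than the fitted probabilities (the probabilities are null quantities;
their correlation does not measure observed co-occurrence); both the sign of
k − μ and the indicator correlation must agree for inclusion. The full pair
table is always returned and exported, significant or not. One-sided
upper-tail P-values target co-occurrence in excess of chance; the lower tail
is exposed for negatively associated pairs but never drives inclusion.

**Calibration.** With the cohort's true covariate-driven probabilities the
per-pair upper-tail test at nominal 0.05 rejects ~4–5% of null pairs
(n = 2000, K = 10). With plug-in probabilities refit on the same cohort the
test is conservative (~2%): the fitted margins absorb part of the
co-occurrence variance, so true rejection rates fall below nominal, never
above. Propagating the estimation uncertainty (delta method) is deliberately
omitted; the conservatism is safe-side for network construction and is
asserted (rate ≤ nominal) in the acceptance tests.

The covariate-blind binomial baseline (expected count N·(C_y/N)(C_z/N)) is
implemented for contrast; in simulations where two conditions share a strong
age effect but are conditionally independent, the baseline flags the pair
(P < 0.001) while the adjusted test does not — the core motivation for
individualized probabilities.

## Directed test

For an ordered pair y → z, eligibility requires both conditions with both
onsets dated; each eligible dog contributes

q_d = [p̂_y/(p̂_y + p̂_z)] · w(S_d, W),  w(S, W) = (W/S)(2 − W/S) if S > W else 1,

the second factor being the probability that two independent uniform onsets
on a span of S months fall within W months (verified against Monte Carlo to
< 0.01). The observed count k_dir is the number of eligible dogs with
onset(y) strictly before onset(z) and a gap ≤ W. Same-month onsets are ties
and count in neither direction — month-resolution data cannot order them.
The span S_d defaults to the dog's whole medical-history span (latest minus
earliest onset across all its conditions, the survey-style observation-window
proxy); a pair-specific alternative (the pair's own gap) is available via
`span_mode="pair"`. Both directions of every pair are tested; Bonferroni
uses m = number of ordered tests performed (2 per testable pair), default
α = 0.01, default W = 12 months (single window per run, configurable; no
multi-window sweep). Per dog, the two directed probabilities sum exactly to
the window term.

## Stratified analysis

Dogs are partitioned into puppy / young adult / mature adult / senior by
age within weight class (left-closed, right-open intervals in both age and
weight; an age exactly at a cutoff belongs to the stage starting there; ages
beyond the table are senior). The shipped cutoff table is a stand-in
approximating veterinary life-stage guidelines (smaller dogs reach
seniority later) and should be overridden via configuration when authorative
cutoffs are available. Within each stratum the inclusion filter is
re-applied and the risk models are refit — stratum-specific covariate
effects, with age retained as a covariate (configurable) — then the
undirected scan runs with a per-stratum Bonferroni multiplier (default
α = 0.01). A stratum with < 2 retainable conditions yields an empty
network, not an error. Cross-stratum outputs: shared-edge overlap matrix,
pairs unique to each stratum, pairs present in every stratified network that
has at least one edge, and set differences against the unstratified network.
Stratification trades confounding control for power: for a dependence
present at all ages the within-stratum P-values are stochastically larger
than the pooled one, which the tests check on replicates.

## Network topology

Edge density |E|/C(|V|,2); clustering reported as global transitivity
(closed-triplet ratio) with average-local clustering computed alongside in
the output metadata, since the two are often conflated; degree and
betweenness centralization follow Freeman's convention (sum of differences
from the maximum, normalized by the star-graph maximum: star = 1, any
regular graph = 0; degenerate for n < 3, where 0 is returned). Directed
networks are projected to undirected before topology summaries.

The degree-distribution comparison fits a discrete power law
(x^−α/ζ(α, xmin), α by bounded MLE, xmin by KS-distance scan over observed
values) and a discrete exponential (geometric, closed-form MLE) on the same
x ≥ xmin support, then applies the Vuong normalized log-likelihood-ratio
test (two-sided normal P-value); a preferred model is declared only below
the configured significance level (default 0.1). Zero-degree nodes are
excluded (unsupported by the power law) and a constant degree sequence is
rejected as undefined. On simulated data the comparison picks the generating
family in ≥ 80% of significant replicates (geometric at 160 nodes,
power-law exponent 2.5 at n = 5000).

## Synthetic cohort generator

The generator is the package's test bed: it draws covariates from marginals
calibrated to a large owner-reported survey cohort — age gamma(shape 2.398,
scale 3.507) truncated to [0.1, 25] years, targeting median 7.75 / IQR
4.08–11.00 (the target quartiles are slightly left-skewed, so a
two-parameter gamma lands at 4.42/7.27/11.18; configurable); weight
log-normal(μ 3.794, σ 0.753 in log-lbs) least-squares calibrated to median
50.9 / IQR 25–69 lbs; sex mix 46.81/45.83/2.58/4.79% (spayed F / neutered M
/ intact F / intact M); 50/50 purebred/mixed — then draws condition
indicators from per-condition logistic models with true coefficients
supplied by the configuration. `default_coefficients` solves intercepts for
target prevalences (default uniform 0.05–0.25 at the covariate means) with
positive age effects in 80% of conditions, per-lb weight effects of order
0.004, and modest breed/sex effects.

Planted dependence adds δ ≥ 0 to condition z's logit when the dog has
condition y — a *conditional* log-odds boost given covariates, not a
marginal odds ratio; planting must form a DAG and conditions are generated
in topological order. Onset ages are uniform between a per-condition
minimum age and the dog's current age, converted to calendar months ending
at a fixed survey month (2021-12). A planted direction (y → z, max lag)
overwrites onset(z) with onset(y) plus a Uniform(0, max lag) month lag
(rounded; a rounded lag of 0 produces a tie that the directed test counts
in neither direction). Every directed plant must also be a dependent plant:
ordering presumes co-occurrence. Dogs with zero conditions are generated
and left in place for the inclusion filter to remove, mirroring the
analysis pipeline. Identical configuration (including seed) reproduces the
cohort byte for byte.

What the generator does **not** emulate: recall bias, reporting lag and
survivor bias in owner-reported data; misreported or reversed onset dates;
genetic/breed relatedness beyond the binary background flag; condition
categories carry no semantics (assigned cyclically). Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
model's own assumptions, not robustness to those real-data pathologies.

## Problem sizes and numerical choices

Simulation-based checks use: 100 random 15-dog instances (tail oracle,
tolerance 0.02 absolute); 1,000 null cohorts of 2,000 dogs × 10 conditions
(type-I calibration, band 5% ± 2% at the true probabilities); 100
replicates of 10,000 dogs (confounding control, ≥ 90% success); 100
replicates of 20,000 dogs × 20 conditions with five disjoint planted pairs
at δ = 1.5 (≥ 80% recovery, ≤ 5% of replicates with any false inclusion);
40 replicates of 20,000 dogs with a planted ≤ 6-month ordering at W = 12
(≥ 80% forward-only inclusion); 200 refits of 20,000 dogs (Wald coverage
95% ± 3%); exhaustive 4-node graphs plus random graphs to 12 nodes against
brute-force topology oracles. These sizes were chosen so each property is
measured with adequate Monte-Carlo precision while the whole suite runs in
a couple of minutes.

Ties in the directed test are excluded by construction; degenerate
variances (σ² = 0) raise rather than returning a P-value; Bonferroni caps
adjusted P-values at 1; exported CSV floats use a fixed `%.10g` format and
GraphML nodes are written in sorted order so that identical runs produce
identical bytes. Run manifests record a SHA-256 per output file; stage wall
times are written to a separate file so manifests of identical runs compare
equal.

## Known limitations

- The plug-in test is conservative (see Calibration); very weak true
  dependencies near the significance boundary are harder to detect than a
  perfectly calibrated test would allow.
- Non-converged (quasi-separated) risk models remove their condition from
  all pairwise tests rather than being repaired; rare conditions with empty
  covariate cells therefore drop out silently except for the log entry.
- The directed null assumes onsets uniform on the dog's span and
  independence of the direction and window terms; real reporting processes
  need not satisfy either.
- The exact Poisson-binomial oracle is O(n²) and intentionally capped;
  it is a validation tool, not a scan backend.
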