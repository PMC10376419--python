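# Methods

`gutsem` re-implements, as a tested pipeline, a style of gut-microbiome
case-control analysis used in mild-cognitive-impairment (MCI) studies:
compositional differential abundance on genus-level 16S counts, diversity
and ordination statistics, and sex-specific latent-variable ("dysbiosis
factor") risk models estimated by structural equation modeling. This note
documents the models, the numerical choices, and what the synthetic-data
experiments do and do not establish.

## Compositional representation

Sequencing counts are compositional: only ratios are informative. All
abundance-level inference runs on centered log-ratio (CLR) coordinates,

    clr_i(x) = ln(x_i + c) − (1/p) Σ_j ln(x_j + c),

with pseudo-count `c = 0.5` (the conventional Dirichlet prior for this kind
of analysis; the choice matters only for rare taxa). Two variants exist:

- `clr_point_estimate` — deterministic, used for quick inspection;
- `dirichlet_clr` — the working representation: each Monte-Carlo instance
  draws the latent composition per sample from Dirichlet(x + 0.5) and
  CLR-transforms it, propagating count uncertainty into every downstream
  statistic. Default 128 instances; estimates stabilize well below that for
  the cohort sizes targeted here.

The SEM stage consumes the element-wise mean of the ensemble
(`clr_mode: mc-mean`), which is deterministic given the ensemble; `point`
and `single-instance` modes are provided as sensitivity knobs.

A note on a deliberately *non*-asserted identity: the mean of the MC
ensemble does not converge to the log point estimate but to the exact
Dirichlet expectation ψ(α_i) − mean_j ψ(α_j) (digamma function). For counts
(8, 2) the Jensen gap between the two is 0.0770. Tests therefore check MC
consistency against the digamma expectation.

## Differential abundance

Per genus, per MC instance: the between-group difference of CLR medians is
divided by the larger of the two within-group dispersions, where dispersion
is the median absolute difference between each sample and a randomly paired
same-group sample (one fresh pairing per instance, seed-controlled). The
reported effect is the median over instances; this is the standardized,
sample-size-free effect statistic of the ALDEx2 family. p-values are
rank-sum tests on instance CLR values (tie-corrected normal approximation,
no continuity correction — matching the convention `correct = FALSE`),
averaged over instances, then Benjamini–Hochberg adjusted across genera.
Taxa with effect > +0.2 are called enriched in cases ("more"), < −0.2
depleted ("less"); 0.2 is the field's convention and is configurable.

The random within-group pairing is drawn per group *membership* (groups
ordered by first sample index), not per case/control role, which makes
effects exactly antisymmetric under a label swap at a fixed seed.

Two calibration facts shape testing: (i) the effect is standardized, so its
null sampling sd (~0.36 at 20 + 20 samples) is intrinsic to the estimator,
not a generator setting; (ii) per-taxon medians over R replicates have se
≈ 1.25·0.36/√R, so null-centering checks use R = 300 to make the check
about centering rather than replicate noise.

## Diversity and ordination

Alpha diversity uses genus-level proportions: Shannon entropy (nats),
Simpson 1 − Σp², observed richness, and Pielou evenness H/ln(richness)
(undefined, reported missing, at richness 1). Beta diversity is Bray–Curtis
on counts. Ordination is non-metric MDS minimizing Kruskal stress-1 (k = 2,
20 random restarts, 300 iterations, tolerance 1e-7). Group separation is
tested by PERMANOVA with Anderson's pseudo-F on squared distances,

    F = (SS_between/(a−1)) / (SS_within/(N−a)),  SS from pairwise d²,

with seed-controlled label permutations, p = (1 + #{F* ≥ F})/(1 + B), and
an exhaustive-enumeration option for tiny designs. With Monte-Carlo
permutations the observed partition itself is re-drawn occasionally (ties
count in the tail), so the attainable minimum p is slightly above
1/(B + 1); the exhaustive option returns the exact tail proportion.

## Latent-variable risk model

The core model: CLR abundances of the classified genera are indicators of
one or two latent factors — lv1 for case-enriched, lv2 for case-depleted
taxa — with latent variances fixed at 1 and observed variables
standardized. Disease status is an ordered (binary) indicator: a
standard-normal latent response thresholded at τ = Φ⁻¹(control proportion),
regressed on the latent factors. Inputs to estimation are Pearson
correlations among CLR columns and two-step maximum-likelihood polyserial
correlations between each CLR column and the disease response.

Estimation is diagonally weighted least squares:

    F(θ) = Σ_k w_k (s_k − σ_k(θ))²

over non-redundant moments, with w_k the inverse asymptotic variance of the
√n-scaled statistic: (1 − r²)² for Pearson entries (delta method), unit
variance for polyserial entries (a documented simplification — the exact
expression buys little at these n), and p(1−p)/φ(τ)² for the threshold
(saturated, so it never contributes to F). Optimization is L-BFGS-B with an
analytic gradient, 5 jittered restarts, ftol 1e-10; loadings and the latent
correlation are bounded to (−0.995, 0.995) and a soft penalty keeps the
disease response variance decomposition valid. After fitting, each factor
is reflected if needed so its first indicator loads non-negatively, making
scores comparable across refits.

Fit statistics: χ² = (n−1)·F_min; GFI = 1 − F_min/F_0 with F_0 the
discrepancy of the zero model (all σ = 0); AGFI = 1 − (1−GFI)·m/df for m
moments; RMSEA = √(max((χ²−df)/(df(n−1)), 0)), so RMSEA = 0 exactly when
χ² ≤ df. Saturated models (df = 0) report GFI 1, AGFI missing, RMSEA 0, and
are logged. Fit-index targets default to GFI ≥ 0.94, AGFI ≥ 0.89,
RMSEA ≤ 0.01 — the weaker of the two sex-specific models this pipeline is
patterned on — and are configurable.

**Indicator pruning.** Starting from all classified taxa, indicators are
removed one at a time until the targets are met: at each step the indicator
with the smallest absolute loading is dropped and the model refit
(deterministic; ties break on indicator order; at least 3 indicators per
factor are kept). The rationale for loading-based rather than
fit-improvement-based selection: a truly uninformative indicator has a
near-zero loading and is correctly *modeled* by the factor model, so its
presence barely degrades the fit indices — greedy best-fit-improvement
deletion then frequently sacrifices a well-loading indicator that happens
to carry sampling misfit, while weakest-loading deletion removes planted
pure-noise indicators before any informative one in simulation (10/10
seeds). If the targets are unreachable at the minimum model size,
`prune_indicators` raises with the full trajectory; the pipeline's default
policy (`on_pruning_failure: best`) then keeps the trajectory's final
model and logs the failure, since small cohorts cannot always reach
strict index targets.

**Latent collapse.** In two-factor models a high |lv1–lv2| correlation
(default threshold 0.85, ≥ convention) indicates one dysbiosis dimension
and triggers refitting with lv1 only — mirroring the analysis branch where
the male model collapsed to a single factor. The threshold is a package
default; the antecedent analysis reported only "a strong correlation".

**Blinded scoring.** The measurement part (factors → taxa) is extracted and
*refit* on the CLR data without the disease column, and per-sample factor
scores are computed by the regression (empirical-Bayes) method,

    score = Ψ Λᵀ (Λ Ψ Λᵀ + Θ)⁻¹ x,

on standardized rows. Refitting, rather than slicing the joint fit,
reproduces the "disease-blinded" scoring design.

**Risk model.** Logistic regression (maximum likelihood, no penalty) on the
factor scores, evaluated by stratified 10-fold cross-validation with SMOTE
class balancing applied inside each training fold only (k = 5 neighbors,
capped at minority−1; synthetic points are uniform interpolations between
minority nearest neighbors). Out-of-fold predicted probabilities give the
ROC and trapezoid AUC (identical to the tie-corrected Mann–Whitney
statistic); both out-of-fold and apparent AUC are reported, labeled. Note
that, as in the design this follows, indicator selection and pruning happen
on the full cohort before cross-validation, so out-of-fold AUC retains some
selection optimism; the null-data experiments quantify it (mean ≈ 0.55).

## Synthetic cohorts

The generator plants exactly the structure the pipeline is meant to
recover. Per sample, a dysbiosis score z ~ N(1, σ_z) for cases and
N(0, σ_z) for controls; log relative abundance of the lv1 taxon set rises
by `loading_strength`·z and of the lv2 set falls by it, on top of a
per-dataset N(0, 1) baseline giving realistic rank-abundance skew. Counts
are Dirichlet-multinomial: expected compositions scaled by concentration
1/overdispersion (overdispersion 0 = pure multinomial), depths
Poisson(20 000). Defaults: 18 cases / 23 controls per stratum (the female
cell of the cohort design this emulates; the male cell is 11/17), 50
genera, 8 lv1 + 3 lv2 taxa, loading 1.0, overdispersion 0.02 (Dirichlet
concentration 50, mid-range for stool 16S data).

σ_z (latent_sd) calibrates how well the dysbiosis factor separates groups:
with a case–control gap of 1, the factor's own discrimination is
AUC = Φ(1/(√2·σ_z)). The default σ_z = 0.5 puts that oracle at 0.92, so a
*fitted* risk model — which estimates the factor with attenuation (score–
truth correlation ≈ 0.94) and evaluates it out-of-fold at n ≈ 41 — attains
a mean AUC in the high 0.8s, the regime a usable microbiome risk model
reports. A sexed cohort is two independent strata (separate baselines and
latent draws, optionally different taxon sets); null cohorts use the same
marginal process with group labels permuted independently of z.

What passing the synthetic experiments does *not* show about real data:
taxa are independent given one factor (no ecological interaction
structure), baselines are log-normal-ish with no phylogenetic correlation,
depths are homogeneous, there are no batch or covariate effects (age is a
known confounder in the motivating cohort and is not simulated), and the
true model is exactly the fitted model class.

## Problem sizes in the checks

The shipped acceptance experiments use: 300 null replicates for effect
centering (per-taxon median se ≈ 0.026), 20 replicates each for planted
classification and end-to-end AUC, 200 null replicates × 999 permutations
for PERMANOVA type-I error, n = 5000 for sampled DWLS recovery, and the
cohort-scale strata (11/17 and 18/23) for the pipeline run. These sizes
make each stochastic check's precision explicit in its test.

## Known limitations

- DWLS here is the plain diagonally weighted estimator; no mean-and-
  variance-adjusted ("scaled") test statistic is computed, and fit indices
  use the unscaled χ².
- Polyserial weights use the unit-variance simplification noted above.
- No covariate adjustment (age, BMI) in the risk model; the cohort summary
  reports their group differences but the SEM does not condition on them.
- Bray–Curtis is a semimetric; NMDS and PERMANOVA treat it as such, and no
  phylogeny-aware distances are provided.
- The latent-collapse threshold (0.85) and pruning targets are defaults to
  be revisited per dataset, not estimated quantities.
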