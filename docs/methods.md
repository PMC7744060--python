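# Methods

## Measurement model

The package implements the Alkire–Foster dual-cutoff counting approach for
*m* ≥ 2 binary deprivation indicators. Dichotomization is rule-based: a
codebook lists, per indicator, the full set of categorical response codes
and the subset that flags deprivation; `b_ij = 1` iff respondent *i*'s
response to indicator *j* is in that subset. Indicator weights `w_j` are
stored as exact rationals summing to 1 (default: equal weights `1/m`), so
the weighted deprivation score `c_i = Σ_j w_j b_ij` is an integer numerator
over a fixed denominator and the identification test `c_i ≥ k/m` is an
exact integer comparison. This removes a real failure mode: with float
weights, scores that should equal the cutoff exactly (e.g. 2/4 at k = 2)
can fall on either side of it.

All three indices are weight-aware and reduce to the unweighted textbook
formulas under unit weights:

- `HCR_k = Σ_{i∈Q} s_i / Σ_i s_i`, the weighted share identified;
- `A_k = Σ_{i∈Q} s_i c_i / Σ_{i∈Q} s_i`, a *conditional* mean — reported
  as undefined (`None`/NaN), never 0, when the identified set is empty;
- `M_k = Σ_{i∈Q} s_i c_i / Σ_i s_i`, the mean censored score, so
  `M = HCR × A` holds identically.

Two computational paths coexist deliberately. The scalar estimators
(`headcount_ratio`, `average_intensity`, `adjusted_headcount`) convert
sampling weights to exact rationals (floats are binary rationals, so
`Fraction(w)` is lossless) and return `Fraction`s; on this path the product
identity and the subgroup decomposition `M = Σ_g share_g · M_g` are exact
identities, not approximations. `af_profile` is the vectorized float path
used for large samples and for standard errors; its agreement with the
rational path is held to 1e-12 by tests.

## Standard errors

Published tables for this family of indices report standard errors without
printing the estimator. We provide two and cross-check them against each
other:

- **Linearized** (default): each index is a ratio estimator of a weighted
  mean, so `Var ≈ Σ s_i² r_i² / (Σ s_i)²` with residuals `r_i = 1{i∈Q} −
  HCR` for HCR and `r_i = ĉ_i − M` for M (ĉ the censored score). For
  A = M/HCR the delta method gives `Var(A) = [Var(M) − 2A·Cov(M,HCR) +
  A²·Var(HCR)] / HCR²`. Under unit weights the HCR formula reduces to the
  binomial `√(p(1−p)/n)`. No finite-population correction is applied (no
  frame size is assumed).
- **Bootstrap**: nonparametric resampling of respondents with replacement,
  default 1,000 replicates, seeded (default seed 20200403) and
  reproducible. Replicates with an empty identified set contribute no A
  value; A's bootstrap SE is reported only when at least two replicates
  define it.

The two agree asymptotically; tests enforce agreement within 20% relative
at n = 5,000 with unit weights.

## Missing responses

Item non-response has no canonical treatment in this setting, so the
dichotomizer takes an explicit `missing_policy`: `drop` (default) removes
respondents with any missing indicator response and logs the count;
`not_deprived` keeps them with `b_ij = 0`, which biases HCR downward and
is therefore not the default. The full-run metadata records dropped-row
counts so replication differences are diagnosable.

## Subgroups and overlap

`subgroup_decompose` estimates the full profile per group plus weighted
population shares and verifies the decomposition identity internally (1e-9
on the float path). `pairwise_overlap` reports, for each indicator pair,
the weighted share deprived in *both at least* (not exactly-two), which
equals HCR(k=2) on the two-column submatrix — a cross-check enforced in
tests along with the Fréchet bounds. Association between binary indicators
is summarised by the weighted phi (Pearson) coefficient; phi is NaN when a
column has zero variance. Phi is the default because it needs no
distributional assumption; a tetrachoric correlation would add a bivariate
normality assumption without changing any downstream quantity here.

## Count regressions

The outcome is the unweighted deprivation count `d_i = Σ_j b_ij ∈ {0..m}`.
Families: OLS with HC1 robust standard errors, and Poisson maximum
likelihood with the standard robust sandwich covariance — the common pair
for count outcomes when the variance model is not trusted. Fits are
unweighted by default with a `use_sample_weights` option (WLS for the
linear model, var-weighted GLM pseudo-likelihood for Poisson), because
weighting conventions for regression differ across publications even when
descriptive tables are weighted; surfacing the choice beats hiding it.

Covariate coding: race/ethnicity enters as white/black/hispanic dummies
with {other, 2+ races} as the reference; education is an ordered 1–4 score
(less than high school, high school, some college, bachelor's+); household
income arrives as a 1–21 category and is imputed to the category midpoint
(open-ended top category: 1.5 × its lower bound) before taking the natural
log. The 21-category bounds table packaged here is the package's own
documented definition — users with a real survey extract should supply the
survey's actual bounds. Rows with any missing covariate are dropped and
logged; constant columns are flagged as collinear with the intercept.

A Poisson coefficient β maps to a percent change in the expected count via
`(e^β − 1) × 100`; the transform is monotone and asymmetric (−β does not
give the negated percentage). Note that evaluating it at a coefficient
printed to two decimals (e.g. 0.39 → 47.7%) can differ slightly from a
percentage computed from the unrounded estimate.

## Synthetic data generator

The generator emulates a SHED-like weighted survey so the whole pipeline is
testable offline. Defaults are fixed emulation conditions, not estimates:

- n = 1,030 respondents (the April 2020 supplement's size); indicator
  marginals (0.205, 0.12, 0.23, 0.148), matching the observed hardship
  rates of roughly 20.5% (financial condition), 12% (employment), 23%
  (income drop), 14.8% (bills);
- dependence: a single standard-normal latent hardship factor; indicator
  *j* is deprived when `√ρ·z_i + √(1−ρ)·e_ij` falls below the probit
  threshold `Φ⁻¹(p_j)`, preserving each marginal exactly while ρ controls
  the positive association. The `shed_like` preset sets ρ = 0.6, encoding
  the strong observed co-occurrence of economic hardships with one
  parameter; ρ = 0 gives independent indicators for closed-form checks;
- within the deprived (non-deprived) state, the concrete response code is
  uniform over the deprived (non-deprived) code set;
- demographics from fixed category mixes mirroring the emulated sample's
  composition (race/ethnicity 63.2/11.8/7.2/16.4/1.4%, four age bands,
  four education levels, marital mix, household-size mix, a 21-category
  income mix, 87.4% metro); a uniform state draw with 31 of 51 states
  under a pre-April stay-at-home order;
- sampling weights i.i.d. lognormal (σ = 0.5), normalized to mean 1 —
  weights are independent of deprivations, so weighted estimators remain
  exactly unbiased;
- optional `regression_truth`: counts drawn from `Poisson(exp(x'β))`
  truncated at m, with the deprived indicators placed uniformly, for
  parameter-recovery studies (with the default magnitudes, truncation
  affects ≪1% of draws).

What the generator does **not** emulate: panel recruitment, raking /
post-stratification structure in the weights (they are i.i.d. noise),
item non-response, and any dependence structure beyond one common factor.
Passing tests therefore validate the estimators and their calibration, not
the fidelity of any particular real-world joint distribution.

## Analytic oracles and the recovery study

Under equal weights the population count distribution is Poisson-binomial;
`implied_hcr_independent` enumerates all 2^m outcomes exactly (guarded at
m ≤ 20). Under ρ > 0, `af_truth` integrates the latent factor with
101-node Gauss–Hermite quadrature, giving population HCR/A/M at every k to
near machine precision (it reduces exactly to the Poisson-binomial at
ρ = 0, a tested identity).

`recovery_study` draws `reps` surveys (child seeds from a SeedSequence, so
one seed reproduces the whole study), runs the full
dichotomize-and-estimate pipeline, and reports per cell (statistic × k):
truth, mean estimate, bias, the Monte-Carlo SE of the bias
(sd/√reps), RMSE, and empirical coverage of the ±1.96·SE linearized
intervals. Coverage is reported for every cell, with an a-priori
`coverage_applicable` flag marking cells where the binomial normal
approximation is adequate (expected identified count `n·p·(1−p) ≥ 5`);
at the default marginals with ρ = 0 the k = 4 cell has an expected count
below 1, where no normal-theory interval can attain nominal coverage and a
calibration claim would be meaningless.

Two properties of such studies are worth keeping in mind when reading
results. First, for exactly unbiased estimators the per-cell bias z-score
is ~N(0, 1) *regardless of the number of replications*, so across many
cells some |z| values near or above 2 are expected by chance; a persistent
sign across independent studies, or growth with √reps, is what would
indicate real bias. Second, 500-replication coverage estimates carry a
sampling SD of about 0.01, so single-run cell values scatter around the
true coverage accordingly. Problem sizes used in the packaged studies
(n = 1,030 × 500 reps for recovery; n = 200,000 for closed-form
agreement; n = 5,000 for regression recovery and bootstrap/linearized
agreement) were chosen to make these Monte-Carlo checks sharp at desk
scale.

## Numerical and design notes

- Identification ties: `c_i = k/m` counts as identified (≥, exact rational
  comparison).
- Empty identified set: A undefined, M = 0, SE of A undefined.
- Display convention: HCR and M in percent, A on [0, 1]; displayed
  percentages are full-precision values rounded half-even to one decimal;
  full precision is always stored alongside.
- Degenerate inputs: zero total weight, all-rows-dropped, out-of-range k,
  and zero-variance phi columns raise or flag rather than returning
  silently wrong numbers.
- The decomposition identity is asserted internally on every
  `subgroup_decompose` call, making silent share/weight misalignment
  impossible.

## Limitations

- Only the adjusted headcount (M0) family member is implemented; no
  depth/severity variants, dominance curves, or inequality-among-the-poor
  decompositions.
- Weights are consumed as given; no raking, trimming, or replicate-weight
  machinery.
- The linearized variances treat the sample as independent draws
  (weights-only design); clustering or stratification in a real design
  would require replicate weights the package does not construct.
- The Poisson fit is a pseudo-likelihood under truncation-at-m data
  generation; with realistic hardship rates the truncation is negligible,
  but counts near the indicator ceiling would bias any Poisson model.
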