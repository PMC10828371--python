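# Methods

`sweetspot` implements a two-stage discovery procedure for *sweet spots* —
optimal values of continuous physiological phenotypes — using
health-deficit scores as the outcome, together with the replication
power-planning machinery, and a synthetic-cohort generator that makes every
stage testable without access to restricted cohort data.

## Health-deficit instruments

Five instruments place each participant on the unit interval, higher =
less healthy:

* **I, frailty index**: mean of binary/graded deficit indicators (default
  51). The denominator is the number of *observed* deficits; a participant
  with fewer than 80% of deficits observed (`min_deficit_fraction`) gets a
  missing score. On complete-case analyses this floor is moot, but the
  package must define behavior for partial records and this is the
  standard deficit-accumulation convention.
* **II, five-disease count**: cancer, cardiovascular disease, major
  pulmonary disease, dementia, diabetes, each confirmed by either the
  diagnosis flag or a paired medication/treatment flag; score =
  confirmed/5. Health levels are categorical: 0 diseases = healthiest,
  exactly 1 = intermediate (excluded from two-group variance comparisons),
  ≥ 2 = least healthy.
* **III, other chronic conditions**: normalized count over a configurable
  flag set (default 28) disjoint from instrument II by construction; same
  observed-denominator rule as the frailty index.
* **IV / V, cognitive and physical composites**: each test score is
  oriented by its declared direction of risk (inversion = negation; any
  monotone inversion is equivalent after ranking), rank-normalized to
  (r − 0.5)/n using average ranks over non-missing values, averaged within
  domain over the participant's observed tests, then averaged across
  domains with equal domain weight. A participant missing an entire domain
  gets a missing composite. Whether to average domains before or after
  handling within-domain missingness is genuinely open; the domain-mean-of-
  observed-tests rule is this package's declared choice.

Continuous instruments are cut into quartile health levels on the pooled
cohort (all ages and sexes together), using inclusive linear-interpolation
quantiles (recorded in the run manifest). Boundaries are half-open with
ties going to the less-healthy side except below the first quartile, i.e.
healthiest means strictly `score < q1`.

## Variance screen

The biological premise: a phenotype under homeostatic control should be
*less variable* in healthier people. The screen pre-filters the phenotype
panel — columns with more than 24% missingness are dropped (with a named
exemption list for scarce-but-important biomarkers), and within any pair
with pairwise-complete Pearson |r| > 0.9 the later column in input order
is dropped.

For each phenotype × instrument × sex × age stratum (<55, 55–64, 65–74,
≥75), the healthiest and least-healthy groups are compared with the
two-group Brown–Forsythe test: absolute deviations from each group's
*median* (robust to the right-skew typical of deficit scores), one-way F
statistic on those deviations with (1, N−2) degrees of freedom.
Combinations where either group has fewer than 30 complete cases are
skipped and logged. The Bonferroni denominator is the *planned* fixed
product #phenotypes × #instruments × #sexes × #strata — skipped strata
still count, keeping the correction conservative and the denominator
auditable from the logs. A phenotype is selected when at least one of its
comparisons is significant after correction **and** the healthiest group
has the lower variance; the test itself is two-sided and directionality is
imposed afterwards through the recorded variance direction.

## Segmented sweet-spot estimation

Per sex, instrument scores are residualized on age by OLS (optionally on a
one-hot covariate design, reference level = first category); sweet spots
are assumed constant in age but not sex, so ages are pooled after
residualization. For each selected phenotype x and residualized score y,
the one-breakpoint model

    y = β0 + β1·x + δ·(x − ψ)+ + ε

is fitted by iterative linearization: at working value ψ⁽ᵗ⁾ the design is
expanded with (x − ψ⁽ᵗ⁾)+ and the negative gap indicator −1{x > ψ⁽ᵗ⁾};
the gap coefficient γ̂ drives the update ψ⁽ᵗ⁺¹⁾ = ψ⁽ᵗ⁾ + γ̂/δ̂, converging
when |γ̂| < 1e−8 (≤ 50 iterations), started from the median of x with
restarts from the 10/30/70/90th percentiles, and ψ projected into the
[2nd, 98th] percentile range of x. A 501-point quantile grid search (exact
OLS at each candidate breakpoint) always runs alongside: if it finds a
lower SSE the grid solution is reported and the fit flagged
`converged=False, method="grid"`. Convergence of the iteration to an
inferior local optimum is thereby treated as a failure of the iteration,
never of the fit — a grid estimate is a valid segmented fit and is
classified normally rather than demoted to a straight line; the
straight-line fallback applies only when no segmented fit is obtainable
(constant x, too few pairs). This hybrid guarantees by construction that
the reported SSE never exceeds the grid oracle's.

Slope standard errors and 95% CIs come from the OLS covariance at the
final ψ̂, i.e. they condition on the estimated breakpoint (the common
practice; the package documents rather than corrects this). The breakpoint
standard error uses the delta method on the gap coefficient,
se(ψ̂) = se(γ̂)/|δ̂|, with t(n−4) quantiles. Simulated coverage of the ψ
CI at the package's reference recovery scenario is ≈ 0.95 (the test suite
asserts membership in [0.90, 0.98], acknowledging delta-method slack).

A breakpoint is a **sweet spot** iff (1) the two slopes have opposite
signs, (2) both slope CIs exclude zero, and (3) the slope difference is
significant after Bonferroni correction over the fixed product
#selected phenotypes × 2 sexes × #instruments. Same-sign slopes with both
CIs excluding zero are classified increasing/decreasing; an
opposite-sign shape failing the criteria is `nonmonotonic_nonsignificant`;
anything else is flat.

### Pseudo-score test for the slope change

The test of H0: δ = 0 augments the straight-line model with the *mean* of
the working covariates (x − ψ_k)+ over k_eval = 10 fixed candidate
breakpoints at equally spaced interior quantiles of x, and refers the
studentized coefficient to t(n−3), two-sided. Because the candidate
breakpoints are functions of x alone, the null distribution is exact under
Gaussian errors — simulated null rejection is nominal to Monte-Carlo
precision. The number and placement of evaluation points is a design
choice (recorded in the manifest); calibration simulations, not numeric
identity with any particular implementation, are the correctness
criterion.

## Power analysis and replication planning

For a standard-normal covariate, breakpoint ψ on the standardized scale,
response standard deviation σ and slope difference δ, the score statistic
is asymptotically normal with unit variance and noncentrality

    ncp = √n · (δ/σ) · sd_r(u_ψ),      u_a = (X − a)+,

where sd_r is the standard deviation after projecting out the intercept
and linear term. All required moments E[u_a], E[u_a·u_b], E[X·u_a] have
closed forms in the normal pdf/cdf, so two-sided power
Φ(−z_{α/2} + |ncp|) + Φ(−z_{α/2} − |ncp|) is analytic and equals α exactly
at δ = 0. An optional `k_eval` variant computes the noncentrality of the
actual 10-point pseudo-score test (cross-moments of the working
covariates); it matches Monte-Carlo rejection rates of
`score_test_slope_change` to well within ±0.03 at the reference scenario
(analytic 0.9525 vs simulated ≈ 0.952 at n=300, δ=0.05, σ=0.07, ψ=0).

The minimal detectable slope difference is the root of
power(δ) = target, found by bracketed Brent iteration (tolerance 1e−5);
power is strictly increasing in δ so the root is unique. At the reference
replication scenario (σ=0.07, ψ=−0.24, α=0.05, power 0.8) the thresholds
are 0.0396 at n=282 and 0.0682 at n=95. Replication subsets take each
phenotype's largest |δ̂| across instruments and sexes from the primary
scan (standardized by the phenotype's sample SD, recorded in the manifest)
and keep phenotypes exceeding the threshold.

All power computations live on the standardized covariate scale (mean 0,
SD 1); the breakpoint-position and effect-size assumptions only make
sense there.

## Synthetic-cohort generator

The generator's defaults define the package's reference study conditions:
n = 10,000 participants (6,000 in the unit-test fixture), ages uniform on
45–85, 52.3% female, 51 deficits, 5 disease flags with medication
confirmation, 28 chronic flags, 7 cognitive tests in three domains, 5
physical tests, and an 18-phenotype panel (6 V-shaped, 3 increasing, 3
decreasing, 6 null). A single latent *health-deficit load*

    load = 0.18 + 0.20·(age − 45)/40 + 0.30·(u − ½),   u ~ U(0, 1),

clipped to (0, 1), drives everything: deficits are independent Bernoulli
draws with probability load × per-deficit susceptibility (susceptibility
means 0.33 F / 0.29 M, calibrated once so the female frailty-index mean
sits at ≈ 0.092 and male at ≈ 0.081, matching a typical community cohort);
disease and chronic flags and test scores are analogous monotone
functions of the load. The *linear* dependence on u (rather than a
sigmoid) is deliberate: it keeps the planted phenotype relationships
piecewise-linear in expectation after age residualization, so the
segmented model is correctly specified up to noise. Right-skew of
instruments I–III emerges from the small Bernoulli probabilities.

Phenotypes are generated by inverting the planted relationship: for a
V-shape with breakpoint ψ and slopes (b_l < 0 < b_r on the latent-percentile
scale), each participant lands on a random side and gets
x = ψ + u/b_side + noise; monotone phenotypes use one side; null
phenotypes are independent homoskedastic Gaussians. The noise SD is
`base_sd` over the healthiest latent tertile, `base_sd × factor` over the
least-healthy tertile, linear in between — so the heteroskedasticity
factor *is* the planted tertile-to-tertile residual-SD ratio. Monotone
phenotypes' `base_sd` is sized at ~45% of their latent-driven spread so
that measures sharing the latent driver correlate near 0.8, like distinct
but related measures in a real panel, instead of collapsing into the
correlation prefilter as near-duplicates. When a phenotype is declared
sex-specific, the male breakpoint is shifted by 5% of the planted support
width. Missingness is completely at random, default 1% per column; truth
(per-sex relationship, breakpoint, slopes, heteroskedasticity factor) is
written to a JSON registry beside the cohort, and the latent percentile is
kept as a `latent_u` column for validation only.

What the generator does **not** emulate: informative missingness,
longitudinal waves, sampling weights, realistic phenotype units and
correlation structure beyond the single shared latent factor, or
age-dependent optima. Passing tests therefore demonstrate that the
pipeline recovers truth under its own model assumptions — correctness of
the machinery, not transportability of any biological finding.

## Numerical choices and degenerate inputs

* Quantiles: inclusive linear interpolation everywhere (`numpy` default).
* Brown–Forsythe with all absolute deviations equal returns (W, p) = (0, 1);
  perfect spread separation with zero within-group variation returns
  (∞, 0). Groups below 2 observations are errors.
* `fit_segmented` requires ≥ 20 complete pairs and non-constant x;
  `residualize_age` rejects constant age.
* The grid and the iterative scheme share the same interior-percentile
  breakpoint constraint, so their solutions are directly comparable.
* Bonferroni denominators are fixed planned products, never the count of
  tests actually performed.
* Pipeline seeding: one root seed in the config; per-stage child seeds are
  derived through `numpy` SeedSequence spawning, so stages are independent
  and the whole run is reproducible byte-for-byte.

## Problem sizes used in the shipped checks

The test suite exercises the pipeline at n = 6,000 (unit fixtures) and
n = 10,000 (end-to-end planted-truth demo), 200-replicate parameter
recovery at n = 2,000, 100-dataset oracle-equivalence checks, 2,000–5,000
replicate calibration of the Brown–Forsythe and score tests, and
3,000-replicate power self-consistency — sizes chosen so the full suite
documents the method's operating characteristics while remaining quick to
run on a laptop.

## Known limitations

* Slope CIs condition on ψ̂; breakpoint-search uncertainty is reflected
  only in the ψ CI via the delta method.
* Single breakpoint only; genuinely smooth nonlinear relationships will be
  approximated by the closest broken line and may be classified monotone.
* The analytic power formula is asymptotic; at very small n or extreme
  breakpoint positions it can drift from finite-sample rejection rates.
* The screen's complete-case rule conditions on the instrument score and
  the single phenotype under test, not on the full phenotype panel.
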