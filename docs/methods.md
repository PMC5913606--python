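# Methods

## Model and estimands

All analyses concern repeated methylation measures y_ij (beta values) of
individual j at measurement i, a binary individual-level exposure z_j, and
age x_ij centred at a configurable origin (default: the minimum age
present, so "baseline" means the first time-point).  The trajectory model
is

    y_ij = (β00 + β01 z_j + u0j) + (β10 + β11 z_j + u1j) x_ij + ε_ij

with (u0j, u1j) ~ N(0, Σ_u) (unstructured), ε_ij ~ N(0, σ_e²), independent
of the u's.  The exposure-related estimands are β01 (baseline effect) and
β11 (age-interaction / slope effect).  A CpG counts as a hit when the
smaller of the two Wald p-values falls below the significance threshold
(default 1×10⁻⁷, the conventional epigenome-wide level).

## Cluster-robust linear regression

OLS across all repeated measures estimates the same fixed effects; the
sandwich estimator V = (X′X)⁻¹ [Σ_j w_j′w_j] (X′X)⁻¹ with
w_j = Σ_{k∈j} e_k x_k supplies standard errors valid under arbitrary
within-individual residual correlation.  Implementation notes:

* All CpGs with complete data share one least-squares factorization of X;
  the per-cluster score sums are vectorized across CpGs
  (`np.add.reduceat` over cluster-sorted rows + one einsum), so the cost
  per additional CpG is a handful of matrix products.
* CpGs with missing values are refit per missingness pattern: the bread
  (X′X)⁻¹ and the cluster count m are recomputed on exactly the rows used.
  A CpG with fewer usable rows than parameters is flagged `unfit`; m ≤ p
  flags the inference `unreliable`.  Per-CpG complete-case subsetting is
  the assumed missing-data policy throughout.
* No finite-sample correction is applied by default, matching the bare
  sandwich formula; the CR1 factor m/(m−1) is available behind
  `small_sample_correction`.  With hundreds of clusters the difference is
  negligible.
* Wald p-values use the standard normal by default; Student t with m − p
  degrees of freedom is available (`df_method="t_clusters_minus_p"`).  At
  the cohort sizes of interest (m ≈ 500–700) the two are indistinguishable;
  the default is declared so results are reproducible.
* A design with condition number above 1e8 triggers a warning; solving is
  QR-based throughout rather than via the normal equations.
* Degenerate Wald cases: SE = 0 with a zero estimate gives p = 1; SE = 0
  with a nonzero estimate gives p = 0 plus a runtime warning.

## Mixed models

Estimation is REML — standard for variance-component inference; maximum
likelihood would bias σ_e² and Σ_u downward at these cluster counts.
Writing V_j = σ_e²(I + Z_j G Z_j′) with G = Σ_u/σ_e², the fixed effects
and σ_e² are profiled out analytically, leaving ≤3 free parameters: G is
parameterized by its Cholesky factor with log-transformed diagonal, which
keeps Σ_u positive semidefinite unconditionally.  The profiled −2·REML
criterion

    f(θ) = (n−p) log RSS_V + Σ_j log|I + Z_j G Z_j′| + log|X′V0⁻¹X|

is minimized with L-BFGS-B (bounds ±(7,9) on the log-diagonal, max 200
iterations, relative tolerance 1e-8, finite-difference step 1e-6).
Numerical choices:

* Clusters sharing a random-effects design Z_j — all of them, in a
  balanced panel — share one small V0 inverse per evaluation, and the
  outcome-independent sufficient statistic Σ_k X_k ⊗ X_k is precomputed,
  so an objective evaluation costs O(n_rep² p²) regardless of the number
  of individuals.  One fit at 464 individuals × 5 ages takes ~10 ms.
* A log-diagonal element at its lower bound (variance ratio ≤ e⁻¹⁴) sets
  the `boundary` flag; the fit is still returned.  An intercept+slope fit
  whose clusters never contain two distinct ages is returned as `failed`
  (the slope variance is unidentifiable), never silently replaced by the
  intercept-only model — the two are distinct strategies.
* Line searches can stall from finite-difference noise once the criterion
  has flattened; a solution whose projected gradient is small (≤1e-3 on
  the −2·log-likelihood scale, the resolution of the finite-difference
  gradient) is classified converged.  Stationarity is verified in tests by
  direct perturbation of the criterion.
* Fixed-effect covariance is σ̂_e²(X′V0⁻¹X)⁻¹ at the estimated components;
  Wald p-values use the normal reference, matching the robust route (no
  Satterthwaite/Kenward–Roger degrees of freedom — with hundreds of
  clusters the refinement is immaterial).
* Every CpG is optimized from the same fixed start (θ = 0, i.e. Σ_u =
  σ_e² I), making batch results independent of fitting order and thread
  count.

In a balanced panel the fixed-effect columns lie in the span of the
random-effects design within each cluster, so GLS and OLS point estimates
coincide exactly; the two longitudinal methods then differ only in their
standard errors.  This identity is exercised directly by the test suite.

## Cross-sectional EWAS and hit-selection strategies

Observations at one time-point come from distinct individuals, so the
per-time-point exposure regressions use classical OLS standard errors and
t reference (n − p df).  The only difference from a robust fit restricted
to the same rows is classical-vs-HC0 variance, which the tests document.
Time-points are matched by exact age in simulated data and by a
configurable binning tolerance (default ±0.5 y) for real cohorts with age
jitter.  Selection rules: `baseline` (first time-point p < τ),
`any_timepoint` (min over time-points), `all_timepoints` (max over
time-points); longitudinal strategies use the minimum over (β01, β11)
p-values.  No multiplicity adjustment is applied beyond the fixed
threshold, mirroring standard EWAS practice.

## Simulator

The generator draws exposure Bernoulli(prevalence), gives every individual
the full equally spaced age grid (balanced panel), and simulates each CpG
from the mixed model above.  Per replicate: 100 CpGs, of which 6 carry an
effect — one per scenario — at random positions; the remainder are null
(β01 = β11 = 0).  Scenario patterns:

| scenario | β01 | β10 | β11 | reading |
|---|---|---|---|---|
| i   | 0.02 | 0     | 0      | constant exposure effect, no age trend |
| ii  | 0    | 0     | 0.004  | diverging from a common baseline; unexposed flat |
| iii | 0    | 0.002 | 0.004  | diverging from a common baseline on an age trend |
| iv  | 0.02 | 0.002 | 0      | constant effect plus age trend |
| v   | 0.02 | 0.002 | 0.004  | baseline effect that diverges further |
| vi  | 0.02 | 0.002 | −0.00125 | baseline effect that converges (halved by age 18) |

Scenarios (ii) and (iii) differ only in the presence of the shared age
trend β10 — the one reading under which the two patterns are distinct.
Scenario (vi)'s interaction is constrained to the opposite sign of the
baseline effect and small enough that the gap does not cross zero within
the age span.

Default generative parameters: 464 individuals (the scale of the public
whole-blood smoking-methylation cohort the simulation design mirrors),
prevalence 0.5 (maximum power symmetry; a ~10% prevalence matching the
prenatal-smoking application can be configured), ages 10–18 with 5 repeats
(3 and 9 as secondary designs), sd(u0) = 0.035, sd(u1) = 0.008/yr,
corr(u0,u1) = −0.3, σ_e = 0.01, baseline means U(0.2, 0.8).  Effect sizes
(β01 = 0.02, β11 = 0.004) were chosen once so that baseline and
interaction Wald statistics sit in the 5–6 range at the default cohort
size — detectable but not saturated against the 1×10⁻⁷ threshold, and
standard errors (≈0.0033 for β01, ≈0.0008 for β11) of realistic magnitude
for methylation beta values.

Simulated values are Gaussian and **not** clipped to [0, 1] by default:
the generative model is the linear mixed model itself, and clipping would
induce exactly the kind of bias the recovery checks are meant to detect
(clipping is available as an option).  What the generator does *not*
emulate: probe-level array artifacts, batch effects, cell-composition
signal, heteroskedastic beta-value noise near the boundaries, missing
data, and age jitter.  Passing tests therefore demonstrate correctness of
the estimators under the stated generative model, not robustness to the
full messiness of array data.

Randomness: one master seed; the stream for replicate r is derived via
`SeedSequence(seed, spawn_key=(r,))`, so replicates are non-overlapping
and independent of generation order or parallel scheduling.

## Evaluation harness

Power per (strategy, scenario) is the fraction of replicates in which that
scenario's causal CpG is a hit.  Type I error pools the null CpGs across
replicates (denominator = 94 × replicates) — a per-test rate, not a
familywise one.  Relative bias is (β̂ − β)/β, reported as NA whenever the
true parameter is zero; summaries give mean, SD and the 2.5%/97.5%
quantiles (the quantile pair is a documented choice).  Per-replicate
failures are isolated and counted; a run aborts only if more than 10% of
replicates fail.

Problem sizes: the harness defaults to 100 replicates per configuration
(Monte-Carlo SE ≤ 0.05 on any power estimate), and the bundled acceptance
computations use 200 replicates for bias (MC SE on mean relative bias
≈ 0.015), 500 null-CpG fits for Type I calibration (MC SD 0.0097 at
α = 0.05), 60 replicates for the six-strategy power comparison and 150 for
the repeats comparison.  These sizes make every directional claim testable
at 3-MC-SD resolution; a full-scale study would simply raise
`n_replicates` to 1000.

## Known limitations

* Exposure is binary in v1; the code path accepts continuous exposures but
  none of the calibration claims have been checked for them.
* The cross-sectional and longitudinal models share one covariate set;
  time-point-specific nuisance adjustments (e.g. surrogate variables) are
  out of scope, as are normalization, QC and cell-type deconvolution.
* Random effects are limited to a two-level intercept(+slope) structure;
  no GEE working correlations other than independence, no non-Gaussian
  outcomes.
* Wald inference throughout; no small-sample df refinements, so inference
  with few clusters (m ≲ 50) should use the t option and caution.
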