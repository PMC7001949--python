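# Methods

`absrisk` estimates the probability that a healthy individual of age *a*
develops a disease of interest during the next *τ* years, in the presence of
competing mortality, and validates such models in independent studies. This
note records the model, the numerical choices, and what the synthetic-data
machinery does and does not emulate.

## The absolute-risk model

Disease incidence given a risk-factor profile *Z* follows a proportional
hazards model λ(t | Z) = λ₀(t) exp(βᵀZ), with *t* measured in years of age.
The absolute risk over [a, a+τ) is

    AR(a, τ; Z) = ∫ₐ^{a+τ} λ₀(t) e^{βᵀZ}
                  exp( −∫ₐ^t [ λ₀(u) e^{βᵀZ} + m(u) ] du ) dt,

where m(u) is the age-specific competing (all-cause) mortality rate, assumed
independent of *Z*. The three ingredients are supplied separately, so a model
can be re-targeted to a new population by swapping any one of them:

1. **Log relative risks β**, one per design column, typically published
   hazard ratios or (under a rare-disease approximation) odds ratios.
   Continuous covariates contribute one column; a K-level categorical
   contributes K−1 indicators against its first declared level; interactions
   are elementwise column products. Column order is deterministic
   (declaration order, main effects before interactions) so coefficient
   files are unambiguous.
2. **Marginal incidence rates λ_m(t)** from a registry, on single-year or
   coarser age strata, expanded piecewise-constant to integer ages (no
   smoothing — constancy is the minimal assumption for tabulated rates).
3. **A reference dataset** of complete covariate rows representative of the
   target population, defining the risk-factor distribution F(Z). Optional
   positive row weights are honoured in every expectation taken over the
   reference (calibration, imputation, reported reference risks).

## Baseline-hazard calibration

λ₀(t) is derived from λ_m(t) = λ₀(t) · E[e^{βᵀZ} | T ≥ t] by fixed-point
iteration. Iteration 0 uses the rare-disease approximation
λ₀(t) = λ_m(t) / mean_w[e^{βᵀZ_j}]; each subsequent pass re-weights reference
row *j* by its disease-free survival exp(−Σ_{u<t} λ₀(u) e^{βᵀz_j}) — disease
hazard only, matching the survivor distribution of the proportional-hazards
model — and recomputes λ₀. Iteration stops when the maximum relative change
over ages falls below `tol` (default 1e-4, configurable; default
`max_iter` 50, and the result reports which rule fired). The model gives no
canonical stopping rule; in practice convergence takes 2–4 passes because
the survivor correction is second-order for cumulative risks below ~20%.
With β = 0 the estimate equals λ_m exactly after one pass. Survivor
re-weighting accumulates from the first covered age of the rate table; rates
should therefore cover ages from well before the prediction window when the
disease is not rare.

## Discrete-age evaluation of the risk integral

Rates are tabulated per integer age, so both λ₀ and m are piecewise constant
on year-of-age intervals. Under that assumption the integral above has a
closed form per year: with h = λ₀(t) e^{βᵀZ} and c = h + m(t), the
probability of onset during year *t* for a subject event-free at its start
is (h/c)(1 − e^{−c}), and the event-free probability compounds by e^{−c}.
The default `method="exact"` sums these terms, which reproduces fine-grid
quadrature of the integral to numerical precision at any hazard level.

`method="riemann"` instead sums the integrand at integer ages (survival
factor exp of minus the cumulative sum over *earlier* ages, onset
probability h itself), a convention used by several registry-calibrated risk
calculators. Its relative error versus the exact integral is ≈ (h+m)/2 —
under 1% below roughly 0.02/yr total hazard, ~2% at 0.04/yr. We keep it as
an option for comparability with tools that use it; all defaults are
"exact". τ = 0 returns risk 0 by convention. Interval splitting
(`compute_absolute_risk_split_interval`) composes
risk = risk₁(a→c) + surv₁(a→c) · risk₂(c→a+τ), each part with its own β and
its own recalibrated λ₀; with identical parameter sets this reproduces the
single-interval result exactly because the exact per-year terms compose.

## Missing covariates: hot-deck imputation on the risk-score scale

Risk depends on *Z* only through R = βᵀZ, so missingness is handled
model-free on that scalar. The score is partitioned R = R_obs + R_unobs over
design columns; a column is observable iff every covariate it references —
including all interaction factors — is observed (an observed factor equal to
zero does not rescue an interaction column whose other factor is missing).
Reference scores are recomputed under the profile's own missing pattern
(masked to its observed columns), cut into `n_bins` = 100 equal-probability
weighted-quantile strata ("percentile strata"), and the profile is matched
to the stratum containing its observable score (ties at a cut-point go to
the lower bin; with degenerate references the match snaps to the nearest
populated bin, so a matched stratum is never empty). `n_imputations` = 5
donors (configurable) are drawn from the stratum with replacement, with
reference weights as sampling probabilities; each donor's unobservable score
component completes the profile and the reported risk averages the completed
risks. The reported linear predictor for an incomplete profile is the
weighted mean full score of all stratum members. A complete profile
short-circuits to the plug-in risk, independent of the seed. An all-missing
profile matches the whole reference and returns the population-average risk.
Masking the reference to the observed columns is the only reading under
which "similar" means similar on what is actually observed; it also makes
the all-missing case collapse correctly.

## SNPs from published summary statistics

Independent SNPs enter via their published per-allele odds ratio θ_k and
allele frequency f_k alone. Each SNP is one design column holding the dosage
G_k ∈ {0,1,2} with coefficient log θ_k, i.e. jointly a polygenic risk score
Σ_k log(θ_k) G_k assumed independent of the non-genetic covariates
(correlated-SNP modelling requires the general covariate path with a
genotyped reference). Reference genotypes are simulated under Hardy-Weinberg
equilibrium — `n_imputations` = 5 multiply-imputed genotype sets per
reference row, stacked with weights divided accordingly — conditioned on a
binary family-history (FH) indicator when the model declares one:
Pr(g | FH=1) ∝ θ^{g/2} · HWE(g), the rare-disease/Mendelian tilt. When SNPs
are added to a model whose FH coefficient was estimated without them, the FH
log odds ratio is attenuated by 0.5 Σ_k (log θ_k)² · 2f_k(1−f_k), the share
of heritability the SNPs explain; disable `apply_fh_attenuation` if the
supplied coefficient is already SNP-adjusted. A SNP-only model (no covariate
spec) simulates 10,000 internal reference profiles by default and, when
asked to predict without profiles, scores those profiles and reports their
mean — the population-average risk. A SNP appearing both as a declared
covariate and in the summary table is rejected as double counting. Missing
genotypes in prediction profiles flow through the risk-score imputation like
any other covariate, which is equivalent to averaging over the population
distribution of the missing SNPs given the observed ones.

## Validation

Subjects are cases if onset falls within min(τ, observed follow-up) of
entry; predicted risks use per-subject age_start = entry age and the same
horizon (τ = None validates over total follow-up). For nested case-control
designs every statistic is inverse-probability weighted by the sampling
probability π_i(Y_i, Z_i); when π was not recorded it can be estimated by
logistic regression of inclusion on outcome, entry age, follow-up and the
outcome interactions (`fit_selection_model`). Unit weights reproduce the
unweighted statistics exactly, and integer IPW weights reproduce
row-duplication for all point estimates.

* **Risk categories**: left-continuous inverse of the IPW-weighted empirical
  score distribution at c/C (default C = 10); ties go to the lower category.
* **Absolute-risk calibration**: HL = Σ_c (p̂_o,c − p̂_e,c)² / Var[p̂_o,c],
  referred to χ² with **C** degrees of freedom (the convention of the
  statistic's source, not the classical C−2), with
  Var[p̂_o,c] = (p_c(1−p_c) + Ê[(Y−p_c)²(1−π)/π | c]) / (IPW category mass)
  — binomial term plus a two-phase correction that vanishes in a full
  cohort. Var[p̂_e,c] is deliberately not included in the denominator. A
  category with zero variance but nonzero discrepancy raises rather than
  reporting an infinite statistic.
* **Relative-risk calibration**: category RRs against the overall IPW
  proportion (observed) and overall IPW mean predicted risk (expected);
  covariance by the delta method on the diagonal matrix of category
  absolute-risk variances, approximating the overall proportion by the mean
  over the equal-mass categories; the quadratic form drops the last category
  (the sum constraint makes the full matrix singular; which category to drop
  is arbitrary and documented) and is referred to χ² with C−1 df.
* **Discrimination**: δ̂ = IPW concordance Pr[R_case > R_control], ties 0.5,
  computed in O(n log n) from weighted placement values. Variance:
  Var ≈ (1/n₁) Ê_w[(P₁−δ)²/π₁] + (1/n₀) Ê_w[(P₀−δ)²/π₀], where P are the
  placement values, the /π factor combines the placement variance with the
  two-phase correction, and n₁, n₀ are the IPW-estimated cohort case and
  control counts. With all scores tied δ̂ = 0.5 is returned flagged
  degenerate.
* **Expected/observed ratio**: IPW sum of predicted over IPW sum of observed
  cases; CI is log-scale Wald with Var[log(E/O)] ≈ Var[p̂_o]/p̂_o², treating
  the expected count as fixed (no canonical construction exists; this is the
  standard choice and is documented as such).

The HL p-value does not adjust degrees of freedom for estimated sampling
weights (plug-in weights); this matches common practice and is a known
approximation.

## Synthetic data: what it emulates and what it does not

`simulate_cohort` draws onset ages from a Weibull-baseline Cox model,
Λ₀(t) = λ t^γ, by inverse transform T = (−log U / (λ e^{βᵀZ}))^{1/γ}, with
covariates resampled from a reference dataset (or independent declared
marginals via `simulate_reference`), genotypes under HWE conditional on FH,
integer entry ages discrete-uniform on 50–72 and follow-up discrete-uniform
on 5–13 years, defaults λ = 0.9e-6, γ = 2.15. Onset is continuous; entry and
exit are integers. Prevalent cases (onset ≤ entry) are excluded and redrawn,
because absolute risk conditions on being disease-free at the interval
start. Nested case-control selection is Bernoulli with logistic
probabilities in (intercept, outcome, entry, follow-up, outcome×entry,
outcome×follow-up), defaults (−6.52, 8.47, 0.05, 0.11, −0.09, 0.04): cases
are selected with probability ~0.5–0.9 (mean ≈ 0.75), controls below ~0.1.
The subsample carries its true selection probabilities so estimated weights
can be checked against an oracle.

Not emulated: covariate-dependent mortality, measurement error, informative
censoring, correlated SNPs or linkage disequilibrium, secular rate trends,
and delayed entry other than by age. Passing tests therefore demonstrate
internal statistical correctness of the estimators under a correctly
specified proportional-hazards world, not robustness to those features of
real data.

`weibull_yearly_baseline` exposes the per-age hazard whose yearly increments
equal the continuous Weibull cumulative hazard; a piecewise-constant model
built on it matches the generator's cumulative hazard exactly at integer
ages, which is what makes simulate-then-validate an exact self-consistency
check rather than an approximate one.

## Problem sizes and oracle design in the checks

* Quadrature: 54-point grid (βᵀz ∈ {−1,0,1}, λ₀ ∈ {1e-4, 1e-3, 1e-2},
  m ∈ {0, 0.01}, τ ∈ {5, 10, 30}) against Δt = 1e-3 midpoint integration.
* Baseline-hazard recovery: 1e6 simulated covariate rows. The oracle is
  Rao-Blackwellized — it computes the marginal rates implied exactly by the
  simulated covariate sample rather than drawing event indicators, because
  at any feasible sample size pure event noise (per-age relative SE ≈ 1.4%)
  would swamp the estimator error being measured (< 1e-6).
* Imputation: 2000 donor draws against exact stratum enumeration, 3
  Monte-Carlo-SE band.
* Variance validity: 2000 replicates of an n = 5000 two-phase draw with
  fixed population score quintiles and known true π, isolating the variance
  formulas from cut-point estimation noise; 10% agreement band.
* Self-consistency: 200 cohorts of n = 10,000. These runs use the Weibull
  shape γ = 2.15 with scale λ = 2e-5: at the printed default scale a cohort
  of this size yields only ~20 cases, too few for the χ² approximation that
  the check itself is testing, so the scaled-down condition raises the event
  rate to keep ~50 cases per decile. Checks: mean E/O within 3 SE of 1,
  HL rejection rate at α = 0.05 within 3 binomial SE of nominal, mean
  p-value within 3 SE of 0.5.

## Known limitations

* No uncertainty is attached to individual risk predictions (bootstrap over
  the β and the reference rows is possible in principle but not
  implemented, matching the scope of comparable risk tools).
* Competing mortality is covariate-independent.
* The imputation reports a single averaged risk, not between-imputation
  variability.
* Split-interval prediction matches donors on the first parameter set's
  observable score only.
* The selection-model fitter handles the standard outcome × (entry,
  follow-up) design; other selection mechanisms require user-supplied
  weights.
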