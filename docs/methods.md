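# Methods

This note documents the statistical procedure the package implements,
the choices made where the design was genuinely open, and the limits of
what the test suite demonstrates.

## Measurement-error model

Daily intake of a nearly-daily dietary component is modeled on a
transformed scale as

    g(r_ij; λ, c) = x_i'β + u_i + ε_ij,
    u_i ~ N(0, σ_u²),   ε_ij ~ N(0, σ_ε²),

with `g(r) = ((r + c)^λ − 1)/λ` for λ ∈ (0, 1] and `log(r + c)` at
λ = 0. The person-level deviation `u_i` carries between-person
variation in usual intake; `ε_ij` carries day-to-day variation, which
is the nuisance being removed.

**Transform selection.** λ is chosen by exhaustive evaluation of the
Box-Cox profile log-likelihood (including the Jacobian term) over the
grid {0.01, …, 1.00}. A grid keeps selection deterministic and
reproducible across replicate refits; the resolution (0.01) is far
below the scale at which downstream summaries respond to λ.

**Zero intakes.** The model requires positive values. Zero person-days
are accepted up to a 5% share (configurable), in which case an offset
of half the smallest positive intake is added before transforming.
Above the threshold the data look episodically consumed and are
rejected with guidance: an amount-only model cannot represent
consumption probability, and no offset choice fixes that.

**Estimation.** β, σ_u², σ_ε² are estimated by REML with the
random-intercept covariance inverted in closed form, profiling β out
at each variance evaluation, and a Nelder-Mead search over the log
variances (floored at e⁻⁵⁰, so boundary cases like zero within-person
variance are representable to numerical precision). A weighted one-way
ANOVA moment estimator provides the starting point and the fallback
when the optimizer fails; the fallback is surfaced via
`converged=False` and refits are refused downstream unless explicitly
overridden. Survey weights enter as person-level weights in the
likelihood — for β *and* the variance components — so point estimates
are design-consistent. Weighted model-based standard errors are not
attempted: all uncertainty comes from the replication module, which
makes the weighting question one of point-estimate consistency only.

**One-day mode.** With a single recall per person, σ_u² and σ_ε² are
not separately identified. Given an external ratio r = σ_ε²/σ_u², β is
fitted by weighted least squares and the total residual variance
σ_tot² is split as σ_u² = σ_tot²/(1+r), σ_ε² = σ_tot²·r/(1+r) — the
components always sum to σ_tot² exactly. Because the ratio is an
assumption, the CLI supports a ratio sweep and the error messages
insist on sensitivity analysis.

## Usual-intake simulation

Person *i*'s usual intake given their deviation u is the expectation
over days

    T_i(u) = E[ g⁻¹(x_i'β + u + ε) ],   ε ~ N(0, σ_ε²),

computed by Gauss-Hermite quadrature, default 9 nodes. The
pseudo-population draws m = 100 independent u per sampled person
(defaults; both configurable), giving n·m records each carrying
weight/m. Only u is imputed; ε is integrated out analytically, which
is precisely the correction for within-person variation.

Numerical details:

- When 1/λ is an integer the inverse transform is a polynomial and is
  evaluated globally, keeping the quadrature *exact* for the identity
  (λ=1, any node count) and quadratic (λ=0.5, ≥2 nodes) inverses. For
  fractional 1/λ, quadrature points below the transform's range have
  no real preimage and contribute zero intake. At λ=0, 9 nodes
  reproduce the lognormal day-average exp(b + σ_ε²/2) to well under
  0.1% for σ_ε ≤ 0.7.
- Per-person RNG streams are derived from the root seed plus a hash of
  the person id, so runs are bit-reproducible and removing persons
  never shifts the draws of the others.
- Weighted quantiles invert the weighted empirical CDF with linear
  interpolation between order statistics placed at (cum − w/2)/W; with
  equal weights this is the common midpoint convention ({1,2,3,4} at
  the median gives 2.5). Stated because conventions differ across
  software.

## Adequacy

**EAR cut-point.** Prevalence of inadequacy is the weighted share of
pseudo-persons with total intake strictly below their own
sex-/age-/status-specific EAR; excess is the share above the UL.
Reference values ship as editable CSV, not constants. Age intervals
are half-open (age_min, age_max], so a boundary age (e.g. 50 in an
"≤50 / >50" split) belongs to the younger group.

**Full probability.** When the requirement distribution is skewed (the
canonical case: iron in menstruating women) the cut-point method is
invalid; instead each pseudo-person contributes their probability of
inadequacy, 1 − F_req(a·y), averaged with weights. F_req is a
tabulated percentile table interpolated piecewise-linearly in the
requirement (a log-linear option exists), constant 0/1 outside the
table. The absorption fraction a (default 0.18, the mixed-diet
assumption behind recommended iron intakes) is applied to intake;
dividing the requirement quantiles by a instead would be equivalent —
do not do both. A point-mass table collapses the method to the
cut-point estimator exactly, which the tests exploit as an
equivalence oracle.

## Interventions

The temporal scope of a nutrient source dictates where it enters the
pipeline, and the package enforces this structurally rather than by
list order:

- **Fortification (add-then-shrink).** A fortified vehicle food
  changes what a recall would measure, so `intake += grams × level`
  is applied to recall records *before* fitting. When a person's
  vehicle consumption is constant across days, λ=1, and the
  consumption is included in the prediction function, this provably
  shifts that person's usual intake by exactly consumption × level
  (the addition is absorbed by the vehicle coefficient); the tests
  use this as an oracle.
- **Supplement programs and fixed additions (shrink-then-add).**
  Supplements and breast milk are longer-scope sources quantified
  outside the 24HR, so their contribution is added to the simulated
  usual intakes. Program assignment is an independent seeded Bernoulli
  per pseudo-person (dose × coverage in expectation), uncorrelated
  with food intake; an eligibility predicate supports targeted
  programs. Fixed additions map stratum- or person-level keys to
  amounts (e.g. regional breast-milk contributions). Each additive
  spec draws from a stream keyed by its label, so adding a scenario
  never perturbs another's draws, and shrink-then-add steps commute.

`total_intake = usual_food_intake + supplement_contribution` holds
exactly per record through any chain of additions.

## Replication

Every statistic (means, percentiles, prevalences — under every
scenario) gets an SE by re-running the entire pipeline per replicate:

- **BRR** for two-PSU-per-stratum designs: replicate weights multiply
  the base weight by (2 − F) / F per half-sample following Hadamard
  matrix columns (Sylvester construction, so replicate counts are
  powers of two ≥ #strata + 1); SE² = Σ_r (θ_r − θ₀)² / (R(1−F)²).
  Default F = 0.3, the convention for the national surveys this kind
  of analysis typically targets; F = 0 (full drop-out) is available.
  Pre-computed replicate weight columns (`repw_1..repw_R`) are used
  when present.
- **Bootstrap** for other designs: person-level resampling with
  replacement within strata, default R = 200; SE is the replicate
  standard deviation.

Replicate r re-runs with seed `root ⊕ r`, so random interventions are
redrawn per replicate and reruns are reproducible. Replicate failures
are logged and counted; more than 10% aborts the run with diagnostics
(a documented choice — silent degradation of the SE would be worse
than a loud failure). CIs are normal-approximation θ₀ ± 1.96·SE,
matching the mean ± SE reporting style of survey tables; no t
correction is attempted.

## Synthetic data

The generator simulates exactly under the model: transformed intake =
linear predictor + u + ε, plus survey apparatus — stratified two-PSU
designs, weights as inverse inclusion probabilities with log-uniform
dispersion (so weighted and unweighted estimates differ detectably),
a zero-inflated gamma vehicle food (both consumers and non-consumers),
and discrete-dose supplement usage (supplement amounts cluster on a
few dosages, as real questionnaire data do). Closed-form truths are
available for λ = 1 (usual intake Normal(β₀+1, σ_u²)) and λ = 0
(lognormal: mean exp(β₀ + σ_u²/2 + σ_ε²/2)).

Because the generator satisfies the model's assumptions by
construction, passing pipeline tests demonstrate that the estimation
machinery is correct — not that the model is right for real surveys.
In particular the generator has no systematic misreporting, no
intake-requirement correlation, no seasonal or sequence effects, and
symmetric Gaussian deviations on the transformed scale.

## Problem sizes used in the checks

Parameter-recovery and distribution checks run at 2000 persons × 2
recalls with m = 100 (closed-form agreement within 1% on means and
medians, 2 pp on prevalence); the lognormal mean check uses 20 000
persons so survey sampling noise sits well inside the 1% band; the
SE-calibration experiment compares BRR (16 strata, 32 replicates) and
bootstrap (R = 100) SEs against the empirical SD of the estimator
across 200 independently simulated surveys of 240 persons. These sizes
were chosen so each check's Monte-Carlo noise is small relative to the
tolerance it asserts.

## Known limitations

- Episodically consumed components (two-part models), multivariate
  nutrient models, and density/ratio estimands are out of scope.
- No individual-level usual-intake prediction: pseudo-persons impute
  the *population* distribution; they are not shrinkage estimates for
  specific people.
- The one-day mode inherits bias directly from a misspecified external
  variance ratio; only sensitivity analysis bounds it.
- BRR replicate counts are limited to Sylvester (power-of-two)
  Hadamard orders.
- Behavioral responses to interventions (substitution, changed
  consumption of the fortified vehicle) are not modeled.
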