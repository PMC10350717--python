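# Methods

## The projection model

`prevcast` projects the prevalence of binary health indicators from
repeated cross-sectional surveys by declaring future waves to be missing
data.  The combined table holds the observed waves (with their own item
and unit non-response) plus one fully missing pseudo-sample per projection
year.  All missing values — past non-response and future waves alike — are
filled by multiple imputation with chained equations (fully conditional
specification), and per-cell prevalences are pooled across the `m`
completed datasets with Rubin's rules.

The approach assumes:

* **MAR** — missingness depends only on observed quantities.  For the
  pseudo-samples this holds by construction (everything is missing, and
  the design margins are fixed); for observed-wave non-response it is an
  assumption, as in any imputation analysis.
* **Trend continuation** — the conditional models, with calendar year as a
  predictor, extrapolate the fitted time trends.  An abrupt shock in a
  future year is by definition unprojectable; the hold-out diagnostic
  makes that failure mode visible rather than hiding it.
* **Forecast margins are fixed** — uncertainty in the population forecast
  itself is not propagated.  Sampling variability of the observed surveys
  is likewise not resampled (no bootstrap layer); the reported intervals
  carry within- and between-imputation variance only.

## Pseudo-sample construction

Cell counts per (sex, age) are apportioned from the forecast by the
largest-remainder (Hamilton) method, cells ordered by (sex level order,
age), ties on remainders broken by the lowest index.  Margins therefore
match the forecast *exactly*; the alternative — multinomial sampling of
cells — would inject demographic noise into every projection and is
deliberately not used.  Pseudo-record ages are the integer years of the
forecast cells; age enters models as a continuous predictor.

Scenario projections (`apply_scenario`) overwrite one imputable variable
in a pseudo-sample with a constant or a draw from a stated distribution
before imputation, so the remaining variables are imputed *conditional on*
the scenario.

## Imputation models

* **Binary ("logreg"):** logistic regression fitted by IRLS with step
  halving.  A ridge penalty `r‖β‖²` (default `r = 1e-5`, intercept
  unpenalized, applied on internally standardized predictors) guards
  against separation in small waves; the penalty also makes the fit —
  and hence BIC — invariant to affine rescaling of predictors.
  Imputation is *proper*: β\* ~ MVN(β̂, V̂) with V̂ the inverse penalized
  observed information, then independent Bernoulli draws from
  logistic(Xβ\*).
* **Categorical ("polyreg"):** multinomial logistic regression refit on a
  bootstrap resample of the fitting records for each draw (resampling is
  retried up to 10 times until every observed level is present).  The
  bootstrap replaces a parametric posterior, which is harder to keep
  stable for multinomial fits; predictors are standardized internally for
  the L-BFGS solver.
* **Term language:** main effects, products of (dummy-coded) variables,
  and restricted cubic splines.  The spline uses the truncated-power
  basis with knots at the Harrell quantiles of the *distinct* observed
  values (0.10/0.50/0.90 for three knots), giving `df = k − 1` columns
  that are exactly linear beyond the boundary knots.  Knots are frozen
  from genuinely observed records before pseudo-waves are appended, so
  projection years always sit in the linear tail — the property that
  makes spline trends safe to extrapolate.
* **Model selection:** forward stepwise search minimizing
  BIC = k·ln(n) − 2·logL (unpenalized log-likelihood at the lightly
  penalized estimate; at `r = 1e-5` the discrepancy is far below one BIC
  unit).  A spline candidate *replaces* the linear term of its variable,
  so linear-vs-spline year enters the search as a head-to-head
  comparison.  The fitting set is available-case — observed outcome and
  complete candidate predictors — since selection precedes imputation.

## Engine

Defaults: `m = 50` datasets, `10` cycles.  Each dataset runs on an
independent substream spawned from the master seed (bit-for-bit
reproducible; datasets are independent chains).  Initialization fills
every missing cell uniformly from the variable's observed values.  Visit
order is ascending missing count (ties by schema order).  On each visit
the model is refit on records whose outcome was *originally observed*,
using current completed predictor values of all records, and every
originally missing cell is redrawn; originally observed cells are never
modified.  Per-iteration means and variances of the imputed values are
kept as chain traces for convergence inspection.

## Pooling

Prevalences are pooled on the proportion scale with Wald within-variance
q(1−q)/n, matching how such projections are usually displayed; a
logit-scale alternative was considered and rejected as the default
because the completed cells here are large and far from the boundary.
Degrees of freedom use Rubin's classical large-sample form (not the
small-sample Barnard–Rubin adjustment — completed pseudo-samples are
large).  With B = 0 the normal quantile replaces the t.  Intervals are
truncated to [0, 1] after computation.

## Synthetic data

The generator emulates the structure of five Finnish-style
health-examination waves: per-sex invited sample sizes
(5000/5000, 4999/5000, 4000/4000, 4000/4000, 1635/1542 for
1997/2002/2007/2012/2017), ages uniform on 25–64, five areas, three
education levels (age-dependent), binary marital status
(age-dependent), and binary indicators driven by logit-linear models in
sex, age (per decade, centered at 45), year (per decade, centered at
2007), optional year², a year×age product and covariate effects.  The
default indicator coefficients were chosen once to resemble the published
levels and trends (obesity ≈ 15→22% rising with a year×age interaction;
smoking falling with curvature; hypertension high, strongly age-graded,
slowly falling); they are shape parameters, not estimates.

Missingness is item-level and MAR by construction: masking probabilities
depend only on sex, age and year, via per-(sex, wave) probability tables
set to the published missingness percentages for the three indicators
(e.g. obesity, men, 1997: 32.1%) and a mild logit-linear rule for the
covariates.  Unit non-response is not separately modelled — a record with
all maskable cells missing and one with scattered item non-response are
treated identically downstream, which matches how the engine consumes
them.  What the generator does *not* reproduce: the real joint
distribution of the indicators, survey weighting, clustered sampling, or
any dependence of non-response on unobserved health.  Passing tests
therefore demonstrate that the machinery recovers known structure under
MAR, not that real-survey projections are unbiased.

Ground truth per (indicator, year, sex) is computed by exact enumeration
over the discrete covariate grid (integer ages × education × marital),
optionally reweighted by a forecast's age margin — this is the truth that
a forecast-matched pseudo-sample targets.  The population forecast is a
smooth Gaussian age pyramid (means 42/44 years by sex) with an optional
per-cell growth rule.

A small continuous layer (BMI, systolic/diastolic pressure, medication)
exists to exercise the clinical indicator definitions (BMI ≥ 30;
SBP ≥ 140 or DBP ≥ 90 or antihypertensive medication); the main fixture
draws indicators directly on the logit scale for speed.

## Numerical choices and degenerate inputs

* IRLS: start at β = 0, step halving on the penalized objective,
  convergence on max |gradient| < 1e-9, hard failure after 100 iterations
  (reported with the gradient norm and problem size).
* MVN draws use an eigendecomposition of the symmetrized covariance;
  eigenvalues below −1e-10 are an error, small negatives are clipped.
* One-level outcomes raise a degenerate-outcome error rather than
  fitting; a variable with no observed values at all cannot be
  initialized and stops the engine with a named error.
* Largest-remainder ties: lowest cell index wins (deterministic).
* Printed missingness percentages round half-up to one decimal.

## Test and acceptance problem sizes

The statistical acceptance suite runs at reduced scale, chosen as the
smallest sizes at which the checked effects are comfortably powered:
MCAR unbiasedness at n = 4000, 50% missing, m = 10, 50 seeded runs;
projection coverage at 100 replicates of 5 × 1000-per-wave surveys with
m = 10 and 5 cycles (coverage counted per replicate × horizon × sex cell,
threshold 85%); BIC recovery at n = 5000 with 100 replicates per
scenario; the level-shift negative control at 30 replicates of
800-per-wave surveys.  The acceptance script runs the full pipeline at
one fifth of the published wave sizes with m = 10 and 5 cycles, plus a
full-size generation pass for the structural quantities (wave sizes,
missingness calibration).

## Known limitations

* No survey design weights, stratification or clustering.
* Forecast uncertainty and sampling variability are not propagated.
* Only parametric imputers are provided, on purpose: non-parametric
  imputers (e.g. random forests) cannot extrapolate beyond the observed
  range of `year` and are unsuitable for projection.
* No joint-model (multivariate normal) imputation and no passive
  imputation of derived variables.
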