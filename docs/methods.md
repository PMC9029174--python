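# Methods

`pippk` implements a population pharmacokinetic analysis of piperacillin
in critically ill adults end-to-end: structural modelling, nonparametric
population estimation, Bayesian individual posteriors, internal and
external model evaluation, and Monte Carlo dosing simulation. This note
records the model, the numerical choices, and what the synthetic-data
machinery does and does not establish.

## Structural model

Drug amounts follow a linear two-compartment system with zero-order
(constant-rate) infusion input into, and first-order elimination from,
the central compartment:

    dA1/dt = R(t) - (ke + KCP) A1 + KPC A2
    dA2/dt = KCP A1 - KPC A2,            ke = CL / V

with concentration C = A1 / V (total drug, mg/L). Parameters: clearance
CL (L/h), central volume V (L), and distribution rate constants KCP, KPC
(1/h); KCP = KPC = 0 degenerates to one compartment. Units are hours,
mg, L and mg/L throughout; a bolus is a zero-duration dose.

Profiles are evaluated in closed form, segment by segment, through the
spectral decomposition of the 2x2 rate matrix (hybrid rate constants
alpha, beta are its eigenvalue magnitudes). The propagator uses
`expm1`-based integrals so the beta -> 0 (one-compartment, KPC = 0)
limit is exact, and a Jordan-form branch covers the measure-zero
repeated-eigenvalue case. The closed form is the primary evaluator
because Monte Carlo dosing simulation needs 1e5-1e6 profile evaluations;
an adaptive Runge-Kutta integration of the mass-balance system is kept
solely as an independent cross-check (agreement < 1e-6 relative is part
of the test suite).

Steady state over a dosing interval is obtained from the periodic
fixed point of the one-interval affine state map, solved in closed form
(2x2 linear solve); an explicit run-in (default 40 doses, configurable)
is the fallback when that solve is ill-conditioned, and a long run-in is
the oracle used to validate the fixed point in tests. Note that a
40-dose run-in itself carries O(e^{-beta * 40 tau}) residual when the
peripheral compartment is deep (beta around 0.016/h for the reference
parameters), which is why validation uses a 250-dose run-in.

## Covariate model and calculators

The final clearance model is the renal link CL = TVCL * (CRCL / 60),
with CRCL the creatinine clearance normalised to 1.73 m2 body surface
area and TVCL the typical clearance at the 60 mL/min/1.73 m2 reference.
Cockcroft-Gault is computed on total body weight (configurable
convention; the source study does not state which weight it used), BSA
normalisation uses DuBois-DuBois, and CKD-EPI is the 2009 two-level
creatinine equation without a race coefficient (race adjustments derived
in North American cohorts are not applicable here). Covariate screening
fits linear, logarithmic, power and quadratic regressions per
(parameter, covariate) pair, plus group-mean models for categorical
covariates, ranked by R^2 on the original scale.

## Residual error model

Observation SD is polynomial in concentration, SD_poly = C0 + C1*C,
inflated multiplicatively (gamma * SD_poly) or additively
(sqrt(SD_poly^2 + lambda^2)). The reference model is gamma = 5 with
C0 = 1, C1 = 0.1, i.e. SD = 5 * (1 + 0.1 C) mg/L — around 50% CV at
100 mg/L. Observation likelihoods are Gaussian on untransformed
concentrations with SD evaluated at the predicted concentration.
Observations below the 2.5 mg/L assay limit are used as-is when
positive; there is no below-quantification censoring model.

## Nonparametric population estimation

The population model is a discrete mixing distribution: support points
theta_j in a bounded box (defaults TVCL 0.3-15 L/h, V 2-50 L, KCP/KPC
1e-3-5 /h, spanning the reference moments +/- 3 SD and literature
ranges) with probability weights w_j. For a fixed grid the mixture
log-likelihood sum_i log sum_j w_j L_ij is concave in w and is maximised
by multiplicative EM updates (monotone by construction; convergence at
relative change < 1e-8, iteration caps of 500 within refinement cycles
and 2000 for final solves). The grid itself adapts:

1. initialise with a scrambled Sobol grid of 20 * 2^d points in the box;
2. each cycle: prune weights below 1e-8 of the maximum (keeping the 20
   best-likelihood points alive regardless, so several basins survive
   EM's concentration), then add +/-delta-per-axis perturbations around
   all survivors and full diagonal perturbations around the 12
   highest-weight points;
3. delta follows a pattern-search schedule: doubled (up to the initial
   20% of each axis range) while a cycle improves the likelihood,
   halved when it does not, converged when the minimum radius (0.1% of
   range) stops paying;
4. after the cycle loop, the highest-weight support points are polished
   by Nelder-Mead on the mixture objective with the other points held
   fixed, and the weights re-solved.

Steps 2-4 depart from a plain halving schedule because axis-aligned
moves with a monotone shrinking radius stall on the curved TVCL-KPC
likelihood ridge this model exhibits; with the polish step the fit
recovers a noise-free single-point population to within the grid
tolerance. A reported -2LL sequence is non-increasing across cycles (a
cycle that fails to improve keeps the previous solution), and the whole
fit is deterministic given its seed. AIC/BIC use p = number of
structural parameters per support point plus estimated error parameters;
the support-point count is deliberately not penalised (documented
convention). Reported parameter summaries (mean, SD, median, CV% =
100*SD/mean) are weighted moments of the fitted discrete distribution.

`npag_fit(..., restarts=n)` repeats the whole fit from n different
initial grids (seeds derived deterministically from the configured seed)
and keeps the highest-likelihood solution; the parameter-recovery tests
use 3 restarts.

## Bayesian posteriors and predictions

Each subject's posterior over the population support points is
prior-weight times subject likelihood, normalised (computed in the log
domain with max-subtraction; likelihood magnitudes below e^-700 are
safe). "Population predicted" is the prior-weighted mean prediction,
"individual predicted" the posterior-weighted mean (posterior-mode
prediction is available behind an option). External validation applies
the fitted distribution unchanged as prior; the covariate link
recomputes each external subject's clearance from their own CRCL.

## Model evaluation

* Observed-vs-predicted OLS with t-based slope CI; weighted
  prediction-error bias (mean of (obs - pred)/SD(pred)) and imprecision
  (variance of weighted errors — the "(SD * wpe)^2" phrasing in the
  source is ambiguous and is implemented as this variance).
* VPC: parameters resampled from the fitted distribution per subject
  per replicate, residual noise added (negative draws truncated at 0);
  each observation is compared with the 5th-95th percentile band of its
  own n_sim replicates, coverage ~0.90 expected under a correct model;
  plotted bands pool replicates by nominal time (sparse designs need no
  smoothing).
* NPDE: rank-based prediction-distribution errors, mid-rank tie
  convention, clipped to [1/(2n_sim), 1 - 1/(2n_sim)], probit
  transformed; mean, variance and a Shapiro-Wilk statistic summarise.
  No within-subject decorrelation step is applied — with 1-3
  observations per subject the whitening matrix is barely estimable, so
  the simple pde is computed (documented simplification).
* Bland-Altman: differences as percent of the pair mean
  (100*(obs-pred)/((obs+pred)/2); the exact denominator is unstated in
  the source, so pair-mean was chosen and absolute mode is available);
  limits of agreement are bias +/- 1.96 sample SD.
* External validation: prediction error = observed - predicted (the
  sign convention that makes "observations below predictions" a
  negative bias); MPE with normal-approximation 95% CI; RMSPE with the
  CI built on the mean squared error and square-rooted (lower endpoint
  clamped at 0). The 20% bias acceptance rule is evaluated relative to
  the mean observed concentration of the evaluated subset — the source
  never states the denominator, so this choice is explicit and
  configurable. A <100 mg/L subset reproduces the qualitative pattern
  that precision improves inside the developing assay's range.

## Dosing simulation

PTA: n_sim parameter sets are sampled either by weighted resampling of a
fitted discrete distribution or, in "moments mode", from independent
log-normals matched to the published mean/SD per parameter (the
published support points are unavailable, so moments mode lets dosing
simulations run without a fit); CL = TVCL * (CRCL/60) is applied per
draw at the scenario's renal function (30/60/90/130 mL/min/1.73 m2
conventionally). One steady-state interval is simulated per draw and
fT>MIC — the fraction of the interval with unbound concentration
(fu = 0.70, i.e. 30% protein binding, identical for all subjects)
strictly above the MIC — is computed by bracketing threshold crossings
on a scan grid along the piecewise-exponential segments and refining
each crossing by bisection to 1e-6 h (a 1e-4 h brute-force grid is the
test oracle). Ties at the threshold count as failure (conservative;
measure-zero under continuous kinetics). PTA(MIC) is the fraction of
draws attaining the target fraction (0.5 or 1.0 of the interval); FTA
averages PTA over an isolate-frequency MIC distribution restricted to
MIC <= the clinical breakpoint (16 mg/L for P. aeruginosa), with >= 85%
deemed optimal. The bundled `synthetic_eucast_like_pa` distribution is
an invented wild-type-shaped stand-in (live surveillance distributions
are version-dependent and not redistributable); FTA behaviour is
therefore validated as orderings (monotone in renal function, q6h >=
q8h at equal dose, 100% target <= 50% target) rather than as absolute
percentages. Body-size scenario labels are accepted but do not alter
kinetics: the final model carries no body-size covariate.

## Synthetic data

The generator is the package's stand-in for the undeposited clinical
datasets. The default design: 24 subjects; regimen menu 4 g q8h / 2 g
q6h / 3.3 g q4h with 0.5-h infusions, assigned 50/25/25% (the menu is
published, the mix is not; this is the package's choice); sampling at
steady state (day-5 context, realised as closed-form periodic initial
conditions rather than simulating five literal days — equivalent under
time-invariant parameters) at pre-dose, 1 h and 3 h, with 1-3 samples
per subject weighted (0.25, 0.5, 0.25); covariates log-normal matched
to the published median/IQR (CrCL median 60, IQR 47-83; age 72,
57-78 y; weight 69, 57-77 kg; BMI 22, 21-31 — height derived from
weight and BMI), sex 38% male; serum creatinine back-calculated from
the drawn CrCL through Cockcroft-Gault so the covariate set is
internally consistent (a fully correlated mode deriving CrCL from drawn
age/weight/SCr is available); structural parameters log-normal matched
by moments to TVCL 3.33 (1.24), V 10.69 (4.50), KCP 1.15 (0.15),
KPC 0.08 (0.09); residual noise SD = 5(1 + 0.1 C) with negative draws
resampled (counted and reported). Log-normal marginals are a choice —
the source reports no distributional forms — motivated by positivity
and standard PK practice; covariates are mutually independent by
default because only marginals are published.

External-style cohorts: `rich_q6h` (20 subjects, 4 g q6h, 20-min
infusion, 6 samples at pre-dose, end of infusion, 0.67, 1, 3.5, 6 h)
and `rich_tds` (10 subjects, 4 g q8h, per-subject infusion duration
uniform 0.5-1 h, 20 evenly spaced samples across two intervals), drawn
by default from a high-renal-function population (CrCL median 107, IQR
92-122) to emulate higher-clearance external cohorts.

The recovery ("rich") design used by the parameter-recovery tests is 50
subjects on 4 g q8h with 10 samples across the interval, half sampled
after the first dose and half at steady state: a single-interval
steady-state design is nearly non-identifiable along a TVCL-KPC ridge
(two parameter vectors can agree within ~1e-4 mg/L over one interval),
while first-dose data alone barely express clearance; the mixed design
makes CL and V jointly identifiable.

What passing tests show — and what they do not: the synthetic cohorts
share the published design, covariate marginals, parameter moments and
error model, but real data add model misspecification, within-day renal
drift, censoring below the assay limit, irregular dose timing and
correlated covariates, none of which are emulated. Recovery and
calibration results therefore validate the estimation machinery under
the stated statistical structure, not clinical performance.

## Known limitations and numerical notes

* Under the reference error model (about 50% CV at typical peak
  concentrations) the maximum-likelihood mixing distribution is
  systematically over-dispersed in finite samples: fitted SDs exceed
  the generating SDs and the fitted *mean* clearance runs a few to
  ~15% high even though the median tracks the truth closely. This is a
  property of the estimand (the over-dispersed solution genuinely has
  higher likelihood than the truth-supported one), not of the search;
  heavier optimisation does not remove it, and at moderate noise
  (gamma around 2) it largely disappears.
* Problem sizes in the test suite (cohorts of 24-50 subjects, 300-1000
  Monte Carlo replicates, 20-seed recovery studies with 3 restarts)
  are chosen to exercise every claim at desk scale.
* Nominal infusion durations are treated as exact; the source notes
  infusions were timed only approximately.
* Degenerate inputs: duplicate dose start times are rejected as
  ambiguous; overlapping infusions otherwise superpose; observations
  exactly at a bolus time take the pre-dose value; concentrations are
  clipped at zero after floating-point round-off.
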