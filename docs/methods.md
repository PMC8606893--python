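# Methods

## Structural and statistical model

Concentrations follow a one-compartment model with first-order absorption
and elimination after oral dosing. For a dose D (mg) given at time 0 the
analytic (Bateman) solution is

    C(t) = D·Ka / (V·(Ka − ke)) · (e^(−ke·t) − e^(−Ka·t)),   ke = CL/V,

evaluated in mg/L internally and scaled ×1000 to ng/ml, the unit of the
5–15 ng/ml TDM window. Multiple doses superpose linearly; steady state
uses the closed-form geometric accumulation rather than long explicit
superposition (equivalent by linearity, and exact — verified against an
independent ODE integration in the test suite). The flip-flop degeneracy
Ka = ke is handled by the analytic limit (D/V)·Ka·t·e^(−Ka·t), never by
division by zero. Bioavailability F is folded into the apparent parameters
CL/F and V/F throughout; there is no lag time.

Population structure: typical values scale allometrically with body weight
around a 70 kg standard (exponent 0.75 on CL/F, 1 on V/F). Inter-individual
variability is a lognormal factor e^η on CL/F only — V/F and Ka carry no
random effect, matching the estimability of sparse trough-dominated TDM
data. Residual error is additive in ng/ml, representing assay noise (the
immunoassay's linear range is 3.5–30 ng/ml). Optional covariate relations
take the power form TV·(cov/median)^θ for continuous covariates and TV·θ^cov
for binary ones; each contributes exactly one estimated θ (1 df).

The shipped published parameter set (`siropk/models/…yaml`, loadable via
`published_model()`) is θ_CL = 11.3 L/h/70 kg, θ_V = 388 L/70 kg,
Ka = 0.485 h⁻¹ fixed, ω = 0.303, σ = 3.578 ng/ml. The reported ω value is
interpreted as the **SD of η** (≈30% CV on clearance — typical for
sirolimus); interpreting it as a variance would imply ≈59% CV, which is
inconsistent with the attainment probabilities the model is meant to
produce. A loader switch (`omega_is_variance=True`) implements the
alternative reading.

## Estimation (FOCE-I)

The inner problem finds each subject's empirical Bayes η̂ by minimising the
penalised objective Σ_j (y_j − f_j(η))²/σ² + η²/ω², using a safeguarded
Gauss–Newton iteration (backtracking line search, step clamp, start at 0 —
the objective is unimodal for this model class), vectorised across
subjects. The outer objective linearises f in η at η̂:

    G_i = ∂f_i/∂η |_{η̂},  C_i = G_i ω² G_iᵀ + σ² I,
    r_i = y_i − f_i(η̂_i) + G_i η̂_i,
    OFV = Σ_i [ log det C_i + r_iᵀ C_i⁻¹ r_i ],

computed with rank-1 determinant/Sherman–Morrison identities. The N·log 2π
constant is excluded by default (NONMEM convention; it cancels from every
ΔOFV comparison) and switchable. With a purely additive residual the
η-dependence of the residual covariance vanishes, so FOCE-I coincides with
FOCE; the linearisation is written generally. The test suite checks the
OFV against an adaptive-quadrature −2 log marginal likelihood on small
instances (agreement ≲0.2 units, tolerance 0.5).

Fixed effects, ω and σ are optimised by Nelder–Mead on a log-transformed
parameter vector (power-covariate θs enter untransformed; categorical θs on
the log scale); Ka stays fixed. Relative standard errors come from a
central finite-difference Hessian of the OFV at the optimum (relative step
1e-4; covariance 2·H⁻¹), omitted if the Hessian is not positive definite.
Initial estimates are taken from the ModelSpec passed to `fit_model`, as in
NONMEM control streams.

Stepwise covariate selection runs forward inclusion then backward
elimination with ΔOFV thresholds computed from the χ²(1 df) quantile
function at p = 0.05 (3.84) and p = 0.01 (6.63), applied iteratively
(standard practice; a candidate is re-evaluated against each enlarged
model). Forward ties break deterministically on declared candidate order;
every ΔOFV is logged.

Observations below the 3.5 ng/ml quantitation limit are flagged BQL and
**excluded from fitting** (discard handling — the simplest defensible
default for sparse TDM data; a likelihood-based BQL treatment is out of
scope). This matters quantitatively: see "Synthetic data" below.

## Diagnostics

CWRES uses the same conditional linearisation: CWRES_i =
C_i^(−1/2)(y_i − E_i) with E_i = f_i(η̂_i) − G_i η̂_i, computed via the
rank-1 inverse square root; under a correct model it is approximately
standard normal (checked by self-simulation at ≥500 observations:
|mean| < 0.1, |var − 1| < 0.2). The goodness-of-fit table exports
observed/population/individual predictions, CWRES and Blom normal
quantiles — the numeric content of the usual GOF panels; rendered plots
are deliberately not part of the tested surface.

The bootstrap resamples subjects with replacement to the original cohort
size (default 1,000 replicates), refits each replicate starting from the
full-data estimates, drops non-converged replicates (counted), and reports
2.5/97.5 percentile intervals.

The pc-VPC corrects each observed and simulated concentration by
(bin median population prediction)/(own population prediction) — a factor
invariant to dose rescaling — using quantile time bins (default 6, equal
observation counts; bins with <2 observations merge with a neighbour).
Observed 2.5/50/97.5 percentiles are compared with the 95% envelope of the
same statistic across simulated replicates (default 1,000; 200 in the
scaled-down test runs), plus the typical predicted interquartile band.

## Dose simulation and recommendation

Virtual patients draw η ~ N(0, ω²) on clearance; the mg/kg/day dose is
split into two administrations 12 h apart and the exposure metric is the
**model-predicted steady-state trough without residual error** — TDM
targets are trough-based and the additive residual represents assay noise,
not true exposure. `include_residual=True` implements the alternative; the
choice moves the headline attainment probabilities by several points, so it
is logged on every pipeline run. The default grid is the study design:
7 weights (5–60 kg) × 10 doses (0.01–0.10 mg/kg/day) × 1,000 virtual
patients, seed-reproducible (cell seeds spawn deterministically from the
grid seed).

Because the trough is monotone decreasing in η, in-window and exceedance
probabilities also have an exact closed form (normal CDF at the η roots of
trough = 5 and trough = 15, located by Brent bisection); the Monte Carlo
and analytic routes agree to MC error and cross-validate each other in the
tests.

Recommendation: per simulated weight the dose maximising in-window
probability wins, ties going to the lower dose (safety). Consecutive
weights sharing a best dose merge into bands. Interior band boundaries are
**not** grid midpoints: they are placed at the crossover weight where the
two adjacent doses' analytic in-window probabilities are equal (bisection,
reported to 0.1 kg). This crossover rule is this package's reconstruction
of how a published band edge can fall between simulated weights, and the
output labels it as such.

Known discrepancy: with this metric and the published parameters, the
in-window probability at 0.07 mg/kg/day is ≈81.5% at 5 kg and ≈86.2% at
10 kg, a few points below the published 85.2–89.4 band, and the per-weight
best doses shift by one 0.01 mg/kg/day step at the extremes of the weight
range. The source simulation's exact exposure metric (sampling time,
residual handling, steady-state definition) is not stated; the trough's
log-sensitivity to η here is ≈1.3, and a metric with unit sensitivity
would be needed to reproduce the published probabilities. The 0.06→0.05
crossover lands at 25.0 kg, close to the published 24.5 kg band edge,
supporting the overall reconstruction. The acceptance suite keeps the
published bound as-is and reports the computed value honestly.

## Synthetic data

The generator emulates a 15-subject pediatric TDM cohort: weights uniform
on 4–54 kg by default (a truncated normal 22.3 ± 9.9 kg is available),
twice-daily dosing at a per-subject rate drawn from 0.03–0.08 mg/kg/day,
and two sampling designs — `trough-sparse` (default; 3–6 pre-dose samples
spread over four weeks, the realistic TDM schedule; 4 samples by default)
and `rich` (6 samples across one dosing interval at two weeks plus 3
troughs, needed because V/F is weakly identifiable from troughs alone).
Simulated concentrations below 3.5 ng/ml (including any negatives produced
by the additive error) are flagged BQL and carry the limit value. Extra
covariates (age, albumin, creatinine, hematocrit) are drawn from plausible
pediatric distributions purely as distractors for covariate-selection
tests; by construction they do not affect concentrations.

What passing tests show — and don't: the generator reproduces the
*assumed* statistical structure (lognormal clearance IIV, additive noise,
assay censoring), so recovery and calibration results demonstrate the
estimator and diagnostics are correct under the model, not that the model
describes any real cohort; real TDM data add adherence lapses, dose
titration, intra-individual variability and model misspecification that
are out of scope here.

Censoring interacts with the discard BQL policy: at 0.05 mg/kg/day about
9% of rich-design observations fall below the quantitation limit, and
discarding them biases CL/F downward by ≈8% and ω by ≈20% (the estimator
itself is nearly unbiased: ≈−3% CL, ≈+1% ω when dosing keeps
concentrations inside the assay range). The estimator-bias property test
therefore runs at 0.08 mg/kg/day (≈2% censored), while the headline
parameter-recovery experiment keeps 0.05 mg/kg/day and simply absorbs the
censoring bias inside its 15%/25% tolerances.

## Problem sizes and numerical choices

Recovery experiments use 200 subjects × 9 observations × 5 replicate
seeds; the estimator-bias property uses 100 subjects × 5 replicates;
CWRES calibration uses ≈530 observations; pc-VPC self-consistency uses 20
seeds × 200 simulations; bootstrap tests use 8–10 replicates on 30–50
subjects. These sizes keep a full run in minutes on one CPU while leaving
Monte Carlo error well inside the asserted tolerances. Inner Newton
tolerance 1e-8 on η (|η| clamped at 8); ∂f/∂η by central differences
(step 1e-5); outer Nelder–Mead xatol/fatol 1e-4 with adaptive simplex;
seeds everywhere derive from a single master seed via `SeedSequence`.

## Limitations

- Single compartment, linear elimination, no lag or transit absorption;
  no inter-occasion variability, no mixture models.
- BQL handling is discard-only; no M3-style censored likelihood.
- CYP3A4/CYP3A5 genotype effects are deliberately not modelled.
- The bootstrap does not re-run covariate selection per replicate.
- Dose recommendations are initial-dose only; TDM-based adaptation after
  the first measurement is out of scope.
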