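# Methods

This note records the modelling assumptions, numerical choices and
known limitations of `digoxinpk`. It documents *how* results are
computed; every empirical number quoted here is recomputed by the test
suite or by `scripts/acceptance.py`.

## Structural and statistical model

One-compartment disposition with first-order absorption, parameterised
by apparent oral clearance CL/F (L/h), apparent volume Vd/F (L) and
absorption rate constant k_a (h⁻¹). Bioavailability F is never a
separate parameter: trough-only data cannot identify it, so all
clearances and volumes are apparent quantities. k_a is fixed at
1.0 h⁻¹ and Vd/F at 6.0 L/kg body weight — at steady state the trough
is driven almost entirely by CL/F, so neither is estimable from (or
influential on) trough data, but both are needed to evaluate the
closed-form prediction.

All observations are treated as steady-state samples (dosing histories
in the target population are months long against a digoxin half-life of
1.5–2 days). The steady-state concentration is evaluated by multiple-
dose superposition at the recorded time after the last dose (6–24 h);
when no time is recorded the trough proper, t = τ, is used. Near the
removable singularity k_a = k_e the analytic limit expression replaces
the generic formula (unreachable with k_a = 1 and digoxin-like k_e
≈ 0.02 h⁻¹, but it must not produce NaNs on exotic inputs).

Interindividual variability is an exponential (lognormal) random effect
on CL/F with SD ω, reported in percent as 100·ω. Residual error is
either additive (SD σ ng/mL) or multiplicative (proportional, SD σ);
the multiplicative likelihood reads y | η ~ N(f, (σ·f)²), the standard
proportional-error interpretation, with f > 0 guaranteed because
below-quantification rows never enter estimation.

Covariate effects on clearance are multiplicative: power terms
`(value/reference)^θ` for continuous covariates, `1 + θ·flag` for
categorical ones. Creatinine clearance is normalised to 60 mL/min (the
convention of the published final model); other continuous covariates
are normalised to their dataset median rounded to two significant
figures. Cockcroft–Gault uses actual body weight (no obesity
adjustment is attempted; the data to justify one do not exist here) and
is capped at 120 mL/min to avoid extrapolating renal drug clearance
into the hyperfiltration range.

## Estimation

The marginal likelihood integrates the scalar random effect per
patient. Because the integral is one-dimensional, adaptive
Gauss–Hermite quadrature is both cheap and near-exact: the integrand is
re-centred at the conditional mode η̂_i (found by a damped, vectorised
Newton iteration with finite-difference derivatives) and scaled by the
curvature there. 21 nodes is the default; on the test fixtures the OFV
changes by < 1e−6 when the node count is doubled, so quadrature error
is negligible against optimiser tolerance. The Laplace approximation
(the same mode and curvature without quadrature refinement) is the fast
option and typically sits within ~0.01 OFV units per patient of the
quadrature value. ω = 0 is handled as the degenerate fixed-effects
likelihood. The original analysis used a FOCE-family algorithm in a
commercial tool; absolute OFV values are therefore not comparable
across implementations, only OFV *differences* and the resulting
estimates and decisions.

Optimisation is L-BFGS-B over log(tvCL/F), raw covariate coefficients,
log ω and log σ, with finite-difference gradients (step 1e−6) and an
OFV tolerance of ~1e−9; per-patient modes are warm-started between
objective evaluations. Parameter points that violate model validity
(e.g. a proportional-effect multiplier ≤ 0, probed occasionally on
small bootstrap replicates) are penalised rather than raised, so the
optimiser backs off instead of crashing. Starting values: tvCL/F from
the naive pooled estimate (mean dose rate / mean trough), ω = σ = 0.3,
coefficients 0. Two starts ±50 % apart reach OFVs within 0.1 on the
test datasets.

Standard errors come from the central finite-difference Hessian of the
marginal −log L on the transformed scale, mapped to the natural scale
by the delta method; RSE% = 100·SE/|estimate|. A non-positive-definite
Hessian marks SEs unavailable rather than reporting garbage. Empirical
Bayes estimates are the conditional modes; a patient with no usable
observations gets η̂ = 0 (full shrinkage, logged).

## Covariate selection

Forward selection only, mirroring the original procedure: all eight
candidates (sex, age, BMI, CL_CR, eGFR, amiodarone, diltiazem,
verapamil) are tried one at a time on top of the current model; the
largest OFV drop enters if it reaches 3.84 (χ²₁ at α = 0.05, applied
inclusively — a drop of exactly 3.84 counts). CL_CR and eGFR are
declared collinear: when one enters, the other is blocked from all
later steps (they measure the same physiology; admitting both produces
an unstable, clinically uninterpretable pair), with exact ties broken
in favour of CL_CR, which is not indexed to body surface area and
tracks individual drug clearance more directly. No backward-elimination
pass is implemented (none was used originally); the hook is the
`threshold`/`candidates` configuration.

**Multiplicity caveat.** Each candidate is tested at the 5 % level, so
on covariate-free data the chance that *some* candidate enters is
roughly 1 − 0.95^k with k ≈ 5–6 effectively independent candidates
(CL_CR/eGFR and the demographic covariates are mutually correlated),
i.e. a ~25 % family-wise false-inclusion rate per dataset. Observed
false inclusions on null synthetic data behave accordingly (about 3 in
10 datasets admit one or two spurious covariates, most often BMI).
This is a property of the per-candidate-threshold procedure itself, not
of the implementation; a stricter second-stage α or backward pass would
reduce it but would no longer be the procedure being reproduced.

## Diagnostics and bootstrap

PRED is the population prediction (η = 0), IPRED the prediction at η̂.
CWRES uses the first-order conditional linearisation around η̂ (the de
facto standard): y_i ~ N(f_i(η̂) − G_i·η̂, G_i ω² G_iᵀ + H_i), with
G_i = ∂f_i/∂η at η̂ (numeric, central differences) and H_i the residual
covariance evaluated at IPRED (σ²·IPRED² for the multiplicative model).
The residual vector is decorrelated with the Cholesky factor of that
covariance. On correctly specified study-scale synthetic data CWRES is
calibrated to mean ≈ 0, SD ≈ 1 with ≥ 93 % of values within ±2.

The bootstrap resamples *patients* with replacement to the original
patient count (all of a patient's observations travel together;
observation totals therefore vary per replicate), refits the fixed
final-model structure warm-started at the original estimates, and
summarises converged replicates by mean and 2.5/97.5 percentiles.
"Success" is optimiser convergence; finite SEs are not required (SEs
are not computed in replicates at all). Resampling is unstratified —
whether the original bootstrap stratified by e.g. amiodarone use is
unknown, and at 16 % prevalence unstratified replicates essentially
always retain both strata.

## Dosing simulation

Each scenario (daily dose 250/125/62.5 µg × CL_CR 90/60/30 mL/min ×
amiodarone yes/no) draws η per iteration, evaluates the closed-form
trough at τ = 24 h, and by default applies a multiplicative residual
draw on top, so the simulated quantity is an *observed* trough — the
scale on which the 0.9 and 1.2 ng/mL risk thresholds are defined and
measured in practice. This default was chosen because the IIV-only
distribution visibly understates the published exceedance table's
spread (deviations up to ~12 percentage points, worst in the mid-range
cells), while including the residual reproduces all 36 cells to within
~2 percentage points; the IIV-only view remains available via
`include_residual=False` for sensitivity analysis. Residual draws are
truncated at ε > −1 (resampled) so concentrations stay positive — a
< 0.4 % tail at σ = 36.6 %.

Body weight is fixed at the cohort mean 57 kg (configurable); at steady
state the trough depends on weight only weakly through k_e. CL_CR
values are fixed scenario constants, not sampled. The default draw
count is 10⁵ — the original 1,000 per cell leaves ±1.5 pp Monte Carlo
noise; the larger n makes comparison error visible separately from
sampling error. Reported probabilities are percentages of simulated
iterations.

## Synthetic cohort generator

The generator emulates the study population's *marginal* covariate
structure: age N(67, 14²) truncated ≥ 19 y; weight N(57, 15²) ≥ 30 kg
(truncation lifts the realised mean ~1.3 kg); height N(161, 11²); 38 %
female; amiodarone/diltiazem/verapamil 16/8/6 %; daily dose
250/125/62.5 µg at 13/77/10 % (the 4 % "other doses" folded into the
majority 125 µg). Serum creatinine — not CL_CR — is the sampled
quantity, lognormal with median 0.94 mg/dL and log-SD 0.317, taken
directly from the reported creatinine median/IQR; deriving CL_CR
through Cockcroft–Gault then yields median ≈ 56.9 and
IQR ≈ [41.6, 77.0] mL/min against the reported 56.5 [40.7–75.6],
and keeps age/weight/sex/CL_CR mutually coherent by construction.

Observation counts per patient are 1 + NegBin(r = 0.6, mean 7.86):
median 5, IQR [2, 12], mean ≈ 8.9, so 391 patients yield ≈ 3,465
troughs — all three reported summaries at once. Sampling times after
the last dose are Beta(4, 1)-distributed over [6, 24] h (median ≈ 21 h):
TDM samples are intended pre-dose troughs with occasional earlier
draws, and the 6 h floor mirrors the trough-eligibility rule. A
uniform law over the window puts the median draw at 15 h and inflates
the simulated median trough well above the reported ~0.77 ng/mL; the
trough-skewed law centres it. Concentrations below the assay-era
quantification limit (0.3 ng/mL before December 2016, 0.2 after; eras
assigned 90/10) are flagged BLQ and excluded from estimation, exactly
as in the original analysis.

What the generator does **not** emulate: joint covariate structure
(height–weight correlation, disease-severity effects), dose titration
against renal function or measured levels, dropout, dose changes over
time, and any clinical-outcome process. Consequently, passing
recovery tests show that *the estimation machinery is consistent under
the stated data-generating process*, not that the published estimates
are correct for the real population; the real-data point estimates are
explicitly not reproducible from synthetic data and are used only as
generating truth.

A known, deliberate consequence of emulating the BLQ design: excluding
censored troughs removes the lowest concentrations (preferentially from
high-clearance, low-dose patients), which biases the refitted typical
clearance ~5–8 % low and σ ~10–15 % low at study scale. The same
mechanism operated in the original analysis; the recovery tolerances
(±10 % / ±20 %) accommodate it, and fits to uncensored synthetic data
recover the generating values to ~2 %.

## Reproducibility and problem sizes

Every random draw descends from an explicit seed; the pipeline derives
per-stage sub-seeds as stable SHA-256 hashes of (global seed, stage
name), so stages are independently reproducible and adding a stage
never perturbs another's stream. Identical configurations produce
byte-identical numeric artifacts.

Problem sizes used by the checks (chosen as the package's standard
test conditions): ODE-oracle comparison on 100 random parameter sets
(CL ∈ [1, 20] L/h, Vd ∈ [100, 600] L, τ ∈ {12, 24} h); parameter
recovery at the study scale (391 patients) with medians over 5 seeds;
selection recovery over 10 + 10 seeds; bootstrap at 100 replicates
(scaled from the original 1,000); dosing grid at 10⁵ draws per cell.
The full pipeline on a 50-patient cohort completes in well under a
minute on one CPU.

## Known limitations

* Trough-only data: no absorption information, no multi-compartment
  disposition, no inter-occasion variability, single random effect.
* BLQ handling is exclusion (as in the original analysis), not a
  censored-likelihood (M3-type) treatment; the induced small biases are
  described above.
* CWRES uses numerical derivatives; for models with near-flat
  individual likelihoods the linearisation SD can drift from 1.
* The forward-selection procedure inherits the multiplicity property
  discussed above; interpret single-dataset covariate inclusions at the
  3.84 threshold accordingly.
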