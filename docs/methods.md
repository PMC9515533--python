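# Methods

## Structural and statistical model

`siropk` models once-daily oral sirolimus with one-compartment, first-order
absorption kinetics. Internally all doses are micrograms, volumes litres,
clearances L/h and times hours, so concentrations come out in ng/ml (µg/L)
and land directly on the clinical 5–15 ng/ml trough window. Single-dose
concentrations follow the Bateman solution; the steady-state trough under
repeated dosing is the closed-form geometric accumulation of that solution,
evaluated at τ = 24 h immediately before the next dose (the TDM trough
convention). The flip-flop limit Ka → ke is rejected with an explicit error
at |Ka − ke| < 10⁻¹⁰·Ka rather than handled by the L'Hôpital limit: the
plausible pediatric parameter ranges never approach it, and a silent limit
switch would hide parameter pathologies. An independent ODE integrator
(`pk.ode_oracle`, LSODA on the depot/central system with bolus events) exists
purely as a cross-check in the tests and is never part of the analysis path.

Between-patient variability is a single lognormal random effect on clearance,
`CL_i = TVCL·exp(η_i)`, η ~ N(0, ω²). Typical values carry fixed allometric
exponents (0.75 for CL/F, 1 for V/F, 70 kg reference — not estimated).
Additional covariates enter either as a power of the covariate scaled by its
population median (continuous) or as a linear proportional factor
`1 + θ·Cov` (categorical 0/1). Linear coefficients are bounds-checked so the
factor stays positive; fits that violate the bound are rejected, not clipped.
Residual error is additive, proportional or mixed on the observation scale.

The bundled published parameter set is: θ_CL = 10.4 L/h, θ_V = 583 L,
Ka = 0.485 h⁻¹ (fixed), θ_POS = −0.762 on CL/F, ω_CL = 0.303, additive
σ = 3.674 ng/ml. Parameter tables of this kind do not always state whether
variability entries are SDs or variances; `siropk` reads both ω and σ as
standard deviations by default (≈31% CV for clearance), which keeps the
simulated exceedance probabilities in a clinically sensible range, and
exposes `as_variance` switches on both specs for the other reading.

## Likelihood and estimation

The per-subject joint −2 log density (2π constants dropped) is

    J_i(η) = Σ_obs [(y − f(η))²/g² + ln g²] + η²/ω² + ln ω²,

with g² the residual variance at the conditional prediction (constant under
additive error, so FOCE and FOCE-I coincide there). The objective function
value is the Laplace approximation

    OFV = Σ_i [ J_i(η̂_i) + ln(H_i/2) ],   H_i = J_i''(η̂_i),

which equals −2 ln L minus n_obs·ln 2π (the customary NONMEM normalization)
and reduces exactly to the fixed-effects residual objective as ω → 0. The
tests verify this against direct adaptive quadrature of the marginal
likelihood. Absolute OFVs from this package are therefore mutually
comparable; only differences matter for covariate decisions.

Conditional modes are found for all subjects simultaneously by a damped
Newton iteration with central finite differences (step 10⁻⁴), step clipping
to ±1, backtracking on any subject whose step increases J, iterates confined
to [−5ω, 5ω], and a bounded scalar minimizer as per-subject fallback;
convergence tolerance is 10⁻⁹ on the step. H_i is the same central second
difference at the mode, floored at a tiny positive value.

The outer problem runs Nelder-Mead on transformed parameters: logs of
θ_CL, θ_V, ω, σ (and Ka when freed), tanh to (−1, 1) for linear covariate
coefficients, identity for power coefficients. Default starting values are
documented and data-driven: θ_CL and θ_V from a naive pooled least-squares
fit (η = 0, errors ignored), ω = 0.3, σ = half the observation SD, covariate
coefficients 0. Termination uses `fatol = 10⁻⁷`, just above the numerical
noise floor of the finite-difference Laplace terms (~10⁻⁷), so refitting at
an optimum moves the OFV by well under 10⁻⁶. Optimizer failures yield a
flagged, non-converged result rather than any silent fallback. Subjects with
a single observation are retained; their η̂ is simply heavily shrunk, as in
real sparse TDM analyses.

Stepwise covariate search: forward steps add the candidate with the largest
OFV drop while that drop exceeds 3.84 (χ²₁, p < 0.05), ties broken by
candidate order; backward steps remove any included effect whose removal
raises the OFV by at most 6.63 (p < 0.01), smallest rise first. Every tested
move is recorded in the trace. Non-converged candidate fits are recorded and
skipped.

## Diagnostics

PRED is the population prediction (η = 0), IPRED the prediction at the
empirical Bayes mode. CWRES uses the standard FOCE-I first-order
linearization about η̂: residuals `y − f(η̂) + G·η̂` standardized by the
inverse symmetric square root of `G ω² Gᵀ + Σ_res`, with G = ∂f/∂η by central
difference. With ω = 0 and additive error this reduces to (DV − PRED)/σ.
Distribution summaries use a Gaussian KDE with Silverman's bandwidth on a
200-point grid spanning mean ± 4 SD, and Q-Q pairs at (i − ½)/n probability
points; fewer than 10 residuals, or a constant vector, is refused.

## Bootstrap

Resampling draws subjects (the exchangeable unit) with replacement;
duplicates receive fresh ids. Replicates refit from the base-fit estimates;
non-converged replicates are dropped from summaries but counted, and fewer
than 50% converged escalates to an error. Percentile intervals use linear
interpolation of order statistics (numpy default, "type 7"), so the 95%
interval is bit-reproducible given the seed chain (`SeedSequence(seed)`
spawned per replicate). Bias is (median − estimate)/estimate × 100%.

## Dose simulation

Each arm (weight × comedication state) draws `n = 1000` η values, converts
them to individual clearances, and evaluates closed-form steady-state troughs
for each candidate dose (0.01–0.10 mg/kg/day in 0.01 steps; weights
10–60 kg). Because troughs are linear in dose, one set of draws serves all
doses in an arm — common random numbers that sharpen dose contrasts and make
exceedance probabilities exactly monotone in dose. Arm generators derive
from the master seed as `SeedSequence([seed, round(1000·weight), pos])`.

The decision endpoint is the model-predicted trough *without* residual error:
the additive 3.674 ng/ml largely reflects assay and within-subject noise, not
the patient's underlying exposure, and including it would smear ~37% noise
onto a ~9 ng/ml endpoint (an `include_residual` switch restores it, with
truncation at zero). The recommended dose maximizes the probability of a
trough in the inclusive [5, 15] ng/ml window; ties break toward the lower
dose (safety-first), and an all-zero PTA grid raises a no-feasible-dose
signal. The weight-band table runs the recommendation on a 1 kg grid from 10
to 60 kg and merges contiguous weights sharing a dose; band boundaries are
outputs of the simulation, not inputs, so they wobble by a few kg between
seeds where adjacent doses have near-identical PTA (the 20 and 40 kg arms sit
on such knife edges; the 10/30/50 kg arms do not).

## Synthetic cohorts

The generator emulates the study population: n = 24 (16 boys/8 girls; SEX
coded 0 = boy), weight from a truncated lognormal with median 22 kg on
[10, 63] kg (log-SD 0.32, matched to the reported mean/SD), age median 7.94 y
on [2.15, 17.92] y, fourteen routine laboratory covariates as independent
truncated normals at their reported means/SDs/ranges, and comedication
prevalences 11/24, 4/24, 2/24, 12/24 (cefdinir, omeprazole, posaconazole,
sulfamethoxazole), assigned by exact counts at n = 24 and by Bernoulli draws
otherwise. What it deliberately does not emulate: covariate correlations
(none are reported), assay quantification limits, longitudinal weight change,
or dose titration — so passing tests demonstrate correct machinery under the
stated generating model, not robustness to those real-data features.

The default observation design is therapy-initiation TDM: once-daily
0.06 mg/kg/day with trough samples on days 3, 7 and 28 after the first dose,
computed by exact superposition over the administered doses (no steady-state
shortcut) and perturbed by the residual model, redrawing until positive. The
early, accumulation-phase troughs are deliberate: a steady-state trough has
elasticity ≈ −1.2 to clearance but only ≈ +0.2 to volume, so steady-state-only
designs leave V/F barely identifiable (the published bootstrap interval for
V/F, spanning nearly the whole positive axis, shows the same pathology);
troughs at days 3 and 7 carry the accumulation information that separates V
from CL. Under this design, fitting 200 subjects × 3 troughs recovers θ_CL
and θ_V within ±10%, and the covariate search detects the posaconazole
effect from a 30% prevalence — both exercised in the acceptance tests.

## Problem sizes used in the test suite

Parameter recovery uses 200 subjects × 3 troughs (fixed seed); the
false-inclusion calibration runs 200 replicates of study-sized (n = 24)
datasets with an information-free continuous covariate, giving an observed
entry rate around 5–8% at the 3.84 threshold (the slight upward drift from
5% is the known small-sample behavior of approximate-likelihood ratio
tests); CWRES calibration uses ~1,000 simulated observations; bootstrap
mechanics use 30–100 replicates. The full simulation grid (6 weights × 10
doses × 2 comedication states × 1,000 patients) evaluates in well under a
second thanks to the closed-form trough.

## Known limitations

* The raw clinical dataset is not deposited, so the published estimates are a
  fixture, not a reproduction target; only quantities derivable from the
  final model are recomputed.
* With posaconazole, the final model puts the *steady-state* typical trough
  of 0.02 mg/kg/day above 15 ng/ml at 20 kg and heavier — seemingly at odds
  with the published claim that this dose never exceeds the window. The
  simulated time point behind that claim is not stated (an early,
  pre-steady-state day would reconcile it); `siropk` reports the steady-state
  mechanics and leaves the discrepancy visible rather than forcing agreement,
  and no correctness claim is attached to the with-posaconazole dose table.
* Single random effect on CL/F only (as published); no inter-occasion
  variability, covariance structure, lag time, nonlinear elimination or
  multi-compartment kinetics.
* Standard errors are not computed; bootstrap percentiles are the supported
  uncertainty summary.
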