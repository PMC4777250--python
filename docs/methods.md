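# Methods

## The model

Serum disposition of the antibody follows a linear two-compartment model.
With amounts per kg body weight (A_depot, A_c, A_p), central concentration
C = A_c/V_c, and first-order absorption from an s.c. depot:

    dA_depot/dt = -Ka * A_depot
    dA_c/dt     =  Ka * A_depot - (CL/Vc) * A_c - (Q/Vc) * A_c + (Q/Vp) * A_p
    dA_p/dt     =  (Q/Vc) * A_c - (Q/Vp) * A_p

i.v. boluses add the dose directly to A_c; s.c. doses add F1 x dose to the
depot.  Circulating NK cells follow an indirect-response (turnover) model in
which the drug inhibits cell production:

    dR/dt = Kin * (1 - Emax * C / (EC50 + C)) - Kout * R,    Kin = R0 * Kout

The baseline steady state R(0) = R0 fixes Kin, which is therefore derived
and never estimated separately.  Emax is a dimensionless fractional
inhibition in [0, 1]; an Emax of 0.94 means production can be shut down by
94% at saturating drug levels, leaving a steady-state floor of R0*(1-Emax).

Because the PK is linear, the concentration has an exact closed form: a
bi-exponential (i.v.) or tri-exponential (s.c.) per dose, superposed over
the regimen using the micro rate constants k10 = CL/Vc, k12 = Q/Vc,
k21 = Q/Vp and the disposition eigenvalues.  The package carries this
closed form (`analytic_pk`) alongside the stiff ODE integration
(`simulate`, LSODA, rtol 1e-8 / atol 1e-9, dose times as integration
breakpoints) and tests them against each other to 1e-6 of the peak
concentration; the closed form is the oracle, the ODE path is what the PD
coupling actually needs.

Units are fixed package-wide: days, ug/kg doses, ug/mL concentrations,
10^3 cells/uL NK counts, mL/day/kg clearances, mL/kg volumes.  All doses
and parameters are per kg body weight; no explicit body-weight covariate is
modelled.  Observations drawn exactly at a dose time are pre-dose troughs.

Default parameter values (`CYNO_TYPICAL`) are the population typical values
estimated for the anti-IL-15 antibody in cynomolgus monkeys: Ka 0.522/day,
CL 3.66 mL/day/kg, Vc 44.8 mL/kg, Q 5.07 mL/day/kg, Vp 24.3 mL/kg,
F1 0.824, R0 0.584e3 cells/uL, Kout 0.305/day, Emax 0.941,
EC50 0.0978 ug/mL.  Handy derived quantities: Kin = 0.178e3 cells/uL/day,
NK-cell half-life ln2/Kout = 2.27 days, terminal PK half-life
ln2/lambda_z = 14.5 days, model Vss = Vc + Vp = 69.1 mL/kg.

## Noncompartmental analysis

`il15pkpd.nca` implements the standard single-dose toolbox: linear/log
hybrid trapezoids (log rule only on strictly decreasing positive segments),
AUC/AUMC extrapolation with tail terms C_last/lz and
C_last*t_last/lz + C_last/lz^2, C0 by log back-extrapolation of the first
two positive i.v. points, CL = Dose/AUCinf, MRT = AUMCinf/AUCinf,
Vss = CL*MRT, accumulation ratios and dose-normalised bioavailability.
Where the method family leaves choices open, the package decides once and
documents it:

* lambda_z point selection: best adjusted-r^2 over all contiguous terminal
  suffixes of >= 3 points (after tmax for s.c., after the first post-dose
  point for i.v.), near-ties within 1e-4 resolved toward more points;
* BLQ records excluded from areas and regression by default, with an
  optional LLOQ/2 imputation for sensitivity analyses;
* tmax ties resolve to the earliest time.

## The virtual-study generator

`builtin_designs()` transcribes the three study protocols the analysis
assumes: a single-dose study (2 groups x 3 monkeys, 0.1 and 1 mg/kg i.v.),
a 1-month study (5 groups x 10, weekly doses x5: control, 30, 60,
150 mg/kg i.v., 150 mg/kg s.c., recovery sampling in 4 monkeys/group to
day 336), and a 3-month study (4 groups x 12, weekly s.c. x13: control, 5,
30, 150 mg/kg, recovery to day 204) — 104 animals in total, matching the
programme the model was built on (~1300 PK and ~1000 PD records after
censoring).  The protocols label the first dosing day "Day 1"; the package
uses days after first dose, and the 1-month arm carries five weekly doses
(the protocol's own summary wording).

Virtual animals are drawn with log-normal between-subject variability,
P_i = TVP * exp(eta), eta ~ N(0, omega^2), with the reference omega^2 in
`CYNO_VARIABILITY` (e.g. 17.1% on CL, 40.4% on R0, 63.2% on Kout, 90.7% on
EC50); F1 carries no random effect.  Individual Emax values are capped at 1
(the log-normal tail would otherwise make production negative); at 2.45%
BSV this touches well under 0.1% of draws.  Observations get proportional
residual error Y = F*(1+eps) with sigma^2 = 0.0349 (PK) and 0.217 (PD);
additive components are fixed at zero.  PK samples below the 0.1 ug/mL
assay limit are flagged BLQ (control-arm PK is BLQ by construction); the
rare negative PD values (eps < -1) are truncated at zero and counted in the
dataset provenance.  Recovery-phase animals are deterministically the first
subjects of each arm, since the protocols do not say how they were chosen.

What the generator does *not* emulate: body-weight distributions and sex
effects (the programme found none), immunogenicity (none was detected),
assay drift, dropout, or real sampling-time jitter.  Passing recovery tests
therefore demonstrate estimator correctness under the stated statistical
model, not robustness to features real data may add.

## Estimation

All modes share the proportional-error likelihood Y ~ N(F, F^2 sigma^2)
with observation-type-specific sigma^2, and optimise on transformed scales
(log for positive parameters, logit for F1 and Emax), making results
invariant to initial-value scaling.  Initial values are crude data-scale
guesses (R0 starts at the mean baseline NK count).  Identifiability guards
fix F1/Ka when no s.c. arms are present and refuse datasets lacking PK or
PD records outright.

* **pooled** — naive-pooled maximum likelihood with the residual variances
  profiled out in closed form and a 3-start jittered multistart (fixed
  seed) guarding the nonlinear EC50/Emax directions.  On zero-BSV data it
  recovers all nine structural parameters to better than 0.1%.  At the full
  reference heterogeneity it is badly biased (EC50 can be off by an order
  of magnitude) — that is a property of naive pooling, not of the
  optimiser, and is why the recovery benchmarks use the mixed mode.
* **two_stage** — per-subject fits over the parameters each subject's data
  can support, then geometric-mean typical values and log-scale sample
  variances as omega^2 estimates; subjects failing their fit are dropped
  with a log message, >50% failures aborts.
* **laplace** — mixed-effects estimation with log-normal random effects on
  a configurable subset (default CL, Vc, Ka on the PK side; R0, Kout, EC50
  on the PD side; Emax's 2.45% BSV is left to the residual).  The marginal
  likelihood is approximated by the Laplace method: per-subject MAP random
  effects from damped Newton iterations batched across each arm (prediction
  Jacobians by forward differences; curvature from the exact second
  derivative of the proportional-error term w.r.t. the prediction, floored
  for stability, times Jacobian outer products; warm-started between outer
  evaluations), plus the log-determinant correction.  The fit runs
  sequentially: simultaneous pooled warm start, then the PK block, then the
  PD block conditioned on each subject's empirical-Bayes PK parameters.
  The factorisation is justified by the weak PK->PD coupling of this system
  (fixing PK at truth moves PD estimates by far less than their standard
  errors; the package tests this).  This mode plays the role first-order
  conditional estimation plays in dedicated mixed-effects software; it is
  a documented approximation, not a reimplementation of any such tool.

All simplex optimisations run staged (PK block alone, then PD block alone,
then the joint or mixed objective — single-block evaluations are far
cheaper), and the mixed-effects outer stages restart Nelder-Mead once from
the found optimum: re-inflating the simplex reliably escapes the premature
collapse NM is prone to in 8-10 dimensions, which replicate experiments
showed could otherwise contribute estimate swings of tens of percent of
pure optimisation noise on the flattest direction (EC50).

Standard errors come from central-difference Hessians of the -2LL surface
at the optimum, delta-transformed to the natural scale and reported as
%RSE = 100*SE/estimate.  Between-subject variability is reported both as
100*sqrt(omega^2) (the convention used for recovery checks) and as the
log-normal CV 100*sqrt(exp(omega^2)-1).

### Numerical engine

Estimation and VPC simulation run on a vectorised analytic engine: exact
closed-form concentrations, and NK dynamics integrated by an exponential
one-step scheme (production frozen at its midpoint value over each 0.25-day
step, for which the linear turnover update is exact), unrolled into
cumulative sums processed in overflow-safe blocks.  The engine agrees with
the stiff ODE reference to ~2e-5 relative on the reference scenarios —
three orders of magnitude below the residual noise.  During the PD block
the PK parameters are frozen, so per-arm midpoint concentrations are cached
and invalidated by a byte-comparison of the PK columns.  The synthetic-data
generator deliberately does *not* use this engine: datasets come from the
stiff ODE solver, so estimator and generator do not share their numerics.

## Visual predictive check and residuals

`vpc` recovers each arm's design from the dataset's own dose records,
simulates `n_reps` replicate studies (default 500) under the fitted
parameters and variability, and reports the 5th/50th/95th percentiles per
nominal sampling time (the designs are balanced, so no binning algorithm is
needed).  BLQ observations are plotted at the quantification limit and
excluded from coverage counts; simulated values are not censored before
taking percentiles.  On self-simulated data the 5-95% band covers ~90% of
observations (tested with a binomial tolerance).  Residual diagnostics
report population weighted residuals (Y-F)/(F*sigma) — the package's
stand-in for linearisation-based conditional weighted residuals, adequate
for detecting the gross misspecifications it is tested against (e.g.
forcing Emax to 0.5 leaves a strong negative on-treatment PD trend).

## Problem sizes and determinism

The bundled benchmarks use the full 104-animal, three-study programme for
parameter recovery (one mixed-effects fit, ~10-15 minutes on one core),
dense 0.25-day grids over 60 days for the noise-free NCA identities, and
500-replicate VPCs; the pooled-calibration suite runs ten replicate
programmes at zero BSV.  Every stochastic step
flows through an explicit `numpy` Generator seed — same seed, same dataset,
byte for byte — and the optimisers are deterministic given the data and
spec, so fits are reproducible end to end.

## Known limitations

* The Laplace mode estimates random effects on a subset of parameters; the
  BSV of Q, Vp and Emax is absorbed into residual error, which slightly
  inflates sigma^2 estimates and can bias omega^2 for correlated
  directions (e.g. omega_CL absorbs some of Q's variability).
* The sequential PK-then-PD factorisation ignores the (weak) feedback of
  PD data on PK parameters; standard errors are block-wise and ignore
  cross-block covariance.
* The CL-Vc random-effect correlation is supported by the generator but
  defaults to zero and is not estimated.
* No likelihood-based BLQ treatment in the default path (records are
  discarded; LLOQ/2 imputation is available as a sensitivity option).
* NCA covers single-dose profiles and single-interval partial areas only;
  no urine data, no sparse-sampling variance estimators.
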