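# Methods

This note records the model, the statistical machinery, the numerical
choices and the known limitations of `oralpax`, in the package's own
words. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Structural PK model

Oral paclitaxel is described by four compartments: gut, a well-stirred
liver, a central and one peripheral distribution compartment.

**Absorption.** Each dose `d` given at time `T_d` keeps its own
absorption clock. The absorption rate out of the gut follows a Weibull
density in the time since that dose,

    w(t) = (BETA/ALPHA) (t/ALPHA)^(BETA-1) exp(-(t/ALPHA)^BETA),

with the scale ALPHA selected by the daily-dose index (first vs second
dose of a dosing day; the second daily dose absorbs later) and the shape
BETA by formulation (drinking solution vs the amorphous-solid-dispersion
tablet/capsule). Internally the gut amount follows the Weibull
*survival* curve, `dA/dt = -h(t) A` with `h` the Weibull hazard, so that
the absorption rate into the liver equals `F_d · Dose_d · w(t)` exactly
and absorption is complete. Applying the density expression itself as a
rate constant would strand a fraction `exp(-1)` of every dose in the gut
and break mass balance; that literal variant is retained as
`absorption_mode="pdf_rate"` for comparison, and the direct-input
interpretation (`input = F · Dose · w(t)`, `absorption_mode="input"`)
coincides with the default hazard form because the gut has no competing
loss. All three are exercised in the tests.

Each dose's amount is scaled on entry by its relative gut
bioavailability `F_d = rF_formulation · rF_2nd/1st^[second dose] ·
exp(eta_rF,BSV + eta_rF,BOV(occasion))`, with the drinking solution as
the reference (`rF_solution = 1`, fixed).

**Well-stirred liver and the ritonavir interaction.** The intrinsic
clearance is inhibited by the ritonavir plasma concentration through

    CLint(t) = CLint0 - Imax · C_rtv(t) / (KI + C_rtv(t)),

floored at zero (sampled individuals can have `CLint0·exp(eta) < Imax`;
a negative clearance is unphysical, and a floor event raises a runtime
warning). The liver balance is

    dA_H/dt = sum_d inputs + Q_H (C_c - C_H) - fu · CLint(t) · C_H,

with `Q_H = 80 L/h`, `V_H = 1 L` and `fu = 0.13` fixed. At steady state
this reproduces the algebraic extraction ratio
`E_H = fu·CLint/(Q_H + fu·CLint)` and hepatic bioavailability
`F_H = 1 - E_H` exactly (asserted to 1e-6). Central and peripheral
compartments exchange through the inter-compartmental clearance Q; all
elimination is hepatic (renal elimination is a minor route and is not
modelled).

**Ritonavir.** A two-compartment model with first-order elimination and
an inverse-Gaussian density input (mean = mean absorption time, shape =
relative variance of the input density; the density integrates to one so
the input totals `F·Dose`). The published source model's numeric values
are not public; the packaged `ritonavir` block carries clearly labelled
synthetic plausible values and is meant to be replaced by user
configuration. Ritonavir is solved first and enters the paclitaxel
system as a forcing function; profiles are cached per (regimen,
parameters) because designs repeat one ritonavir schedule across many
subjects.

**IV paclitaxel plug-in.** A standard three-compartment mamillary model
with zero-order infusions and either linear (`CL·C`) or saturable
(`vmax·C/(km+C)`) elimination, used only for schedule comparisons. Its
packaged values are synthetic stand-ins as well.

## TSP-1 turnover model

Platelet-normalised thrombospondin-1 follows an indirect-response model

    dC/dt = kin0 · (1 + C_pac/(EC50 + C_pac)) - kout · C,

with `kout = 1/Turnover` (`Turnover = 233 h`, fixed to the platelet
life-span because it is not identifiable from the data) and
`kin0 = E_BASE · kout`, so the unstimulated system is stationary at the
(individual) baseline. The implicit maximum stimulation of 1 caps TSP-1
below twice its baseline.

## Statistical model

Random effects are lognormal, `P_i = P · exp(eta_BSV + eta_BOV)`, and
diagonal: BSV on ALPHA (one draw shared by the first- and second-dose
scales — the reported variability does not distinguish them), CLint0,
Vc, rF_gut and the TSP-1 baseline; BOV on rF_gut with one effect per
dosing occasion ("each dose administration is an occasion"). Reported
CV% convert to standard deviations as `omega = CV/100` (the first-order
reporting convention; the exact lognormal conversion
`omega = sqrt(log(1+(CV/100)^2))` is available by flag). Residual error
is proportional for both observation channels,
`C_obs = C_pred (1 + eps)`; an additive variant exists chiefly for the
analytically tractable test problems.

## Estimation

The marginal likelihood is approximated subject-by-subject with the
Laplace method *with interaction* (the proportional residual variance
`sigma^2 yhat^2` depends on the random effects through the prediction) —
this package's stand-in for the first-order conditional method of
classical NLME software; agreement is asserted on parameter recovery,
not on objective-function values of other software.

* Penalized individual objective:
  `g(eta) = sum_j [log(2 pi v_j) + (y_j - yhat_j)^2/v_j] +
  eta' Omega^-1 eta + log|2 pi Omega|`.
* Subject OFV: `g(eta_hat) - d log(2 pi) + log|H/2|` at the inner
  optimum, exact for linear-Gaussian subjects (asserted against the
  closed-form Gaussian integral to 1e-4).
* Inner optimisation: damped Gauss-Newton on `eta`, with gradients and
  the FOCE-style expected Hessian
  (`sum_j J_j J_j' [2/(sigma^2 f^2) + 4/f^2] + 2 Omega^-1` for the
  proportional model) built from forward-difference prediction
  sensitivities (step 1e-4). Newton steps are trust-regioned to a
  maximum component of 3 on the log scale; inner starts are the
  subject's previous optimum and zero; a Nelder-Mead fallback covers
  non-finite starts. A full finite-difference Hessian (`hessian="fd"`)
  replaces the Gauss-Newton one on demand or when it is not positive
  definite.
* Outer optimisation: Nelder-Mead over log-transformed fixed effects,
  omegas and sigmas (positivity without hard bounds; points violating
  typical-value constraints such as `Imax <= CLint0` are rejected with
  an infinite objective). Everything not listed for estimation is fixed
  at its configured value — the FIX mechanism used for `rF_solution`,
  the turnover time, and the physiological constants.
* Empirical-Bayes etas, eta-shrinkage `100·(1 - SD(eta_hat)/omega)` and
  convergence metadata are reported with every fit.

**Sequential PK->PD.** The PD stage freezes the population PK fixed
effects, omegas and residual error at the PK results and re-estimates
the subjects' PK random effects jointly with the PD parameters from the
combined paclitaxel + TSP-1 records (the population-PK-parameters
sequential approach; whether the PK etas should be re-estimated with the
PK records included is not settled — the joint-records variant is this
package's choice). BOV etas are included in PK fits
(`estimate_bov=True`; omitting them against BOV-bearing data distorts
the fixed effects badly, because 45.8 CV% occasion noise cannot be
absorbed by a 25.8 CV% residual) but omitted in the PD stage, where
dose-level bioavailability noise averages out over the 233-h turnover
and one eta per occasion would add dozens of dimensions per subject.

## Numerical choices

* Reference ODE path: stiff-capable adaptive solver (LSODA), rtol 1e-8,
  atol 1e-10, with dose times and infusion start/stop as mandatory
  breakpoints.
* Fast path: fixed-step RK4 on the 3-state liver/central/peripheral
  system (the gut is analytic), step 0.01 h capped by the explicit
  stability bound `2.5/lambda_max` with
  `lambda_max = (Q_H + fu·CLint0)/V_H` (~177/h typically, larger for
  high-clearance individuals). Agrees with the reference path to ~1e-6
  relative; used for simulation, trial generation and all estimation
  loops. Estimation uses a nominal 0.02 h step, which the stability cap
  reduces to ~0.014 h.
* Long-horizon TSP-1 driver: a quasi-steady-state reduction of the
  liver compartment (input enters the central compartment scaled by
  `1 - E_H(t)`, leaves with clearance `Q_H·E_H(t)`). The liver
  equilibrates in well under a minute while the driver feeds a 233-h
  turnover; the reduction is non-stiff, runs at 0.25-h steps, and
  matches the full model to a small fraction of a percent (asserted in
  the tests at 1%).
* Gut flush: a dose's gut content is treated as exhausted once its
  survival falls below 1e-12 (beyond ~2.5 ALPHA), bounding work per
  right-hand-side evaluation on long regimens.
* NCA metrics: Cmax/Tmax from the grid maximum with local quadratic
  refinement; AUC by trapezoid on the dense grid (simulation grids are
  0.02-0.05 h); time-above-threshold by linear interpolation of the
  crossings; no extrapolation beyond the stated window.
* pcVPC: equal-count bins (default 8) on time-after-most-recent-dose
  (the publication does not state its binning); observations and
  simulations are scaled by bin-median population prediction over
  record population prediction; 10th/50th/90th percentiles with 95%
  simulation intervals; `n_sim=1` flags degenerate intervals.
* Likelihood-ratio thresholds are the chi-square 0.99 quantiles (6.63
  at 1 df, 9.21 at 2 df).

## Synthetic trials

`oralpax.synthetic` emulates the three study designs the model was
developed on: a single 100 mg drinking-solution dose with a 30-min
ritonavir lead (17 subjects; ritonavir 100 or 200 mg alternating); a
two-week 30 mg solution/capsule crossover; and the twice-daily low-dose
metronomic study (capsule 5-40 mg/day, tablet 40-60 mg/day, 7-h dose
interval, ritonavir 200 mg/day split over the two administrations, with
TSP-1 sampled on days 1, 2 and 8 of cycle 1 and day 1 of cycles 2-3).
Exact per-study sampling times are not on public record; templates use a
rich 0-24 h grid after the first daily dose (0.25-24 h), chosen to
resolve the ~2 h absorption peak, as a fixture convention. Time zero is
each subject's first administered dose, so with a ritonavir lead the
paclitaxel dose sits at +0.5 h. Pre-dose records with zero predicted
concentration are emitted with the missing flag set: they carry no
information under a proportional error model.

The generator draws BSV and per-occasion BOV etas, simulates each
subject at the realised parameters, applies proportional noise, and
writes the full truth (parameter values and every eta draw) to a
sidecar for recovery studies. It does **not** emulate: dropout or
censoring (no quantification limit is modelled), dose modifications or
non-adherence, covariate structure (body size, organ function),
between-subject ritonavir PK variability (the inhibitor runs at its
typical curve, mirroring the use of fixed-effect imputation when
inhibitor sampling is absent), or assay-specific error beyond the
proportional term. Passing recovery tests therefore demonstrate that
the estimation machinery inverts the generative model at realistic
noise levels — not that the model is correct for any real dataset.

## Problem sizes used in the checks

Parameter recovery runs pool a single-dose solution arm (8 subjects)
with a day-1 capsule LDM arm (10 subjects, 10-40 mg/day): the solution
arm pins CLint0 and Vc (its relative bioavailability is the fixed
reference), after which the capsule arm identifies rF_capsule — the
same pooling that made the original three-study analysis identifiable.
Recovery is judged as the median absolute relative error over three
seeds at a 20% bound. The sequential PD stage uses 10 subjects dosed
for 43 days with the full TSP-1 sampling schedule, starting EC50 at
500 ng/mL, and is judged against the published 95% CI span (122-724
ng/mL); a no-effect comparator (EC50 fixed at 1e5 ng/mL) must never
beat the full model on effect-bearing data. The pcVPC self-check uses
12-subject single-dose trials, 150 simulation replicates and 5 bins.
These sizes are deliberate scale-downs of the source studies chosen to
keep the whole suite fast; tolerances are never scaled with them.

## Known limitations

* The Laplace/Gauss-Newton objective is an approximation; its OFV is
  comparable between nested fits of this package but not to other
  software.
* Omegas are diagonal; correlated random effects are not supported.
* The outer optimizer is derivative-free and intended for the handful
  of free parameters typical of a confirmatory refit, not for
  large-scale covariate searches.
* Parameter uncertainty (standard errors, sampling-importance
  resampling) is out of scope; likelihood-ratio comparison is the
  supported inferential tool.
* The packaged ritonavir and IV paclitaxel values are synthetic: any
  quantity that depends on inhibitor exposure or on the IV comparator
  reflects that configuration, not a published model.
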