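"""Nonlinear mixed-effects estimation by Laplace approximation.

The marginal likelihood of each subject's data is approximated by the
Laplace method with interaction (the proportional residual variance
depends on the model prediction, hence on the random effects), the
package's stand-in for the FOCE-I method of classical NLME software:

* the penalized individual objective is

  ``g(eta) = sum_j [log(2 pi v_j) + (y_j - yhat_j)^2 / v_j]
             + eta' Omega^-1 eta + log|2 pi Omega|``

  with ``v_j = sigma^2 yhat_j^2`` (proportional) or ``sigma^2``
  (additive), and ``yhat`` the subject's model prediction at ``eta``;

* the subject's contribution to the objective function value (OFV,
  -2 log marginal likelihood) is

  ``OFV_i = g(eta_hat) - d log(2 pi) + log|H/2|``

  where ``eta_hat`` minimises ``g``, ``H`` is the Hessian of ``g`` there
  and ``d`` the number of random effects — exact for linear-Gaussian
  subjects;

* the population fit minimises ``sum_i OFV_i`` over log-transformed fixed
  effects, omegas and sigmas (Nelder-Mead), warm-starting each subject's
  inner optimisation from its previous optimum.

The Hessian is either a FOCE-style Gauss-Newton approximation built from
finite-difference prediction sensitivities (``hessian='gn'``, the fast
default, exact for models linear in eta with additive error) or a full
central finite-difference Hessian (``hessian='fd'``).

Random effects are diagonal: BSV on ALPHA (shared by both daily-dose
scales), CLint0, Vc, rF_gut and the TSP-1 baseline; optional BOV on
rF_gut with one effect per dosing occasion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import pkmodels as pkm
from .errors import InputError, ParameterError
from .params import DispositionParams, ModelConfig
from .simulate import paclitaxel_concentrations
from ._fast import oral_conc_fast, oral_conc_qss, tsp1_fast
from .trial import StudyDataset

__all__ = [
    "EstimationOptions",
    "EstimationProblem",
    "EstimationResult",
    "SubjectData",
    "prepare_subjects",
    "individual_penalized_nll",
    "laplace_marginal_nll",
    "fit_population",
    "lrt_compare",
    "LRTResult",
    "fit_pd_sequential",
]

_PK_THETA = ("alpha_first_dose", "alpha_second_dose", "beta_solution",
             "beta_asd", "clint0", "ki", "imax", "vc", "q", "vp",
             "rf_tablet", "rf_capsule", "rf_second_over_first",
             "rf_solution")
_PD_THETA = ("ec50", "ebase", "turnover_time")
_BSV_NAMES = ("alpha", "clint0", "vc", "rf_gut")


def _get_theta(config: ModelConfig, name: str) -> float:
    if name in _PK_THETA:
        return getattr(config.paclitaxel, name)
    if name == "ec50":
        return config.tsp1.ec50
    if name == "ebase":
        return config.tsp1.baseline
    if name == "turnover_time":
        return config.tsp1.turnover_time
    raise ParameterError(f"unknown fixed effect {name!r}")


def _set_thetas(config: ModelConfig, values: dict) -> ModelConfig:
    pk = {k: v for k, v in values.items() if k in _PK_THETA}
    if pk:
        config = config.replace(paclitaxel=replace(config.paclitaxel, **pk))
    pd_map = {"ec50": "ec50", "ebase": "baseline",
              "turnover_time": "turnover_time"}
    pdv = {pd_map[k]: v for k, v in values.items() if k in pd_map}
    if pdv:
        config = config.replace(tsp1=replace(config.tsp1, **pdv))
    return config


@dataclass
class EstimationOptions:
    """Numerical knobs of the population fit."""

    error_model: str = "proportional"     # or 'additive'
    hessian: str = "gn"                   # or 'fd'
    fast: bool = True
    step: float = 0.02                    # RK4 step of the fast PK path, h
    pd_driver_step: float = 0.25          # grid for the TSP-1 driver, h
    estimate_bov: bool = False            # include per-occasion BOV etas
    maxiter: int = 400
    inner_maxiter: int = 60
    fd_step: float = 1e-4                 # sensitivity step on eta
    xatol: float = 2e-3
    fatol: float = 5e-3

    def __post_init__(self):
        if self.error_model not in ("proportional", "additive"):
            raise ParameterError("error_model must be proportional|additive")
        if self.hessian not in ("gn", "fd"):
            raise ParameterError("hessian must be 'gn' or 'fd'")


_EXHAUST_LOGQ = -np.log(1e-12)
_FORM_CODE = {"solution": 0, "tablet": 1, "capsule": 2}


@dataclass
class SubjectData:
    """Pre-extracted per-subject arrays plus the cached ritonavir curve.

    Dose bookkeeping (times, raw amounts, formulation and daily-dose
    codes, occasion indices) and the integration knot grids are computed
    once so each likelihood evaluation is a handful of vector operations
    plus one compiled ODE sweep.
    """

    sid: object
    pac_doses: tuple
    occasions: tuple
    pk_t: np.ndarray
    pk_y: np.ndarray
    pd_t: np.ndarray
    pd_y: np.ndarray
    rtv_profile: object

    def __post_init__(self):
        self.dose_t = np.array([d.time for d in self.pac_doses])
        self.dose_amt_ug = np.array(
            [d.amount * 1000.0 for d in self.pac_doses])
        self.is_second = np.array(
            [d.daily_dose_index == "second" for d in self.pac_doses])
        self.form_code = np.array(
            [_FORM_CODE[d.formulation] for d in self.pac_doses], dtype=int)
        self.dose_occ = tuple(d.occasion for d in self.pac_doses)
        if len(self.pk_t):
            k = np.unique(np.concatenate([[0.0], self.dose_t, self.pk_t]))
            self.knots_pk = k[k <= self.pk_t[-1] + 1e-9]
        else:
            self.knots_pk = np.array([0.0])
        if isinstance(self.rtv_profile, pkm.ConcProfile):
            self.rtv_t = self.rtv_profile.t
            self.rtv_c = self.rtv_profile.c
        else:
            self.rtv_t = np.array([0.0, 1e6])
            self.rtv_c = np.zeros(2)
        self._pd_cache = {}

    def pd_grid(self, step: float):
        """Dense paclitaxel grid driving the TSP-1 model (cached)."""
        key = round(step, 6)
        if key not in self._pd_cache:
            horizon = float(self.pd_t[-1])
            grid = np.unique(np.concatenate(
                [np.arange(0.0, horizon + step, step), self.pd_t]))
            grid = grid[grid <= horizon + 1e-9]
            knots = np.unique(np.concatenate([[0.0], self.dose_t, grid]))
            self._pd_cache[key] = (grid, knots)
        return self._pd_cache[key]


def prepare_subjects(dataset: StudyDataset, config: ModelConfig,
                     include_pd: bool = False) -> list[SubjectData]:
    """Slice the record table per subject and pre-solve ritonavir PK.

    The ritonavir model is fixed external configuration, so each subject's
    inhibitor curve is solved once and reused across every likelihood
    evaluation.
    """
    out = []
    for sid in dataset.subjects:
        regimen = dataset.subject_regimen(sid)
        obs = dataset.observations(sid)
        obs = obs[obs["MDV"].fillna(0).astype(float) != 1]
        pk = obs[obs["CMT"] == "pac"].sort_values("TIME")
        pdo = obs[obs["CMT"] == "tsp1"].sort_values("TIME") if include_pd \
            else obs.iloc[0:0]
        horizon = max(regimen.horizon, 1.0)
        if regimen.ritonavir:
            if config.ritonavir is None:
                raise InputError("dataset has ritonavir doses but the "
                                 "config lacks a ritonavir block")
            rtv = pkm.solve_ritonavir(
                regimen.ritonavir, config.ritonavir, horizon,
                grid_step=0.05 if horizon <= 100 else 0.1)
        else:
            rtv = pkm.ConcProfile.constant(0.0, horizon)
        out.append(SubjectData(
            sid=sid,
            pac_doses=tuple(regimen.paclitaxel),
            occasions=tuple(sorted({d.occasion for d in regimen.paclitaxel})),
            pk_t=pk["TIME"].astype(float).to_numpy(),
            pk_y=pk["DV"].astype(float).to_numpy(),
            pd_t=pdo["TIME"].astype(float).to_numpy(),
            pd_y=pdo["DV"].astype(float).to_numpy(),
            rtv_profile=rtv,
        ))
    return out


def _eta_layout(subject: SubjectData, omega: dict, include_pd: bool,
                options: EstimationOptions) -> list:
    names = [n for n in _BSV_NAMES if omega.get(n, 0.0) > 0]
    if options.estimate_bov and omega.get("bov_rf_gut", 0.0) > 0:
        names += [("bov", occ) for occ in subject.occasions]
    if include_pd and omega.get("ebase", 0.0) > 0 and len(subject.pd_t):
        names.append("ebase")
    return names


def _omega_vector(names, omega: dict) -> np.ndarray:
    out = np.empty(len(names))
    for i, n in enumerate(names):
        out[i] = omega["bov_rf_gut"] if isinstance(n, tuple) else omega[n]
    return out


def _dose_vectors(subject: SubjectData, pop, eta: dict):
    """Per-dose Weibull parameters and gut amounts at the given etas."""
    e_alpha = np.exp(eta.get("alpha", 0.0))
    alpha_d = np.where(subject.is_second, pop.alpha_second_dose,
                       pop.alpha_first_dose) * e_alpha
    beta_d = np.where(subject.form_code == 0, pop.beta_solution,
                      pop.beta_asd)
    rf_d = np.choose(subject.form_code,
                     [pop.rf_solution, pop.rf_tablet, pop.rf_capsule]) \
        * np.where(subject.is_second, pop.rf_second_over_first, 1.0)
    e_rf = eta.get("rf_gut", 0.0)
    if subject.dose_occ:
        bov = np.array([eta.get(("bov", occ), 0.0)
                        for occ in subject.dose_occ])
    else:
        bov = 0.0
    amt = subject.dose_amt_ug * rf_d * np.exp(e_rf + bov)
    cut_d = alpha_d * _EXHAUST_LOGQ ** (1.0 / beta_d)
    return alpha_d, beta_d, amt, cut_d


def _predict(subject: SubjectData, config: ModelConfig, eta: dict,
             options: EstimationOptions, need_pd: bool):
    """Model predictions for one subject at the given random effects."""
    pop = config.paclitaxel
    physio = config.physio
    clint0 = pop.clint0 * np.exp(eta.get("clint0", 0.0))
    vc = pop.vc * np.exp(eta.get("vc", 0.0))
    if not options.fast:
        return _predict_reference(subject, config, eta, options, need_pd,
                                  clint0, vc)
    if not all(np.isfinite(v) for v in eta.values()) or clint0 > 1e8:
        # hopeless parameter point (overflowing etas): report +inf
        # predictions so the penalized objective rejects it
        n = len(subject.pk_t)
        return np.full(n, np.inf), np.full(len(subject.pd_t), np.inf)
    alpha_d, beta_d, amt, cut_d = _dose_vectors(subject, pop, eta)
    lam = (physio.hepatic_blood_flow
           + physio.fraction_unbound * clint0) / physio.liver_volume
    h = max(min(options.step, 2.5 / lam), 1e-5)

    def conc(t_obs, knots):
        return oral_conc_fast(
            t_obs, knots, subject.dose_t, amt, alpha_d, beta_d, cut_d,
            clint0, pop.imax, pop.ki, vc, pop.q, pop.vp,
            physio.hepatic_blood_flow, physio.liver_volume,
            physio.fraction_unbound, subject.rtv_t, subject.rtv_c, h)

    yhat_pk = conc(subject.pk_t, subject.knots_pk) \
        if len(subject.pk_t) else np.empty(0)
    yhat_pd = np.empty(0)
    if need_pd and len(subject.pd_t):
        grid, knots = subject.pd_grid(options.pd_driver_step)
        # the long-horizon driver uses the non-stiff quasi-steady-state
        # liver reduction; the TSP-1 turnover (233 h) cannot see the
        # sub-minute liver equilibration it removes
        pac = oral_conc_qss(
            grid, knots, subject.dose_t, amt, alpha_d, beta_d, cut_d,
            clint0, pop.imax, pop.ki, vc, pop.q, pop.vp,
            physio.hepatic_blood_flow, physio.fraction_unbound,
            subject.rtv_t, subject.rtv_c, options.pd_driver_step)
        baseline = config.tsp1.baseline * np.exp(eta.get("ebase", 0.0))
        yhat_pd = tsp1_fast(subject.pd_t, grid, pac, config.tsp1.ec50,
                            baseline, config.tsp1.kout,
                            options.pd_driver_step)
    return yhat_pk, yhat_pd


def _predict_reference(subject, config, eta, options, need_pd, clint0, vc):
    """Adaptive-solver prediction path (slow; for cross-validation)."""
    pop = config.paclitaxel
    disp = DispositionParams(clint0=clint0, ki=pop.ki, imax=pop.imax,
                             vc=vc, q=pop.q, vp=pop.vp)
    alpha_d, beta_d, amt, _ = _dose_vectors(subject, pop, eta)
    gut = [pkm.GutDose(t, a, al, be) for t, a, al, be in
           zip(subject.dose_t, amt, alpha_d, beta_d)]
    yhat_pk = paclitaxel_concentrations(
        gut, disp, config.physio, subject.rtv_profile, subject.pk_t,
        fast=False)
    yhat_pd = np.empty(0)
    if need_pd and len(subject.pd_t):
        grid, _ = subject.pd_grid(options.pd_driver_step)
        pac = paclitaxel_concentrations(
            gut, disp, config.physio, subject.rtv_profile, grid,
            fast=False)
        baseline = config.tsp1.baseline * np.exp(eta.get("ebase", 0.0))
        yhat_pd = pkm.solve_tsp1(
            pkm.ConcProfile(grid, pac) if len(grid) > 1 else
            pkm.ConcProfile.constant(0.0),
            config.tsp1, subject.pd_t, baseline)
    return yhat_pk, yhat_pd


def _data_nll(y, yhat, sigma, error_model):
    """-2 log-likelihood of one observation block (with constants)."""
    if len(y) == 0:
        return 0.0
    if error_model == "proportional":
        v = sigma ** 2 * yhat ** 2
        if np.any(v <= 0):
            bad = v <= 0
            if np.any(y[bad] != 0):
                return np.inf
            v = np.where(bad, 1e-300, v)
    else:
        v = np.full_like(yhat, sigma ** 2)
    return float(np.sum(np.log(2 * np.pi * v) + (y - yhat) ** 2 / v))


def individual_penalized_nll(eta_vec, subject: SubjectData,
                             config: ModelConfig, omega: dict,
                             sigma_pk: float, sigma_pd: float = 0.0,
                             options: EstimationOptions | None = None,
                             eta_names=None, include_pd: bool = False,
                             _pred_out: list | None = None) -> float:
    """Penalized individual -2 log posterior ``g(eta)`` (see module docs).

    ``eta_vec`` is ordered as ``eta_names`` (default: the subject's active
    BSV/BOV layout).  Infinite when a proportional-error prediction is
    zero against a nonzero observation.
    """
    options = options or EstimationOptions()
    if eta_names is None:
        eta_names = _eta_layout(subject, omega, include_pd, options)
    eta = dict(zip(eta_names, np.asarray(eta_vec, dtype=float)))
    yhat_pk, yhat_pd = _predict(subject, config, eta, options, include_pd)
    if _pred_out is not None:
        _pred_out[:] = [yhat_pk, yhat_pd]
    nll = _data_nll(subject.pk_y, yhat_pk, sigma_pk, options.error_model)
    if include_pd and len(subject.pd_t):
        nll += _data_nll(subject.pd_y, yhat_pd, sigma_pd,
                         options.error_model)
    if len(eta_names):
        om = _omega_vector(eta_names, omega)
        ev = np.asarray(eta_vec, dtype=float)
        nll += float(np.sum(ev ** 2 / om ** 2)
                     + np.sum(np.log(2 * np.pi * om ** 2)))
    return nll


def _jacobians(subject, config, eta_names, eta_hat, options, include_pd,
               f_pk, f_pd):
    """Forward-difference prediction sensitivities d(yhat)/d(eta)."""
    d = len(eta_names)
    h = options.fd_step
    eta0 = dict(zip(eta_names, eta_hat))
    J_pk = np.zeros((len(f_pk), d))
    J_pd = np.zeros((len(f_pd), d))
    for k in range(d):
        ep = dict(eta0)
        ep[eta_names[k]] = eta_hat[k] + h
        fp_pk, fp_pd = _predict(subject, config, ep, options, include_pd)
        J_pk[:, k] = (fp_pk - f_pk) / h
        if len(f_pd):
            J_pd[:, k] = (fp_pd - f_pd) / h
    return J_pk, J_pd


def _gn_hessian_from_jac(blocks, eta_names, omega, error_model):
    """FOCE-style (expected) Gauss-Newton Hessian of g.

    For the proportional model the residual variance depends on the
    prediction, contributing the interaction term 4/f^2 on top of the
    least-squares curvature 2/(sigma^2 f^2); exact for models linear in
    eta with additive error.
    """
    d = len(eta_names)
    H = np.zeros((d, d))
    for f, J, sigma in blocks:
        if len(f) == 0:
            continue
        fs = np.maximum(np.abs(f), 1e-12)
        if error_model == "proportional":
            w = 2.0 / (sigma ** 2 * fs ** 2) + 4.0 / fs ** 2
        else:
            w = np.full_like(fs, 2.0 / sigma ** 2)
        H += (J * w[:, None]).T @ J
    om = _omega_vector(eta_names, omega)
    H += np.diag(2.0 / om ** 2)
    return H


def _g_gradient(blocks, eta, omega_vec, error_model):
    """Exact gradient of g given the prediction Jacobians."""
    grad = 2.0 * eta / omega_vec ** 2
    for (y, f, J, sigma) in blocks:
        if len(f) == 0:
            continue
        fs = np.maximum(np.abs(f), 1e-12)
        r = y - f
        if error_model == "proportional":
            coef = 2.0 / fs - 2.0 * r / (sigma ** 2 * fs ** 2) \
                - 2.0 * r ** 2 / (sigma ** 2 * fs ** 3)
        else:
            coef = -2.0 * r / sigma ** 2
        grad = grad + J.T @ coef
    return grad


def _fd_hessian(g, eta_hat, h=1e-3):
    d = len(eta_hat)
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h
            ej[j] = h
            H[i, j] = H[j, i] = (
                g(eta_hat + ei + ej) - g(eta_hat + ei - ej)
                - g(eta_hat - ei + ej) + g(eta_hat - ei - ej)) / (4 * h * h)
    return H


def _inner_newton(g_parts, jac, eta0, omega_vec, eta_names, omega,
                  error_model, maxiter):
    """Damped Gauss-Newton minimisation of g over eta.

    Each iteration costs d+1 model evaluations (value + Jacobian); the
    final Jacobian doubles as the Laplace Hessian input.  Returns
    (eta_hat, g_value, blocks_at_opt, converged).
    """
    eta = np.asarray(eta0, dtype=float)
    g0, yb = g_parts(eta)
    if not np.isfinite(g0):
        return eta, g0, yb, False
    converged = False
    for _ in range(maxiter):
        J_blocks = jac(eta, yb)
        grad = _g_gradient(
            [(y, f, J, s) for (y, f, s), J in zip(yb, J_blocks)],
            eta, omega_vec, error_model)
        H = _gn_hessian_from_jac(
            [(f, J, s) for (y, f, s), J in zip(yb, J_blocks)],
            eta_names, omega, error_model)
        try:
            step = -np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        # trust region on the log-scale effects: a |eta| move beyond ~3
        # is far outside any plausible random effect and only arises from
        # near-singular Hessian directions
        biggest = float(np.max(np.abs(step)))
        if biggest > 3.0:
            step *= 3.0 / biggest
        t = 1.0
        improved = False
        while t > 1e-4:
            trial = eta + t * step
            g1, yb1 = g_parts(trial)
            if g1 < g0 - 1e-12:
                improved = True
                break
            t *= 0.5
        if not improved:
            converged = True
            break
        moved = float(np.max(np.abs(t * step)))
        eta, g0, yb = trial, g1, yb1
        if moved < 1e-4:
            converged = True
            break
    return eta, g0, yb, converged


def _subject_ofv(subject, config, omega, sigma_pk, sigma_pd, options,
                 include_pd, warm=None):
    """One subject's Laplace OFV contribution and the eta optimum."""
    eta_names = _eta_layout(subject, omega, include_pd, options)
    d = len(eta_names)

    def g(ev):
        return individual_penalized_nll(
            ev, subject, config, omega, sigma_pk, sigma_pd, options,
            eta_names, include_pd)

    if d == 0:
        return g(np.empty(0)), np.empty(0), eta_names, True
    omega_vec = _omega_vector(eta_names, omega)

    def g_parts(ev):
        pred = []
        val = individual_penalized_nll(
            ev, subject, config, omega, sigma_pk, sigma_pd, options,
            eta_names, include_pd, _pred_out=pred)
        f_pk, f_pd = pred
        blocks = [(subject.pk_y, f_pk, sigma_pk)]
        if include_pd and len(subject.pd_t):
            blocks.append((subject.pd_y, f_pd, sigma_pd))
        return val, blocks

    def jac(ev, blocks):
        f_pk = blocks[0][1]
        f_pd = blocks[1][1] if len(blocks) > 1 else np.empty(0)
        J_pk, J_pd = _jacobians(subject, config, eta_names, ev, options,
                                include_pd, f_pk, f_pd)
        return [J_pk] + ([J_pd] if len(blocks) > 1 else [])

    starts = [np.zeros(d)]
    if warm is not None and len(warm) == d and np.all(np.isfinite(warm)):
        starts.insert(0, np.asarray(warm, dtype=float))
    best = None
    for x0 in starts:
        eta_hat, g_val, yb, ok = _inner_newton(
            g_parts, jac, x0, omega_vec, eta_names, omega,
            options.error_model, options.inner_maxiter)
        if best is None or g_val < best[1]:
            best = (eta_hat, g_val, yb, ok)
        if best[3] and np.isfinite(best[1]):
            break
    eta_hat, g_val, yb, ok = best
    if not np.isfinite(g_val):
        # fall back to a derivative-free search from zero
        res = optimize.minimize(g, np.zeros(d), method="Nelder-Mead",
                                options={"maxiter": 200 * d})
        eta_hat, g_val, ok = res.x, res.fun, res.success
        _, yb = g_parts(eta_hat)
    if options.hessian == "gn":
        J_blocks = jac(eta_hat, yb)
        H = _gn_hessian_from_jac(
            [(f, J, s) for (y, f, s), J in zip(yb, J_blocks)],
            eta_names, omega, options.error_model)
    else:
        H = _fd_hessian(g, eta_hat)
    sign, logdet = np.linalg.slogdet(H / 2.0)
    if sign <= 0:
        H = _fd_hessian(g, eta_hat)
        sign, logdet = np.linalg.slogdet(H / 2.0)
        if sign <= 0:
            return np.inf, eta_hat, eta_names, False
    ofv = g_val - d * np.log(2 * np.pi) + logdet
    return float(ofv), eta_hat, eta_names, bool(ok)


def laplace_marginal_nll(config: ModelConfig, subjects, omega: dict,
                         sigma_pk: float, sigma_pd: float = 0.0,
                         options: EstimationOptions | None = None,
                         include_pd: bool = False,
                         warm_store: dict | None = None) -> float:
    """Total OFV (-2 log marginal likelihood, Laplace) over subjects.

    Additive over independent subjects; subjects whose inner optimisation
    fails are flagged with a warning and contribute +inf, making the
    failure visible to the outer optimizer.
    """
    options = options or EstimationOptions()
    total = 0.0
    for s in subjects:
        warm = warm_store.get(s.sid) if warm_store is not None else None
        ofv, eta_hat, names, ok = _subject_ofv(
            s, config, omega, sigma_pk, sigma_pd, options, include_pd, warm)
        if warm_store is not None:
            warm_store[s.sid] = eta_hat
        if not ok:
            warnings.warn(
                f"inner optimisation unreliable for subject {s.sid}",
                RuntimeWarning, stacklevel=2)
        total += ofv
    return total


@dataclass
class EstimationProblem:
    """Specification of one population fit.

    ``estimate`` / ``estimate_omega`` / ``estimate_sigma`` name the free
    parameters; everything else is fixed at its value in ``config``
    (the FIX mechanism — e.g. the TSP-1 turnover time or rf_solution stay
    at their configured values unless listed).  ``model`` selects the
    likelihood: 'pk' (paclitaxel records) or 'pd' (paclitaxel + TSP-1,
    with sequential-fit semantics handled by :func:`fit_pd_sequential`).
    """

    dataset: StudyDataset
    config: ModelConfig
    estimate: tuple = ("clint0", "vc", "rf_capsule")
    estimate_omega: tuple = ()
    estimate_sigma: tuple = ()
    model: str = "pk"
    options: EstimationOptions = field(default_factory=EstimationOptions)

    def __post_init__(self):
        for n in self.estimate:
            _get_theta(self.config, n)  # raises on unknown names
        for n in self.estimate_omega:
            if n not in _BSV_NAMES + ("bov_rf_gut", "ebase"):
                raise ParameterError(f"unknown omega {n!r}")
        for n in self.estimate_sigma:
            if n not in ("pk", "pd"):
                raise ParameterError(f"unknown sigma {n!r}")
        if self.model not in ("pk", "pd"):
            raise ParameterError("model must be 'pk' or 'pd'")


def _initial_omega(config: ModelConfig) -> dict:
    spec = config.random_effects
    om = {n: spec.omega_bsv(n) for n in _BSV_NAMES}
    om["bov_rf_gut"] = spec.omega_bov_rf_gut
    om["ebase"] = spec.omega_ebase
    return om


@dataclass
class EstimationResult:
    """Fitted population parameters with diagnostics.

    ``theta``/``omega``/``sigma`` are on the natural scale (omegas as SDs
    of the log-scale effects); ``etas`` holds the empirical-Bayes modes at
    the optimum and ``shrinkage`` the eta-shrinkage
    ``100 * (1 - SD(eta_hat)/omega)`` per random effect.
    """

    theta: dict
    omega: dict
    sigma: dict
    ofv: float
    etas: pd.DataFrame
    shrinkage: dict
    config: ModelConfig
    success: bool
    n_subjects: int
    n_obs: int
    nfev: int
    message: str
    model: str = "pk"

    def summary(self) -> str:
        lines = [
            "Population PK/PD fit (Laplace with interaction)",
            f"  model: {self.model}   subjects: {self.n_subjects}   "
            f"observations: {self.n_obs}",
            f"  OFV: {self.ofv:.3f}   converged: {self.success}   "
            f"evaluations: {self.nfev}",
            "",
            f"  {'parameter':<22}{'estimate':>12}",
        ]
        for k, v in self.theta.items():
            lines.append(f"  {k:<22}{v:>12.4g}")
        for k, v in self.omega.items():
            lines.append(f"  omega_{k:<16}{v:>12.4g}")
        for k, v in self.sigma.items():
            lines.append(f"  sigma_{k:<16}{v:>12.4g}")
        if self.shrinkage:
            lines.append("")
            for k, v in self.shrinkage.items():
                lines.append(f"  shrinkage_{k:<12}{v:>11.1f}%")
        return "\n".join(lines)


def fit_population(problem: EstimationProblem) -> EstimationResult:
    """Maximum (approximate marginal) likelihood population fit.

    All free parameters are optimised on the log scale, guaranteeing
    positivity without hard bounds; the fit is deterministic given the
    data and initial values.
    """
    options = problem.options
    include_pd = problem.model == "pd"
    subjects = prepare_subjects(problem.dataset, problem.config, include_pd)
    theta_names = tuple(problem.estimate)
    omega_names = tuple(problem.estimate_omega)
    sigma_names = tuple(problem.estimate_sigma)
    omega0 = _initial_omega(problem.config)
    spec = problem.config.random_effects
    sigma0 = {"pk": spec.sigma_pk, "pd": spec.sigma_pd}
    for n in omega_names:
        if omega0[n] <= 0:
            raise ParameterError(
                f"omega {n!r} is estimated but its initial value is 0")

    x0 = np.log(np.concatenate([
        [_get_theta(problem.config, n) for n in theta_names],
        [omega0[n] for n in omega_names],
        [sigma0[n] for n in sigma_names]]))
    warm: dict = {}
    nt, no = len(theta_names), len(omega_names)

    def unpack(x):
        vals = np.exp(x)
        config = _set_thetas(problem.config,
                             dict(zip(theta_names, vals[:nt])))
        omega = dict(omega0)
        omega.update(dict(zip(omega_names, vals[nt:nt + no])))
        sigma = dict(sigma0)
        sigma.update(dict(zip(sigma_names, vals[nt + no:])))
        return config, omega, sigma

    def objective(x):
        try:
            config, omega, sigma = unpack(x)
        except ParameterError:
            # outside the parameter domain (e.g. clint0 below imax):
            # reject the point and let the optimizer back off
            return np.inf
        return laplace_marginal_nll(config, subjects, omega, sigma["pk"],
                                    sigma["pd"], options, include_pd, warm)

    if len(x0):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={"maxiter": options.maxiter,
                         "xatol": options.xatol, "fatol": options.fatol,
                         "adaptive": True})
        x_hat, success, nfev, message = res.x, bool(res.success), \
            res.nfev, res.message
    else:
        x_hat, success, nfev, message = x0, True, 0, "nothing to estimate"

    config, omega, sigma = unpack(x_hat)
    # final pass for OFV, empirical-Bayes etas and shrinkage
    ofv = 0.0
    eta_rows = []
    for s in subjects:
        o, eta_hat, names, ok = _subject_ofv(
            s, config, omega, sigma["pk"], sigma["pd"], options, include_pd,
            warm.get(s.sid))
        ofv += o
        row = {"ID": s.sid}
        row.update({
            (f"bov_{n[1]}" if isinstance(n, tuple) else n): e
            for n, e in zip(names, eta_hat)})
        eta_rows.append(row)
    etas = pd.DataFrame(eta_rows).set_index("ID") if eta_rows \
        else pd.DataFrame()
    shrinkage = {}
    for name in etas.columns if len(etas) else []:
        om = omega["bov_rf_gut"] if name.startswith("bov_") else omega[name]
        vals = etas[name].dropna().to_numpy()
        if om > 0 and len(vals) > 1:
            shrinkage[name] = float(
                np.clip(100.0 * (1.0 - vals.std(ddof=1) / om), 0.0, 100.0))
    n_obs = sum(len(s.pk_t) + len(s.pd_t) for s in subjects)
    return EstimationResult(
        theta={n: _get_theta(config, n) for n in theta_names},
        omega={n: omega[n] for n in omega_names},
        sigma={n: sigma[n] for n in sigma_names},
        ofv=float(ofv), etas=etas, shrinkage=shrinkage, config=config,
        success=success, n_subjects=len(subjects), n_obs=n_obs,
        nfev=nfev, message=str(message), model=problem.model)


@dataclass(frozen=True)
class LRTResult:
    dofv: float
    df: int
    threshold: float
    significant: bool


def lrt_compare(ofv_full: float, ofv_reduced: float, df: int) -> LRTResult:
    """Likelihood-ratio comparison of nested models at p < 0.01.

    Significant when the OFV drop exceeds the chi-square 0.99 quantile
    (6.63 for 1 df, 9.21 for 2 df).  A negative drop for nested models is
    numerical noise and triggers a warning.
    """
    if df < 1:
        raise InputError("df must be >= 1")
    dofv = ofv_reduced - ofv_full
    if dofv < 0:
        warnings.warn(
            "reduced model has lower OFV than the full model "
            "(numerical noise for nested fits)", UserWarning, stacklevel=2)
    threshold = float(stats.chi2.ppf(0.99, df))
    return LRTResult(dofv=float(dofv), df=df, threshold=threshold,
                     significant=bool(dofv > threshold))


def fit_pd_sequential(pk_result: EstimationResult, dataset: StudyDataset,
                      estimate: tuple = ("ec50", "ebase"),
                      estimate_omega: tuple = ("ebase",),
                      estimate_sigma: tuple = ("pd",),
                      options: EstimationOptions | None = None
                      ) -> EstimationResult:
    """Sequential PK->PD fit with fixed population PK parameters.

    The population PK fixed effects, omegas and residual error are frozen
    at the PK fit's estimates; the subjects' PK random effects are
    re-estimated jointly with the PD parameters using both the paclitaxel
    and TSP-1 records, so PK uncertainty propagates into the individual PD
    drivers.  The TSP-1 turnover time stays fixed unless listed in
    ``estimate``.  Subjects without TSP-1 records contribute PK-only.
    """
    options = options or EstimationOptions()
    n_pd = len(dataset.observations(cmt="tsp1"))
    if n_pd == 0:
        warnings.warn("no TSP-1 observations: returning the PK result "
                      "unchanged", UserWarning, stacklevel=2)
        return pk_result
    problem = EstimationProblem(
        dataset=dataset, config=pk_result.config, estimate=estimate,
        estimate_omega=estimate_omega, estimate_sigma=estimate_sigma,
        model="pd", options=options)
    return fit_population(problem)
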