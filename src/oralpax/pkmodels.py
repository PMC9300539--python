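"""Model equations and ODE solvers for the oral paclitaxel PK/PD system.

The structural model has four paclitaxel compartments: gut (one absorption
clock per dose), a well-stirred liver, central and peripheral.  Absorption
from the gut follows a Weibull time-varying rate; hepatic elimination and
first pass follow the well-stirred liver model with an intrinsic clearance
inhibited by the ritonavir plasma concentration through an Imax/KI
relationship.  Ritonavir itself is a two-compartment model with an
inverse-Gaussian density input, solved first and fed into the paclitaxel
system as a forcing function.  TSP-1 is an indirect-response (turnover)
model whose formation rate is stimulated by paclitaxel plasma
concentration.

Absorption-rate interpretation
------------------------------
The published absorption-rate expression

    w(t) = (BETA/ALPHA) * (t/ALPHA)**(BETA-1) * exp(-(t/ALPHA)**BETA)

is the Weibull probability density.  The default gut model keeps the gut
amount on the Weibull *survival* curve (``dA/dt = -h(t) A`` with ``h`` the
Weibull hazard), so the absorption rate into the liver equals
``amount * w(t)`` exactly and absorption is complete — identical to the
direct-input interpretation ``input = F * Dose * w(t)``.  A literal
``pdf_rate`` variant, which applies ``w`` itself as the rate constant and
therefore leaves a fraction ``exp(-1)`` of each dose unabsorbed, is kept
for comparison (``absorption_mode='pdf_rate'``).

Units: amounts ug, volumes L, concentrations ng/mL (= ug/L), time h.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InputError, IntegrationError, ParameterError
from .params import (MG_TO_UG, IVPaclitaxelParams, PaclitaxelPopParams,
                     PhysioConstants, RitonavirPopParams, TSP1Params)

__all__ = [
    "weibull_absorption_rate",
    "weibull_survival",
    "weibull_hazard",
    "intrinsic_clearance",
    "hepatic_extraction",
    "hepatic_bioavailability",
    "inverse_gaussian_input",
    "kin_stimulation",
    "tsp1_rhs",
    "ritonavir_rhs",
    "oral_paclitaxel_rhs",
    "iv_paclitaxel_rhs",
    "GutDose",
    "Infusion",
    "ConcProfile",
    "solve_ritonavir",
    "solve_oral_paclitaxel",
    "solve_oral_paclitaxel_full",
    "solve_iv_paclitaxel",
    "solve_tsp1",
]

#: default solver tolerances (stiff-capable adaptive integrator)
RTOL = 1e-8
ATOL = 1e-10

# beyond this survival quantile a dose's gut content is treated as exhausted
_EXHAUST_LOGQ = -math.log(1e-12)


def _check_weibull(alpha: float, beta: float) -> None:
    if alpha <= 0 or beta <= 0:
        raise ParameterError(
            f"Weibull parameters must be positive, got alpha={alpha}, "
            f"beta={beta}")


def weibull_absorption_rate(t_since_dose, alpha: float, beta: float):
    """Weibull absorption-rate density ``w(t)`` (1/h).

    ``w(t) = (beta/alpha) (t/alpha)^(beta-1) exp(-(t/alpha)^beta)`` with
    ``t`` the time after the most recent dose.  Returns 0 at ``t = 0`` for
    ``beta > 1`` and reduces to the exponential density for ``beta = 1``.
    """
    _check_weibull(alpha, beta)
    t = np.asarray(t_since_dose, dtype=float)
    if np.any(t < 0):
        raise InputError("t_since_dose must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        x = t / alpha
        out = (beta / alpha) * x ** (beta - 1.0) * np.exp(-(x ** beta))
    out = np.where(t == 0, beta / alpha if beta == 1.0 else
                   (np.inf if beta < 1.0 else 0.0), out)
    return out if out.ndim else float(out)


def weibull_survival(t_since_dose, alpha: float, beta: float):
    """Fraction of a dose still in the gut at ``t`` (``exp(-(t/a)^b)``)."""
    _check_weibull(alpha, beta)
    t = np.asarray(t_since_dose, dtype=float)
    out = np.exp(-((t / alpha) ** beta))
    return out if out.ndim else float(out)


def weibull_hazard(t_since_dose, alpha: float, beta: float):
    """Weibull hazard ``(beta/alpha)(t/alpha)^(beta-1)``, the gut rate
    constant under which the gut amount follows :func:`weibull_survival`."""
    _check_weibull(alpha, beta)
    t = np.asarray(t_since_dose, dtype=float)
    with np.errstate(divide="ignore"):
        out = (beta / alpha) * (t / alpha) ** (beta - 1.0)
    if beta < 1.0:
        out = np.where(t == 0, np.inf, out)
    return out if out.ndim else float(out)


def intrinsic_clearance(c_ritonavir, clint0: float, imax: float, ki: float,
                        floor: bool = True):
    """Ritonavir-inhibited intrinsic clearance, L/h.

    ``CLint = CLint0 - Imax * C/(KI + C)``, monotone non-increasing in the
    ritonavir concentration.  For sampled individuals the expression can go
    negative (``clint0*exp(eta) < imax``); it is floored at zero because a
    negative clearance is unphysical.
    """
    if clint0 <= 0 or imax <= 0 or ki <= 0:
        raise ParameterError("clint0, imax and ki must be positive")
    c = np.asarray(c_ritonavir, dtype=float)
    if np.any(c < 0):
        raise InputError("ritonavir concentration must be >= 0")
    out = clint0 - imax * c / (ki + c)
    if floor:
        if np.any(out < 0):
            warnings.warn(
                "intrinsic clearance went negative and was floored at 0",
                RuntimeWarning, stacklevel=2)
        out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def hepatic_extraction(clint, fu: float, qh: float):
    """Well-stirred-liver extraction ratio ``E_H`` in [0, 1)."""
    if not (0 < fu <= 1):
        raise ParameterError(f"fu must be in (0, 1], got {fu}")
    if qh <= 0:
        raise ParameterError(f"qh must be > 0, got {qh}")
    cl = np.asarray(clint, dtype=float)
    if np.any(cl < 0):
        raise InputError("clint must be >= 0")
    out = cl * fu / (qh + cl * fu)
    return out if out.ndim else float(out)


def hepatic_bioavailability(clint, fu: float, qh: float):
    """Hepatic bioavailability ``F_H = 1 - E_H``."""
    return 1.0 - hepatic_extraction(clint, fu, qh)


def _ig_density(t, mean: float, relvar: float):
    """Inverse-Gaussian density with given mean and relative variance."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.sqrt(mean / (2.0 * np.pi * relvar * tp ** 3)) * np.exp(
        -((tp - mean) ** 2) / (2.0 * relvar * mean * tp))
    return out


def inverse_gaussian_input(t_since_dose, dose: float,
                           params: RitonavirPopParams):
    """Ritonavir input rate (same unit as ``dose`` per hour).

    The rate is ``F * dose * g(t)`` with ``g`` an inverse-Gaussian density
    of mean ``mean_absorption_time`` and relative variance ``input_shape``;
    the density integrates to one so the total input equals ``F * dose``.
    """
    if dose <= 0:
        raise InputError(f"dose must be > 0, got {dose}")
    if params.mean_absorption_time <= 0 or params.input_shape <= 0:
        raise ParameterError("mean_absorption_time and input_shape must be > 0")
    t = np.asarray(t_since_dose, dtype=float)
    if np.any(t < 0):
        raise InputError("t_since_dose must be >= 0")
    out = params.bioavailable_fraction * dose * _ig_density(
        t, params.mean_absorption_time, params.input_shape)
    return out if out.ndim else float(out)


def kin_stimulation(c_paclitaxel, ec50: float):
    """TSP-1 formation-rate multiplier ``1 + C/(EC50 + C)`` in [1, 2)."""
    if ec50 <= 0:
        raise ParameterError(f"ec50 must be > 0, got {ec50}")
    c = np.asarray(c_paclitaxel, dtype=float)
    if np.any(c < 0):
        raise InputError("paclitaxel concentration must be >= 0")
    out = 1.0 + c / (ec50 + c)
    return out if out.ndim else float(out)


def tsp1_rhs(c_tsp1, c_paclitaxel, params: TSP1Params,
             baseline: float | None = None):
    """Turnover-model derivative ``kin0*stim - kout*C``.

    ``baseline`` overrides the population baseline for an individual; the
    zero-order formation rate is tied to it (``kin0 = baseline * kout``) so
    the unstimulated system is stationary at the baseline.
    """
    base = params.baseline if baseline is None else baseline
    kin0 = base * params.kout
    return kin0 * kin_stimulation(c_paclitaxel, params.ec50) \
        - params.kout * np.asarray(c_tsp1, dtype=float)


# ---------------------------------------------------------------------------
# dose/forcing containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GutDose:
    """A dose as it enters the gut: time (h), amount (ug, after relative
    bioavailability), and its Weibull absorption parameters."""

    time: float
    amount_ug: float
    alpha: float
    beta: float

    @property
    def exhaust_time(self) -> float:
        """Time after dosing by which the gut content is numerically gone."""
        return self.alpha * _EXHAUST_LOGQ ** (1.0 / self.beta)


@dataclass(frozen=True)
class Infusion:
    """Zero-order IV input: start (h), total amount (ug), duration (h)."""

    time: float
    amount_ug: float
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InputError("infusion duration must be > 0")
        if self.amount_ug < 0:
            raise InputError("infusion amount (rate) must be >= 0")

    @property
    def rate(self) -> float:
        return self.amount_ug / self.duration


class ConcProfile:
    """A concentration-time curve, callable by linear interpolation."""

    def __init__(self, t: np.ndarray, c: np.ndarray):
        self.t = np.asarray(t, dtype=float)
        self.c = np.asarray(c, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.c.shape:
            raise InputError("profile t and c must be 1-D and equal length")
        if np.any(np.diff(self.t) <= 0):
            raise InputError("profile time grid must be strictly increasing")

    def __call__(self, t):
        return np.interp(t, self.t, self.c, left=self.c[0], right=self.c[-1])

    @classmethod
    def constant(cls, value: float, horizon: float = 1e6) -> "ConcProfile":
        return cls(np.array([0.0, max(horizon, 1.0)]),
                   np.array([value, value]))


def _segment_solve(rhs, y0, breakpoints, t_eval, rtol, atol,
                   events_context="model", t_start: float = 0.0):
    """Integrate from ``t_start`` piecewise between breakpoints, returning
    states at ``t_eval`` (sorted, all >= ``t_start``).

    Dose/infusion start and stop times must appear among ``breakpoints`` so
    the adaptive solver never steps over an input discontinuity.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    if len(t_eval) == 0:
        return np.empty((0, len(y0)))
    if t_eval[0] < t_start:
        raise InputError(
            f"{events_context}: t_eval starts before t={t_start}")
    t_end = t_eval[-1]
    bps = np.asarray(breakpoints, dtype=float)
    bps = np.unique(np.concatenate(
        [bps[(bps > t_start) & (bps < t_end)], [t_start, t_end]]))
    y = np.array(y0, dtype=float)
    out = np.empty((len(t_eval), len(y)))
    filled = t_eval == t_start
    out[filled] = y
    for a, b in zip(bps[:-1], bps[1:]):
        inside = (t_eval > a) & (t_eval <= b)
        te = np.unique(np.concatenate([t_eval[inside], [b]]))
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=te,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"{events_context}: solver failed in [{a}, {b}] h "
                f"(state {y.tolist()}): {sol.message}")
        for j, tj in enumerate(sol.t):
            sel = inside & (t_eval == tj)
            out[sel] = sol.y[:, j]
            filled |= sel
        y = sol.y[:, -1]
    return out


# ---------------------------------------------------------------------------
# ritonavir
# ---------------------------------------------------------------------------

def ritonavir_rhs(state, t: float, params: RitonavirPopParams,
                  doses: Sequence) -> np.ndarray:
    """Two-compartment ritonavir dynamics with IG input.

    ``state = [A_c, A_p]`` in ug; ``doses`` is a sequence of objects with
    ``time`` (h) and ``amount`` (mg).  Concentration in ng/mL is
    ``A_c / Vc`` (amounts kept in ug, so no further factor).
    """
    a_c, a_p = state
    inp = 0.0
    for d in doses:
        dt = t - d.time
        if dt > 0:
            inp += MG_TO_UG * inverse_gaussian_input(dt, d.amount, params)
    cl, vc, q, vp = (params.clearance, params.vc, params.q_inter, params.vp)
    dc = inp - (cl / vc) * a_c - (q / vc) * a_c + (q / vp) * a_p
    dp = (q / vc) * a_c - (q / vp) * a_p
    return np.array([dc, dp])


_RTV_CACHE: dict = {}


def solve_ritonavir(doses: Sequence, params: RitonavirPopParams,
                    horizon: float, grid_step: float = 0.05,
                    rtol: float = RTOL, atol: float = ATOL) -> ConcProfile:
    """Solve ritonavir PK and return the plasma profile (ng/mL).

    ``doses`` carry ``time`` h and ``amount`` mg.  The profile covers
    ``[0, horizon]`` on a uniform grid of ``grid_step`` h plus dose times.
    Profiles are cached on (regimen, parameters): the inhibitor model is
    fixed configuration, and study designs repeat the same ritonavir
    schedule across many subjects.
    """
    if not doses:
        return ConcProfile.constant(0.0, max(horizon, 1.0))
    key = (tuple((d.time, d.amount) for d in doses), params,
           round(horizon, 9), grid_step, rtol, atol)
    hit = _RTV_CACHE.get(key)
    if hit is not None:
        return hit
    t_grid = np.unique(np.concatenate([
        np.arange(0.0, horizon + grid_step / 2, grid_step),
        [d.time for d in doses], [horizon]]))
    t_grid = t_grid[t_grid <= horizon + 1e-12]
    t_d = np.array([d.time for d in doses])
    amt_ug = np.array([d.amount for d in doses]) * MG_TO_UG \
        * params.bioavailable_fraction
    mat, shape = params.mean_absorption_time, params.input_shape
    cutoff = 48.0 + 10.0 * mat  # IG density is numerically zero beyond
    cl, vc, q, vp = (params.clearance, params.vc, params.q_inter,
                     params.vp)

    def rhs(t, y):
        dt = t - t_d
        m = (dt > 0.0) & (dt < cutoff)
        inp = float(np.sum(amt_ug[m] * _ig_density(dt[m], mat, shape))) \
            if np.any(m) else 0.0
        a_c, a_p = y
        return [inp - (cl / vc) * a_c - (q / vc) * a_c + (q / vp) * a_p,
                (q / vc) * a_c - (q / vp) * a_p]

    states = _segment_solve(rhs, [0.0, 0.0], t_d, t_grid, rtol, atol,
                            "ritonavir PK")
    profile = ConcProfile(t_grid, np.maximum(states[:, 0] / params.vc, 0.0))
    if len(_RTV_CACHE) > 64:
        _RTV_CACHE.clear()
    _RTV_CACHE[key] = profile
    return profile


# ---------------------------------------------------------------------------
# oral paclitaxel
# ---------------------------------------------------------------------------

def oral_paclitaxel_rhs(state, t: float, params: PaclitaxelPopParams,
                        physio: PhysioConstants,
                        c_ritonavir_fn: Callable,
                        active_doses: Sequence[GutDose],
                        absorption_mode: str = "rate") -> np.ndarray:
    """Full-state oral paclitaxel dynamics.

    ``state = [gut_1..gut_m, A_H, A_c, A_p]`` (ug) with one gut slot per
    dose in ``active_doses`` (each with its own absorption clock).  The
    liver balance is ``sum_d input_d + Q_H (C_c - C_H) - fu CLint(t) C_H``
    with ``C_x = A_x / V_x``; central and peripheral exchange via the
    inter-compartmental clearance Q, and hepatic outflow returns to the
    central compartment.
    """
    m = len(active_doses)
    gut = np.asarray(state[:m], dtype=float)
    a_h, a_c, a_p = state[m], state[m + 1], state[m + 2]
    absorbed = 0.0
    dgut = np.zeros(m)
    for i, d in enumerate(active_doses):
        dt = t - d.time
        if dt <= 0:
            continue
        if absorption_mode == "rate":
            k = weibull_hazard(dt, d.alpha, d.beta)
            flux = min(k, 1e6) * gut[i]
            dgut[i] = -flux
        elif absorption_mode == "pdf_rate":
            k = weibull_absorption_rate(dt, d.alpha, d.beta)
            flux = k * gut[i]
            dgut[i] = -flux
        elif absorption_mode == "input":
            flux = d.amount_ug * weibull_absorption_rate(dt, d.alpha, d.beta)
            dgut[i] = -flux
        else:
            raise InputError(f"unknown absorption_mode {absorption_mode!r}")
        absorbed += flux
    c_rtv = float(np.asarray(c_ritonavir_fn(t)))
    clint = intrinsic_clearance(c_rtv, params.clint0, params.imax, params.ki)
    qh, vh, fu = (physio.hepatic_blood_flow, physio.liver_volume,
                  physio.fraction_unbound)
    c_h = a_h / vh
    c_c = a_c / params.vc
    c_p = a_p / params.vp
    da_h = absorbed + qh * (c_c - c_h) - fu * clint * c_h
    da_c = qh * (c_h - c_c) - params.q * (c_c - c_p)
    da_p = params.q * (c_c - c_p)
    return np.concatenate([dgut, [da_h, da_c, da_p]])


def solve_oral_paclitaxel_full(gut_doses: Sequence[GutDose],
                               params: PaclitaxelPopParams,
                               physio: PhysioConstants,
                               c_ritonavir_fn: Callable,
                               t_eval,
                               absorption_mode: str = "rate",
                               rtol: float = RTOL, atol: float = ATOL):
    """Reference solver carrying explicit per-dose gut states.

    Returns ``(conc_central ng/mL, states)`` where states has columns
    ``gut_1..gut_m, A_H, A_c, A_p``.  Slower than
    :func:`solve_oral_paclitaxel`; used for cross-checks and for the
    literal ``pdf_rate`` absorption variant.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    m = len(gut_doses)
    y0 = np.zeros(m + 3)
    bps = sorted({d.time for d in gut_doses})

    def rhs(t, y):
        dy = oral_paclitaxel_rhs(y, t, params, physio, c_ritonavir_fn,
                                 gut_doses, absorption_mode)
        return dy

    # integrate segment by segment, adding each dose to its gut slot
    all_bp = np.unique(np.concatenate([bps, t_eval[[0, -1]]]))
    out = np.empty((len(t_eval), m + 3))
    filled = np.zeros(len(t_eval), dtype=bool)
    y = y0.copy()
    t_cur = min(t_eval[0], all_bp[0]) if len(t_eval) else all_bp[0]
    sel0 = t_eval == t_cur
    segs = [b for b in all_bp if b > t_cur] + (
        [t_eval[-1]] if len(t_eval) and t_eval[-1] > all_bp[-1] else [])
    for i, d in enumerate(gut_doses):
        if d.time <= t_cur:
            y[i] += d.amount_ug
    out[sel0] = y
    filled |= sel0
    for b in np.unique(segs):
        inside = (t_eval > t_cur) & (t_eval <= b) & ~filled
        pts = np.unique(np.concatenate([t_eval[inside], [b]]))
        sol = solve_ivp(rhs, (t_cur, b), y, method="LSODA", t_eval=pts,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"oral paclitaxel PK: solver failed at t={t_cur}: "
                f"{sol.message}")
        for j, tj in enumerate(sol.t):
            sel = inside & (t_eval == tj)
            out[sel] = sol.y[:, j]
            filled |= sel
        y = sol.y[:, -1]
        for i, d in enumerate(gut_doses):
            if d.time == b:
                y[i] += d.amount_ug
        t_cur = b
    conc = out[:, m + 1] / params.vc
    return np.maximum(conc, 0.0), out


def _absorption_input(t, gut_doses: Sequence[GutDose],
                      t_d, a_d, al_d, be_d, cut_d):
    """Total absorption flux into the liver at time(s) t, ug/h."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    total = np.zeros_like(t)
    for td, ad, al, be, cu in zip(t_d, a_d, al_d, be_d, cut_d):
        dt = t - td
        m = (dt > 0) & (dt < cu)
        if np.any(m):
            x = dt[m] / al
            total[m] += ad * (be / al) * x ** (be - 1.0) * np.exp(-x ** be)
    return total


def solve_oral_paclitaxel(gut_doses: Sequence[GutDose],
                          params: PaclitaxelPopParams,
                          physio: PhysioConstants,
                          c_ritonavir_fn: Callable,
                          t_eval,
                          rtol: float = RTOL, atol: float = ATOL,
                          return_states: bool = False):
    """Fast oral paclitaxel solver (default absorption interpretation).

    Because the gut states are autonomous, their trajectories are known in
    closed form (``amount * Weibull survival``) and the absorption flux
    ``sum_d amount_d * w_d(t - t_d)`` enters the 3-state
    liver/central/peripheral system as a forcing function.  This is exact
    for both the 'rate' (hazard) and 'input' interpretations, which
    coincide.  Returns central-compartment concentrations (ng/mL) at
    ``t_eval``; with ``return_states`` also the [A_H, A_c, A_p] states.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    if len(gut_doses) == 0:
        z = np.zeros(len(t_eval))
        return (z, np.zeros((len(t_eval), 3))) if return_states else z
    t_d = np.array([d.time for d in gut_doses])
    a_d = np.array([d.amount_ug for d in gut_doses])
    al_d = np.array([d.alpha for d in gut_doses])
    be_d = np.array([d.beta for d in gut_doses])
    cut_d = np.array([d.exhaust_time for d in gut_doses])

    qh, vh, fu = (physio.hepatic_blood_flow, physio.liver_volume,
                  physio.fraction_unbound)
    vc, q, vp = params.vc, params.q, params.vp
    clint0, imax, ki = params.clint0, params.imax, params.ki

    def rhs(t, y):
        a_h, a_c, a_p = y
        inp = _absorption_input(t, gut_doses, t_d, a_d, al_d, be_d, cut_d)[0]
        c_rtv = float(np.asarray(c_ritonavir_fn(t)))
        clint = max(clint0 - imax * c_rtv / (ki + c_rtv), 0.0)
        c_h = a_h / vh
        c_c = a_c / vc
        c_p = a_p / vp
        return np.array([
            inp + qh * (c_c - c_h) - fu * clint * c_h,
            qh * (c_h - c_c) - q * (c_c - c_p),
            q * (c_c - c_p),
        ])

    states = _segment_solve(rhs, [0.0, 0.0, 0.0], t_d, t_eval, rtol, atol,
                            "oral paclitaxel PK")
    conc = np.maximum(states[:, 1] / vc, 0.0)
    return (conc, states) if return_states else conc


# ---------------------------------------------------------------------------
# IV paclitaxel plug-in
# ---------------------------------------------------------------------------

def iv_paclitaxel_rhs(state, t: float, params: IVPaclitaxelParams,
                      infusions: Sequence[Infusion]) -> np.ndarray:
    """Three-compartment mamillary IV model with zero-order infusions.

    ``state = [A_c, A_2, A_3]`` ug.  Overlapping infusions are additive.
    Elimination from the central compartment is linear (``CL * C``) or
    saturable (``vmax * C/(km + C)``) depending on the parameter mode.
    """
    a_c, a_2, a_3 = state
    rate = sum(inf.rate for inf in infusions
               if inf.time < t <= inf.time + inf.duration)
    c_c = a_c / params.vc
    c_2 = a_2 / params.v2
    c_3 = a_3 / params.v3
    if params.elimination == "linear":
        elim = params.cl * c_c
    else:
        elim = params.vmax * c_c / (params.km + c_c)
    d_c = rate - elim - params.q2 * (c_c - c_2) - params.q3 * (c_c - c_3)
    d_2 = params.q2 * (c_c - c_2)
    d_3 = params.q3 * (c_c - c_3)
    return np.array([d_c, d_2, d_3])


def solve_iv_paclitaxel(infusions: Sequence[Infusion],
                        params: IVPaclitaxelParams, t_eval,
                        rtol: float = RTOL, atol: float = ATOL) -> np.ndarray:
    """Central-compartment IV paclitaxel concentrations (ng/mL) at t_eval."""
    t_eval = np.asarray(t_eval, dtype=float)
    if len(infusions) == 0:
        return np.zeros(len(t_eval))
    bps = sorted({inf.time for inf in infusions}
                 | {inf.time + inf.duration for inf in infusions})

    def rhs(t, y):
        return iv_paclitaxel_rhs(y, t, params, infusions)

    states = _segment_solve(rhs, [0.0, 0.0, 0.0], bps, t_eval, rtol, atol,
                            "IV paclitaxel PK")
    return np.maximum(states[:, 0] / params.vc, 0.0)


# ---------------------------------------------------------------------------
# TSP-1 turnover
# ---------------------------------------------------------------------------

def solve_tsp1(c_paclitaxel_fn: Callable, params: TSP1Params, t_eval,
               baseline: float | None = None,
               rtol: float = RTOL, atol: float = ATOL) -> np.ndarray:
    """TSP-1 trajectory under a paclitaxel concentration driver.

    Starts at the (individual) baseline, which is also the steady state of
    the unstimulated system.  Returns values at ``t_eval`` in
    ng/mL/10^6 platelets.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    base = params.baseline if baseline is None else baseline
    if base <= 0:
        raise ParameterError("baseline must be > 0")

    def rhs(t, y):
        c = float(np.asarray(c_paclitaxel_fn(t)))
        return np.atleast_1d(tsp1_rhs(y[0], max(c, 0.0), params, base))

    states = _segment_solve(rhs, [base], [t_eval[0], t_eval[-1]], t_eval,
                            rtol, atol, "TSP-1 turnover")
    return states[:, 0]
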