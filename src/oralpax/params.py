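"""Parameter containers for the oral paclitaxel / ritonavir / TSP-1 model.

All containers are plain dataclasses validated on construction.  Unit
conventions used throughout the package:

* amounts in micrograms (ug), volumes in litres (L),
* concentrations in ng/mL, which equals ug/L, so ``C = A_ug / V_L``
  without any further conversion factor,
* times in hours; clearances and flows in L/h,
* TSP-1 in ng/mL per 10^6 platelets (platelet-normalised).

Doses are specified in mg at the interface and converted to ug
(``mg * 1000``) when they enter the ODE systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace, asdict
from importlib import resources
from typing import Literal

import yaml

from .errors import ParameterError

MG_TO_UG = 1000.0

__all__ = [
    "PhysioConstants",
    "PaclitaxelPopParams",
    "DispositionParams",
    "RitonavirPopParams",
    "IVPaclitaxelParams",
    "TSP1Params",
    "RandomEffectsSpec",
    "ModelConfig",
    "cv_to_omega",
    "load_config",
    "save_config",
    "default_config",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


def cv_to_omega(cv_percent: float, exact: bool = False) -> float:
    """Convert a reported CV% to a random-effect standard deviation omega.

    The default is the first-order reporting convention ``omega = CV/100``
    under which a 25.1 CV% is an omega of 0.251.  With ``exact=True`` the
    lognormal moment relation ``omega = sqrt(log(1 + (CV/100)^2))`` is used
    instead.
    """
    _require(cv_percent >= 0, f"CV% must be nonnegative, got {cv_percent}")
    frac = cv_percent / 100.0
    if exact:
        return math.sqrt(math.log1p(frac * frac))
    return frac


@dataclass(frozen=True)
class PhysioConstants:
    """Fixed physiological constants of the well-stirred liver model.

    hepatic_blood_flow
        Q_H, hepatic blood flow in L/h (fixed at 80 L/h).
    liver_volume
        V_H, liver compartment volume in L (fixed at 1 L).
    fraction_unbound
        fu, unbound fraction of paclitaxel in plasma (0.13).
    """

    hepatic_blood_flow: float = 80.0
    liver_volume: float = 1.0
    fraction_unbound: float = 0.13

    def __post_init__(self) -> None:
        _require(self.hepatic_blood_flow > 0, "hepatic_blood_flow must be > 0")
        _require(self.liver_volume > 0, "liver_volume must be > 0")
        _require(
            0 < self.fraction_unbound <= 1,
            f"fraction_unbound must be in (0, 1], got {self.fraction_unbound}",
        )


@dataclass(frozen=True)
class PaclitaxelPopParams:
    """Population (typical-value) parameters of the oral paclitaxel PK model.

    Absorption follows a Weibull time-varying rate with scale ALPHA (h),
    selected by daily-dose index, and shape BETA, selected by formulation.
    Disposition is a central + one peripheral compartment behind a
    well-stirred liver whose intrinsic clearance is inhibited by ritonavir
    through an Imax/KI relationship.  Relative gut bioavailabilities are
    expressed against the drinking solution (rf_solution fixed at 1).
    """

    alpha_first_dose: float = 1.68
    alpha_second_dose: float = 1.97
    beta_solution: float = 2.53
    beta_asd: float = 3.57
    clint0: float = 746.0
    ki: float = 375.0
    imax: float = 570.0
    vc: float = 128.0
    q: float = 33.4
    vp: float = 375.0
    rf_solution: float = 1.0
    rf_tablet: float = 0.97
    rf_capsule: float = 0.46
    rf_second_over_first: float = 0.59

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _require(v > 0, f"{f.name} must be > 0, got {v}")
        for name in ("rf_solution", "rf_tablet", "rf_capsule",
                     "rf_second_over_first"):
            v = getattr(self, name)
            _require(0 < v <= 2, f"{name} must be in (0, 2], got {v}")
        _require(
            self.imax <= self.clint0,
            f"imax ({self.imax}) must not exceed clint0 ({self.clint0}); "
            "the typical intrinsic clearance would go negative",
        )

    def alpha_for(self, daily_dose_index: str) -> float:
        if daily_dose_index == "first":
            return self.alpha_first_dose
        if daily_dose_index == "second":
            return self.alpha_second_dose
        raise ParameterError(f"unknown daily dose index {daily_dose_index!r}")

    def beta_for(self, formulation: str) -> float:
        if formulation == "solution":
            return self.beta_solution
        if formulation in ("tablet", "capsule"):
            return self.beta_asd
        raise ParameterError(f"unknown oral formulation {formulation!r}")

    def rf_for(self, formulation: str, daily_dose_index: str) -> float:
        base = {
            "solution": self.rf_solution,
            "tablet": self.rf_tablet,
            "capsule": self.rf_capsule,
        }.get(formulation)
        if base is None:
            raise ParameterError(f"unknown oral formulation {formulation!r}")
        if daily_dose_index == "second":
            return base * self.rf_second_over_first
        return base


@dataclass(frozen=True)
class RitonavirPopParams:
    """Two-compartment ritonavir PK with inverse-Gaussian density input.

    ``input_shape`` is the relative variance of the inverse-Gaussian input
    density (variance of absorption time divided by the squared mean
    absorption time); the density integrates to one so the total amount
    entering the central compartment is ``bioavailable_fraction * dose``.
    """

    clearance: float
    vc: float
    q_inter: float
    vp: float
    bioavailable_fraction: float = 1.0
    mean_absorption_time: float = 1.2
    input_shape: float = 0.4

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _require(v > 0, f"{f.name} must be > 0, got {v}")
        _require(
            self.bioavailable_fraction <= 1,
            "bioavailable_fraction must be in (0, 1]",
        )


@dataclass(frozen=True)
class IVPaclitaxelParams:
    """Three-compartment mamillary IV paclitaxel model (plug-in).

    Elimination from the central compartment is either linear (``cl`` L/h)
    or saturable Michaelis-Menten (``vmax`` ug/h, ``km`` ng/mL), selected
    by ``elimination``; exactly the parameters of the active mode are used.
    """

    vc: float
    v2: float
    v3: float
    q2: float
    q3: float
    elimination: Literal["linear", "saturable"] = "linear"
    cl: float | None = None
    vmax: float | None = None
    km: float | None = None

    def __post_init__(self) -> None:
        for name in ("vc", "v2", "v3", "q2", "q3"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        if self.elimination == "linear":
            _require(self.cl is not None and self.cl > 0,
                     "linear elimination requires cl > 0")
        elif self.elimination == "saturable":
            _require(self.vmax is not None and self.vmax > 0,
                     "saturable elimination requires vmax > 0")
            _require(self.km is not None and self.km > 0,
                     "saturable elimination requires km > 0")
        else:
            raise ParameterError(
                f"elimination must be 'linear' or 'saturable', "
                f"got {self.elimination!r}"
            )


@dataclass(frozen=True)
class TSP1Params:
    """Turnover (indirect response) model for platelet-normalised TSP-1.

    The system is initialised at steady state, so the zero-order formation
    rate is tied to the baseline: ``kin0 = baseline * kout`` with
    ``kout = 1 / turnover_time``.  Paclitaxel stimulates formation through
    ``kin = kin0 * (1 + C/(EC50 + C))`` (implicit Emax of 1, so TSP-1 can
    at most double).
    """

    ec50: float = 284.0
    baseline: float = 43.8
    turnover_time: float = 233.0

    def __post_init__(self) -> None:
        _require(self.ec50 > 0, "ec50 must be > 0")
        _require(self.baseline > 0, "baseline must be > 0")
        _require(self.turnover_time > 0, "turnover_time must be > 0")

    @property
    def kout(self) -> float:
        """First-order loss rate constant, 1/h."""
        return 1.0 / self.turnover_time

    @property
    def kin0(self) -> float:
        """Baseline zero-order formation rate; equals baseline * kout."""
        return self.baseline * self.kout


@dataclass(frozen=True)
class DispositionParams:
    """Disposition block of one (possibly individual) paclitaxel model.

    Unlike :class:`PaclitaxelPopParams` this carries no typical-value
    constraint between ``imax`` and ``clint0``: sampled individuals can
    have ``clint0 * exp(eta) < imax`` and rely on the clearance floor.
    """

    clint0: float
    ki: float
    imax: float
    vc: float
    q: float
    vp: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) > 0,
                     f"{f.name} must be > 0, got {getattr(self, f.name)}")


#: parameters that carry between-subject variability in the PK layer
PK_BSV_PARAMS = ("alpha", "clint0", "vc", "rf_gut")


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Variance components (as CV%) and proportional residual errors.

    ``bsv_cv`` maps PK parameter names (``alpha``, ``clint0``, ``vc``,
    ``rf_gut``) to between-subject CV%; ``bov_cv_rf_gut`` is the
    between-occasion CV% on relative gut bioavailability (each dose
    administration is an occasion).  ``sigma_prop_pk`` / ``sigma_prop_pd``
    are the proportional residual-error SDs (as CV%) of the paclitaxel and
    TSP-1 observation layers; ``bsv_ebase_cv`` is the BSV on the TSP-1
    baseline.  Conversion CV% -> omega follows :func:`cv_to_omega`.
    """

    bsv_cv: dict = field(default_factory=lambda: {
        "alpha": 35.1, "clint0": 25.1, "vc": 53.8, "rf_gut": 38.2,
    })
    bov_cv_rf_gut: float = 45.8
    sigma_prop_pk: float = 25.8
    bsv_ebase_cv: float = 28.2
    sigma_prop_pd: float = 13.8
    exact_lognormal: bool = False

    def __post_init__(self) -> None:
        for name, cv in self.bsv_cv.items():
            _require(name in PK_BSV_PARAMS,
                     f"unknown BSV parameter {name!r}")
            _require(cv >= 0, f"BSV CV% for {name} must be >= 0")
        for name in ("bov_cv_rf_gut", "sigma_prop_pk", "bsv_ebase_cv",
                     "sigma_prop_pd"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")

    def omega_bsv(self, name: str) -> float:
        return cv_to_omega(self.bsv_cv.get(name, 0.0), self.exact_lognormal)

    @property
    def omega_bov_rf_gut(self) -> float:
        return cv_to_omega(self.bov_cv_rf_gut, self.exact_lognormal)

    @property
    def sigma_pk(self) -> float:
        """Proportional residual SD for paclitaxel observations."""
        return self.sigma_prop_pk / 100.0

    @property
    def sigma_pd(self) -> float:
        return self.sigma_prop_pd / 100.0

    @property
    def omega_ebase(self) -> float:
        return cv_to_omega(self.bsv_ebase_cv, self.exact_lognormal)


@dataclass(frozen=True)
class ModelConfig:
    """Bundle of all parameter blocks read from one configuration file."""

    paclitaxel: PaclitaxelPopParams
    physio: PhysioConstants
    tsp1: TSP1Params
    random_effects: RandomEffectsSpec
    ritonavir: RitonavirPopParams | None = None
    iv_paclitaxel: IVPaclitaxelParams | None = None

    def replace(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


_BLOCK_TYPES = {
    "paclitaxel": PaclitaxelPopParams,
    "physio": PhysioConstants,
    "tsp1": TSP1Params,
    "random_effects": RandomEffectsSpec,
    "ritonavir": RitonavirPopParams,
    "iv_paclitaxel": IVPaclitaxelParams,
}


def _config_from_mapping(data: dict) -> ModelConfig:
    if not isinstance(data, dict):
        raise ParameterError("configuration root must be a mapping")
    kwargs = {}
    for block, cls in _BLOCK_TYPES.items():
        if block in data and data[block] is not None:
            raw = dict(data[block])
            try:
                kwargs[block] = cls(**raw)
            except TypeError as exc:
                raise ParameterError(f"config block {block!r}: {exc}") from exc
    for required in ("paclitaxel", "physio", "tsp1", "random_effects"):
        if required not in kwargs:
            kwargs[required] = _BLOCK_TYPES[required]()
    return ModelConfig(**kwargs)


def load_config(path) -> ModelConfig:
    """Read a YAML parameter configuration into a :class:`ModelConfig`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _config_from_mapping(data or {})


def save_config(config: ModelConfig, path) -> None:
    data = {}
    for block in _BLOCK_TYPES:
        value = getattr(config, block)
        if value is not None:
            data[block] = asdict(value)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def default_config() -> ModelConfig:
    """The packaged default configuration.

    The ``paclitaxel``, ``physio``, ``tsp1`` and ``random_effects`` blocks
    carry the published population estimates; the ``ritonavir`` and
    ``iv_paclitaxel`` blocks are synthetic plausible values standing in for
    external literature models and are meant to be replaced by the user.
    """
    ref = resources.files("oralpax") / "config" / "default_params.yaml"
    with resources.as_file(ref) as path:
        return load_config(path)
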