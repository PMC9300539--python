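"""Virtual trials with the statistical structure the analysis assumes.

Three study templates are provided, mirroring the designs the model was
developed on:

``study1``
    proof of concept: a single 100 mg paclitaxel drinking-solution dose
    with ritonavir given 30 min before (100 or 200 mg, alternating over
    subjects), rich sampling over 24 h; 17 subjects.
``study2``
    randomized crossover: 30 mg once weekly over two weeks, drinking
    solution one week and capsule the other (order alternating over
    subjects), ritonavir 100 mg 30 min before each dose.
``study3``
    low-dose metronomic dose escalation: twice-daily dosing with a 7-h
    interval, capsule daily doses 5-40 mg or tablet 40-60 mg (subjects
    spread over the nine dose levels), ritonavir 100 mg with each
    paclitaxel dose (200 mg/day, split evenly because only the daily
    total is on record); TSP-1 sampled on days 1, 2 and 8 of cycle 1 and
    day 1 of cycles 2 and 3; 37 subjects.

Exact per-study sampling times are not on public record; the templates
use a rich 0-24 h grid after the first daily dose (a fixture convention
chosen to resolve the ~2 h absorption peak).  Generated datasets carry
the full truth (population parameters and each subject's realised etas)
in a sidecar mapping for parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import pkmodels as pkm
from .errors import InputError
from .params import ModelConfig
from .simulate import (IndividualParams, apply_residual_error,
                       gut_doses_for, paclitaxel_concentrations,
                       sample_individual)
from ._fast import tsp1_fast
from .trial import Regimen, RegimenDesign, StudyDataset, build_regimen

__all__ = ["TrialDesignSpec", "generate_trial", "generate_pd_observations",
           "DEFAULT_PK_GRID", "CAPSULE_DAILY_DOSES", "TABLET_DAILY_DOSES"]

#: rich post-dose sampling grid (h), resolving the ~2 h absorption peak
DEFAULT_PK_GRID = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0,
                   10.0, 24.0)
CAPSULE_DAILY_DOSES = (5.0, 10.0, 15.0, 20.0, 30.0, 40.0)
TABLET_DAILY_DOSES = (40.0, 50.0, 60.0)
#: TSP-1 sampling days (1-based): cycle 1 days 1/2/8, day 1 of cycles 2-3
DEFAULT_PD_DAYS = (1, 2, 8, 22, 43)


@dataclass(frozen=True)
class TrialDesignSpec:
    """Declarative description of a virtual trial.

    For templated studies the dose levels are the studied ones; ``custom``
    uses ``custom_designs`` (one :class:`~oralpax.trial.RegimenDesign` per
    subject, cycled).  ``n_days`` limits the dosing duration of study-3
    style regimens; ``pd_sampling_days`` are 1-based calendar days whose
    pre-first-dose time carries a TSP-1 sample (empty: no PD records).
    ``ritonavir_sampled_fraction`` is the fraction of subjects whose
    ritonavir plasma is sampled on the PK grid (the rest carry only
    ritonavir dose records, as when inhibitor PK is imputed from fixed
    effects).
    """

    template: str = "study3"
    n_subjects: int = 37
    n_days: int = 21
    pk_sampling_grid: tuple = DEFAULT_PK_GRID
    pd_sampling_days: tuple = DEFAULT_PD_DAYS
    ritonavir_sampled_fraction: float = 0.0
    custom_designs: tuple = ()

    def __post_init__(self):
        if self.template not in ("study1", "study2", "study3", "custom"):
            raise InputError(f"unknown template {self.template!r}")
        if self.n_subjects < 1:
            raise InputError("n_subjects must be > 0")
        if not 0 <= self.ritonavir_sampled_fraction <= 1:
            raise InputError("ritonavir_sampled_fraction must be in [0,1]")
        if self.template == "custom" and not self.custom_designs:
            raise InputError("custom template needs custom_designs")


def _subject_design(spec: TrialDesignSpec, i: int) -> RegimenDesign:
    grid = tuple(spec.pk_sampling_grid)
    if spec.template == "study1":
        # sampling grid is relative to the paclitaxel dose, which follows
        # the ritonavir lead
        return RegimenDesign(
            formulation="solution", daily_dose_mg=100.0, doses_per_day=1,
            n_days=1, ritonavir_dose_mg=100.0 if i % 2 == 0 else 200.0,
            ritonavir_lead_h=0.5,
            observation_times=tuple(0.5 + t for t in grid))
    if spec.template == "study2":
        first = "solution" if i % 2 == 0 else "capsule"
        obs = tuple(0.5 + t for t in grid) \
            + tuple(168.5 + t for t in grid)
        return RegimenDesign(
            formulation=first, daily_dose_mg=30.0, doses_per_day=1,
            n_days=8, dose_days=(0, 7), ritonavir_dose_mg=100.0,
            ritonavir_lead_h=0.5, observation_times=obs)
    if spec.template == "study3":
        levels = [("capsule", d) for d in CAPSULE_DAILY_DOSES] + \
            [("tablet", d) for d in TABLET_DAILY_DOSES]
        form, daily = levels[i % len(levels)]
        return RegimenDesign(
            formulation=form, daily_dose_mg=daily, doses_per_day=2,
            second_dose_interval_h=7.0, n_days=spec.n_days,
            ritonavir_dose_mg=100.0, ritonavir_lead_h=0.0,
            observation_times=grid)
    return spec.custom_designs[i % len(spec.custom_designs)]


def _study2_regimen(design: RegimenDesign, i: int) -> Regimen:
    """Crossover: week-1 formulation from the design, the other in week 2."""
    reg = build_regimen(design)
    other = "capsule" if design.formulation == "solution" else "solution"
    pac = []
    for d in reg.paclitaxel:
        if d.time >= 168.0 - 1e-9:
            d = type(d)(time=d.time, amount=d.amount, route=d.route,
                        formulation=other,
                        daily_dose_index=d.daily_dose_index,
                        occasion=d.occasion)
        pac.append(d)
    return Regimen(paclitaxel=tuple(pac), ritonavir=reg.ritonavir,
                   observation_times=reg.observation_times)


def _pd_times(spec: TrialDesignSpec) -> np.ndarray:
    return np.array(sorted(24.0 * (np.asarray(spec.pd_sampling_days) - 1)))


def generate_trial(spec: TrialDesignSpec, config: ModelConfig, seed=None
                   ) -> tuple[StudyDataset, dict]:
    """Simulate one virtual trial; returns (dataset, truth-sidecar).

    Per subject: BSV etas (and one BOV eta per dosing occasion) are drawn,
    the PK/PD system is simulated at the subject's realised parameters,
    and proportional residual error is applied at the design's sampling
    times.  Deterministic given the seed.  The sidecar carries the
    generating parameter values and every subject's eta draws.
    """
    rng = np.random.default_rng(seed)
    spec_err = config.random_effects
    rows: list[dict] = []
    truth_subjects = {}
    pd_times = _pd_times(spec) if len(spec.pd_sampling_days) else \
        np.empty(0)
    for i in range(spec.n_subjects):
        sid = i + 1
        design = _subject_design(spec, i)
        regimen = (_study2_regimen(design, i) if spec.template == "study2"
                   else build_regimen(design))
        occasions = sorted({d.occasion for d in regimen.paclitaxel})
        ind = sample_individual(config, occasions, rng)
        truth_subjects[str(sid)] = {k: float(v) for k, v in ind.etas.items()}
        obs_t = np.asarray(sorted(set(regimen.observation_times)))
        pd_t = pd_times[pd_times <= max(regimen.horizon, 0) + 24.0] \
            if len(pd_times) else np.empty(0)
        horizon = max([regimen.horizon, *obs_t[-1:],
                       *(pd_t[-1:] if len(pd_t) else [])])
        rtv_profile = pkm.solve_ritonavir(
            regimen.ritonavir, config.ritonavir, horizon,
            grid_step=0.05 if horizon <= 100 else 0.1) \
            if regimen.ritonavir else pkm.ConcProfile.constant(0.0, horizon)
        gd = gut_doses_for(regimen.paclitaxel, ind)
        pk_pred = paclitaxel_concentrations(
            gd, ind, config.physio, rtv_profile, obs_t)
        pk_obs = apply_residual_error(pk_pred, spec_err.sigma_pk, rng)
        rtv_sampled = rng.random() < spec.ritonavir_sampled_fraction
        for d in regimen.paclitaxel:
            rows.append(dict(
                ID=sid, TIME=d.time, EVID=1, AMT=d.amount, CMT="pac",
                ROUTE=d.route, FORM=d.formulation, DDI=d.daily_dose_index,
                OCC=d.occasion, DV=np.nan, MDV=1, DUR=np.nan))
        for d in regimen.ritonavir:
            rows.append(dict(
                ID=sid, TIME=d.time, EVID=1, AMT=d.amount, CMT="rtv",
                ROUTE="oral", FORM="solution", DDI=np.nan, OCC=d.occasion,
                DV=np.nan, MDV=1, DUR=np.nan))
        for t, y, pred in zip(obs_t, pk_obs, pk_pred):
            # zero-prediction (pre-dose) samples carry no information for
            # a proportional-error model and are flagged missing
            missing = pred <= 0.0
            rows.append(dict(
                ID=sid, TIME=float(t), EVID=0, AMT=np.nan, CMT="pac",
                ROUTE=np.nan, FORM=np.nan, DDI=np.nan, OCC=np.nan,
                DV=np.nan if missing else float(max(y, 0.0)),
                MDV=1 if missing else 0, DUR=np.nan))
        if rtv_sampled:
            for t in obs_t:
                y = float(rtv_profile(t)) * (
                    1.0 + rng.normal(0.0, spec_err.sigma_pk))
                rows.append(dict(
                    ID=sid, TIME=float(t), EVID=0, AMT=np.nan, CMT="rtv",
                    ROUTE=np.nan, FORM=np.nan, DDI=np.nan, OCC=np.nan,
                    DV=max(y, 0.0), MDV=0, DUR=np.nan))
        if len(pd_t):
            grid = np.unique(np.concatenate(
                [np.arange(0.0, pd_t[-1] + 0.25, 0.25), pd_t]))
            pac_dense = paclitaxel_concentrations(
                gd, ind, config.physio, rtv_profile, grid)
            tsp_pred = tsp1_fast(pd_t, grid, pac_dense, config.tsp1.ec50,
                                 ind.tsp1_baseline, config.tsp1.kout, 0.25)
            tsp_obs = apply_residual_error(tsp_pred, spec_err.sigma_pd, rng)
            for t, y in zip(pd_t, tsp_obs):
                rows.append(dict(
                    ID=sid, TIME=float(t), EVID=0, AMT=np.nan, CMT="tsp1",
                    ROUTE=np.nan, FORM=np.nan, DDI=np.nan, OCC=np.nan,
                    DV=float(max(y, 0.0)), MDV=0, DUR=np.nan))
    df = pd.DataFrame(rows).sort_values(
        ["ID", "TIME", "EVID"], ascending=[True, True, False],
        kind="stable").reset_index(drop=True)
    dataset = StudyDataset(df)
    truth = {
        "seed": seed,
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(spec).items() if k != "custom_designs"},
        "paclitaxel": asdict(config.paclitaxel),
        "tsp1": asdict(config.tsp1),
        "random_effects": asdict(config.random_effects),
        "subject_etas": truth_subjects,
    }
    return dataset, truth


def generate_pd_observations(dataset: StudyDataset, config: ModelConfig,
                             pd_sampling_days=DEFAULT_PD_DAYS, seed=None,
                             subject_etas: dict | None = None
                             ) -> pd.DataFrame:
    """TSP-1 observation records for an existing (PK) trial dataset.

    Uses each subject's stored eta draws when ``subject_etas`` (the truth
    sidecar mapping) is given, otherwise fresh baseline etas; the PK
    driver is re-simulated from the dose records.  Returns the new rows
    only, in dataset column layout.
    """
    rng = np.random.default_rng(seed)
    pd_t_all = np.array(sorted(24.0 * (np.asarray(pd_sampling_days) - 1)),
                        dtype=float)
    spec_err = config.random_effects
    rows = []
    for sid in dataset.subjects:
        regimen = dataset.subject_regimen(sid)
        if not regimen.paclitaxel:
            continue
        etas = (subject_etas or {}).get(str(sid))
        if etas is not None:
            ind = _individual_from_etas(config, etas)
        else:
            ind = sample_individual(
                config, sorted({d.occasion for d in regimen.paclitaxel}),
                rng)
        pd_t = pd_t_all[pd_t_all <= regimen.horizon + 24.0]
        if not len(pd_t):
            continue
        horizon = max(regimen.horizon, pd_t[-1])
        rtv_profile = pkm.solve_ritonavir(
            regimen.ritonavir, config.ritonavir, horizon,
            grid_step=0.05 if horizon <= 100 else 0.1) \
            if regimen.ritonavir else pkm.ConcProfile.constant(0.0, horizon)
        gd = gut_doses_for(regimen.paclitaxel, ind)
        grid = np.unique(np.concatenate(
            [np.arange(0.0, pd_t[-1] + 0.25, 0.25), pd_t]))
        pac = paclitaxel_concentrations(gd, ind, config.physio,
                                        rtv_profile, grid)
        tsp = tsp1_fast(pd_t, grid, pac, config.tsp1.ec50,
                        ind.tsp1_baseline, config.tsp1.kout, 0.25)
        tsp = apply_residual_error(tsp, spec_err.sigma_pd, rng)
        for t, y in zip(pd_t, tsp):
            rows.append(dict(
                ID=sid, TIME=float(t), EVID=0, AMT=np.nan, CMT="tsp1",
                ROUTE=np.nan, FORM=np.nan, DDI=np.nan, OCC=np.nan,
                DV=float(max(y, 0.0)), MDV=0, DUR=np.nan))
    return pd.DataFrame(rows)


def _individual_from_etas(config: ModelConfig, etas: dict
                          ) -> IndividualParams:
    e = {k: float(v) for k, v in etas.items()}
    bov = {int(k.split("_", 1)[1]): float(np.exp(v))
           for k, v in e.items() if k.startswith("bov_")}
    return IndividualParams(
        pop=config.paclitaxel, etas=e, bov_multipliers=bov,
        tsp1_baseline=config.tsp1.baseline
        * float(np.exp(e.get("ebase", 0.0))))
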