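"""Regimen construction and NONMEM-style longitudinal dataset handling.

A :class:`Regimen` is the dosing history of one subject (paclitaxel and
ritonavir kept separate) plus an observation time grid.  A
:class:`StudyDataset` is the flat record table joining dose rows and
observation rows (paclitaxel plasma, ritonavir plasma, TSP-1) across
subjects, in one flexible CSV dialect (comma-separated, header row) rather
than strict NONMEM:

====  =======================================================
ID    subject identifier
TIME  hours since the subject's first dose (t = 0 at first dose)
EVID  1 for dose rows, 0 for observation rows
AMT   dose amount in mg (dose rows only)
CMT   channel: ``pac`` / ``rtv`` / ``tsp1``
ROUTE ``oral`` or ``iv_infusion`` (dose rows)
FORM  formulation: ``solution`` / ``capsule`` / ``tablet`` / ``iv``
DDI   daily-dose index ``first`` / ``second`` (oral paclitaxel doses)
OCC   occasion number (each paclitaxel dose administration is an occasion)
DV    observed value (ng/mL; TSP-1 ng/mL/1e6 platelets)
MDV   1 when DV is missing
DUR   infusion duration in h (IV dose rows)
====  =======================================================

Unknown extra columns are preserved opaquely on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DatasetValidationError, InputError

__all__ = [
    "DoseEvent",
    "Regimen",
    "RegimenDesign",
    "IVRegimenDesign",
    "build_regimen",
    "build_iv_regimen",
    "StudyDataset",
    "read_dataset",
    "write_dataset",
    "assign_occasions",
]

ORAL_FORMULATIONS = ("solution", "capsule", "tablet")
CANONICAL_COLUMNS = ["ID", "TIME", "EVID", "AMT", "CMT", "ROUTE", "FORM",
                     "DDI", "OCC", "DV", "MDV", "DUR"]


@dataclass(frozen=True)
class DoseEvent:
    """One dose administration.

    ``daily_dose_index`` ('first'/'second') selects the Weibull ALPHA and
    the second-dose bioavailability factor and is defined only for oral
    routes; ``occasion`` numbers dose administrations sequentially within a
    subject.
    """

    time: float
    amount: float  # mg
    route: str = "oral"
    formulation: str = "capsule"
    infusion_duration: float | None = None
    daily_dose_index: str | None = None
    occasion: int = 1

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InputError(f"dose time must be >= 0, got {self.time}")
        if self.amount <= 0:
            raise InputError(f"dose amount must be > 0, got {self.amount}")
        if self.route not in ("oral", "iv_infusion"):
            raise InputError(f"unknown route {self.route!r}")
        if self.route == "oral":
            if self.formulation not in ORAL_FORMULATIONS:
                raise InputError(
                    f"unknown oral formulation {self.formulation!r}")
            if self.daily_dose_index not in ("first", "second"):
                raise InputError(
                    "oral doses need daily_dose_index 'first' or 'second'")
        else:
            if self.infusion_duration is None or self.infusion_duration <= 0:
                raise InputError("iv_infusion doses need infusion_duration > 0")


@dataclass(frozen=True)
class Regimen:
    """Dosing history for one subject, drugs kept on separate channels."""

    paclitaxel: tuple[DoseEvent, ...] = ()
    ritonavir: tuple[DoseEvent, ...] = ()
    observation_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "paclitaxel",
                           tuple(sorted(self.paclitaxel, key=lambda d: d.time)))
        object.__setattr__(self, "ritonavir",
                           tuple(sorted(self.ritonavir, key=lambda d: d.time)))
        object.__setattr__(self, "observation_times",
                           tuple(float(t) for t in self.observation_times))
        seen = {}
        for d in self.paclitaxel:
            if d.time in seen:
                raise InputError(
                    f"two paclitaxel doses at identical time {d.time} h")
            seen[d.time] = d

    @property
    def horizon(self) -> float:
        """Last event or observation time, h."""
        times = [d.time + (d.infusion_duration or 0.0)
                 for d in self.paclitaxel + self.ritonavir]
        times.extend(self.observation_times)
        return max(times, default=0.0)


@dataclass(frozen=True)
class RegimenDesign:
    """Declarative description of an oral paclitaxel (+ ritonavir) regimen.

    ``daily_dose_mg`` is the total paclitaxel per dosing day, split evenly
    over ``doses_per_day`` administrations; with two daily doses the second
    follows the first after ``second_dose_interval_h`` (7 h in the LDM
    studies).  ``dose_days`` lists the dosing days (0-based); the default is
    every day of ``n_days``.  Ritonavir is given at ``ritonavir_dose_mg``
    with every paclitaxel administration, ``ritonavir_lead_h`` before it
    (0.5 h in the single-dose and crossover studies, 0 in the LDM study).
    """

    formulation: str = "tablet"
    daily_dose_mg: float = 40.0
    doses_per_day: int = 2
    second_dose_interval_h: float = 7.0
    n_days: int = 21
    dose_days: tuple[int, ...] | None = None
    ritonavir_dose_mg: float = 100.0
    ritonavir_lead_h: float = 0.0
    observation_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.formulation not in ORAL_FORMULATIONS:
            raise InputError(f"unknown formulation {self.formulation!r}")
        if self.doses_per_day not in (1, 2):
            raise InputError("doses_per_day must be 1 or 2")
        if self.daily_dose_mg < 0:
            raise InputError("daily_dose_mg must be >= 0")


@dataclass(frozen=True)
class IVRegimenDesign:
    """IV paclitaxel schedule: repeated zero-order infusions."""

    dose_mg: float = 315.0           # 175 mg/m2 at BSA 1.8 m2
    infusion_duration_h: float = 3.0
    interval_h: float = 504.0        # 3-weekly
    n_doses: int = 1
    observation_times: tuple[float, ...] = ()


def build_regimen(design: RegimenDesign | IVRegimenDesign) -> Regimen:
    """Materialise a design into explicit, occasion-numbered dose events."""
    if isinstance(design, IVRegimenDesign):
        return _build_iv(design)
    if design.daily_dose_mg == 0 or design.n_days == 0:
        return Regimen(observation_times=design.observation_times)
    days = (tuple(range(design.n_days)) if design.dose_days is None
            else tuple(sorted(design.dose_days)))
    per_dose = design.daily_dose_mg / design.doses_per_day
    lead = design.ritonavir_lead_h if design.ritonavir_dose_mg > 0 else 0.0
    pac, rtv = [], []
    occ = 0
    for day in days:
        t0 = 24.0 * day
        # time origin is the first administered dose; with a ritonavir
        # lead, ritonavir opens the day and paclitaxel follows `lead` h
        # later
        times = [t0 + lead]
        if design.doses_per_day == 2:
            times.append(t0 + lead + design.second_dose_interval_h)
        for k, t in enumerate(times):
            occ += 1
            pac.append(DoseEvent(
                time=t, amount=per_dose, route="oral",
                formulation=design.formulation,
                daily_dose_index="first" if k == 0 else "second",
                occasion=occ,
            ))
            if design.ritonavir_dose_mg > 0:
                rtv.append(DoseEvent(
                    time=t - lead,
                    amount=design.ritonavir_dose_mg, route="oral",
                    formulation="solution", daily_dose_index="first",
                    occasion=occ,
                ))
    return Regimen(paclitaxel=tuple(pac), ritonavir=tuple(rtv),
                   observation_times=design.observation_times)


def _build_iv(design: IVRegimenDesign) -> Regimen:
    doses = tuple(
        DoseEvent(time=i * design.interval_h, amount=design.dose_mg,
                  route="iv_infusion", formulation="iv",
                  infusion_duration=design.infusion_duration_h, occasion=i + 1)
        for i in range(design.n_doses)
    )
    return Regimen(paclitaxel=doses,
                   observation_times=design.observation_times)


def build_iv_regimen(dose_mg: float, infusion_duration_h: float,
                     interval_h: float, n_doses: int,
                     observation_times: Sequence[float] = ()) -> Regimen:
    return build_regimen(IVRegimenDesign(
        dose_mg=dose_mg, infusion_duration_h=infusion_duration_h,
        interval_h=interval_h, n_doses=n_doses,
        observation_times=tuple(observation_times)))


class StudyDataset:
    """Record table of doses and observations across subjects."""

    def __init__(self, records: pd.DataFrame, validate: bool = True):
        df = records.copy()
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        extra = [c for c in df.columns if c not in CANONICAL_COLUMNS]
        self.records = df[CANONICAL_COLUMNS + extra].reset_index(drop=True)
        if validate:
            problems = self.validate()
            if problems:
                raise DatasetValidationError(problems)

    # -- construction -------------------------------------------------
    @classmethod
    def from_rows(cls, rows: Iterable[dict], validate: bool = True
                  ) -> "StudyDataset":
        return cls(pd.DataFrame(list(rows)), validate=validate)

    def copy(self) -> "StudyDataset":
        return StudyDataset(self.records.copy(), validate=False)

    # -- basic access -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.records["ID"]))

    def for_subject(self, subject_id) -> pd.DataFrame:
        return self.records[self.records["ID"] == subject_id]

    def doses(self, subject_id=None, cmt: str | None = None) -> pd.DataFrame:
        df = self.records[self.records["EVID"] == 1]
        if subject_id is not None:
            df = df[df["ID"] == subject_id]
        if cmt is not None:
            df = df[df["CMT"] == cmt]
        return df

    def observations(self, subject_id=None, cmt: str | None = None
                     ) -> pd.DataFrame:
        df = self.records[self.records["EVID"] == 0]
        if subject_id is not None:
            df = df[df["ID"] == subject_id]
        if cmt is not None:
            df = df[df["CMT"] == cmt]
        return df

    def subject_regimen(self, subject_id) -> Regimen:
        """Reconstruct the dosing history of one subject as a Regimen."""
        pac, rtv = [], []
        for _, row in self.doses(subject_id).iterrows():
            ddi = row["DDI"] if isinstance(row["DDI"], str) and row["DDI"] \
                else None
            if ddi is None and row["ROUTE"] == "oral":
                ddi = "first"  # ritonavir rows carry no daily-dose index
            ev = DoseEvent(
                time=float(row["TIME"]), amount=float(row["AMT"]),
                route=row["ROUTE"], formulation=row["FORM"],
                infusion_duration=(float(row["DUR"])
                                   if pd.notna(row.get("DUR")) else None),
                daily_dose_index=ddi,
                occasion=int(row["OCC"]) if pd.notna(row["OCC"]) else 1,
            )
            (pac if row["CMT"] == "pac" else rtv).append(ev)
        obs_t = self.observations(subject_id)["TIME"].astype(float)
        return Regimen(paclitaxel=tuple(pac), ritonavir=tuple(rtv),
                       observation_times=tuple(sorted(set(obs_t))))

    # -- validation ---------------------------------------------------
    def validate(self) -> list[str]:
        """Return a list of human-readable problems (empty when valid)."""
        problems: list[str] = []
        df = self.records
        for col in ("ID", "TIME", "EVID", "CMT"):
            if df[col].isna().any():
                bad = df.index[df[col].isna()].tolist()
                problems.append(f"column {col} missing in rows {bad}")
        if problems:
            return problems
        if not df["EVID"].isin([0, 1]).all():
            bad = df.index[~df["EVID"].isin([0, 1])].tolist()
            problems.append(f"EVID must be 0 or 1; offending rows {bad}")
        tneg = df.index[df["TIME"].astype(float) < 0].tolist()
        if tneg:
            problems.append(f"negative TIME in rows {tneg}")
        for sid, grp in df.groupby("ID", sort=False):
            t = grp["TIME"].astype(float).to_numpy()
            if np.any(np.diff(t) < 0):
                problems.append(f"times not sorted for subject {sid}")
        dose = df[df["EVID"] == 1]
        bad_amt = dose.index[~(dose["AMT"].astype(float) > 0)].tolist()
        if bad_amt:
            problems.append(
                f"dose rows without positive AMT: rows {bad_amt}")
        bad_route = dose.index[~dose["ROUTE"].isin(
            ["oral", "iv_infusion"])].tolist()
        if bad_route:
            problems.append(f"dose rows without valid ROUTE: rows {bad_route}")
        obs = df[df["EVID"] == 0]
        mdv = obs["MDV"].fillna(0).astype(float)
        no_value = obs.index[(obs["DV"].isna()) & (mdv != 1)].tolist()
        if no_value:
            problems.append(
                f"observation rows with neither DV nor MDV=1: rows {no_value}")
        bad_cmt = df.index[~df["CMT"].isin(["pac", "rtv", "tsp1"])].tolist()
        if bad_cmt:
            problems.append(f"unknown CMT in rows {bad_cmt}")
        return problems


def assign_occasions(dataset: StudyDataset) -> StudyDataset:
    """Number occasions 1..n per subject; each paclitaxel dose is an occasion.

    Observation rows (and ritonavir dose rows) inherit the occasion of the
    most recent paclitaxel dose; records before the first dose belong to
    occasion 1.
    """
    df = dataset.records.copy()
    for sid, grp in df.groupby("ID", sort=False):
        is_pac_dose = (grp["EVID"] == 1) & (grp["CMT"] == "pac")
        pac_doses = grp[is_pac_dose].sort_values("TIME")
        if len(pac_doses) == 0:
            pac_doses = grp[grp["EVID"] == 1].sort_values("TIME")
        if len(pac_doses) == 0:
            df.loc[grp.index, "OCC"] = 1
            continue
        dose_times = pac_doses["TIME"].astype(float).to_numpy()
        df.loc[pac_doses.index, "OCC"] = np.arange(1, len(pac_doses) + 1)
        others = grp.index.difference(pac_doses.index)
        t = grp.loc[others, "TIME"].astype(float).to_numpy()
        occ = np.searchsorted(dose_times, t, side="right")
        df.loc[others, "OCC"] = np.maximum(occ, 1)
    df["OCC"] = df["OCC"].astype(int)
    return StudyDataset(df, validate=False)


def write_dataset(dataset: StudyDataset, path) -> None:
    df = dataset.records.copy()
    df.to_csv(path, index=False)


def read_dataset(path, validate: bool = True) -> StudyDataset:
    df = pd.read_csv(path, dtype={"CMT": "string", "ROUTE": "string",
                                  "FORM": "string", "DDI": "string"},
                     float_precision="round_trip")
    for col in ("CMT", "ROUTE", "FORM", "DDI"):
        if col in df.columns:
            df[col] = df[col].astype(object).where(df[col].notna(), np.nan)
    return StudyDataset(df, validate=validate)
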