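"""Virtual monkey-study generation.

The package ships the three study designs used for the antibody programme —
a single-dose i.v. PK/PD study, a 1-month weekly-dose toxicology study with a
long recovery phase, and a 3-month weekly-dose toxicology study — with their
nominal dose levels and blood-sampling schedules.  ``simulate_study`` draws
virtual animals from the population model (log-normal between-subject
variability, proportional residual error) and produces an event-record
dataset with assay-limit censoring, standing in for the raw in-life data.

Time is expressed in days relative to the first dose (day 0); baseline
immunophenotyping samples carry negative times.  Samples drawn exactly at a
dose time are pre-dose troughs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model
from .params import (
    PARAM_NAMES,
    ROUTE_IV,
    ROUTE_SC,
    PopulationParameters,
    Regimen,
    VariabilitySpec,
)

__all__ = [
    "StudyArm",
    "StudyDesign",
    "StudyDataset",
    "builtin_designs",
    "draw_individual",
    "simulate_study",
]

DEFAULT_LLOQ = 0.1  # ug/mL

_HOUR = 1.0 / 24.0


@dataclass(frozen=True)
class StudyArm:
    """One dose group: label, dose level (ug/kg; 0 for control), route,
    number of weekly doses, and group size."""

    label: str
    dose: float
    route: str
    n_doses: int
    n_subjects: int
    interval: float = 7.0

    def regimen(self) -> Regimen:
        if self.dose <= 0 or self.n_doses == 0:
            return Regimen((), label=self.label)
        return Regimen.weekly(self.dose, self.route, self.n_doses, self.interval, label=self.label)


@dataclass(frozen=True)
class StudyDesign:
    """Arms plus nominal PK/PD sampling schedules.

    ``n_recovery`` subjects per arm (deterministically the first ones) are
    additionally sampled at the recovery-phase times.
    """

    label: str
    arms: tuple[StudyArm, ...]
    pk_times: tuple[float, ...]
    pd_times: tuple[float, ...]
    recovery_pk_times: tuple[float, ...] = ()
    recovery_pd_times: tuple[float, ...] = ()
    n_recovery: int = 0
    lloq: float = DEFAULT_LLOQ

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("design needs at least one arm")
        if len(self.pk_times) == 0 and len(self.pd_times) == 0:
            raise ValueError("design has no sampling times")
        for arm in self.arms:
            if arm.n_subjects < 1:
                raise ValueError(f"arm {arm.label!r} must have >= 1 subject")

    @property
    def n_subjects(self) -> int:
        return sum(a.n_subjects for a in self.arms)

    def subject_pk_times(self, subject_index: int) -> np.ndarray:
        t = list(self.pk_times)
        if subject_index < self.n_recovery:
            t += list(self.recovery_pk_times)
        return np.unique(np.asarray(t, dtype=float))

    def subject_pd_times(self, subject_index: int) -> np.ndarray:
        t = list(self.pd_times)
        if subject_index < self.n_recovery:
            t += list(self.recovery_pd_times)
        return np.unique(np.asarray(t, dtype=float))


def _offsets(*hours: float) -> tuple[float, ...]:
    return tuple(h * _HOUR for h in hours)


def builtin_designs() -> dict[str, StudyDesign]:
    """The three bundled study designs.

    Day numbering in the underlying study protocols starts at Day 1 = first
    dose; here times are days after first dose (protocol day minus one).

    * ``single``: two groups of 3 monkeys, 0.1 and 1 mg/kg i.v. once,
      PK and PD sampled predose and on days 3-42, with two extra baseline
      PD samples.
    * ``one_month``: five groups of 10, weekly doses x5 (control, 30, 60,
      150 i.v.; 150 s.c.), rich profiles after the first and fourth dose,
      recovery sampling in 4 monkeys per group out to day 336.
    * ``three_month``: four groups of 12, weekly s.c. doses x13 (control,
      5, 30, 150), rich profiles after the first and thirteenth dose,
      recovery sampling in 4 monkeys per group out to day 204.
    """
    single = StudyDesign(
        label="single",
        arms=(
            StudyArm("0.1 mg/kg iv", 100.0, ROUTE_IV, 1, 3),
            StudyArm("1 mg/kg iv", 1000.0, ROUTE_IV, 1, 3),
        ),
        pk_times=(0.0, 3.0, 5.0, 8.0, 14.0, 21.0, 28.0, 35.0, 42.0),
        pd_times=(-7.0, -3.0, 0.0, 3.0, 5.0, 8.0, 14.0, 21.0, 28.0, 35.0, 42.0),
    )

    day1 = _offsets(0.5, 2, 8, 24, 96, 168)
    one_month_pk = (0.0,) + day1 + (14.0,) + tuple(21.0 + o for o in _offsets(0.5, 2, 8, 24, 96, 168))
    one_month = StudyDesign(
        label="one_month",
        arms=(
            StudyArm("control", 0.0, ROUTE_IV, 0, 10),
            StudyArm("30 mg/kg iv", 30000.0, ROUTE_IV, 5, 10),
            StudyArm("60 mg/kg iv", 60000.0, ROUTE_IV, 5, 10),
            StudyArm("150 mg/kg iv", 150000.0, ROUTE_IV, 5, 10),
            StudyArm("150 mg/kg sc", 150000.0, ROUTE_SC, 5, 10),
        ),
        pk_times=one_month_pk,
        pd_times=(-7.0, -3.0, 14.0, 29.0),
        recovery_pk_times=tuple(float(d - 1) for d in (43, 57, 71, 85, 113, 141, 169, 197, 225, 253, 281, 309, 337)),
        recovery_pd_times=tuple(float(d - 1) for d in (57, 85, 113, 141, 169, 197, 225, 253, 281, 309, 337)),
        n_recovery=4,
    )

    three_month_pk = (
        (0.0,) + _offsets(0.5, 2, 8, 24, 48, 168)
        + (28.0, 56.0)
        + tuple(84.0 + o for o in _offsets(0.5, 2, 8, 24, 96, 168))
        + (92.0,)
    )
    three_month = StudyDesign(
        label="three_month",
        arms=(
            StudyArm("control", 0.0, ROUTE_SC, 0, 12),
            StudyArm("5 mg/kg sc", 5000.0, ROUTE_SC, 13, 12),
            StudyArm("30 mg/kg sc", 30000.0, ROUTE_SC, 13, 12),
            StudyArm("150 mg/kg sc", 150000.0, ROUTE_SC, 13, 12),
        ),
        pk_times=three_month_pk,
        pd_times=(-10.0, -7.0, -3.0, 0.0, 2.0, 7.0, 14.0, 28.0, 56.0, 92.0),
        recovery_pk_times=tuple(float(d - 1) for d in (106, 120, 134, 148, 176, 205)),
        recovery_pd_times=tuple(float(d - 1) for d in (120, 148, 176, 205)),
        n_recovery=4,
    )
    return {"single": single, "one_month": one_month, "three_month": three_month}


def draw_individual(
    params: PopulationParameters,
    var: VariabilitySpec,
    rng: np.random.Generator | int,
) -> PopulationParameters:
    """One individual parameter set, P_i = TVP * exp(eta), eta ~ N(0, omega^2).

    Parameters without a random effect (e.g. the bioavailability F1) are
    copied unchanged.  An optional correlation between the CL and Vc random
    effects is honoured.  Individual Emax values are capped at 1 (the
    log-normal tail would otherwise produce a negative production rate).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    eta = _draw_etas(var, rng, 1)[0]
    return _individual_from_eta(params, eta)


def _draw_etas(var: VariabilitySpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """(n, 10) matrix of random effects in canonical parameter order."""
    eta = np.zeros((n, len(PARAM_NAMES)))
    names = [p for p in PARAM_NAMES if var.omega2.get(p, 0.0) > 0]
    corr = var.corr_cl_vc
    for name in names:
        if corr != 0.0 and name in ("cl", "vc"):
            continue
        i = PARAM_NAMES.index(name)
        eta[:, i] = rng.normal(0.0, np.sqrt(var.omega2[name]), size=n)
    if corr != 0.0 and var.omega2.get("cl", 0.0) > 0 and var.omega2.get("vc", 0.0) > 0:
        scl, svc = np.sqrt(var.omega2["cl"]), np.sqrt(var.omega2["vc"])
        cov = np.array([[scl**2, corr * scl * svc], [corr * scl * svc, svc**2]])
        draws = rng.multivariate_normal(np.zeros(2), cov, size=n)
        eta[:, PARAM_NAMES.index("cl")] = draws[:, 0]
        eta[:, PARAM_NAMES.index("vc")] = draws[:, 1]
    return eta


def _individual_from_eta(params: PopulationParameters, eta: np.ndarray) -> PopulationParameters:
    values = params.as_array() * np.exp(eta)
    values[PARAM_NAMES.index("emax")] = min(values[PARAM_NAMES.index("emax")], 1.0)
    values[PARAM_NAMES.index("f1")] = params.f1  # no BSV on bioavailability
    return PopulationParameters.from_array(values)


@dataclass
class StudyDataset:
    """Event records for one (virtual) study plus provenance.

    ``records`` is a tidy frame with columns ID, ARM, TIME, AMT, ROUTE,
    DVTYPE, DV, BLQ — one row per dose or observation.  ``true_parameters``
    (simulated datasets only) holds each subject's individual parameter
    draw and is used exclusively for recovery scoring, never by estimators.
    """

    records: pd.DataFrame
    lloq: float = DEFAULT_LLOQ
    design_label: str = ""
    seed: int | None = None
    true_parameters: pd.DataFrame | None = None
    n_truncated_pd: int = 0

    @property
    def subjects(self) -> list[str]:
        return list(self.records["ID"].unique())

    def doses(self) -> pd.DataFrame:
        return self.records[self.records["DVTYPE"] == "DOSE"]

    def observations(self, dvtype: str | None = None, include_blq: bool = True) -> pd.DataFrame:
        obs = self.records[self.records["DVTYPE"].isin(["PK", "PD"])]
        if dvtype is not None:
            obs = obs[obs["DVTYPE"] == dvtype]
        if not include_blq:
            obs = obs[obs["BLQ"] == 0]
        return obs

    def subject_regimen(self, subject: str) -> Regimen:
        rows = self.records[(self.records["ID"] == subject) & (self.records["DVTYPE"] == "DOSE")]
        from .params import DoseEvent

        events = tuple(
            DoseEvent(float(r.TIME), float(r.AMT), ROUTE_IV if r.ROUTE == "IV" else ROUTE_SC)
            for r in rows.itertuples()
        )
        return Regimen(events)

    def validate(self) -> None:
        from .dataio import validate_records

        validate_records(self.records)


def simulate_study(
    design: StudyDesign,
    params: PopulationParameters,
    var: VariabilitySpec,
    seed: int | np.random.Generator,
    id_prefix: str | None = None,
) -> StudyDataset:
    """Simulate one virtual study under the population model.

    Per subject: draw individual parameters, integrate the PK/PD system
    (stiff ODE solver; dose times as breakpoints), sample at the design
    times, apply proportional residual error with the observation-type
    specific variance, censor PK values below the LLOQ as BLQ, and truncate
    (rare) negative PD values at zero.  Identical seeds give identical
    datasets.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    prefix = id_prefix if id_prefix is not None else (design.label + "-" if design.label else "")
    sd_pk = float(np.sqrt(var.sigma2_prop_pk))
    sd_pd = float(np.sqrt(var.sigma2_prop_pd))

    rows: list[dict] = []
    truths: list[dict] = []
    n_trunc = 0
    for arm in design.arms:
        regimen = arm.regimen()
        route_code = "IV" if arm.route == ROUTE_IV else "SC"
        arm_label = f"{prefix}{arm.label}"  # unique across combined designs
        for j in range(arm.n_subjects):
            sid = f"{prefix}{arm.label}#{j + 1}"
            indiv = _individual_from_eta(params, _draw_etas(var, rng, 1)[0])
            truths.append({"ID": sid, "ARM": arm_label, **indiv.as_dict()})

            pk_t = design.subject_pk_times(j)
            pd_t = design.subject_pd_times(j)
            grid = np.unique(np.concatenate([pk_t, pd_t]))
            if len(regimen):
                traj = model.simulate(indiv, regimen, grid)
                conc = dict(zip(np.round(grid, 9), traj.conc))
                nk = dict(zip(np.round(grid, 9), traj.r))
            else:
                conc = {np.round(t, 9): 0.0 for t in grid}
                nk = {np.round(t, 9): indiv.r0 for t in grid}

            for ev in regimen.events:
                rows.append(
                    dict(ID=sid, ARM=arm_label, TIME=ev.time, AMT=ev.amount,
                         ROUTE=route_code, DVTYPE="DOSE", DV=np.nan, BLQ=0)
                )
            eps_pk = rng.normal(0.0, sd_pk, size=pk_t.size) if sd_pk > 0 else np.zeros(pk_t.size)
            for t, e in zip(pk_t, eps_pk):
                y = conc[np.round(t, 9)] * (1.0 + e)
                blq = int(y < design.lloq)
                rows.append(
                    dict(ID=sid, ARM=arm_label, TIME=t, AMT=np.nan, ROUTE="",
                         DVTYPE="PK", DV=(np.nan if blq else y), BLQ=blq)
                )
            eps_pd = rng.normal(0.0, sd_pd, size=pd_t.size) if sd_pd > 0 else np.zeros(pd_t.size)
            for t, e in zip(pd_t, eps_pd):
                y = nk[np.round(t, 9)] * (1.0 + e)
                if y < 0:
                    y = 0.0
                    n_trunc += 1
                rows.append(
                    dict(ID=sid, ARM=arm_label, TIME=t, AMT=np.nan, ROUTE="",
                         DVTYPE="PD", DV=y, BLQ=0)
                )

    records = pd.DataFrame(rows).sort_values(["ID", "TIME", "DVTYPE"], kind="stable")
    records = records.reset_index(drop=True)
    return StudyDataset(
        records=records,
        lloq=design.lloq,
        design_label=design.label,
        seed=int(seed) if isinstance(seed, (int, np.integer)) else None,
        true_parameters=pd.DataFrame(truths),
        n_truncated_pd=n_trunc,
    )


def combine(datasets: list[StudyDataset]) -> StudyDataset:
    """Concatenate several studies into one pooled analysis dataset."""
    records = pd.concat([d.records for d in datasets], ignore_index=True)
    truths = [d.true_parameters for d in datasets if d.true_parameters is not None]
    return StudyDataset(
        records=records,
        lloq=datasets[0].lloq,
        design_label="+".join(d.design_label for d in datasets),
        seed=None,
        true_parameters=pd.concat(truths, ignore_index=True) if truths else None,
        n_truncated_pd=sum(d.n_truncated_pd for d in datasets),
    )
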