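"""Parameter and dosing containers shared by simulation, NCA, and estimation.

Units are fixed package-wide: time in days, doses in ug per kg body weight,
concentrations in ug/mL, NK-cell counts in 10^3 cells/uL.  Clearances are
mL/day/kg and volumes mL/kg, i.e. everything is body-weight normalised, which
is how toxicology studies in macaques report dosing and how the population
estimates used as defaults here were derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "PopulationParameters",
    "VariabilitySpec",
    "DoseEvent",
    "Regimen",
    "CYNO_TYPICAL",
    "CYNO_VARIABILITY",
]

#: Canonical parameter order used whenever parameters travel as a flat vector.
PARAM_NAMES = ("ka", "cl", "vc", "q", "vp", "f1", "r0", "kout", "emax", "ec50")

ROUTE_IV = "iv_bolus"
ROUTE_SC = "sc"
ROUTES = (ROUTE_IV, ROUTE_SC)


@dataclass(frozen=True)
class PopulationParameters:
    """Structural parameters of the coupled two-compartment PK / NK-cell model.

    Parameters
    ----------
    ka : float
        First-order absorption rate from the s.c. depot, 1/day.
    cl : float
        Linear clearance from the central compartment, mL/day/kg.
    vc : float
        Central volume of distribution, mL/kg.
    q : float
        Inter-compartmental clearance, mL/day/kg.
    vp : float
        Peripheral volume of distribution, mL/kg.
    f1 : float
        Absolute s.c. bioavailability, in (0, 1].
    r0 : float
        Baseline NK-cell count, 10^3 cells/uL.
    kout : float
        First-order loss rate of NK cells, 1/day.
    emax : float
        Maximal fractional inhibition of NK-cell production, in [0, 1].
    ec50 : float
        Drug concentration giving half-maximal inhibition, ug/mL.

    The production rate ``kin`` is never stored: at baseline the NK pool is at
    steady state, so ``kin = r0 * kout`` by construction.
    """

    ka: float
    cl: float
    vc: float
    q: float
    vp: float
    f1: float
    r0: float
    kout: float
    emax: float
    ec50: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"parameter {f.name!r} must be finite and > 0, got {v!r}")
        if not 0 < self.f1 <= 1:
            raise ValueError(f"f1 must lie in (0, 1], got {self.f1}")
        if not 0 <= self.emax <= 1:
            raise ValueError(f"emax must lie in [0, 1], got {self.emax}")

    @property
    def kin(self) -> float:
        """NK-cell production rate, 10^3 cells/uL/day (baseline steady state)."""
        return self.r0 * self.kout

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "PopulationParameters":
        values = list(values)
        if len(values) != len(PARAM_NAMES):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {len(values)}")
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    def replace(self, **kwargs: float) -> "PopulationParameters":
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAM_NAMES}


@dataclass(frozen=True)
class VariabilitySpec:
    """Between-subject and residual variability of the population model.

    ``omega2`` maps parameter names to the variance of the log-normal random
    effect eta (individual value = typical * exp(eta)).  Parameters absent
    from the map carry no between-subject variability.  Residual error is
    proportional, ``Y = F * (1 + eps)``, with observation-type specific
    variances for PK (drug concentration) and PD (NK count) records; the
    additive components are fixed to zero.
    """

    omega2: Mapping[str, float] = field(default_factory=dict)
    corr_cl_vc: float = 0.0
    sigma2_prop_pk: float = 0.0
    sigma2_prop_pd: float = 0.0
    sigma2_add_pk: float = 0.0
    sigma2_add_pd: float = 0.0

    def __post_init__(self) -> None:
        for name, w2 in self.omega2.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r} in omega2")
            if w2 < 0:
                raise ValueError(f"omega2[{name!r}] must be >= 0, got {w2}")
        if not -1.0 <= self.corr_cl_vc <= 1.0:
            raise ValueError("corr_cl_vc must lie in [-1, 1]")
        for attr in ("sigma2_prop_pk", "sigma2_prop_pd", "sigma2_add_pk", "sigma2_add_pd"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        # Additive residual components are structurally fixed to zero.
        if self.sigma2_add_pk != 0.0 or self.sigma2_add_pd != 0.0:
            raise ValueError("additive residual variances are fixed to 0 in this model")

    def bsv_percent(self, name: str) -> float:
        """Between-subject variability reported as 100*sqrt(omega^2)."""
        return 100.0 * math.sqrt(self.omega2.get(name, 0.0))

    def bsv_cv_percent(self, name: str) -> float:
        """Log-normal CV form, 100*sqrt(exp(omega^2)-1) (alternative reporting)."""
        return 100.0 * math.sqrt(math.expm1(self.omega2.get(name, 0.0)))

    @classmethod
    def from_bsv_percent(
        cls,
        bsv: Mapping[str, float],
        sigma2_prop_pk: float = 0.0,
        sigma2_prop_pd: float = 0.0,
        corr_cl_vc: float = 0.0,
    ) -> "VariabilitySpec":
        omega2 = {k: (v / 100.0) ** 2 for k, v in bsv.items()}
        return cls(
            omega2=omega2,
            corr_cl_vc=corr_cl_vc,
            sigma2_prop_pk=sigma2_prop_pk,
            sigma2_prop_pd=sigma2_prop_pd,
        )


@dataclass(frozen=True)
class DoseEvent:
    """One administration: time (day), amount (ug/kg), route."""

    time: float
    amount: float
    route: str

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")
        if self.route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES}, got {self.route!r}")


@dataclass(frozen=True)
class Regimen:
    """An ordered dosing schedule for one subject or arm."""

    events: tuple[DoseEvent, ...]
    label: str = ""

    def __post_init__(self) -> None:
        events = tuple(self.events)
        times = [e.time for e in events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose events must be sorted by time")
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events], dtype=float)

    @property
    def amounts(self) -> np.ndarray:
        return np.array([e.amount for e in self.events], dtype=float)

    @property
    def routes(self) -> tuple[str, ...]:
        return tuple(e.route for e in self.events)

    @classmethod
    def single(cls, amount: float, route: str = ROUTE_IV, time: float = 0.0, label: str = "") -> "Regimen":
        return cls((DoseEvent(time, amount, route),), label=label)

    @classmethod
    def weekly(
        cls,
        amount: float,
        route: str,
        n_doses: int,
        interval: float = 7.0,
        start: float = 0.0,
        label: str = "",
    ) -> "Regimen":
        events = tuple(DoseEvent(start + i * interval, amount, route) for i in range(n_doses))
        return cls(events, label=label)

    def scaled(self, factor: float) -> "Regimen":
        return Regimen(
            tuple(DoseEvent(e.time, e.amount * factor, e.route) for e in self.events),
            label=self.label,
        )


#: Population typical values estimated for the anti-IL-15 antibody in
#: cynomolgus monkeys (simultaneous PK/PD fit of three studies).
CYNO_TYPICAL = PopulationParameters(
    ka=0.522,     # 1/day
    cl=3.66,      # mL/day/kg
    vc=44.8,      # mL/kg
    q=5.07,       # mL/day/kg
    vp=24.3,      # mL/kg
    f1=0.824,     # -
    r0=0.584,     # 10^3 cells/uL
    kout=0.305,   # 1/day
    emax=0.941,   # fractional inhibition (dimensionless)
    ec50=0.0978,  # ug/mL
)

#: Matching between-subject variability (percent, 100*sqrt(omega^2)) and
#: proportional residual variances from the same population analysis.
CYNO_VARIABILITY = VariabilitySpec.from_bsv_percent(
    {
        "ka": 23.7,
        "cl": 17.1,
        "vc": 15.2,
        "q": 72.1,
        "vp": 12.6,
        "r0": 40.4,
        "kout": 63.2,
        "emax": 2.45,
        "ec50": 90.7,
    },
    sigma2_prop_pk=0.0349,
    sigma2_prop_pd=0.217,
)
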