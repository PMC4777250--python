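"""Noncompartmental analysis of concentration-time profiles.

Implements the standard toolbox for single-dose and steady-state antibody
PK: linear/log hybrid trapezoidal areas, terminal-slope regression with
automatic point selection, back-extrapolated C0 for i.v. bolus data, moment
areas, and the derived parameters CL = Dose/AUCinf, MRT = AUMCinf/AUCinf,
Vss = CL*MRT, accumulation ratios and relative bioavailability.

Conventions (documented choices where the underlying method family leaves
room):

* the log trapezoid is used only on segments where both concentrations are
  positive and strictly decreasing; otherwise the linear rule applies;
* the terminal rate constant lambda_z is the best adjusted-r^2 ordinary
  least-squares fit of ln(C) on t over all contiguous terminal point sets of
  at least three points, starting after tmax (s.c.) or after the first
  post-dose point (i.v.); near-ties (adjusted r^2 within 1e-4) are resolved
  toward the set with more points;
* BLQ records are excluded from areas and regression (optionally imputed at
  LLOQ/2 for sensitivity analyses);
* tmax ties resolve to the earliest time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ROUTE_IV, ROUTE_SC

__all__ = [
    "ConcentrationProfile",
    "LambdaZDiagnostics",
    "NCAResult",
    "InsufficientDataError",
    "auc_trapezoidal",
    "aumc_trapezoidal",
    "lambda_z",
    "nca_single_dose",
    "accumulation_ratio",
    "bioavailability",
    "nca_table",
]

DEFAULT_LLOQ = 0.1  # ug/mL, quantification limit of the serum assay


class InsufficientDataError(ValueError):
    """Raised when a profile has too few usable points for the operation."""


@dataclass(frozen=True)
class ConcentrationProfile:
    """One subject's concentration-time profile for a single dosing occasion.

    ``blq`` flags records below the quantification limit; their ``conc``
    entries are ignored (the LLOQ itself lives in metadata, not in the data).
    """

    subject: str
    route: str
    dose: float  # ug/kg
    times: np.ndarray
    conc: np.ndarray
    blq: np.ndarray | None = None
    lloq: float = DEFAULT_LLOQ

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.conc, dtype=float)
        blq = (
            np.zeros(times.size, dtype=bool)
            if self.blq is None
            else np.asarray(self.blq, dtype=bool)
        )
        if times.shape != conc.shape or times.shape != blq.shape:
            raise ValueError("times, conc, and blq must have identical shapes")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(conc[~blq] < 0):
            raise ValueError("concentrations must be >= 0")
        if self.route not in (ROUTE_IV, ROUTE_SC):
            raise ValueError(f"unknown route {self.route!r}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "blq", blq)

    def usable(self, impute_blq_half_lloq: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Quantifiable (t, C) pairs; optionally impute BLQ at LLOQ/2."""
        if impute_blq_half_lloq:
            c = np.where(self.blq, self.lloq / 2.0, self.conc)
            return self.times, c
        return self.times[~self.blq], self.conc[~self.blq]

    def scaled(self, factor: float) -> "ConcentrationProfile":
        return ConcentrationProfile(
            self.subject, self.route, self.dose * factor, self.times, self.conc * factor,
            self.blq, self.lloq,
        )


def _segment_areas(t: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment AUC and AUMC using the linear/log hybrid rule."""
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    t1, t2 = t[:-1], t[1:]
    use_log = (c1 > 0) & (c2 > 0) & (c2 < c1)
    auc = np.where(use_log, 0.0, dt * (c1 + c2) / 2.0)
    aumc = np.where(use_log, 0.0, dt * (t1 * c1 + t2 * c2) / 2.0)
    if use_log.any():
        k = np.log(np.where(use_log, c1 / np.where(c2 > 0, c2, 1.0), math.e)) / np.where(
            use_log, dt, 1.0
        )
        auc_log = (c1 - c2) / k
        aumc_log = (t1 * c1 - t2 * c2) / k + (c1 - c2) / (k * k)
        auc = np.where(use_log, auc_log, auc)
        aumc = np.where(use_log, aumc_log, aumc)
    return auc, aumc


def _window(profile: ConcentrationProfile, t_start: float, t_end: float,
            impute: bool = False) -> tuple[np.ndarray, np.ndarray]:
    t, c = profile.usable(impute)
    m = (t >= t_start - 1e-12) & (t <= t_end + 1e-12)
    return t[m], c[m]


def auc_trapezoidal(
    profile: ConcentrationProfile,
    t_start: float,
    t_end: float,
    impute_blq_half_lloq: bool = False,
) -> float:
    """Partial AUC over [t_start, t_end] by the linear/log trapezoidal rule."""
    t, c = _window(profile, t_start, t_end, impute_blq_half_lloq)
    if t.size < 2:
        raise InsufficientDataError(
            f"need >=2 quantifiable points in [{t_start}, {t_end}], found {t.size}"
        )
    return float(_segment_areas(t, c)[0].sum())


def aumc_trapezoidal(
    profile: ConcentrationProfile,
    t_start: float,
    t_end: float,
    impute_blq_half_lloq: bool = False,
) -> float:
    """Partial AUMC (first-moment area) over [t_start, t_end]."""
    t, c = _window(profile, t_start, t_end, impute_blq_half_lloq)
    if t.size < 2:
        raise InsufficientDataError(
            f"need >=2 quantifiable points in [{t_start}, {t_end}], found {t.size}"
        )
    return float(_segment_areas(t, c)[1].sum())


@dataclass(frozen=True)
class LambdaZDiagnostics:
    n_points: int
    adj_r_squared: float
    t_first: float
    t_last: float


def lambda_z(profile: ConcentrationProfile) -> tuple[float, LambdaZDiagnostics]:
    """Terminal log-linear rate constant by OLS on ln(C) vs t.

    Returns ``(nan, diagnostics)`` when no admissible point set yields a
    negative slope.  Raises :class:`InsufficientDataError` with fewer than
    three usable terminal points.
    """
    t, c = profile.usable()
    pos = c > 0
    t, c = t[pos], c[pos]
    if t.size == 0:
        raise InsufficientDataError("no positive concentrations")
    imax = int(np.argmax(c))  # earliest maximum (argmax takes the first)
    # start candidates strictly after tmax (s.c.) / after first post-dose point (i.v.)
    first = imax + 1 if profile.route == ROUTE_SC else max(imax, 1) + 0
    if profile.route == ROUTE_IV:
        first = 1  # exclude the first post-dose point
    candidates = range(first, t.size - 2)
    best = None  # (adj_r2, n, slope)
    for i in candidates:
        tt, lc = t[i:], np.log(c[i:])
        n = tt.size
        slope, intercept = np.polyfit(tt, lc, 1)
        if slope >= 0:
            continue
        fitted = slope * tt + intercept
        ss_res = float(np.sum((lc - fitted) ** 2))
        ss_tot = float(np.sum((lc - lc.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        cand = (adj, n, -slope, tt[0], tt[-1])
        if best is None or adj > best[0] + 1e-4 or (abs(adj - best[0]) <= 1e-4 and n > best[1]):
            best = cand
    if not any(True for _ in range(first, t.size - 2)):
        raise InsufficientDataError("fewer than 3 terminal points after tmax")
    if best is None:
        return float("nan"), LambdaZDiagnostics(0, float("nan"), float("nan"), float("nan"))
    adj, n, lz, t_first, t_last = best
    return float(lz), LambdaZDiagnostics(int(n), float(adj), float(t_first), float(t_last))


@dataclass(frozen=True)
class NCAResult:
    """Per-profile noncompartmental parameter set.

    ``cmax_or_c0`` is the back-extrapolated C0 for i.v. bolus profiles and
    the observed Cmax for s.c. profiles.  Quantities depending on lambda_z
    are NaN when the terminal slope could not be estimated.  CL, MRT and Vss
    are reported for i.v. data only.
    """

    subject: str
    route: str
    dose: float
    cmax_or_c0: float
    tmax: float
    auc_last: float
    auc_inf: float
    aumc_inf: float
    lambda_z: float
    t_half: float
    cl: float
    mrt: float
    vss: float
    lz_diagnostics: LambdaZDiagnostics = field(repr=False, default=None)

    def as_dict(self) -> dict[str, float]:
        d = {
            "subject": self.subject, "route": self.route, "dose": self.dose,
            "cmax_or_c0": self.cmax_or_c0, "tmax": self.tmax,
            "auc_last": self.auc_last, "auc_inf": self.auc_inf,
            "aumc_inf": self.aumc_inf, "lambda_z": self.lambda_z,
            "t_half": self.t_half, "cl": self.cl, "mrt": self.mrt, "vss": self.vss,
        }
        if self.lz_diagnostics is not None:
            d["lz_n_points"] = self.lz_diagnostics.n_points
            d["lz_adj_r2"] = self.lz_diagnostics.adj_r_squared
        return d


def _c0_extrapolated(t: np.ndarray, c: np.ndarray) -> float:
    """C0 by log-linear back-extrapolation of the first two positive points."""
    pos = c > 0
    tp, cp = t[pos], c[pos]
    if tp.size < 2:
        raise InsufficientDataError("need >=2 positive points to extrapolate C0")
    t1, t2 = tp[0], tp[1]
    c1, c2 = cp[0], cp[1]
    if c2 >= c1:  # not declining: fall back to the first observation
        return float(c1)
    slope = (math.log(c2) - math.log(c1)) / (t2 - t1)
    return float(math.exp(math.log(c1) - slope * t1))


def nca_single_dose(profile: ConcentrationProfile, route: str | None = None) -> NCAResult:
    """Full single-dose NCA for one profile (dose at time 0)."""
    route = route or profile.route
    t, c = profile.usable()
    if t.size < 2:
        raise InsufficientDataError("need >=2 quantifiable points")

    if route == ROUTE_IV:
        c0 = _c0_extrapolated(t, c)
        if t[0] > 0:  # prepend the extrapolated point for areas from t=0
            t = np.concatenate([[0.0], t])
            c = np.concatenate([[c0], c])
        peak = c0
        tmax = 0.0
    else:
        imax = int(np.argmax(c))
        peak = float(c[imax])
        tmax = float(t[imax])
        if t[0] > 0:  # absorption phase: C(0) = 0
            t = np.concatenate([[0.0], t])
            c = np.concatenate([[0.0], c])

    seg_auc, seg_aumc = _segment_areas(t, c)
    auc_last = float(seg_auc.sum())
    aumc_last = float(seg_aumc.sum())

    try:
        lz, diag = lambda_z(profile)
    except InsufficientDataError:
        lz, diag = float("nan"), LambdaZDiagnostics(0, float("nan"), float("nan"), float("nan"))

    nan = float("nan")
    if math.isfinite(lz) and lz > 0:
        c_last, t_last = float(c[-1]), float(t[-1])
        auc_inf = auc_last + c_last / lz
        aumc_inf = aumc_last + c_last * t_last / lz + c_last / lz**2
        t_half = math.log(2.0) / lz
        if route == ROUTE_IV:
            cl = profile.dose / auc_inf
            mrt = aumc_inf / auc_inf
            vss = cl * mrt
        else:
            cl = mrt = vss = nan
    else:
        auc_inf = aumc_inf = t_half = cl = mrt = vss = nan

    return NCAResult(
        subject=profile.subject, route=route, dose=profile.dose,
        cmax_or_c0=peak, tmax=tmax, auc_last=auc_last, auc_inf=auc_inf,
        aumc_inf=aumc_inf, lambda_z=lz, t_half=t_half, cl=cl, mrt=mrt, vss=vss,
        lz_diagnostics=diag,
    )


def accumulation_ratio(
    profile_first: ConcentrationProfile,
    profile_later: ConcentrationProfile,
    tau: float,
) -> float:
    """AUC over one dosing interval, later occasion over first occasion.

    Each profile's window starts at its first sampling time (the respective
    dose time re-referenced to zero is the caller's responsibility; the
    profiles simply need to span a full ``tau``).
    """
    for prof in (profile_first, profile_later):
        t = prof.usable()[0]
        if t.size < 2 or (t[-1] - t[0]) + 1e-9 < tau:
            raise ValueError(f"profile {prof.subject!r} does not span a full interval of {tau} days")
    a_first = auc_trapezoidal(profile_first, profile_first.times[0], profile_first.times[0] + tau)
    a_later = auc_trapezoidal(profile_later, profile_later.times[0], profile_later.times[0] + tau)
    return a_later / a_first


def bioavailability(auc_sc: float, auc_iv: float, dose_sc: float, dose_iv: float) -> float:
    """Relative bioavailability F from dose-normalised areas."""
    if auc_iv <= 0:
        raise ValueError("i.v. AUC must be positive")
    return (auc_sc / dose_sc) / (auc_iv / dose_iv)


def nca_table(profiles, route: str | None = None) -> pd.DataFrame:
    """Tidy one-row-per-subject NCA summary for a collection of profiles."""
    rows = [nca_single_dose(p, route).as_dict() for p in profiles]
    return pd.DataFrame(rows)
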