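"""Population parameter estimation from event-record datasets.

Three estimation modes are provided, all sharing the proportional-error
observation model ``Y ~ Normal(F, F^2 sigma^2)`` with observation-type
specific variances (PK and PD contributions are summed, i.e. the fit is
simultaneous):

``pooled``
    Naive-pooled maximum likelihood: every observation is attributed to the
    typical animal and between-subject variability is ignored.  Fast,
    robust, and adequate when heterogeneity is modest; biased toward the
    population mean (not the median/typical value) when it is not.  The
    residual variances are profiled out in closed form.

``two_stage``
    Each subject is fitted individually (over the parameters its own data
    can support); typical values are the geometric means of the individual
    estimates and the random-effect variances are the sample variances of
    their logs.

``laplace``
    Mixed-effects estimation with log-normal random effects on a
    configurable subset of parameters, using the Laplace approximation of
    the marginal likelihood (Gauss-Newton curvature, warm-started inner MAP
    Newton iterations batched across subjects).  Run sequentially: a pooled
    warm start, then a PK block with random effects, then a PD block that
    conditions on each subject's empirical-Bayes PK parameters.  This is
    the mode to use when the data carry real between-subject variability;
    it plays the role the first-order conditional estimator plays in
    dedicated mixed-effects tools, which this package does not reimplement.

Parameters are estimated on transformed scales (log for rates, clearances,
volumes, concentrations and counts; logit for the bounded F1 and Emax), so
results are invariant to initial-value scaling and positivity/bounds hold by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .engine import batch_concentrations, batch_response
from .params import PARAM_NAMES, PopulationParameters, Regimen, VariabilitySpec
from .study import StudyDataset

__all__ = [
    "FitSpec",
    "FitResult",
    "UnidentifiableError",
    "default_initial_estimates",
    "objective_pooled",
    "fit",
    "fit_pooled",
    "two_stage",
    "fit_laplace",
]

_IDX = {n: i for i, n in enumerate(PARAM_NAMES)}
_LOGIT_PARAMS = ("f1", "emax")

DEFAULT_ETA_PK = ("cl", "vc", "ka")
DEFAULT_ETA_PD = ("r0", "kout", "ec50")


class UnidentifiableError(ValueError):
    """Raised when the requested fit is structurally unidentifiable."""


class FitFailure(RuntimeError):
    """Raised when optimisation fails irrecoverably."""


# --------------------------------------------------------------------------
# specs and results


@dataclass(frozen=True)
class FitSpec:
    """Everything that controls a fit.

    ``init`` are the starting typical values (defaults are deliberately
    crude, data-scale guesses, not any particular published estimate).
    ``blq`` is the below-quantification policy: ``"discard"`` (default) or
    ``"impute_half_lloq"``.
    """

    mode: str = "pooled"
    init: PopulationParameters | None = None
    init_omega2: dict[str, float] = field(default_factory=dict)
    init_sigma2_pk: float = 0.04
    init_sigma2_pd: float = 0.1
    blq: str = "discard"
    n_starts: int = 3
    jitter_sd: float = 0.2
    seed: int = 20
    maxiter: int = 4000
    xatol: float = 1e-6
    fatol: float = 1e-8
    eta_pk: tuple[str, ...] = DEFAULT_ETA_PK
    eta_pd: tuple[str, ...] = DEFAULT_ETA_PD
    laplace_maxiter: int = 1200
    grid_step: float = 0.25
    compute_se: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("pooled", "two_stage", "laplace"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.blq not in ("discard", "impute_half_lloq"):
            raise ValueError(f"unknown BLQ policy {self.blq!r}")
        if self.xatol <= 0 or self.fatol <= 0:
            raise ValueError("tolerances must be > 0")


def default_initial_estimates(dataset: StudyDataset | None = None) -> PopulationParameters:
    """Crude data-scale starting values.

    R0 starts at the mean of the pre-first-dose PD observations when a
    dataset is given; everything else is an order-of-magnitude guess for a
    monoclonal antibody in a small primate.
    """
    r0 = 0.5
    if dataset is not None:
        pd_obs = dataset.observations("PD", include_blq=False)
        base = pd_obs[pd_obs["TIME"] <= 0]["DV"]
        if len(base) >= 3 and base.mean() > 0:
            r0 = float(base.mean())
    return PopulationParameters(
        ka=0.5, cl=5.0, vc=50.0, q=5.0, vp=25.0, f1=0.7,
        r0=r0, kout=0.5, emax=0.9, ec50=1.0,
    )


@dataclass
class FitResult:
    """Point estimates, uncertainties, and diagnostics of one fit."""

    mode: str
    params: PopulationParameters
    se: dict[str, float]
    rse_percent: dict[str, float]
    omega2: dict[str, float]
    sigma2: dict[str, float]
    objective: float
    converged: bool
    fixed: tuple[str, ...] = ()
    messages: tuple[str, ...] = ()
    n_subjects: int = 0
    n_pk: int = 0
    n_pd: int = 0
    eta: pd.DataFrame | None = None
    shrinkage_percent: dict[str, float] = field(default_factory=dict)
    spec: FitSpec | None = None

    def bsv_percent(self, name: str) -> float:
        return 100.0 * math.sqrt(self.omega2.get(name, 0.0))

    def bsv_cv_percent(self, name: str) -> float:
        return 100.0 * math.sqrt(math.expm1(self.omega2.get(name, 0.0)))

    def parameter_table(self) -> pd.DataFrame:
        rows = []
        for name in PARAM_NAMES:
            est = getattr(self.params, name)
            rows.append(
                {
                    "parameter": name,
                    "estimate": est,
                    "rse_percent": self.rse_percent.get(name, float("nan")),
                    "bsv_percent": self.bsv_percent(name) if name in self.omega2 else float("nan"),
                    "bsv_cv_percent": self.bsv_cv_percent(name) if name in self.omega2 else float("nan"),
                    "fixed": name in self.fixed,
                }
            )
        for key, val in self.sigma2.items():
            rows.append(
                {"parameter": key, "estimate": val, "rse_percent": float("nan"),
                 "bsv_percent": float("nan"), "bsv_cv_percent": float("nan"), "fixed": False}
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"PK/PD population fit ({self.mode} mode)",
            f"  subjects: {self.n_subjects}   PK obs: {self.n_pk}   PD obs: {self.n_pd}",
            f"  -2 log-likelihood: {self.objective:.3f}   converged: {self.converged}",
            "",
            f"  {'parameter':<14}{'estimate':>12}{'%RSE':>9}{'BSV%':>9}",
        ]
        tab = self.parameter_table()
        for row in tab.itertuples():
            est = f"{row.estimate:.4g}" + ("  (fixed)" if row.fixed else "")
            rse = f"{row.rse_percent:.3g}" if np.isfinite(row.rse_percent) else "-"
            bsv = f"{row.bsv_percent:.3g}" if np.isfinite(row.bsv_percent) else "-"
            lines.append(f"  {row.parameter:<14}{est:>12}{rse:>9}{bsv:>9}")
        if self.messages:
            lines.append("")
            lines.extend(f"  note: {m}" for m in self.messages)
        return "\n".join(lines)


# --------------------------------------------------------------------------
# dataset -> fitting structures


@dataclass
class _ArmData:
    """Per-arm observation layout shared by all estimators.

    Observations are stored as (subject index, time index, value) triplets
    against the arm's unique sampling-time vectors, so the prediction engine
    runs once per arm and predictions are gathered by indexing.
    """

    label: str
    regimen: Regimen
    subject_ids: list[str]
    pk_times: np.ndarray
    pk_subj: np.ndarray
    pk_tidx: np.ndarray
    pk_y: np.ndarray
    pd_times: np.ndarray
    pd_subj: np.ndarray
    pd_tidx: np.ndarray
    pd_y: np.ndarray

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def _build_arms(dataset: StudyDataset, blq: str = "discard") -> list[_ArmData]:
    arms: list[_ArmData] = []
    records = dataset.records
    for label, grp in records.groupby("ARM", sort=True):
        subject_ids = list(dict.fromkeys(grp["ID"]))
        sidx = {s: i for i, s in enumerate(subject_ids)}
        # all subjects in an arm share the dosing schedule by construction;
        # use the first subject's dose rows
        first = grp[grp["ID"] == subject_ids[0]]
        dose_rows = first[first["DVTYPE"] == "DOSE"]
        from .params import DoseEvent, ROUTE_IV, ROUTE_SC

        regimen = Regimen(
            tuple(
                DoseEvent(float(r.TIME), float(r.AMT), ROUTE_IV if r.ROUTE == "IV" else ROUTE_SC)
                for r in dose_rows.itertuples()
            ),
            label=str(label),
        )

        def _obs(dvtype: str):
            obs = grp[grp["DVTYPE"] == dvtype]
            if blq == "discard":
                obs = obs[obs["BLQ"] == 0]
                y = obs["DV"].to_numpy(dtype=float)
            else:
                y = np.where(obs["BLQ"].to_numpy() == 1, dataset.lloq / 2.0, obs["DV"].to_numpy(dtype=float))
            t = obs["TIME"].to_numpy(dtype=float)
            subj = np.array([sidx[s] for s in obs["ID"]], dtype=int)
            times_u = np.unique(t)
            tidx = np.searchsorted(times_u, t)
            return times_u, subj, tidx, y

        pk_times, pk_subj, pk_tidx, pk_y = _obs("PK")
        pd_times, pd_subj, pd_tidx, pd_y = _obs("PD")
        arms.append(
            _ArmData(str(label), regimen, subject_ids, pk_times, pk_subj, pk_tidx, pk_y,
                     pd_times, pd_subj, pd_tidx, pd_y)
        )
    return arms


# --------------------------------------------------------------------------
# parameter transforms


def _to_internal(values: np.ndarray, names: Sequence[str]) -> np.ndarray:
    x = np.empty(len(names))
    for j, n in enumerate(names):
        v = values[_IDX[n]]
        x[j] = math.log(v / (1.0 - v)) if n in _LOGIT_PARAMS else math.log(v)
    return x


def _from_internal(x: np.ndarray, names: Sequence[str], base: np.ndarray) -> np.ndarray:
    values = base.copy()
    for j, n in enumerate(names):
        if n in _LOGIT_PARAMS:
            values[_IDX[n]] = 1.0 / (1.0 + math.exp(-x[j]))
        else:
            values[_IDX[n]] = math.exp(x[j])
    return values


def _natural_se(x: np.ndarray, se_x: np.ndarray, names: Sequence[str]) -> dict[str, float]:
    out = {}
    for j, n in enumerate(names):
        if n in _LOGIT_PARAMS:
            p = 1.0 / (1.0 + math.exp(-x[j]))
            out[n] = se_x[j] * p * (1.0 - p)
        else:
            out[n] = se_x[j] * math.exp(x[j])
    return out


# --------------------------------------------------------------------------
# pooled objective


_LOG_2PI = math.log(2.0 * math.pi)


def _pooled_predictions(theta: np.ndarray, arms: list[_ArmData], step: float):
    """Flat (F_pk, F_pd) prediction vectors for the typical subject."""
    f_pk, f_pd = [], []
    row = theta[None, :]
    for arm in arms:
        if arm.pk_y.size:
            c = batch_concentrations(row, arm.regimen, arm.pk_times)[0]
            f_pk.append(c[arm.pk_tidx])
        if arm.pd_y.size:
            r = batch_response(row, arm.regimen, arm.pd_times, step=step)[0]
            f_pd.append(r[arm.pd_tidx])
    cat = lambda parts: np.concatenate(parts) if parts else np.empty(0)
    return cat(f_pk), cat(f_pd)


def _neg2ll_proportional(y: np.ndarray, f: np.ndarray, sigma2: float | None) -> tuple[float, float]:
    """(-2LL, sigma2-used); profiles sigma2 when None."""
    if y.size == 0:
        return 0.0, float("nan")
    u2 = ((y - f) / f) ** 2
    if sigma2 is None:
        sigma2 = float(np.mean(u2))
        sigma2 = max(sigma2, 1e-12)
    val = y.size * (math.log(sigma2) + _LOG_2PI) + float(np.sum(u2)) / sigma2 + 2.0 * float(np.sum(np.log(f)))
    return val, sigma2


def objective_pooled(
    dataset_or_arms,
    params: PopulationParameters,
    sigma2_pk: float | None = None,
    sigma2_pd: float | None = None,
    blq: str = "discard",
    grid_step: float = 0.25,
) -> float:
    """-2 log-likelihood of the naive-pooled model, PK and PD summed.

    Residual variances may be fixed or profiled (None).  Non-positive
    predictions at observation times are penalised rather than crashing the
    optimiser.
    """
    arms = dataset_or_arms if isinstance(dataset_or_arms, list) else _build_arms(dataset_or_arms, blq)
    y_pk = np.concatenate([a.pk_y for a in arms]) if arms else np.empty(0)
    y_pd = np.concatenate([a.pd_y for a in arms]) if arms else np.empty(0)
    if y_pk.size == 0 and y_pd.size == 0:
        raise ValueError("no observations to fit")
    f_pk, f_pd = _pooled_predictions(params.as_array(), arms, grid_step)
    return _objective_from_predictions(y_pk, f_pk, y_pd, f_pd, sigma2_pk, sigma2_pd)[0]


def _objective_from_predictions(y_pk, f_pk, y_pd, f_pd, sigma2_pk, sigma2_pd):
    penalty = 0.0
    for f in (f_pk, f_pd):
        bad = f <= 1e-12
        if bad.any():
            penalty += 1e8 * float(bad.sum())
    if penalty:
        return 1e12 + penalty, sigma2_pk, sigma2_pd
    v_pk, s_pk = _neg2ll_proportional(y_pk, f_pk, sigma2_pk)
    v_pd, s_pd = _neg2ll_proportional(y_pd, f_pd, sigma2_pd)
    return v_pk + v_pd, s_pk, s_pd


# --------------------------------------------------------------------------
# identifiability bookkeeping


def _identifiability(arms: list[_ArmData]) -> tuple[set[str], list[str]]:
    """Free structural parameters supported by the dosing routes present."""
    routes = {e.route for a in arms for e in a.regimen.events}
    fixed: set[str] = set()
    notes: list[str] = []
    from .params import ROUTE_IV, ROUTE_SC

    if ROUTE_SC not in routes:
        fixed |= {"ka", "f1"}
        notes.append("no s.c. doses: ka and f1 are unidentifiable and fixed at their initial values")
    elif ROUTE_IV not in routes:
        fixed |= {"f1"}
        notes.append("no i.v. doses: f1 cannot be separated from CL/Vc and is fixed at its initial value")
    return fixed, notes


# --------------------------------------------------------------------------
# pooled fit


_PK_NAMES = ("ka", "cl", "vc", "q", "vp", "f1")
_PD_NAMES = ("r0", "kout", "emax", "ec50")


def _pk_predictions(theta: np.ndarray, arms: list[_ArmData]) -> np.ndarray:
    parts = []
    row = theta[None, :]
    for arm in arms:
        if arm.pk_y.size:
            c = batch_concentrations(row, arm.regimen, arm.pk_times)[0]
            parts.append(c[arm.pk_tidx])
    return np.concatenate(parts) if parts else np.empty(0)


def _pd_predictions(theta: np.ndarray, arms: list[_ArmData], step: float) -> np.ndarray:
    parts = []
    row = theta[None, :]
    for arm in arms:
        if arm.pd_y.size:
            r = batch_response(row, arm.regimen, arm.pd_times, step=step)[0]
            parts.append(r[arm.pd_tidx])
    return np.concatenate(parts) if parts else np.empty(0)


def _staged_minimize(
    arms: list[_ArmData],
    base: np.ndarray,
    free: Sequence[str],
    x0: np.ndarray,
    spec: FitSpec,
) -> "minimize":
    """Pooled optimisation in three stages: PK block alone, PD block alone,
    then the simultaneous objective.  Far more robust than a cold 10-dim
    simplex and cheaper, since the single-block evaluations are much faster
    than the joint one."""
    y_pk = np.concatenate([a.pk_y for a in arms])
    y_pd = np.concatenate([a.pd_y for a in arms])
    free = list(free)
    empty = np.empty(0)

    def joint(x: np.ndarray) -> float:
        theta = _from_internal(x, free, base)
        f_pk, f_pd = _pooled_predictions(theta, arms, spec.grid_step)
        return _objective_from_predictions(y_pk, f_pk, y_pd, f_pd, None, None)[0]

    x = x0.copy()
    pk_idx = [j for j, n in enumerate(free) if n in _PK_NAMES]
    pd_idx = [j for j, n in enumerate(free) if n in _PD_NAMES]

    if pk_idx and y_pk.size:
        def pk_obj(sub: np.ndarray) -> float:
            xx = x.copy()
            xx[pk_idx] = sub
            theta = _from_internal(xx, free, base)
            return _objective_from_predictions(y_pk, _pk_predictions(theta, arms), empty, empty, None, None)[0]

        r = minimize(pk_obj, x[pk_idx], method="Nelder-Mead",
                     options=dict(maxiter=1500, xatol=1e-5, fatol=1e-7))
        x[pk_idx] = r.x
    if pd_idx and y_pd.size:
        def pd_obj(sub: np.ndarray) -> float:
            xx = x.copy()
            xx[pd_idx] = sub
            theta = _from_internal(xx, free, base)
            return _objective_from_predictions(empty, empty, y_pd, _pd_predictions(theta, arms, spec.grid_step), None, None)[0]

        r = minimize(pd_obj, x[pd_idx], method="Nelder-Mead",
                     options=dict(maxiter=1500, xatol=1e-5, fatol=1e-7))
        x[pd_idx] = r.x

    return minimize(joint, x, method="Nelder-Mead",
                    options=dict(maxiter=spec.maxiter, xatol=spec.xatol, fatol=spec.fatol))


def fit_pooled(dataset: StudyDataset, spec: FitSpec) -> FitResult:
    arms = _build_arms(dataset, spec.blq)
    n_pk = int(sum(a.pk_y.size for a in arms))
    n_pd = int(sum(a.pd_y.size for a in arms))
    if n_pk == 0 or n_pd == 0:
        raise UnidentifiableError(
            f"simultaneous fit requires both PK and PD observations (found {n_pk} PK, {n_pd} PD); "
            "refusing to fit"
        )
    init = spec.init or default_initial_estimates(dataset)
    fixed, notes = _identifiability(arms)
    free = [n for n in PARAM_NAMES if n not in fixed]
    base = init.as_array()
    y_pk = np.concatenate([a.pk_y for a in arms])
    y_pd = np.concatenate([a.pd_y for a in arms])

    def objective(x: np.ndarray) -> float:
        theta = _from_internal(x, free, base)
        f_pk, f_pd = _pooled_predictions(theta, arms, spec.grid_step)
        return _objective_from_predictions(y_pk, f_pk, y_pd, f_pd, None, None)[0]

    x0 = _to_internal(base, free)
    rng = np.random.default_rng(spec.seed)
    best = None
    for s in range(max(1, spec.n_starts)):
        xs = x0 if s == 0 else x0 + rng.normal(0.0, spec.jitter_sd, size=x0.size)
        res = _staged_minimize(arms, base, free, xs, spec)
        if best is None or res.fun < best.fun:
            best = res
    res = best

    theta = _from_internal(res.x, free, base)
    params = PopulationParameters.from_array(theta)
    f_pk, f_pd = _pooled_predictions(theta, arms, spec.grid_step)
    obj, s_pk, s_pd = _objective_from_predictions(y_pk, f_pk, y_pd, f_pd, None, None)

    se, rse = {}, {}
    if spec.compute_se:
        se_x = _fd_se(objective, res.x)
        se = _natural_se(res.x, se_x, free)
        rse = {n: 100.0 * se[n] / getattr(params, n) for n in free}

    return FitResult(
        mode="pooled", params=params, se=se, rse_percent=rse,
        omega2={}, sigma2={"prop_pk": s_pk, "prop_pd": s_pd},
        objective=float(obj), converged=bool(res.success or res.fun <= best.fun),
        fixed=tuple(sorted(fixed)), messages=tuple(notes),
        n_subjects=sum(a.n_subjects for a in arms), n_pk=n_pk, n_pd=n_pd, spec=spec,
    )


def _fd_se(fun: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Standard errors from a central-difference Hessian of a -2LL surface."""
    n = x.size
    hess = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h * h)
    try:
        cov = 2.0 * np.linalg.inv(hess)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)


# --------------------------------------------------------------------------
# two-stage


def _subject_arms(arms: list[_ArmData]) -> list[tuple[str, _ArmData]]:
    """Split arm structures into single-subject structures."""
    out = []
    for arm in arms:
        for i, sid in enumerate(arm.subject_ids):
            mk = arm.pk_subj == i
            md = arm.pd_subj == i
            sub = _ArmData(
                label=arm.label, regimen=arm.regimen, subject_ids=[sid],
                pk_times=arm.pk_times, pk_subj=np.zeros(mk.sum(), dtype=int),
                pk_tidx=arm.pk_tidx[mk], pk_y=arm.pk_y[mk],
                pd_times=arm.pd_times, pd_subj=np.zeros(md.sum(), dtype=int),
                pd_tidx=arm.pd_tidx[md], pd_y=arm.pd_y[md],
            )
            out.append((sid, sub))
    return out


def _subject_free_names(sub: _ArmData, spec: FitSpec) -> list[str]:
    """Parameters a single subject's data can plausibly support."""
    from .params import ROUTE_SC

    free: list[str] = []
    n_pk, n_pd = sub.pk_y.size, sub.pd_y.size
    has_sc = any(e.route == ROUTE_SC for e in sub.regimen.events)
    if n_pk >= 5:
        free += ["cl", "vc", "q", "vp"]
        if has_sc:
            free += ["ka"]
    elif n_pk >= 3:
        free += ["cl", "vc"]
    if n_pd >= 6 and len(sub.regimen):
        free += ["r0", "kout", "ec50", "emax"]
    elif n_pd >= 4 and len(sub.regimen):
        free += ["r0", "kout"]
    elif n_pd >= 2:
        free += ["r0"]
    return free


def two_stage(dataset: StudyDataset, spec: FitSpec) -> FitResult:
    """Per-subject fits, then log-scale mean/variance across subjects.

    Subjects whose individual fit fails (too little data, optimiser failure)
    are dropped with a logged message; more than 50% failures aborts.
    """
    arms = _build_arms(dataset, spec.blq)
    subjects = _subject_arms(arms)
    if len(subjects) < 3:
        raise UnidentifiableError("two-stage estimation needs at least 3 subjects")
    init = spec.init or default_initial_estimates(dataset)
    base = init.as_array()
    notes: list[str] = []

    estimates: dict[str, dict[str, float]] = {}
    n_attempted = 0
    for sid, sub in subjects:
        if sub.pk_y.size + sub.pd_y.size < 4:
            notes.append(f"{sid}: fewer than 4 observations, skipped")
            continue
        free = _subject_free_names(sub, spec)
        if not free:
            notes.append(f"{sid}: no identifiable parameters, skipped")
            continue
        n_attempted += 1
        try:
            x0 = _to_internal(base, free)
            sub_spec = replace(spec, maxiter=min(spec.maxiter, 2000), xatol=1e-6, fatol=1e-9)
            res = _staged_minimize([sub], base, free, x0, sub_spec)
            theta = _from_internal(res.x, free, base)
            for name in free:
                estimates.setdefault(name, {})[sid] = theta[_IDX[name]]
        except Exception as exc:  # noqa: BLE001 - failures are data, not bugs
            notes.append(f"{sid}: individual fit failed ({exc})")

    n_ok = len({s for d in estimates.values() for s in d})
    if n_attempted and n_ok < 0.5 * n_attempted:
        raise FitFailure(f"more than half of the individual fits failed ({n_ok}/{n_attempted} usable)")

    values = base.copy()
    se: dict[str, float] = {}
    omega2: dict[str, float] = {}
    fixed = [n for n in PARAM_NAMES if n not in estimates]
    for name, per_subj in estimates.items():
        logs = np.log(np.array(list(per_subj.values())))
        values[_IDX[name]] = math.exp(float(np.mean(logs)))
        if logs.size >= 2:
            omega2[name] = float(np.var(logs, ddof=1))
            se[name] = float(np.std(logs, ddof=1) / math.sqrt(logs.size)) * values[_IDX[name]]
    values[_IDX["emax"]] = min(values[_IDX["emax"]], 1.0)
    params = PopulationParameters.from_array(values)
    rse = {n: 100.0 * se[n] / getattr(params, n) for n in se}

    f_pk, f_pd = _pooled_predictions(values, arms, spec.grid_step)
    y_pk = np.concatenate([a.pk_y for a in arms])
    y_pd = np.concatenate([a.pd_y for a in arms])
    obj, s_pk, s_pd = _objective_from_predictions(y_pk, f_pk, y_pd, f_pd, None, None)

    return FitResult(
        mode="two_stage", params=params, se=se, rse_percent=rse, omega2=omega2,
        sigma2={"prop_pk": s_pk, "prop_pd": s_pd}, objective=float(obj),
        converged=True, fixed=tuple(sorted(fixed)), messages=tuple(notes[:50]),
        n_subjects=len(subjects), n_pk=int(y_pk.size), n_pd=int(y_pd.size), spec=spec,
    )


# --------------------------------------------------------------------------
# Laplace mixed-effects


def _arm_predict(theta_mat: np.ndarray, arm: _ArmData, dvtype: str, step: float,
                 cache: dict | None = None) -> np.ndarray:
    """Flat per-observation predictions for one arm given per-subject thetas."""
    if dvtype == "PK":
        pred = batch_concentrations(theta_mat, arm.regimen, arm.pk_times)
        return pred[arm.pk_subj, arm.pk_tidx]
    pred = batch_response(theta_mat, arm.regimen, arm.pd_times, step=step, _cache=cache)
    return pred[arm.pd_subj, arm.pd_tidx]


class _LaplaceBlock:
    """Marginal -2LL of one observation block (PK or PD) under the Laplace
    approximation, with warm-started batched inner MAP iterations."""

    def __init__(
        self,
        arms: list[_ArmData],
        dvtype: str,
        eta_names: tuple[str, ...],
        base_mult: dict[str, np.ndarray] | None,
        step: float,
    ) -> None:
        self.dvtype = dvtype
        self.eta_names = eta_names
        self.eta_idx = np.array([_IDX[n] for n in eta_names], dtype=int)
        self.step = step
        self.arms = [a for a in arms if (a.pk_y.size if dvtype == "PK" else a.pd_y.size) > 0]
        # per-arm multiplicative individual adjustments (e.g. EB PK etas)
        self.base_mult = base_mult or {a.label: np.ones((a.n_subjects, len(PARAM_NAMES))) for a in self.arms}
        self.warm = {a.label: np.zeros((a.n_subjects, len(eta_names))) for a in self.arms}
        self.conc_cache: dict[str, dict] = {a.label: {} for a in self.arms}
        self.n_obs = int(sum((a.pk_y.size if dvtype == "PK" else a.pd_y.size) for a in self.arms))

    def _y(self, arm: _ArmData) -> np.ndarray:
        return arm.pk_y if self.dvtype == "PK" else arm.pd_y

    def _subj(self, arm: _ArmData) -> np.ndarray:
        return arm.pk_subj if self.dvtype == "PK" else arm.pd_subj

    def _theta_mat(self, arm: _ArmData, theta: np.ndarray, eta: np.ndarray) -> np.ndarray:
        mat = np.tile(theta, (arm.n_subjects, 1)) * self.base_mult[arm.label]
        mat[:, self.eta_idx] *= np.exp(np.clip(eta, -12.0, 12.0))
        # keep individual emax physical
        mat[:, _IDX["emax"]] = np.minimum(mat[:, _IDX["emax"]], 1.0)
        return mat

    def _curvature(self, jac: np.ndarray, f0: np.ndarray, y: np.ndarray,
                   subj: np.ndarray, n_sub: int, sigma2: float, om_inv: np.ndarray,
                   d: int) -> np.ndarray:
        """Per-subject Hessian approximation of the conditional objective.

        Uses the exact second derivative of the proportional-error term with
        respect to the prediction, (3u^2 - 2u)/sigma^2 - 1 with u = y/F
        (floored away from zero for stability), times the prediction
        Jacobian outer products; second derivatives of F itself are
        neglected, as in conditional-estimation practice.
        """
        f = np.maximum(f0, 1e-12)
        u = y / f
        w = np.maximum((3.0 * u * u - 2.0 * u) / sigma2 - 1.0, 0.3 / sigma2) / (f * f)
        hess = np.zeros((n_sub, d, d))
        np.add.at(hess, subj, (jac[:, :, None] * jac[:, None, :]) * w[:, None, None])
        hess += np.eye(d)[None, :, :] * om_inv[None, :]
        return hess

    def neg2ll(self, theta: np.ndarray, omega2: np.ndarray, sigma2: float,
               inner_iters: int = 12) -> float:
        d = len(self.eta_names)
        om_inv = 1.0 / np.maximum(omega2, 1e-10)
        logdet_om = float(np.sum(np.log(np.maximum(omega2, 1e-10))))
        total = 0.0
        h = 1e-5
        for arm in self.arms:
            y = self._y(arm)
            subj = self._subj(arm)
            n_sub = arm.n_subjects
            eta = self.warm[arm.label].copy()

            def g_parts(eta_m: np.ndarray):
                f = _arm_predict(self._theta_mat(arm, theta, eta_m), arm, self.dvtype, self.step,
                                 cache=self.conc_cache[arm.label])
                f = np.maximum(f, 1e-12)
                u2 = ((y - f) / f) ** 2
                per_obs = u2 / sigma2 + np.log(sigma2) + 2.0 * np.log(f) + _LOG_2PI
                g_data = np.zeros(n_sub)
                np.add.at(g_data, subj, 0.5 * per_obs)
                g_prior = 0.5 * np.sum(eta_m * eta_m * om_inv, axis=1) + 0.5 * (logdet_om + d * _LOG_2PI)
                return f, g_data + g_prior

            def jacobian(eta_m: np.ndarray, f0: np.ndarray) -> np.ndarray:
                jac = np.empty((y.size, d))
                for k in range(d):
                    ep = eta_m.copy()
                    ep[:, k] += h
                    fk = _arm_predict(self._theta_mat(arm, theta, ep), arm, self.dvtype, self.step,
                                      cache=self.conc_cache[arm.label])
                    jac[:, k] = (fk - f0) / h
                return jac

            f0, g0 = g_parts(eta)
            jac = None
            for _ in range(inner_iters):
                jac = jacobian(eta, f0)
                f = np.maximum(f0, 1e-12)
                # gradient: sum_o J_o * [1/F - (y-F)y/(F^3 s2)] + Om^-1 eta
                coef = 1.0 / f - (y - f0) * y / (f ** 3 * sigma2)
                grad = np.zeros((n_sub, d))
                np.add.at(grad, subj, jac * coef[:, None])
                grad += eta * om_inv
                if float(np.abs(grad).max()) < 1e-3:
                    break
                hess = self._curvature(jac, f0, y, subj, n_sub, sigma2, om_inv, d)
                try:
                    delta = -np.linalg.solve(hess, grad[..., None])[..., 0]
                except np.linalg.LinAlgError:
                    break
                # cap steps: random effects live on the log scale, jumps
                # beyond ~2 per iteration are never warranted
                dmax = np.max(np.abs(delta), axis=1, keepdims=True)
                delta *= np.minimum(1.0, 2.0 / np.maximum(dmax, 1e-300))
                # damped update, per-subject backtracking
                improved = np.zeros(n_sub, dtype=bool)
                scale = np.ones(n_sub)
                eta_new, g_new, f_new = eta, g0, f0
                for _bt in range(4):
                    trial = np.clip(eta + scale[:, None] * delta, -10.0, 10.0)
                    f_t, g_t = g_parts(trial)
                    better = g_t < g_new - 1e-12
                    upd = better & ~improved
                    if upd.any():
                        eta_new = np.where(upd[:, None], trial, eta_new)
                        g_new = np.where(upd, g_t, g_new)
                        mask_obs = upd[subj]
                        f_new = np.where(mask_obs, f_t, f_new)
                        improved |= upd
                    scale = np.where(improved, scale, scale * 0.5)
                    if improved.all():
                        break
                if not improved.any():
                    break  # local mode within backtracking resolution
                eta, g0, f0 = eta_new, g_new, f_new

            # Laplace correction with the same curvature at the mode
            jac = jacobian(eta, f0)
            hess = self._curvature(jac, f0, y, subj, n_sub, sigma2, om_inv, d)
            sign, logdet = np.linalg.slogdet(hess)
            total += float(np.sum(2.0 * g0 + logdet - d * _LOG_2PI))
            self.warm[arm.label] = eta
        return total

    def eb_etas(self) -> dict[str, np.ndarray]:
        """Current per-arm MAP random effects (empirical Bayes estimates)."""
        return {label: eta.copy() for label, eta in self.warm.items()}


def _nm_with_restart(fun, x0, maxiter: int):
    """Nelder-Mead with one restart from the found optimum.

    Restarting re-inflates the simplex, which reliably escapes the premature
    collapse NM is prone to in 8-10 dimensions with mildly noisy objectives;
    the restarted run is usually short."""
    opts = dict(maxiter=maxiter, xatol=1e-4, fatol=1e-3)
    res = minimize(fun, x0, method="Nelder-Mead", options=opts)
    res2 = minimize(fun, res.x, method="Nelder-Mead", options=opts)
    return res2 if res2.fun <= res.fun else res


def _nm_converged(res) -> bool:
    """Accept a Nelder-Mead stop as converged when the final simplex is
    flat on the -2LL scale even if the iteration cap was reached."""
    if res.success:
        return True
    try:
        fvals = res.final_simplex[1]
        return bool(np.max(fvals) - np.min(fvals) < 1.0)
    except Exception:
        return False


def fit_laplace(dataset: StudyDataset, spec: FitSpec) -> FitResult:
    """Sequential mixed-effects fit: pooled warm start, PK block with
    random effects, then PD block conditioned on empirical-Bayes PK."""
    arms = _build_arms(dataset, spec.blq)
    n_pk = int(sum(a.pk_y.size for a in arms))
    n_pd = int(sum(a.pd_y.size for a in arms))
    if n_pk == 0 or n_pd == 0:
        raise UnidentifiableError(
            f"simultaneous fit requires both PK and PD observations (found {n_pk} PK, {n_pd} PD)"
        )
    fixed, notes = _identifiability(arms)

    # coarse pooled warm start: multistart guards the nonlinear PD
    # parameters, but fine polishing is wasted ahead of the mixed stages
    pooled_spec = replace(spec, mode="pooled", compute_se=False,
                          maxiter=min(spec.maxiter, 1500), xatol=1e-4, fatol=1e-6)
    pooled = fit_pooled(dataset, pooled_spec)
    theta0 = pooled.params.as_array()
    notes = list(notes) + ["pooled warm start (multistart) preceded the mixed-effects stages"]

    # ---- PK block ------------------------------------------------------
    eta_pk = tuple(n for n in spec.eta_pk if n not in fixed)
    pk_free = [n for n in ("ka", "cl", "vc", "q", "vp", "f1") if n not in fixed]
    pk_block = _LaplaceBlock(arms, "PK", eta_pk, None, spec.grid_step)
    om0 = np.array([spec.init_omega2.get(n, 0.05) for n in eta_pk])
    s0 = max(pooled.sigma2["prop_pk"], 1e-4)

    def pk_obj(xz: np.ndarray) -> float:
        theta = _from_internal(xz[: len(pk_free)], pk_free, theta0)
        om = np.exp(xz[len(pk_free):-1])
        s2 = math.exp(xz[-1])
        return pk_block.neg2ll(theta, om, s2)

    x_pk0 = np.concatenate([_to_internal(theta0, pk_free), np.log(om0), [math.log(s0)]])
    res_pk = _nm_with_restart(pk_obj, x_pk0, spec.laplace_maxiter)
    theta_pk = _from_internal(res_pk.x[: len(pk_free)], pk_free, theta0)
    om_pk = np.exp(res_pk.x[len(pk_free):-1])
    s2_pk = math.exp(res_pk.x[-1])
    pk_obj(res_pk.x)  # refresh warm etas at the optimum

    # EB PK multipliers for the PD stage
    eb = pk_block.eb_etas()
    eta_pk_idx = np.array([_IDX[n] for n in eta_pk], dtype=int)
    base_mult = {}
    for arm in arms:
        mult = np.ones((arm.n_subjects, len(PARAM_NAMES)))
        if arm.label in eb and len(eta_pk):
            mult[:, eta_pk_idx] = np.exp(eb[arm.label])
        base_mult[arm.label] = mult

    # ---- PD block ------------------------------------------------------
    eta_pd = tuple(spec.eta_pd)
    pd_free = ["r0", "kout", "emax", "ec50"]
    theta_base_pd = theta_pk.copy()
    pd_block = _LaplaceBlock(arms, "PD", eta_pd, base_mult, spec.grid_step)
    om0_pd = np.array([spec.init_omega2.get(n, 0.1) for n in eta_pd])
    s0_pd = max(pooled.sigma2["prop_pd"], 1e-4)

    def pd_obj(xz: np.ndarray) -> float:
        theta = _from_internal(xz[: len(pd_free)], pd_free, theta_base_pd)
        om = np.exp(xz[len(pd_free):-1])
        s2 = math.exp(xz[-1])
        return pd_block.neg2ll(theta, om, s2)

    x_pd0 = np.concatenate([_to_internal(theta0, pd_free), np.log(om0_pd), [math.log(s0_pd)]])
    res_pd = _nm_with_restart(pd_obj, x_pd0, spec.laplace_maxiter)
    theta_pd = _from_internal(res_pd.x[: len(pd_free)], pd_free, theta_base_pd)
    om_pd = np.exp(res_pd.x[len(pd_free):-1])
    s2_pd = math.exp(res_pd.x[-1])
    pd_obj(res_pd.x)

    values = theta_pk.copy()
    for n in pd_free:
        values[_IDX[n]] = theta_pd[_IDX[n]]
    params = PopulationParameters.from_array(values)
    omega2 = {n: float(w) for n, w in zip(eta_pk, om_pk)}
    omega2.update({n: float(w) for n, w in zip(eta_pd, om_pd)})

    # standard errors from the outer FD Hessians, block-wise
    se: dict[str, float] = {}
    rse: dict[str, float] = {}
    if spec.compute_se:
        se_pk = _fd_se(pk_obj, res_pk.x, h=1e-3)
        se.update(_natural_se(res_pk.x[: len(pk_free)], se_pk[: len(pk_free)], pk_free))
        se_pd = _fd_se(pd_obj, res_pd.x, h=1e-3)
        se.update(_natural_se(res_pd.x[: len(pd_free)], se_pd[: len(pd_free)], pd_free))
        rse = {n: 100.0 * se[n] / getattr(params, n) for n in se}

    # EB etas and shrinkage
    eta_frames = []
    for arm in arms:
        if arm.label in pd_block.warm:
            frame = pd.DataFrame(pd_block.warm[arm.label], columns=[f"eta_{n}" for n in eta_pd])
            frame.insert(0, "ID", arm.subject_ids)
            eta_frames.append(frame)
    eta_df = pd.concat(eta_frames, ignore_index=True) if eta_frames else None
    shrink = {}
    if eta_df is not None:
        for n, w in zip(eta_pd, om_pd):
            if w > 0:
                shrink[n] = 100.0 * (1.0 - float(eta_df[f"eta_{n}"].std(ddof=1)) / math.sqrt(w))

    converged = bool(_nm_converged(res_pk) and _nm_converged(res_pd))
    return FitResult(
        mode="laplace", params=params, se=se, rse_percent=rse, omega2=omega2,
        sigma2={"prop_pk": float(s2_pk), "prop_pd": float(s2_pd)},
        objective=float(res_pk.fun + res_pd.fun), converged=converged,
        fixed=tuple(sorted(fixed)), messages=tuple(notes),
        n_subjects=sum(a.n_subjects for a in arms), n_pk=n_pk, n_pd=n_pd,
        eta=eta_df, shrinkage_percent=shrink, spec=spec,
    )


def fit(dataset: StudyDataset, spec: FitSpec | None = None) -> FitResult:
    """Fit the population model to an event-record dataset (mode dispatch)."""
    spec = spec or FitSpec()
    if spec.mode == "pooled":
        return fit_pooled(dataset, spec)
    if spec.mode == "two_stage":
        return two_stage(dataset, spec)
    return fit_laplace(dataset, spec)
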