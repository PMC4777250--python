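"""Goodness-of-fit residuals and the visual predictive check (VPC).

The VPC simulates many replicate studies under the fitted (or assumed)
population model — re-drawing between-subject random effects and residual
errors for the same designs as the observed dataset — and summarises each
nominal sampling time by the 5th, 50th and 95th percentiles of the simulated
observations.  A well-specified model should leave roughly 90% of the
observed points inside the 5th-95th band.

Replicate studies are simulated with the analytic/exponential-integrator
prediction engine (hundreds of replicates would be needlessly slow through
the stiff ODE solver; the two agree to ~0.1%, far below the residual noise).
Time bins are the exact nominal sampling times, since the bundled designs
are balanced.  BLQ observations are plotted at the quantification limit and
excluded from coverage counts.

Residual diagnostics report population weighted residuals,
``(Y - F) / (F * sigma)``, under the proportional-error model.  These play
the role conditional weighted residuals play in linearisation-based
mixed-effects software; they are an approximation to those, not a
reimplementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import batch_concentrations, batch_response
from .estimation import FitResult, _build_arms
from .params import PARAM_NAMES, PopulationParameters, VariabilitySpec
from .study import StudyDataset, _draw_etas, _individual_from_eta

__all__ = ["VPCResult", "vpc", "coverage", "residual_table", "plot_vpc"]

_IDX = {n: i for i, n in enumerate(PARAM_NAMES)}


@dataclass
class VPCResult:
    """Percentile bands and observed overlay, one row per arm x type x time.

    ``bands`` columns: ARM, DVTYPE, TIME, p5, p50, p95, n_sim.
    ``observed`` columns: ARM, DVTYPE, TIME, DV, BLQ.
    """

    bands: pd.DataFrame
    observed: pd.DataFrame
    n_reps: int
    seed: int | None = None
    lloq: float = 0.1

    def arm_bands(self, arm: str, dvtype: str) -> pd.DataFrame:
        b = self.bands
        return b[(b["ARM"] == arm) & (b["DVTYPE"] == dvtype)].sort_values("TIME")


def vpc(
    dataset: StudyDataset,
    params: PopulationParameters,
    var: VariabilitySpec,
    n_reps: int = 500,
    seed: int | np.random.Generator = 0,
    grid_step: float = 0.25,
) -> VPCResult:
    """Visual predictive check of ``dataset`` against the population model.

    The replicate designs (arms, dose schedules, subject counts, sampling
    times) are recovered from the dataset's own dose and observation
    records.  Percentiles are computed per nominal time across all simulated
    subjects and replicates.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    arms = _build_arms(dataset, blq="discard")
    sd_pk = float(np.sqrt(var.sigma2_prop_pk))
    sd_pd = float(np.sqrt(var.sigma2_prop_pd))

    band_rows = []
    obs_frames = []
    for arm in arms:
        n_sub = arm.n_subjects
        sims = {"PK": [], "PD": []}
        for _ in range(n_reps):
            eta = _draw_etas(var, rng, n_sub)
            theta = np.vstack([
                _individual_from_eta(params, eta[i]).as_array() for i in range(n_sub)
            ])
            if arm.pk_times.size and len(arm.regimen):
                c = batch_concentrations(theta, arm.regimen, arm.pk_times)
                y = c * (1.0 + rng.normal(0.0, sd_pk, size=c.shape)) if sd_pk > 0 else c
                sims["PK"].append(y)
            if arm.pd_times.size:
                r = batch_response(theta, arm.regimen, arm.pd_times, step=grid_step)
                y = r * (1.0 + rng.normal(0.0, sd_pd, size=r.shape)) if sd_pd > 0 else r
                sims["PD"].append(np.maximum(y, 0.0))
        for dvtype, times in (("PK", arm.pk_times), ("PD", arm.pd_times)):
            if not sims[dvtype]:
                continue
            stack = np.concatenate(sims[dvtype], axis=0)  # (reps*n_sub, n_times)
            p5, p50, p95 = np.percentile(stack, [5.0, 50.0, 95.0], axis=0)
            for k, t in enumerate(times):
                band_rows.append(
                    dict(ARM=arm.label, DVTYPE=dvtype, TIME=float(t),
                         p5=float(p5[k]), p50=float(p50[k]), p95=float(p95[k]),
                         n_sim=stack.shape[0])
                )

    obs = dataset.records[dataset.records["DVTYPE"].isin(["PK", "PD"])]
    observed = obs[["ARM", "DVTYPE", "TIME", "DV", "BLQ"]].copy()
    observed.loc[observed["BLQ"] == 1, "DV"] = dataset.lloq

    bands = pd.DataFrame(band_rows)
    # percentile ordering is structural; assert it rather than trust it
    assert (bands["p5"] <= bands["p50"]).all() and (bands["p50"] <= bands["p95"]).all()
    return VPCResult(
        bands=bands, observed=observed, n_reps=n_reps,
        seed=int(seed) if isinstance(seed, (int, np.integer)) else None,
        lloq=dataset.lloq,
    )


def coverage(result: VPCResult) -> float:
    """Fraction of non-BLQ observed points inside the 5th-95th band."""
    merged = result.observed[result.observed["BLQ"] == 0].merge(
        result.bands, on=["ARM", "DVTYPE", "TIME"], how="inner"
    )
    if merged.empty:
        raise ValueError("no observed points align with VPC bands")
    inside = (merged["DV"] >= merged["p5"]) & (merged["DV"] <= merged["p95"])
    return float(inside.mean())


def residual_table(dataset: StudyDataset, fit: FitResult, grid_step: float = 0.25) -> pd.DataFrame:
    """Per-observation predictions and weighted residuals for a fitted model.

    Columns: ID, ARM, DVTYPE, TIME, DV, PRED (population prediction), IPRED
    (individual prediction where empirical-Bayes random effects exist, else
    equal to PRED), WRES = (DV - PRED)/(PRED*sigma).  Observations with an
    undefined residual (PRED = 0) are flagged in the ``flag`` column.
    """
    if not fit.converged:
        raise ValueError("residual diagnostics require a converged fit")
    arms = _build_arms(dataset, blq="discard")
    sig = {"PK": np.sqrt(fit.sigma2.get("prop_pk", np.nan)),
           "PD": np.sqrt(fit.sigma2.get("prop_pd", np.nan))}
    theta = fit.params.as_array()

    eta_map: dict[str, np.ndarray] = {}
    eta_cols: list[str] = []
    if fit.eta is not None:
        eta_cols = [c for c in fit.eta.columns if c.startswith("eta_")]
        for row in fit.eta.itertuples(index=False):
            eta_map[row.ID] = np.array([getattr(row, c) for c in eta_cols])

    rows = []
    for arm in arms:
        pred_pk = batch_concentrations(theta[None, :], arm.regimen, arm.pk_times)[0] if arm.pk_times.size else None
        pred_pd = batch_response(theta[None, :], arm.regimen, arm.pd_times, step=grid_step)[0] if arm.pd_times.size else None

        ipred_cache: dict[str, tuple[np.ndarray | None, np.ndarray | None]] = {}

        def ipred_for(sid: str):
            if sid in ipred_cache:
                return ipred_cache[sid]
            if sid not in eta_map or not eta_cols:
                ipred_cache[sid] = (pred_pk, pred_pd)
                return ipred_cache[sid]
            th = theta.copy()
            for c, e in zip(eta_cols, eta_map[sid]):
                th[_IDX[c[4:]]] *= np.exp(e)
            ipk = batch_concentrations(th[None, :], arm.regimen, arm.pk_times)[0] if arm.pk_times.size else None
            ipd = batch_response(th[None, :], arm.regimen, arm.pd_times, step=grid_step)[0] if arm.pd_times.size else None
            ipred_cache[sid] = (ipk, ipd)
            return ipred_cache[sid]

        for dvtype, subj, tidx, y, times, pred in (
            ("PK", arm.pk_subj, arm.pk_tidx, arm.pk_y, arm.pk_times, pred_pk),
            ("PD", arm.pd_subj, arm.pd_tidx, arm.pd_y, arm.pd_times, pred_pd),
        ):
            if pred is None or y.size == 0:
                continue
            for s, k, yy in zip(subj, tidx, y):
                sid = arm.subject_ids[s]
                f = float(pred[k])
                ip = ipred_for(sid)[0 if dvtype == "PK" else 1]
                fi = float(ip[k]) if ip is not None else f
                if f <= 0:
                    rows.append(dict(ID=sid, ARM=arm.label, DVTYPE=dvtype, TIME=float(times[k]),
                                     DV=float(yy), PRED=f, IPRED=fi, WRES=np.nan, flag="PRED=0"))
                else:
                    rows.append(dict(ID=sid, ARM=arm.label, DVTYPE=dvtype, TIME=float(times[k]),
                                     DV=float(yy), PRED=f, IPRED=fi,
                                     WRES=(float(yy) - f) / (f * sig[dvtype]), flag=""))
    return pd.DataFrame(rows)


def plot_vpc(result: VPCResult, dvtype: str = "PK", arms: list[str] | None = None, log_scale: bool | None = None):
    """Matplotlib figure: observed points over simulated percentile bands."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    all_arms = sorted(result.bands.loc[result.bands["DVTYPE"] == dvtype, "ARM"].unique())
    arms = arms or all_arms
    if log_scale is None:
        log_scale = dvtype == "PK"
    n = len(arms)
    ncols = min(3, max(1, n))
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.2 * ncols, 3.2 * nrows), squeeze=False)
    for ax, arm in zip(axes.ravel(), arms):
        band = result.arm_bands(arm, dvtype)
        obs = result.observed
        obs = obs[(obs["ARM"] == arm) & (obs["DVTYPE"] == dvtype)]
        ax.plot(band["TIME"], band["p50"], "-", color="tab:blue", label="median")
        ax.plot(band["TIME"], band["p5"], "--", color="tab:blue", lw=0.9, label="5th/95th")
        ax.plot(band["TIME"], band["p95"], "--", color="tab:blue", lw=0.9)
        ax.fill_between(band["TIME"], band["p5"], band["p95"], color="tab:blue", alpha=0.15)
        ax.plot(obs["TIME"], obs["DV"], "o", ms=3, color="black", alpha=0.6, label="observed")
        if log_scale:
            ax.set_yscale("log")
        ax.set_title(arm, fontsize=9)
        ax.set_xlabel("time (day)")
        ax.set_ylabel("conc (ug/mL)" if dvtype == "PK" else "NK (10^3/uL)")
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    return fig
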