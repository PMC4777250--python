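"""Model/Results front-end tying the pipeline together.

``PKPDModel`` is constructed from an event-record dataset (a
:class:`~il15pkpd.study.StudyDataset`, a tidy dataframe in the same dialect,
or a CSV file); ``fit`` returns a :class:`PKPDResults` carrying the
estimates, their uncertainties and diagnostics, with ``summary()``,
``vpc()``, ``residuals()`` and ``simulate()`` hanging off the results
object, in the spirit of the statsmodels Model/Results split.

Example
-------
>>> from il15pkpd import PKPDModel, builtin_designs, simulate_study
>>> from il15pkpd.params import CYNO_TYPICAL, CYNO_VARIABILITY
>>> data = simulate_study(builtin_designs()["single"], CYNO_TYPICAL,
...                       CYNO_VARIABILITY, seed=7)
>>> model = PKPDModel(data)
>>> results = model.fit(method="pooled")
>>> print(results.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics, estimation
from .estimation import FitResult, FitSpec
from .params import PopulationParameters, Regimen, VariabilitySpec
from .study import StudyDataset, simulate_study

__all__ = ["PKPDModel", "PKPDResults"]


class PKPDModel:
    """The coupled two-compartment PK / NK-cell indirect-response model,
    bound to one analysis dataset."""

    def __init__(self, dataset: StudyDataset):
        if not isinstance(dataset, StudyDataset):
            raise TypeError("dataset must be a StudyDataset; see from_dataframe/from_csv")
        dataset.validate()
        self.dataset = dataset

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, lloq: float = 0.1) -> "PKPDModel":
        """Build from a tidy event-record table (columns ID, ARM, TIME, AMT,
        ROUTE, DVTYPE, DV, BLQ)."""
        return cls(StudyDataset(records=frame.copy(), lloq=lloq))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PKPDModel":
        from .dataio import read_dataset

        return cls(read_dataset(path))

    @property
    def n_subjects(self) -> int:
        return len(self.dataset.subjects)

    def fit(self, method: str = "pooled", spec: FitSpec | None = None, **kwargs) -> "PKPDResults":
        """Estimate population parameters; see :mod:`il15pkpd.estimation`
        for the available methods (``pooled``, ``two_stage``, ``laplace``)."""
        if spec is None:
            spec = FitSpec(mode=method, **kwargs)
        elif kwargs:
            spec = replace(spec, mode=method, **kwargs)
        else:
            spec = replace(spec, mode=method)
        result = estimation.fit(self.dataset, spec)
        return PKPDResults(self, result)


class PKPDResults:
    """Estimates, uncertainties and diagnostics of a population fit."""

    def __init__(self, model: PKPDModel, result: FitResult):
        self.model = model
        self._result = result

    # -- estimates -------------------------------------------------------
    @property
    def params(self) -> PopulationParameters:
        return self._result.params

    @property
    def bse(self) -> dict[str, float]:
        """Standard errors of the structural estimates (natural scale)."""
        return dict(self._result.se)

    @property
    def rse_percent(self) -> dict[str, float]:
        return dict(self._result.rse_percent)

    @property
    def omega2(self) -> dict[str, float]:
        return dict(self._result.omega2)

    @property
    def sigma2(self) -> dict[str, float]:
        return dict(self._result.sigma2)

    @property
    def objective(self) -> float:
        return self._result.objective

    @property
    def converged(self) -> bool:
        return self._result.converged

    @property
    def mode(self) -> str:
        return self._result.mode

    @property
    def fit_result(self) -> FitResult:
        """The underlying estimation-layer result."""
        return self._result

    def variability(self) -> VariabilitySpec:
        """Estimated variability as a spec usable for simulation/VPC."""
        return VariabilitySpec(
            omega2=self._result.omega2,
            sigma2_prop_pk=float(self._result.sigma2.get("prop_pk", 0.0) or 0.0),
            sigma2_prop_pd=float(self._result.sigma2.get("prop_pd", 0.0) or 0.0),
        )

    def parameter_table(self) -> pd.DataFrame:
        return self._result.parameter_table()

    def summary(self) -> str:
        return self._result.summary()

    # -- simulation-based diagnostics ------------------------------------
    def vpc(self, n_reps: int = 500, seed: int = 0) -> diagnostics.VPCResult:
        """Visual predictive check of the data against the fitted model."""
        return diagnostics.vpc(
            self.model.dataset, self.params, self.variability(), n_reps=n_reps, seed=seed
        )

    def residuals(self) -> pd.DataFrame:
        """Population predictions and weighted residuals per observation."""
        return diagnostics.residual_table(self.model.dataset, self._result)

    def simulate(self, design, seed: int = 0) -> StudyDataset:
        """Simulate a replicate study under the fitted model."""
        return simulate_study(design, self.params, self.variability(), seed)

    def predict_profile(self, regimen: Regimen, times) -> pd.DataFrame:
        """Typical-subject concentration and NK-count profile for a regimen."""
        from .model import simulate

        traj = simulate(self.params, regimen, np.asarray(times, dtype=float))
        return traj.as_frame()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<PKPDResults mode={self.mode} converged={self.converged} objective={self.objective:.2f}>"
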