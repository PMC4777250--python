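"""Shared fixtures: reference parameters and small deterministic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from il15pkpd.params import CYNO_TYPICAL, CYNO_VARIABILITY, Regimen, VariabilitySpec
from il15pkpd.study import StudyArm, StudyDesign, builtin_designs, combine, simulate_study


@pytest.fixture(scope="session")
def pop():
    """Reference population typical values."""
    return CYNO_TYPICAL


@pytest.fixture(scope="session")
def var():
    """Reference variability (BSV + residual)."""
    return CYNO_VARIABILITY


@pytest.fixture(scope="session")
def no_var():
    """Degenerate variability: no BSV, no residual error."""
    return VariabilitySpec()


@pytest.fixture(scope="session")
def designs():
    return builtin_designs()


def shrink_design(design: StudyDesign, n_subjects: int, n_recovery: int | None = None) -> StudyDesign:
    """Copy of a design with fewer subjects per arm (for fast tests)."""
    arms = tuple(
        StudyArm(a.label, a.dose, a.route, a.n_doses, n_subjects, a.interval) for a in design.arms
    )
    return StudyDesign(
        design.label, arms, design.pk_times, design.pd_times,
        design.recovery_pk_times, design.recovery_pd_times,
        min(design.n_recovery, n_recovery if n_recovery is not None else n_subjects),
        design.lloq,
    )


@pytest.fixture(scope="session")
def noise_free_small(designs, pop, no_var):
    """Noise-free single-dose + 1-month dataset, one subject per arm.

    With zero variability every subject in an arm is identical, so one
    subject per arm carries the full information content at a fraction of
    the cost.  Includes i.v. and s.c. arms, so all ten structural
    parameters are identifiable.
    """
    small = [shrink_design(designs["single"], 1), shrink_design(designs["one_month"], 1)]
    return combine([simulate_study(d, pop, no_var, seed=11) for d in small])


@pytest.fixture(scope="session")
def stochastic_single(designs, pop, var):
    """Single-dose study at the reference variability, fixed seed."""
    return simulate_study(designs["single"], pop, var, seed=42)
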