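"""Structural model: right-hand side, simulation, analytic oracle, derived
quantities, and the core dynamical invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from il15pkpd.model import (
    InvalidStateError,
    analytic_pk,
    derived_quantities,
    disposition_rates,
    pkpd_rhs,
    simulate,
    steady_state_response,
)
from il15pkpd.params import DoseEvent, PopulationParameters, Regimen


class TestRhs:
    def test_baseline_is_steady_state(self, pop):
        """With no drug, dR/dt = Kin - Kout*R0 = 0 by construction."""
        deriv = pkpd_rhs(np.array([0.0, 0.0, 0.0, pop.r0]), 0.0, pop)
        assert np.allclose(deriv, 0.0)

    def test_saturating_concentration_limit(self, pop):
        """As C -> inf the inhibition saturates at Emax: at R = R0 the NK
        derivative tends to -R0*Kout*Emax = -0.1676 (reference values)."""
        big_c = 1e9
        state = np.array([0.0, big_c * pop.vc, 0.0, pop.r0])
        deriv = pkpd_rhs(state, 0.0, pop)
        expected = -pop.r0 * pop.kout * pop.emax
        assert deriv[3] == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(-0.16760, abs=5e-5)

    def test_half_maximal_inhibition_at_ec50(self, pop):
        """At C = EC50 the production term is inhibited by exactly Emax/2."""
        state = np.array([0.0, pop.ec50 * pop.vc, 0.0, pop.r0])
        deriv = pkpd_rhs(state, 0.0, pop)
        expected = pop.kin * (1.0 - pop.emax / 2.0) - pop.kout * pop.r0
        assert deriv[3] == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_state_rejected(self, pop):
        with pytest.raises(InvalidStateError):
            pkpd_rhs(np.array([0.0, np.nan, 0.0, 0.5]), 0.0, pop)
        with pytest.raises(InvalidStateError):
            pkpd_rhs(np.array([0.0, 0.0, 0.0]), 0.0, pop)


class TestSimulate:
    def test_empty_regimen_stays_at_baseline(self, pop):
        t = np.linspace(0.0, 50.0, 40)
        traj = simulate(pop, Regimen(()), t)
        assert np.allclose(traj.conc, 0.0)
        assert np.allclose(traj.r, pop.r0, rtol=1e-7)

    def test_iv_bolus_initial_concentration(self, pop):
        """C just after a 1 mg/kg i.v. bolus equals Dose/Vc = 22.32 ug/mL."""
        traj = simulate(pop, Regimen.single(1000.0), np.array([1e-7, 1.0]))
        assert traj.conc[0] == pytest.approx(1000.0 / pop.vc, rel=1e-5)
        assert traj.conc[0] == pytest.approx(22.32, rel=1e-3)

    def test_saturating_exposure_drives_r_to_floor(self, pop):
        """Under sustained C >> EC50 the NK count settles at R0*(1-Emax)."""
        reg = Regimen.weekly(150000.0, "iv_bolus", 20)
        traj = simulate(pop, reg, np.array([0.5, 100.0, 133.0]))
        floor = pop.r0 * (1.0 - pop.emax)
        assert floor == pytest.approx(0.0345, abs=2e-4)
        assert traj.r[-1] == pytest.approx(floor, rel=0.02)

    def test_states_nonnegative(self, pop):
        reg = Regimen(
            (
                DoseEvent(0.0, 5000.0, "sc"),
                DoseEvent(3.0, 1000.0, "iv_bolus"),
                DoseEvent(10.0, 5000.0, "sc"),
            )
        )
        traj = simulate(pop, reg, np.linspace(0.0, 120.0, 300))
        for arr in (traj.adepot, traj.ac, traj.ap, traj.r):
            assert np.all(arr >= 0.0)

    def test_r_initialised_at_baseline(self, pop):
        traj = simulate(pop, Regimen.single(1000.0), np.array([0.0, 1.0]))
        assert traj.r[0] == pytest.approx(pop.r0, rel=1e-9)


REGIMENS = {
    "single_iv": Regimen.single(1000.0),
    "single_sc": Regimen.single(1000.0, "sc"),
    "weekly_iv_x5": Regimen.weekly(30000.0, "iv_bolus", 5),
    "weekly_sc_x13": Regimen.weekly(150000.0, "sc", 13),
    "mixed_x20": Regimen(
        tuple(
            DoseEvent(7.0 * i, 10000.0, "iv_bolus" if i % 2 == 0 else "sc") for i in range(20)
        )
    ),
}


class TestAnalyticOracle:
    @pytest.mark.parametrize("name", sorted(REGIMENS))
    def test_numeric_matches_closed_form(self, pop, name):
        """Numerically integrated C(t) agrees with the exact biexponential /
        triexponential superposition to 1e-6 of the peak over 350 days."""
        reg = REGIMENS[name]
        t = np.union1d(np.linspace(0.01, 350.0, 260), reg.times + 1e-4)
        traj = simulate(pop, reg, t, rtol=1e-10, atol=1e-12)
        c_exact = analytic_pk(pop, reg, t)
        assert np.max(np.abs(traj.conc - c_exact)) <= 1e-6 * c_exact.max()

    def test_superposition_linearity(self, pop):
        """Doubling every dose doubles C(t) exactly; R(t) does not double."""
        reg = REGIMENS["weekly_iv_x5"]
        t = np.linspace(0.5, 60.0, 80)
        c1 = analytic_pk(pop, reg, t)
        c2 = analytic_pk(pop, reg.scaled(2.0), t)
        assert np.allclose(c2, 2.0 * c1, rtol=1e-12)
        r1 = simulate(pop, reg, t).r
        r2 = simulate(pop, reg.scaled(2.0), t).r
        assert not np.allclose(r2, 2.0 * r1, rtol=0.05)

    def test_one_compartment_degenerate_limit(self, pop):
        """As Q -> 0 the solution collapses to C0*exp(-k10*t)."""
        p = pop.replace(q=1e-9)
        t = np.linspace(0.1, 30.0, 40)
        c = analytic_pk(p, Regimen.single(1000.0), t)
        k10 = p.cl / p.vc
        assert np.allclose(c, (1000.0 / p.vc) * np.exp(-k10 * t), rtol=1e-5)

    def test_unit_iv_auc_is_dose_over_cl(self, pop):
        """AUCinf = Dose/CL for linear PK (dense trapezoid vs identity)."""
        t = np.linspace(1e-4, 400.0, 40000)
        c = analytic_pk(pop, Regimen.single(1.0), t)
        auc = np.trapezoid(c, t) + c[-1] / disposition_rates(pop)[4]
        assert auc == pytest.approx(1.0 / pop.cl, rel=1e-3)

    def test_ka_eigenvalue_singularity_is_removable(self, pop):
        lam_z = disposition_rates(pop)[4]
        p = pop.replace(ka=float(lam_z))
        t = np.linspace(0.1, 50.0, 30)
        with pytest.warns(UserWarning, match="perturbing"):
            c = analytic_pk(p, Regimen.single(1000.0, "sc"), t)
        assert np.all(np.isfinite(c)) and np.all(c >= 0)


class TestDerivedQuantities:
    def test_nk_half_life(self, pop):
        """Kout = 0.305/day corresponds to a 2.27-day NK-cell half-life."""
        dq = derived_quantities(pop)
        assert round(dq.nk_half_life, 2) == 2.27

    def test_kin_value(self, pop):
        """Kin = R0*Kout = 0.584*0.305 = 0.178 >= the rounded 0.17."""
        dq = derived_quantities(pop)
        assert dq.kin == pytest.approx(0.17812, rel=1e-10)
        assert dq.kin >= 0.17

    def test_terminal_half_life_from_eigenvalue(self, pop):
        """The slow eigenvalue of the disposition matrix gives a terminal
        half-life inside the observed 12.7-18 day range."""
        k10 = pop.cl / pop.vc
        k12 = pop.q / pop.vc
        k21 = pop.q / pop.vp
        a = k10 + k12 + k21
        lam_z = (a - np.sqrt(a * a - 4.0 * k10 * k21)) / 2.0  # independent quadratic
        dq = derived_quantities(pop)
        assert dq.lambda_z == pytest.approx(lam_z, rel=1e-12)
        assert dq.lambda_z == pytest.approx(0.04794, abs=1e-5)
        assert 12.7 <= dq.terminal_half_life <= 18.0

    def test_model_vss(self, pop):
        assert derived_quantities(pop).vss == pytest.approx(69.1, abs=1e-9)


class TestSteadyStateSuppression:
    @given(
        c1=st.floats(min_value=1e-6, max_value=1e5),
        ratio=st.floats(min_value=1.001, max_value=1e4),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_and_bounded(self, c1, ratio):
        """Steady-state NK count is strictly decreasing in the sustained
        concentration and bounded in [R0*(1-Emax), R0]."""
        pop = PopulationParameters(
            ka=0.522, cl=3.66, vc=44.8, q=5.07, vp=24.3, f1=0.824,
            r0=0.584, kout=0.305, emax=0.941, ec50=0.0978,
        )
        r1 = steady_state_response(c1, pop)
        r2 = steady_state_response(c1 * ratio, pop)
        assert r2 < r1
        floor, ceil = pop.r0 * (1.0 - pop.emax), pop.r0
        assert floor <= r2 <= r1 <= ceil
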