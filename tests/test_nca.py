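"""Noncompartmental analysis: trapezoid rules, terminal slope, derived
parameters, and convergence to the model's analytic counterparts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from il15pkpd.model import analytic_pk, derived_quantities, simulate
from il15pkpd.nca import (
    ConcentrationProfile,
    InsufficientDataError,
    accumulation_ratio,
    auc_trapezoidal,
    bioavailability,
    lambda_z,
    nca_single_dose,
    nca_table,
)
from il15pkpd.params import Regimen


def profile(times, conc, route="iv_bolus", dose=1000.0, subject="s", blq=None):
    return ConcentrationProfile(subject, route, dose, np.asarray(times, float),
                                np.asarray(conc, float), blq)


class TestTrapezoid:
    def test_log_rule_on_descending_pair(self):
        """(0, 10) -> (1, 5): log trapezoid gives 5/ln2 = 7.213."""
        area = auc_trapezoidal(profile([0.0, 1.0], [10.0, 5.0]), 0.0, 1.0)
        assert area == pytest.approx(5.0 / np.log(2.0), rel=1e-12)

    def test_linear_rule_on_ascending_pair(self):
        area = auc_trapezoidal(profile([0.0, 1.0], [5.0, 10.0]), 0.0, 1.0)
        assert area == pytest.approx(7.5, rel=1e-12)

    def test_constant_profile(self):
        area = auc_trapezoidal(profile([0.0, 3.0, 7.0], [2.0, 2.0, 2.0]), 0.0, 7.0)
        assert area == pytest.approx(14.0, rel=1e-12)

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            auc_trapezoidal(profile([0.0, 1.0, 2.0], [1.0, 2.0, 3.0]), 1.5, 1.8)

    def test_blq_excluded_by_default(self):
        p = profile([0.0, 1.0, 2.0], [10.0, 0.0, 2.5], blq=[False, True, False])
        # only the (0, 10) -> (2, 2.5) log segment remains
        k = np.log(10.0 / 2.5) / 2.0
        assert auc_trapezoidal(p, 0.0, 2.0) == pytest.approx((10.0 - 2.5) / k, rel=1e-12)

    def test_auc_additivity(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0.0, 30.0, 25))
        c = 10.0 * np.exp(-0.2 * t) * rng.uniform(0.8, 1.2, t.size)
        p = profile(t, c)
        a, b = t[0], t[-1]
        mid = t[12]
        assert auc_trapezoidal(p, a, mid) + auc_trapezoidal(p, mid, b) == pytest.approx(
            auc_trapezoidal(p, a, b), rel=1e-10
        )

    @given(k=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=40, deadline=None)
    def test_dose_linearity(self, k):
        """Scaling a profile by k scales areas by k and leaves the shape
        parameters (lambda_z, t1/2, tmax) unchanged."""
        t = np.arange(0.0, 43.0, 3.0) + 0.5
        c = 20.0 * np.exp(-0.1 * t)
        p1, pk = profile(t, c), profile(t, k * c, dose=1000.0 * k)
        r1, rk = nca_single_dose(p1), nca_single_dose(pk)
        assert rk.auc_inf == pytest.approx(k * r1.auc_inf, rel=1e-9)
        assert rk.aumc_inf == pytest.approx(k * r1.aumc_inf, rel=1e-9)
        assert rk.lambda_z == pytest.approx(r1.lambda_z, rel=1e-9)
        assert rk.tmax == r1.tmax


class TestLambdaZ:
    def test_exact_monoexponential(self):
        """C = 2*exp(-0.0546 t) sampled days 3-42: lambda_z = 0.0546 and
        t1/2 = 12.7 days."""
        t = np.array([3.0, 5.0, 8.0, 14.0, 21.0, 28.0, 35.0, 42.0])
        lz, diag = lambda_z(profile(t, 2.0 * np.exp(-0.0546 * t)))
        assert lz == pytest.approx(0.0546, rel=1e-9)
        assert np.log(2.0) / lz == pytest.approx(12.7, abs=0.02)
        assert diag.n_points >= 3

    def test_simulated_terminal_phase_matches_eigenvalue(self, pop):
        """On the noise-free simulated i.v. profile sampled days 14-42 the
        regression recovers the model's slow eigenvalue 0.04794/day."""
        t = np.array([14.0, 17.0, 21.0, 24.0, 28.0, 31.0, 35.0, 38.0, 42.0])
        c = analytic_pk(pop, Regimen.single(1000.0), t)
        lz, _ = lambda_z(profile(t, c))
        assert lz == pytest.approx(derived_quantities(pop).lambda_z, rel=5e-3)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            lambda_z(profile([0.0, 1.0], [10.0, 5.0]))

    def test_rising_profile_has_no_terminal_slope(self):
        t = np.arange(1.0, 9.0)
        lz, diag = lambda_z(profile(t, np.exp(0.2 * t)))
        assert np.isnan(lz)
        assert diag.n_points == 0


class TestSingleDoseNCA:
    def test_monoexponential_identities(self):
        """One-compartment decay: MRT = 1/k, CL = k*V, Vss = V exactly."""
        k, v, dose = 0.15, 50.0, 1000.0
        t = np.arange(0.25, 40.0, 0.75)
        c = (dose / v) * np.exp(-k * t)
        res = nca_single_dose(profile(t, c, dose=dose))
        assert res.cl == pytest.approx(k * v, rel=1e-6)
        assert res.mrt == pytest.approx(1.0 / k, rel=1e-6)
        assert res.vss == pytest.approx(v, rel=1e-6)
        assert res.cmax_or_c0 == pytest.approx(dose / v, rel=1e-6)

    def test_simulated_iv_clearance_and_vss(self, pop):
        """Noise-free 1 mg/kg i.v. simulation + NCA recovers CL = 3.66
        mL/day/kg within 2% and Vss = Vc+Vp = 69.1 mL/kg within 3%."""
        t = np.round(np.arange(0.01, 60.01, 0.25), 9)
        traj = simulate(pop, Regimen.single(1000.0), t)
        res = nca_single_dose(profile(t, traj.conc))
        assert res.cl == pytest.approx(pop.cl, rel=0.02)
        assert res.vss == pytest.approx(pop.vc + pop.vp, rel=0.03)
        assert 12.7 <= res.t_half <= 18.0

    def test_lambda_z_missing_leaves_partial_areas(self):
        p = profile([0.0, 1.0], [10.0, 5.0])
        res = nca_single_dose(p)
        assert res.auc_last > 0
        assert np.isnan(res.auc_inf) and np.isnan(res.cl) and np.isnan(res.t_half)

    def test_sc_profile_reports_cmax_not_cl(self, pop):
        t = np.round(np.arange(0.25, 60.0, 0.25), 9)
        c = analytic_pk(pop, Regimen.single(1000.0, "sc"), t)
        res = nca_single_dose(profile(t, c, route="sc"))
        assert res.tmax > 0
        assert np.isnan(res.cl) and np.isnan(res.vss)


class TestRatios:
    def test_identical_profiles_no_accumulation(self):
        t = np.arange(0.0, 7.5, 0.5)
        c = 10.0 * np.exp(-0.3 * t)
        assert accumulation_ratio(profile(t, c), profile(t, c), 7.0) == pytest.approx(1.0)

    def test_weekly_iv_accumulation_in_observed_band(self, pop):
        """Day-22/Day-1 AUC-tau ratio of the noise-free weekly 30 mg/kg
        i.v. simulation falls in the observed 2.1-2.6 band (about 2.17)."""
        reg = Regimen.weekly(30000.0, "iv_bolus", 5)
        t1 = np.round(np.arange(0.02, 7.0001, 0.02), 9)
        first = profile(t1, analytic_pk(pop, reg, t1), dose=30000.0)
        later = profile(t1 + 21.0, analytic_pk(pop, reg, t1 + 21.0), dose=30000.0)
        ratio = accumulation_ratio(first, later, 7.0 - 0.02)
        assert 2.1 <= ratio <= 2.6
        assert ratio == pytest.approx(2.17, abs=0.02)

    def test_profile_not_spanning_tau(self):
        t = np.arange(0.0, 3.0, 0.5)
        p = profile(t, 10.0 * np.exp(-0.3 * t))
        with pytest.raises(ValueError, match="full interval"):
            accumulation_ratio(p, p, 7.0)

    def test_bioavailability_identities(self, pop):
        assert bioavailability(10.0, 10.0, 1.0, 1.0) == pytest.approx(1.0)
        assert bioavailability(0.0, 10.0, 1.0, 1.0) == 0.0
        with pytest.raises(ValueError):
            bioavailability(1.0, 0.0, 1.0, 1.0)

    def test_simulated_absolute_bioavailability(self, pop):
        """Noise-free single-dose s.c./i.v. AUCinf ratio returns F1 = 0.824
        within 1% (linear-PK identity)."""
        t = np.round(np.arange(0.01, 60.01, 0.25), 9)
        res_iv = nca_single_dose(profile(t, simulate(pop, Regimen.single(1000.0), t).conc))
        res_sc = nca_single_dose(
            profile(t, simulate(pop, Regimen.single(1000.0, "sc"), t).conc, route="sc")
        )
        f = bioavailability(res_sc.auc_inf, res_iv.auc_inf, 1000.0, 1000.0)
        assert f == pytest.approx(pop.f1, rel=0.01)


def test_nca_table_layout(pop):
    t = np.round(np.arange(0.01, 42.0, 0.5), 9)
    profiles = [
        profile(t, simulate(pop, Regimen.single(d), t).conc, dose=d, subject=f"s{i}")
        for i, d in enumerate((100.0, 1000.0))
    ]
    tab = nca_table(profiles)
    assert list(tab["subject"]) == ["s0", "s1"]
    assert {"cl", "vss", "t_half", "auc_inf", "lambda_z"} <= set(tab.columns)
    # dose-proportionality of the two noise-free profiles
    assert tab["auc_inf"][1] == pytest.approx(10.0 * tab["auc_inf"][0], rel=1e-3)
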