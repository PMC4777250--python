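"""Estimation layer: objectives, identifiability guards, self-consistency
on noise-free data, two-stage variance recovery, and pooled calibration."""

import numpy as np
import pytest

from il15pkpd import estimation as est
from il15pkpd.estimation import FitSpec, UnidentifiableError, objective_pooled
from il15pkpd.params import PARAM_NAMES, VariabilitySpec
from il15pkpd.study import StudyArm, StudyDesign, combine, simulate_study

from conftest import shrink_design


def strip_sc_arms(dataset):
    """Copy of a dataset without s.c.-dosed subjects."""
    sc_ids = set(dataset.records.loc[dataset.records["ROUTE"] == "SC", "ID"])
    records = dataset.records[~dataset.records["ID"].isin(sc_ids)].reset_index(drop=True)
    from il15pkpd.study import StudyDataset

    return StudyDataset(records=records, lloq=dataset.lloq, design_label=dataset.design_label)


class TestPooledObjective:
    def test_zero_at_truth_for_noise_free_data(self, noise_free_small, pop):
        """With data generated noise-free at the evaluated parameters the
        relative-residual sum vanishes: -2LL at fixed sigma^2 reduces to its
        deterministic floor, and perturbing CL strictly increases it."""
        base = objective_pooled(noise_free_small, pop, sigma2_pk=0.0349, sigma2_pd=0.217)
        worse = objective_pooled(
            noise_free_small, pop.replace(cl=pop.cl * 1.1), sigma2_pk=0.0349, sigma2_pd=0.217
        )
        assert worse > base + 1.0

    def test_perturbing_each_structural_parameter_increases_profiled_objective(
        self, noise_free_small, pop
    ):
        base = objective_pooled(noise_free_small, pop)
        for name in ("cl", "vc", "ka", "kout", "ec50", "r0"):
            worse = objective_pooled(noise_free_small, pop.replace(**{name: getattr(pop, name) * 1.15}))
            assert worse > base, name

    def test_requires_observations(self, pop):
        with pytest.raises(ValueError):
            objective_pooled([], pop)


class TestPooledFit:
    @pytest.fixture(scope="class")
    def noise_free_fit(self, noise_free_small):
        spec = FitSpec(mode="pooled", n_starts=1, compute_se=False)
        return est.fit(noise_free_small, spec)

    def test_recovers_structural_parameters_within_one_percent(self, noise_free_fit, pop):
        """Self-consistency: fitting noise-free zero-BSV data regenerates
        every one of the nine structural parameters within 1%."""
        for name in PARAM_NAMES:
            assert getattr(noise_free_fit.params, name) == pytest.approx(
                getattr(pop, name), rel=0.01
            ), name

    def test_profiled_residual_variances_collapse(self, noise_free_fit):
        assert noise_free_fit.sigma2["prop_pk"] < 1e-4
        assert noise_free_fit.sigma2["prop_pd"] < 1e-4

    def test_refuses_dataset_without_pd(self, noise_free_small):
        from il15pkpd.study import StudyDataset

        records = noise_free_small.records
        pk_only = StudyDataset(records=records[records["DVTYPE"] != "PD"].reset_index(drop=True))
        with pytest.raises(UnidentifiableError, match="PD"):
            est.fit(pk_only, FitSpec(mode="pooled"))

    def test_f1_flagged_unidentifiable_without_sc_arms(self, noise_free_small):
        spec = FitSpec(mode="pooled", n_starts=1, compute_se=False, maxiter=400)
        res = est.fit(strip_sc_arms(noise_free_small), spec)
        assert "f1" in res.fixed
        assert any("s.c." in m for m in res.messages)

    def test_transform_invariance_to_initial_scaling(self, noise_free_small, pop):
        """Starting values scaled by x2 or /2 lead to the same optimum
        (estimation happens on log/logit scales)."""
        results = []
        for fac in (2.0, 0.5):
            init = est.default_initial_estimates(noise_free_small)
            scaled = init.replace(
                **{n: getattr(init, n) * fac for n in ("cl", "vc", "q", "vp", "ka", "kout", "ec50")}
            )
            spec = FitSpec(mode="pooled", init=scaled, n_starts=1, compute_se=False)
            results.append(est.fit(noise_free_small, spec).params.as_array())
        assert np.allclose(results[0], results[1], rtol=5e-3)


class TestTwoStage:
    def test_zero_bsv_gives_zero_variance(self, designs, pop, no_var):
        """Subjects simulated without BSV or residual error carry identical
        data, so the across-subject variance of every individually fitted
        parameter collapses to zero."""
        design = StudyDesign(
            "za",
            (StudyArm("iv", 1000.0, "iv_bolus", 1, 4),),
            pk_times=designs["single"].pk_times,
            pd_times=designs["single"].pd_times,
        )
        ds = simulate_study(design, pop, no_var, seed=23)
        res = est.two_stage(ds, FitSpec(mode="two_stage", compute_se=False))
        assert res.omega2  # at least CL and R0 were estimated per subject
        for name, w2 in res.omega2.items():
            assert w2 == pytest.approx(0.0, abs=1e-8), name

    def test_single_subject_rejected(self, designs, pop, no_var):
        tiny = shrink_design(designs["single"], 1)
        tiny = StudyDesign(tiny.label, tiny.arms[:1], tiny.pk_times, tiny.pd_times)
        ds = simulate_study(tiny, pop, no_var, seed=2)
        with pytest.raises(UnidentifiableError):
            est.two_stage(ds, FitSpec(mode="two_stage"))

    def test_recovers_cl_variance_at_n48(self, pop):
        """48 subjects with rich i.v. PK and omega^2_CL = 0.0292: the
        across-subject variance of log CL-hat recovers the simulated BSV
        within Monte-Carlo bounds."""
        design = StudyDesign(
            "rich",
            (StudyArm("iv", 1000.0, "iv_bolus", 1, 48),),
            pk_times=(0.25, 1.0, 3.0, 5.0, 8.0, 14.0, 21.0, 28.0, 35.0, 42.0),
            pd_times=(-3.0, 0.0, 3.0, 8.0, 21.0, 42.0),
        )
        var = VariabilitySpec(omega2={"cl": 0.0292}, sigma2_prop_pk=0.0025)
        ds = simulate_study(design, pop, var, seed=31)
        res = est.two_stage(ds, FitSpec(mode="two_stage", init=pop.replace(cl=4.0, vc=40.0), compute_se=False))
        # sample variance of 48 lognormal draws: sd ~ omega2*sqrt(2/47) ~ 0.006
        assert res.omega2["cl"] == pytest.approx(0.0292, abs=0.015)
        assert res.params.cl == pytest.approx(pop.cl, rel=0.08)


class TestPooledCalibration:
    def test_median_relative_error_within_reported_precision(self, designs, pop):
        """Calibration of the pooled estimator in its own regime (no
        between-subject variability, proportional residual error at the
        reference magnitudes): over 10 replicate studies the median relative
        error of each structural parameter stays within the relative
        standard error reported for that parameter in the reference
        population analysis."""
        printed_rse = {
            "ka": 7.11, "cl": 3.22, "vc": 4.51, "q": 17.9, "vp": 8.25,
            "f1": 3.65, "r0": 4.96, "kout": 14.9, "emax": 0.386, "ec50": 28.0,
        }
        var = VariabilitySpec(sigma2_prop_pk=0.0349, sigma2_prop_pd=0.217)
        errors = {n: [] for n in PARAM_NAMES}
        for rep in range(10):
            ds = combine(
                [simulate_study(d, pop, var, seed=900 + 10 * rep + k) for k, d in enumerate(designs.values())]
            )
            spec = FitSpec(mode="pooled", n_starts=1, compute_se=False, maxiter=2500)
            res = est.fit(ds, spec)
            for n in PARAM_NAMES:
                errors[n].append(abs(getattr(res.params, n) / getattr(pop, n) - 1.0))
        for n in PARAM_NAMES:
            med = float(np.median(errors[n]))
            assert med <= printed_rse[n] / 100.0, (n, med)

    def test_pd_estimates_insensitive_to_fixing_pk_at_truth(self, noise_free_small, pop):
        """Weak PK->PD coupling: fixing the PK parameters at truth versus
        co-estimating them moves the PD estimates by well under 5% on rich
        noise-free data."""
        spec = FitSpec(mode="pooled", n_starts=1, compute_se=False)
        co = est.fit(noise_free_small, spec)
        # fixed-PK fit: start from truth and only optimise the PD block
        from il15pkpd.estimation import _build_arms, _from_internal, _pooled_predictions, _objective_from_predictions, _to_internal
        from scipy.optimize import minimize

        arms = _build_arms(noise_free_small, "discard")
        y_pk = np.concatenate([a.pk_y for a in arms])
        y_pd = np.concatenate([a.pd_y for a in arms])
        free = ["r0", "kout", "emax", "ec50"]
        base = pop.as_array()

        def obj(x):
            theta = _from_internal(x, free, base)
            f_pk, f_pd = _pooled_predictions(theta, arms, 0.25)
            return _objective_from_predictions(y_pk, f_pk, y_pd, f_pd, None, None)[0]

        start = est.default_initial_estimates(noise_free_small)
        res = minimize(obj, _to_internal(start.as_array(), free), method="Nelder-Mead",
                       options=dict(maxiter=2000, xatol=1e-6, fatol=1e-8))
        theta_fixed = _from_internal(res.x, free, base)
        for j, name in [(6, "r0"), (7, "kout"), (8, "emax"), (9, "ec50")]:
            assert theta_fixed[j] == pytest.approx(getattr(co.params, name), rel=0.05), name
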