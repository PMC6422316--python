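"""Likelihood construction, MAP fitting, BIC and model selection."""

import math

import numpy as np
import pytest

from thrombosim import (FitDataset, ObservationSeries, Prior,
                        default_parameters, fit_individual, log_likelihood,
                        bic)
from thrombosim.schedules import built_in_schedule
from thrombosim.synthetic import generate_virtual_cohort

_LOG2PI = math.log(2.0 * math.pi)


class TestBic:
    def test_reference_value(self):
        assert bic(-100.0, 5, 50) == pytest.approx(200.0 + 5 * math.log(50.0))

    def test_no_parameters(self):
        assert bic(-12.5, 0, 10) == pytest.approx(25.0)

    def test_useless_parameter_costs_ln_n(self):
        assert bic(-50.0, 4, 80) - bic(-50.0, 3, 80) == pytest.approx(
            math.log(80.0))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bic(0.0, -1, 10)
        with pytest.raises(ValueError):
            bic(0.0, 1, 0)


class TestSeriesLikelihood:
    def test_gaussian_identity_zero_residuals(self):
        """Zero residuals with fixed log-scale SD sigma and N points give
        logL = -(N/2) ln(2 pi sigma^2)."""
        from thrombosim.fitting import _series_loglik
        sigma = 0.2
        values = np.array([10.0, 20.0, 40.0])
        s = ObservationSeries("pop", "x", "platelets", [0, 1, 2], values,
                              sds=sigma * values)
        ll, _ = _series_loglik(values.copy(), s)
        assert ll == pytest.approx(-1.5 * math.log(2 * math.pi * sigma**2))

    def test_doubling_sigma_quarters_quadratic_term(self):
        from thrombosim.fitting import _series_loglik
        values = np.array([10.0, 20.0])
        pred = values * np.exp(0.1)
        quad = []
        for sigma in (0.1, 0.2):
            s = ObservationSeries("pop", "x", "platelets", [0, 1], values,
                                  sds=sigma * values)
            ll, _ = _series_loglik(pred, s)
            # subtract the normalization to isolate the quadratic part
            quad.append(-(ll + values.size * (math.log(sigma)
                                              + 0.5 * _LOG2PI)))
        assert quad[0] == pytest.approx(4.0 * quad[1])

    def test_population_term_at_mean_is_pure_normalization(self):
        """A virtual-participation term whose simulated value equals the
        published mean contributes only the normalization constant."""
        from thrombosim.fitting import _series_loglik
        s = ObservationSeries("harker", "pop", "mkc_count_rel", [0.0], [2.0],
                              sds=[0.5])
        ll, _ = _series_loglik(np.array([2.0]), s)
        sigma_log = 0.5 / 2.0
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi * sigma_log**2))

    def test_profiled_sigma_reported_as_residual_cv(self):
        from thrombosim.fitting import _series_loglik
        values = np.array([100.0, 100.0, 100.0, 100.0])
        pred = values * np.exp([0.1, -0.1, 0.1, -0.1])
        _, cv = _series_loglik(pred, ObservationSeries(
            "individual", "p", "platelets", np.arange(4.0), values))
        assert cv == pytest.approx(0.1)


class TestPrior:
    def test_from_samples_matches_log_moments(self):
        samples = np.exp([0.0, 0.5, 1.0])
        p = Prior.from_samples("x", samples)
        assert p.log_location == pytest.approx(0.5)
        assert p.log_scale == pytest.approx(0.5)

    def test_logpdf_is_lognormal(self):
        p = Prior("x", 0.0, 1.0)
        assert p.logpdf(1.0) == pytest.approx(-0.5 * _LOG2PI)
        assert p.logpdf(math.e) == pytest.approx(-0.5 * (1.0 + _LOG2PI))

    def test_scale_validation(self):
        with pytest.raises(ValueError):
            Prior("x", 0.0, 0.0)


class TestFitIndividual:
    def test_noise_free_self_consistency(self):
        """Noise-free observations generated from known parameters are
        recovered to better than 1% relative error."""
        cohort = generate_virtual_cohort(
            1, schedule_mix=("CHOP-21",), n_cycles=3, seed=9, noise_cv=0.0,
            iiv_distributions={"pd_cyclo": 0.4, "r_pl_0_nor": 0.15},
            with_tpo=False)
        vp = cohort[0]
        fr = fit_individual(vp.datasets(), default_parameters(), priors=None,
                            iiv_names=["pd_cyclo", "r_pl_0_nor"],
                            rtol=1e-6, compute_se=False)
        for name in ("pd_cyclo", "r_pl_0_nor"):
            assert fr.estimates[name] == pytest.approx(vp.truth[name],
                                                       rel=0.01)
        assert np.mean(list(fr.residual_cv.values())) < 0.01

    def test_flat_data_surfaces_nonidentifiability(self):
        """A steady-state series without therapy carries no information on
        chemotherapy toxicity: the reported uncertainty must be large."""
        days = np.arange(0.0, 30.0, 3.0)
        s = ObservationSeries("individual", "p0", "platelets", days,
                              np.full(days.size, 250.0))
        from thrombosim.schedules import TherapySchedule
        ds = FitDataset(schedule=TherapySchedule(), series=[s], days=31.0)
        fr = fit_individual([ds], default_parameters(), priors=None,
                            iiv_names=["pd_cyclo"], maxfev=40)
        assert fr.rel_se["pd_cyclo"] > 1.0

    def test_deterministic_given_seed_list(self):
        cohort = generate_virtual_cohort(
            1, schedule_mix=("CHOP-21",), n_cycles=3, seed=9,
            iiv_distributions={"pd_cyclo": 0.4}, with_tpo=False)
        vp = cohort[0]
        kw = dict(priors=None, iiv_names=["pd_cyclo"], maxfev=30,
                  compute_se=False, seeds=(1, 2))
        f1 = fit_individual(vp.datasets(), default_parameters(), **kw)
        f2 = fit_individual(vp.datasets(), default_parameters(), **kw)
        assert f1.estimates == f2.estimates


class TestLogLikelihoodTotal:
    def test_simulation_failure_returns_minus_inf(self):
        p = default_parameters()
        s = ObservationSeries("individual", "p", "platelets", [0.0], [250.0])
        from thrombosim.schedules import TherapySchedule
        ds = FitDataset(schedule=TherapySchedule(), series=[s], days=1.0)
        p.set("rk_dorm_act", 19.0)  # violates the admissible range
        ll, info = log_likelihood(p, [ds])
        assert ll == -np.inf and "error" in info

    def test_weights_scale_contributions(self):
        p = default_parameters()
        sched = built_in_schedule("CHOP-21", n_cycles=1)
        s = ObservationSeries("pop", "x", "platelets", [5.0, 10.0],
                              [250.0, 200.0], sds=[25.0, 20.0])
        ds1 = FitDataset(schedule=sched, series=[s], days=15.0, weight=1.0)
        ds2 = FitDataset(schedule=sched, series=[s], days=15.0, weight=2.0)
        ll1, _ = log_likelihood(p, [ds1])
        ll2, _ = log_likelihood(p, [ds2])
        assert ll2 == pytest.approx(2.0 * ll1)
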