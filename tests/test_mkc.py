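"""Megakaryocyte fate algebra, steady ploidy distribution, calibration."""

import numpy as np
import pytest

from thrombosim.mkc import (DORMANT_PLOIDIES, MKCParams, MKCState,
                            calibrate_ploidy_baseline, mkc_rhs,
                            proplatelet_rhs_and_efflux,
                            steady_ploidy_distribution)
from thrombosim.regulation import ZParams
from thrombosim.synthetic import HARKER_BASELINE_PLOIDY


def _degenerate_params():
    """p1 ~ 0, p2 ~ 1, no dormancy, equal transit everywhere: every ploidy
    class becomes a plain transit stage."""
    return MKCParams(
        t_endo=15.0, t_pp=15.0, p1_base=1e-9, p2_base=1.0 - 1e-9,
        q64_nor=1.0 - 1e-9,
        z_p1=ZParams(1e-10, 1e-9, 0.5),
        z_q64=ZParams(0.5, 1.0 - 1e-9, 1.0),
        t_rev_dorm={8: 10.0, 16: 10.0, 32: 10.0})


class TestSteadyDistribution:
    def test_frequencies_sum_to_one(self):
        freqs, _ = steady_ploidy_distribution(MKCParams(), 1.0)
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0 for v in freqs.values())

    def test_degenerate_chain_is_uniform(self):
        """Equal flux and equal transit across all seven ploidies gives a
        uniform distribution 1/7 (flux-balance argument)."""
        freqs, _ = steady_ploidy_distribution(_degenerate_params(), 1.0)
        for ploidy, f in freqs.items():
            assert f == pytest.approx(1.0 / 7.0, abs=1e-6), ploidy

    def test_default_calibration_reproduces_baseline_table(self):
        freqs, _ = steady_ploidy_distribution(MKCParams(), 1.0)
        assert freqs[16] == pytest.approx(0.47, abs=0.005)
        assert freqs[8] == pytest.approx(0.19, abs=0.005)
        assert freqs[32] == pytest.approx(0.21, abs=0.005)
        assert freqs[64] == pytest.approx(0.006, abs=0.001)

    def test_rhs_vanishes_at_solution(self):
        params = MKCParams()
        _, st = steady_ploidy_distribution(params, 2.5)
        d_act, d_dor = mkc_rhs(st, cm_efflux=2.5, params=params)
        np.testing.assert_allclose(d_act, 0.0, atol=1e-10)
        np.testing.assert_allclose(d_dor, 0.0, atol=1e-10)


class TestFateAlgebra:
    def test_ploidy4_advances_with_probability_one(self):
        """The inflow into ploidy 8 is the full ploidy-4 efflux: immature MKC
        neither go dormant nor form proplatelets."""
        params = MKCParams()
        st = MKCState(active=np.array([0.0, 15.0, 0, 0, 0, 0, 0.0]),
                      dormant=np.zeros(3))
        d_act, _ = mkc_rhs(st, cm_efflux=0.0, params=params)
        assert d_act[2] == pytest.approx(15.0 / params.t_endo)

    def test_dormant_death_only_via_osteoblast_loss(self):
        """With d_osteo_loss = 0 the dormant outflux equals the reactivation
        flux exactly."""
        params = MKCParams(d_osteo_loss=0.0)
        dor = np.array([3.0, 5.0, 7.0])
        st = MKCState(active=np.zeros(7), dormant=dor.copy())
        _, d_dor = mkc_rhs(st, cm_efflux=0.0, params=params)
        for j, ploidy in enumerate(DORMANT_PLOIDIES):
            krev = params.k_revdorm(ploidy, 1.0, 1.0)
            assert d_dor[j] == pytest.approx(-krev * dor[j])

    def test_tpo_shifts_fates_towards_endomitosis(self):
        params = MKCParams()
        assert params.p1(3.0) < params.p1(1.0) < params.p1(0.3)
        assert params.q64(1.0) == pytest.approx(params.q64_nor)
        assert params.q64(5.0) > 4 * params.q64_nor
        assert params.k_revdorm(16, 3.0, 1.0) > params.k_revdorm(16, 1.0, 1.0)

    def test_capacity_floor_prevents_blowup(self):
        params = MKCParams()
        assert np.isfinite(params.k_revdorm(16, 1.0, 0.0))


class TestProplatelets:
    def test_no_active_mkc_no_influx(self):
        st = MKCState(active=np.zeros(7), dormant=np.zeros(3), c_pp=0.0)
        d_pp, efflux = proplatelet_rhs_and_efflux(st, MKCParams())
        assert d_pp == 0.0 and efflux == 0.0

    def test_ploidy16_weight(self):
        """Only ploidy-16 cells: influx = 8 * p1 * c / T_PP (2^(k-1) = 8)."""
        params = MKCParams()
        c = 11.0
        st = MKCState(active=np.array([0, 0, 0, c, 0, 0, 0.0]),
                      dormant=np.zeros(3))
        d_pp, _ = proplatelet_rhs_and_efflux(st, params)
        assert d_pp == pytest.approx(8.0 * params.p1_base * c / params.t_pp)

    def test_steady_state_efflux_flux_balance(self):
        """At the proplatelet steady state the platelet efflux equals
        npt_pcu times the ploidy-weighted committed influx."""
        params = MKCParams()
        _, st = steady_ploidy_distribution(params, 1.0)
        d_pp, efflux = proplatelet_rhs_and_efflux(st, params)
        assert d_pp == pytest.approx(0.0, abs=1e-10)
        influx = st.c_pp / params.t_pp  # steady state: influx = content/T_PP
        assert efflux == pytest.approx(params.npt_pcu * influx)

    def test_production_homogeneous_in_mkc_mass(self):
        params = MKCParams()
        _, st = steady_ploidy_distribution(params, 1.0)
        d1, _ = proplatelet_rhs_and_efflux(
            MKCState(st.active, st.dormant, 0.0), params)
        d2, _ = proplatelet_rhs_and_efflux(
            MKCState(2.0 * st.active, st.dormant, 0.0), params)
        assert d2 == pytest.approx(2.0 * d1)


class TestCalibration:
    def test_self_recovery(self):
        """Calibrating to the model's own steady distribution is a fixed
        point: the residual is ~0."""
        params = MKCParams()
        freqs, _ = steady_ploidy_distribution(params, 1.0)
        targets = {k: freqs[k] for k in (8, 16, 32, 64)}
        _, info = calibrate_ploidy_baseline(targets, params)
        assert info["max_abs_deviation"] < 1e-6

    def test_harker_baseline_from_remote_start(self):
        start = MKCParams(p1_base=0.5, p2_base=0.5, t_pp=4.0,
                          t_rev_dorm={8: 20.0, 16: 20.0, 32: 20.0})
        fitted, info = calibrate_ploidy_baseline(HARKER_BASELINE_PLOIDY, start)
        assert info["max_abs_deviation"] <= 0.02
        # tie groups preserved: ploidy 16/32 reactivation times equal
        assert fitted.t_rev_dorm[16] == fitted.t_rev_dorm[32]

    def test_uniform_target_with_degenerate_dynamics(self):
        start = _degenerate_params()
        targets = {8: 1 / 7, 16: 1 / 7, 32: 1 / 7, 64: 1 / 7}
        _, info = calibrate_ploidy_baseline(targets, start)
        assert info["max_abs_deviation"] < 1e-4

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            calibrate_ploidy_baseline({}, MKCParams())
        with pytest.raises(ValueError):
            calibrate_ploidy_baseline({8: 0.9, 16: 0.9}, MKCParams())
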