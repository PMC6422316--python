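"""Full-model assembly, events, observables and clinical summaries."""

import numpy as np
import pytest

import thrombosim._core as _core
from thrombosim import (ChemoDoseEvent, Drug, PegTPOEvent, TherapySchedule,
                        TransfusionEvent, built_in_schedule,
                        default_parameters, init_steady_state, simulate,
                        thrombopenia_grade)
from thrombosim.mkc import MKCParams, MKCState, mkc_rhs, proplatelet_rhs_and_efflux
from thrombosim.osteo import OsteoParams, OsteoState, osteo_rhs
from thrombosim.platelets import PlateletParams, PlateletState, platelet_rhs
from thrombosim.stem_cm import CMParams, StemParams, cm_rhs, stem_rhs
from thrombosim.tpo import TPOParams, TPOState, tpo_rhs


class TestSteadyState:
    def test_residual_at_machine_precision(self, build):
        resid = build.rhs(0.0, build.y0)
        assert np.max(np.abs(resid)) < 1e-12

    def test_short_unperturbed_run_stays_flat(self, build):
        traj = simulate(build, days=100.0)
        assert np.max(np.abs(traj.y - 1.0)[:, build.y0 > 0]) < 1e-8
        assert traj.platelets[-1] == pytest.approx(
            build.params["r_pl_0_nor"], rel=1e-8)

    def test_dormant_active_ratio_configurable(self):
        p = default_parameters()
        p.set("rk_dorm_act", 50.0)
        b = init_steady_state(p)
        lay = b.layout
        ratio = b.norms[lay["SD"]] / b.norms[lay["SA"]]
        assert ratio == pytest.approx(50.0)

    def test_scale_invariance_of_relative_dynamics(self):
        """Halving the baseline count rescales observables but leaves the
        relative trajectories unchanged."""
        sched = built_in_schedule("CHOP-21", n_cycles=2)
        b1 = init_steady_state(default_parameters(),
                               baseline_platelet_count=250.0)
        b2 = init_steady_state(default_parameters(),
                               baseline_platelet_count=125.0)
        t1 = simulate(b1, sched, days=50.0)
        t2 = simulate(b2, sched, days=50.0)
        np.testing.assert_allclose(t1.platelets / 250.0, t2.platelets / 125.0,
                                   rtol=1e-6)
        np.testing.assert_allclose(t1.tpo_rel, t2.tpo_rel, rtol=1e-6)

    def test_infeasible_parameters_raise(self):
        p = default_parameters()
        p.set("rk_dorm_act", 10.0)  # outside the admissible range
        with pytest.raises(ValueError):
            init_steady_state(p)


class TestCoreConsistency:
    def test_flat_core_equals_module_composition(self, build, rng):
        """The compiled flat RHS agrees with the composition of the
        per-module rhs functions on random perturbed states."""
        params = build.params
        lay = build.layout
        n = lay["n_states"]
        mkc_par = MKCParams.from_registry(params)
        mkc_par.t_pp = build.theta[_core.T_PP]
        stem_par = StemParams(
            t_cycle=params["t_cycle"], p_delta=params["p_delta"],
            b_s_act=params["b_s_act"], k_dorm_nor=params["k_dorm_nor"],
            rk_dorm_act=params["rk_dorm_act"],
            d_osteo_loss=params["d_osteo_loss"])
        cm_par = CMParams(n_cm=build.n_cm, n_cm_early=build.n_early,
                          t_sub=params["t_sub_cm"],
                          amp_regulation=params.zparams("amp_cm"))
        ost_par = OsteoParams(params["osteo_alpha1"], params["osteo_beta1"],
                              params["osteo_alpha2"], params["osteo_beta2"],
                              params["d_psi"])
        plt_par = PlateletParams.from_registry(
            params, k_s=build.theta[_core.K_S], h_s=build.theta[_core.H_S])
        ploidy_vals = np.array([2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0])
        tpo_par = TPOParams(
            t_tpo=params["t_tpo"], k_m_tpo=params["k_m_tpo"],
            w_plc=build.theta[_core.W_PLC], w_pp=build.theta[_core.W_PP],
            w_mkc=build.theta[_core.W_MKC_BASE] * ploidy_vals,
            alpha=build.theta[_core.ALPHA], q_tpo=params["q_tpo"],
            fr_tpo_dir=params["fr_tpo_dir"], t_del=params["t_del"],
            t_del_p32=params["t_del_p32"])

        for _ in range(5):
            y = np.exp(rng.normal(0.0, 0.3, n))  # positive, near baseline
            core = build.rhs(0.0, y) * build.norms
            ya = y * build.norms

            cy, dx, et = ya[lay["CY"]], ya[lay["DX1"]], ya[lay["ET1"]]
            psi = {}
            for tgt, names in (("S", ("pd_cyclo", "pd_s_doxo", "pd_scm_etop")),
                               ("CM", ("pd_cm_cyclo", "pd_cm_doxo",
                                       "pd_scm_etop")),
                               ("imm", ("pd_imm_cd", "pd_imm_cd",
                                        "pd_imm_etop")),
                               ("mat", ("pd_mat_cd", "pd_mat_cd",
                                        "pd_mat_etop"))):
                psi[tgt] = (params[names[0]] * cy + params[names[1]] * dx
                            + params[names[2]] * et)
            psi["ost"] = params["c_pd_osteo"] * psi["CM"]

            d_ost = osteo_rhs(OsteoState(ya[lay["OC"]], ya[lay["OB"]],
                                         ya[lay["OL"]]), psi["ost"], ost_par)
            np.testing.assert_allclose(
                core[[lay["OC"], lay["OB"], lay["OL"]]], d_ost, rtol=1e-9)

            cap = y[lay["OB"]]
            cttb = (ya[lay["MA"]].sum() + ya[lay["MD"]].sum()) / \
                build.theta[_core.CTTB_NOR]
            d_stem = stem_rhs(ya[lay["SA"]], ya[lay["SD"]], cap_dor=cap,
                              cttb=cttb, psi_s=psi["S"],
                              osteo_loss=ya[lay["OL"]], c_ob_rel=cap,
                              params=stem_par)
            np.testing.assert_allclose(core[[lay["SA"], lay["SD"]]], d_stem,
                                       rtol=1e-9)

            from thrombosim.stem_cm import stem_efflux
            tpo_del = y[lay["DEL"]]
            d_cm, cm_out = cm_rhs(ya[lay["CM"]],
                                  stem_influx=stem_efflux(ya[lay["SA"]],
                                                          stem_par),
                                  tpo_delayed_rel=tpo_del, psi_cm=psi["CM"],
                                  params=cm_par)
            np.testing.assert_allclose(core[lay["CM"]], d_cm, rtol=1e-9)

            st = MKCState(active=ya[lay["MA"]].copy(),
                          dormant=ya[lay["MD"]].copy(), c_pp=ya[lay["PP"]])
            d_act, d_dor = mkc_rhs(
                st, cm_efflux=cm_out, tpo_del=tpo_del,
                tpo_del_p32=y[lay["DEL32"]], cap_dor=cap,
                osteo_loss=ya[lay["OL"]], c_ob_rel=cap, psi_imm=psi["imm"],
                psi_mat=psi["mat"], params=mkc_par)
            np.testing.assert_allclose(core[lay["MA"]], d_act, rtol=1e-9)
            np.testing.assert_allclose(core[lay["MD"]], d_dor, rtol=1e-9)

            d_pp, pp_out = proplatelet_rhs_and_efflux(st, mkc_par, tpo_del)
            assert core[lay["PP"]] == pytest.approx(d_pp, rel=1e-9)

            pstate = PlateletState(plc=ya[lay["PLC"]].copy(),
                                   pls=ya[lay["PLS"]].copy(),
                                   plc_labeled=ya[lay["PLL"]].copy())
            d_plc, d_pls, d_lab = platelet_rhs(pstate, pp_out, plt_par)
            np.testing.assert_allclose(core[lay["PLC"]], d_plc, rtol=1e-9)
            np.testing.assert_allclose(core[lay["PLS"]], d_pls, rtol=1e-9)
            np.testing.assert_allclose(core[lay["PLL"]], d_lab, rtol=1e-9)

            mkc_pools = ya[lay["MA"]].copy()
            mkc_pools[2:5] += ya[lay["MD"]]
            tstate = TPOState(endo_rel=ya[lay["TE"]], peg0=ya[lay["TP0"]],
                              peg1=ya[lay["TP1"]], peg2_rel=ya[lay["TP2"]],
                              del_main=ya[lay["DEL"]],
                              del_p32=ya[lay["DEL32"]])
            d_tpo = tpo_rhs(tstate,
                            plc_total=ya[lay["PLC"]].sum() + ya[lay["PLL"]].sum(),
                            pls_total=ya[lay["PLS"]].sum(),
                            mkc_pools=mkc_pools, pp_pool=ya[lay["PP"]],
                            params=tpo_par)
            np.testing.assert_allclose(
                core[[lay["TE"], lay["TP0"], lay["TP1"], lay["TP2"],
                      lay["DEL"], lay["DEL32"]]], d_tpo, rtol=1e-9)


class TestEventsAndSchedules:
    def test_schedule_file_order_irrelevant(self, build):
        """Two events at distinct times give identical results regardless of
        their ordering in the schedule definition."""
        e1 = ChemoDoseEvent(Drug.CYCLOPHOSPHAMIDE, 750.0, 0.0)
        e2 = PegTPOEvent(3.0, 4.0)
        t_a = simulate(build, TherapySchedule([e1, e2]), days=30.0)
        t_b = simulate(build, TherapySchedule([e2, e1]), days=30.0)
        np.testing.assert_allclose(t_a.platelets, t_b.platelets, rtol=1e-12)

    def test_transfusion_raises_count_immediately(self, build):
        sched = TherapySchedule([TransfusionEvent(30.0, 2.0)])
        traj = simulate(build, sched, days=10.0)
        before = traj.value_at(1.9, "platelets")
        after = traj.value_at(2.3, "platelets")
        assert after - before == pytest.approx(30.0, abs=2.5)

    def test_single_pulse_nadir_window_and_overshoot(self, build):
        """One CHOP-like pulse: platelet nadir between days 7 and 14, then a
        transient overshoot above baseline."""
        sched = built_in_schedule("CHOP-21", n_cycles=1)
        traj = simulate(build, sched, days=60.0)
        plts = traj.platelets
        early = traj.days <= 20.0
        i = int(np.argmin(plts[early]))
        assert 7.0 <= traj.days[i] <= 14.0
        assert plts[i] < build.params["r_pl_0_nor"] * 0.95
        assert np.max(plts[i:]) > build.params["r_pl_0_nor"] * 1.02

    def test_post_therapy_oscillations_damp(self, build):
        """After a single cycle the platelet deviation from baseline decays:
        the maximal deviation over successive 60-day windows (past the acute
        overshoot) strictly decreases."""
        sched = built_in_schedule("CHOP-21", n_cycles=1)
        traj = simulate(build, sched, days=210.0)
        base = build.params["r_pl_0_nor"]
        dev = np.abs(traj.platelets - base)
        maxima = []
        for a in (30.0, 90.0, 150.0):
            m = (traj.days >= a) & (traj.days < a + 60.0)
            maxima.append(float(np.max(dev[m])))
        assert maxima[0] > maxima[1] > maxima[2]

    def test_nonnegative_states_under_therapy(self, build):
        sched = built_in_schedule("CHOEP-14", n_cycles=6)
        traj = simulate(build, sched, days=110.0)
        assert np.min(traj.y) > -1e-9

    def test_tolerance_refinement_stability(self, build):
        """Halving the solver tolerances changes platelet observables by less
        than 0.1% relative."""
        sched = built_in_schedule("CHOP-21", n_cycles=2)
        t1 = simulate(build, sched, days=50.0, rtol=1e-6, atol=1e-9)
        t2 = simulate(build, sched, days=50.0, rtol=5e-7, atol=5e-10)
        assert np.max(np.abs(t1.platelets / t2.platelets - 1.0)) < 1e-3

    def test_builtin_schedule_composition(self):
        chop = built_in_schedule("CHOP-14", n_cycles=6)
        assert len(chop.cycle_starts) == 6
        assert chop.cycle_starts[1] - chop.cycle_starts[0] == 14.0
        choep = built_in_schedule("CHOEP-21", n_cycles=6)
        etop = [e for e in choep.events if isinstance(e, ChemoDoseEvent)
                and e.drug == Drug.ETOPOSIDE]
        assert len(etop) == 18  # 3 days x 6 cycles

    def test_shift_and_omit(self):
        base = built_in_schedule("CHOP-21", n_cycles=3)
        shifted = base.shift_last_cycle(5)
        assert shifted.cycle_starts[-1] == 47.0
        omitted = base.shift_last_cycle("omit")
        assert len(omitted.cycle_starts) == 2


class TestGrades:
    @pytest.mark.parametrize("count, grade", [
        (250.0, 0), (100.0, 0), (99.0, 1), (75.0, 1), (74.0, 2), (50.0, 2),
        (30.0, 3), (25.0, 3), (20.0, 4), (0.0, 4)])
    def test_thresholds(self, count, grade):
        assert thrombopenia_grade([count])[0] == grade

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            thrombopenia_grade([-1.0])
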