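"""Full-model assembly, steady-state initialization and therapy simulation.

``init_steady_state`` back-solves the steady state of every sub-system
(osteoblast fixed point, stem-cell dormancy ratio, CM/MKC flux balance,
platelet chain with quasi-constant consumption, TPO production constant) and
returns a :class:`ModelBuild` holding the packed parameter vector, the state
norms and the initial condition (all ones/zeros in normalized units).

``simulate`` integrates the stiff system (BDF) through a therapy schedule,
restarting at every event and applying boluses as state jumps, and returns a
:class:`Trajectory` with derived clinical observables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _core
from .chemo import Drug
from .mkc import MKCParams, steady_ploidy_distribution
from .osteo import OsteoParams, osteo_steady_state
from .platelets import PlateletParams, steady_state_chain
from .registry import ModelParameters, default_parameters
from .schedules import (ChemoDoseEvent, PegTPOEvent, TherapySchedule,
                        TransfusionEvent)
from .stem_cm import CMParams, cm_steady_state
from .tpo import TPOParams

__all__ = ["ModelBuild", "Trajectory", "init_steady_state", "simulate",
           "thrombopenia_grade", "cycle_nadirs", "scenario_shift_last_cycle",
           "GRADE_THRESHOLDS"]

#: CTCAE v4 platelet thresholds (1e9/L) for grades 1-4
GRADE_THRESHOLDS = (100.0, 75.0, 50.0, 25.0)

_STD_DOSE_KEY = {Drug.CYCLOPHOSPHAMIDE: "std_dose_cyclo",
                 Drug.DOXORUBICIN: "std_dose_doxo",
                 Drug.ETOPOSIDE: "std_dose_etop",
                 Drug.PROCARBAZINE: "std_dose_procar"}
_PK_STATE = {Drug.CYCLOPHOSPHAMIDE: "CY", Drug.DOXORUBICIN: "DX1",
             Drug.ETOPOSIDE: "ET1", Drug.PROCARBAZINE: "PR0"}
_INFUSION_SLOT = {Drug.CYCLOPHOSPHAMIDE: _core.INF_CY,
                  Drug.DOXORUBICIN: _core.INF_DX,
                  Drug.ETOPOSIDE: _core.INF_ET}


@dataclass
class ModelBuild:
    """Packed full model: parameters, norms and steady-state initial values."""

    params: ModelParameters
    theta: np.ndarray
    norms: np.ndarray
    layout: dict
    n_cm: int
    n_early: int
    n_age: int
    circ_nor: float          # circulating platelet pool, internal units
    mkc_total_nor: float     # active+dormant MKC pool, internal units
    plt_scale: float         # 1e9/L per internal circulating unit
    y0: np.ndarray = field(repr=False, default=None)

    def rhs(self, t, y):
        return _core.rhs(t, y, self.theta, self.norms, self.n_cm,
                         self.n_early, self.n_age)

    # -- observables (normalized state vector or matrix) --------------------
    def platelets(self, y) -> np.ndarray:
        """Circulating platelet count in 1e9/L (labeled pool included)."""
        lay = self.layout
        ya = np.atleast_2d(y) * self.norms
        total = ya[:, lay["PLC"]].sum(axis=1) + ya[:, lay["PLL"]].sum(axis=1)
        return np.squeeze(total * self.plt_scale)

    def tpo_rel(self, y) -> np.ndarray:
        lay = self.layout
        ya = np.atleast_2d(y) * self.norms
        return np.squeeze(ya[:, lay["TE"]] + ya[:, lay["TP2"]])

    def mkc_total_rel(self, y) -> np.ndarray:
        lay = self.layout
        ya = np.atleast_2d(y) * self.norms
        total = ya[:, lay["MA"]].sum(axis=1) + ya[:, lay["MD"]].sum(axis=1)
        return np.squeeze(total / self.mkc_total_nor)

    def ploidy_fractions(self, y) -> pd.DataFrame:
        """Frequencies of ploidies 2..128 among all MKC (active + dormant)."""
        lay = self.layout
        ya = np.atleast_2d(y) * self.norms
        act = ya[:, lay["MA"]]
        dor = ya[:, lay["MD"]]
        totals = act.copy()
        totals[:, 2:5] += dor
        denom = totals.sum(axis=1, keepdims=True)
        frac = totals / np.where(denom > 0, denom, 1.0)
        return pd.DataFrame(frac, columns=[f"ploidy_{p}"
                                           for p in (2, 4, 8, 16, 32, 64, 128)])

    def c_ob_rel(self, y) -> np.ndarray:
        return np.squeeze(np.atleast_2d(y)[:, self.layout["OB"]].copy())


def _pack_theta(params: ModelParameters, mkc: MKCParams) -> np.ndarray:
    t = np.zeros(_core.N_THETA)
    t[_core.T_CYCLE] = params["t_cycle"]
    t[_core.P_DELTA] = params["p_delta"]
    t[_core.B_S_ACT] = params["b_s_act"]
    t[_core.K_DORM_NOR] = params["k_dorm_nor"]
    t[_core.K_ACT] = params["k_dorm_nor"] / params["rk_dorm_act"]
    t[_core.D_OSTEO_LOSS] = params["d_osteo_loss"]
    t[_core.T_SUB_CM] = params["t_sub_cm"]
    t[_core.Z_AMP:_core.Z_AMP + 6] = params.zparams("amp_cm").as_tuple()
    t[_core.A1] = params["osteo_alpha1"]
    t[_core.B1] = params["osteo_beta1"]
    t[_core.A2] = params["osteo_alpha2"]
    t[_core.B2] = params["osteo_beta2"]
    t[_core.D_PSI] = params["d_psi"]
    t[_core.T_ENDO] = mkc.t_endo
    t[_core.T_DORM] = mkc.t_dorm_mkc
    t[_core.T_PP] = mkc.t_pp
    t[_core.P2_TIED] = mkc.p2_base
    t[_core.Z_P1:_core.Z_P1 + 6] = mkc.z_p1.as_tuple()
    t[_core.Z_Q64:_core.Z_Q64 + 6] = mkc.z_q64.as_tuple()
    t[_core.Z_KREV:_core.Z_KREV + 6] = mkc.z_krev.as_tuple()
    t[_core.TREV8] = mkc.t_rev_dorm[8]
    t[_core.TREV16] = mkc.t_rev_dorm[16]
    t[_core.TREV32] = mkc.t_rev_dorm[32]
    t[_core.NPT] = mkc.npt_pcu
    t[_core.T_PL] = params["t_pl"]
    t[_core.K_CIRC] = params["k_circ"]
    t[_core.P_ELIM] = params["p_elim"]
    t[_core.KBASE_SC] = params["k_base_sc"]
    t[_core.GAMMA_SC] = params["gamma_sc"]
    t[_core.T_TPO] = params["t_tpo"]
    t[_core.KM_TPO] = params["k_m_tpo"]
    t[_core.Q_TPO] = params["q_tpo"]
    t[_core.FR_DIR] = params["fr_tpo_dir"]
    t[_core.T_DEL] = params["t_del"]
    t[_core.T_DEL32] = params["t_del_p32"]
    t[_core.K_CY] = params["pk_cyclo_k"]
    t[_core.DXK10] = params["pk_doxo_k10"]
    t[_core.DXK12] = params["pk_doxo_k12"]
    t[_core.DXK21] = params["pk_doxo_k21"]
    t[_core.ETK10] = params["pk_etop_k10"]
    t[_core.ETK12] = params["pk_etop_k12"]
    t[_core.ETK21] = params["pk_etop_k21"]
    t[_core.PRKA] = params["pk_procar_ka"]
    t[_core.PRKE] = params["pk_procar_ke"]
    pd_rows = (("pd_cyclo", "pd_s_doxo", "pd_scm_etop"),
               ("pd_cm_cyclo", "pd_cm_doxo", "pd_scm_etop"),
               ("pd_imm_cd", "pd_imm_cd", "pd_imm_etop"),
               ("pd_mat_cd", "pd_mat_cd", "pd_mat_etop"))
    for r, row in enumerate(pd_rows):
        for c, name in enumerate(row):
            t[_core.PD0 + 3 * r + c] = params[name]
    t[_core.C_PD_OSTEO] = params["c_pd_osteo"]
    return t


def init_steady_state(params: ModelParameters | None = None,
                      baseline_platelet_count: float | None = None,
                      check_residual: bool = True) -> ModelBuild:
    """Back-solve the steady state and pack the full model.

    The absolute scale of the internal cell pools is anchored at an active
    stem-cell pool of 1; ``baseline_platelet_count`` (1e9/L) overrides the
    registry's ``r_pl_0_nor`` to set the observable platelet scale.
    """
    if params is None:
        params = default_parameters()
    report = params.audit()
    if not report.ok:
        raise ValueError("parameter registry violates constraints: "
                         + "; ".join(report.violations))
    if baseline_platelet_count is not None:
        params = params.copy()
        params.set("r_pl_0_nor", baseline_platelet_count)

    n_cm = int(params["n_cm"])
    n_early = int(params["n_cm_early"])
    n_age = int(params["n_age"])
    lay = _core.state_layout(n_cm, n_age)
    mkc = MKCParams.from_registry(params)
    theta = _pack_theta(params, mkc)

    # 1. osteoblast/osteoclast fixed point
    ost = OsteoParams(params["osteo_alpha1"], params["osteo_beta1"],
                      params["osteo_alpha2"], params["osteo_beta2"],
                      params["d_psi"])
    oc_ss, ob_ss = osteo_steady_state(ost)

    # 2. stem cells: active pool 1, dormant = rk_dorm_act
    s_act, s_dorm = 1.0, params["rk_dorm_act"]

    # 3. CM chain at baseline amplification
    cm_par = CMParams(n_cm=n_cm, n_cm_early=n_early, t_sub=params["t_sub_cm"],
                      amp_regulation=params.zparams("amp_cm"))
    stem_flux = s_act / params["t_cycle"]  # 2(1-p) = 1 at p = 0.5
    cm_states, cm_efflux = cm_steady_state(stem_flux, cm_par)

    # 4. MKC fixed point (linear solve) and proplatelets
    _, mkc_state = steady_ploidy_distribution(mkc, cm_efflux)

    # 5. platelet chain with quasi-constant consumption
    production = mkc.npt_pcu * mkc_state.c_pp / mkc.t_pp
    plt0 = PlateletParams.from_registry(params)
    chain0 = steady_state_chain(production, plt0)
    circ_free = float(np.sum(chain0.plc))
    k_s = params["k_s_rel"] * production
    h_s = params["h_s_rel"] * circ_free
    plt = PlateletParams.from_registry(params, k_s=k_s, h_s=h_s)
    chain = steady_state_chain(production, plt)
    circ_nor = float(np.sum(chain.plc))
    theta[_core.K_S] = k_s
    theta[_core.H_S] = h_s

    # 6. TPO: receptor weights from pool shares, production from steady state
    d_spec = params["d_spec_nor"]
    w_nor = d_spec * (1.0 + params["k_m_tpo"])
    plat_pool = circ_nor + float(np.sum(chain.pls))
    ploidy_vals = np.array([2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0])
    mkc_w_pool = float(np.dot(ploidy_vals, mkc_state.active))
    mkc_w_pool += float(np.dot(ploidy_vals[2:5], mkc_state.dormant))
    theta[_core.W_PLC] = params["share_plc"] * w_nor / plat_pool
    theta[_core.W_MKC_BASE] = params["share_mkc"] * w_nor / mkc_w_pool
    theta[_core.W_PP] = params["share_pp"] * w_nor / mkc_state.c_pp
    theta[_core.ALPHA] = 1.0 / params["t_tpo"] + d_spec

    # 7. norms and the normalized initial state
    norms = np.ones(lay["n_states"])
    norms[lay["OC"]] = oc_ss
    norms[lay["OB"]] = ob_ss
    norms[lay["SA"]] = s_act
    norms[lay["SD"]] = s_dorm
    norms[lay["CM"]] = cm_states
    norms[lay["MA"]] = mkc_state.active
    norms[lay["MD"]] = mkc_state.dormant
    norms[lay["PP"]] = mkc_state.c_pp
    norms[lay["PLC"]] = chain.plc
    norms[lay["PLS"]] = chain.pls
    mkc_total_nor = float(np.sum(mkc_state.active) + np.sum(mkc_state.dormant))
    theta[_core.CTTB_NOR] = mkc_total_nor

    y0 = np.zeros(lay["n_states"])
    for key in ("OC", "OB", "SA", "SD", "CM", "MA", "MD", "PP", "PLC", "PLS"):
        y0[lay[key]] = 1.0
    y0[lay["TE"]] = 1.0
    y0[lay["DEL"]] = 1.0
    y0[lay["DEL32"]] = 1.0

    build = ModelBuild(params=params, theta=theta, norms=norms, layout=lay,
                       n_cm=n_cm, n_early=n_early, n_age=n_age,
                       circ_nor=circ_nor, mkc_total_nor=mkc_total_nor,
                       plt_scale=params["r_pl_0_nor"] / circ_nor, y0=y0)

    if check_residual:
        resid = build.rhs(0.0, y0)
        # relative units: states are O(1), so the raw residual is relative
        worst = float(np.max(np.abs(resid)))
        if worst > 1e-8:
            i = int(np.argmax(np.abs(resid)))
            raise RuntimeError(
                f"steady-state residual {worst:.3e} at state index {i}; "
                "the parameter combination breaks a balance condition")
    return build


# ---------------------------------------------------------------------------
# event handling & integration
# ---------------------------------------------------------------------------

def _event_times_and_jumps(build: ModelBuild, schedule: TherapySchedule):
    """Jump list [(t_h, fn(y))] and infusion windows [(t0, t1, slot, rate)]."""
    jumps, infusions = [], []
    lay = build.layout
    params = build.params
    for ev in schedule.events:
        t_h = 24.0 * ev.day
        if isinstance(ev, ChemoDoseEvent):
            rel = ev.amount / params[_STD_DOSE_KEY[ev.drug]]
            idx = lay[_PK_STATE[ev.drug]]
            if ev.infusion_hours > 0 and ev.drug in _INFUSION_SLOT:
                infusions.append((t_h, t_h + ev.infusion_hours,
                                  _INFUSION_SLOT[ev.drug],
                                  rel / ev.infusion_hours))
            else:
                jumps.append((t_h, idx, rel))
        elif isinstance(ev, PegTPOEvent):
            jumps.append((t_h, lay["TP0"],
                          ev.dose_ug_per_kg * params["peg_dose_scale"]))
        elif isinstance(ev, TransfusionEvent):
            # distribute over circulating age classes by the steady profile
            profile = build.norms[lay["PLC"]] / build.circ_nor
            amount = ev.amount / build.plt_scale
            jumps.append((t_h, lay["PLC"], amount * profile / build.norms[lay["PLC"]]))
        else:
            raise TypeError(f"unknown event {ev!r}")
    return jumps, infusions


@dataclass
class Trajectory:
    """Simulated time course with derived observables."""

    t_h: np.ndarray
    y: np.ndarray  # (n_t, n_states), normalized units
    build: ModelBuild

    @property
    def days(self) -> np.ndarray:
        return self.t_h / 24.0

    @property
    def platelets(self) -> np.ndarray:
        return np.atleast_1d(self.build.platelets(self.y))

    @property
    def tpo_rel(self) -> np.ndarray:
        return np.atleast_1d(self.build.tpo_rel(self.y))

    @property
    def mkc_total_rel(self) -> np.ndarray:
        return np.atleast_1d(self.build.mkc_total_rel(self.y))

    @property
    def c_ob_rel(self) -> np.ndarray:
        return np.atleast_1d(self.build.c_ob_rel(self.y))

    def ploidy_fractions(self) -> pd.DataFrame:
        return self.build.ploidy_fractions(self.y)

    def value_at(self, days, observable: str) -> np.ndarray:
        series = getattr(self, observable)
        return np.interp(np.atleast_1d(days) * 24.0, self.t_h, series)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({
            "day": self.days,
            "platelets_1e9_per_L": self.platelets,
            "tpo_rel": self.tpo_rel,
            "mkc_total_rel": self.mkc_total_rel,
            "c_ob_rel": self.c_ob_rel,
        })
        frame = pd.concat([frame, self.ploidy_fractions()], axis=1)
        frame["grade"] = thrombopenia_grade(frame["platelets_1e9_per_L"])
        return frame


def simulate(build: ModelBuild, schedule: TherapySchedule | None = None,
             days: float = 100.0, rtol: float = 1e-6, atol: float = 1e-9,
             points_per_day: int = 4, y0: np.ndarray | None = None,
             t0_h: float = 0.0, extra_days=None) -> Trajectory:
    """Integrate the full model through a therapy schedule.

    Stiff BDF integration, restarted at every event; boluses are applied as
    state jumps, infusions as piecewise-constant inputs.  Output on a uniform
    sub-daily grid (``points_per_day``) plus event-adjacent samples;
    ``extra_days`` adds exact output times (e.g. observation days).
    """
    if schedule is None:
        schedule = TherapySchedule()
    jumps, infusions = _event_times_and_jumps(build, schedule)
    t_end = t0_h + 24.0 * days
    breaks = sorted({t for t, *_ in jumps}
                    | {t0 for t0, t1, *_ in infusions}
                    | {t1 for t0, t1, *_ in infusions}
                    | {t0_h, t_end})
    breaks = [t for t in breaks if t0_h <= t <= t_end]

    grid = np.linspace(t0_h, t_end, int(days * points_per_day) + 1)
    if extra_days is not None:
        extra = 24.0 * np.asarray(extra_days, dtype=float)
        extra = extra[(extra >= t0_h) & (extra <= t_end)]
        grid = np.unique(np.concatenate([grid, extra]))
    y = (build.y0 if y0 is None else y0).copy()
    theta = build.theta.copy()
    ts, ys = [t0_h], [y.copy()]

    def rhs(t, yy):
        return _core.rhs(t, yy, theta, build.norms, build.n_cm, build.n_early,
                         build.n_age)

    for a, b in zip(breaks[:-1], breaks[1:]):
        # apply bolus jumps at segment start
        for t_j, idx, amount in jumps:
            if t_j == a:
                y[idx] = y[idx] + amount
        theta[_core.INF_CY] = theta[_core.INF_DX] = theta[_core.INF_ET] = 0.0
        for t0, t1, slot, rate in infusions:
            if t0 <= a < t1:
                theta[slot] = rate
        t_eval = grid[(grid > a) & (grid < b)]
        t_eval = np.unique(np.concatenate([[a], t_eval, [b]]))
        sol = solve_ivp(rhs, (a, b), y, method="BDF", t_eval=t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t = {sol.t[-1] / 24.0:.2f} d: "
                f"{sol.message}")
        ts.extend(sol.t[1:].tolist())
        ys.extend(sol.y.T[1:])
        y = sol.y[:, -1].copy()
    return Trajectory(t_h=np.array(ts), y=np.vstack(ys), build=build)


# ---------------------------------------------------------------------------
# clinical summaries
# ---------------------------------------------------------------------------

def thrombopenia_grade(platelets) -> np.ndarray:
    """CTCAE v4 thrombocytopenia grade per sample (counts in 1e9/L)."""
    x = np.asarray(platelets, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative platelet counts")
    grade = np.zeros(x.shape, dtype=int)
    for g, thr in enumerate(GRADE_THRESHOLDS, start=1):
        grade[x < thr] = g
    return grade


def cycle_nadirs(traj: Trajectory, cycle_starts_days) -> pd.DataFrame:
    """Per-cycle platelet nadir and worst grade.

    Cycle ``i`` spans from its start to the next cycle start (or the end of
    the trajectory for the last cycle).
    """
    starts = sorted(cycle_starts_days)
    edges = [24.0 * s for s in starts] + [traj.t_h[-1]]
    rows = []
    plts = traj.platelets
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        m = (traj.t_h >= a) & (traj.t_h <= b)
        if not np.any(m):
            continue
        nadir = float(np.min(plts[m]))
        rows.append(dict(cycle=i + 1, start_day=a / 24.0, nadir=nadir,
                         grade=int(thrombopenia_grade([nadir])[0]),
                         mean_tpo_rel=float(np.mean(traj.tpo_rel[m]))))
    return pd.DataFrame(rows)


def scenario_shift_last_cycle(build: ModelBuild, base_schedule: TherapySchedule,
                              shifts=(-5, 0, 5, 10, "omit"),
                              followup_days: float = 90.0,
                              rtol: float = 1e-6, atol: float = 1e-9) -> dict:
    """Simulate alternative timings of the last chemotherapy cycle.

    Returns ``{shift: {"trajectory", "nadir", "grade"}}`` where the nadir is
    taken over the window from the penultimate cycle start to the end of the
    follow-up (a common window across scenarios).
    """
    if len(base_schedule.cycle_starts) < 2:
        raise ValueError("base schedule needs at least two cycles")
    penult = base_schedule.cycle_starts[-2]
    horizon = base_schedule.last_event_day + 10.0 + followup_days
    out = {}
    for shift in shifts:
        sched = (base_schedule if shift == 0
                 else base_schedule.shift_last_cycle(shift))
        traj = simulate(build, sched, days=horizon, rtol=rtol, atol=atol)
        m = traj.t_h >= 24.0 * penult
        nadir = float(np.min(traj.platelets[m]))
        out[shift] = {"trajectory": traj, "nadir": nadir,
                      "grade": int(thrombopenia_grade([nadir])[0])}
    return out
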