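"""Ploidy-resolved megakaryocyte (MKC) dynamics.

Megakaryocytes of ploidies 2-128 mature in parallel.  Ploidies 2 and 4 form a
plain endomitosis chain; cells of ploidies 8, 16 and 32 have three fates —
proplatelet formation (probability ``p1``), endomitosis to the next ploidy
(``(1-p1)*p2``) or entry into a dormant state (``(1-p1)*(1-p2)``, limited by
bone-marrow capacity).  Ploidy-64 cells advance to 128 only under elevated
TPO; ploidy-128 cells only form proplatelets.  Dormant cells reactivate
TPO-dependently (with a longer delay for ploidy 32) and die when supporting
osteoblasts are lost.

TPO suppresses proplatelet formation (``p1`` decreases with delayed TPO) and
promotes endomitosis and dormant-cell mobilization, which produces the
biphasic platelet response to TPO injections: an initial dip followed by a
multi-week elevation.

Proplatelet production: each MKC leaving to the proplatelet compartment
contributes platelet-equivalents in proportion to its ploidy, so the influx
is ``sum_k 2^(k-1) * p_{k,1} / T_PP * C_act_k`` over ploidies 8-128.  The
fate probability appears in the influx so that the flux feeding proplatelets
is exactly the flux of cells committed to proplatelet formation in the fate
algebra; total production remains proportional to megakaryocyte mass at any
fixed TPO level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .regulation import ZParams, z_function
from .registry import ModelParameters

__all__ = ["PLOIDIES", "DORMANT_PLOIDIES", "MKCParams", "MKCState", "mkc_rhs",
           "proplatelet_rhs_and_efflux", "steady_ploidy_distribution",
           "calibrate_ploidy_baseline"]

#: active ploidy classes 2^k, k = 1..7
PLOIDIES = (2, 4, 8, 16, 32, 64, 128)
#: ploidies with a dormant state
DORMANT_PLOIDIES = (8, 16, 32)

# floor on the bone-marrow capacity inside 1/Cap_dor (reactivation) to
# prevent blowup when osteoblasts are fully depleted
CAP_FLOOR = 1e-6


@dataclass
class MKCState:
    active: np.ndarray   # counts for ploidies 2..128 (length 7)
    dormant: np.ndarray  # counts for ploidies 8, 16, 32 (length 3)
    c_pp: float = 0.0    # proplatelet content (platelet-equivalents/npt_pcu)


@dataclass
class MKCParams:
    t_endo: float = 15.0      # h, endomitosis stage time
    t_dorm_mkc: float = 12.0  # h, dormancy-entry transit
    t_pp: float = 16.3        # h, proplatelet transit
    p1_base: float = 0.2157   # baseline proplatelet probability (tied 8/16/32)
    p2_base: float = 0.2044   # baseline next-ploidy probability (tied 8/16/32)
    q64_nor: float = 0.005    # baseline 64->128 advance probability
    t_rev_dorm: dict = field(default_factory=lambda: {8: 1.9, 16: 97.7, 32: 97.7})
    npt_pcu: float = 500.0    # platelets per ploidy unit
    d_osteo_loss: float = 0.5
    z_p1: ZParams | None = None    # decreasing in delayed TPO; y_nor = p1_base
    z_q64: ZParams | None = None   # increasing; y_nor = q64_nor
    z_krev: ZParams | None = None  # increasing multiplier on 1/t_rev

    def __post_init__(self):
        if self.z_p1 is None:
            self.z_p1 = ZParams(0.05, self.p1_base, 0.85, 1.2, 2.0, "decreasing")
        if self.z_q64 is None:
            self.z_q64 = ZParams(1e-4, self.q64_nor, 0.6, 2.0, 2.0, "increasing")
        if self.z_krev is None:
            self.z_krev = ZParams(0.3, 1.0, 6.0, 1.0, 2.0, "increasing")

    @classmethod
    def from_registry(cls, params: ModelParameters) -> "MKCParams":
        return cls(
            t_endo=params["t_endo"], t_dorm_mkc=params["t_dorm_mkc"],
            t_pp=params["t_pp"], p1_base=params["p1_8"], p2_base=params["p2_8"],
            q64_nor=params["q64_nor"],
            t_rev_dorm={8: params["t_rev_dorm_8"], 16: params["t_rev_dorm_16"],
                        32: params["t_rev_dorm_32"]},
            npt_pcu=params["npt_pcu"], d_osteo_loss=params["d_osteo_loss"],
            z_p1=params.zparams("p1_mkc"), z_q64=params.zparams("q64"),
            z_krev=params.zparams("krev"))

    # regulated instantaneous values ---------------------------------------
    def p1(self, tpo_del: float) -> float:
        return float(z_function(tpo_del, self.z_p1))

    def q64(self, tpo_del: float) -> float:
        return float(z_function(tpo_del, self.z_q64))

    def k_revdorm(self, ploidy: int, tpo_del: float, cap_dor: float) -> float:
        """Reactivation rate: (1/Cap_dor) * Z(delayed TPO) / t_rev_nor."""
        mult = float(z_function(tpo_del, self.z_krev))
        return mult / (self.t_rev_dorm[ploidy] * max(cap_dor, CAP_FLOOR))


def mkc_rhs(state: MKCState, *, cm_efflux: float, tpo_del: float = 1.0,
            tpo_del_p32: float = 1.0, cap_dor: float = 1.0,
            osteo_loss: float = 0.0, c_ob_rel: float = 1.0,
            psi_imm: float = 0.0, psi_mat: float = 0.0, params: MKCParams):
    """Derivatives ``(d_active, d_dormant)`` of the MKC fate algebra."""
    act, dor = state.active, state.dormant
    p1 = params.p1(tpo_del)
    q64 = params.q64(tpo_del)
    p2 = params.p2_base
    te, tp = params.t_endo, params.t_pp
    kdorm = (1.0 - p1) * (1.0 - p2) / params.t_dorm_mkc * cap_dor
    death = params.d_osteo_loss * osteo_loss * c_ob_rel

    d_act = np.empty(7)
    d_dor = np.empty(3)
    # immature chain: ploidies 2, 4 (no dormancy, no proplatelets)
    d_act[0] = cm_efflux - act[0] / te - psi_imm * act[0]
    d_act[1] = act[0] / te - act[1] / te - psi_imm * act[1]
    # ploidies 8, 16, 32: three fates + dormancy exchange
    inflow = act[1] / te  # ploidy-4 cells advance with probability 1
    for j, ploidy in enumerate(DORMANT_PLOIDIES):
        i = 2 + j
        sig = tpo_del_p32 if ploidy == 32 else tpo_del
        krev = params.k_revdorm(ploidy, sig, cap_dor)
        out = p2 * (1.0 - p1) / te + p1 / tp + kdorm + psi_mat
        d_act[i] = inflow + krev * dor[j] - out * act[i]
        d_dor[j] = kdorm * act[i] - (krev + death) * dor[j]
        inflow = p2 * (1.0 - p1) / te * act[i]
    # ploidy 64: advance only under elevated TPO
    p64_1 = 1.0 - q64
    d_act[5] = inflow - (q64 / te + p64_1 / tp + psi_mat) * act[5]
    # ploidy 128: proplatelets only
    d_act[6] = q64 / te * act[5] - (1.0 / tp + psi_mat) * act[6]
    return d_act, d_dor


def proplatelet_rhs_and_efflux(state: MKCState, params: MKCParams,
                               tpo_del: float = 1.0):
    """Proplatelet balance and platelet efflux.

    Returns ``(dC_PP/dt, efflux)`` where the influx weights each
    proplatelet-committed MKC by half its ploidy (platelet-equivalents per
    diploid set) and the efflux is ``npt_pcu * C_PP / T_PP``.
    """
    act = state.active
    p1 = params.p1(tpo_del)
    p64_1 = 1.0 - params.q64(tpo_del)
    p_out = np.array([0.0, 0.0, p1, p1, p1, p64_1, 1.0])
    weights = np.array([0.0, 0.0, 4.0, 8.0, 16.0, 32.0, 64.0])  # 2^(k-1)
    influx = float(np.sum(weights * p_out * act)) / params.t_pp
    d_pp = influx - state.c_pp / params.t_pp
    efflux = params.npt_pcu * state.c_pp / params.t_pp
    return d_pp, efflux


# ---------------------------------------------------------------------------
# steady state & calibration
# ---------------------------------------------------------------------------

def _baseline_system(params: MKCParams, cm_influx: float):
    """Linear system ``M x + c`` of the baseline MKC dynamics (x = 10 states)."""
    def f(x):
        st = MKCState(active=x[:7].copy(), dormant=x[7:].copy())
        da, dd = mkc_rhs(st, cm_efflux=cm_influx, params=params)
        return np.concatenate([da, dd])

    c = f(np.zeros(10))
    M = np.empty((10, 10))
    for i in range(10):
        e = np.zeros(10)
        e[i] = 1.0
        M[:, i] = f(e) - c
    return M, c


def steady_ploidy_distribution(params: MKCParams, cm_influx: float = 1.0):
    """Baseline steady state of the MKC sub-model.

    Solves the linear fixed point of :func:`mkc_rhs` at relative TPO = 1 and
    full bone-marrow capacity.  Returns ``(freqs, state)`` where ``freqs``
    maps each ploidy to its frequency among all megakaryocytes (active plus
    dormant, the population a histological count sees); frequencies sum to 1.
    """
    M, c = _baseline_system(params, cm_influx)
    try:
        x = np.linalg.solve(M, -c)
    except np.linalg.LinAlgError as err:
        raise RuntimeError(f"MKC steady state is singular: {err}") from err
    if np.any(x < -1e-9 * max(1.0, np.max(np.abs(x)))):
        raise RuntimeError("MKC steady state has negative components; "
                           "check transition parameters")
    x = np.clip(x, 0.0, None)
    active, dormant = x[:7], x[7:]
    totals = active.copy()
    for j, ploidy in enumerate(DORMANT_PLOIDIES):
        totals[2 + j] += dormant[j]
    freqs = {p: totals[i] / totals.sum() for i, p in enumerate(PLOIDIES)}
    st = MKCState(active=active, dormant=dormant)
    d_pp, _ = proplatelet_rhs_and_efflux(st, params)
    st.c_pp = d_pp * params.t_pp  # influx * t_pp at steady state
    return freqs, st


def calibrate_ploidy_baseline(target_freqs: dict, params: MKCParams,
                              adjust_q64: bool = False):
    """Fit free baseline transition parameters to a target ploidy table.

    Free parameters (log-scale): the tied transition probabilities ``p1`` and
    ``p2`` of ploidies 8/16/32, the reactivation times of ploidy 8 and of the
    tied pair 16/32, and the proplatelet transit time.  Returns
    ``(fitted_params, info)`` where ``info`` reports the achieved frequencies
    and the maximal absolute deviation.
    """
    if not target_freqs:
        raise ValueError("no target frequencies given")
    tot = sum(target_freqs.values())
    if tot > 1.0 + 1e-9:
        raise ValueError("target frequencies exceed 1")
    keys = sorted(target_freqs)
    targets = np.array([target_freqs[k] for k in keys])

    def logit(p):
        return np.log(p / (1.0 - p))

    x0 = np.array([logit(params.p1_base), logit(params.p2_base),
                   np.log(params.t_rev_dorm[8]), np.log(params.t_rev_dorm[16]),
                   np.log(params.t_pp)])

    def build(x) -> MKCParams:
        p1 = float(1.0 / (1.0 + np.exp(-x[0])))
        p2 = float(1.0 / (1.0 + np.exp(-x[1])))
        # keep the suppression-regulation plateaus strictly around the fitted
        # baseline so any p1 in (0,1) yields a valid block
        z1 = params.z_p1
        z_p1 = ZParams(min(z1.y_min, 0.5 * p1), p1,
                       max(z1.y_max, 0.5 + 0.5 * p1), z1.b, z1.lim_sig,
                       "decreasing")
        return MKCParams(
            t_endo=params.t_endo, t_dorm_mkc=params.t_dorm_mkc,
            t_pp=float(np.exp(x[4])), p1_base=p1, p2_base=p2,
            q64_nor=params.q64_nor,
            t_rev_dorm={8: float(np.exp(x[2])), 16: float(np.exp(x[3])),
                        32: float(np.exp(x[3]))},
            npt_pcu=params.npt_pcu, d_osteo_loss=params.d_osteo_loss,
            z_p1=z_p1, z_q64=params.z_q64, z_krev=params.z_krev)

    def residuals(x):
        try:
            freqs, _ = steady_ploidy_distribution(build(x))
        except (RuntimeError, ValueError):
            return np.full(len(keys), 1.0)
        return np.array([freqs[k] for k in keys]) - targets

    # deterministic multi-start: the supplied parameters plus coarse probes of
    # the dormancy-residence axis, which carries the only strong nonlinearity
    starts = [x0]
    for trev16 in (10.0, 100.0, 400.0):
        alt = x0.copy()
        alt[3] = np.log(trev16)
        starts.append(alt)
    best = None
    for s in starts:
        sol = least_squares(residuals, s, method="trf", xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-16:
            break
    sol = best
    fitted = build(sol.x)
    freqs, _ = steady_ploidy_distribution(fitted)
    achieved = {k: freqs[k] for k in keys}
    info = {
        "achieved": achieved,
        "max_abs_deviation": max(abs(achieved[k] - target_freqs[k])
                                 for k in keys),
        "converged": bool(sol.success),
    }
    return fitted, info
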