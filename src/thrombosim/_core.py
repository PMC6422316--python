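"""Flat, compiled right-hand side of the full thrombopoiesis ODE system.

The public modules (:mod:`osteo`, :mod:`stem_cm`, :mod:`mkc`,
:mod:`platelets`, :mod:`tpo`, :mod:`chemo`) define the model piecewise with
readable dataclasses.  For integration and fitting the whole system is
evaluated thousands of times, so this module provides a single flat
``rhs(t, y, theta, norms, n_cm, n_early, n_age)`` over a packed parameter
vector, compiled with numba when available.  A consistency test guarantees
that the flat core equals the composition of the module functions.

State layout (normalized to steady state; ``norms`` carries the absolute
scales, 1.0 for states that vanish at baseline)::

    0 OC, 1 OB, 2 OSTEO_LOSS, 3 S_ACT, 4 S_DORM,
    5 .. 5+n_cm-1                CM stages,
    MA0 .. MA0+6                 active MKC (ploidies 2..128),
    MD0 .. MD0+2                 dormant MKC (ploidies 8, 16, 32),
    PP,
    PLC0..+n-1, PLS0..+n-1, PLL0..+n-1   platelets (circ, spleen, labeled),
    TE, TP0, TP1, TP2, DEL, DEL32        TPO,
    CY, DX1, DX2, ET1, ET2, PR0, PR1     drug PK.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

# ---------------------------------------------------------------------------
# fixed state indices (head of the vector)
# ---------------------------------------------------------------------------
I_OC, I_OB, I_OL, I_SA, I_SD, CM0 = 0, 1, 2, 3, 4, 5

# ---------------------------------------------------------------------------
# theta indices
# ---------------------------------------------------------------------------
T_CYCLE, P_DELTA, B_S_ACT, K_DORM_NOR, K_ACT, D_OSTEO_LOSS, T_SUB_CM = range(7)
Z_AMP = 7            # 6 slots: y_min, y_nor, y_max, b, lim_sig, sign
A1, B1, A2, B2, D_PSI = 13, 14, 15, 16, 17
T_ENDO, T_DORM, T_PP, P2_TIED = 18, 19, 20, 21
Z_P1 = 22            # 6 slots
Z_Q64 = 28           # 6 slots
Z_KREV = 34          # 6 slots
TREV8, TREV16, TREV32, NPT = 40, 41, 42, 43
T_PL, K_CIRC, K_S, H_S, P_ELIM, KBASE_SC, GAMMA_SC = 44, 45, 46, 47, 48, 49, 50
T_TPO, KM_TPO, W_PLC, W_PP, W_MKC_BASE, ALPHA = 51, 52, 53, 54, 55, 56
Q_TPO, FR_DIR, T_DEL, T_DEL32 = 57, 58, 59, 60
K_CY, DXK10, DXK12, DXK21, ETK10, ETK12, ETK21, PRKA, PRKE = range(61, 70)
PD0 = 70             # 12 slots: (S, CM, MKC_imm, MKC) x (cyclo, doxo, etop)
C_PD_OSTEO = 82
CTTB_NOR = 83
INF_CY, INF_DX, INF_ET = 84, 85, 86
N_THETA = 87

_CAP_FLOOR = 1e-6
_X_FLOOR = 1e-12


@njit(cache=True)
def _z(x, ymin, ynor, ymax, b, lim, sign):
    """Sigmoidal Z-kernel (see :mod:`thrombosim.regulation`)."""
    if x < _X_FLOOR:
        x = _X_FLOOR
    if sign < 0.0:
        x = 1.0 / x
    t = math.exp(lim * math.tanh(b * math.log(x) / lim))
    base = (ymax - ynor) / (ymax - ymin)
    return ymax - (ymax - ymin) * base ** t


@njit(cache=True)
def rhs(t, y, theta, norms, n_cm, n_early, n_age):
    ny = y.shape[0]
    ya = y * norms  # absolute pools
    d = np.zeros(ny)

    # -- layout offsets -----------------------------------------------------
    MA0 = CM0 + n_cm
    MD0 = MA0 + 7
    I_PP = MD0 + 3
    PLC0 = I_PP + 1
    PLS0 = PLC0 + n_age
    PLL0 = PLS0 + n_age
    I_TE = PLL0 + n_age
    I_TP0, I_TP1, I_TP2 = I_TE + 1, I_TE + 2, I_TE + 3
    I_DEL, I_DEL32 = I_TE + 4, I_TE + 5
    I_CY = I_TE + 6
    I_DX1, I_DX2, I_ET1, I_ET2, I_PR0, I_PR1 = (I_CY + 1, I_CY + 2, I_CY + 3,
                                                I_CY + 4, I_CY + 5, I_CY + 6)

    # -- drug PK ------------------------------------------------------------
    cy = ya[I_CY]
    dx = ya[I_DX1]
    et = ya[I_ET1]
    d[I_CY] = -theta[K_CY] * cy + theta[INF_CY]
    d[I_DX1] = (-(theta[DXK10] + theta[DXK12]) * dx
                + theta[DXK21] * ya[I_DX2] + theta[INF_DX])
    d[I_DX2] = theta[DXK12] * dx - theta[DXK21] * ya[I_DX2]
    d[I_ET1] = (-(theta[ETK10] + theta[ETK12]) * et
                + theta[ETK21] * ya[I_ET2] + theta[INF_ET])
    d[I_ET2] = theta[ETK12] * et - theta[ETK21] * ya[I_ET2]
    d[I_PR0] = -theta[PRKA] * ya[I_PR0]
    d[I_PR1] = theta[PRKA] * ya[I_PR0] - theta[PRKE] * ya[I_PR1]

    # toxicity functions (procarbazine effect fixed to zero)
    psi_s = theta[PD0 + 0] * cy + theta[PD0 + 1] * dx + theta[PD0 + 2] * et
    psi_cm = theta[PD0 + 3] * cy + theta[PD0 + 4] * dx + theta[PD0 + 5] * et
    psi_imm = theta[PD0 + 6] * cy + theta[PD0 + 7] * dx + theta[PD0 + 8] * et
    psi_mat = theta[PD0 + 9] * cy + theta[PD0 + 10] * dx + theta[PD0 + 11] * et
    psi_ost = theta[C_PD_OSTEO] * psi_cm

    # -- osteoblasts / osteoclasts -------------------------------------------
    oc = ya[I_OC]
    ob = ya[I_OB]
    loss = ya[I_OL]
    if oc < 0.0:
        oc = 0.0
    ob_guard = ob if ob > 1e-9 else 1e-9
    d[I_OC] = (theta[A1] * math.sqrt(oc) / math.sqrt(ob_guard)
               - theta[B1] * oc - loss * oc)
    d[I_OB] = theta[A2] * oc - theta[B2] * ob - loss * ob
    d[I_OL] = psi_ost - theta[D_PSI] * loss
    cap_dor = y[I_OB]  # relative osteoblast count = capacity
    if cap_dor < 0.0:
        cap_dor = 0.0
    c_ob_rel = cap_dor
    death_dorm = theta[D_OSTEO_LOSS] * loss * c_ob_rel

    # -- delayed TPO signals -------------------------------------------------
    tpo_del = y[I_DEL]
    tpo_del32 = y[I_DEL32]

    # -- MKC regulated quantities --------------------------------------------
    p1 = _z(tpo_del, theta[Z_P1], theta[Z_P1 + 1], theta[Z_P1 + 2],
            theta[Z_P1 + 3], theta[Z_P1 + 4], theta[Z_P1 + 5])
    q64 = _z(tpo_del, theta[Z_Q64], theta[Z_Q64 + 1], theta[Z_Q64 + 2],
             theta[Z_Q64 + 3], theta[Z_Q64 + 4], theta[Z_Q64 + 5])
    krev_mult = _z(tpo_del, theta[Z_KREV], theta[Z_KREV + 1],
                   theta[Z_KREV + 2], theta[Z_KREV + 3], theta[Z_KREV + 4],
                   theta[Z_KREV + 5])
    krev_mult32 = _z(tpo_del32, theta[Z_KREV], theta[Z_KREV + 1],
                     theta[Z_KREV + 2], theta[Z_KREV + 3], theta[Z_KREV + 4],
                     theta[Z_KREV + 5])
    p2 = theta[P2_TIED]
    te = theta[T_ENDO]
    tp = theta[T_PP]
    cap_g = cap_dor if cap_dor > _CAP_FLOOR else _CAP_FLOOR
    kdorm = (1.0 - p1) * (1.0 - p2) / theta[T_DORM] * cap_dor

    # -- stem cells -----------------------------------------------------------
    # relative MKC mass (feedback mediator)
    mkc_sum = 0.0
    for i in range(7):
        mkc_sum += ya[MA0 + i]
    for i in range(3):
        mkc_sum += ya[MD0 + i]
    cttb = mkc_sum / theta[CTTB_NOR]
    s_rel = y[I_SA]
    if s_rel < _X_FLOOR:
        s_rel = _X_FLOOR
    sb = s_rel ** theta[B_S_ACT]
    p_self = theta[P_DELTA] * math.tanh(1.0 / sb - sb) + 0.5
    k_dorm_s = theta[K_DORM_NOR] * cttb
    dorm_flux = cap_dor * k_dorm_s * ya[I_SA]
    d[I_SA] = ((2.0 * p_self - 1.0) * ya[I_SA] / theta[T_CYCLE]
               + theta[K_ACT] * ya[I_SD] - dorm_flux - psi_s * ya[I_SA])
    d[I_SD] = dorm_flux - (theta[K_ACT] + death_dorm) * ya[I_SD]

    # -- CM chain --------------------------------------------------------------
    amp_early = _z(tpo_del, theta[Z_AMP], theta[Z_AMP + 1], theta[Z_AMP + 2],
                   theta[Z_AMP + 3], theta[Z_AMP + 4], theta[Z_AMP + 5])
    amp_late = theta[Z_AMP + 1]  # y_nor: late stages are TPO-independent
    influx = 2.0 * (1.0 - p_self) * ya[I_SA] / theta[T_CYCLE]
    for i in range(n_cm):
        amp = amp_early if i < n_early else amp_late
        a_half = math.sqrt(amp)
        out_rate = ya[CM0 + i] / theta[T_SUB_CM]
        d[CM0 + i] = a_half * influx - out_rate - psi_cm * ya[CM0 + i]
        influx = a_half * out_rate
    cm_efflux = influx

    # -- MKC fate algebra -------------------------------------------------------
    d[MA0 + 0] = cm_efflux - ya[MA0] / te - psi_imm * ya[MA0]
    d[MA0 + 1] = ya[MA0] / te - ya[MA0 + 1] / te - psi_imm * ya[MA0 + 1]
    inflow = ya[MA0 + 1] / te
    for j in range(3):  # ploidies 8, 16, 32
        i = MA0 + 2 + j
        trev = theta[TREV8 + j]
        mult = krev_mult32 if j == 2 else krev_mult
        krev = mult / (trev * cap_g)
        out = p2 * (1.0 - p1) / te + p1 / tp + kdorm + psi_mat
        d[i] = inflow + krev * ya[MD0 + j] - out * ya[i]
        d[MD0 + j] = kdorm * ya[i] - (krev + death_dorm) * ya[MD0 + j]
        inflow = p2 * (1.0 - p1) / te * ya[i]
    p64_1 = 1.0 - q64
    d[MA0 + 5] = inflow - (q64 / te + p64_1 / tp + psi_mat) * ya[MA0 + 5]
    d[MA0 + 6] = q64 / te * ya[MA0 + 5] - (1.0 / tp + psi_mat) * ya[MA0 + 6]

    # -- proplatelets -----------------------------------------------------------
    pp_in = (4.0 * p1 * ya[MA0 + 2] + 8.0 * p1 * ya[MA0 + 3]
             + 16.0 * p1 * ya[MA0 + 4] + 32.0 * p64_1 * ya[MA0 + 5]
             + 64.0 * ya[MA0 + 6]) / tp
    d[I_PP] = pp_in - ya[I_PP] / tp
    pp_out = theta[NPT] * ya[I_PP] / tp

    # -- platelets ---------------------------------------------------------------
    aging = n_age / theta[T_PL]
    circ = 0.0
    for i in range(n_age):
        circ += ya[PLC0 + i] + ya[PLL0 + i]
    if circ > 0.0:
        cp = circ ** theta[P_ELIM]
        elim = theta[K_S] * cp / (cp + theta[H_S] ** theta[P_ELIM]) / circ
    else:
        elim = 0.0
    for i in range(n_age):
        ksc = theta[KBASE_SC] * ((i + 1.0) / n_age) ** theta[GAMMA_SC]
        if i == 0:
            in_c = theta[K_CIRC] * pp_out
            in_s = (1.0 - theta[K_CIRC]) * pp_out
            in_l = 0.0
        else:
            in_c = ya[PLC0 + i - 1] * aging
            in_s = ya[PLS0 + i - 1] * aging
            in_l = ya[PLL0 + i - 1] * aging
        d[PLC0 + i] = (in_c - ya[PLC0 + i] * aging + ksc * ya[PLS0 + i]
                       - elim * ya[PLC0 + i])
        d[PLS0 + i] = in_s - ya[PLS0 + i] * aging - ksc * ya[PLS0 + i]
        d[PLL0 + i] = in_l - ya[PLL0 + i] * aging - elim * ya[PLL0 + i]

    # -- TPO -----------------------------------------------------------------------
    q = theta[Q_TPO]
    fr = theta[FR_DIR]
    d[I_TP0] = -q * ya[I_TP0]
    d[I_TP1] = q * (1.0 - fr) * ya[I_TP0] - q * ya[I_TP1]
    inj = q * fr * ya[I_TP0] + q * ya[I_TP1]
    c_rel = ya[I_TE] + ya[I_TP2]
    plat_pool = 0.0
    for i in range(n_age):
        plat_pool += ya[PLC0 + i] + ya[PLS0 + i] + ya[PLL0 + i]
    mkc_w = 0.0
    for k in range(7):
        mkc_w += (2.0 ** (k + 1)) * ya[MA0 + k]
    for j in range(3):
        mkc_w += (2.0 ** (3 + j)) * ya[MD0 + j]
    w = (theta[W_PLC] * plat_pool + theta[W_MKC_BASE] * mkc_w
         + theta[W_PP] * ya[I_PP])
    degr = (c_rel / theta[T_TPO]
            + w * c_rel / (1.0 + theta[KM_TPO] * c_rel))
    split = ya[I_TE] + ya[I_TP2]
    fr_endo = ya[I_TE] / split if split > 1e-12 else 1.0
    d[I_TE] = theta[ALPHA] - fr_endo * degr
    d[I_TP2] = inj - (1.0 - fr_endo) * degr
    d[I_DEL] = (c_rel - ya[I_DEL]) / theta[T_DEL]
    d[I_DEL32] = (c_rel - ya[I_DEL32]) / theta[T_DEL32]

    return d / norms


def state_layout(n_cm: int, n_age: int) -> dict:
    """Named state indices for a given configuration."""
    MA0 = CM0 + n_cm
    MD0 = MA0 + 7
    I_PP_ = MD0 + 3
    PLC0 = I_PP_ + 1
    PLS0 = PLC0 + n_age
    PLL0 = PLS0 + n_age
    I_TE_ = PLL0 + n_age
    lay = {
        "OC": I_OC, "OB": I_OB, "OL": I_OL, "SA": I_SA, "SD": I_SD,
        "CM": slice(CM0, CM0 + n_cm),
        "MA": slice(MA0, MA0 + 7), "MD": slice(MD0, MD0 + 3), "PP": I_PP_,
        "PLC": slice(PLC0, PLC0 + n_age), "PLS": slice(PLS0, PLS0 + n_age),
        "PLL": slice(PLL0, PLL0 + n_age),
        "TE": I_TE_, "TP0": I_TE_ + 1, "TP1": I_TE_ + 2, "TP2": I_TE_ + 3,
        "DEL": I_TE_ + 4, "DEL32": I_TE_ + 5,
        "CY": I_TE_ + 6, "DX1": I_TE_ + 7, "DX2": I_TE_ + 8,
        "ET1": I_TE_ + 9, "ET2": I_TE_ + 10, "PR0": I_TE_ + 11,
        "PR1": I_TE_ + 12,
    }
    lay["n_states"] = I_TE_ + 13
    return lay
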