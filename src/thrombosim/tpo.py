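"""Endogenous and pegylated thrombopoietin (TPO).

Endogenous TPO is produced at a constant rate and removed by an unspecific
first-order pathway plus a receptor-mediated, Michaelis-Menten-saturated
consumption by platelets (circulating and spleen), megakaryocytes and
proplatelets.  The constant production is not a free parameter: it is fixed
by the steady-state condition at relative TPO = 1.

Pegylated TPO injected subcutaneously passes two absorption compartments
(with a fraction entering the circulation directly) and then shares the
degradation law of endogenous TPO; degradation is apportioned between the
endogenous and pegylated fractions by their relative abundance.  Two
first-order lag states provide the delayed TPO signal that drives the
Z-regulations of CM and MKC (a longer lag for reactivation of dormant
ploidy-32 megakaryocytes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .registry import ModelParameters

__all__ = ["TPOParams", "TPOState", "peg_absorption_rhs", "derive_alpha",
           "tpo_rhs"]

# guard for the endogenous/pegylated degradation split when both vanish
_SPLIT_EPS = 1e-12


@dataclass
class TPOParams:
    t_tpo: float = 40.0        # h, unspecific degradation time
    k_m_tpo: float = 1.0       # Michaelis constant (relative TPO units)
    w_plc: float = 0.0         # specific elimination per platelet unit
    w_pp: float = 0.0          # per proplatelet unit
    w_mkc: np.ndarray = field(default_factory=lambda: np.zeros(7))
    alpha: float = 0.0         # endogenous production (derived)
    q_tpo: float = 0.045       # 1/h, absorption transfer rate
    fr_tpo_dir: float = 0.05   # direct-entry fraction
    t_del: float = 36.0        # h, main action delay
    t_del_p32: float = 120.0   # h, delay for dormant ploidy-32 reactivation
    c_tpo_nor: float = 1.0     # dose normalization of injections
    r_tpo_nor_0: float = 100.0  # pg/mL observable scale

    def __post_init__(self):
        if not (0.0 <= self.fr_tpo_dir <= 1.0):
            raise ValueError("fr_tpo_dir must lie in [0, 1]")

    @classmethod
    def from_registry(cls, params: ModelParameters) -> "TPOParams":
        return cls(t_tpo=params["t_tpo"], k_m_tpo=params["k_m_tpo"],
                   q_tpo=params["q_tpo"], fr_tpo_dir=params["fr_tpo_dir"],
                   t_del=params["t_del"], t_del_p32=params["t_del_p32"],
                   r_tpo_nor_0=params["r_tpo_nor_0"])


@dataclass
class TPOState:
    endo_rel: float = 1.0
    peg0: float = 0.0
    peg1: float = 0.0
    peg2_rel: float = 0.0
    del_main: float = 1.0
    del_p32: float = 1.0

    @property
    def total_rel(self) -> float:
        return self.endo_rel + self.peg2_rel


def peg_absorption_rhs(state: TPOState, params: TPOParams):
    """Absorption-compartment derivatives and the circulation influx ``Inj``.

    A fraction ``fr_tpo_dir`` of the injected depot enters circulation
    directly; the remainder transits one lymphatic compartment.  The total
    injected mass is recovered in the integral of ``Inj``.
    """
    q, fr = params.q_tpo, params.fr_tpo_dir
    d_peg0 = -q * (1.0 - fr) * state.peg0 - q * fr * state.peg0
    d_peg1 = q * (1.0 - fr) * state.peg0 - q * state.peg1
    inj = q * fr * state.peg0 + q * state.peg1
    return d_peg0, d_peg1, inj


def derive_alpha(params: TPOParams, plc_nor: float, pls_nor: float,
                 mkc_nor: np.ndarray, pp_nor: float) -> float:
    """Endogenous production rate fixed by the steady state at TPO = 1.

    ``alpha = 1/T_TPO + W_nor / (1 + k_m)`` with ``W_nor`` the receptor-
    weighted sum over the consuming pools at their normal values.
    """
    w_nor = (params.w_plc * (plc_nor + pls_nor)
             + float(np.dot(params.w_mkc, mkc_nor)) + params.w_pp * pp_nor)
    return 1.0 / params.t_tpo + w_nor / (1.0 + params.k_m_tpo)


def tpo_rhs(state: TPOState, *, plc_total: float, pls_total: float,
            mkc_pools: np.ndarray, pp_pool: float, params: TPOParams):
    """Derivatives of the six TPO states.

    ``mkc_pools`` holds active-plus-dormant megakaryocyte counts per ploidy
    class (dormant cells consume TPO like active ones).  Degradation acts on
    the total relative TPO and is split between the endogenous and pegylated
    fractions proportionally to their abundance.
    """
    d_peg0, d_peg1, inj = peg_absorption_rhs(state, params)
    c_rel = state.total_rel
    w = (params.w_plc * (plc_total + pls_total)
         + float(np.dot(params.w_mkc, mkc_pools)) + params.w_pp * pp_pool)
    degr = c_rel / params.t_tpo + w * c_rel / (1.0 + params.k_m_tpo * c_rel)
    split = state.endo_rel + state.peg2_rel
    if split > _SPLIT_EPS:
        fr_endo = state.endo_rel / split
    else:
        fr_endo = 1.0
    d_endo = params.alpha - fr_endo * degr
    d_peg2 = inj / params.c_tpo_nor - (1.0 - fr_endo) * degr
    d_del = (c_rel - state.del_main) / params.t_del
    d_del32 = (c_rel - state.del_p32) / params.t_del_p32
    return d_endo, d_peg0, d_peg1, d_peg2, d_del, d_del32
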