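"""Stem cells and megakaryocyte progenitors (CM).

The stem compartment has an actively cycling pool and a dormant pool.
Megakaryocyte mass feeds back on quiescence: the active-to-dormant transition
rate scales with the relative total megakaryocyte count (``cttb_rel``), and
entry into dormancy is limited by the osteoblast-set bone-marrow capacity.
Self-renewal of active stem cells is regulated by their own relative count.

Committed progenitors (CM) form a chain of fixed-cycle-time sub-compartments;
only the early stages amplify TPO-dependently.  Per-stage amplification A is
split symmetrically: sqrt(A) applied at influx and sqrt(A) at efflux, which
preserves total amplification and the steady-state fluxes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .regulation import ZParams, z_function
from .registry import RK_DORM_ACT_RANGE

__all__ = ["StemParams", "CMParams", "self_renewal_p", "derive_k_act",
           "cttb_rel", "stem_rhs", "cm_rhs", "cm_steady_state"]


@dataclass
class StemParams:
    t_cycle: float = 24.0       # h
    p_delta: float = 0.1        # self-renewal amplitude
    b_s_act: float = 0.5        # feedback steepness (IIV)
    k_dorm_nor: float = 0.05    # 1/h
    rk_dorm_act: float = 100.0  # dormant:active steady-state ratio
    d_osteo_loss: float = 0.5   # dormant death per unit osteoblast loss (IIV)

    def __post_init__(self):
        if not (0.0 < self.p_delta < 0.5):
            raise ValueError("p_delta must lie in (0, 0.5)")
        if self.t_cycle <= 0:
            raise ValueError("t_cycle must be positive")

    @property
    def k_act(self) -> float:
        return derive_k_act(self.k_dorm_nor, self.rk_dorm_act)


@dataclass
class CMParams:
    n_cm: int = 7
    n_cm_early: int = 4
    t_sub: float = 15.0  # h per stage
    amp_regulation: ZParams = field(
        default_factory=lambda: ZParams(1.05, 2.0, 2.8))

    def __post_init__(self):
        if self.n_cm_early > self.n_cm or self.n_cm < 1:
            raise ValueError("need 1 <= n_cm_early <= n_cm")
        if self.t_sub <= 0:
            raise ValueError("t_sub must be positive")

    @property
    def n_cm_late(self) -> int:
        return self.n_cm - self.n_cm_early

    def amplification(self, tpo_delayed_rel: float) -> np.ndarray:
        """Per-stage amplification; TPO-regulated for early stages only."""
        a = np.full(self.n_cm, self.amp_regulation.y_nor)
        a[: self.n_cm_early] = z_function(tpo_delayed_rel, self.amp_regulation)
        return a


def self_renewal_p(c_s_rel: float, b: float, p_delta: float = 0.1) -> float:
    """Self-renewal probability ``p = p_delta*tanh(c^-b - c^b) + 0.5``.

    Strictly decreasing in the relative active stem count ``c_s_rel``; equals
    0.5 at baseline and stays within ``(0.5 - p_delta, 0.5 + p_delta)``.
    """
    if c_s_rel <= 0:
        raise ValueError("relative stem count must be positive")
    cb = c_s_rel ** b
    return p_delta * math.tanh(1.0 / cb - cb) + 0.5


def derive_k_act(k_dorm_nor: float, rk_dorm_act: float) -> float:
    """Dormancy-exit rate from the steady-state ratio of dormant to active cells."""
    lo, hi = RK_DORM_ACT_RANGE
    if not (lo <= rk_dorm_act <= hi):
        import warnings
        warnings.warn(
            f"rk_dorm_act={rk_dorm_act} outside the admissible range [{lo}, {hi}]",
            stacklevel=2)
    return k_dorm_nor / rk_dorm_act


def cttb_rel(mkc_active: np.ndarray, mkc_dormant: np.ndarray,
             norm_total: float) -> float:
    """Relative total megakaryocyte count mediating the stem-cell feedback.

    Sum of active MKC (all ploidies) and dormant MKC (ploidies 8-32) divided
    by the same sum at steady state; equals 1 at baseline.
    """
    if norm_total <= 0:
        raise ValueError("norm_total must be positive")
    return (float(np.sum(mkc_active)) + float(np.sum(mkc_dormant))) / norm_total


def stem_rhs(c_s_act: float, c_s_dorm: float, *, cap_dor: float, cttb: float,
             psi_s: float, osteo_loss: float, c_ob_rel: float,
             params: StemParams, c_s_act_nor: float = 1.0):
    """Derivatives ``(dC_S_act/dt, dC_S_dorm/dt)`` of the stem sub-system."""
    p = self_renewal_p(max(c_s_act, 1e-12) / c_s_act_nor, params.b_s_act,
                       params.p_delta)
    k_dorm = params.k_dorm_nor * cttb
    dormancy_flux = cap_dor * k_dorm * c_s_act
    d_act = ((2.0 * p - 1.0) * c_s_act / params.t_cycle
             + params.k_act * c_s_dorm - dormancy_flux - psi_s * c_s_act)
    d_dorm = (dormancy_flux
              - (params.k_act
                 + params.d_osteo_loss * osteo_loss * c_ob_rel) * c_s_dorm)
    return d_act, d_dorm


def stem_efflux(c_s_act: float, params: StemParams,
                c_s_act_nor: float = 1.0) -> float:
    """Differentiation flux into CM: ``2(1-p) * C_S_act / T_cycle``."""
    p = self_renewal_p(max(c_s_act, 1e-12) / c_s_act_nor, params.b_s_act,
                       params.p_delta)
    return 2.0 * (1.0 - p) * c_s_act / params.t_cycle


def cm_rhs(c_cm: np.ndarray, *, stem_influx: float, tpo_delayed_rel: float,
           psi_cm: float, params: CMParams):
    """Derivatives of the CM chain and its efflux into the MKC compartment.

    Returns ``(dC_CM/dt, efflux)``.  Stage ``i`` receives
    ``sqrt(A_i) * influx_i`` and passes ``sqrt(A_i) * C_i / t_sub`` onward, so
    a full stage multiplies throughput by ``A_i``.
    """
    amp = params.amplification(tpo_delayed_rel)
    a_half = np.sqrt(amp)
    d = np.empty_like(c_cm)
    influx = stem_influx
    for i in range(params.n_cm):
        out_rate = c_cm[i] / params.t_sub
        d[i] = a_half[i] * influx - out_rate - psi_cm * c_cm[i]
        influx = a_half[i] * out_rate
    return d, influx


def cm_steady_state(stem_influx: float, params: CMParams,
                    tpo_delayed_rel: float = 1.0):
    """Baseline stage contents and efflux of the CM chain (no toxicity)."""
    amp = params.amplification(tpo_delayed_rel)
    a_half = np.sqrt(amp)
    c = np.empty(params.n_cm)
    influx = stem_influx
    for i in range(params.n_cm):
        c[i] = params.t_sub * a_half[i] * influx
        influx = amp[i] * influx
    return c, influx
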