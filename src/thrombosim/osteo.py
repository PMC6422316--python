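"""Osteoblast/osteoclast dynamics and bone-marrow capacity.

A power-law interaction model of bone remodelling (osteoclasts stimulated by
osteoblast-dependent autocrine/paracrine signalling, osteoblasts produced by
osteoclast activity) provides the count of osteoblasts, which in turn sets the
bone-marrow capacity for dormant stem cells and dormant megakaryocytes.
Chemotherapy acts on both cell types through a first-order delayed loss state
``osteo_loss`` driven by the CM-proportional toxicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["OsteoParams", "OsteoState", "osteo_rhs", "osteo_steady_state",
           "capacity"]

# floor on the osteoblast count inside the power-law term; avoids division
# blowup during extreme depletion without altering physiological dynamics
OB_FLOOR = 1e-9


@dataclass
class OsteoParams:
    alpha1: float  # osteoclast production rate, 1/h
    beta1: float   # osteoclast removal rate, 1/h
    alpha2: float  # osteoblast production rate, 1/h
    beta2: float   # osteoblast removal rate, 1/h
    d_psi: float   # decay rate of the delayed chemo effect, 1/h
    c_ob_nor: float = 1.0  # normal osteoblast count

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2,
               self.d_psi, self.c_ob_nor) <= 0:
            raise ValueError("OsteoParams requires strictly positive rates")


@dataclass
class OsteoState:
    c_oc: float
    c_ob: float
    osteo_loss: float = 0.0


def osteo_rhs(state: OsteoState, psi_osteo: float, params: OsteoParams):
    """Time derivatives ``(dC_OC/dt, dC_OB/dt, dOsteo_loss/dt)``.

    Osteoclasts follow ``alpha1 * C_OC^0.5 * C_OB^-0.5`` production with
    first-order removal; osteoblasts are produced proportionally to
    osteoclasts.  The accumulated loss rate ``osteo_loss`` removes both cell
    types and relaxes with rate ``d_psi``.
    """
    oc = max(state.c_oc, 0.0)
    ob = max(state.c_ob, OB_FLOOR)
    loss = state.osteo_loss
    d_oc = (params.alpha1 * math.sqrt(oc) / math.sqrt(ob)
            - params.beta1 * oc - loss * oc)
    d_ob = params.alpha2 * oc - params.beta2 * state.c_ob - loss * state.c_ob
    d_loss = psi_osteo - params.d_psi * loss
    return d_oc, d_ob, d_loss


def osteo_steady_state(params: OsteoParams):
    """Toxicity-free fixed point ``(oc_ss, ob_ss)``.

    From the osteoblast balance ``OB = (alpha2/beta2) OC`` and the osteoclast
    balance ``OC * OB = (alpha1/beta1)^2``.
    """
    oc = (params.alpha1 / params.beta1) * math.sqrt(params.beta2 / params.alpha2)
    ob = (params.alpha2 / params.beta2) * oc
    return oc, ob


def capacity(c_ob: float, c_ob_nor: float) -> float:
    """Bone-marrow capacity for dormant cells: the relative osteoblast count."""
    if c_ob_nor <= 0:
        raise ValueError("c_ob_nor must be positive")
    if c_ob < 0:
        raise ValueError("c_ob must be nonnegative")
    return c_ob / c_ob_nor
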