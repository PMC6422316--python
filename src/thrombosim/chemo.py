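"""Chemotherapy pharmacokinetics and compartment toxicity functions.

Four haematotoxic drugs are modelled: cyclophosphamide (1-compartment i.v.
bolus), doxorubicin and etoposide (2-compartment i.v.), and procarbazine
(oral, first-order absorption).  Central-compartment concentrations are
normalized per standard dose (750 / 50 / 100 / 100 mg/m^2), so the
pharmacodynamic coefficients ``pd`` are interpretable as per-standard-dose
toxicities; the absolute PK scale would otherwise be confounded with ``pd``.

The toxicity of compartment Y is the dose-normalized linear combination
``Psi_Y = sum_X pd_{X,Y} * C_{X,1}`` with no drug-drug interaction terms; the
osteoblast/osteoclast toxicity is proportional to the CM toxicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.linalg import expm

from .registry import ModelParameters

__all__ = ["Drug", "DrugDose", "PKModel", "ToxicityMap", "simulate_pk",
           "toxicity", "pk_models_from_registry", "toxicity_map_from_registry",
           "TARGETS"]


class Drug(str, Enum):
    CYCLOPHOSPHAMIDE = "cyclophosphamide"
    DOXORUBICIN = "doxorubicin"
    ETOPOSIDE = "etoposide"
    PROCARBAZINE = "procarbazine"


#: toxicity target compartments: stem, CM, immature MKC (ploidies 2-4),
#: mature MKC (ploidies 8-128), osteoblasts/osteoclasts
TARGETS = ("S", "CM", "MKC_imm", "MKC", "OST")


@dataclass(frozen=True)
class DrugDose:
    drug: Drug
    amount: float        # mg/m^2
    time: float          # h
    duration: float = 0.0  # infusion duration, h; 0 = bolus

    def __post_init__(self):
        if self.amount < 0 or self.duration < 0:
            raise ValueError("dose amount and duration must be nonnegative")


@dataclass
class PKModel:
    """Linear compartmental PK model.

    ``rate_matrix`` is the system matrix A of ``dc/dt = A c + input`` over all
    compartments; the drug enters ``input_compartment`` (0 = central for i.v.,
    the absorption depot for oral drugs) and the *observed* concentration is
    compartment ``central`` scaled by ``volume_scale``.  Doses are normalized
    by ``std_dose`` before entering.
    """

    rate_matrix: np.ndarray
    std_dose: float
    input_compartment: int = 0
    central: int = 0
    volume_scale: float = 1.0

    @property
    def n_compartments(self) -> int:
        return self.rate_matrix.shape[0]


def pk_models_from_registry(params: ModelParameters) -> dict[Drug, PKModel]:
    """Build the four structural PK models from registry rate constants."""
    k_cy = params["pk_cyclo_k"]
    d10, d12, d21 = (params["pk_doxo_k10"], params["pk_doxo_k12"],
                     params["pk_doxo_k21"])
    e10, e12, e21 = (params["pk_etop_k10"], params["pk_etop_k12"],
                     params["pk_etop_k21"])
    ka, ke = params["pk_procar_ka"], params["pk_procar_ke"]
    two_cpt = lambda k10, k12, k21: np.array(
        [[-(k10 + k12), k21], [k12, -k21]])
    return {
        Drug.CYCLOPHOSPHAMIDE: PKModel(np.array([[-k_cy]]),
                                       params["std_dose_cyclo"]),
        Drug.DOXORUBICIN: PKModel(two_cpt(d10, d12, d21),
                                  params["std_dose_doxo"]),
        Drug.ETOPOSIDE: PKModel(two_cpt(e10, e12, e21),
                                params["std_dose_etop"]),
        # oral: depot -> central with first-order absorption
        Drug.PROCARBAZINE: PKModel(np.array([[-ka, 0.0], [ka, -ke]]),
                                   params["std_dose_procar"],
                                   input_compartment=0, central=1),
    }


def _propagate(A: np.ndarray, c0: np.ndarray, u: np.ndarray, dt: float):
    """Advance ``dc/dt = A c + u`` (u constant) by ``dt`` exactly."""
    n = A.shape[0]
    if not np.any(u):
        return expm(A * dt) @ c0
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = A * dt
    aug[:n, n] = u * dt
    phi = expm(aug)
    return phi[:n, :n] @ c0 + phi[:n, n]


def simulate_pk(doses: list[DrugDose], models: dict[Drug, PKModel],
                t_grid: np.ndarray) -> dict[Drug, np.ndarray]:
    """Central-compartment concentration series per drug on ``t_grid``.

    Boluses are instantaneous additions to the input compartment; infusions
    are constant-rate inputs over their duration.  The solution is exact
    (matrix exponential per segment) and superposition over repeated doses
    holds by linearity.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be increasing")
    for dose in doses:
        if dose.drug not in models:
            raise KeyError(f"no PK model configured for drug {dose.drug}")
    out = {}
    for drug, model in models.items():
        ddoses = sorted([d for d in doses if d.drug == drug],
                        key=lambda d: d.time)
        # breakpoints: dose starts and infusion ends
        breaks = sorted({d.time for d in ddoses}
                        | {d.time + d.duration for d in ddoses if d.duration > 0})
        n = model.n_compartments
        conc = np.zeros_like(t_grid)
        c = np.zeros(n)
        t_cur = t_grid[0] if t_grid.size else 0.0
        # walk through segments between breakpoints, sampling the grid
        seg_edges = [t for t in breaks if t > t_cur]
        edges = [t_cur] + seg_edges + [max(t_grid[-1], t_cur) if t_grid.size else t_cur]
        # apply any doses at or before start
        for d in ddoses:
            if d.duration == 0 and d.time <= t_cur:
                c[model.input_compartment] += d.amount / model.std_dose
        gi = 0
        last_edge = edges[-1]
        for a, b in zip(edges[:-1], edges[1:]):
            # boluses exactly at segment start (after the first edge); a grid
            # point at a dose time therefore reports the post-dose state
            if a != edges[0]:
                for d in ddoses:
                    if d.duration == 0 and d.time == a:
                        c[model.input_compartment] += d.amount / model.std_dose
            u = np.zeros(n)
            for d in ddoses:
                if d.duration > 0 and d.time <= a < d.time + d.duration:
                    u[model.input_compartment] += d.amount / (
                        model.std_dose * d.duration)
            while gi < t_grid.size and a <= t_grid[gi] and (
                    t_grid[gi] < b or b == last_edge):
                cc = _propagate(model.rate_matrix, c, u, t_grid[gi] - a)
                conc[gi] = model.volume_scale * cc[model.central]
                gi += 1
            c = _propagate(model.rate_matrix, c, u, b - a)
        out[drug] = conc
    return out


@dataclass
class ToxicityMap:
    """Pharmacodynamic coefficients pd(drug, target) and the osteoblast link."""

    pd: dict = field(default_factory=dict)  # (Drug, target) -> 1/(conc*h)
    c_pd_osteo: float = 0.0
    tie_groups: dict = field(default_factory=dict)

    def coefficient(self, drug: Drug, target: str) -> float:
        return self.pd.get((drug, target), 0.0)


def toxicity_map_from_registry(params: ModelParameters) -> ToxicityMap:
    pd = {}
    for target, cd_name, et_name in (
            ("S", "pd_cyclo", "pd_scm_etop"),
            ("CM", "pd_cyclo", "pd_scm_etop"),
            ("MKC_imm", "pd_imm_cd", "pd_imm_etop"),
            ("MKC", "pd_mat_cd", "pd_mat_etop")):
        pd[(Drug.CYCLOPHOSPHAMIDE, target)] = params[cd_name]
        pd[(Drug.DOXORUBICIN, target)] = params[cd_name]
        pd[(Drug.ETOPOSIDE, target)] = params[et_name]
        pd[(Drug.PROCARBAZINE, target)] = params["pd_procar"]
    ties = {
        "pd_scm_cd": ["pd_cyclo", "pd_s_doxo", "pd_cm_cyclo", "pd_cm_doxo"],
        "mkc_p1": ["p1_8", "p1_16", "p1_32"],
        "mkc_p2": ["p2_8", "p2_16", "p2_32"],
        "mkc_trev": ["t_rev_dorm_16", "t_rev_dorm_32"],
    }
    return ToxicityMap(pd=pd, c_pd_osteo=params["c_pd_osteo"], tie_groups=ties)


def toxicity(concentrations: dict[Drug, float], tox: ToxicityMap,
             target: str) -> float:
    """Toxicity rate ``Psi_target`` (1/h) for given central concentrations."""
    if target not in TARGETS:
        raise KeyError(f"unknown toxicity target {target!r}")
    for drug, c in concentrations.items():
        if c < 0:
            raise ValueError(f"negative concentration for {drug}")
    if target == "OST":
        return tox.c_pd_osteo * toxicity(concentrations, tox, "CM")
    return sum(tox.coefficient(drug, target) * c
               for drug, c in concentrations.items())
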