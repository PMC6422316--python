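"""Model parameter registry.

Every named parameter of the thrombopoiesis model lives here, with unit,
status, bounds, tie-group and a short provenance note.  Statuses:

``fixed``
    set from biological knowledge and never estimated;
``population``
    estimated once for the whole population;
``iiv``
    estimated per patient (inter-individual variability);
``tied``
    follows the value of its tie-group leader (parsimony constraint);
``derived``
    computed from other parameters / the steady state (never free).

Internally the model works in hours and in cell pools normalized to the
steady state; absolute observable scales enter only through
``r_pl_0_nor`` (platelets, 1e9/L) and ``r_tpo_nor_0`` (TPO, pg/mL).
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import yaml

from .regulation import ZParams

__all__ = ["Parameter", "ModelParameters", "AuditReport", "default_parameters"]

STATUSES = ("fixed", "population", "iiv", "tied", "derived")

# Admissible ranges printed in the main text.
RK_DORM_ACT_RANGE = (20.0, 209.0)
NPT_PCU_RANGE = (125.0, 1000.0)


@dataclass
class Parameter:
    name: str
    value: float
    unit: str = "1"
    status: str = "fixed"
    bounds: tuple | None = None
    tie_group: str | None = None
    note: str = ""

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r} for {self.name}")


@dataclass
class AuditReport:
    n_estimated: int
    n_total: int
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _p(name, value, unit="1", status="fixed", bounds=None, tie=None, note=""):
    return Parameter(name, float(value), unit, status, bounds, tie, note)


def _default_entries() -> list[Parameter]:
    e = []
    # ----- structural counts & times (fixed by biology) -------------------
    e += [
        _p("t_cycle", 24.0, "h", note="active stem-cell cycle time"),
        _p("p_delta", 0.1, "1", note="self-renewal amplitude; p in (0.4, 0.6)"),
        _p("n_cm", 7, "1", note="CM sub-compartments"),
        _p("n_cm_early", 4, "1", note="TPO-dependent early CM sub-compartments"),
        _p("t_sub_cm", 15.0, "h", note="per-stage CM cycle time"),
        _p("t_endo", 15.0, "h", note="endomitosis / blast mitosis stage time"),
        _p("t_dorm_mkc", 12.0, "h", note="transit into MKC dormancy"),
        _p("n_age", 7, "1", note="platelet age sub-compartments"),
    ]
    # ----- stem cells ------------------------------------------------------
    e += [
        _p("b_s_act", 0.4, "1", "iiv", (0.05, 5.0),
           note="steepness of self-renewal feedback"),
        _p("k_dorm_nor", 0.05, "1/h", "population", (1e-3, 1.0),
           note="normal active->dormant stem transition rate"),
        _p("rk_dorm_act", 100.0, "1", "iiv", RK_DORM_ACT_RANGE,
           note="dormant:active stem ratio at steady state"),
        _p("k_act", 5e-4, "1/h", "derived",
           note="dormancy->activation rate, = k_dorm_nor / rk_dorm_act"),
        _p("d_osteo_loss", 1.0, "1", "iiv", (0.01, 5.0),
           note="death-rate coefficient of dormant cells per unit osteoblast loss"),
    ]
    # ----- osteoblast/osteoclast (Komarova) -------------------------------
    e += [
        _p("osteo_alpha1", 3.0 / 24.0, "1/h", note="osteoclast production (Komarova)"),
        _p("osteo_beta1", 0.2 / 24.0, "1/h", note="osteoclast removal (Komarova)"),
        _p("osteo_alpha2", 4.0 / 24.0, "1/h", note="osteoblast production (Komarova)"),
        _p("osteo_beta2", 0.02 / 24.0, "1/h", note="osteoblast removal (Komarova)"),
        _p("d_psi", 1.0 / 72.0, "1/h", "population", (1e-3, 0.1),
           note="decay rate of the delayed chemo effect on osteoblasts (~3 d)"),
        _p("c_pd_osteo", 0.008, "1", "population", (1e-5, 0.05),
           note="osteoblast toxicity proportional to CM toxicity"),
    ]
    # ----- MKC baseline transition parameters (calibrated, see mkc) -------
    # Ploidy-8/16/32 transition probabilities are tied (parsimony), as are the
    # reactivation transit times of ploidies 16 and 32.
    e += [
        _p("p1_8", 0.2157, "1", "population", (0.01, 0.95), tie="mkc_p1",
           note="baseline proplatelet-formation probability, ploidies 8/16/32"),
        _p("p1_16", 0.2157, "1", "tied", tie="mkc_p1"),
        _p("p1_32", 0.2157, "1", "tied", tie="mkc_p1"),
        _p("p2_8", 0.2044, "1", "population", (0.01, 0.95), tie="mkc_p2",
           note="baseline next-ploidy probability, ploidies 8/16/32"),
        _p("p2_16", 0.2044, "1", "tied", tie="mkc_p2"),
        _p("p2_32", 0.2044, "1", "tied", tie="mkc_p2"),
        _p("q64_nor", 0.005, "1", note="baseline 64->128 advance probability (~0)"),
        _p("t_rev_dorm_8", 1.9, "h", "population", (0.1, 500.0),
           note="normal dormant->active reactivation time, ploidy 8"),
        _p("t_rev_dorm_16", 97.7, "h", "population", (1.0, 2000.0), tie="mkc_trev",
           note="normal reactivation time, ploidies 16/32 (tied)"),
        _p("t_rev_dorm_32", 97.7, "h", "tied", tie="mkc_trev"),
        _p("t_pp", 16.3, "h", "population", (0.5, 48.0),
           note="proplatelet transit time"),
        _p("npt_pcu", 500.0, "1", "iiv", NPT_PCU_RANGE,
           note="platelets produced per ploidy unit"),
    ]
    # ----- Z-regulations ---------------------------------------------------
    # CM early-stage amplification (increasing in delayed TPO, y_nor = 2).
    e += [
        _p("z_amp_cm.y_min", 1.05), _p("z_amp_cm.y_nor", 2.0),
        _p("z_amp_cm.y_max", 2.2),
        _p("b_amp_cm", 1.0, "1", "population", (0.1, 10.0),
           note="steepness of CM amplification regulation"),
        # Proplatelet-formation probability p1 (decreasing in delayed TPO);
        # y_nor follows the tied baseline p1.
        _p("z_p1.y_min", 0.05), _p("z_p1.y_max", 0.85),
        _p("b_p1", 1.2, "1", "population", (0.1, 10.0),
           note="steepness of proplatelet-suppression regulation"),
        # Ploidy-64 advance probability q64 = 1 - p64_1 (increasing, ~0 at baseline).
        _p("z_q64.y_min", 1e-4), _p("z_q64.y_max", 0.6),
        _p("b_q64", 2.0, "1", note="steep: advance exceeds zero only at elevated TPO"),
        # Dormant-MKC reactivation multiplier (increasing in delayed TPO).
        _p("z_krev.y_min", 0.3), _p("z_krev.y_nor", 1.0), _p("z_krev.y_max", 6.0),
        _p("b_revdorm", 1.0, "1", "population", (0.1, 10.0),
           note="steepness of dormant-MKC reactivation regulation"),
        _p("lim_sig", 2.0, "1", note="saturation bound shared by all regulations"),
    ]
    # ----- platelets -------------------------------------------------------
    e += [
        _p("t_pl", 240.0, "h", "iiv", (96.0, 400.0),
           note="total platelet transit (age-chain) time"),
        _p("k_circ", 0.5, "1", "population", (0.05, 0.95),
           note="fraction of new platelets entering circulation directly"),
        _p("k_base_sc", 0.05, "1/h", note="scale of age-dependent spleen release"),
        _p("gamma_sc", 2.0, "1", note="age exponent of spleen release"),
        _p("k_s_rel", 0.25, "1", "iiv", (0.01, 0.8),
           note="maximal quasi-constant platelet consumption / normal production"),
        _p("h_s_rel", 0.04, "1", "population", (0.005, 0.5),
           note="half-effect count of quasi-constant consumption / normal count"),
        _p("p_elim", 4.0, "1", note="Hill power of quasi-constant consumption (>1)"),
        _p("r_pl_0_nor", 250.0, "1e9/L", "iiv", (80.0, 450.0),
           note="individual steady-state platelet count"),
    ]
    # ----- TPO -------------------------------------------------------------
    e += [
        _p("t_tpo", 40.0, "h", "population", (5.0, 200.0),
           note="unspecific TPO degradation time"),
        _p("k_m_tpo", 1.0, "1", "population", (0.01, 20.0),
           note="Michaelis constant of receptor-mediated TPO elimination"),
        _p("d_spec_nor", 0.05, "1/h", note="specific TPO elimination at baseline"),
        _p("share_plc", 0.55, "1", note="receptor-mass share of platelets (incl. spleen)"),
        _p("share_mkc", 0.40, "1", note="receptor-mass share of megakaryocytes"),
        _p("share_pp", 0.05, "1", note="receptor-mass share of proplatelets"),
        _p("q_tpo", 0.045, "1/h", "population", (0.005, 0.5),
           note="peg-TPO absorption transfer rate"),
        _p("fr_tpo_dir", 0.05, "1", "population", (0.0, 1.0),
           note="fraction of a subcutaneous dose entering circulation directly"),
        _p("t_del", 36.0, "h", "population", (4.0, 200.0),
           note="delay of TPO action on CM/MKC"),
        _p("t_del_p32", 120.0, "h", "population", (12.0, 600.0),
           note="longer delay for reactivation of dormant ploidy-32 MKC"),
        _p("peg_dose_scale", 15.0, "rel/(ug/kg)", note="relative TPO units per ug/kg"),
        _p("r_tpo_nor_0", 100.0, "pg/mL", "iiv", (20.0, 500.0),
           note="individual steady-state TPO concentration"),
    ]
    # ----- chemotherapy PK (structural placeholders, configurable) --------
    e += [
        _p("pk_cyclo_k", 0.115, "1/h", note="cyclophosphamide elimination (1-cpt)"),
        _p("pk_doxo_k10", 0.5, "1/h"), _p("pk_doxo_k12", 1.0, "1/h"),
        _p("pk_doxo_k21", 0.05, "1/h"),
        _p("pk_etop_k10", 0.25, "1/h"), _p("pk_etop_k12", 0.4, "1/h"),
        _p("pk_etop_k21", 0.15, "1/h"),
        _p("pk_procar_ka", 1.0, "1/h"), _p("pk_procar_ke", 0.7, "1/h"),
        _p("std_dose_cyclo", 750.0, "mg/m2"), _p("std_dose_doxo", 50.0, "mg/m2"),
        _p("std_dose_etop", 100.0, "mg/m2"), _p("std_dose_procar", 100.0, "mg/m2"),
    ]
    # ----- chemotherapy PD -------------------------------------------------
    # Ties: stem and CM toxicities equal; cyclophosphamide and doxorubicin
    # effects equal (per standard dose).  Procarbazine effect fixed to zero
    # (unidentifiable).
    e += [
        _p("pd_cyclo", 0.3, "1/(conc*h)", "iiv", (0.005, 2.0), tie="pd_scm_cd",
           note="toxicity of cyclophosphamide (=doxorubicin) on S and CM"),
        _p("pd_s_doxo", 0.3, "1/(conc*h)", "tied", tie="pd_scm_cd"),
        _p("pd_cm_cyclo", 0.3, "1/(conc*h)", "tied", tie="pd_scm_cd"),
        _p("pd_cm_doxo", 0.3, "1/(conc*h)", "tied", tie="pd_scm_cd"),
        _p("pd_scm_etop", 0.1, "1/(conc*h)", "population", (0.0, 2.0),
           note="etoposide toxicity on S and CM"),
        _p("pd_imm_cd", 0.2, "1/(conc*h)", "population", (0.0, 2.0),
           note="cyclo/doxo toxicity on immature MKC (ploidies 2-4)"),
        _p("pd_imm_etop", 0.05, "1/(conc*h)",
           note="etoposide toxicity on immature MKC; fixed (parsimony)"),
        _p("pd_mat_cd", 0.1, "1/(conc*h)", "population", (0.0, 2.0),
           note="cyclo/doxo toxicity on mature MKC (ploidies 8-128)"),
        _p("pd_mat_etop", 0.02, "1/(conc*h)",
           note="etoposide toxicity on mature MKC; fixed (parsimony)"),
        _p("pd_procar", 0.0, "1/(conc*h)",
           note="procarbazine PD effect unidentifiable; fixed to zero"),
    ]
    return e


class ModelParameters:
    """Registry of named model parameters with tie-group resolution."""

    def __init__(self, entries: list[Parameter]):
        self._params: dict[str, Parameter] = {}
        self._tie_leader: dict[str, str] = {}
        for par in entries:
            if par.name in self._params:
                raise ValueError(f"duplicate parameter {par.name}")
            self._params[par.name] = par
            if par.tie_group and par.status != "tied":
                self._tie_leader[par.tie_group] = par.name

    # -- access ------------------------------------------------------------
    def param(self, name: str) -> Parameter:
        return self._params[name]

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __getitem__(self, name: str) -> float:
        par = self._params[name]
        if par.status == "tied":
            return self._params[self._tie_leader[par.tie_group]].value
        return par.value

    def set(self, name: str, value: float) -> None:
        par = self._params[name]
        if par.status == "tied":
            name = self._tie_leader[par.tie_group]
            par = self._params[name]
        par.value = float(value)
        # propagate to followers so serialized form stays consistent
        if par.tie_group:
            for q in self._params.values():
                if q.tie_group == par.tie_group:
                    q.value = float(value)

    def update(self, mapping: dict) -> None:
        for k, v in mapping.items():
            self.set(k, v)

    def copy(self) -> "ModelParameters":
        return _copy.deepcopy(self)

    def names(self, status: str | None = None) -> list[str]:
        return [p.name for p in self._params.values()
                if status is None or p.status == status]

    # -- Z-regulation assembly ----------------------------------------------
    def zparams(self, regulation: str) -> ZParams:
        """Build the ZParams block for a named regulation."""
        if regulation == "amp_cm":
            return ZParams(self["z_amp_cm.y_min"], self["z_amp_cm.y_nor"],
                           self["z_amp_cm.y_max"], self["b_amp_cm"],
                           self["lim_sig"], "increasing")
        if regulation == "p1_mkc":
            return ZParams(self["z_p1.y_min"], self["p1_8"], self["z_p1.y_max"],
                           self["b_p1"], self["lim_sig"], "decreasing")
        if regulation == "q64":
            return ZParams(self["z_q64.y_min"], self["q64_nor"],
                           self["z_q64.y_max"], self["b_q64"], self["lim_sig"],
                           "increasing")
        if regulation == "krev":
            return ZParams(self["z_krev.y_min"], self["z_krev.y_nor"],
                           self["z_krev.y_max"], self["b_revdorm"],
                           self["lim_sig"], "increasing")
        raise KeyError(f"unknown regulation {regulation!r}")

    # -- audit ---------------------------------------------------------------
    def audit(self) -> AuditReport:
        """Check printed structural constraints and the estimated-parameter budget."""
        v = []

        def expect(cond, msg):
            if not cond:
                v.append(msg)

        expect(self["t_cycle"] == 24.0, "stem cell cycle time must be 24 h")
        expect(self["t_sub_cm"] == 15.0, "CM stage time must be 15 h")
        expect(self["t_endo"] == 15.0, "MKC endomitosis stage time must be 15 h")
        expect(self["t_dorm_mkc"] == 12.0, "MKC dormancy transit must be 12 h")
        expect(self["p_delta"] == 0.1, "self-renewal amplitude p_delta must be 0.1")
        expect(self["pd_procar"] == 0.0, "procarbazine PD effect must be zero")
        lo, hi = RK_DORM_ACT_RANGE
        expect(lo <= self["rk_dorm_act"] <= hi,
               f"rk_dorm_act outside [{lo}, {hi}]")
        lo, hi = NPT_PCU_RANGE
        expect(lo <= self["npt_pcu"] <= hi, f"npt_pcu outside [{lo}, {hi}]")
        expect(0.0 <= self["fr_tpo_dir"] <= 1.0, "fr_tpo_dir outside [0, 1]")
        expect(self["n_cm_early"] <= self["n_cm"], "n_cm_early must not exceed n_cm")
        # tie groups internally consistent
        for par in self._params.values():
            if par.tie_group:
                leader = self._tie_leader[par.tie_group]
                expect(par.value == self._params[leader].value,
                       f"tie group {par.tie_group}: {par.name} != {leader}")
        n_est = len(self.names("population")) + len(self.names("iiv"))
        expect(n_est <= 31, f"{n_est} estimated parameters exceed the budget of 31")
        return AuditReport(n_estimated=n_est, n_total=len(self._params),
                           violations=v)

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for par in self._params.values():
            out[par.name] = {
                "value": par.value, "unit": par.unit, "status": par.status,
                "bounds": list(par.bounds) if par.bounds else None,
                "tie_group": par.tie_group, "note": par.note,
            }
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"parameters": self.to_dict()}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            raw = yaml.safe_load(fh)["parameters"]
        entries = [
            Parameter(name, d["value"], d.get("unit", "1"),
                      d.get("status", "fixed"),
                      tuple(d["bounds"]) if d.get("bounds") else None,
                      d.get("tie_group"), d.get("note", ""))
            for name, d in raw.items()
        ]
        return cls(entries)

    @classmethod
    def default(cls) -> "ModelParameters":
        return cls(_default_entries())


def default_parameters() -> ModelParameters:
    """Fresh registry with documented default values."""
    return ModelParameters.default()
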