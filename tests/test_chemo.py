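"""Chemotherapy PK solutions and compartment toxicity functions."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from thrombosim.chemo import (Drug, DrugDose, PKModel, simulate_pk, toxicity,
                              pk_models_from_registry,
                              toxicity_map_from_registry)
from thrombosim.registry import default_parameters


@pytest.fixture(scope="module")
def models():
    return pk_models_from_registry(default_parameters())


@pytest.fixture(scope="module")
def toxmap():
    return toxicity_map_from_registry(default_parameters())


class TestSimulatePK:
    def test_no_doses_gives_zero(self, models):
        t = np.linspace(0, 48, 25)
        conc = simulate_pk([], models, t)
        for series in conc.values():
            assert np.all(series == 0.0)

    def test_one_compartment_bolus_closed_form(self, models):
        k = default_parameters()["pk_cyclo_k"]
        t = np.linspace(0, 72, 145)
        conc = simulate_pk([DrugDose(Drug.CYCLOPHOSPHAMIDE, 750.0, 0.0)],
                           models, t)[Drug.CYCLOPHOSPHAMIDE]
        np.testing.assert_allclose(conc, np.exp(-k * t), rtol=1e-9)
        # concentration halves after one half-life
        half = math.log(2.0) / k
        assert np.interp(half, t, conc) == pytest.approx(0.5, rel=1e-3)

    def test_superposition_of_two_boluses(self, models):
        """Two doxorubicin boluses equal the sum of shifted single-dose
        solutions, cross-checked against a numeric ODE oracle."""
        model = models[Drug.DOXORUBICIN]
        t = np.linspace(0, 96, 97)
        both = simulate_pk([DrugDose(Drug.DOXORUBICIN, 50.0, 0.0),
                            DrugDose(Drug.DOXORUBICIN, 50.0, 24.0)],
                           models, t)[Drug.DOXORUBICIN]
        single = simulate_pk([DrugDose(Drug.DOXORUBICIN, 50.0, 0.0)],
                             models, t)[Drug.DOXORUBICIN]
        shifted = np.where(t >= 24.0, np.interp(t - 24.0, t, single), 0.0)
        np.testing.assert_allclose(both, single + shifted, atol=1e-10)

        def ode(tt, y):
            dy = model.rate_matrix @ y
            return dy

        sol = solve_ivp(ode, (0, 96), np.array([1.0, 0.0]), t_eval=t,
                        rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(single, sol.y[0], atol=1e-6)

    def test_infusion_mass_and_oracle(self, models):
        """A 2-hour etoposide infusion matches a numeric ODE with constant
        input, and total drug decays to zero afterwards."""
        model = models[Drug.ETOPOSIDE]
        t = np.linspace(0, 120, 241)
        conc = simulate_pk([DrugDose(Drug.ETOPOSIDE, 100.0, 0.0, 2.0)],
                           models, t)[Drug.ETOPOSIDE]

        def ode(tt, y):
            u = np.array([0.5 if tt < 2.0 else 0.0, 0.0])
            return model.rate_matrix @ y + u

        sol = solve_ivp(ode, (0, 120), np.zeros(2), t_eval=t, rtol=1e-10,
                        atol=1e-13, max_step=0.5)
        np.testing.assert_allclose(conc, sol.y[0], atol=1e-5)
        assert conc[-1] < 1e-3  # slow peripheral compartment still draining

    def test_mass_decay_after_last_dose(self, models):
        """Total drug across compartments is non-increasing after dosing."""
        model = models[Drug.DOXORUBICIN]
        t = np.linspace(1.0, 600.0, 400)
        from thrombosim.chemo import _propagate
        c = np.array([1.0, 0.0])
        masses = []
        for dt in np.diff(np.concatenate([[0.0], t])):
            c = _propagate(model.rate_matrix, c, np.zeros(2), dt)
            masses.append(c.sum())
        masses = np.array(masses)
        assert np.all(np.diff(masses) <= 1e-12)
        assert masses[-1] < 1e-3

    def test_unknown_drug_rejected(self, models):
        models2 = {Drug.CYCLOPHOSPHAMIDE: models[Drug.CYCLOPHOSPHAMIDE]}
        with pytest.raises(KeyError):
            simulate_pk([DrugDose(Drug.ETOPOSIDE, 100.0, 0.0)], models2,
                        np.linspace(0, 10, 5))


class TestToxicity:
    def test_zero_concentrations(self, toxmap):
        conc = {d: 0.0 for d in Drug}
        for target in ("S", "CM", "MKC_imm", "MKC", "OST"):
            assert toxicity(conc, toxmap, target) == 0.0

    def test_linear_combination(self, toxmap):
        conc = {Drug.CYCLOPHOSPHAMIDE: 5.0}
        expected = 5.0 * toxmap.coefficient(Drug.CYCLOPHOSPHAMIDE, "CM")
        assert toxicity(conc, toxmap, "CM") == pytest.approx(expected)

    def test_procarbazine_has_no_effect(self, toxmap):
        conc = {Drug.PROCARBAZINE: 10.0}
        for target in ("S", "CM", "MKC_imm", "MKC", "OST"):
            assert toxicity(conc, toxmap, target) == 0.0

    def test_osteoblast_toxicity_proportional_to_cm(self, toxmap):
        conc = {Drug.CYCLOPHOSPHAMIDE: 2.0, Drug.ETOPOSIDE: 1.0}
        assert toxicity(conc, toxmap, "OST") == pytest.approx(
            toxmap.c_pd_osteo * toxicity(conc, toxmap, "CM"))

    def test_additivity_across_drugs(self, toxmap):
        a = toxicity({Drug.CYCLOPHOSPHAMIDE: 2.0}, toxmap, "S")
        b = toxicity({Drug.ETOPOSIDE: 3.0}, toxmap, "S")
        ab = toxicity({Drug.CYCLOPHOSPHAMIDE: 2.0, Drug.ETOPOSIDE: 3.0},
                      toxmap, "S")
        assert ab == pytest.approx(a + b)

    def test_stem_cm_tie_and_cyclo_doxo_tie(self, toxmap):
        for drug in (Drug.CYCLOPHOSPHAMIDE, Drug.DOXORUBICIN, Drug.ETOPOSIDE):
            assert toxmap.coefficient(drug, "S") == toxmap.coefficient(drug, "CM")
        for target in ("S", "CM", "MKC_imm", "MKC"):
            assert toxmap.coefficient(Drug.CYCLOPHOSPHAMIDE, target) == \
                toxmap.coefficient(Drug.DOXORUBICIN, target)

    def test_negative_concentration_rejected(self, toxmap):
        with pytest.raises(ValueError):
            toxicity({Drug.CYCLOPHOSPHAMIDE: -1.0}, toxmap, "S")
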