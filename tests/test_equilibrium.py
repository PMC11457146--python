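"""Gas- and adsorbed-phase equilibrium distributions and selectivities."""

import numpy as np
import pytest

from alkatherm.dataset import generate_synthetic_table
from alkatherm.equilibrium import (
    DHF0_C_ATOM,
    DHF0_H_ATOM,
    R_KJ,
    EquilibriumResult,
    ThermoState,
    adsorbed_distribution,
    atomization_energy,
    gas_distribution,
    ideal_gas_chemical_potential,
    relative_selectivity,
    selectivity,
    states_from_models,
    states_from_table,
)


def make_states(exponent_kj, n_c=10):
    """States whose Boltzmann exponents are the given values (in kJ/mol)."""
    return [
        ThermoState(name=f"iso{i}", n_carbons=n_c, dhf0=0.0, gibbs_function=g)
        for i, g in enumerate(exponent_kj)
    ]


class TestAtomizationEnergy:
    def test_printed_constants_arithmetic(self):
        assert atomization_energy(1, 4, 0.0) == pytest.approx(
            711.185 + 4 * 216.035
        )
        assert DHF0_C_ATOM == 711.185 and DHF0_H_ATOM == 216.035

    def test_zero_when_formation_equals_atoms(self):
        dhf0 = 3 * DHF0_C_ATOM + 8 * DHF0_H_ATOM
        assert atomization_energy(3, 8, dhf0) == pytest.approx(0.0)

    def test_isomer_difference_cancels_constants(self):
        d_a = atomization_energy(10, 22, -250.0)
        d_b = atomization_energy(10, 22, -280.0)
        assert d_a - d_b == pytest.approx(-(-250.0 - (-280.0)))

    def test_inconsistent_formula_rejected(self):
        with pytest.raises(ValueError):
            atomization_energy(10, 20, -250.0)
        with pytest.raises(ValueError):
            atomization_energy(0, 2, 0.0)


class TestGasDistribution:
    def test_identical_isomers_split_evenly(self):
        result = gas_distribution(make_states([50.0, 50.0]), 500.0)
        np.testing.assert_allclose(result.mole_fractions, [0.5, 0.5])

    def test_rt_ln2_gap_gives_two_to_one(self):
        T = 500.0
        gap = R_KJ * T * np.log(2.0)
        result = gas_distribution(make_states([50.0, 50.0 + gap]), T)
        assert result.fraction("iso0") / result.fraction("iso1") == pytest.approx(
            2.0, rel=1e-12
        )

    def test_normalization_within_1e12(self):
        rng = np.random.default_rng(5)
        exps = rng.normal(0.0, 80.0, size=40)
        for T in (300.0, 500.0, 800.0):
            y = gas_distribution(make_states(exps), T).mole_fractions
            assert abs(y.sum() - 1.0) < 1e-12
            assert (y > 0).all()

    def test_uniform_exponent_shift_invariance(self):
        rng = np.random.default_rng(6)
        exps = rng.normal(0.0, 50.0, size=20)
        base = gas_distribution(make_states(exps), 500.0).mole_fractions
        shifted = gas_distribution(make_states(exps + 321.0), 500.0).mole_fractions
        np.testing.assert_allclose(base, shifted, rtol=0, atol=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            gas_distribution([], 500.0)
        with pytest.raises(ValueError):
            gas_distribution(make_states([0.0, 1.0]), -1.0)
        mixed = make_states([0.0]) + [
            ThermoState("other", 9, 0.0, 0.0)
        ]
        with pytest.raises(ValueError, match="formula"):
            gas_distribution(mixed, 500.0)
        with pytest.raises(ValueError):
            gas_distribution(make_states([0.0, -np.inf]), 500.0)


class TestAdsorbedDistribution:
    def test_equal_henry_coefficients_reproduce_gas_phase(self):
        gas = gas_distribution(make_states([10.0, 25.0, 40.0]), 500.0)
        ads = adsorbed_distribution(gas, {n: 2.0e-6 for n in gas.names})
        np.testing.assert_allclose(ads.mole_fractions, gas.mole_fractions, atol=1e-14)

    def test_three_to_one_reweighting(self):
        gas = gas_distribution(make_states([50.0, 50.0]), 500.0)
        ads = adsorbed_distribution(gas, {"iso0": 3.0, "iso1": 1.0})
        np.testing.assert_allclose(ads.mole_fractions, [0.75, 0.25])

    def test_common_scaling_invariance(self):
        gas = gas_distribution(make_states([10.0, 20.0, 35.0]), 500.0)
        kh = {"iso0": 1e-7, "iso1": 5e-6, "iso2": 2e-5}
        a = adsorbed_distribution(gas, kh).mole_fractions
        b = adsorbed_distribution(gas, {k: 1e4 * v for k, v in kh.items()})
        np.testing.assert_allclose(a, b.mole_fractions, atol=1e-14)
        assert abs(a.sum() - 1.0) < 1e-12

    def test_missing_coefficients_named(self):
        gas = gas_distribution(make_states([0.0, 1.0, 2.0]), 500.0)
        with pytest.raises(KeyError, match="iso2"):
            adsorbed_distribution(gas, {"iso0": 1.0, "iso1": 1.0})


class TestSelectivity:
    def test_even_split(self):
        np.testing.assert_allclose(selectivity([0.5, 0.5]), [1.0, 1.0])

    def test_four_to_one(self):
        np.testing.assert_allclose(selectivity([0.2, 0.8]), [0.25, 4.0])

    def test_monotone_in_mole_fraction(self):
        y = np.linspace(0.01, 0.95, 40)
        assert (np.diff(selectivity(y)) > 0).all()  # strictly increasing map

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            selectivity([1.0])
        with pytest.raises(ValueError):
            selectivity([1.0, 0.0])

    def test_relative_selectivity(self):
        res = EquilibriumResult(
            phase="gas", temperature=500.0, names=("a", "b"),
            mole_fractions=np.array([0.2, 0.8]),
        )
        np.testing.assert_allclose(relative_selectivity(res, "a"), [1.0, 16.0])
        np.testing.assert_allclose(res.relative_selectivities("b"), [1 / 16.0, 1.0])
        with pytest.raises(KeyError):
            relative_selectivity(res, "zzz")

    def test_reference_invariant_to_relabelling_others(self):
        y = np.array([0.5, 0.3, 0.2])
        res1 = EquilibriumResult("gas", 500.0, ("r", "a", "b"), y)
        res2 = EquilibriumResult("gas", 500.0, ("r", "b", "a"), y)
        s1 = relative_selectivity(res1, "r")
        s2 = relative_selectivity(res2, "r")
        assert s1[0] == s2[0] == 1.0
        assert set(np.round(s1[1:], 12)) == set(np.round(s2[1:], 12))


class TestChemicalPotential:
    def test_density_term_common_to_isomers(self):
        a = ThermoState("a", 10, -250.0, 40.0)
        b = ThermoState("b", 10, -270.0, 55.0)
        for rho in (1e-7, 1e-5):
            diff = ideal_gas_chemical_potential(
                a, 500.0, rho
            ) - ideal_gas_chemical_potential(b, 500.0, rho)
            assert diff == pytest.approx((-250.0 + 40.0) - (-270.0 + 55.0))

    def test_guards(self):
        s = ThermoState("a", 10, -250.0, 40.0)
        with pytest.raises(ValueError):
            ideal_gas_chemical_potential(s, -5.0, 1e-6)
        with pytest.raises(ValueError):
            ideal_gas_chemical_potential(s, 500.0, 0.0)


class TestPipelines:
    def test_table_and_model_distributions_rank_alike(self):
        """Gas-phase C10 distributions at 500 K from tabulated values and from
        the fitted group-contribution model must rank isomers consistently."""
        from scipy.stats import spearmanr

        from alkatherm.isomers import enumerate_isomers
        from alkatherm.regression import fit_property, fit_temperature_polynomials

        table, _ = generate_synthetic_table(
            seed=21,
            n_max=10,
            temperatures=(0.0, 400.0, 500.0, 600.0),
            sigma=0.3,
            properties=("dHf", "G_minus_H0"),
        )
        dhf = fit_temperature_polynomials(fit_property(table, "dHf"))
        gf = fit_temperature_polynomials(fit_property(table, "G_minus_H0"))

        states_tab = [
            s for s in states_from_table(table, 500.0)
            if table.molecule(s.name).n_carbons == 10
        ]
        molecules = [(s.name, table.molecule(s.name)) for s in states_tab]
        states_lr = states_from_models(molecules, dhf, gf, 500.0)

        y_tab = gas_distribution(states_tab, 500.0).mole_fractions
        y_lr = gas_distribution(states_lr, 500.0).mole_fractions
        assert len(y_tab) == 75
        rho = spearmanr(y_tab, y_lr).statistic
        assert rho > 0.99

    def test_full_chain_to_adsorbed_phase(self):
        table, _ = generate_synthetic_table(
            seed=23, n_max=6, temperatures=(0.0, 450.0, 500.0, 550.0),
            properties=("dHf", "G_minus_H0"),
        )
        states = [
            s for s in states_from_table(table, 500.0)
            if table.molecule(s.name).n_carbons == 6
        ]
        gas = gas_distribution(states, 500.0)
        rng = np.random.default_rng(9)
        kh = {n: float(rng.lognormal(-12, 1)) for n in gas.names}
        ads = adsorbed_distribution(gas, kh)
        assert abs(gas.mole_fractions.sum() - 1) < 1e-12
        assert abs(ads.mole_fractions.sum() - 1) < 1e-12
        frame = ads.to_frame(reference=gas.names[0])
        assert frame.loc[0, "relative_selectivity"] == pytest.approx(1.0)
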