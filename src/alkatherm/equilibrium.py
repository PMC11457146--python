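"""Reaction-equilibrium distributions of alkane isomers in gas and adsorbed phase.

Hydroisomerization interconverts the constitutional isomers of one alkane
formula; at chemical equilibrium the ideal-gas chemical potentials of all
isomers are equal.  Because every isomer shares the same atomic composition,
all composition-dependent reference terms (atomization energy, atomic
enthalpies, the density term with its reference density) cancel between
isomers, and the gas-phase mole fractions reduce to Boltzmann weights over
the isomer-specific part of the chemical potential,

.. math::

    y_i \\propto \\exp\\!\\left[-\\frac{(G^0 - H^0(0\\,\\mathrm{K}))_i(T)
        + \\Delta_f H^0_i(0\\,\\mathrm{K})}{R T}\\right].

The weights are evaluated with a log-sum-exp shift, so uniformly shifting
all exponents changes nothing numerically or analytically.

At infinite dilution the adsorbed phase follows Henry's law: the adsorbed
mole fractions are the gas-phase ones reweighted by the Henry coefficients,
:math:`x_i \\propto K_{H,i}\\, y_i` (any common scale of the coefficients
cancels).  Selectivities are :math:`s_i = y_i / (1 - y_i)` and relative
selectivities :math:`s_{\\mathrm{rel},i} = s_i / s_\\mathrm{ref}` against a
named reference isomer (typically the linear alkane).

Pressure effects are ignored — the intended regime is infinite dilution at
or above 500 K — and alkene or carbenium intermediates are outside the
network: only the alkane isomer family appears.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .dataset import HenryTable, TrainingTable

__all__ = [
    "R_KJ",
    "DHF0_C_ATOM",
    "DHF0_H_ATOM",
    "ThermoState",
    "EquilibriumResult",
    "atomization_energy",
    "ideal_gas_chemical_potential",
    "gas_distribution",
    "adsorbed_distribution",
    "selectivity",
    "relative_selectivity",
    "states_from_table",
    "states_from_models",
]

#: Molar gas constant in kJ mol^-1 K^-1.
R_KJ = 8.314462618e-3

#: Enthalpy of formation of atomic carbon at 0 K, kJ/mol (JANAF).
DHF0_C_ATOM = 711.185
#: Enthalpy of formation of atomic hydrogen at 0 K, kJ/mol (JANAF).
DHF0_H_ATOM = 216.035


@dataclass(frozen=True)
class ThermoState:
    """Thermochemical inputs of one isomer for the equilibrium layer.

    ``gibbs_function`` is :math:`(G^0 - H^0(0 K))` at the working temperature
    and ``dhf0`` is :math:`\\Delta_f H^0` at 0 K, both in kJ/mol.
    """

    name: str
    n_carbons: int
    dhf0: float
    gibbs_function: float

    @property
    def n_hydrogens(self) -> int:
        return 2 * self.n_carbons + 2


def atomization_energy(
    a_C: int,
    a_H: int,
    dhf0: float,
    dhf0_C: float = DHF0_C_ATOM,
    dhf0_H: float = DHF0_H_ATOM,
) -> float:
    """Atomization energy D0 = a_C dHf(C) + a_H dHf(H) - dHf(molecule), kJ/mol.

    For a saturated acyclic alkane ``a_H`` must equal ``2 a_C + 2``; the
    atomic constants default to the JANAF 0 K values and are overridable.
    """
    if a_C < 1:
        raise ValueError("a_C must be >= 1")
    if a_H != 2 * a_C + 2:
        raise ValueError(f"C{a_C}H{a_H} is not an acyclic alkane formula")
    return a_C * dhf0_C + a_H * dhf0_H - dhf0


def ideal_gas_chemical_potential(
    state: ThermoState,
    T: float,
    number_density: float,
    rho0: float = 1.0,
) -> float:
    """Full ideal-gas chemical potential mu_i(T, rho) in kJ/mol.

    ``number_density`` and ``rho0`` are in molecules per cubic angstrom
    (reference 1 molecule/A^3).  The isomer-specific reference part is
    ``dhf0 + gibbs_function``; the density term ``RT ln(rho/rho0)`` is common
    to all isomers of a mixture at the same density, which is why it cancels
    from the equilibrium distribution (see :func:`gas_distribution`).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if number_density <= 0 or rho0 <= 0:
        raise ValueError("densities must be positive")
    mu_ref = state.dhf0 + state.gibbs_function
    return mu_ref + R_KJ * T * np.log(number_density / rho0)


@dataclass(frozen=True)
class EquilibriumResult:
    """Mole fractions of an isomer family in one phase at one temperature."""

    phase: str
    temperature: float
    names: tuple[str, ...]
    mole_fractions: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.mole_fractions, dtype=float)
        if len(y) != len(self.names):
            raise ValueError("names and mole fractions differ in length")
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            raise ValueError("mole fractions must be finite and nonnegative")
        object.__setattr__(self, "mole_fractions", y)

    def fraction(self, name: str) -> float:
        return float(self.mole_fractions[self.names.index(name)])

    def selectivities(self) -> np.ndarray:
        return selectivity(self.mole_fractions)

    def relative_selectivities(self, reference: str) -> np.ndarray:
        return relative_selectivity(self, reference)

    def to_frame(self, reference: str | None = None) -> pd.DataFrame:
        """Tabulate mole fractions and (relative) selectivities."""
        out = pd.DataFrame(
            {
                "isomer": self.names,
                f"y_{self.phase}": self.mole_fractions,
                "selectivity": self.selectivities(),
            }
        )
        if reference is not None:
            out["relative_selectivity"] = self.relative_selectivities(reference)
        return out


def gas_distribution(states: Sequence[ThermoState], T: float) -> EquilibriumResult:
    """Gas-phase equilibrium mole fractions of an isomer family at T.

    All states must share one molecular formula; the Boltzmann exponent of
    isomer *i* is ``(gibbs_function + dhf0) / (R T)`` and the distribution is
    invariant to adding any constant to all exponents.
    """
    if not states:
        raise ValueError("no isomers given")
    if T <= 0:
        raise ValueError("temperature must be positive")
    formulas = {s.n_carbons for s in states}
    if len(formulas) > 1:
        raise ValueError(
            f"isomers must share one formula; got carbon counts {sorted(formulas)}"
        )
    names = tuple(s.name for s in states)
    if len(set(names)) != len(names):
        raise ValueError("duplicate isomer names")
    exponents = np.array([-(s.gibbs_function + s.dhf0) / (R_KJ * T) for s in states])
    if not np.all(np.isfinite(exponents)):
        raise ValueError("non-finite chemical-potential input")
    log_y = exponents - logsumexp(exponents)
    return EquilibriumResult(
        phase="gas", temperature=T, names=names, mole_fractions=np.exp(log_y)
    )


def adsorbed_distribution(
    gas: EquilibriumResult,
    henry: HenryTable | Mapping[str, float],
    zeolite: str | None = None,
    T: float | None = None,
) -> EquilibriumResult:
    """Adsorbed-phase distribution from Henry's law at infinite dilution.

    ``x_i = K_H,i y_i / sum_j K_H,j y_j``; scaling every coefficient by a
    common factor leaves the result unchanged.  Raises a named error listing
    the isomers for which coefficients are missing.
    """
    if isinstance(henry, HenryTable):
        if zeolite is None or T is None:
            raise ValueError("zeolite and T are required with a HenryTable")
        coeffs = henry.coefficients(zeolite, T)
        lookup = coeffs.to_dict()
    else:
        lookup = dict(henry)
    missing = [n for n in gas.names if n not in lookup]
    if missing:
        raise KeyError(f"missing Henry coefficients for isomers: {missing}")
    kh = np.array([lookup[n] for n in gas.names], dtype=float)
    if np.any(kh <= 0) or not np.all(np.isfinite(kh)):
        raise ValueError("Henry coefficients must be finite and positive")
    weights = kh * gas.mole_fractions
    return EquilibriumResult(
        phase="adsorbed",
        temperature=T if T is not None else gas.temperature,
        names=gas.names,
        mole_fractions=weights / weights.sum(),
    )


def selectivity(mole_fractions: np.ndarray | Sequence[float]) -> np.ndarray:
    """Component selectivity s_i = y_i / (1 - y_i) within one phase."""
    y = np.asarray(mole_fractions, dtype=float)
    if y.size < 2:
        raise ValueError("selectivity needs at least two components")
    if np.any(y >= 1.0):
        raise ValueError("a mole fraction of 1 gives an undefined selectivity")
    return y / (1.0 - y)


def relative_selectivity(result: EquilibriumResult, reference: str) -> np.ndarray:
    """Selectivities normalized by a reference isomer (its value becomes 1)."""
    if reference not in result.names:
        raise KeyError(f"reference isomer {reference!r} not in result")
    s = result.selectivities()
    return s / s[result.names.index(reference)]


# ---------------------------------------------------------------------------
# Convenience constructors
# ---------------------------------------------------------------------------


def states_from_table(table: TrainingTable, T: float) -> list[ThermoState]:
    """Build ThermoStates from tabulated dHf(0 K) and (G0-H0(0K))(T)."""
    states = []
    for isomer in table.isomers("dHf"):
        mol = table.molecule(isomer)
        states.append(
            ThermoState(
                name=isomer,
                n_carbons=mol.n_carbons,
                dhf0=table.value(isomer, "dHf", 0.0),
                gibbs_function=table.value(isomer, "G_minus_H0", T),
            )
        )
    return states


def states_from_models(molecules, dhf_model, gibbs_model, T: float) -> list[ThermoState]:
    """Build ThermoStates from fitted models (dHf at 0 K, G0-H0(0K) at T).

    ``molecules`` is an iterable of (name, Molecule) pairs; the models are
    anything :func:`alkatherm.regression.predict` accepts.
    """
    from .regression import predict

    states = []
    for name, mol in molecules:
        states.append(
            ThermoState(
                name=name,
                n_carbons=mol.n_carbons,
                dhf0=predict(mol, dhf_model, 0.0),
                gibbs_function=predict(mol, gibbs_model, T),
            )
        )
    return states
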