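"""Thermochemical training tables, Henry-coefficient tables and synthetic data.

The training data follow the layout of the classic statistical-mechanical
ideal-gas tables for C1–C10 alkanes: for every isomer and temperature the
four properties

* ``dGf``        — Gibbs free energy of formation,
* ``dHf``        — enthalpy of formation,
* ``G_minus_H0`` — Gibbs energy function :math:`G^0 - H^0(0\\,\\mathrm{K})`
  (stored signed, exactly as tabulated),
* ``H_minus_H0`` — enthalpy function :math:`H^0 - H^0(0\\,\\mathrm{K})`,

all in kJ/mol on a common temperature grid per property (0 K rows allowed —
``dHf`` at 0 K feeds the equilibrium layer).  Isomers are identified by
shorthand names (``2,2,5-m-C7``) or SMILES.

Two file layouts are read: a tidy CSV (``isomer,T,property,value``) and a
wide spreadsheet workbook with one worksheet per property (first column the
isomer, remaining columns the temperatures); a schema map can rename
worksheets and columns for workbooks with different headers.

:func:`generate_synthetic_table` plants an exactly group-additive model with
quadratic-in-temperature coefficients and optional Gaussian noise, and
returns the ground truth alongside the table so regression tests can check
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .groups import count_groups
from .isomers import enumerate_isomers
from .molecule import Molecule, MoleculeError, molecule_to_name, name_to_molecule, parse_smiles

__all__ = [
    "PROPERTIES",
    "TrainingTable",
    "HenryTable",
    "read_training_table",
    "write_training_table",
    "read_henry_table",
    "PlantedModel",
    "generate_synthetic_table",
    "resolve_isomer",
]

#: Canonical property identifiers, all in kJ/mol.
PROPERTIES = ("dGf", "dHf", "G_minus_H0", "H_minus_H0")

_TIDY_COLUMNS = ["isomer", "T", "property", "value"]


def resolve_isomer(identifier: str) -> Molecule:
    """Resolve an isomer identifier (shorthand name or SMILES) to a molecule."""
    try:
        return name_to_molecule(identifier)
    except MoleculeError:
        pass
    try:
        return parse_smiles(identifier)
    except MoleculeError:
        raise MoleculeError(
            f"isomer {identifier!r} is neither a shorthand name nor a SMILES string"
        ) from None


class TrainingTable:
    """Isomer x temperature x property grid of thermochemical values.

    Wraps a tidy :class:`pandas.DataFrame` with columns
    ``isomer, T, property, value`` and validates on construction that every
    isomer identifier resolves, every value is finite, no (isomer, T,
    property) cell is duplicated and the temperature grid is identical
    across isomers within each property.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _TIDY_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"training table is missing columns {missing}")
        frame = frame.loc[:, _TIDY_COLUMNS].copy()
        if frame.empty:
            raise ValueError("training table is empty")
        frame["T"] = pd.to_numeric(frame["T"], errors="raise")
        frame["value"] = pd.to_numeric(frame["value"], errors="raise")
        if not np.isfinite(frame["value"]).all():
            bad = frame.loc[~np.isfinite(frame["value"])]
            raise ValueError(f"non-finite values, e.g. row {bad.index[0]}")
        unknown = set(frame["property"]) - set(PROPERTIES)
        if unknown:
            raise ValueError(
                f"unknown properties {sorted(unknown)}; expected {PROPERTIES}"
            )
        if frame.duplicated(["isomer", "T", "property"]).any():
            raise ValueError("duplicated (isomer, T, property) records")
        self._molecules: dict[str, Molecule] = {}
        for iso in frame["isomer"].unique():
            self._molecules[iso] = resolve_isomer(iso)  # raises on unknown names
        for prop, sub in frame.groupby("property"):
            grids = {
                iso: tuple(sorted(g["T"])) for iso, g in sub.groupby("isomer")
            }
            if len(set(grids.values())) > 1:
                raise ValueError(
                    f"inconsistent temperature grids across isomers for {prop!r}"
                )
        self._frame = frame.sort_values(["property", "isomer", "T"]).reset_index(
            drop=True
        )

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying tidy DataFrame (isomer, T, property, value)."""
        return self._frame

    @property
    def properties(self) -> list[str]:
        return sorted(self._frame["property"].unique())

    def isomers(self, prop: str | None = None) -> list[str]:
        sub = self._frame if prop is None else self._select(prop)
        return sorted(sub["isomer"].unique())

    def molecule(self, isomer: str) -> Molecule:
        return self._molecules[isomer]

    def temperatures(self, prop: str) -> np.ndarray:
        return np.array(sorted(self._select(prop)["T"].unique()))

    def _select(self, prop: str) -> pd.DataFrame:
        if prop not in set(self._frame["property"]):
            raise KeyError(f"property {prop!r} not in table")
        return self._frame[self._frame["property"] == prop]

    def values(self, prop: str, T: float) -> pd.Series:
        """Values of one property at one temperature, indexed by isomer."""
        sub = self._select(prop)
        sub = sub[np.isclose(sub["T"], T)]
        if sub.empty:
            raise KeyError(f"temperature {T} K not in table for {prop!r}")
        return sub.set_index("isomer")["value"].sort_index()

    def value(self, isomer: str, prop: str, T: float) -> float:
        return float(self.values(prop, T).loc[isomer])


def read_training_table(
    path: str | Path,
    format: str | None = None,
    schema: Mapping[str, str] | None = None,
) -> TrainingTable:
    """Read a training table from a tidy CSV or a wide xlsx workbook.

    Parameters
    ----------
    path
        File to read.  ``format`` (``"csv"`` or ``"xlsx"``) defaults to the
        file suffix.
    schema
        Optional renaming map applied to worksheet names (xlsx) or column
        names (csv), e.g. ``{"DHf0": "dHf"}``, for sources whose headers
        differ from the canonical property identifiers.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    schema = dict(schema or {})
    if fmt == "csv":
        frame = pd.read_csv(path)
        if schema:
            frame = frame.rename(columns=schema)
        return TrainingTable(frame)
    if fmt in ("xlsx", "xls"):
        sheets = pd.read_excel(path, sheet_name=None)
        records = []
        for sheet, wide in sheets.items():
            prop = schema.get(sheet, sheet)
            if prop not in PROPERTIES:
                continue  # ignore unrelated worksheets
            if wide.empty:
                continue
            iso_col = wide.columns[0]
            long = wide.melt(id_vars=[iso_col], var_name="T", value_name="value")
            long = long.rename(columns={iso_col: "isomer"})
            long["property"] = prop
            records.append(long)
        if not records:
            raise ValueError(
                f"{path}: no worksheet matches a property in {PROPERTIES}"
                " (pass a schema map to rename worksheets)"
            )
        return TrainingTable(pd.concat(records, ignore_index=True))
    raise ValueError(f"unsupported training-table format {fmt!r}")


def write_training_table(table: TrainingTable, path: str | Path) -> None:
    """Write a tidy CSV that round-trips to 12 significant digits."""
    table.frame.to_csv(path, index=False, float_format="%.12g")


@dataclass(frozen=True)
class HenryTable:
    """Henry coefficients K_H (mol kg^-1 Pa^-1) per isomer, zeolite and T."""

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in ("isomer", "zeolite", "T", "KH") if c not in self.frame.columns]
        if missing:
            raise ValueError(f"henry table is missing columns {missing}")
        if (self.frame["KH"] <= 0).any() or not np.isfinite(self.frame["KH"]).all():
            raise ValueError("Henry coefficients must be finite and strictly positive")

    def coefficients(self, zeolite: str, T: float) -> pd.Series:
        sub = self.frame[
            (self.frame["zeolite"] == zeolite) & np.isclose(self.frame["T"], T)
        ]
        if sub.empty:
            raise KeyError(f"no Henry coefficients for {zeolite!r} at {T} K")
        return sub.set_index("isomer")["KH"]


def read_henry_table(path: str | Path) -> HenryTable:
    """Read a Henry-coefficient CSV with columns isomer, zeolite, T, KH."""
    return HenryTable(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Synthetic group-additive data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedModel:
    """Ground-truth coefficients behind a synthetic table.

    Each descriptor key (and the intercept) carries a quadratic temperature
    polynomial ``alpha(T) = A + B*T + C*T**2`` per property, in kJ/mol.
    """

    properties: tuple[str, ...]
    keys: tuple[str, ...]
    coefficients: Mapping[str, Mapping[str, tuple[float, float, float]]]
    intercepts: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)

    def coefficient(self, prop: str, key: str, T: float) -> float:
        a, b, c = self.coefficients[prop][key]
        return a + b * T + c * T * T

    def intercept(self, prop: str, T: float) -> float:
        a, b, c = self.intercepts.get(prop, (0.0, 0.0, 0.0))
        return a + b * T + c * T * T

    def value(self, counts: Mapping[str, int], prop: str, T: float) -> float:
        total = self.intercept(prop, T)
        for key, x in counts.items():
            total += x * self.coefficient(prop, key, T)
        return total


def generate_synthetic_table(
    seed: int = 0,
    n_max: int = 8,
    temperatures: Sequence[float] = (300.0, 400.0, 500.0, 600.0),
    properties: Iterable[str] = PROPERTIES,
    sigma: float = 0.0,
    order: str = "second",
    planted: PlantedModel | None = None,
) -> tuple[TrainingTable, PlantedModel]:
    """Exactly group-additive synthetic training data for C1..n_max isomers.

    Coefficient magnitudes emulate alkane thermochemistry: per-group constants
    of tens of kJ/mol with mild linear and weak quadratic temperature
    dependence.  ``sigma`` adds i.i.d. Gaussian noise in kJ/mol (0 by
    default, giving data the regression layer must reproduce to machine
    precision).  Returns the table together with the planted ground truth.
    """
    rng = np.random.default_rng(seed)
    properties = tuple(properties)
    molecules: list[tuple[str, Molecule]] = []
    for n in range(1, n_max + 1):
        for m in enumerate_isomers(n):
            try:
                ident = molecule_to_name(m)
            except MoleculeError:
                ident = m.canonical_smiles
            molecules.append((ident, m))
    counts = {ident: count_groups(m, order) for ident, m in molecules}
    keys = tuple(sorted({k for c in counts.values() for k in c}))
    if planted is None:
        coeffs = {
            prop: {
                key: (
                    float(rng.normal(-20.0, 15.0)),
                    float(rng.normal(0.0, 0.05)),
                    float(rng.normal(0.0, 5e-5)),
                )
                for key in keys
            }
            for prop in properties
        }
        intercepts = {
            prop: (
                float(rng.normal(0.0, 5.0)),
                float(rng.normal(0.0, 0.01)),
                float(rng.normal(0.0, 1e-5)),
            )
            for prop in properties
        }
        planted = PlantedModel(properties, keys, coeffs, intercepts)
    records = []
    for prop in properties:
        for ident, _ in molecules:
            for T in temperatures:
                value = planted.value(counts[ident], prop, float(T))
                if sigma > 0:
                    value += float(rng.normal(0.0, sigma))
                records.append((ident, float(T), prop, value))
    table = TrainingTable(pd.DataFrame(records, columns=_TIDY_COLUMNS))
    return table, planted
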