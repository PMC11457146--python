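"""Linear regression of thermochemical properties on group occurrences.

The model is ordinary least squares per property and per temperature,

.. math::

    y = \\alpha_0 + \\sum_{k=1}^{N_\\mathrm{descriptor}} \\alpha_k x_k ,

where :math:`x_k` is the occurrence count of first- or second-order group
*k* in the molecule and :math:`y` the property in kJ/mol.  The solver is
SVD-based (:func:`numpy.linalg.lstsq`) with a relative singular-value cutoff
of 1e-10, returning the minimum-norm solution when the design is
rank-deficient — the intercept and the count-sum direction are near-collinear
for homologous series, so this happens routinely and is deliberate: the
fitted *predictions* are unique even when individual coefficients are not.

To interpolate in temperature, the per-temperature coefficients are refitted
to quadratic polynomials :math:`\\alpha_k(T) = A_k + B_k T + C_k T^2`
independently per descriptor key.  Prediction for molecules containing
groups outside the fitted key set routes those occurrences through a
group-approximation map (see :mod:`alkatherm.groups`).

No regularization and no weighting anywhere: coefficients are reproducible,
plain least-squares quantities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import TrainingTable
from .groups import apply_approximation, build_approximation_map, count_groups
from .molecule import Molecule

__all__ = [
    "PropertyModel",
    "TempPolynomial",
    "fit_property",
    "mae",
    "fit_temperature_polynomials",
    "predict",
    "export_coefficients_csv",
]

#: Relative singular-value cutoff of the least-squares solver.
RCOND = 1e-10


def _read_json_source(source: str | Path) -> str:
    """Accept either a path to a JSON file or JSON text itself."""
    if isinstance(source, Path):
        return source.read_text()
    text = str(source)
    if text.lstrip().startswith("{"):
        return text
    return Path(text).read_text()


@dataclass
class PropertyModel:
    """Per-temperature least-squares fit of one thermochemical property."""

    property: str
    order: str
    keys: tuple[str, ...]
    temperatures: tuple[float, ...]
    #: per temperature: intercept alpha_0 in kJ/mol
    intercepts: dict[float, float]
    #: per temperature: coefficient vector aligned with ``keys``, kJ/mol
    coefficients: dict[float, np.ndarray]
    #: per temperature: {"mae": ..., "max_residual": ...} on the training set
    diagnostics: dict[float, dict[str, float]] = field(default_factory=dict)

    def coefficient(self, T: float, key: str) -> float:
        return float(self.coefficients[T][self.keys.index(key)])

    def evaluate(self, counts: Mapping[str, int], T: float) -> float:
        """alpha_0(T) + sum_k x_k alpha_k(T) for a descriptor vector."""
        if T not in self.coefficients:
            raise KeyError(f"temperature {T} K was not fitted")
        total = self.intercepts[T]
        vec = self.coefficients[T]
        index = {k: j for j, k in enumerate(self.keys)}
        for key, x in counts.items():
            if key not in index:
                raise KeyError(
                    f"group {key!r} is outside the fitted key set and no "
                    f"approximation was applied"
                )
            total += x * vec[index[key]]
        return float(total)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "property": self.property,
            "order": self.order,
            "keys": list(self.keys),
            "temperatures": list(self.temperatures),
            "intercepts": {str(t): v for t, v in self.intercepts.items()},
            "coefficients": {
                str(t): list(map(float, v)) for t, v in self.coefficients.items()
            },
            "diagnostics": {str(t): d for t, d in self.diagnostics.items()},
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PropertyModel":
        p = json.loads(_read_json_source(source))
        return cls(
            property=p["property"],
            order=p["order"],
            keys=tuple(p["keys"]),
            temperatures=tuple(p["temperatures"]),
            intercepts={float(t): v for t, v in p["intercepts"].items()},
            coefficients={
                float(t): np.asarray(v, dtype=float)
                for t, v in p["coefficients"].items()
            },
            diagnostics={float(t): d for t, d in p["diagnostics"].items()},
        )


def fit_property(
    table: TrainingTable,
    prop: str,
    temperatures: Sequence[float] | None = None,
    order: str = "second",
    approximation: Mapping[str, str] | None = None,
) -> PropertyModel:
    """Fit the group-occurrence model at each temperature separately.

    ``approximation`` optionally re-keys training descriptors before the fit
    (normally unnecessary: the training set defines the key universe).
    """
    if temperatures is None:
        temperatures = [float(t) for t in table.temperatures(prop)]
    isomers = table.isomers(prop)
    vectors = [
        apply_approximation(count_groups(table.molecule(i), order), approximation)
        for i in isomers
    ]
    keys = tuple(sorted({k for v in vectors for k in v}))
    col = {k: j for j, k in enumerate(keys)}
    design = np.zeros((len(isomers), len(keys) + 1))
    design[:, 0] = 1.0  # intercept column
    for i, v in enumerate(vectors):
        for k, x in v.items():
            design[i, col[k] + 1] = x

    intercepts: dict[float, float] = {}
    coefficients: dict[float, np.ndarray] = {}
    diagnostics: dict[float, dict[str, float]] = {}
    for T in temperatures:
        y = table.values(prop, T).loc[isomers].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(design, y, rcond=RCOND)
        resid = design @ beta - y
        intercepts[T] = float(beta[0])
        coefficients[T] = beta[1:]
        diagnostics[T] = {
            "mae": float(np.mean(np.abs(resid))),
            "max_residual": float(np.max(np.abs(resid))) if len(resid) else 0.0,
        }
    return PropertyModel(
        property=prop,
        order=order,
        keys=keys,
        temperatures=tuple(float(t) for t in temperatures),
        intercepts=intercepts,
        coefficients=coefficients,
        diagnostics=diagnostics,
    )


def mae(
    model: PropertyModel,
    table: TrainingTable,
    temperatures: Sequence[float] | None = None,
) -> float:
    """Mean absolute error of a fitted model against a table, in kJ/mol.

    By default the scope is every isomer at every fitted temperature.
    """
    temps = list(temperatures) if temperatures is not None else list(model.temperatures)
    if not temps:
        raise ValueError("empty temperature scope")
    errors = []
    for T in temps:
        values = table.values(model.property, T)
        for isomer, y in values.items():
            counts = count_groups(table.molecule(isomer), model.order)
            errors.append(abs(model.evaluate(counts, T) - y))
    return float(np.mean(errors))


@dataclass
class TempPolynomial:
    """Quadratic temperature polynomials for every fitted coefficient.

    For each descriptor key (and the intercept) the per-temperature
    least-squares coefficients are refitted as alpha(T) = A + B*T + C*T^2
    with A in kJ/mol, B in kJ/(mol K), C in kJ/(mol K^2).  ``residuals``
    records the largest |polynomial - per-temperature coefficient| per key,
    so a coefficient that is not actually quadratic in T cannot fail
    silently.
    """

    property: str
    order: str
    keys: tuple[str, ...]
    fitted_range: tuple[float, float]
    #: key -> (A, B, C); the intercept is stored under ``"alpha0"``
    polynomials: dict[str, tuple[float, float, float]]
    residuals: dict[str, float] = field(default_factory=dict)

    INTERCEPT_KEY = "alpha0"

    def coefficient(self, key: str, T: float) -> float:
        a, b, c = self.polynomials[key]
        return a + b * T + c * T * T

    def evaluate(self, counts: Mapping[str, int], T: float) -> float:
        total = self.coefficient(self.INTERCEPT_KEY, T)
        for key, x in counts.items():
            if key not in self.polynomials:
                raise KeyError(
                    f"group {key!r} is outside the fitted key set and no "
                    f"approximation was applied"
                )
            total += x * self.coefficient(key, T)
        return float(total)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "property": self.property,
            "order": self.order,
            "keys": list(self.keys),
            "fitted_range": list(self.fitted_range),
            "polynomials": {k: list(v) for k, v in self.polynomials.items()},
            "residuals": self.residuals,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TempPolynomial":
        p = json.loads(_read_json_source(source))
        return cls(
            property=p["property"],
            order=p["order"],
            keys=tuple(p["keys"]),
            fitted_range=tuple(p["fitted_range"]),
            polynomials={k: tuple(v) for k, v in p["polynomials"].items()},
            residuals=p["residuals"],
        )


def fit_temperature_polynomials(model: PropertyModel) -> TempPolynomial:
    """Refit each per-temperature coefficient to a quadratic in T."""
    temps = np.asarray(model.temperatures, dtype=float)
    if len(temps) < 3:
        raise ValueError("need at least 3 fitted temperatures for a quadratic")
    vander = np.column_stack([np.ones_like(temps), temps, temps**2])
    series = {
        TempPolynomial.INTERCEPT_KEY: np.array(
            [model.intercepts[t] for t in model.temperatures]
        )
    }
    for j, key in enumerate(model.keys):
        series[key] = np.array([model.coefficients[t][j] for t in model.temperatures])
    polynomials: dict[str, tuple[float, float, float]] = {}
    residuals: dict[str, float] = {}
    for key, values in series.items():
        abc, *_ = np.linalg.lstsq(vander, values, rcond=RCOND)
        polynomials[key] = (float(abc[0]), float(abc[1]), float(abc[2]))
        residuals[key] = float(np.max(np.abs(vander @ abc - values)))
    return TempPolynomial(
        property=model.property,
        order=model.order,
        keys=model.keys,
        fitted_range=(float(temps.min()), float(temps.max())),
        polynomials=polynomials,
        residuals=residuals,
    )


def predict(
    molecule: Molecule,
    model: PropertyModel | TempPolynomial,
    T: float,
    approximation: Mapping[str, str] | None = None,
) -> float:
    """Predict a property (kJ/mol) for a molecule at temperature T.

    Occurrences of groups outside the model's key set are re-keyed through
    ``approximation``; when none is given, the default demotion-rule map onto
    the fitted key universe is built automatically.  Temperatures outside the
    fitted range trigger a warning (the quadratic extrapolates smoothly but
    without support).
    """
    counts = count_groups(molecule, model.order)
    known = set(model.keys)
    if any(k not in known for k in counts):
        if approximation is None:
            approximation = build_approximation_map(known)
        counts = apply_approximation(counts, approximation)
    if isinstance(model, TempPolynomial):
        lo, hi = model.fitted_range
        if not lo <= T <= hi:
            warnings.warn(
                f"T = {T} K is outside the fitted range [{lo}, {hi}] K; "
                f"extrapolating the coefficient polynomials",
                stacklevel=2,
            )
    return model.evaluate(counts, T)


def export_coefficients_csv(poly: TempPolynomial, path: str | Path) -> None:
    """Write the quadratic coefficients as CSV (key, A, B, C)."""
    rows = [
        {"key": k, "A": a, "B": b, "C": c}
        for k, (a, b, c) in sorted(poly.polynomials.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
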