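"""Fit the group-contribution linear model and predict beyond the training set.

Generates a synthetic group-additive training table for C1-C8 (stand-in for
tabulated ideal-gas thermochemistry), fits the per-temperature linear
regression with first- and second-order descriptors, refits the coefficients
as quadratics in temperature, and predicts the enthalpy of formation of a
C13 isomer whose groups are partly absent from the training molecules —
those are routed through the approximation map automatically.
"""

from alkatherm import (
    fit_property,
    fit_temperature_polynomials,
    generate_synthetic_table,
    mae,
    name_to_molecule,
    predict,
)

table, _ = generate_synthetic_table(
    seed=7, n_max=8, temperatures=(0.0, 300.0, 400.0, 500.0, 600.0), sigma=0.2
)
print(f"training table: {len(table.isomers())} isomers x "
      f"{len(table.temperatures('dHf'))} temperatures x {len(table.properties)} properties")

for order in ("first", "second"):
    model = fit_property(table, "dHf", order=order)
    print(f"  dHf MAE ({order} order): {mae(model, table):.3f} kJ/mol")

model = fit_property(table, "dHf", order="second")
poly = fit_temperature_polynomials(model)
print(f"coefficient polynomial residuals (max): {max(poly.residuals.values()):.2e} kJ/mol")

big = name_to_molecule("5-tb-C9")  # 5-tert-butylnonane, C13
value = predict(big, poly, 400.0)
print(f"predicted dHf(5-tb-C9, 400 K) = {value:.2f} kJ/mol "
      "(out-of-training groups approximated)")
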