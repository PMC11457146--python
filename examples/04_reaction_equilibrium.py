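"""Gas- and adsorbed-phase hydroisomerization equilibrium of C6 isomers.

At reaction equilibrium every isomer of one formula has the same chemical
potential, so the gas-phase mole fractions are Boltzmann weights over
(G0 - H0(0 K))(T) + dHf(0 K).  Inside a zeolite at infinite dilution the
distribution is reweighted by the Henry coefficients (here illustrative
values of the magnitude typical for alkanes in MTW at 500 K).  Relative
selectivities are reported against the linear isomer, as is conventional.
"""

import numpy as np

from alkatherm import (
    adsorbed_distribution,
    gas_distribution,
    generate_synthetic_table,
    relative_selectivity,
    states_from_table,
)

table, _ = generate_synthetic_table(
    seed=5, n_max=6, temperatures=(0.0, 450.0, 500.0, 550.0),
    properties=("dHf", "G_minus_H0"),
)
states = [s for s in states_from_table(table, 500.0) if s.n_carbons == 6]
gas = gas_distribution(states, 500.0)

rng = np.random.default_rng(5)
henry = {s.name: float(rng.lognormal(-13, 1)) for s in states}  # mol/kg/Pa
ads = adsorbed_distribution(gas, henry)

print(f"{'isomer':<12} {'y_gas':>10} {'y_ads':>10} {'s_rel(ads)':>12}")
srel = relative_selectivity(ads, "n-C6")
for name, yg, ya, s in zip(gas.names, gas.mole_fractions, ads.mole_fractions, srel):
    print(f"{name:<12} {yg:>10.3e} {ya:>10.3e} {s:>12.3e}")
print(f"sums: gas {gas.mole_fractions.sum():.12f}, ads {ads.mole_fractions.sum():.12f}")
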