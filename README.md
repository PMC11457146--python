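# alkatherm

Group-contribution thermochemistry of branched alkanes, and the downstream
reaction-equilibrium analysis of zeolite-catalyzed hydroisomerization.

Experimental ideal-gas thermochemistry is essentially complete only up to
decane: tables list the Gibbs energy function (G° − H°(0 K)), the enthalpy
function (H° − H°(0 K)) and the formation quantities Δ<sub>f</sub>G°,
Δ<sub>f</sub>H° for every C1–C10 isomer on a temperature grid. Process and
catalyst design for catalytic dewaxing, sustainable aviation fuel and
lubricant production needs those properties for *longer*, highly branched
alkanes — where almost no data exist. `alkatherm` is for computational
chemists and chemical engineers who need to extrapolate that table and turn
it into equilibrium product distributions inside zeolites.

## What it computes

**Second-order group-contribution linear regression.** Each carbon is a
united atom (CH4, CH3, CH2, CH, C); a *second-order group* is a central
united atom plus the multiset of its neighbours, e.g. CH2(CH3)(CH). For a
property *y* at temperature *T*,

&nbsp;&nbsp;&nbsp;&nbsp;*y* = α₀ + Σ<sub>k</sub> α<sub>k</sub> x<sub>k</sub>,

where x<sub>k</sub> counts occurrences of group *k*. There are exactly 69
such groups for acyclic alkanes (4/10/20/35 for CH3/CH2/CH/C centers), plus
a special CH4 descriptor for methane; the C1–C10 training molecules exercise
46 descriptors. The regression is an SVD-based least squares fit at each
temperature separately; the coefficients are then refitted as quadratics
α<sub>k</sub>(T) = A + B·T + C·T². Groups that never occur below C11 are
approximated by a similar in-training group obtained by demoting one
neighbour at a time (C → CH → CH2 → CH3).

**Reaction equilibria.** Equating ideal-gas chemical potentials of all
isomers of one formula gives Boltzmann mole fractions with exponent
[(G° − H°(0 K))(T) + Δ<sub>f</sub>H°(0 K)]/RT; at infinite dilution in a
zeolite the adsorbed-phase distribution is the gas one reweighted by Henry
coefficients, x<sub>i</sub> ∝ K<sub>H,i</sub> y<sub>i</sub>. Selectivities
s<sub>i</sub> = y<sub>i</sub>/(1 − y<sub>i</sub>) and relative selectivities
s<sub>i</sub>/s<sub>ref</sub> complete the picture.

**Supporting machinery.** A carbon-only SMILES parser/writer with a
deterministic centroid-rooted canonical form; a shorthand-name grammar
(`n-C10`, `2,2,5-m-C7`, `3-e-2,2,4-m-C5`); enumeration of all constitutional
isomers (free trees with degree ≤ 4) with structural filters; and an
automated generator of RASPA2 molecule/force-field files with the complete
united-atom interaction lists (bonds, bends, torsions, intra-LJ pairs beyond
three bonds) needed to compute Henry coefficients by Monte Carlo.

## Worked example

```bash
python examples/03_fit_and_predict.py
```

```
training table: 40 isomers x 5 temperatures x 4 properties
  dHf MAE (first order): 26.379 kJ/mol
  dHf MAE (second order): 0.085 kJ/mol
coefficient polynomial residuals (max): 2.55e-01 kJ/mol
predicted dHf(5-tb-C9, 400 K) = -455.25 kJ/mol (out-of-training groups approximated)
```

The table here is synthetic group-additive C1–C8 data with 0.2 kJ/mol of
noise (`generate_synthetic_table`); real tabulated data are read with
`read_training_table` from tidy CSV or per-property spreadsheet worksheets.
The two MAE lines show why second-order groups matter: first-order counts
cannot see branching patterns, second-order counts nearly interpolate the
data. The last line predicts a C13 isomer — outside the training range —
with its unseen groups routed through the approximation map.

```bash
python examples/05_raspa_force_field.py
```

```
n-C14: 13 bonds, 12 bends, 11 torsions, 55 intra-LJ pairs -> 91 total
wrote: n-C14.def, pseudo_atoms.def, force_field_mixing_rules.def, force_field.def
first torsion line: 0 1 2 3 TRAPPE_DIHEDRAL 0 355.03 -68.19 791.32
```

The other examples cover isomer enumeration/filtering (`01`), the group
universe and approximation rule (`02`) and gas/adsorbed equilibria with
relative selectivities (`04`). A thin CLI exposes the same operations
(`alkatherm isomers|fit|predict|equilibrium|ffgen --help`).

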