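# Methods

## Molecular representation

Alkanes are acyclic and saturated, so a molecule is a free tree whose
vertices are united atoms; the type of a site (CH4, CH3, CH2, CH, C) is a
pure function of its degree and hydrogen counts follow as 2n + 2. Only
constitutional isomery is represented — stereocenters of branched alkanes
are deliberately ignored, as the thermochemical tables being modelled do not
resolve them either.

Canonical SMILES are produced without an external toolkit: the tree is
rooted at its centroid (for a bicentroid, at the vertex whose AHU-style
rooted signature is lexicographically smaller) and children are rendered in
(subtree size, signature) order, smallest first, the last child continuing
the chain. This gives a deterministic string, identical for isomorphic
graphs; it is *not* the same string rdkit would produce, but the test suite
checks that both canonicalizations induce the same equivalence classes.

The shorthand name grammar is `[locants-code-]* [n-]C<parent>`, with branch
codes `m, e, p, ip, b, ib, sb, tb, pe, ipe, neope, tpe` (all alkyl branches
to four carbons, plus the common five-carbon ones; five carbons is the hard
cap). Naming a graph picks the longest chain, then the orientation/chain
with the most substituents, then the lowest locants — the usual convention.
A molecule whose branch is outside the code table (possible from C12 up)
raises, and callers fall back to canonical SMILES; `IsomerSet.names()` does
this automatically.

## Group descriptors

A second-order group is (center type, neighbour-type multiset), written
`center(n1)(n2)...` with neighbours in the fixed order CH3 < CH2 < CH < C.
Enumerating all valence-consistent combinations gives 69 groups —
multisets of size 1, 2, 3, 4 over four types: 4 + 10 + 20 + 35. Methane has
no neighbours and carries the special descriptor `CH4`, kept outside the 69
but counted as a 70th descriptor column. Exhaustive enumeration shows that
exactly 45 of the 69 groups occur in C1–C10 molecules (a group's minimal
carbon count is 1 + |neighbours| + Σ completion costs, with cost 0/1/2/3
for CH3/CH2/CH/C neighbours, and the bound is attained by completing with
methyls); with CH4 that makes 46 descriptors spanned by the training set.

Groups absent from a training set are approximated by a nearby in-training
group: breadth-first search over single neighbour demotions
C → CH → CH2 → CH3, nearest hit first. Ties at equal depth are resolved by
demoting the lowest-valence demotable neighbour first (so a CH2 neighbour
becomes CH3 before a C neighbour becomes CH), then by generation order; if
no demotion path lands in-training the first-order center type is the
fallback. The rule reproduces the canonical example
C(C)(CH2)(CH2)(CH2) → C(C)(CH2)(CH2)(CH3), where both one-step candidates
exist in C1–C10 and the low-valence demotion is the conventional choice.
The default map can be overridden by a user CSV (`out_key,in_key`), since
any curated approximation list takes precedence over a reconstruction.

## Isomer enumeration

Constitutional isomers of CnH2n+2 are the unlabelled degree-≤4 free trees
on n vertices. Generation is delegated to `networkx.nonisomorphic_trees`
(Wright–Richmond–Odlyzko–McKay) with a degree filter; members are converted
to canonical SMILES and sorted, so the order is stable. C10 (75 isomers)
takes milliseconds, C14 (1858) well under a second; beyond ~C16 the
unconstrained tree count grows faster than the constrained one and a
dedicated degree-bounded generator would be the next step. Tests verify the
counts against an independent brute-force oracle (all Prüfer sequences,
bucketed by an independently coded tree certificate) for n ≤ 8.

Structural filters — maximum branch size, no geminal substitution, minimum
locant distance — operate on the same main-chain selection as naming, so
"branch" means what the name says it means.

## Regression

Ordinary least squares per property per temperature, solved by SVD with a
relative cutoff of 1e−10 (`numpy.linalg.lstsq`), returning the minimum-norm
solution under rank deficiency. Rank deficiency is structural, not
accidental: the identity #CH3 − #CH − 2·#C + 2·#CH4 = 2 holds for every
alkane, so the intercept column lies in the span of the count columns (and
further homogeneous identities link second-order counts). Consequences,
documented rather than fought:

* individual coefficients are identified only up to the null space; the
  minimum-norm representative is reported and is reproducible;
* *predictions* are unique and are what all quality metrics use;
* adding a constant to every training value shifts every prediction by that
  constant exactly, but spreads across coefficients rather than landing
  only on α₀ — the equivariance test asserts the prediction-level statement.

No regularization and no weighting. The MAE diagnostic averages
|prediction − table| over all isomers at all fitted temperatures by default
(a temperature subset can be passed).

Temperature dependence: each coefficient series α<sub>k</sub>(T) is refitted
independently as A + B·T + C·T². Because the minimum-norm solution is a
fixed linear map of the per-temperature target vector, planting exactly
quadratic-in-T data makes every coefficient exactly quadratic in T, which
the tests exploit for machine-precision recovery. The largest
|polynomial − coefficient| residual per key is stored so a non-quadratic
temperature dependence cannot pass silently. Predictions outside the fitted
temperature range warn and extrapolate the quadratic.

## Synthetic training data

`generate_synthetic_table` emulates the structure of the tabulated
ideal-gas properties: C1–C(n_max) isomers on a shared temperature grid,
four properties in kJ/mol, values generated *exactly* group-additively from
planted quadratic coefficient polynomials, plus optional i.i.d. Gaussian
noise. Defaults: per-group constants A ~ N(−20, 15) kJ/mol with
B ~ N(0, 0.05) kJ/(mol·K) and C ~ N(0, 5·10⁻⁵) kJ/(mol·K²) — magnitudes of
the same order as real per-group contributions and their temperature drift;
σ = 0 by default so the regression layer must reproduce the table to
machine precision. What the generator does *not* emulate: correlated
deviations from group additivity (real tables are not exactly additive —
that is precisely the residual the method accepts), anharmonic temperature
shapes beyond quadratic, and inter-property thermodynamic consistency
(G, H, and the formation quantities are drawn independently). Passing tests
therefore demonstrate correct recovery of additive structure and correct
plumbing, not the real-data MAE level, which requires the tabulated C1–C10
workbook as input.

## Equilibrium layer

Gas phase: mole fractions are Boltzmann weights with exponent
[(G° − H°(0 K))(T) + Δ<sub>f</sub>H°(0 K)]/RT. This reduced form is what
equating full ideal-gas chemical potentials of equal-formula isomers leaves
after the atomization-energy and density terms cancel; the full
μ(T, ρ) = μ_ref + RT ln(ρ/ρ₀) form is exposed with ρ₀ = 1 molecule/Å³ for
completeness, and the atomization energy D₀ = a_C·711.185 + a_H·216.035 −
Δ<sub>f</sub>H°(0 K) kJ/mol uses overridable atomic constants.
R = 8.314462618 J/(mol·K). Weights are evaluated through a log-sum-exp
shift, so distributions are identical (≤1e−12) under any uniform exponent
shift and normalize to 1 within 1e−12 even when raw weights span hundreds
of orders of magnitude. Mixed formulas, non-positive temperatures and
non-finite inputs are rejected rather than silently saturated.

Adsorbed phase: Henry's-law reweighting of the gas distribution, valid at
infinite dilution; the intended regime is ≥500 K where pressure effects on
the distribution are negligible. Finite-loading mixture adsorption (IAST)
and the alkene/carbenium elementary steps of the actual catalytic cycle are
out of scope; the isomer family is treated as directly interconverting.
Henry coefficients are inputs (mol·kg⁻¹·Pa⁻¹, strictly positive), normally
produced by CBMC/Widom simulations with the files from the force-field
generator.

## Force-field generation

Interaction enumeration on the united-atom tree: bonds are edges; bends are
neighbour pairs at each center (Σ d(d−1)/2); torsions are simple 3-edge
paths, canonicalized against reversal; intramolecular Lennard-Jones applies
to pairs separated by *more than three* bonds (1–5 and beyond, no scaled
1–4 term). That exclusion convention is the one that makes the linear-chain
census (n−1) + (n−2) + (n−3) + (n−3)(n−4)/2 — 91 for n-C14 — and it
partitions all C(n,2) pairs together with the ≤3-bond neighbourhood.

Parameters ship as editable CSVs: the united-atom alkane Lennard-Jones set
of Dubbeldam et al. (CH4 158.5 K/3.72 Å … C 0.8 K/6.38 Å), TraPPE-zeo Si/O
for the framework, harmonic stretch (96500 K/Å², 1.54 Å), per-center
harmonic bends and TraPPE cosine-series torsions keyed by the middle atom
pair. Nothing is hard-coded as ground truth; tests only require that every
enumerated interaction resolves and that writers are deterministic. Files
target the RASPA2 dialect (molecule `.def`, `pseudo_atoms.def`,
`force_field_mixing_rules.def` with shifted-at-12-Å/no-tail-corrections,
`force_field.def`), and the n-C14 golden file in `tests/data` was produced
by this generator and audited once by hand. Coulomb terms are omitted
throughout — alkanes are nonpolar.

## Problem sizes and tolerances

Default test problem sizes: synthetic tables to C7 (noise studies to C6,
rank-agreement study to C10), property tests on 500 random trees of ≤12
sites, brute-force oracles to n = 8. Machine-precision claims use 1e−8
kJ/mol (regression recovery) and 1e−12 (normalization/invariance); both are
far below any physically meaningful scale and far above float64 noise for
these problem sizes. The Spearman rank-agreement threshold between
table-based and model-based C10 distributions is 0.99 on 75 isomers.

## Known limitations

* The shorthand-name writer covers branches to five carbons only; beyond
  that SMILES is the interchange format (the parser side has no such limit
  other than branch codes).
* First-order fits share the rank-deficiency caveat above; comparing raw
  coefficient values between fits of different orders is meaningless —
  compare predictions.
* The approximation rule is a reconstruction of a convention from a single
  published example; a curated map should be supplied via CSV when
  available.
* Extrapolation beyond the fitted temperature range and beyond ~C20 in
  chain length is mechanically possible but scientifically unsupported.
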