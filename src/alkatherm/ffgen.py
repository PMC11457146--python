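"""United-atom interaction enumeration and RASPA2 input-file generation.

Configurational-bias Monte Carlo of an alkane needs the complete list of its
intramolecular interactions.  For a united-atom chain these are

* **bonds** — every edge of the carbon tree (rigid or harmonic stretch),
* **bends** — every pair of bonds sharing a central site,
* **torsions** — every simple path of three consecutive bonds,
* **intramolecular Lennard-Jones pairs** — every pair of sites separated by
  *more than three bonds* (1-5 and beyond; no scaled 1-4 LJ term).

For linear C_n the counts are n-1, n-2, n-3 and (n-3)(n-4)/2, e.g. 91 in
total for n-tetradecane (13 + 12 + 11 + 55).  The pair convention matters:
pairs within three bonds are handled by the bonded terms, so the bonded
neighbourhood and the intra-LJ list partition all C(n,2) site pairs.

Nonbonded parameters default to the united-atom alkane set of Dubbeldam et
al. and the TraPPE-zeo set for zeolite frameworks (Coulomb terms are
omitted: alkanes are nonpolar); bonded constants follow the TraPPE-family
conventions.  All of them ship as editable CSVs next to this module — none
are hard-coded.  Lennard-Jones interactions are written truncated and
shifted at 12 A without tail corrections, matching common zeolite-adsorption
practice.  The writers target the RASPA2 file dialect and produce
byte-identical output for identical input.
"""

from __future__ import annotations

import csv
from collections import deque
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .molecule import Molecule

__all__ = [
    "InteractionList",
    "ParameterSet",
    "enumerate_interactions",
    "write_raspa_files",
    "RASPA_DIALECT",
]

#: Output dialect of the file writers.
RASPA_DIALECT = "raspa2"

#: Graph distance (in bonds) beyond which a site pair interacts through
#: intramolecular Lennard-Jones: strictly more than three bonds.
LJ_EXCLUSION_BONDS = 3


@dataclass(frozen=True)
class InteractionList:
    """Complete intramolecular interaction lists of one molecule."""

    bonds: tuple[tuple[int, int], ...]
    bends: tuple[tuple[int, int, int], ...]
    torsions: tuple[tuple[int, int, int, int], ...]
    intra_lj: tuple[tuple[int, int], ...]

    @property
    def total(self) -> int:
        return (
            len(self.bonds) + len(self.bends) + len(self.torsions) + len(self.intra_lj)
        )


def _distances_from(m: Molecule, source: int) -> list[int]:
    dist = [-1] * m.n_carbons
    dist[source] = 0
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in m.neighbors(v):
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def enumerate_interactions(m: Molecule) -> InteractionList:
    """Enumerate bonds, bends, torsions and intra-LJ pairs of a molecule.

    All lists are duplicate-free and deterministically ordered.  Bends are
    ``(i, j, k)`` with *j* the central site and ``i < k``; torsions
    ``(i, j, k, l)`` run along a 3-bond path and are canonicalized against
    reversal.
    """
    bonds = tuple(m.bonds)
    bends = []
    for j in range(m.n_carbons):
        nbrs = sorted(m.neighbors(j))
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                bends.append((nbrs[a], j, nbrs[b]))
    torsions = set()
    for j, k in bonds:
        for i in m.neighbors(j):
            if i == k:
                continue
            for l in m.neighbors(k):
                if l == j:
                    continue
                quad = (i, j, k, l)
                torsions.add(min(quad, quad[::-1]))
    intra_lj = []
    for i in range(m.n_carbons):
        dist = _distances_from(m, i)
        for j in range(i + 1, m.n_carbons):
            if dist[j] > LJ_EXCLUSION_BONDS:
                intra_lj.append((i, j))
    return InteractionList(
        bonds=bonds,
        bends=tuple(sorted(bends)),
        torsions=tuple(sorted(torsions)),
        intra_lj=tuple(intra_lj),
    )


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


def _read_csv_rows(path: Path | None, package_name: str | None) -> list[dict]:
    if path is not None:
        text = Path(path).read_text()
    else:
        text = (
            resources.files("alkatherm").joinpath(f"data/{package_name}").read_text()
        )
    return list(csv.DictReader(text.splitlines()))


@dataclass
class ParameterSet:
    """Force-field parameters resolving every enumerated interaction.

    ``lj`` maps a united-atom (or zeolite) type to ``(epsilon/kB [K],
    sigma [A])``; ``bond`` is a single (style, k, r0) stretch entry applied
    to every C-C bond; ``bends`` maps the central type to (style, k, theta0);
    ``torsions`` maps the unordered pair of middle types to a cosine-series
    style with four constants (in K).
    """

    lj: dict[str, tuple[float, float]]
    bond: tuple[str, float, float]
    bends: dict[str, tuple[str, float, float]]
    torsions: dict[frozenset, tuple[str, tuple[float, float, float, float]]]
    charges: dict[str, float] = field(default_factory=dict)
    cutoff: float = 12.0
    truncation: str = "shifted"
    tail_corrections: bool = False

    @classmethod
    def default(cls) -> "ParameterSet":
        """Load the packaged CSV defaults (Dubbeldam alkanes + TraPPE-zeo)."""
        return cls.from_csv()

    @classmethod
    def from_csv(
        cls,
        lj_path: str | Path | None = None,
        bonded_path: str | Path | None = None,
    ) -> "ParameterSet":
        lj_rows = _read_csv_rows(
            Path(lj_path) if lj_path else None, "lj_params.csv"
        )
        bonded_rows = _read_csv_rows(
            Path(bonded_path) if bonded_path else None, "bonded_params.csv"
        )
        lj = {}
        charges = {}
        for row in lj_rows:
            lj[row["type"]] = (float(row["epsilon_K"]), float(row["sigma_A"]))
            charges[row["type"]] = float(row.get("charge", 0) or 0)
        bond = None
        bends: dict[str, tuple[str, float, float]] = {}
        torsions: dict[frozenset, tuple[str, tuple[float, ...]]] = {}
        for row in bonded_rows:
            cls_name = row["class"]
            style = row["style"]
            if cls_name == "bond":
                bond = (style, float(row["p1"]), float(row["p2"]))
            elif cls_name == "bend":
                center = row["pattern"].split("-")[1]
                bends[center] = (style, float(row["p1"]), float(row["p2"]))
            elif cls_name == "torsion":
                mid = frozenset(row["pattern"].split("-")[1:3])
                torsions[mid] = (
                    style,
                    tuple(float(row[f"p{i}"]) for i in range(1, 5)),
                )
            else:
                raise ValueError(f"unknown bonded parameter class {cls_name!r}")
        if bond is None:
            raise ValueError("bonded parameter file defines no bond stretch entry")
        for eps, sig in lj.values():
            if eps < 0 or sig <= 0:
                raise ValueError("Lennard-Jones parameters must be positive")
        return cls(lj=lj, bond=bond, bends=bends, torsions=torsions, charges=charges)

    # -- resolution --------------------------------------------------------

    def lj_for(self, atom_type: str) -> tuple[float, float]:
        try:
            return self.lj[atom_type]
        except KeyError:
            raise KeyError(f"no Lennard-Jones parameters for type {atom_type!r}") from None

    def bend_for(self, center_type: str) -> tuple[str, float, float]:
        try:
            return self.bends[center_type]
        except KeyError:
            raise KeyError(f"no bend parameters for center {center_type!r}") from None

    def torsion_for(self, type_j: str, type_k: str):
        key = frozenset((type_j, type_k))
        try:
            return self.torsions[key]
        except KeyError:
            raise KeyError(
                f"no torsion parameters for middle pair {type_j}-{type_k}"
            ) from None


# ---------------------------------------------------------------------------
# RASPA2 writers
# ---------------------------------------------------------------------------


def _molecule_def(m: Molecule, inter: InteractionList, params: ParameterSet) -> str:
    types = m.atom_types
    lines = [
        "# critical constants: Critical Temperature [T], Critical Pressure [Pa],"
        " and Acentric factor [-]",
        "0.0",
        "0.0",
        "0.0",
        "# Number Of Atoms",
        str(m.n_carbons),
        "# Number Of Groups",
        "1",
        "# Alkane-group",
        "flexible",
        "# number of atoms",
        str(m.n_carbons),
        "# atomic positions",
    ]
    for i, t in enumerate(types):
        lines.append(f"{i} {t}")
    lines.append(
        "# Chiral centers Bond  BondDipoles Bend  UrayBradley InvBend  Torsion"
        " Imp. Torsion Bond/Bond Stretch/Bend Bend/Bend Stretch/Torsion"
        " Bend/Torsion IntraVDW IntraCoulomb"
    )
    counts = [
        0,
        len(inter.bonds),
        0,
        len(inter.bends),
        0,
        0,
        len(inter.torsions),
        0,
        0,
        0,
        0,
        0,
        0,
        len(inter.intra_lj),
        0,
    ]
    lines.append(" ".join(str(c) for c in counts))
    if inter.bonds:
        style, k, r0 = params.bond
        lines.append("# Bond stretch: atom n1-n2, type, parameters")
        for a, b in inter.bonds:
            lines.append(f"{a} {b} {style} {k:g} {r0:g}")
    if inter.bends:
        lines.append("# Bond bending: atom n1-n2-n3, type, parameters")
        for a, b, c in inter.bends:
            style, k, theta0 = params.bend_for(types[b])
            lines.append(f"{a} {b} {c} {style} {k:g} {theta0:g}")
    if inter.torsions:
        lines.append("# Torsion: atom n1-n2-n3-n4, type, parameters")
        for a, b, c, d in inter.torsions:
            style, ps = params.torsion_for(types[b], types[c])
            lines.append(
                f"{a} {b} {c} {d} {style} " + " ".join(f"{p:g}" for p in ps)
            )
    if inter.intra_lj:
        lines.append("# Intra VDW: atom n1-n2")
        for a, b in inter.intra_lj:
            lines.append(f"{a} {b}")
    lines.append("# Number of config moves")
    lines.append("0")
    return "\n".join(lines) + "\n"


def _pseudo_atoms_def(params: ParameterSet) -> str:
    types = sorted(params.lj)
    lines = [
        "#number of pseudo atoms",
        str(len(types)),
        "#type      print   as    chem  oxidation   mass        charge"
        "   polarization B-factor radii  connectivity anisotropic"
        " anisotropic-type   tinker-type",
    ]
    masses = {"CH4": 16.04246, "CH3": 15.03452, "CH2": 14.02658, "CH": 13.01864,
              "C": 12.0107, "Si": 28.0855, "O": 15.9994}
    for t in types:
        mass = masses.get(t, 0.0)
        charge = params.charges.get(t, 0.0)
        chem = "Si" if t == "Si" else ("O" if t == "O" else "C")
        lines.append(
            f"{t:<10} yes {chem:>5} {chem:>5} 0 {mass:>10.5f} {charge:>8.4f}"
            f" 0.0 1.0 1.0 0 0 relative 0"
        )
    return "\n".join(lines) + "\n"


def _mixing_rules_def(params: ParameterSet) -> str:
    types = sorted(params.lj)
    lines = [
        "# general rule for shifted vs truncated",
        params.truncation,
        "# general rule tailcorrections",
        "yes" if params.tail_corrections else "no",
        "# number of defined interactions",
        str(len(types)),
        "# type interaction, parameters.  IMPORTANT: define shortest matches"
        " first, so that more specific ones overwrites these",
    ]
    for t in types:
        eps, sig = params.lj_for(t)
        lines.append(f"{t:<10} lennard-jones {eps:g} {sig:g}")
    lines += [
        "# general mixing rule for Lennard-Jones",
        "Lorentz-Berthelot",
    ]
    return "\n".join(lines) + "\n"


def _force_field_def(params: ParameterSet) -> str:
    return "\n".join(
        [
            "# rules to overwrite",
            "0",
            "# number of defined interactions",
            "0",
            "# mixing rules to overwrite",
            "0",
        ]
    ) + "\n"


def write_raspa_files(
    m: Molecule,
    params: ParameterSet | None = None,
    outdir: str | Path = ".",
    name: str | None = None,
) -> list[Path]:
    """Write the RASPA2 molecule definition and force-field files.

    Produces ``<name>.def`` (the flexible molecule with its full interaction
    lists), ``pseudo_atoms.def``, ``force_field_mixing_rules.def`` and
    ``force_field.def`` in ``outdir``.  Output is deterministic: rewriting
    the same molecule yields byte-identical files.
    """
    if params is None:
        params = ParameterSet.default()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name is None:
        name = m.label or m.canonical_smiles
    inter = enumerate_interactions(m)
    files = {
        f"{name}.def": _molecule_def(m, inter, params),
        "pseudo_atoms.def": _pseudo_atoms_def(params),
        "force_field_mixing_rules.def": _mixing_rules_def(params),
        "force_field.def": _force_field_def(params),
    }
    written = []
    for fname, text in files.items():
        path = outdir / fname
        path.write_text(text)
        written.append(path)
    return written
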