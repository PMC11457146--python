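"""United-atom graphs for branched alkanes.

An acyclic alkane :math:`\\mathrm{C}_n\\mathrm{H}_{2n+2}` is represented as a
free tree whose vertices are united-atom sites (a carbon together with its
implicit hydrogens).  The site type is a pure function of the vertex degree:

====== ======
degree  type
====== ======
0       CH4
1       CH3
2       CH2
3       CH
4       C
====== ======

Only constitutional isomery matters here: no stereochemistry, no rings, no
heteroatoms.  Three interchangeable encodings are supported —

* a carbon-only acyclic SMILES subset (``CC(C)C`` …),
* a compact shorthand naming scheme (``n-C10``, ``2,2,5-m-C7``,
  ``3-e-2,2,4-m-C5`` …) with locants, branch codes and a parent chain, and
* the :class:`Molecule` graph itself.

The canonical SMILES writer roots the tree at its centroid and orders
subtrees by a recursively defined signature, so equal graphs always render
to the same string without any external toolkit.
"""

from __future__ import annotations

import re
from functools import cached_property
from typing import Iterable, Sequence

__all__ = [
    "Molecule",
    "MoleculeError",
    "SmilesError",
    "NameError_",
    "NamingError",
    "UA_TYPES",
    "atom_type_for_degree",
    "parse_smiles",
    "write_smiles",
    "name_to_molecule",
    "molecule_to_name",
    "branch_profile",
    "BRANCH_CODES",
]

#: United-atom site types in the fixed sort order used throughout the package.
UA_TYPES = ("CH3", "CH2", "CH", "C")

_TYPE_BY_DEGREE = {0: "CH4", 1: "CH3", 2: "CH2", 3: "CH", 4: "C"}


class MoleculeError(ValueError):
    """An invalid united-atom graph (cycle, degree > 4, disconnected...)."""


class SmilesError(MoleculeError):
    """Malformed or out-of-subset SMILES input."""


class NamingError(MoleculeError):
    """A shorthand name that cannot be parsed or produced."""


# backwards-compatible aliases
NameError_ = NamingError


def atom_type_for_degree(degree: int) -> str:
    """Map a site's degree to its united-atom type (0→CH4 ... 4→C)."""
    try:
        return _TYPE_BY_DEGREE[degree]
    except KeyError:  # pragma: no cover - guarded by Molecule validation
        raise MoleculeError(f"carbon degree {degree} exceeds 4") from None


class Molecule:
    """A branched alkane as a tree of united-atom carbon sites.

    Parameters
    ----------
    bonds
        Unordered pairs of site indices.  Indices must cover ``0..n-1``.
    n_atoms
        Number of sites.  Required for methane (no bonds); otherwise inferred
        as ``max(index) + 1``.
    label
        Optional display name carried through pipelines (not part of graph
        identity).
    """

    def __init__(
        self,
        bonds: Iterable[tuple[int, int]] = (),
        n_atoms: int | None = None,
        label: str | None = None,
    ):
        bond_list = [tuple(sorted((int(a), int(b)))) for a, b in bonds]
        if n_atoms is None:
            if not bond_list:
                raise MoleculeError("n_atoms is required when there are no bonds")
            n_atoms = max(max(b) for b in bond_list) + 1
        n_atoms = int(n_atoms)
        if n_atoms < 1:
            raise MoleculeError("a molecule needs at least one carbon")
        adj: list[set[int]] = [set() for _ in range(n_atoms)]
        for a, b in bond_list:
            if a == b:
                raise MoleculeError(f"self-bond on site {a}")
            if not (0 <= a < n_atoms and 0 <= b < n_atoms):
                raise MoleculeError(f"bond ({a},{b}) outside 0..{n_atoms - 1}")
            if b in adj[a]:
                raise MoleculeError(f"duplicate bond ({a},{b})")
            adj[a].add(b)
            adj[b].add(a)
        if len(bond_list) != n_atoms - 1:
            raise MoleculeError(
                f"{len(bond_list)} bonds on {n_atoms} sites: not a tree"
            )
        for i, nbrs in enumerate(adj):
            if len(nbrs) > 4:
                raise MoleculeError(f"site {i} has degree {len(nbrs)} > 4")
        # connectivity (tree edge count alone does not rule out cycle+island)
        if n_atoms > 1:
            seen = {0}
            stack = [0]
            while stack:
                v = stack.pop()
                for w in adj[v]:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            if len(seen) != n_atoms:
                raise MoleculeError("graph is disconnected")
        self._adj: tuple[frozenset[int], ...] = tuple(frozenset(s) for s in adj)
        self.label = label

    # -- basic structure ---------------------------------------------------

    @property
    def n_carbons(self) -> int:
        return len(self._adj)

    @property
    def n_hydrogens(self) -> int:
        return 2 * self.n_carbons + 2

    @property
    def bonds(self) -> list[tuple[int, int]]:
        return sorted(
            (i, j) for i, nbrs in enumerate(self._adj) for j in nbrs if i < j
        )

    def neighbors(self, i: int) -> frozenset[int]:
        return self._adj[i]

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    @cached_property
    def atom_types(self) -> tuple[str, ...]:
        return tuple(atom_type_for_degree(len(n)) for n in self._adj)

    def to_networkx(self):
        """Export as a :class:`networkx.Graph` with ``atom_type`` node data."""
        import networkx as nx

        g = nx.Graph()
        for i, t in enumerate(self.atom_types):
            g.add_node(i, atom_type=t)
        g.add_edges_from(self.bonds)
        return g

    # -- identity ----------------------------------------------------------

    @cached_property
    def canonical_smiles(self) -> str:
        return write_smiles(self)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Molecule):
            return NotImplemented
        return self.canonical_smiles == other.canonical_smiles

    def __hash__(self) -> int:
        return hash(self.canonical_smiles)

    def __repr__(self) -> str:
        lbl = f", label={self.label!r}" if self.label else ""
        return f"Molecule({self.canonical_smiles!r}{lbl})"


# ---------------------------------------------------------------------------
# SMILES
# ---------------------------------------------------------------------------


def parse_smiles(s: str) -> Molecule:
    """Parse an acyclic, carbon-only SMILES string into a :class:`Molecule`.

    Accepted tokens are ``C``, parentheses and whitespace.  Ring-closure
    digits, heteroatoms, charges, explicit hydrogens and bond symbols are all
    rejected — the subset is exactly what saturated acyclic hydrocarbons need.
    """
    bonds: list[tuple[int, int]] = []
    stack: list[int] = []
    current: int | None = None
    n = 0
    for pos, ch in enumerate(s):
        if ch.isspace():
            continue
        if ch == "C":
            idx = n
            n += 1
            if current is not None:
                bonds.append((current, idx))
            current = idx
        elif ch == "(":
            if current is None:
                raise SmilesError(f"branch opened before any atom at position {pos}")
            stack.append(current)
        elif ch == ")":
            if not stack:
                raise SmilesError(f"unmatched ')' at position {pos}")
            current = stack.pop()
        elif ch.isdigit() or ch == "%":
            raise SmilesError("ring closures are not supported for acyclic alkanes")
        else:
            raise SmilesError(f"unsupported SMILES token {ch!r} at position {pos}")
    if stack:
        raise SmilesError("unmatched '(' in SMILES")
    if n == 0:
        raise SmilesError("empty SMILES")
    try:
        return Molecule(bonds, n_atoms=n)
    except MoleculeError as exc:
        raise SmilesError(str(exc)) from None


def _rooted_signature(adj: Sequence[frozenset[int]], root: int, parent: int) -> str:
    """AHU-style canonical signature of the subtree at `root` away from `parent`."""
    children = sorted(
        (_rooted_signature(adj, c, root) for c in adj[root] if c != parent)
    )
    return "(" + "".join(children) + ")"


def _centroids(adj: Sequence[frozenset[int]]) -> list[int]:
    """Centroid(s) of a tree by iterative leaf stripping (1 or 2 vertices)."""
    n = len(adj)
    if n == 1:
        return [0]
    degree = [len(a) for a in adj]
    layer = [i for i in range(n) if degree[i] == 1]
    remaining = n
    while remaining > 2:
        remaining -= len(layer)
        nxt = []
        for leaf in layer:
            for w in adj[leaf]:
                degree[w] -= 1
                if degree[w] == 1:
                    nxt.append(w)
        layer = nxt
    return sorted(layer)


def _render(adj: Sequence[frozenset[int]], root: int, parent: int) -> str:
    children = sorted(
        (c for c in adj[root] if c != parent),
        key=lambda c: (_subtree_size(adj, c, root), _rooted_signature(adj, c, root)),
    )
    out = "C"
    for c in children[:-1]:
        out += "(" + _render(adj, c, root) + ")"
    if children:
        out += _render(adj, children[-1], root)
    return out


def _subtree_size(adj: Sequence[frozenset[int]], root: int, parent: int) -> int:
    total = 1
    for c in adj[root]:
        if c != parent:
            total += _subtree_size(adj, c, root)
    return total


def write_smiles(m: Molecule) -> str:
    """Canonical SMILES for a molecule.

    The tree is rooted at its centroid (for a bicentroid, the vertex whose
    rooted signature is smaller) and children are rendered smallest subtree
    first, so isomorphic graphs always produce the same string and the main
    chain reads left to right.
    """
    adj = m._adj
    cands = _centroids(adj)
    root = min(cands, key=lambda r: _rooted_signature(adj, r, -1))
    return _render(adj, root, -1)


# ---------------------------------------------------------------------------
# Shorthand names
# ---------------------------------------------------------------------------

#: Branch codes of the shorthand grammar.  Each maps to a SMILES fragment
#: whose first atom is the attachment point.  All alkyl branches up to four
#: carbons are covered, plus the common five-carbon ones.
BRANCH_CODES: dict[str, str] = {
    "m": "C",  # methyl
    "e": "CC",  # ethyl
    "p": "CCC",  # n-propyl
    "ip": "C(C)C",  # isopropyl
    "b": "CCCC",  # n-butyl
    "ib": "CC(C)C",  # isobutyl
    "sb": "C(C)CC",  # sec-butyl
    "tb": "C(C)(C)C",  # tert-butyl
    "pe": "CCCCC",  # n-pentyl
    "ipe": "CCC(C)C",  # isopentyl (3-methylbutyl)
    "neope": "CC(C)(C)C",  # neopentyl (2,2-dimethylpropyl)
    "tpe": "C(C)(C)CC",  # tert-pentyl (1,1-dimethylpropyl)
}

_MAX_BRANCH_CARBONS = 5

_PARENT_RE = re.compile(r"^C(\d+)$")
_LOCANTS_RE = re.compile(r"^\d+(,\d+)*$")


def _branch_fragment(code: str) -> Molecule:
    return parse_smiles(BRANCH_CODES[code])


def _code_signature(code: str) -> str:
    """Rooted signature of a branch fragment, as seen from the parent chain."""
    frag = _branch_fragment(code)
    return _rooted_signature(frag._adj, 0, -1)


_SIG_TO_CODE: dict[str, str] = {}


def _sig_to_code() -> dict[str, str]:
    if not _SIG_TO_CODE:
        for code in BRANCH_CODES:
            _SIG_TO_CODE[_code_signature(code)] = code
    return _SIG_TO_CODE


def name_to_molecule(name: str) -> Molecule:
    """Build a molecule from a shorthand name like ``2,2,5-m-C7``.

    Grammar: zero or more ``<locants>-<code>-`` branch specifications followed
    by the parent ``C<n>`` (an optional leading ``n-`` marks the unbranched
    chain).  Locants are 1-based positions on the parent chain; branch codes
    are listed in :data:`BRANCH_CODES` and never exceed five carbons.
    """
    tokens = [t for t in name.strip().split("-") if t]
    if not tokens:
        raise NamingError(f"empty name {name!r}")
    parent_tok = tokens[-1]
    match = _PARENT_RE.match(parent_tok)
    if match is None:
        raise NamingError(f"missing parent chain 'C<n>' in {name!r}")
    parent_len = int(match.group(1))
    if parent_len < 1:
        raise NamingError(f"parent chain length must be >= 1 in {name!r}")
    body = tokens[:-1]
    if body and body[-1] == "n":
        if len(body) > 1:
            raise NamingError(f"'n-' cannot be combined with branches in {name!r}")
        body = []
    if len(body) % 2:
        raise NamingError(f"unpaired locants/branch-code tokens in {name!r}")

    bonds = [(i, i + 1) for i in range(parent_len - 1)]
    n = parent_len
    for loc_tok, code in zip(body[0::2], body[1::2]):
        if not _LOCANTS_RE.match(loc_tok):
            raise NamingError(f"bad locant list {loc_tok!r} in {name!r}")
        if code not in BRANCH_CODES:
            raise NamingError(f"unknown branch code {code!r} in {name!r}")
        frag = _branch_fragment(code)
        for loc in (int(t) for t in loc_tok.split(",")):
            if not 1 <= loc <= parent_len:
                raise NamingError(
                    f"locant {loc} outside parent chain C{parent_len} in {name!r}"
                )
            offset = n
            for a, b in frag.bonds:
                bonds.append((a + offset, b + offset))
            bonds.append((loc - 1, offset))
            n += frag.n_carbons
    try:
        mol = Molecule(bonds, n_atoms=n, label=name)
    except MoleculeError as exc:
        raise NamingError(f"{name!r}: {exc}") from None
    return mol


def _collect_subtree(adj: Sequence[frozenset[int]], root: int, parent: int) -> list[int]:
    out = [root]
    stack = [(root, parent)]
    while stack:
        v, p = stack.pop()
        for w in adj[v]:
            if w != p:
                out.append(w)
                stack.append((w, v))
    return out


def _longest_paths(m: Molecule) -> list[list[int]]:
    """All maximum-length leaf-to-leaf paths (each listed in one direction)."""
    adj = m._adj
    n = m.n_carbons
    if n == 1:
        return [[0]]
    leaves = [i for i in range(n) if len(adj[i]) == 1]

    def path(u: int, v: int) -> list[int]:
        prev = {u: -1}
        stack = [u]
        while stack:
            x = stack.pop()
            if x == v:
                break
            for w in adj[x]:
                if w not in prev:
                    prev[w] = x
                    stack.append(w)
        out = [v]
        while out[-1] != u:
            out.append(prev[out[-1]])
        return out[::-1]

    best: list[list[int]] = []
    best_len = 0
    for i, u in enumerate(leaves):
        for v in leaves[i + 1 :]:
            p = path(u, v)
            if len(p) > best_len:
                best, best_len = [p], len(p)
            elif len(p) == best_len:
                best.append(p)
    return best


def _chain_branches(m: Molecule, chain: list[int]) -> list[tuple[int, int]]:
    """Branches off a main chain as ``(locant, branch root site)`` pairs."""
    on_chain = set(chain)
    out = []
    for pos, atom in enumerate(chain, start=1):
        prev_on = chain[pos - 2] if pos >= 2 else None
        next_on = chain[pos] if pos < len(chain) else None
        for nb in sorted(m._adj[atom]):
            if nb != prev_on and nb != next_on:
                if nb in on_chain:  # pragma: no cover - impossible in a tree
                    raise MoleculeError("chain revisits itself")
                out.append((pos, nb))
    return out


def branch_profile(m: Molecule) -> tuple[int, list[tuple[int, int]]]:
    """Main-chain length and ``(locant, branch size)`` list for a molecule.

    The main chain is a longest path; among equal-length candidates (and the
    two orientations of each) the one carrying the most branches wins, then
    the lexicographically smallest sorted locant list — the usual
    most-substituents / lowest-locants naming convention.
    """
    best_key = None
    best: tuple[int, list[tuple[int, int]]] | None = None
    for path in _longest_paths(m):
        for chain in (path, path[::-1]):
            branches = _chain_branches(m, chain)
            sizes = [
                (loc, _subtree_size(m._adj, root, chain[loc - 1]))
                for loc, root in branches
            ]
            key = (-len(sizes), sorted(loc for loc, _ in sizes), sorted(sizes))
            if best_key is None or key < best_key:
                best_key, best = key, (len(chain), sizes)
    assert best is not None
    return best


def molecule_to_name(m: Molecule) -> str:
    """Shorthand name for a molecule (inverse of :func:`name_to_molecule`).

    Raises :class:`NamingError` when some branch off the main chain is not in
    the supported code table (callers typically fall back to SMILES then).
    """
    if m.n_carbons == 1 or all(d <= 2 for d in map(m.degree, range(m.n_carbons))):
        return f"n-C{m.n_carbons}"
    sig_to_code = _sig_to_code()
    candidates: list[tuple[tuple, str]] = []
    for path in _longest_paths(m):
        for chain in (path, path[::-1]):
            branches = _chain_branches(m, chain)
            coded = []
            ok = True
            for loc, root in branches:
                sig = _rooted_signature(m._adj, root, chain[loc - 1])
                code = sig_to_code.get(sig)
                if code is None:
                    ok = False
                    break
                coded.append((code, loc))
            if not ok:
                continue
            by_code: dict[str, list[int]] = {}
            for code, loc in coded:
                by_code.setdefault(code, []).append(loc)
            parts = [
                f"{','.join(str(l) for l in sorted(locs))}-{code}"
                for code, locs in sorted(by_code.items())
            ]
            name = "-".join(parts + [f"C{len(chain)}"])
            rank = (-len(coded), sorted(loc for _, loc in coded), name)
            candidates.append((rank, name))
    if not candidates:
        raise NamingError(
            f"no shorthand name for {m.canonical_smiles!r}: "
            f"a branch is outside the supported code table"
        )
    return min(candidates)[1]
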