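"""First- and second-order group descriptors for alkanes.

A *first-order* descriptor is simply the united-atom type of a site
(CH4, CH3, CH2, CH, C).  A *second-order* group is a central united atom
together with the multiset of its neighbours' types, written canonically as
``center(n1)(n2)...`` with the neighbours sorted CH3 < CH2 < CH < C, e.g.
``CH2(CH3)(CH)``.  Methane carries the special descriptor key ``CH4``.

Enumerating every valence-consistent (center, neighbour-multiset) pair gives
69 distinct groups: 4 with a CH3 center (multisets of size 1 from 4 types),
10 with CH2 (size 2), 20 with CH (size 3) and 35 with C (size 4).  Only a
subset of these occurs in small alkanes; groups that never appear in a
training set are mapped onto similar in-training groups by stepwise neighbour
"demotion" C → CH → CH2 → CH3 (see :func:`default_approximation`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

import numpy as np

from .molecule import Molecule, UA_TYPES

__all__ = [
    "SecondOrderGroup",
    "METHANE_KEY",
    "enumerate_group_universe",
    "count_groups",
    "default_approximation",
    "build_approximation_map",
    "build_descriptor_matrix",
    "group_key",
    "parse_group_key",
]

#: Descriptor key reserved for methane (a site with no neighbours).
METHANE_KEY = "CH4"

#: Fixed neighbour sort order used in canonical keys.
_TYPE_ORDER = {t: i for i, t in enumerate(UA_TYPES)}  # CH3 < CH2 < CH < C

_VALENCE = {"CH3": 1, "CH2": 2, "CH": 3, "C": 4}

#: One-step neighbour demotions used by the approximation rule.
_DEMOTE = {"C": "CH", "CH": "CH2", "CH2": "CH3"}


def group_key(center: str, neighbors: Iterable[str]) -> str:
    """Canonical text key ``center(n1)(n2)...`` for a second-order group."""
    ordered = sorted(neighbors, key=_TYPE_ORDER.__getitem__)
    return center + "".join(f"({t})" for t in ordered)


def parse_group_key(key: str) -> tuple[str, tuple[str, ...]]:
    """Split a canonical key back into (center, neighbour tuple)."""
    if key == METHANE_KEY:
        return METHANE_KEY, ()
    head, _, rest = key.partition("(")
    if head not in _VALENCE:
        raise ValueError(f"bad group key {key!r}")
    neighbors = tuple(t for t in rest.rstrip(")").split(")(") if t)
    if len(neighbors) != _VALENCE[head]:
        raise ValueError(f"group key {key!r} has wrong neighbour count")
    return head, neighbors


@dataclass(frozen=True)
class SecondOrderGroup:
    """A central united atom plus the multiset of its neighbour types."""

    center: str
    neighbors: tuple[str, ...]

    def __post_init__(self):
        if self.center not in _VALENCE:
            raise ValueError(f"invalid center {self.center!r}")
        if len(self.neighbors) != _VALENCE[self.center]:
            raise ValueError(
                f"{self.center} center needs {_VALENCE[self.center]} neighbours,"
                f" got {len(self.neighbors)}"
            )
        ordered = tuple(sorted(self.neighbors, key=_TYPE_ORDER.__getitem__))
        object.__setattr__(self, "neighbors", ordered)

    @property
    def key(self) -> str:
        return group_key(self.center, self.neighbors)

    @classmethod
    def from_key(cls, key: str) -> "SecondOrderGroup":
        center, neighbors = parse_group_key(key)
        return cls(center, neighbors)

    def __str__(self) -> str:
        return self.key


def enumerate_group_universe() -> list[SecondOrderGroup]:
    """All 69 second-order groups of acyclic alkanes (methane excluded).

    For each center type the neighbour multisets are the combinations with
    repetition of the four united-atom types, so the per-center counts are
    4, 10, 20 and 35 for CH3, CH2, CH and C respectively.
    """
    universe = []
    for center in UA_TYPES:
        for combo in combinations_with_replacement(UA_TYPES, _VALENCE[center]):
            universe.append(SecondOrderGroup(center, combo))
    return universe


def count_groups(m: Molecule, order: str = "second") -> dict[str, int]:
    """Descriptor vector of a molecule.

    ``order="first"`` counts united-atom types; ``order="second"`` counts one
    canonical second-order key per site.  Methane contributes the single key
    ``CH4`` in both cases.  The counts always sum to the number of carbons.
    """
    types = m.atom_types
    if order == "first":
        return dict(Counter(types))
    if order != "second":
        raise ValueError(f"order must be 'first' or 'second', got {order!r}")
    counts: Counter[str] = Counter()
    for i in range(m.n_carbons):
        nbrs = m.neighbors(i)
        if not nbrs:
            counts[METHANE_KEY] += 1
        else:
            counts[group_key(types[i], (types[j] for j in nbrs))] += 1
    return dict(counts)


def _demotion_successors(key: str) -> list[str]:
    """One-demotion neighbours of a group key, lowest-valence neighbour first.

    Demoting the least-substituted demotable neighbour first reproduces the
    convention that C(C)(CH2)(CH2)(CH2) is approximated by
    C(C)(CH2)(CH2)(CH3) rather than by CH-centred alternatives.
    """
    center, neighbors = parse_group_key(key)
    seen = set()
    out = []
    for t in sorted(set(neighbors) & set(_DEMOTE), key=_VALENCE.__getitem__):
        lst = list(neighbors)
        lst[lst.index(t)] = _DEMOTE[t]
        cand = group_key(center, lst)
        if cand not in seen:
            seen.add(cand)
            out.append(cand)
    return out


def default_approximation(group: SecondOrderGroup | str, training_universe) -> str:
    """Map an out-of-training group to a similar in-training key.

    Breadth-first search over single neighbour demotions C→CH→CH2→CH3; the
    nearest in-training key wins, with ties broken by demoting the
    lowest-valence neighbour first and then lexicographically.  If no
    demotion path reaches the training universe the first-order center type
    is returned as a last resort.
    """
    training = set(training_universe)
    if not training:
        raise ValueError("training universe is empty")
    key = group.key if isinstance(group, SecondOrderGroup) else group
    if key in training:
        return key
    frontier = [key]
    visited = {key}
    while frontier:
        nxt: list[str] = []
        for k in frontier:
            for cand in _demotion_successors(k):
                if cand in visited:
                    continue
                visited.add(cand)
                nxt.append(cand)
        hits = [k for k in nxt if k in training]
        if hits:
            # frontier order already encodes the demotion preference; the
            # first hit in generation order is the chosen image
            return hits[0]
        frontier = nxt
    return parse_group_key(key)[0]


def build_approximation_map(training_universe: Iterable[str]) -> dict[str, str]:
    """Total map from every out-of-training group of the 69-group universe
    onto an in-training key (identity is implied for in-training keys)."""
    training = {k for k in training_universe if k != METHANE_KEY}
    return {
        g.key: default_approximation(g, training)
        for g in enumerate_group_universe()
        if g.key not in training
    }


def apply_approximation(
    counts: Mapping[str, int], approximation: Mapping[str, str] | None
) -> dict[str, int]:
    """Re-key a descriptor vector through an approximation map."""
    if not approximation:
        return dict(counts)
    out: Counter[str] = Counter()
    for key, x in counts.items():
        out[approximation.get(key, key)] += x
    return dict(out)


def build_descriptor_matrix(
    molecules: Sequence[Molecule],
    order: str = "second",
    approximation: Mapping[str, str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Occurrence matrix (molecules x descriptor keys).

    Columns are the union of keys over all molecules after re-keying through
    ``approximation``, in sorted canonical-key order; entries are integer
    occurrence counts.  Row sums equal each molecule's carbon count.
    """
    if not molecules:
        raise ValueError("need at least one molecule")
    vectors = [
        apply_approximation(count_groups(m, order), approximation)
        for m in molecules
    ]
    keys = sorted({k for v in vectors for k in v})
    col = {k: j for j, k in enumerate(keys)}
    mat = np.zeros((len(molecules), len(keys)), dtype=np.int64)
    for i, v in enumerate(vectors):
        for k, x in v.items():
            mat[i, col[k]] = x
    return mat, keys
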