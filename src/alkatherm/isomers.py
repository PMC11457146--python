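"""Enumeration and filtering of alkane constitutional isomers.

The constitutional isomers of :math:`\\mathrm{C}_n\\mathrm{H}_{2n+2}` are the
unlabelled free trees on *n* vertices with maximum degree 4 (counting
1, 1, 1, 2, 3, 5, 9, 18, 35, 75 for n = 1..10).  Enumeration delegates the
free-tree generation to :func:`networkx.nonisomorphic_trees` (the
Wright-Richmond-Odlyzko-McKay algorithm) and keeps the degree-constrained
ones, so C14 (1858 isomers) takes well under a second; beyond ~C16 the
unconstrained tree count starts to dominate the cost.

Filtering implements the structural screens used to prune hydroisomerization
networks in narrow-pore zeolites: branches longer than a cutoff, geminal
(same-carbon) double substitution, and branches closer than a minimum locant
distance are all individually toggleable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx

from .molecule import Molecule, branch_profile, molecule_to_name

__all__ = ["IsomerSet", "enumerate_isomers", "filter_isomers"]

MAX_DEGREE = 4


@dataclass(frozen=True)
class IsomerSet:
    """All (or a filtered subset of) constitutional isomers of C_n H_2n+2."""

    n: int
    members: tuple[Molecule, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Molecule]:
        return iter(self.members)

    def smiles(self) -> list[str]:
        return [m.canonical_smiles for m in self.members]

    def names(self) -> list[str]:
        """Shorthand names, falling back to canonical SMILES where the branch
        code table does not cover a member."""
        out = []
        for m in self.members:
            try:
                out.append(molecule_to_name(m))
            except ValueError:
                out.append(m.canonical_smiles)
        return out


def enumerate_isomers(n: int) -> IsomerSet:
    """Every constitutional alkane isomer with ``n`` carbons.

    Members are deduplicated free trees with degree <= 4, ordered by their
    canonical SMILES, so the output is deterministic across runs.
    """
    if n < 1:
        raise ValueError(f"carbon count must be >= 1, got {n}")
    if n == 1:
        members = [Molecule((), n_atoms=1)]
    else:
        members = [
            Molecule(t.edges())
            for t in nx.nonisomorphic_trees(n)
            if max(d for _, d in t.degree()) <= MAX_DEGREE
        ]
    members.sort(key=lambda m: m.canonical_smiles)
    return IsomerSet(n=n, members=tuple(members))


def filter_isomers(
    s: IsomerSet,
    max_branch: int | None = None,
    no_geminal: bool = False,
    min_locant_distance: int | None = None,
) -> IsomerSet:
    """Subset of an isomer set passing structural screens.

    Parameters
    ----------
    max_branch
        Keep only isomers whose branches off the main chain have at most this
        many carbons (e.g. 1 = methyl only, 2 also allows ethyl).
    no_geminal
        Drop isomers with two branches on the same main-chain carbon.
    min_locant_distance
        Drop isomers with two branches whose locants differ by less than
        this (geminal pairs count as distance 0).

    Order is preserved; with no rules the set is returned unchanged.
    """
    if max_branch is None and not no_geminal and min_locant_distance is None:
        return s

    def keep(m: Molecule) -> bool:
        _, branches = branch_profile(m)
        if max_branch is not None and any(size > max_branch for _, size in branches):
            return False
        locants = sorted(loc for loc, _ in branches)
        if no_geminal and len(locants) != len(set(locants)):
            return False
        if min_locant_distance is not None:
            for a, b in zip(locants, locants[1:]):
                if b - a < min_locant_distance:
                    return False
        return True

    return IsomerSet(n=s.n, members=tuple(m for m in s.members if keep(m)))
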