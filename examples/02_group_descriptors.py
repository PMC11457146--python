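"""Second-order group universe, descriptor counting and the approximation rule.

A second-order group is a central united atom plus the multiset of its
neighbours' types: 69 such groups exist for acyclic alkanes.  Only 46
descriptors (45 alkane groups plus methane's CH4 key) occur in the C1-C10
training molecules; the rest, which first appear in longer chains, are
mapped onto similar in-training groups by demoting one neighbour at a time
(C -> CH -> CH2 -> CH3).
"""

from collections import Counter

from alkatherm import (
    count_groups,
    default_approximation,
    enumerate_group_universe,
    enumerate_isomers,
    name_to_molecule,
)

universe = enumerate_group_universe()
print("second-order group universe:", len(universe))
print("  per center:", dict(Counter(g.center for g in universe)))

training_keys = set()
for n in range(1, 11):
    for m in enumerate_isomers(n):
        training_keys |= set(count_groups(m, "second"))
print("descriptors occurring in C1-C10:", len(training_keys))

print("n-butane descriptors:", count_groups(name_to_molecule("n-C4")))
target = "C(C)(CH2)(CH2)(CH2)"  # quaternary carbon next to another, 3 chains
image = default_approximation(target, training_keys - {"CH4"})
print(f"out-of-training {target} is approximated by {image}")
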