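"""Enumerate alkane constitutional isomers and filter them structurally.

Builds the full C10 isomer family, prunes the branches that are too bulky to
form inside a narrow-pore zeolite, and shows the SMILES/shorthand naming
layer.  The counts are the classic alkane isomer series (75 at C10, 1858 at
C14); the filtered set is what a hydroisomerization network inside MTW would
realistically retain.
"""

from alkatherm import enumerate_isomers, filter_isomers, molecule_to_name, name_to_molecule

series = {n: len(enumerate_isomers(n)) for n in range(1, 11)}
print("isomer counts C1..C10:", list(series.values()))

c10 = enumerate_isomers(10)
slim = filter_isomers(c10, max_branch=2, no_geminal=True)
print(f"C10 isomers: {len(c10)}; after max-branch<=2 and no-geminal: {len(slim)}")

m = name_to_molecule("2,2,5-m-C7")
print("2,2,5-m-C7  ->", m.canonical_smiles, "->", molecule_to_name(m))
dropped = set(c10.names()) - set(slim.names())
print("examples of dropped isomers:", sorted(dropped)[:4])
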