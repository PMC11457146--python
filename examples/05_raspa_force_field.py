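"""Generate RASPA2 molecule/force-field input files for n-tetradecane.

A flexible united-atom alkane needs its complete intramolecular interaction
lists: bonds, bends, torsions and the Lennard-Jones pairs beyond three bonds.
For n-C14 that is 13 + 12 + 11 + 55 = 91 interactions — far too many to
type by hand, which is what this generator automates.  Files are written in
the RASPA2 dialect with LJ truncated and shifted at 12 A, no tail
corrections.
"""

from pathlib import Path

from alkatherm import enumerate_interactions, name_to_molecule, write_raspa_files

m = name_to_molecule("n-C14")
inter = enumerate_interactions(m)
print(f"n-C14: {len(inter.bonds)} bonds, {len(inter.bends)} bends, "
      f"{len(inter.torsions)} torsions, {len(inter.intra_lj)} intra-LJ pairs "
      f"-> {inter.total} total")

outdir = Path("scratch/ff-n-C14")
files = write_raspa_files(m, outdir=outdir, name="n-C14")
print("wrote:", ", ".join(f.name for f in files))
print("first torsion line:",
      next(l for l in (outdir / "n-C14.def").read_text().splitlines()
           if "TRAPPE_DIHEDRAL" in l))
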