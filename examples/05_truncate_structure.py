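"""Truncate a guanine nucleotide to its base and cap with hydrogen.

Excited-state QM models of nucleic acids drop the sugar-phosphate
backbone: it carries no transitions in the spectral window of interest
and dominates the cost.  The glycosidic C1'-N9 bond is cut and the
nitrogen capped with H at 1.01 A along the former bond direction.
The small PDB below is an idealized synthetic nucleotide, generated
for this demonstration (not a deposited structure).
"""

import tempfile
from pathlib import Path

import numpy as np

import ecdkit as ek

PDB = """\
ATOM      1  P    DG A   1      -4.000   2.000   0.500  1.00  0.00           P
ATOM      2  OP1  DG A   1      -4.800   3.100   0.900  1.00  0.00           O
ATOM      3  OP2  DG A   1      -4.500   0.700   0.100  1.00  0.00           O
ATOM      4  O5'  DG A   1      -2.900   2.400  -0.500  1.00  0.00           O
ATOM      5  C5'  DG A   1      -2.000   3.400  -0.200  1.00  0.00           C
ATOM      6  C4'  DG A   1      -1.000   3.300  -1.300  1.00  0.00           C
ATOM      7  O4'  DG A   1      -0.300   2.100  -1.200  1.00  0.00           O
ATOM      8  C3'  DG A   1      -1.600   3.200  -2.700  1.00  0.00           C
ATOM      9  O3'  DG A   1      -1.200   4.300  -3.500  1.00  0.00           O
ATOM     10  C2'  DG A   1      -1.000   1.900  -3.200  1.00  0.00           C
ATOM     11  C1'  DG A   1       0.100   1.600  -2.300  1.00  0.00           C
ATOM     12  N9   DG A   1       1.300   1.200  -2.900  1.00  0.00           N
ATOM     13  C8   DG A   1       1.500   0.400  -3.980  1.00  0.00           C
ATOM     14  N7   DG A   1       2.750   0.200  -4.300  1.00  0.00           N
ATOM     15  C5   DG A   1       3.480   0.900  -3.390  1.00  0.00           C
ATOM     16  C6   DG A   1       4.870   1.050  -3.250  1.00  0.00           C
ATOM     17  O6   DG A   1       5.750   0.520  -3.950  1.00  0.00           O
ATOM     18  N1   DG A   1       5.230   1.880  -2.220  1.00  0.00           N
ATOM     19  C2   DG A   1       4.340   2.510  -1.400  1.00  0.00           C
ATOM     20  N2   DG A   1       4.810   3.300  -0.430  1.00  0.00           N
ATOM     21  N3   DG A   1       3.020   2.390  -1.520  1.00  0.00           N
ATOM     22  C4   DG A   1       2.640   1.580  -2.520  1.00  0.00           C
END
"""

with tempfile.TemporaryDirectory() as tmp:
    pdb = Path(tmp) / "guanine.pdb"
    pdb.write_text(PDB)
    mol = ek.read_structure(pdb)

base, bonds = ek.strip_backbone(mol)
capped = ek.cap_with_hydrogens(base, bonds)
h = capped.atoms[-1]
n = bonds[0].base_atom
print(f"input atoms: {len(mol)}; base-only: {len(base)}; capped: {len(capped)}")
print(f"cut bond: C1'-{bonds[0].site} of residue {n.res_name} {n.res_seq}")
print(f"cap atom {h.name} at ({h.coords[0]:.3f}, {h.coords[1]:.3f}, {h.coords[2]:.3f}),"
      f" |N-H| = {np.linalg.norm(h.xyz - n.xyz):.3f} A")
print("22 atoms -> 11 base atoms + 1 cap hydrogen; phosphate and sugar gone.")
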