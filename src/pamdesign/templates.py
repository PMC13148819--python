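"""Embedded geometry and physics tables.

Everything the package needs to build heavy-atom structures is defined
here, in-repo, with no downloads:

* internal-coordinate (NeRF) build recipes for the 20 amino-acid side
  chains, with chi dihedrals as the free variables;
* recipes for the nucleobases, built from the sugar frame (C2', O4', C1')
  with a fixed anti glycosidic torsion, so threading a new base onto an
  existing sugar-phosphate backbone never moves a backbone atom;
* an idealized, helically symmetric B-form sugar-phosphate backbone
  template (rise 3.38 A, twist 36 deg/bp) derived once by least-squares
  against standard bond lengths/angles and frozen here;
* van der Waals radii and well depths, a small partial-charge table, and
  hydrogen-bond donor/acceptor classifications used by the surrogate
  energy function;
* per-residue covalent bond tables used for bonded-pair exclusions.

Angles are degrees, distances Angstrom throughout.
"""

from __future__ import annotations

from typing import Iterable

# --------------------------------------------------------------------------
# residue naming
# --------------------------------------------------------------------------

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

PROTEIN_RESIDUES = set(AA_3TO1)
DNA_RESIDUES = {"DA", "DC", "DG", "DT"}
RNA_RESIDUES = {"A", "C", "G", "U"}
NUCLEIC_RESIDUES = DNA_RESIDUES | RNA_RESIDUES

#: base letter of a nucleotide residue name ("DA" -> "A", "U" -> "U")
def base_letter(resname: str) -> str:
    return resname[-1]


DNA_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

PROTEIN_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
#: the 11 sugar-phosphate atoms treated as nucleic-acid "main chain"
NUCLEIC_BACKBONE_ATOMS = {
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'", "C2'", "C1'", "O4'",
}

WATER_NAMES = {"HOH", "WAT", "DOD"}

# --------------------------------------------------------------------------
# side-chain build recipes
# --------------------------------------------------------------------------
# Each entry: (atom, element, (ref_a, ref_b, ref_c), bond, angle, torsion)
# where torsion is a float (fixed) or ("chi", k, offset) meaning the k-th
# (1-based) chi dihedral of the residue plus a fixed offset.  The atom is
# placed by NeRF: bond from ref_c, angle ref_b-ref_c-atom, torsion
# ref_a-ref_b-ref_c-atom.  CB is shared by every non-glycine residue and
# placed from the backbone with the L-configuration improper.

CB_RECIPE = ("CB", "C", ("C", "N", "CA"), 1.530, 110.5, 120.0)


def _chi(k: int, offset: float = 0.0):
    return ("chi", k, offset)


SIDE_CHAIN_RECIPES: dict[str, list[tuple]] = {
    "ALA": [],
    "SER": [("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, _chi(1))],
    "CYS": [("SG", "S", ("N", "CA", "CB"), 1.808, 113.8, _chi(1))],
    "THR": [
        ("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, _chi(1)),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -120.0)),
    ],
    "VAL": [
        ("CG1", "C", ("N", "CA", "CB"), 1.527, 110.5, _chi(1)),
        ("CG2", "C", ("N", "CA", "CB"), 1.527, 110.5, _chi(1, 120.0)),
    ],
    "LEU": [
        ("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, _chi(1)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2, 120.0)),
    ],
    "ILE": [
        ("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, _chi(1)),
        ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -120.0)),
        ("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.8, _chi(2)),
    ],
    "MET": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, _chi(2)),
        ("CE", "C", ("CB", "CG", "SD"), 1.791, 100.9, _chi(3)),
    ],
    "PRO": [
        ("CG", "C", ("N", "CA", "CB"), 1.492, 104.5, _chi(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.503, 106.1, _chi(2)),
    ],
    "LYS": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
        ("CE", "C", ("CB", "CG", "CD"), 1.520, 111.3, _chi(3)),
        ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.9, _chi(4)),
    ],
    "ARG": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
        ("NE", "N", ("CB", "CG", "CD"), 1.460, 112.0, _chi(3)),
        ("CZ", "C", ("CG", "CD", "NE"), 1.329, 124.2, _chi(4)),
        ("NH1", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
        ("NH2", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0),
    ],
    "ASP": [
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2)),
        ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2, 180.0)),
    ],
    "ASN": [
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, _chi(2)),
        ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, _chi(2, 180.0)),
    ],
    "GLU": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3)),
        ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3, 180.0)),
    ],
    "GLN": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
        ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, _chi(3)),
        ("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, _chi(3, 180.0)),
    ],
    "HIS": [
        ("CG", "C", ("N", "CA", "CB"), 1.504, 113.8, _chi(1)),
        ("ND1", "N", ("CA", "CB", "CG"), 1.378, 122.7, _chi(2)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.354, 131.2, _chi(2, 180.0)),
        ("CE1", "C", ("CB", "CG", "ND1"), 1.321, 109.3, 180.0),
        ("NE2", "N", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0),
    ],
    "PHE": [
        ("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0),
    ],
    "TYR": [
        ("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2, 180.0)),
        ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0),
        ("CZ", "C", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0),
        ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0),
    ],
    "TRP": [
        ("CG", "C", ("N", "CA", "CB"), 1.498, 113.6, _chi(1)),
        ("CD1", "C", ("CA", "CB", "CG"), 1.365, 126.9, _chi(2)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.433, 126.6, _chi(2, 180.0)),
        ("NE1", "N", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
        ("CE2", "C", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
        ("CE3", "C", ("CD1", "CG", "CD2"), 1.398, 133.9, 180.0),
        ("CZ2", "C", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
        ("CZ3", "C", ("CE2", "CD2", "CE3"), 1.382, 118.6, 0.0),
        ("CH2", "C", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0),
    ],
    "GLY": [],
}

#: chi dihedral atom quadruples, in order, per residue (for recomputation)
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "LYS": [
        ("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ"),
    ],
    "ARG": [
        ("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ"),
    ],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ALA": [],
    "GLY": [],
}

#: hybridization class of each chi bond: sp3 chis sample {-60, 60, 180},
#: terminal sp2 chis sample {0, 90}
CHI_TYPES: dict[str, list[str]] = {
    "SER": ["sp3"], "CYS": ["sp3"], "THR": ["sp3"], "VAL": ["sp3"],
    "LEU": ["sp3", "sp3"], "ILE": ["sp3", "sp3"],
    "MET": ["sp3", "sp3", "sp3"],
    "LYS": ["sp3", "sp3", "sp3", "sp3"],
    "ARG": ["sp3", "sp3", "sp3", "sp2"],
    "ASP": ["sp3", "sp2"], "ASN": ["sp3", "sp2"],
    "GLU": ["sp3", "sp3", "sp2"], "GLN": ["sp3", "sp3", "sp2"],
    "HIS": ["sp3", "sp2"], "PHE": ["sp3", "sp2"], "TYR": ["sp3", "sp2"],
    "TRP": ["sp3", "sp2"],
    "ALA": [], "GLY": [], "PRO": ["sp3", "sp3"],
}

CHI_GRID = {"sp3": (-60.0, 60.0, 180.0), "sp2": (0.0, 90.0)}

#: ring-consistent proline (chi1, chi2) conformers (down/up pucker);
#: these close the CD-N ring bond to within ~1e-3 A of 1.473 A
PRO_CONFORMERS = [(-17.0, 16.0), (17.0, -16.0)]

#: hard cap on rotamers per identity (deterministic truncation order)
MAX_ROTAMERS_PER_IDENTITY = 81

# --------------------------------------------------------------------------
# idealized B-form sugar-phosphate backbone template
# --------------------------------------------------------------------------
# One nucleotide of the reference strand, helix axis = z, 5'->3' along +z.
# Residue i is generated by rotating +36 deg * i about z and translating
# +3.38 A * i; the complementary strand is the image under the dyad
# (x, y, z) -> (x, -y, -z).  O3'(i) sits 1.595 A from P(i+1).

HELIX_RISE = 3.38
HELIX_TWIST = 36.0

DNA_BACKBONE_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "P": (4.4540, 7.9499, -2.0032),
    "OP1": (5.1159, 9.1472, -1.4256),
    "OP2": (4.1652, 7.9022, -3.4591),
    "O5'": (3.0908, 7.7092, -1.2146),
    "C5'": (2.7263, 8.5417, -0.0972),
    "C4'": (2.0030, 7.7432, 0.9626),
    "O4'": (2.9454, 6.6648, 1.0414),
    "C3'": (0.7213, 7.0826, 0.4990),
    "O3'": (-0.3852, 7.6173, 1.2175),
    "C2'": (1.2314, 5.9803, -0.4338),
    "C1'": (2.6823, 5.7522, -0.0006),
}

# glycosidic attachment: N9 (purines) / N1 (pyrimidines) is placed from the
# sugar atoms (C2', O4', C1'); the torsion below points the base toward the
# helix axis for the backbone template above.
GLYCOSIDIC_BOND = 1.475
GLYCOSIDIC_ANGLE = 108.2    # O4'-C1'-N
GLYCOSIDIC_TORSION = 164.0  # C2'-O4'-C1'-N
CHI_ANTI = -138.0           # O4'-C1'-N9-C4 (purine) / O4'-C1'-N1-C2 (pyrimidine)

# base recipes: refs "N*" = glycosidic nitrogen of the base
BASE_RECIPES: dict[str, list[tuple]] = {
    "A": [
        ("N9", "N", None, GLYCOSIDIC_BOND, GLYCOSIDIC_ANGLE, GLYCOSIDIC_TORSION),
        ("C4", "C", ("O4'", "C1'", "N9"), 1.374, 126.4, CHI_ANTI),
        ("C8", "C", ("O4'", "C1'", "N9"), 1.371, 127.0, CHI_ANTI + 180.0),
        ("N7", "N", ("C1'", "N9", "C8"), 1.311, 113.9, 180.0),
        ("C5", "C", ("C8", "N9", "C4"), 1.383, 105.9, 0.0),
        ("N3", "N", ("C8", "N9", "C4"), 1.344, 127.0, 180.0),
        ("C2", "C", ("C5", "C4", "N3"), 1.332, 111.9, 0.0),
        ("N1", "N", ("C4", "N3", "C2"), 1.338, 129.3, 0.0),
        ("C6", "C", ("N9", "C4", "C5"), 1.406, 117.0, 180.0),
        ("N6", "N", ("C4", "C5", "C6"), 1.335, 123.7, 180.0),
    ],
    "G": [
        ("N9", "N", None, GLYCOSIDIC_BOND, GLYCOSIDIC_ANGLE, GLYCOSIDIC_TORSION),
        ("C4", "C", ("O4'", "C1'", "N9"), 1.374, 126.4, CHI_ANTI),
        ("C8", "C", ("O4'", "C1'", "N9"), 1.371, 127.0, CHI_ANTI + 180.0),
        ("N7", "N", ("C1'", "N9", "C8"), 1.305, 113.6, 180.0),
        ("C5", "C", ("C8", "N9", "C4"), 1.377, 105.4, 0.0),
        ("N3", "N", ("C8", "N9", "C4"), 1.355, 126.0, 180.0),
        ("C2", "C", ("C5", "C4", "N3"), 1.323, 111.9, 0.0),
        ("N1", "N", ("C4", "N3", "C2"), 1.351, 123.9, 0.0),
        ("N2", "N", ("C4", "N3", "C2"), 1.341, 119.9, 180.0),
        ("C6", "C", ("N9", "C4", "C5"), 1.415, 118.8, 180.0),
        ("O6", "O", ("C4", "C5", "C6"), 1.237, 128.6, 180.0),
    ],
    "C": [
        ("N1", "N", None, GLYCOSIDIC_BOND, GLYCOSIDIC_ANGLE, GLYCOSIDIC_TORSION),
        ("C2", "C", ("O4'", "C1'", "N1"), 1.397, 117.8, CHI_ANTI),
        ("C6", "C", ("O4'", "C1'", "N1"), 1.367, 120.8, CHI_ANTI + 180.0),
        ("O2", "O", ("C6", "N1", "C2"), 1.240, 118.9, 180.0),
        ("N3", "N", ("C6", "N1", "C2"), 1.353, 118.0, 0.0),
        ("C4", "C", ("N1", "C2", "N3"), 1.335, 120.3, 0.0),
        ("C5", "C", ("C2", "N3", "C4"), 1.425, 121.9, 0.0),
        ("N4", "N", ("C2", "N3", "C4"), 1.335, 118.0, 180.0),
    ],
    "T": [
        ("N1", "N", None, GLYCOSIDIC_BOND, GLYCOSIDIC_ANGLE, GLYCOSIDIC_TORSION),
        ("C2", "C", ("O4'", "C1'", "N1"), 1.397, 117.8, CHI_ANTI),
        ("C6", "C", ("O4'", "C1'", "N1"), 1.367, 120.8, CHI_ANTI + 180.0),
        ("O2", "O", ("C6", "N1", "C2"), 1.240, 118.9, 180.0),
        ("N3", "N", ("C6", "N1", "C2"), 1.373, 114.6, 0.0),
        ("C4", "C", ("N1", "C2", "N3"), 1.382, 127.2, 0.0),
        ("C5", "C", ("C2", "N3", "C4"), 1.445, 115.2, 0.0),
        ("O4", "O", ("C2", "N3", "C4"), 1.228, 119.9, 180.0),
        ("C7", "C", ("N3", "C4", "C5"), 1.499, 119.0, 180.0),
    ],
    "U": [
        ("N1", "N", None, GLYCOSIDIC_BOND, GLYCOSIDIC_ANGLE, GLYCOSIDIC_TORSION),
        ("C2", "C", ("O4'", "C1'", "N1"), 1.397, 117.8, CHI_ANTI),
        ("C6", "C", ("O4'", "C1'", "N1"), 1.367, 120.8, CHI_ANTI + 180.0),
        ("O2", "O", ("C6", "N1", "C2"), 1.240, 118.9, 180.0),
        ("N3", "N", ("C6", "N1", "C2"), 1.373, 114.6, 0.0),
        ("C4", "C", ("N1", "C2", "N3"), 1.382, 127.2, 0.0),
        ("C5", "C", ("C2", "N3", "C4"), 1.440, 114.6, 0.0),
        ("O4", "O", ("C2", "N3", "C4"), 1.228, 119.9, 180.0),
    ],
}

#: O2' recipe for RNA residues (non-backbone by the main-chain definition)
RNA_O2_RECIPE = ("O2'", "O", ("C1'", "C3'", "C2'"), 1.413, 110.6, 120.0)

GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "T": "N1", "U": "N1"}

# --------------------------------------------------------------------------
# surrogate energy parameters
# --------------------------------------------------------------------------

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
VDW_EPS = {"C": 0.10, "N": 0.16, "O": 0.20, "S": 0.25, "P": 0.20}

#: formal-charge smearing over terminal polar atoms; (resname, atom) -> q.
#: Nucleotide phosphate oxygens carry -0.6 each regardless of base.
PARTIAL_CHARGES: dict[tuple[str, str], float] = {
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
    ("LYS", "NZ"): 1.0,
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
}
PHOSPHATE_CHARGES = {"OP1": -0.6, "OP2": -0.6}
#: optional protonated-histidine charge (0 by default; see energy module)
HIS_CHARGED = {("HIS", "ND1"): 0.25, ("HIS", "NE2"): 0.25}

#: side-chain hydrogen-bond donors per residue; protein backbone N is a
#: donor for every residue except proline
SIDECHAIN_DONORS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
    "A": {"N6"}, "G": {"N1", "N2"}, "C": {"N4"}, "T": {"N3"}, "U": {"N3"},
}

SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"}, "GLN": {"OE1"}, "HIS": {"ND1", "NE2"}, "MET": {"SD"},
    "A": {"N1", "N3", "N7"}, "G": {"O6", "N3", "N7"},
    "C": {"O2", "N3"}, "T": {"O2", "O4"}, "U": {"O2", "O4"},
}
NUCLEIC_BACKBONE_ACCEPTORS = {"OP1", "OP2", "O5'", "O3'", "O4'", "O2'"}

# --------------------------------------------------------------------------
# covalent bond tables (for bonded-pair exclusions)
# --------------------------------------------------------------------------

_RING_CLOSURES: dict[str, list[tuple[str, str]]] = {
    "PHE": [("CE2", "CZ")],
    "TYR": [("CE2", "CZ")],
    "HIS": [("CE1", "NE2")],
    "TRP": [("NE1", "CE2"), ("CZ3", "CH2")],
    "PRO": [("CD", "N")],
    "A": [("N7", "C5"), ("C5", "C6"), ("N1", "C6")],
    "G": [("N7", "C5"), ("C5", "C6"), ("N1", "C6")],
    "C": [("C5", "C6")],
    "T": [("C5", "C6")],
    "U": [("C5", "C6")],
}

_NUCLEIC_BACKBONE_BONDS = [
    ("P", "OP1"), ("P", "OP2"), ("P", "O5'"), ("O5'", "C5'"),
    ("C5'", "C4'"), ("C4'", "O4'"), ("C4'", "C3'"), ("C3'", "O3'"),
    ("C3'", "C2'"), ("C2'", "C1'"), ("C1'", "O4'"),
]


def residue_bonds(resname: str) -> list[tuple[str, str]]:
    """Covalent heavy-atom bonds within a residue of the given name."""
    bonds: list[tuple[str, str]] = []
    if resname in PROTEIN_RESIDUES:
        bonds += [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]
        if resname != "GLY":
            bonds.append(("CA", "CB"))
        for atom, _elem, refs, *_ in SIDE_CHAIN_RECIPES[resname]:
            bonds.append((refs[2], atom))
        bonds += _RING_CLOSURES.get(resname, [])
    elif resname in NUCLEIC_RESIDUES:
        bonds += _NUCLEIC_BACKBONE_BONDS
        letter = base_letter(resname)
        gn = GLYCOSIDIC_N[letter]
        bonds.append(("C1'", gn))
        for atom, _elem, refs, *_ in BASE_RECIPES[letter]:
            if refs is not None:
                bonds.append((refs[2], atom))
        bonds += _RING_CLOSURES.get(letter, [])
        if resname in RNA_RESIDUES:
            bonds.append(("C2'", "O2'"))
    return bonds


def heavy_atoms(resname: str) -> list[str]:
    """Full heavy-atom name list for a standard residue."""
    if resname in PROTEIN_RESIDUES:
        names = ["N", "CA", "C", "O"]
        if resname != "GLY":
            names.append("CB")
        names += [rec[0] for rec in SIDE_CHAIN_RECIPES[resname]]
        return names
    if resname in NUCLEIC_RESIDUES:
        names = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'"]
        if resname in RNA_RESIDUES:
            names.append("O2'")
        names += [rec[0] for rec in BASE_RECIPES[base_letter(resname)]]
        return names
    raise KeyError(f"no template for residue {resname!r}")


def element_of(resname: str, atom: str) -> str:
    """Element symbol inferred from an atom label (heavy atoms only)."""
    name = atom.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element for atom {atom!r} of {resname!r}")
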