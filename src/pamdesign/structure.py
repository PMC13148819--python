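"""Data model and I/O for protein-nucleic-acid complexes.

The central container is :class:`ComplexModel`: chains of residues with
author numbering preserved verbatim from the input PDB file, an optional
:class:`PamAnnotation` marking the 6-bp PAM window on both strands, and a
provenance trail.  Structure-editing operations (:func:`repair_structure`,
:func:`build_mutant`, :func:`build_pam_variant`) always work on a fixed
backbone: protein side chains are rebuilt from the embedded rotamer
library and nucleobases are threaded onto the existing sugar-phosphate
backbone, so backbone coordinates survive every operation bit-exactly.

Only the ATOM/HETATM/TER/END records of the fixed-column PDB dialect are
interpreted; alternate locations other than blank/'A' are dropped and
models after the first are ignored.  Hydrogens are dropped on input and
never built.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

from . import templates as T

__all__ = [
    "AtomRecord",
    "Residue",
    "PamAnnotation",
    "ComplexModel",
    "PDBFormatError",
    "EmptyStructureError",
    "RepairError",
    "read_pdb",
    "write_pdb",
    "repair_structure",
    "build_mutant",
    "build_pam_variant",
]


class PDBFormatError(ValueError):
    """Malformed PDB content (carries the offending line number)."""


class EmptyStructureError(ValueError):
    """A PDB file without any usable ATOM records."""


class RepairError(ValueError):
    """A residue that cannot be repaired (e.g. incomplete backbone)."""


@dataclass
class AtomRecord:
    name: str
    element: str
    pos: np.ndarray
    is_backbone: bool

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.name, self.element, self.pos.copy(), self.is_backbone)


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name: str
    polymer: str  # protein | dna | rna | other
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not in {self.name} {self.chain_id}{self.number}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def side_chain_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_backbone]

    def backbone_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_backbone]

    def copy(self) -> "Residue":
        return Residue(
            self.chain_id, self.number, self.icode, self.name, self.polymer,
            [a.copy() for a in self.atoms],
        )


@dataclass
class PamAnnotation:
    """Chain/residue addresses of the 6-bp PAM on both strands.

    Position i (0-based, 5'->3' on the non-target strand) pairs with
    position i of ``ts_numbers``.  ``flank`` nucleotides up- and
    downstream on both strands are included in interface distance rules.
    """

    nts_chain: str
    nts_numbers: tuple[int, ...]
    ts_chain: str
    ts_numbers: tuple[int, ...]
    flank: int = 3

    def __post_init__(self) -> None:
        if len(self.nts_numbers) != 6 or len(self.ts_numbers) != 6:
            raise ValueError("a PAM annotation requires exactly 6 positions per strand")
        self.nts_numbers = tuple(self.nts_numbers)
        self.ts_numbers = tuple(self.ts_numbers)


@dataclass
class ComplexModel:
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    pam: PamAnnotation | None = None
    provenance: list[str] = field(default_factory=list)

    # -- access helpers ---------------------------------------------------
    def residues(self):
        for chain in self.chains.values():
            yield from chain

    def get(self, chain_id: str, number: int, icode: str = "") -> Residue:
        for r in self.chains.get(chain_id, []):
            if r.number == number and r.icode == icode:
                return r
        raise KeyError(f"no residue {chain_id}/{number}{icode or ''}")

    def has(self, chain_id: str, number: int, icode: str = "") -> bool:
        try:
            self.get(chain_id, number, icode)
            return True
        except KeyError:
            return False

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def copy(self) -> "ComplexModel":
        return ComplexModel(
            {cid: [r.copy() for r in chain] for cid, chain in self.chains.items()},
            _copy.deepcopy(self.pam),
            list(self.provenance),
        )

    def pam_sequence(self) -> str:
        """Current 6-mer on the non-target strand, 5'->3'."""
        if self.pam is None:
            raise ValueError("model carries no PAM annotation")
        return "".join(
            T.base_letter(self.get(self.pam.nts_chain, n).name) for n in self.pam.nts_numbers
        )

    def equals(self, other: "ComplexModel", tol: float = 5e-4) -> bool:
        """Structural equality: chains, residues, atom names and coordinates."""
        if sorted(self.chains) != sorted(other.chains):
            return False
        for cid, chain in self.chains.items():
            ochain = other.chains[cid]
            if len(chain) != len(ochain):
                return False
            for r, o in zip(chain, ochain):
                if (r.key, r.name) != (o.key, o.name):
                    return False
                if [a.name for a in r.atoms] != [a.name for a in o.atoms]:
                    return False
                for a, b in zip(r.atoms, o.atoms):
                    if not np.allclose(a.pos, b.pos, atol=tol, rtol=0):
                        return False
        return True


# --------------------------------------------------------------------------
# polymer classification
# --------------------------------------------------------------------------

def _polymer_class(resname: str) -> str:
    if resname in T.PROTEIN_RESIDUES:
        return "protein"
    if resname in T.DNA_RESIDUES:
        return "dna"
    if resname in T.RNA_RESIDUES:
        return "rna"
    return "other"


def _is_backbone(polymer: str, atom_name: str) -> bool:
    if polymer == "protein":
        return atom_name in T.PROTEIN_BACKBONE_ATOMS
    if polymer in ("dna", "rna"):
        return atom_name in T.NUCLEIC_BACKBONE_ATOMS
    return False


# --------------------------------------------------------------------------
# PDB input
# --------------------------------------------------------------------------

def read_pdb(path, keep_hetero: bool = False) -> ComplexModel:
    """Parse a fixed-column PDB file into a :class:`ComplexModel`.

    Author chain IDs, residue numbers and insertion codes are preserved
    verbatim.  Hydrogens and altlocs other than blank/'A' are dropped;
    water and non-polymer HETATM residues are dropped unless
    ``keep_hetero``.  Only the first model of a multi-model file is read.
    """
    try:
        with open(path) as fh:
            lines = fh.readlines()
    except OSError as exc:
        raise IOError(f"cannot read PDB file {path!r}: {exc}") from exc

    model = ComplexModel(provenance=[f"read_pdb({path})"])
    closed: set[tuple[str, int, str]] = set()
    current: Residue | None = None

    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec == "ENDMDL":
            break
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if len(line.rstrip("\n")) < 54:
            raise PDBFormatError(f"line {lineno}: truncated ATOM record (missing coordinates)")
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain_id = line[21]
        icode = line[26].strip()
        try:
            number = int(line[22:26])
            pos = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        except ValueError as exc:
            raise PDBFormatError(f"line {lineno}: unparseable ATOM record: {exc}") from exc
        if not np.all(np.isfinite(pos)):
            raise PDBFormatError(f"line {lineno}: non-finite coordinates")

        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = T.element_of(resname, name)
        element = element.upper()
        if element == "H" or element == "D" or name.startswith("H"):
            continue

        polymer = _polymer_class(resname)
        if polymer == "other" and not keep_hetero:
            continue
        if rec == "HETATM" and resname in T.WATER_NAMES and not keep_hetero:
            continue

        key = (chain_id, number, icode)
        if current is None or current.key != key:
            if key in closed:
                raise PDBFormatError(
                    f"line {lineno}: duplicate residue {chain_id}/{number}{icode} ({resname})"
                )
            if current is not None:
                closed.add(current.key)
            current = Residue(chain_id, number, icode, resname, polymer)
            model.chains.setdefault(chain_id, []).append(current)
        current.atoms.append(
            AtomRecord(name, element, pos, _is_backbone(polymer, name))
        )

    if model.n_residues() == 0:
        raise EmptyStructureError(f"no ATOM records usable in {path!r}")
    return model


# --------------------------------------------------------------------------
# PDB output
# --------------------------------------------------------------------------

def write_pdb(model: ComplexModel, path) -> None:
    """Write the model in fixed-column PDB format (3-decimal coordinates)."""
    serial = 1
    out = []
    for cid, chain in model.chains.items():
        last = None
        for res in chain:
            for a in res.atoms:
                name = a.name
                # PDB column rule: names of <4 chars with 1-char elements
                # start in column 14
                field = name if len(name) >= 4 or len(a.element) == 2 else f" {name}"
                out.append(
                    f"ATOM  {serial:5d} {field:<4s} {res.name:>3s} {cid}{res.number:4d}"
                    f"{res.icode or ' '}   {a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
                )
                serial += 1
            last = res
        if last is not None:
            out.append(
                f"TER   {serial:5d}      {last.name:>3s} {cid}{last.number:4d}{last.icode or ' '}"
            )
            serial += 1
    out.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


# --------------------------------------------------------------------------
# repair
# --------------------------------------------------------------------------

def _external_clashes(model: ComplexModel, exclusions) -> list[tuple[str, int, str]]:
    """Residue keys whose side chains clash with atoms outside the residue.

    A clash is an interatomic distance below 0.8x the sum of van der Waals
    radii, skipping pairs within 3 covalent bonds of each other.
    """
    keys = []
    all_atoms = []
    for res in model.residues():
        for a in res.atoms:
            all_atoms.append((res.key, a))
    pos = np.array([a.pos for _, a in all_atoms])
    radii = np.array([T.VDW_RADII.get(a.element, 1.7) for _, a in all_atoms])
    from scipy.spatial import cKDTree

    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=0.8 * 2 * max(T.VDW_RADII.values()), output_type="ndarray")
    clashing: set[tuple[str, int, str]] = set()
    for i, j in pairs:
        ki, ai = all_atoms[i]
        kj, aj = all_atoms[j]
        if ki == kj:
            continue
        if np.linalg.norm(ai.pos - aj.pos) >= 0.8 * (
            T.VDW_RADII.get(ai.element, 1.7) + T.VDW_RADII.get(aj.element, 1.7)
        ):
            continue
        if exclusions.separation(i, j) <= 3:
            continue
        if not ai.is_backbone:
            clashing.add(ki)
        if not aj.is_backbone:
            clashing.add(kj)
    for res in model.residues():
        if res.key in clashing and res.polymer == "protein":
            keys.append(res.key)
    return keys


def repair_structure(model: ComplexModel) -> ComplexModel:
    """Complete missing protein side-chain atoms and relieve steric clashes.

    Every protein residue ends up with the full heavy-atom set of its
    identity; residues whose side chains clash with surrounding atoms are
    re-placed at their lowest-energy rotamer.  Backbone and nucleic-acid
    coordinates are never touched.  The procedure iterates clash
    re-placement to a fixed point, which makes it idempotent.
    """
    from .energy import ComplexTopology
    from .rotamers import best_rotamer_placement

    out = model.copy()
    out.provenance.append("repair_structure")

    # completeness check + completion
    for res in out.residues():
        if res.polymer != "protein":
            continue
        for bb in ("N", "CA", "C", "O"):
            if not res.has_atom(bb):
                raise RepairError(
                    f"residue {res.name} {res.chain_id}/{res.number} is missing "
                    f"backbone atom {bb}"
                )
        expected = set(T.heavy_atoms(res.name)) - {"OXT"}
        present = {a.name for a in res.atoms}
        if not expected <= present:
            best_rotamer_placement(out, res, res.name, replace=True)

    # clash relief, iterated to a fixed point
    for _ in range(10):
        topo = ComplexTopology(out)
        clashing = _external_clashes(out, topo)
        if not clashing:
            break
        changed = False
        for key in sorted(clashing):
            res = out.get(*key)
            before = np.array([a.pos for a in res.side_chain_atoms()])
            best_rotamer_placement(out, res, res.name, replace=True)
            after = np.array([a.pos for a in res.side_chain_atoms()])
            if before.shape != after.shape or not np.allclose(before, after, atol=1e-12):
                changed = True
        if not changed:
            break
    return out


# --------------------------------------------------------------------------
# mutants
# --------------------------------------------------------------------------

def build_mutant(model: ComplexModel, mutations) -> ComplexModel:
    """Rebuild the targeted residues with new identities on a fixed backbone.

    ``mutations`` is an iterable of ``(chain_id, number, new_identity)``
    where the identity is a one-letter amino-acid code (or 3-letter name)
    for protein sites and a one-letter base (or residue name like 'DA')
    for nucleotide sites.  All untouched residues are bit-identical in
    the output.
    """
    from .rotamers import best_rotamer_placement

    out = model.copy()
    applied = []
    for chain_id, number, new in mutations:
        try:
            res = out.get(chain_id, number)
        except KeyError as exc:
            raise KeyError(f"unknown residue address {chain_id}/{number}") from exc
        if res.polymer == "protein":
            new3 = T.AA_1TO3.get(new.upper(), new.upper())
            if new3 not in T.PROTEIN_RESIDUES:
                raise TypeError(
                    f"identity {new!r} is not an amino acid (site {chain_id}/{number} "
                    f"is a protein residue)"
                )
            best_rotamer_placement(out, res, new3, replace=True)
            res.name = new3
        elif res.polymer in ("dna", "rna"):
            letter = new.upper()[-1]
            valid = "ACGT" if res.polymer == "dna" else "ACGU"
            if letter not in valid or (len(new) > 1 and _polymer_class(new.upper()) != res.polymer):
                raise TypeError(
                    f"identity {new!r} is not a {res.polymer.upper()} base "
                    f"(site {chain_id}/{number})"
                )
            _thread_base(res, letter)
        else:
            raise TypeError(f"residue {chain_id}/{number} is not designable")
        applied.append(f"{chain_id}/{number}->{new}")
    if applied:
        out.provenance.append("build_mutant(" + ",".join(applied) + ")")
    return out


def _thread_base(res: Residue, letter: str) -> None:
    """Replace the base of a nucleotide in place, keeping the sugar-phosphate
    backbone bit-identical, by rebuilding base atoms from the embedded
    recipes anchored at the C2'/O4'/C1' sugar frame."""
    from .geometry import place_atom

    coords = {a.name: a.pos for a in res.atoms if a.is_backbone or a.name == "O2'"}
    for need in ("C2'", "O4'", "C1'"):
        if need not in coords:
            raise RepairError(
                f"nucleotide {res.chain_id}/{res.number} lacks sugar atom {need}"
            )
    new_atoms = [a for a in res.atoms if a.is_backbone or a.name == "O2'"]
    gn = T.GLYCOSIDIC_N[letter]
    placed: dict[str, np.ndarray] = dict(coords)
    for atom, elem, refs, bond, angle, tors in T.BASE_RECIPES[letter]:
        if refs is None:
            pos = place_atom(placed["C2'"], placed["O4'"], placed["C1'"], bond, angle, tors)
        else:
            pos = place_atom(placed[refs[0]], placed[refs[1]], placed[refs[2]], bond, angle, tors)
        placed[atom] = pos
        new_atoms.append(AtomRecord(atom, elem, pos, False))
    res.atoms = new_atoms
    res.name = ("D" + letter) if res.polymer == "dna" else letter
    assert res.has_atom(gn)


def build_pam_variant(model: ComplexModel, pam_seq: str) -> ComplexModel:
    """Thread a new 6-mer PAM onto the annotated PAM window.

    Non-target-strand bases take ``pam_seq`` (5'->3'); target-strand
    partners take its complement.  Bases already matching are left
    bit-identical, so threading the current PAM is the identity.
    """
    if model.pam is None:
        raise ValueError("model carries no PAM annotation; cannot thread a PAM variant")
    pam_seq = pam_seq.upper()
    if len(pam_seq) != 6 or any(b not in "ACGT" for b in pam_seq):
        raise ValueError(f"PAM must be a 6-mer over ACGT, got {pam_seq!r}")

    out = model.copy()
    pam = out.pam
    for i, base in enumerate(pam_seq):
        nts = out.get(pam.nts_chain, pam.nts_numbers[i])
        if T.base_letter(nts.name) != base:
            _thread_base(nts, base)
        ts = out.get(pam.ts_chain, pam.ts_numbers[i])
        comp = T.DNA_COMPLEMENT[base]
        if T.base_letter(ts.name) != comp:
            _thread_base(ts, comp)
    out.provenance.append(f"build_pam_variant({pam_seq})")
    return out
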