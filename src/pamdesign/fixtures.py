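"""Deterministic synthetic protein-DNA complex fixtures.

The generator emulates, at desk scale, the geometry every design stage
needs: an idealized B-form DNA duplex (rise 3.38 A, twist 36 deg/bp,
full heavy-atom nucleotides) with an annotated 6-bp PAM window, packed
against an ideal alpha-helical peptide whose side chains reach the PAM
sugar-phosphate backbone.  The default peptide reuses the author residue
numbering of the SaCas9 PAM-interacting sites (Lys37 ... Thr1019), so
constraint files written against those numbers apply to the fixture
verbatim.  Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import templates as T
from .geometry import place_atom, rotation_about_axis
from .rotamers import best_rotamer_placement
from .structure import AtomRecord, ComplexModel, PamAnnotation, Residue

__all__ = [
    "FixtureParams",
    "FixtureError",
    "gen_dna_duplex",
    "gen_toy_complex",
    "default_toy_complex",
    "random_fixture",
    "iteration_resfile_path",
]

#: peptide residue numbers mirroring the PAM-interacting sites of SaCas9
DEFAULT_PEPTIDE_NUMBERS = (37, 782, 787, 803, 822, 882, 968, 993, 1015, 1019)
#: wild-type identities at those sites (K37, E782, T787, N803, K822,
#: Y882, N968, E993, R1015, T1019)
DEFAULT_PEPTIDE_SEQUENCE = "KETNKYNERT"
DEFAULT_DNA = "ACGATTGGGTACGT"  # PAM TTGGGT at offset 4
DEFAULT_PAM_OFFSET = 4


class FixtureError(RuntimeError):
    pass


@dataclass
class FixtureParams:
    dna_sequence: str = DEFAULT_DNA
    pam_offset: int = DEFAULT_PAM_OFFSET
    peptide_sequence: str = DEFAULT_PEPTIDE_SEQUENCE
    peptide_numbers: tuple[int, ...] | None = DEFAULT_PEPTIDE_NUMBERS
    approach_distance: float = 6.0
    jitter: float = 0.0
    seed: int = 0
    rna_sequence: str | None = None

    def __post_init__(self):
        self.dna_sequence = self.dna_sequence.upper()
        if any(b not in "ACGT" for b in self.dna_sequence):
            raise ValueError("dna_sequence must be over ACGT")
        if not (0 <= self.pam_offset <= len(self.dna_sequence) - 6):
            raise ValueError("PAM window does not fit inside dna_sequence")
        if self.approach_distance <= 2:
            raise ValueError("approach_distance must exceed 2 A")
        if self.peptide_numbers is not None and len(self.peptide_numbers) != len(
            self.peptide_sequence
        ):
            raise ValueError("peptide_numbers must match peptide_sequence length")


# --------------------------------------------------------------------------
# DNA duplex
# --------------------------------------------------------------------------

def _helix_step(pos: np.ndarray, step: int) -> np.ndarray:
    R = rotation_about_axis(np.array([0.0, 0.0, 1.0]), T.HELIX_TWIST * step)
    return pos @ R.T + np.array([0.0, 0.0, T.HELIX_RISE * step])


_DYAD = np.array([1.0, -1.0, -1.0])


def _nucleotide(chain_id: str, number: int, letter: str, step: int,
                strand2: bool, drop_phosphate: bool) -> Residue:
    base_template = {k: np.array(v) for k, v in T.DNA_BACKBONE_TEMPLATE.items()}
    if strand2:
        base_template = {k: v * _DYAD for k, v in base_template.items()}
    coords = {k: _helix_step(v, step) for k, v in base_template.items()}
    if drop_phosphate:
        for name in ("P", "OP1", "OP2"):
            coords.pop(name)
    res = Residue(chain_id, number, "", "D" + letter, "dna")
    for name in T.heavy_atoms("D" + letter):
        if name in coords:
            res.atoms.append(
                AtomRecord(name, T.element_of("D" + letter, name), coords[name], True)
            )
    placed = dict(coords)
    for atom, elem, refs, bond, angle, tors in T.BASE_RECIPES[letter]:
        if refs is None:
            pos = place_atom(placed["C2'"], placed["O4'"], placed["C1'"], bond, angle, tors)
        else:
            pos = place_atom(placed[refs[0]], placed[refs[1]], placed[refs[2]], bond, angle, tors)
        placed[atom] = pos
        res.atoms.append(AtomRecord(atom, elem, pos, False))
    return res


def gen_dna_duplex(seq: str, nts_chain: str = "B", ts_chain: str = "C") -> ComplexModel:
    """Idealized B-form duplex for ``seq`` (the 5'->3' non-target strand).

    The complement chain is the reverse complement with antiparallel
    numbering: NTS residue i (number i, 1-based) pairs with TS residue
    number L - i + 1.
    """
    seq = seq.upper()
    if len(seq) < 6:
        raise ValueError("duplex sequence must be at least 6 bp")
    if any(b not in "ACGT" for b in seq):
        raise ValueError(f"invalid DNA sequence {seq!r}")
    L = len(seq)
    model = ComplexModel(provenance=[f"gen_dna_duplex({seq})"])
    model.chains[nts_chain] = [
        _nucleotide(nts_chain, i + 1, seq[i], i, strand2=False, drop_phosphate=(i == 0))
        for i in range(L)
    ]
    # strand II 5'->3' runs from step L-1 down to 0
    model.chains[ts_chain] = [
        _nucleotide(
            ts_chain, j + 1, T.DNA_COMPLEMENT[seq[L - 1 - j]], L - 1 - j,
            strand2=True, drop_phosphate=(j == 0),
        )
        for j in range(L)
    ]
    return model


# --------------------------------------------------------------------------
# peptide helix
# --------------------------------------------------------------------------

_HELIX_PHI, _HELIX_PSI, _OMEGA = -57.0, -47.0, 180.0


def _helix_backbone(n_res: int) -> list[dict[str, np.ndarray]]:
    """Ideal alpha-helix backbone (N, CA, C, O per residue) built by NeRF
    from standard bond geometry and (phi, psi) = (-57, -47)."""
    coords: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = place_atom(np.array([-0.5, 1.2, 0.0]), n, ca, 1.525, 111.0, _HELIX_PSI)
    for i in range(n_res):
        res = {"N": n, "CA": ca, "C": c}
        n_next = place_atom(n, ca, c, 1.329, 116.6, _HELIX_PSI)
        res["O"] = place_atom(n_next, ca, c, 1.231, 122.7, 180.0)
        coords.append(res)
        ca_next = place_atom(ca, c, n_next, 1.458, 121.7, _OMEGA)
        c_next = place_atom(c, n_next, ca_next, 1.525, 111.0, _HELIX_PHI)
        n, ca, c = n_next, ca_next, c_next
    return coords


def _helix_axis(cas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = cas.mean(axis=0)
    _u, _s, vt = np.linalg.svd(cas - centroid)
    axis = vt[0]
    if axis @ (cas[-1] - cas[0]) < 0:
        axis = -axis
    return centroid, axis


# --------------------------------------------------------------------------
# toy complex
# --------------------------------------------------------------------------

def gen_toy_complex(params: FixtureParams | None = None) -> ComplexModel:
    """DNA duplex + alpha-helical peptide packed against the PAM backbone.

    The duplex is rotated about its axis so the PAM window faces +x; the
    peptide helix runs parallel to the DNA axis at a lateral offset set
    by ``approach_distance``, with side chains facing the duplex.  The
    placement contract — at least three peptide side chains within 6 A
    of PAM-region backbone atoms — is verified and violations raise
    :class:`FixtureError`.
    """
    p = params or FixtureParams()
    model = gen_dna_duplex(p.dna_sequence)
    L = len(p.dna_sequence)
    model.pam = PamAnnotation(
        nts_chain="B",
        nts_numbers=tuple(p.pam_offset + 1 + k for k in range(6)),
        ts_chain="C",
        ts_numbers=tuple(L - (p.pam_offset + k) for k in range(6)),
    )

    # rotate duplex so the PAM backbone centroid faces +x
    pam_res = [model.get("B", n) for n in model.pam.nts_numbers]
    pam_res += [model.get("C", n) for n in model.pam.ts_numbers]
    pam_bb = np.array([a.pos for r in pam_res for a in r.atoms if a.is_backbone])
    centroid = pam_bb.mean(axis=0)
    phase = np.degrees(np.arctan2(centroid[1], centroid[0]))
    R = rotation_about_axis(np.array([0.0, 0.0, 1.0]), -phase)
    for res in model.residues():
        for a in res.atoms:
            a.pos = R @ a.pos
    pam_z = float(np.array([a.pos[2] for r in pam_res for a in r.atoms]).mean())

    # ideal helix backbone, axis aligned to z
    n_res = len(p.peptide_sequence)
    numbers = p.peptide_numbers or tuple(range(1, n_res + 1))
    bb = _helix_backbone(n_res)
    cas = np.array([r["CA"] for r in bb])
    h_centroid, h_axis = _helix_axis(cas)
    zhat = np.array([0.0, 0.0, 1.0])
    v = np.cross(h_axis, zhat)
    s = np.linalg.norm(v)
    if s > 1e-9:
        ang = np.degrees(np.arctan2(s, float(h_axis @ zhat)))
        R_align = rotation_about_axis(v / s, ang)
    else:
        R_align = np.eye(3)
    for r in bb:
        for k in r:
            r[k] = R_align @ (r[k] - h_centroid)

    # spin the helix so CA->CB directions at the middle face -x (the DNA)
    cas = np.array([r["CA"] for r in bb])
    mid = slice(max(0, n_res // 2 - 2), min(n_res, n_res // 2 + 3))
    radial = cas[mid].copy()
    radial[:, 2] = 0.0
    mean_dir = radial.mean(axis=0)
    spin = 180.0 - np.degrees(np.arctan2(mean_dir[1], mean_dir[0]))
    R_spin = rotation_about_axis(zhat, spin)
    for r in bb:
        for k in r:
            r[k] = R_spin @ r[k]

    # lateral offset: DNA backbone surface (~10 A) + approach distance,
    # measured from the helix axis to the duplex axis
    offset = np.array([10.0 + p.approach_distance, 0.0, pam_z])
    chain = []
    for i, (letter, number) in enumerate(zip(p.peptide_sequence, numbers)):
        name3 = T.AA_1TO3[letter]
        res = Residue("A", number, "", name3, "protein")
        for bb_name in ("N", "CA", "C", "O"):
            res.atoms.append(
                AtomRecord(bb_name, bb_name[0], bb[i][bb_name] + offset, True)
            )
        chain.append(res)
    # peptide chain first so protein sites precede nucleic ones
    model.chains = {"A": chain, "B": model.chains["B"], "C": model.chains["C"]}

    # grow side chains at their lowest-energy rotamers, N->C, deterministic
    for res in chain:
        best_rotamer_placement(model, res, res.name, replace=True)

    if p.jitter > 0:
        rng = np.random.default_rng(np.random.Philox(p.seed))
        for res in model.residues():
            for a in res.atoms:
                a.pos = a.pos + rng.normal(0.0, p.jitter, 3)

    if p.rna_sequence is not None:
        rna = _rna_strand(p.rna_sequence)
        model.chains["R"] = rna

    # placement contract
    pam_bb = np.array(
        [a.pos for r in _pam_region_residues_local(model) for a in r.atoms if a.is_backbone]
    )
    n_close = 0
    min_d = np.inf
    for res in chain:
        side = np.array([a.pos for a in res.atoms if not a.is_backbone])
        if len(side) == 0:
            continue
        d = np.sqrt(((side[:, None, :] - pam_bb[None, :, :]) ** 2).sum(-1)).min()
        min_d = min(min_d, d)
        if d <= 6.0:
            n_close += 1
    if min_d > 8.0:
        raise FixtureError(
            f"geometry placement failure: nearest peptide side chain is {min_d:.1f} A "
            f"from the PAM backbone"
        )
    model.provenance.append(
        f"gen_toy_complex(seed={p.seed}, jitter={p.jitter}, contacts={n_close})"
    )
    return model


def _pam_region_residues_local(model):
    from .constraints import _pam_region_residues

    return _pam_region_residues(model)


def _rna_strand(seq: str, chain_id: str = "R") -> list[Residue]:
    """A crude single-stranded helical RNA placed clear of the duplex."""
    seq = seq.upper()
    if any(b not in "ACGU" for b in seq):
        raise ValueError(f"invalid RNA sequence {seq!r}")
    out = []
    shift = np.array([-22.0, 0.0, 0.0])
    for i, letter in enumerate(seq):
        res = _nucleotide(chain_id, i + 1, "A" if letter == "U" else letter, i,
                          strand2=False, drop_phosphate=(i == 0))
        res.polymer = "rna"
        res.name = letter
        # thread the right base and add O2'
        from .structure import _thread_base

        for a in res.atoms:
            a.pos = a.pos + shift
        _thread_base(res, letter)
        placed = {a.name: a.pos for a in res.atoms}
        name, elem, refs, bond, angle, tors = T.RNA_O2_RECIPE
        pos = place_atom(placed[refs[0]], placed[refs[1]], placed[refs[2]], bond, angle, tors)
        res.atoms.append(AtomRecord(name, elem, pos, False))
        out.append(res)
    return out


def default_toy_complex(seed: int = 0, jitter: float = 0.0) -> ComplexModel:
    return gen_toy_complex(FixtureParams(seed=seed, jitter=jitter))


def random_fixture(seed: int) -> ComplexModel:
    """A randomized small fixture (sequences and jitter vary with seed)."""
    rng = np.random.default_rng(np.random.Philox(seed))
    L = int(rng.integers(12, 17))
    offset = int(rng.integers(0, L - 6))
    dna = "".join(rng.choice(list("ACGT"), L))
    n_pep = int(rng.integers(8, 13))
    pep = "".join(rng.choice(list("ACDEFGHIKLMNQRSTVWY"), n_pep))
    return gen_toy_complex(
        FixtureParams(
            dna_sequence=dna,
            pam_offset=offset,
            peptide_sequence=pep,
            peptide_numbers=None,
            jitter=float(rng.uniform(0.0, 0.3)),
            seed=seed,
        )
    )


def iteration_resfile_path(iteration: int):
    """Path to the packaged RESFILE mirroring one of the three design
    iterations (applies verbatim to the default toy complex)."""
    from importlib.resources import files

    if iteration not in (1, 2, 3):
        raise ValueError(f"iteration must be 1, 2 or 3, got {iteration}")
    return files("pamdesign").joinpath(f"data/iteration{iteration}.resfile")
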