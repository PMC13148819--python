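"""Discrete side-chain conformer library and fixed-backbone placement.

The library is a coarse, fully embedded chi grid: every sp3 chi is
sampled at {-60, 60, 180} degrees and terminal sp2 chis at {0, 90};
proline gets its two ring-consistent pucker conformers.  Enumeration
order is the deterministic cartesian product of the per-chi grids,
truncated at 81 conformers per identity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import templates as T
from .geometry import place_atom

__all__ = [
    "Rotamer",
    "RotamerLibrary",
    "load_library",
    "build_side_chain",
    "build_rotamers",
    "best_rotamer_placement",
]


@dataclass(frozen=True)
class Rotamer:
    identity: str  # 3-letter amino-acid name
    chis: tuple[float, ...]

    def __post_init__(self):
        n_expected = len(T.CHI_ATOMS[self.identity])
        if len(self.chis) != n_expected:
            raise ValueError(
                f"{self.identity} takes {n_expected} chi angles, got {len(self.chis)}"
            )


class RotamerLibrary:
    """Per-identity rotamer lists in a fixed deterministic order."""

    def __init__(self, rotamers: dict[str, list[Rotamer]]):
        self._rot = rotamers

    def rotamers(self, identity: str) -> list[Rotamer]:
        identity = T.AA_1TO3.get(identity, identity)
        try:
            return self._rot[identity]
        except KeyError:
            raise KeyError(f"unknown amino-acid identity {identity!r}") from None

    def identities(self) -> list[str]:
        return list(self._rot)

    def to_tsv(self) -> str:
        lines = ["identity\tindex\tchis"]
        for ident, rots in self._rot.items():
            for i, r in enumerate(rots):
                chis = ",".join(f"{c:.1f}" for c in r.chis)
                lines.append(f"{ident}\t{i}\t{chis}")
        return "\n".join(lines) + "\n"


_LIBRARY: RotamerLibrary | None = None


def load_library() -> RotamerLibrary:
    """The embedded chi-grid library (built once, cached)."""
    global _LIBRARY
    if _LIBRARY is not None:
        return _LIBRARY
    rot: dict[str, list[Rotamer]] = {}
    for identity in sorted(T.PROTEIN_RESIDUES):
        if identity == "PRO":
            rot[identity] = [Rotamer("PRO", chis) for chis in T.PRO_CONFORMERS]
            continue
        grids = [T.CHI_GRID[t] for t in T.CHI_TYPES[identity]]
        combos = itertools.product(*grids) if grids else [()]
        rots = [Rotamer(identity, tuple(c)) for c in combos]
        rot[identity] = rots[: T.MAX_ROTAMERS_PER_IDENTITY]
    _LIBRARY = RotamerLibrary(rot)
    return _LIBRARY


# --------------------------------------------------------------------------
# coordinate construction
# --------------------------------------------------------------------------

def build_side_chain(
    n: np.ndarray, ca: np.ndarray, c: np.ndarray, identity: str, chis
) -> list[tuple[str, str, np.ndarray]]:
    """Heavy side-chain atoms (name, element, position) for one conformer.

    Atoms are placed by NeRF from the backbone N/CA/C triad, so the
    realized chi dihedrals reproduce ``chis`` exactly.
    """
    identity = T.AA_1TO3.get(identity, identity)
    if identity not in T.PROTEIN_RESIDUES:
        raise KeyError(f"unknown amino-acid identity {identity!r}")
    if identity == "GLY":
        return []
    placed = {"N": np.asarray(n, float), "CA": np.asarray(ca, float), "C": np.asarray(c, float)}
    name, elem, (a, b, cc), bond, angle, tors = T.CB_RECIPE
    placed["CB"] = place_atom(placed[a], placed[b], placed[cc], bond, angle, tors)
    out = [("CB", "C", placed["CB"])]
    chis = tuple(chis)
    for atom, aelem, refs, bond, angle, tors in T.SIDE_CHAIN_RECIPES[identity]:
        if isinstance(tors, tuple):
            _, k, offset = tors
            tors_val = chis[k - 1] + offset
        else:
            tors_val = tors
        pos = place_atom(placed[refs[0]], placed[refs[1]], placed[refs[2]], bond, angle, tors_val)
        placed[atom] = pos
        out.append((atom, aelem, pos))
    return out


def build_rotamers(model, site, identity: str):
    """All library conformers of ``identity`` placed on a site's backbone.

    ``site`` is a ``(chain_id, number)`` address (optionally with icode).
    Returns a list of conformers, each a list of ``(name, element, pos)``
    side-chain atoms; backbone atoms are shared bit-exactly with the site
    and are not part of the returned coordinates.
    """
    res = model.get(*site)
    for bb in ("N", "CA", "C"):
        if not res.has_atom(bb):
            raise ValueError(
                f"site {site} lacks backbone atom {bb}; cannot place rotamers"
            )
    n, ca, c = res.atom("N").pos, res.atom("CA").pos, res.atom("C").pos
    lib = load_library()
    return [build_side_chain(n, ca, c, identity, r.chis) for r in lib.rotamers(identity)]


def best_rotamer_placement(model, res, identity: str, replace: bool = False) -> int:
    """Place the lowest-energy conformer of ``identity`` at a residue.

    The score is the surrogate interaction energy of the candidate side
    chain with everything else in the complex (plus its own backbone),
    using the same pair terms as the design score.  Ties break toward the
    lowest rotamer index, so placement is fully deterministic.  Returns
    the chosen rotamer index; with ``replace`` the residue's side chain
    is swapped in place (backbone untouched).
    """
    from .energy import placement_energies

    identity = T.AA_1TO3.get(identity, identity)
    conformers = build_rotamers(model, (res.chain_id, res.number, res.icode), identity)
    energies = placement_energies(model, res, identity, conformers)
    best_idx = 0
    best_e = None
    for i, e in enumerate(energies):
        if best_e is None or e < best_e - 1e-12:
            best_e, best_idx = e, i
    if replace:
        from .structure import AtomRecord

        backbone = [a for a in res.atoms if a.is_backbone]
        res.atoms = backbone + [
            AtomRecord(name, elem, pos, False) for name, elem, pos in conformers[best_idx]
        ]
        res.name = identity
    return best_idx
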