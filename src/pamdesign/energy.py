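"""Surrogate pairwise energy function and the constrained design score.

The physical part of the score is a deliberately simple heavy-atom
surrogate — capped 12-6 van der Waals, distance-dependent-dielectric
Coulomb over a small embedded partial-charge table, and a geometric
hydrogen-bond term — decomposed into a *binding* component (protein vs
nucleic-acid cross terms) and a *non-binding* component (everything
else).  Absolute values are in surrogate energy units and are not
comparable to any published force field; only orderings, signs and the
constraint arithmetic built on top of them are meaningful.

The total design score is

    E_total = E_non-bind + w_bind * E_bind + w_evo * E_evo
              + w_OOR * N_OOR + w_exist * X_exist

with N_OOR the piecewise distance of the mutation count from the allowed
range [N_mut,min, N_mut,max], X_exist the indicator that a designed
sequence duplicates an already-saved one, and both penalty weights large
positive constants (1000 by default) so that constraint violations
dominate any physical energy difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import templates as T

__all__ = [
    "ScoreWeights",
    "EnergyConfig",
    "EnergyBreakdown",
    "pair_terms",
    "decompose",
    "mutation_count_penalty",
    "duplicate_penalty",
    "total_score",
    "ComplexTopology",
]

VDW_CUTOFF = 8.0
ELEC_CUTOFF = 10.0
HBOND_MIN, HBOND_MAX = 2.6, 3.4
VDW_CAP = 10.0
COULOMB = 332.0
#: all pair terms vanish beyond this distance
INTERACTION_CUTOFF = ELEC_CUTOFF


@dataclass
class ScoreWeights:
    """Multipliers of the design score terms."""

    w_bind: float = 1.0
    w_evo: float = 1.0
    w_oor: float = 1000.0
    w_exist: float = 1000.0

    def __post_init__(self):
        for name in ("w_bind", "w_evo", "w_oor", "w_exist"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.w_oor < 0 or self.w_exist < 0:
            raise ValueError("penalty weights must be non-negative")


@dataclass
class EnergyConfig:
    """Switches of the surrogate energy function.

    ``his_charged`` puts +0.25 on each histidine ring nitrogen (histidine
    can carry a positive charge near physiological pH; neutral by
    default).  ``include_rna_in_binding`` controls whether protein-RNA
    cross terms count toward the binding component (on by default) or
    toward the non-binding remainder.
    """

    his_charged: bool = False
    include_rna_in_binding: bool = True


@dataclass
class EnergyBreakdown:
    non_bind: float
    bind: float
    evo: float
    n_oor: int
    x_exist: int
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    total: float = field(init=False)

    def __post_init__(self):
        w = self.weights
        self.total = (
            self.non_bind
            + w.w_bind * self.bind
            + w.w_evo * self.evo
            + w.w_oor * self.n_oor
            + w.w_exist * self.x_exist
        )

    def to_tsv(self) -> str:
        rows = [
            ("non_bind", self.non_bind), ("bind", self.bind), ("evo", self.evo),
            ("n_oor", self.n_oor), ("x_exist", self.x_exist), ("total", self.total),
        ]
        return "\n".join(f"{k}\t{v:.6f}" for k, v in rows) + "\n"


# --------------------------------------------------------------------------
# penalty terms
# --------------------------------------------------------------------------

def mutation_count_penalty(n_mut: int, n_min: int, n_max: int) -> int:
    """N_OOR: distance of the mutation count from [n_min, n_max]."""
    if n_min > n_max or n_min < 0:
        raise ValueError(f"invalid mutation-count range [{n_min}, {n_max}]")
    if n_mut < n_min:
        return n_min - n_mut
    if n_mut > n_max:
        return n_mut - n_max
    return 0


def duplicate_penalty(seq, reserved) -> int:
    """X_exist: 1 iff the designed sequence is already saved."""
    return 1 if seq in reserved else 0


def total_score(
    non_bind: float,
    bind: float,
    evo: float,
    n_mut: int,
    n_min: int,
    n_max: int,
    is_duplicate: bool,
    weights: ScoreWeights | None = None,
) -> float:
    w = weights or ScoreWeights()
    return (
        non_bind
        + w.w_bind * bind
        + w.w_evo * evo
        + w.w_oor * mutation_count_penalty(n_mut, n_min, n_max)
        + w.w_exist * (1 if is_duplicate else 0)
    )


# --------------------------------------------------------------------------
# per-atom parameters
# --------------------------------------------------------------------------

def atom_charge(resname: str, atom_name: str, his_charged: bool = False) -> float:
    q = T.PARTIAL_CHARGES.get((resname, atom_name))
    if q is not None:
        return q
    if resname in T.NUCLEIC_RESIDUES and atom_name in T.PHOSPHATE_CHARGES:
        return T.PHOSPHATE_CHARGES[atom_name]
    if his_charged:
        q = T.HIS_CHARGED.get((resname, atom_name))
        if q is not None:
            return q
    return 0.0


def _donor_acceptor(resname: str, atom_name: str) -> tuple[bool, bool]:
    if resname in T.PROTEIN_RESIDUES:
        donor = (atom_name == "N" and resname != "PRO") or (
            atom_name in T.SIDECHAIN_DONORS.get(resname, ())
        )
        acceptor = atom_name in ("O", "OXT") or (
            atom_name in T.SIDECHAIN_ACCEPTORS.get(resname, ())
        )
        return donor, acceptor
    if resname in T.NUCLEIC_RESIDUES:
        letter = T.base_letter(resname)
        donor = atom_name in T.SIDECHAIN_DONORS.get(letter, ())
        acceptor = atom_name in T.NUCLEIC_BACKBONE_ACCEPTORS or (
            atom_name in T.SIDECHAIN_ACCEPTORS.get(letter, ())
        )
        return donor, acceptor
    return False, False


@lru_cache(maxsize=None)
def _bond_partners(resname: str) -> dict[str, tuple[str, ...]]:
    out: dict[str, list[str]] = {}
    for a, b in T.residue_bonds(resname):
        out.setdefault(a, []).append(b)
        out.setdefault(b, []).append(a)
    return {k: tuple(v) for k, v in out.items()}


class AtomParams:
    """Vectorized per-atom parameters for a group of atoms."""

    __slots__ = ("pos", "radius", "eps", "charge", "donor", "acceptor", "ante")

    def __init__(self, n: int):
        self.pos = np.zeros((n, 3))
        self.radius = np.zeros(n)
        self.eps = np.zeros(n)
        self.charge = np.zeros(n)
        self.donor = np.zeros(n, dtype=bool)
        self.acceptor = np.zeros(n, dtype=bool)
        self.ante = np.full((n, 3), np.nan)

    def __len__(self):
        return len(self.radius)


def group_params(resname: str, atoms, config: EnergyConfig | None = None) -> AtomParams:
    """Parameters for ``atoms`` = iterable of (name, element, pos) from one
    residue; antecedents are resolved within the given atom set."""
    config = config or EnergyConfig()
    atoms = list(atoms)
    P = AtomParams(len(atoms))
    positions = {name: pos for name, _e, pos in atoms}
    partners = _bond_partners(resname)
    for i, (name, elem, pos) in enumerate(atoms):
        P.pos[i] = pos
        P.radius[i] = T.VDW_RADII.get(elem, 1.70)
        P.eps[i] = T.VDW_EPS.get(elem, 0.10)
        P.charge[i] = atom_charge(resname, name, config.his_charged)
        P.donor[i], P.acceptor[i] = _donor_acceptor(resname, name)
        if P.acceptor[i]:
            for partner in partners.get(name, ()):
                if partner in positions:
                    P.ante[i] = positions[partner]
                    break
    return P


# --------------------------------------------------------------------------
# pair terms
# --------------------------------------------------------------------------

def pair_terms(
    a,
    b,
    resname_a: str,
    resname_b: str,
    ante_a=None,
    ante_b=None,
    config: EnergyConfig | None = None,
) -> tuple[float, float, float]:
    """Surrogate (vdw, elec, hbond) between two atoms in different
    residues or >= 3 bonds apart.

    ``a`` / ``b`` are :class:`AtomRecord`-like objects (``.name``,
    ``.element``, ``.pos``); ``ante_*`` optionally give the acceptor's
    bonded heavy-atom position for the hydrogen-bond angle weight.
    """
    config = config or EnergyConfig()
    r = float(np.linalg.norm(np.asarray(a.pos, float) - np.asarray(b.pos, float)))
    if r == 0.0:
        raise ValueError("degenerate geometry: coincident atoms")
    vdw = elec = hb = 0.0
    if r <= VDW_CUTOFF:
        rmin = T.VDW_RADII.get(a.element, 1.7) + T.VDW_RADII.get(b.element, 1.7)
        eps = math.sqrt(T.VDW_EPS.get(a.element, 0.1) * T.VDW_EPS.get(b.element, 0.1))
        x = (rmin / r) ** 6
        vdw = min(eps * (x * x - 2.0 * x), VDW_CAP)
    if r <= ELEC_CUTOFF:
        qa = atom_charge(resname_a, a.name, config.his_charged)
        qb = atom_charge(resname_b, b.name, config.his_charged)
        if qa != 0.0 and qb != 0.0:
            elec = qa * qb * COULOMB / (4.0 * r * r)
    if HBOND_MIN <= r <= HBOND_MAX:
        da_a = _donor_acceptor(resname_a, a.name)
        da_b = _donor_acceptor(resname_b, b.name)
        wdist = 1.0 - abs(r - 3.0) / 0.4
        cands = []
        if da_a[0] and da_b[1]:
            cands.append(_angle_weight(a.pos, b.pos, ante_b))
        if da_b[0] and da_a[1]:
            cands.append(_angle_weight(b.pos, a.pos, ante_a))
        if cands:
            hb = -1.0 * wdist * max(cands)
    return vdw, elec, hb


def _angle_weight(donor_pos, acceptor_pos, ante_pos) -> float:
    if ante_pos is None or np.any(np.isnan(ante_pos)):
        return 1.0
    from .geometry import bond_angle

    theta = bond_angle(np.asarray(donor_pos, float), np.asarray(acceptor_pos, float),
                       np.asarray(ante_pos, float))
    return max(0.0, 1.0 - abs(theta - 120.0) / 60.0)


def _energy_matrix(A: AtomParams, B: AtomParams) -> np.ndarray:
    """Dense per-pair surrogate energy (vdw + elec + hbond) between two
    atom groups.  No exclusions are applied here."""
    diff = A.pos[:, None, :] - B.pos[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    r = np.where(r == 0.0, np.nan, r)

    rmin = A.radius[:, None] + B.radius[None, :]
    eps = np.sqrt(A.eps[:, None] * B.eps[None, :])
    with np.errstate(invalid="ignore"):
        x = (rmin / r) ** 6
        vdw = np.minimum(eps * (x * x - 2.0 * x), VDW_CAP)
        vdw[~(r <= VDW_CUTOFF)] = 0.0

        qq = A.charge[:, None] * B.charge[None, :]
        elec = np.where((qq != 0.0) & (r <= ELEC_CUTOFF), qq * COULOMB / (4.0 * r * r), 0.0)

        hmask = (r >= HBOND_MIN) & (r <= HBOND_MAX)
        hb = np.zeros_like(r)
        if np.any(hmask):
            wdist = 1.0 - np.abs(r - 3.0) / 0.4
            w_ab = _angle_weight_matrix(A.pos, B.pos, B.ante)      # A donor, B acceptor
            w_ba = _angle_weight_matrix(B.pos, A.pos, A.ante).T    # B donor, A acceptor
            m_ab = A.donor[:, None] & B.acceptor[None, :]
            m_ba = B.donor[None, :] & A.acceptor[:, None]
            w = np.maximum(np.where(m_ab, w_ab, -np.inf), np.where(m_ba, w_ba, -np.inf))
            hb = np.where(hmask & (w > -np.inf), -1.0 * wdist * w, 0.0)

    out = vdw + elec + hb
    return np.nan_to_num(out, nan=0.0)


def _angle_weight_matrix(dpos: np.ndarray, apos: np.ndarray, ante: np.ndarray) -> np.ndarray:
    """w_ang[i, j] for donor i, acceptor j with antecedent ante[j]."""
    u = dpos[:, None, :] - apos[None, :, :]
    v = ante[None, :, :] - apos[None, :, :]
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ijk,ijk->ij", u, v) / (nu * nv)
        theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        w = np.maximum(0.0, 1.0 - np.abs(theta - 120.0) / 60.0)
    return np.where(np.isnan(w), 1.0, w)  # acceptors without antecedent: full weight


def interaction_energy(A: AtomParams, B: AtomParams, factors=None) -> float:
    """Total interaction energy between two disjoint atom groups.

    ``factors`` optionally maps (i, j) index pairs to bonded-exclusion
    scale factors (0 for 1-2/1-3 pairs, 0.5 for 1-4).
    """
    E = _energy_matrix(A, B)
    if factors:
        for (i, j), f in factors.items():
            E[i, j] *= f
    return float(E.sum())


def self_interaction_energy(A: AtomParams, factors=None) -> float:
    """Interaction energy within one atom group (pairs i < j)."""
    E = _energy_matrix(A, A)
    iu = np.triu_indices(len(A), k=1)
    total = E[iu].sum()
    if factors:
        for (i, j), f in factors.items():
            if i < j:
                total += (f - 1.0) * E[i, j]
    return float(total)


# --------------------------------------------------------------------------
# bonded-exclusion topology
# --------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _intra_separations(resname: str) -> dict[tuple[str, str], int]:
    """Bond separations <= 3 between atom names within one residue."""
    return _graph_separations(T.residue_bonds(resname))


@lru_cache(maxsize=None)
def _cross_separations(resname_a: str, resname_b: str, link: tuple[str, str]):
    """Bond separations <= 3 across two covalently linked residues.

    ``link`` is (atom_in_a, atom_in_b), e.g. ("C", "N") for a peptide
    bond from residue a to residue b.  Atom names are tagged "a:" / "b:".
    """
    bonds = [("a:" + x, "a:" + y) for x, y in T.residue_bonds(resname_a)]
    bonds += [("b:" + x, "b:" + y) for x, y in T.residue_bonds(resname_b)]
    bonds.append(("a:" + link[0], "b:" + link[1]))
    seps = _graph_separations(bonds)
    out = {}
    for (x, y), s in seps.items():
        if x.startswith("a:") and y.startswith("b:"):
            out[(x[2:], y[2:])] = s
        elif x.startswith("b:") and y.startswith("a:"):
            out[(y[2:], x[2:])] = s
    return out


def _graph_separations(bonds) -> dict[tuple[str, str], int]:
    adj: dict[str, set[str]] = {}
    for a, b in bonds:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seps: dict[tuple[str, str], int] = {}
    for start in adj:
        dist = {start: 0}
        frontier = [start]
        for d in range(1, 4):
            nxt = []
            for node in frontier:
                for nb in adj[node]:
                    if nb not in dist:
                        dist[nb] = d
                        nxt.append(nb)
            frontier = nxt
        for node, d in dist.items():
            if node != start:
                seps[(start, node)] = min(d, seps.get((start, node), 99))
    return seps


def exclusion_factor(sep: int) -> float:
    if sep <= 2:
        return 0.0
    if sep == 3:
        return 0.5
    return 1.0


def _chain_link(res_a, res_b) -> tuple[str, str] | None:
    """Covalent link atoms between two residues adjacent in a chain."""
    if res_a.polymer == "protein" and res_b.polymer == "protein":
        return ("C", "N")
    if res_a.polymer in ("dna", "rna") and res_b.polymer == res_a.polymer:
        return ("O3'", "P")
    return None


class ComplexTopology:
    """Flat atom indexing + bonded-exclusion bookkeeping for a complex."""

    def __init__(self, model, config: EnergyConfig | None = None):
        self.config = config or EnergyConfig()
        self.atoms: list = []          # AtomRecord refs
        self.residue_of: list[int] = []
        self.residues: list = []
        res_index = {}
        chain_pos = []  # (chain_id, position within chain)
        for cid, chain in model.chains.items():
            for k, res in enumerate(chain):
                res_index[id(res)] = len(self.residues)
                self.residues.append(res)
                chain_pos.append((cid, k))
                for a in res.atoms:
                    self.atoms.append(a)
                    self.residue_of.append(len(self.residues) - 1)

        n = len(self.atoms)
        if n == 0:
            raise ValueError("empty complex")
        self.params = AtomParams(n)
        self.is_protein = np.zeros(n, dtype=bool)
        self.is_dna = np.zeros(n, dtype=bool)
        self.is_rna = np.zeros(n, dtype=bool)
        self._name_index: dict[tuple[int, str], int] = {}
        i = 0
        for ridx, res in enumerate(self.residues):
            rp = group_params(res.name, [(a.name, a.element, a.pos) for a in res.atoms],
                              self.config)
            m = len(res.atoms)
            sl = slice(i, i + m)
            self.params.pos[sl] = rp.pos
            self.params.radius[sl] = rp.radius
            self.params.eps[sl] = rp.eps
            self.params.charge[sl] = rp.charge
            self.params.donor[sl] = rp.donor
            self.params.acceptor[sl] = rp.acceptor
            self.params.ante[sl] = rp.ante
            self.is_protein[sl] = res.polymer == "protein"
            self.is_dna[sl] = res.polymer == "dna"
            self.is_rna[sl] = res.polymer == "rna"
            for k, a in enumerate(res.atoms):
                self._name_index[(ridx, a.name)] = i + k
            i += m

        # excluded pairs: intra-residue plus chain-adjacent cross pairs
        self.exclusions: dict[tuple[int, int], float] = {}
        for ridx, res in enumerate(self.residues):
            for (na, nb), sep in _intra_separations(res.name).items():
                ia = self._name_index.get((ridx, na))
                ib = self._name_index.get((ridx, nb))
                if ia is not None and ib is not None and ia < ib:
                    self.exclusions[(ia, ib)] = exclusion_factor(sep)
        for ridx in range(len(self.residues) - 1):
            ra, rb = self.residues[ridx], self.residues[ridx + 1]
            if chain_pos[ridx][0] != chain_pos[ridx + 1][0]:
                continue
            link = _chain_link(ra, rb)
            if link is None:
                continue
            for (na, nb), sep in _cross_separations(ra.name, rb.name, link).items():
                ia = self._name_index.get((ridx, na))
                ib = self._name_index.get((ridx + 1, nb))
                if ia is not None and ib is not None:
                    lo, hi = min(ia, ib), max(ia, ib)
                    self.exclusions[(lo, hi)] = exclusion_factor(sep)

    def separation(self, i: int, j: int) -> int:
        """Bond separation, saturated at 4 for anything beyond 1-4."""
        lo, hi = (i, j) if i < j else (j, i)
        f = self.exclusions.get((lo, hi))
        if f is None:
            return 4 if self.residue_of[i] != self.residue_of[j] or i == j else 4
        return 3 if f == 0.5 else 2


# --------------------------------------------------------------------------
# decomposition
# --------------------------------------------------------------------------

def decompose(model, weights: ScoreWeights | None = None,
              config: EnergyConfig | None = None) -> EnergyBreakdown:
    """Binding / non-binding decomposition of the surrogate energy.

    ``bind`` sums pair terms between protein atoms and nucleic-acid atoms
    (DNA and, by default, RNA); ``non_bind`` sums every other admissible
    pair.  Bonded 1-2/1-3 pairs are skipped and 1-4 pairs scaled by 0.5.
    """
    weights = weights or ScoreWeights()
    topo = ComplexTopology(model, config)
    P = topo.params
    n = len(P)

    nuc = topo.is_dna | topo.is_rna
    bind_nuc = topo.is_dna | (topo.is_rna if topo.config.include_rna_in_binding else False)

    bind = 0.0
    non_bind = 0.0
    block = 600
    for start in range(0, n, block):
        stop = min(start + block, n)
        sub = AtomParams(stop - start)
        for attr in ("pos", "radius", "eps", "charge", "donor", "acceptor", "ante"):
            setattr(sub, attr, getattr(P, attr)[start:stop])
        E = _energy_matrix(sub, P)
        # keep strictly upper-triangular part of the global matrix
        cols = np.arange(n)[None, :]
        rows = np.arange(start, stop)[:, None]
        E[cols <= rows] = 0.0
        bmask = (topo.is_protein[start:stop, None] & bind_nuc[None, :]) | (
            bind_nuc[start:stop, None] & topo.is_protein[None, :]
        )
        bind += float(E[bmask].sum())
        non_bind += float(E[~bmask].sum())

    # bonded-exclusion corrections (sparse, scalar)
    for (i, j), f in topo.exclusions.items():
        if f == 1.0:
            continue
        e = _pair_energy_scalar(topo, i, j)
        if e == 0.0:
            continue
        corr = (f - 1.0) * e
        if (topo.is_protein[i] and bind_nuc[j]) or (topo.is_protein[j] and bind_nuc[i]):
            bind += corr
        else:
            non_bind += corr

    return EnergyBreakdown(non_bind=non_bind, bind=bind, evo=0.0, n_oor=0, x_exist=0,
                           weights=weights)


def _pair_energy_scalar(topo: ComplexTopology, i: int, j: int) -> float:
    P = topo.params
    sub_a = AtomParams(1)
    sub_b = AtomParams(1)
    for attr in ("pos", "radius", "eps", "charge", "donor", "acceptor", "ante"):
        getattr(sub_a, attr)[0] = getattr(P, attr)[i]
        getattr(sub_b, attr)[0] = getattr(P, attr)[j]
    return float(_energy_matrix(sub_a, sub_b)[0, 0])


# --------------------------------------------------------------------------
# side-chain placement score (used by repair / build_mutant / tables)
# --------------------------------------------------------------------------

def local_exclusion_factors(model, res, identity: str, conf_names: list[str]):
    """Exclusion factors between a candidate side chain at ``res`` (built
    as ``identity``) and nearby atoms of the complex.

    Returns ``(env_atoms, factors)`` where env_atoms is the list of
    (residue, AtomRecord) pairs forming the environment (everything
    except the residue's own side chain) and factors maps
    (conf_index, env_index) to the bonded scale factor.
    """
    env = []
    factors = {}
    chain = model.chains[res.chain_id]
    pos_in_chain = chain.index(res)
    neighbors = {}
    if pos_in_chain > 0:
        neighbors[id(chain[pos_in_chain - 1])] = ("prev", chain[pos_in_chain - 1])
    if pos_in_chain + 1 < len(chain):
        neighbors[id(chain[pos_in_chain + 1])] = ("next", chain[pos_in_chain + 1])
    intra = _intra_separations(identity)
    for other in model.residues():
        for a in other.atoms:
            if other is res and not a.is_backbone:
                continue  # the side chain being replaced
            ei = len(env)
            env.append((other, a))
            if other is res:
                for ci, cname in enumerate(conf_names):
                    sep = intra.get((cname, a.name))
                    if sep is not None:
                        factors[(ci, ei)] = exclusion_factor(sep)
            elif id(other) in neighbors:
                side, nres = neighbors[id(other)]
                link = _chain_link(nres, res) if side == "prev" else _chain_link(res, other)
                if link is None:
                    continue
                if side == "prev":
                    cross = _cross_separations(nres.name, identity, link)
                    for ci, cname in enumerate(conf_names):
                        sep = cross.get((a.name, cname))
                        if sep is not None:
                            factors[(ci, ei)] = exclusion_factor(sep)
                else:
                    cross = _cross_separations(identity, other.name, link)
                    for ci, cname in enumerate(conf_names):
                        sep = cross.get((cname, a.name))
                        if sep is not None:
                            factors[(ci, ei)] = exclusion_factor(sep)
    return env, factors


def interaction_energy_split(A: AtomParams, B: AtomParams, bind_mask: np.ndarray,
                             factors=None) -> tuple[float, float]:
    """Interaction energy between two groups, split into (non_bind, bind)
    by a per-B-atom mask marking nucleic-acid atoms that count toward the
    binding component (group A is assumed protein)."""
    E = _energy_matrix(A, B)
    if factors:
        for (i, j), f in factors.items():
            E[i, j] *= f
    bind = float(E[:, bind_mask].sum())
    non_bind = float(E[:, ~bind_mask].sum())
    return non_bind, bind


def _env_params(model, res, identity: str, conf_names, center,
                config: EnergyConfig, reach: float = 18.0):
    """Residue-grouped environment parameters + exclusion factors for
    candidate side chains at ``res`` built as ``identity``.

    The environment is every atom of the complex except the residue's own
    side chain, truncated to ``reach`` of ``center`` (all pair terms
    vanish beyond the 10 A cutoff, and side chains extend < 8 A)."""
    env, factors = local_exclusion_factors(model, res, identity, conf_names)
    keep = []
    keep_factors: dict[tuple[int, int], float] = {}
    inv = {}
    for ei, (other, a) in enumerate(env):
        if np.linalg.norm(a.pos - center) > reach:
            # never drop bonded partners (they are nearby anyway)
            if not any((ci, ei) in factors for ci in range(len(conf_names))):
                continue
        inv[ei] = len(keep)
        keep.append((other, a))
    for (ci, ei), f in factors.items():
        if ei in inv:
            keep_factors[(ci, inv[ei])] = f
    B = AtomParams(len(keep))
    bind_mask = np.zeros(len(keep), dtype=bool)
    by_res: dict[int, list] = {}
    for other, a in keep:
        by_res.setdefault(id(other), []).append((other, a))
    env_order = []
    idx = 0
    for items in by_res.values():
        other = items[0][0]
        rp = group_params(other.name, [(a.name, a.element, a.pos) for _o, a in items], config)
        sl = slice(idx, idx + len(items))
        for attr in ("pos", "radius", "eps", "charge", "donor", "acceptor", "ante"):
            getattr(B, attr)[sl] = getattr(rp, attr)
        bind_mask[sl] = other.polymer == "dna" or (
            other.polymer == "rna" and config.include_rna_in_binding
        )
        env_order.extend(items)
        idx += len(items)
    order_map = {id(a): k for k, (_o, a) in enumerate(env_order)}
    remapped = {(ci, order_map[id(keep[ei][1])]): f for (ci, ei), f in keep_factors.items()}
    return B, remapped, bind_mask


def _intra_factors(identity: str, conf_names) -> dict[tuple[int, int], float]:
    intra = _intra_separations(identity)
    out = {}
    for i, ni in enumerate(conf_names):
        for j, nj in enumerate(conf_names):
            if i < j:
                sep = intra.get((ni, nj))
                if sep is not None:
                    out[(i, j)] = exclusion_factor(sep)
    return out


def placement_energies(model, res, identity: str, conformers,
                       config: EnergyConfig | None = None) -> list[float]:
    """Environment + internal energy of each candidate conformer.

    All conformers of one identity share atom names, so the environment
    and its exclusion factors are computed once.
    """
    return [nb + b for nb, b in placement_energies_split(model, res, identity,
                                                         conformers, config)]


def placement_energies_split(model, res, identity: str, conformers,
                             config: EnergyConfig | None = None
                             ) -> list[tuple[float, float]]:
    """Like :func:`placement_energies` but split into (non_bind, bind):
    the binding part is the conformer's interaction with nucleic-acid
    atoms; internal strain counts as non-binding."""
    config = config or EnergyConfig()
    if not conformers or not conformers[0]:
        return [(0.0, 0.0) for _ in conformers]
    conf_names = [name for name, _e, _p in conformers[0]]
    center = res.atom("CA").pos
    B, factors, bind_mask = _env_params(model, res, identity, conf_names, center, config)
    self_factors = _intra_factors(identity, conf_names)
    out = []
    for conf in conformers:
        A = group_params(identity, conf, config)
        nb, b = interaction_energy_split(A, B, bind_mask, factors)
        if len(A) > 1:
            nb += self_interaction_energy(A, self_factors)
        out.append((nb, b))
    return out


def side_chain_environment_energy(model, res, identity: str, conformer,
                                  config: EnergyConfig | None = None) -> float:
    """Interaction energy of one placed side-chain conformer with the rest
    of the complex (own backbone included) plus its internal energy."""
    return placement_energies(model, res, identity, [conformer], config)[0]
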