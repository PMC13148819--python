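"""Independent brute-force oracles used by the test suite.

Everything here is written against the plain definitions (scalar loops,
breadth-first bond searches, cartesian-product filters) and deliberately
shares no computational path with the vectorized implementation it
cross-checks.  Parameter tables (radii, charges, donor/acceptor sets)
are shared — the oracles check the computation, not the parameters.
"""

from __future__ import annotations

import itertools
import math

import pamdesign.templates as T


# --------------------------------------------------------------------------
# bond graph and separations
# --------------------------------------------------------------------------

def build_bond_graph(model):
    """Adjacency over atom ids from per-residue templates + chain links."""
    adj = {}

    def add(a, b):
        adj.setdefault(id(a), set()).add(id(b))
        adj.setdefault(id(b), set()).add(id(a))

    for chain in model.chains.values():
        prev = None
        for res in chain:
            atoms = {a.name: a for a in res.atoms}
            for na, nb in T.residue_bonds(res.name):
                if na in atoms and nb in atoms:
                    add(atoms[na], atoms[nb])
            if prev is not None:
                pa = {a.name: a for a in prev.atoms}
                if prev.polymer == "protein" and res.polymer == "protein":
                    if "C" in pa and "N" in atoms:
                        add(pa["C"], atoms["N"])
                elif prev.polymer in ("dna", "rna") and res.polymer == prev.polymer:
                    if "O3'" in pa and "P" in atoms:
                        add(pa["O3'"], atoms["P"])
            prev = res
    return adj


def bond_separation(adj, a, b, cap=4):
    if id(a) == id(b):
        return 0
    frontier = {id(a)}
    seen = {id(a)}
    for d in range(1, cap + 1):
        nxt = set()
        for node in frontier:
            for nb in adj.get(node, ()):
                if nb not in seen:
                    if nb == id(b):
                        return d
                    nxt.add(nb)
                    seen.add(nb)
        frontier = nxt
    return cap + 1


# --------------------------------------------------------------------------
# scalar energy oracle
# --------------------------------------------------------------------------

def _charge(resname, atom):
    q = T.PARTIAL_CHARGES.get((resname, atom))
    if q is not None:
        return q
    if resname in T.NUCLEIC_RESIDUES and atom in T.PHOSPHATE_CHARGES:
        return T.PHOSPHATE_CHARGES[atom]
    return 0.0


def _donor(resname, atom):
    if resname in T.PROTEIN_RESIDUES:
        return (atom == "N" and resname != "PRO") or atom in T.SIDECHAIN_DONORS.get(resname, ())
    if resname in T.NUCLEIC_RESIDUES:
        return atom in T.SIDECHAIN_DONORS.get(T.base_letter(resname), ())
    return False


def _acceptor(resname, atom):
    if resname in T.PROTEIN_RESIDUES:
        return atom in ("O", "OXT") or atom in T.SIDECHAIN_ACCEPTORS.get(resname, ())
    if resname in T.NUCLEIC_RESIDUES:
        return atom in T.NUCLEIC_BACKBONE_ACCEPTORS or atom in T.SIDECHAIN_ACCEPTORS.get(
            T.base_letter(resname), ()
        )
    return False


def _dist(p, q):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(p, q)))


def _angle(a, b, c):
    ux, uy, uz = (a[0] - b[0], a[1] - b[1], a[2] - b[2])
    vx, vy, vz = (c[0] - b[0], c[1] - b[1], c[2] - b[2])
    dot = ux * vx + uy * vy + uz * vz
    nu = math.sqrt(ux * ux + uy * uy + uz * uz)
    nv = math.sqrt(vx * vx + vy * vy + vz * vz)
    return math.degrees(math.acos(max(-1.0, min(1.0, dot / (nu * nv)))))


def _antecedent(res, atom):
    partners = {}
    for na, nb in T.residue_bonds(res.name):
        partners.setdefault(na, []).append(nb)
        partners.setdefault(nb, []).append(na)
    present = {a.name: a for a in res.atoms}
    for partner in partners.get(atom.name, ()):
        if partner in present:
            return present[partner]
    return None


def scalar_pair_energy(res_a, a, res_b, b):
    """(vdw, elec, hbond) computed with plain scalar arithmetic."""
    r = _dist(a.pos, b.pos)
    vdw = elec = hb = 0.0
    if r <= 8.0:
        rmin = T.VDW_RADII[a.element] + T.VDW_RADII[b.element]
        eps = math.sqrt(T.VDW_EPS[a.element] * T.VDW_EPS[b.element])
        x = (rmin / r) ** 6
        vdw = min(eps * (x * x - 2 * x), 10.0)
    if r <= 10.0:
        qa, qb = _charge(res_a.name, a.name), _charge(res_b.name, b.name)
        if qa and qb:
            elec = qa * qb * 332.0 / (4.0 * r * r)
    if 2.6 <= r <= 3.4:
        weights = []
        if _donor(res_a.name, a.name) and _acceptor(res_b.name, b.name):
            ante = _antecedent(res_b, b)
            w = 1.0 if ante is None else max(
                0.0, 1.0 - abs(_angle(a.pos, b.pos, ante.pos) - 120.0) / 60.0
            )
            weights.append(w)
        if _donor(res_b.name, b.name) and _acceptor(res_a.name, a.name):
            ante = _antecedent(res_a, a)
            w = 1.0 if ante is None else max(
                0.0, 1.0 - abs(_angle(b.pos, a.pos, ante.pos) - 120.0) / 60.0
            )
            weights.append(w)
        if weights:
            hb = -(1.0 - abs(r - 3.0) / 0.4) * max(weights)
    return vdw, elec, hb


def brute_force_decompose(model, include_rna=True):
    """(non_bind, bind) by an O(N^2) scalar double loop."""
    adj = build_bond_graph(model)
    flat = [(res, a) for res in model.residues() for a in res.atoms]
    non_bind = bind = 0.0
    for i in range(len(flat)):
        res_a, a = flat[i]
        for j in range(i + 1, len(flat)):
            res_b, b = flat[j]
            sep = bond_separation(adj, a, b)
            if sep <= 2:
                continue
            factor = 0.5 if sep == 3 else 1.0
            e = factor * sum(scalar_pair_energy(res_a, a, res_b, b))
            pa, pb = res_a.polymer, res_b.polymer
            nuc = {"dna", "rna"} if include_rna else {"dna"}
            if (pa == "protein" and pb in nuc) or (pb == "protein" and pa in nuc):
                bind += e
            else:
                non_bind += e
    return non_bind, bind


def count_clashes(model):
    """Independent O(N^2) steric-clash counter: atom pairs (bond
    separation > 3) closer than 0.8x the sum of vdW radii."""
    adj = build_bond_graph(model)
    flat = [(res, a) for res in model.residues() for a in res.atoms]
    n = 0
    for i in range(len(flat)):
        res_a, a = flat[i]
        for j in range(i + 1, len(flat)):
            res_b, b = flat[j]
            if res_a is res_b and a.is_backbone and b.is_backbone:
                continue
            if _dist(a.pos, b.pos) < 0.8 * (T.VDW_RADII[a.element] + T.VDW_RADII[b.element]):
                if bond_separation(adj, a, b) > 3:
                    n += 1
    return n


# --------------------------------------------------------------------------
# design-site selection oracle
# --------------------------------------------------------------------------

def brute_force_site_selection(model, focus, d_side=4.5, d_pam=6.0):
    """Mutable/repackable classification by exhaustive distance loops."""
    pam = model.pam
    region = []
    for chain, numbers in ((pam.nts_chain, pam.nts_numbers), (pam.ts_chain, pam.ts_numbers)):
        for n in range(min(numbers) - pam.flank, max(numbers) + pam.flank + 1):
            try:
                region.append(model.get(chain, n))
            except KeyError:
                pass
    pam_bb = [a.pos for r in region for a in r.atoms if a.is_backbone]
    focus_res = model.get(*focus)
    focus_side = [a.pos for a in focus_res.atoms if not a.is_backbone]
    protein = [r for r in model.residues() if r.polymer == "protein"]

    def side(r):
        return [a.pos for a in r.atoms if not a.is_backbone]

    def within(ps, qs, cut):
        return any(_dist(p, q) <= cut for p in ps for q in qs)

    mutable = {focus}
    for r in protein:
        key = (r.chain_id, r.number)
        if r is not focus_res and within(side(r), focus_side, d_side):
            mutable.add(key)
        if within(side(r), pam_bb, d_pam):
            mutable.add(key)
    mut_side = []
    for c, n in mutable:
        mut_side.extend(side(model.get(c, n)))
    repackable = set()
    for r in protein:
        key = (r.chain_id, r.number)
        if key not in mutable and within(side(r), mut_side, d_side):
            repackable.add(key)
    return sorted(mutable), sorted(repackable)


# --------------------------------------------------------------------------
# enumeration oracle
# --------------------------------------------------------------------------

def brute_force_enumeration(spec):
    """Feasible sequences by filtering the full cartesian product."""
    sites = spec.design_sites
    native = [spec.native_sequence[s.site] for s in sites]
    out = set()
    for combo in itertools.product(*(sorted(s.allowed) for s in sites)):
        n_mut = sum(1 for c, nat in zip(combo, native) if c != nat)
        if spec.n_min <= n_mut <= spec.n_max:
            out.add(combo)
    return out
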