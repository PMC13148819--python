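"""Constrained simulated-annealing Monte Carlo search over rotamer and
sequence space, with an exhaustive oracle for small spaces.

The search state is one rotamer (identity + conformer) per mobile site:
designable sites move in both sequence and conformation, repack-only
sites in conformation only.  The Metropolis criterion acts on the full
design score E_total, including the mutation-count penalty w_OOR*N_OOR
and the duplicate penalty w_exist*X_exist evaluated against the reserved
set frozen at trajectory start.  With the default penalty weights (1000)
any constraint violation dwarfs the physical energy scale of the
packaged fixtures, so trajectories converge into the feasible, novel
part of sequence space whenever it is non-empty.

Energies are precomputed into tables (fixed-environment constant,
per-site self energies, pairwise site-site couplings) so the inner loop
touches no geometry; given a seed, everything is bit-reproducible via a
counter-based Philox generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import templates as T
from .constraints import DesignSpec, enumerate_design_space
from .energy import (
    EnergyBreakdown,
    EnergyConfig,
    ScoreWeights,
    decompose,
    placement_energies_split,
)
from .rotamers import build_rotamers
from .structure import AtomRecord, ComplexModel

__all__ = [
    "AnnealSchedule",
    "DesignRecord",
    "DesignSet",
    "PackedSystem",
    "run_trajectory",
    "run_design",
    "run_repeats",
    "exhaustive_oracle",
    "OracleSizeError",
]

#: sites farther apart than this never produce a nonzero pair table
PAIR_SKIP_DISTANCE = 26.0


@dataclass
class AnnealSchedule:
    t_start: float = 30.0
    t_final: float = 0.3
    cooling: float = 0.85
    steps_per_stage: int | None = None  # default 500 * number of mobile sites

    def __post_init__(self):
        if not (self.t_start > self.t_final > 0):
            raise ValueError("need t_start > t_final > 0")
        if not (0 < self.cooling < 1):
            raise ValueError("cooling factor must be in (0, 1)")

    def temperatures(self) -> list[float]:
        temps = []
        t = self.t_start
        while t >= self.t_final:
            temps.append(t)
            t *= self.cooling
        return temps

    def steps(self, n_sites: int) -> int:
        if self.steps_per_stage is not None:
            return self.steps_per_stage
        return 500 * max(1, n_sites)


@dataclass
class DesignRecord:
    mutations: tuple[tuple[tuple[str, int], str, str], ...]  # (site, native, new)
    n_mut: int
    sequence: tuple[str, ...]
    breakdown: EnergyBreakdown
    state_id: str = ""
    trajectory: int = -1
    seed: int = 0
    assignment: tuple[int, ...] = ()

    @property
    def mutation_string(self) -> str:
        if not self.mutations:
            return "WT"
        return ";".join(f"{nat}{site[1]}{new}" for site, nat, new in self.mutations)


@dataclass
class DesignSet:
    records: list[DesignRecord] = field(default_factory=list)
    reserved: set[tuple[str, ...]] = field(default_factory=set)

    def sequences(self) -> set[tuple[str, ...]]:
        return {r.sequence for r in self.records}

    def to_tsv(self) -> str:
        lines = ["rank\tmutations\tn_mut\tnon_bind\tbind\ttotal\ttrajectory\tseed"]
        for k, r in enumerate(self.records, 1):
            lines.append(
                f"{k}\t{r.mutation_string}\t{r.n_mut}\t{r.breakdown.non_bind:.6f}"
                f"\t{r.breakdown.bind:.6f}\t{r.breakdown.total:.6f}\t{r.trajectory}\t{r.seed}"
            )
        return "\n".join(lines) + "\n"


class OracleSizeError(ValueError):
    pass


# --------------------------------------------------------------------------
# precomputed energy tables
# --------------------------------------------------------------------------

class PackedSystem:
    """Energy tables for one complex + design specification.

    The complex is split into a fixed environment (all atoms except the
    side chains of mobile sites) and per-site conformer sets.  Tables:

    * ``e_fixed``: (non_bind, bind) of the fixed environment alone;
    * ``self_nb/self_b[s][g]``: conformer g of site s against the fixed
      environment, plus internal strain (non-binding);
    * ``pair[(s, t)][g, h]``: side-chain/side-chain coupling (non-binding;
      mobile sites are protein).

    Conformer order per site: identities in deterministic (sorted
    allowed-set) order, library rotamer order within each identity.
    """

    def __init__(self, model: ComplexModel, spec: DesignSpec,
                 config: EnergyConfig | None = None):
        self.spec = spec
        self.config = config or EnergyConfig()
        self.weights = spec.weights

        self.design_sites = [s.site for s in spec.design_sites]
        self.repack_sites = [s.site for s in spec.repack_sites]
        self.sites = self.design_sites + self.repack_sites
        self.n_design = len(self.design_sites)
        for site in self.sites:
            if not model.has(*site):
                raise KeyError(f"design site {site} not present in the model")

        self.native = [spec.native_sequence[s] for s in self.design_sites]

        # stripped model: mobile side chains removed
        self.base = model.copy()
        mobile = set(self.sites)
        for res in self.base.residues():
            if (res.chain_id, res.number) in mobile:
                res.atoms = [a for a in res.atoms if a.is_backbone]
        bd = decompose(self.base, spec.weights, self.config)
        self.e_fixed = (bd.non_bind, bd.bind)

        allowed = {s.site: sorted(s.allowed) for s in spec.design_sites}
        for s in spec.repack_sites:
            allowed[s.site] = [spec.native_sequence.get(s.site) or _native_letter(model, s.site)]
        for site in self.repack_sites:
            if site not in spec.native_sequence:
                allowed[site] = [_native_letter(model, site)]

        self.letters: list[list[str]] = []       # per site, per conformer
        self.identity_of: list[list[str]] = []   # 3-letter identity per conformer
        self.conformers: list[list[list]] = []   # placed atoms per conformer
        self.self_nb: list[np.ndarray] = []
        self.self_b: list[np.ndarray] = []
        self.letter_blocks: list[dict[str, tuple[int, int]]] = []
        for site in self.sites:
            res = self.base.get(*site)
            letters, idents, confs = [], [], []
            nb_list, b_list = [], []
            blocks = {}
            for letter in allowed[site]:
                ident = T.AA_1TO3[letter]
                placed = build_rotamers(self.base, site, ident)
                split = placement_energies_split(self.base, res, ident, placed, self.config)
                start = len(confs)
                for conf, (nb, b) in zip(placed, split):
                    letters.append(letter)
                    idents.append(ident)
                    confs.append(conf)
                    nb_list.append(nb)
                    b_list.append(b)
                blocks[letter] = (start, len(confs))
            self.letters.append(letters)
            self.identity_of.append(idents)
            self.conformers.append(confs)
            self.self_nb.append(np.array(nb_list))
            self.self_b.append(np.array(b_list))
            self.letter_blocks.append(blocks)

        # pairwise coupling tables
        self.pair: dict[tuple[int, int], np.ndarray] = {}
        self.neighbors: list[list[int]] = [[] for _ in self.sites]
        ca = [self.base.get(*s).atom("CA").pos for s in self.sites]
        for i in range(len(self.sites)):
            for j in range(i + 1, len(self.sites)):
                if np.linalg.norm(ca[i] - ca[j]) > PAIR_SKIP_DISTANCE:
                    continue
                tab = self._pair_table(i, j)
                if tab is not None:
                    self.pair[(i, j)] = tab
                    self.neighbors[i].append(j)
                    self.neighbors[j].append(i)

    def _pair_table(self, i: int, j: int) -> np.ndarray | None:
        from .energy import _energy_matrix, group_params

        ni, nj = len(self.conformers[i]), len(self.conformers[j])
        tab = np.zeros((ni, nj))
        any_nonzero = False
        # block by identity so atom counts are uniform within a block
        for li, (ai, bi) in self.letter_blocks[i].items():
            confs_i = self.conformers[i][ai:bi]
            if not confs_i or not confs_i[0]:
                continue
            Pi = _stack_params(self.identity_of[i][ai], confs_i, self.config)
            n_at_i = len(confs_i[0])
            for lj, (aj, bj) in self.letter_blocks[j].items():
                confs_j = self.conformers[j][aj:bj]
                if not confs_j or not confs_j[0]:
                    continue
                Pj = _stack_params(self.identity_of[j][aj], confs_j, self.config)
                n_at_j = len(confs_j[0])
                E = _energy_matrix(Pi, Pj)
                block = E.reshape(len(confs_i), n_at_i, len(confs_j), n_at_j).sum(axis=(1, 3))
                if np.any(block != 0.0):
                    any_nonzero = True
                tab[ai:bi, aj:bj] = block
        return tab if any_nonzero else None

    # -- evaluation helpers ----------------------------------------------
    def initial_assignment(self) -> list[int]:
        """Native identity (or first allowed) at its lowest-self-energy
        rotamer, per site."""
        out = []
        for s, site in enumerate(self.sites):
            if s < self.n_design:
                nat = self.native[s]
                letter = nat if nat in self.letter_blocks[s] else next(iter(self.letter_blocks[s]))
            else:
                letter = next(iter(self.letter_blocks[s]))
            a, b = self.letter_blocks[s][letter]
            tot = self.self_nb[s][a:b] + self.weights.w_bind * self.self_b[s][a:b]
            out.append(a + int(np.argmin(tot)))
        return out

    def sequence_of(self, assignment) -> tuple[str, ...]:
        return tuple(self.letters[s][assignment[s]] for s in range(self.n_design))

    def phys_energy(self, assignment) -> tuple[float, float]:
        """(non_bind, bind) of an assignment, tables + fixed constant."""
        nb, b = self.e_fixed
        for s, g in enumerate(assignment):
            nb += float(self.self_nb[s][g])
            b += float(self.self_b[s][g])
        for (i, j), tab in self.pair.items():
            nb += float(tab[assignment[i], assignment[j]])
        return nb, b

    def weighted_phys(self, assignment) -> float:
        nb, b = self.phys_energy(assignment)
        return nb + self.weights.w_bind * b

    def n_mut(self, assignment) -> int:
        return sum(
            1 for s in range(self.n_design)
            if self.letters[s][assignment[s]] != self.native[s]
        )

    def realize(self, assignment) -> ComplexModel:
        """Materialize an assignment as a full-coordinate complex."""
        out = self.base.copy()
        for s, site in enumerate(self.sites):
            res = out.get(*site)
            conf = self.conformers[s][assignment[s]]
            res.name = self.identity_of[s][assignment[s]]
            res.atoms = [a for a in res.atoms if a.is_backbone] + [
                AtomRecord(name, elem, pos.copy(), False) for name, elem, pos in conf
            ]
        out.provenance.append("realize(" + ",".join(map(str, assignment)) + ")")
        return out

    def record(self, assignment, state_id="", trajectory=-1, seed=0) -> DesignRecord:
        nb, b = self.phys_energy(assignment)
        seq = self.sequence_of(assignment)
        muts = tuple(
            (self.design_sites[s], self.native[s], seq[s])
            for s in range(self.n_design)
            if seq[s] != self.native[s]
        )
        bd = EnergyBreakdown(non_bind=nb, bind=b, evo=0.0, n_oor=0, x_exist=0,
                             weights=self.weights)
        return DesignRecord(
            mutations=muts, n_mut=len(muts), sequence=seq, breakdown=bd,
            state_id=state_id, trajectory=trajectory, seed=seed,
            assignment=tuple(assignment),
        )


def _native_letter(model, site) -> str:
    return T.AA_3TO1[model.get(*site).name]


def _stack_params(identity: str, conformers, config):
    from .energy import AtomParams, group_params

    parts = [group_params(identity, conf, config) for conf in conformers]
    n = sum(len(p) for p in parts)
    P = AtomParams(n)
    i = 0
    for p in parts:
        sl = slice(i, i + len(p))
        for attr in ("pos", "radius", "eps", "charge", "donor", "acceptor", "ante"):
            getattr(P, attr)[sl] = getattr(p, attr)
        i += len(p)
    return P


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

def run_trajectory(
    system: PackedSystem,
    reserved: set,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
    state_id: str = "",
    trajectory: int = -1,
    step_multiplier: int = 1,
) -> DesignRecord | None:
    """One seeded SAMC trajectory.  Returns the lowest-E_total feasible,
    novel state visited, or None (exhaustion) if no such state was seen.

    ``reserved`` is frozen for the duration of the trajectory: the
    duplicate penalty compares against it, not against states visited
    inside the trajectory.
    """
    schedule = schedule or AnnealSchedule()
    w = system.weights
    n_sites = len(system.sites)
    n_design = system.n_design
    rng = np.random.Generator(np.random.Philox(key=abs(int(seed))))

    assignment = system.initial_assignment()
    steps = schedule.steps(n_sites) * step_multiplier

    self_tot = [system.self_nb[s] + w.w_bind * system.self_b[s] for s in range(n_sites)]
    pair = system.pair
    neighbors = system.neighbors
    letters = system.letters
    native = system.native

    phys = system.weighted_phys(assignment) - (
        system.e_fixed[0] + w.w_bind * system.e_fixed[1]
    )
    seq = [letters[s][assignment[s]] for s in range(n_design)]
    n_mut = sum(1 for s in range(n_design) if seq[s] != native[s])
    dup = 1 if tuple(seq) in reserved else 0

    n_min, n_max = system.spec.n_min, system.spec.n_max
    noor = _noor(n_mut, n_min, n_max)

    best_feasible = None  # (phys, assignment tuple)
    if noor == 0 and dup == 0:
        best_feasible = (phys, tuple(assignment))

    counts = [len(c) for c in system.conformers]
    if n_sites == 0 or all(c <= 1 for c in counts):
        # nothing to search; the initial state is the only state
        if best_feasible is None:
            return None
        return system.record(list(best_feasible[1]), state_id, trajectory, seed)

    w_oor, w_exist = w.w_oor, w.w_exist
    exp = math.exp

    for temp in schedule.temperatures():
        u_move = rng.random(steps)
        u_site = rng.random(steps)
        u_conf = rng.random(steps)
        u_acc = rng.random(steps)
        for k in range(steps):
            if u_move[k] < 0.5 and n_design > 0:
                s = int(u_site[k] * n_design)
                g_new = int(u_conf[k] * counts[s])
            else:
                s = int(u_site[k] * n_sites)
                ident = system.identity_of[s][assignment[s]]
                a, b = system.letter_blocks[s][letters[s][assignment[s]]]
                g_new = a + int(u_conf[k] * (b - a))
            g_old = assignment[s]
            if g_new == g_old:
                continue
            d_phys = float(self_tot[s][g_new]) - float(self_tot[s][g_old])
            for t in neighbors[s]:
                if s < t:
                    tab = pair[(s, t)]
                    d_phys += float(tab[g_new, assignment[t]]) - float(tab[g_old, assignment[t]])
                else:
                    tab = pair[(t, s)]
                    d_phys += float(tab[assignment[t], g_new]) - float(tab[assignment[t], g_old])
            if s < n_design and letters[s][g_new] != seq[s]:
                new_letter = letters[s][g_new]
                d_mut = (1 if new_letter != native[s] else 0) - (
                    1 if seq[s] != native[s] else 0
                )
                new_n_mut = n_mut + d_mut
                new_noor = _noor(new_n_mut, n_min, n_max)
                old_letter = seq[s]
                seq[s] = new_letter
                new_dup = 1 if tuple(seq) in reserved else 0
                seq[s] = old_letter
            else:
                new_letter = None
                new_n_mut, new_noor, new_dup = n_mut, noor, dup
            d_total = d_phys + w_oor * (new_noor - noor) + w_exist * (new_dup - dup)
            if d_total <= 0.0 or u_acc[k] < exp(-d_total / temp):
                assignment[s] = g_new
                phys += d_phys
                if new_letter is not None:
                    seq[s] = new_letter
                    n_mut, noor, dup = new_n_mut, new_noor, new_dup
                if noor == 0 and dup == 0 and (
                    best_feasible is None or phys < best_feasible[0] - 1e-12
                ):
                    best_feasible = (phys, tuple(assignment))

    if best_feasible is None:
        return None
    return system.record(list(best_feasible[1]), state_id, trajectory, seed)


def _noor(n_mut, n_min, n_max):
    if n_mut < n_min:
        return n_min - n_mut
    if n_mut > n_max:
        return n_mut - n_max
    return 0


# --------------------------------------------------------------------------
# multi-trajectory design
# --------------------------------------------------------------------------

def run_design(
    model_or_system,
    spec: DesignSpec | None = None,
    schedule: AnnealSchedule | None = None,
    n_traj: int = 1000,
    base_seed: int = 0,
    reserved: set | None = None,
    state_id: str = "",
    config: EnergyConfig | None = None,
) -> DesignSet:
    """Sequential uniqueness-enforced design generation.

    Trajectory i runs with seed ``base_seed + i``; each returned sequence
    joins the reserved set before the next trajectory starts.  A
    trajectory that signals exhaustion is retried once with 3x steps;
    if it still finds nothing novel and feasible the run stops early.
    Records are sorted by E_total ascending, ties by trajectory index.
    """
    if isinstance(model_or_system, PackedSystem):
        system = model_or_system
    else:
        system = PackedSystem(model_or_system, spec, config)
    schedule = schedule or AnnealSchedule()
    reserved = set(reserved) if reserved else set()
    records: list[DesignRecord] = []
    for i in range(n_traj):
        rec = run_trajectory(system, reserved, schedule, seed=base_seed + i,
                             state_id=state_id, trajectory=i)
        if rec is None:
            rec = run_trajectory(system, reserved, schedule, seed=base_seed + i,
                                 state_id=state_id, trajectory=i, step_multiplier=3)
        if rec is None:
            break
        records.append(rec)
        reserved.add(rec.sequence)
    records.sort(key=lambda r: (r.breakdown.total, r.trajectory))
    return DesignSet(records=records, reserved=reserved)


@dataclass
class ConvergenceReport:
    kept: list[int]                       # indices of kept repeats
    best_totals: list[float]              # best E_total per repeat
    spread: float                         # max-min among kept repeats
    recurrence: dict[tuple[str, ...], int]  # sequence -> #repeats producing it

    def to_tsv(self) -> str:
        lines = ["sequence\trepeats"]
        for seq, n in sorted(self.recurrence.items(), key=lambda kv: (-kv[1], kv[0])):
            lines.append(f"{''.join(seq)}\t{n}")
        return "\n".join(lines) + "\n"


def run_repeats(
    model_or_system,
    spec: DesignSpec | None = None,
    schedule: AnnealSchedule | None = None,
    n_traj: int = 1000,
    n_repeats: int = 10,
    keep: int = 3,
    base_seed: int = 0,
    state_id: str = "",
    config: EnergyConfig | None = None,
) -> tuple[list[DesignSet], ConvergenceReport]:
    """Independent repeats with disjoint seed blocks; the ``keep`` repeats
    with the lowest best E_total are retained for analysis."""
    if not (n_repeats >= keep >= 1):
        raise ValueError("need n_repeats >= keep >= 1")
    if isinstance(model_or_system, PackedSystem):
        system = model_or_system
    else:
        system = PackedSystem(model_or_system, spec, config)
    sets = [
        run_design(system, schedule=schedule, n_traj=n_traj,
                   base_seed=base_seed + r * max(1, n_traj), state_id=state_id)
        for r in range(n_repeats)
    ]
    best = [s.records[0].breakdown.total if s.records else math.inf for s in sets]
    order = sorted(range(n_repeats), key=lambda r: (best[r], r))
    kept = sorted(order[:keep])
    recurrence: dict[tuple[str, ...], int] = {}
    for s in sets:
        for seq in s.sequences():
            recurrence[seq] = recurrence.get(seq, 0) + 1
    finite = [best[r] for r in kept if math.isfinite(best[r])]
    spread = (max(finite) - min(finite)) if finite else math.inf
    return sets, ConvergenceReport(kept, best, spread, recurrence)


# --------------------------------------------------------------------------
# exhaustive oracle
# --------------------------------------------------------------------------

def exhaustive_oracle(
    model_or_system,
    spec: DesignSpec | None = None,
    config: EnergyConfig | None = None,
    max_sequences: int = 10**4,
    max_rotamer_products: int = 10**5,
) -> DesignRecord:
    """Global optimum by exhaustive search (test oracle).

    Every feasible sequence is evaluated at its best rotamer assignment.
    Rotamer optimization is exact: sites are partitioned into coupling
    components (connected via nonzero pair tables); uncoupled sites take
    their per-site best, coupled components are enumerated exhaustively
    up to ``max_rotamer_products`` combinations.
    """
    if isinstance(model_or_system, PackedSystem):
        system = model_or_system
    else:
        system = PackedSystem(model_or_system, spec, config)
    spec = system.spec
    space = enumerate_design_space(spec, cap=max_sequences)
    if space.count > max_sequences:
        raise OracleSizeError(f"feasible space of {space.count} sequences is too large")
    if space.count == 0:
        raise OracleSizeError("feasible space is empty")

    # coupling components over mobile sites
    n_sites = len(system.sites)
    comp = list(range(n_sites))

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for (i, j) in system.pair:
        ci, cj = find(i), find(j)
        if ci != cj:
            comp[cj] = ci
    groups: dict[int, list[int]] = {}
    for s in range(n_sites):
        groups.setdefault(find(s), []).append(s)

    w = system.weights
    self_tot = [system.self_nb[s] + w.w_bind * system.self_b[s] for s in range(n_sites)]

    best: tuple[float, list[int]] | None = None
    for seq in space:
        # conformer index ranges per site under this sequence
        ranges = []
        for s in range(n_sites):
            letter = seq[s] if s < system.n_design else system.letters[s][0]
            a, b = system.letter_blocks[s][letter]
            ranges.append((a, b))
        total = 0.0
        assignment = [0] * n_sites
        for members in groups.values():
            prod = 1
            for s in members:
                prod *= ranges[s][1] - ranges[s][0]
            if prod > max_rotamer_products:
                raise OracleSizeError(
                    f"rotamer component of size {prod} exceeds the oracle cap"
                )
            if len(members) == 1:
                s = members[0]
                a, b = ranges[s]
                g = a + int(np.argmin(self_tot[s][a:b]))
                assignment[s] = g
                total += float(self_tot[s][g])
            else:
                e, gs = _best_component(system, self_tot, members, ranges)
                for s, g in zip(members, gs):
                    assignment[s] = g
                total += e
        if best is None or total < best[0] - 1e-12:
            best = (total, assignment)
    return system.record(best[1])


def _best_component(system, self_tot, members, ranges):
    import itertools

    pair = system.pair
    edges = [
        (i, j) for (i, j) in pair
        if i in members and j in members
    ]
    best_e = None
    best_g = None
    spans = [range(ranges[s][0], ranges[s][1]) for s in members]
    pos = {s: k for k, s in enumerate(members)}
    for combo in itertools.product(*spans):
        e = sum(float(self_tot[s][g]) for s, g in zip(members, combo))
        for (i, j) in edges:
            e += float(pair[(i, j)][combo[pos[i]], combo[pos[j]]])
        if best_e is None or e < best_e - 1e-12:
            best_e, best_g = e, list(combo)
    return best_e, best_g
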