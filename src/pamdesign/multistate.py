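"""Multi-PAM design objective and the three-iteration design driver.

A variant's fitness for PAM relaxation is judged across a panel of PAM
states (structural models differing only in the 6-bp PAM and its
complement): the per-state binding energies e_bind^i are aggregated into
their mean mu and mean absolute deviation

    MAD = (1/n) * sum_i |e_bind^i - mu|

A MAD of zero means identical binding across all PAM states — the
relaxation objective — while mu ranks overall binding strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import templates as T
from .constraints import (
    DesignSpec,
    SiteConstraint,
    build_design_spec,
    enumerate_design_space,
    select_design_sites,
)
from .energy import EnergyConfig, ScoreWeights, decompose
from .samc import AnnealSchedule, DesignSet, PackedSystem, exhaustive_oracle, run_repeats
from .structure import ComplexModel, build_mutant, build_pam_variant

__all__ = [
    "PAPER_PAMS",
    "PamState",
    "MultiStateSummary",
    "IterationSettings",
    "mad",
    "build_pam_states",
    "evaluate_variant",
    "rank_variants",
    "run_iteration_protocol",
]

#: the four PAM states used for NNGRRT -> NNNRRT relaxation (position 3
#: varied over A/C/G/T on a TTNGGT background)
PAPER_PAMS = ("TTAGGT", "TTCGGT", "TTGGGT", "TTTGGT")


def mad(values) -> float:
    """Mean absolute deviation around the arithmetic mean."""
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("MAD of an empty list is undefined")
    mu = sum(vals) / len(vals)
    return sum(abs(v - mu) for v in vals) / len(vals)


@dataclass
class PamState:
    pam: str
    model: ComplexModel
    index: int


@dataclass
class MultiStateSummary:
    variant: tuple[tuple[tuple[str, int], str, str], ...]  # (site, native, new)
    e_bind: dict[str, float]
    mu: float = field(init=False)
    mad: float = field(init=False)
    mean_total: float = 0.0

    def __post_init__(self):
        vals = list(self.e_bind.values())
        self.mu = sum(vals) / len(vals)
        self.mad = mad(vals)

    @property
    def mutation_string(self) -> str:
        if not self.variant:
            return "WT"
        return ";".join(f"{nat}{site[1]}{new}" for site, nat, new in self.variant)


def build_pam_states(model: ComplexModel, pams=PAPER_PAMS) -> list[PamState]:
    """Structural models differing only in the PAM (and complement)."""
    return [
        PamState(pam=p, model=build_pam_variant(model, p), index=i + 1)
        for i, p in enumerate(pams)
    ]


# --------------------------------------------------------------------------
# variant evaluation
# --------------------------------------------------------------------------

def evaluate_variant(
    variant,
    states: list[PamState],
    repack_sites=(),
    weights: ScoreWeights | None = None,
    config: EnergyConfig | None = None,
) -> MultiStateSummary:
    """Binding energies of one variant across all PAM states.

    ``variant`` is a tuple of ``(site, native, new)`` mutations (empty
    for wild type).  In each state the variant is built on the fixed
    backbone and the mutated plus ``repack_sites`` side chains are
    repacked exactly (exhaustive best-rotamer search over the coupling
    components), then the surrogate binding energy is recorded.
    """
    weights = weights or ScoreWeights()
    config = config or EnergyConfig()
    _check_states(states)
    e_bind: dict[str, float] = {}
    totals = []
    for st in states:
        mutated = build_mutant(st.model, [(s[0][0], s[0][1], s[2]) for s in variant])
        sites = [s[0] for s in variant] + [r for r in repack_sites if r not in
                                           {s[0] for s in variant}]
        if sites:
            constraints = []
            for site in sites:
                res = mutated.get(*site)
                constraints.append(SiteConstraint(site[0], site[1], "repack-only"))
            spec = build_design_spec(mutated, constraints, 0, 0, weights)
            system = PackedSystem(mutated, spec, config)
            best = exhaustive_oracle(system)
            mutated = system.realize(best.assignment)
        bd = decompose(mutated, weights, config)
        e_bind[st.pam] = bd.bind
        totals.append(bd.total)
    return MultiStateSummary(
        variant=tuple(variant),
        e_bind=e_bind,
        mean_total=sum(totals) / len(totals),
    )


def _check_states(states):
    if not states:
        raise ValueError("need at least one PAM state")
    ref = states[0].model
    pam_res = set()
    if ref.pam is not None:
        pam_res = {(ref.pam.nts_chain, n) for n in ref.pam.nts_numbers}
        pam_res |= {(ref.pam.ts_chain, n) for n in ref.pam.ts_numbers}
    for st in states[1:]:
        for res, res0 in zip(st.model.residues(), ref.residues()):
            key = (res.chain_id, res.number)
            if key in pam_res:
                continue
            if res.name != res0.name or len(res.atoms) != len(res0.atoms):
                raise ValueError(f"PAM states differ outside the PAM at {key}")
            for a, b in zip(res.atoms, res0.atoms):
                if not np.array_equal(a.pos, b.pos):
                    raise ValueError(f"PAM states differ outside the PAM at {key}")


# --------------------------------------------------------------------------
# ranking
# --------------------------------------------------------------------------

def rank_variants(
    summaries,
    mean_cut: float | None = None,
    mad_cut: float | None = None,
) -> list[MultiStateSummary]:
    """Filter by the optional mu / MAD thresholds (strict <), then sort
    ascending by mu, ties by MAD, then by mutation list."""
    kept = [
        s for s in summaries
        if (mean_cut is None or s.mu < mean_cut) and (mad_cut is None or s.mad < mad_cut)
    ]
    return sorted(kept, key=lambda s: (s.mu, s.mad, s.mutation_string))


def summaries_to_tsv(summaries, pams=PAPER_PAMS) -> str:
    header = ["variant"] + [f"e_bind[{p}]" for p in pams] + ["mu", "mad", "mean_total"]
    lines = ["\t".join(header)]
    for s in summaries:
        row = [s.mutation_string]
        row += [f"{s.e_bind[p]:.6f}" for p in pams]
        row += [f"{s.mu:.6f}", f"{s.mad:.6f}", f"{s.mean_total:.6f}"]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# iteration protocol
# --------------------------------------------------------------------------

#: allowed identity sets of the third design iteration, by residue number
ITERATION3_SETS = {
    37: "KR", 782: "EK", 787: "TMFW", 803: "NKW",
    822: "KR", 882: "YR", 968: "NKR",
}
ITERATION1_ALLOWED = "CHKNQRSTY"


@dataclass
class IterationSettings:
    pams: tuple[str, ...] = PAPER_PAMS
    focus: tuple[str, int] = ("A", 1015)
    n_traj: int = 1000
    n_repeats: int = 10
    keep: int = 3
    base_seed: int = 0
    schedule: AnnealSchedule | None = None
    mean_cut: float | None = None
    mad_cut: float | None = None
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    config: EnergyConfig = field(default_factory=EnergyConfig)
    include_repack: bool = True


def iteration_spec(model: ComplexModel, iteration: int,
                   settings: IterationSettings) -> DesignSpec:
    """The per-iteration design specification.

    Iteration 1: single-mutant scan at the focus site over the nine
    polar/positive identities (plus native Arg), mutation count 0-1.
    Iteration 2: focus fixed to His, every other mutable site samples all
    twenty identities, exactly two mutations.  Iteration 3: focus fixed
    to His plus the seven favorable-substitution sets, exactly three
    mutations.  Mutable/repackable sites come from the distance rules of
    :func:`select_design_sites`.
    """
    if iteration not in (1, 2, 3):
        raise ValueError(f"iteration must be 1, 2 or 3, got {iteration}")
    sel = select_design_sites(model, settings.focus)
    focus = settings.focus
    constraints: list[SiteConstraint] = []
    if iteration == 1:
        constraints.append(
            SiteConstraint(focus[0], focus[1], "design", frozenset(ITERATION1_ALLOWED))
        )
        n_min, n_max = 0, 1
    elif iteration == 2:
        constraints.append(SiteConstraint(focus[0], focus[1], "design", frozenset("H")))
        for site in sel.mutable:
            if site != focus:
                constraints.append(
                    SiteConstraint(site[0], site[1], "design", frozenset(T.AA_1TO3))
                )
        n_min, n_max = 2, 2
    else:
        constraints.append(SiteConstraint(focus[0], focus[1], "design", frozenset("H")))
        for number, letters in ITERATION3_SETS.items():
            placed = False
            for site in sel.mutable:
                if site[1] == number:
                    constraints.append(
                        SiteConstraint(site[0], number, "design", frozenset(letters))
                    )
                    placed = True
                    break
            if not placed:
                if not model.has(focus[0], number):
                    raise KeyError(
                        f"iteration-3 site {number} not present in the model"
                    )
                constraints.append(
                    SiteConstraint(focus[0], number, "design", frozenset(letters))
                )
        n_min, n_max = 3, 3
    if settings.include_repack:
        covered = {c.site for c in constraints}
        for site in sel.repackable:
            if site not in covered:
                constraints.append(SiteConstraint(site[0], site[1], "repack-only"))
    return build_design_spec(model, constraints, n_min, n_max, settings.weights)


@dataclass
class IterationResult:
    iteration: int
    spec: DesignSpec
    feasible_space_size: int
    design_sets: dict[str, list[DesignSet]]  # per PAM state
    summaries: list[MultiStateSummary]       # ranked

    def to_tsv(self) -> str:
        return summaries_to_tsv(self.summaries, pams=tuple(self.design_sets))


def run_iteration_protocol(
    model: ComplexModel,
    iteration: int,
    settings: IterationSettings | None = None,
) -> IterationResult:
    """One design iteration over all PAM states.

    Builds the PAM state models, runs the repeat protocol per state,
    pools the union of produced variants, evaluates every variant on
    every state, and returns the ranked multi-state summaries.
    """
    settings = settings or IterationSettings()
    if model.pam is None:
        raise ValueError("model carries no PAM annotation")
    spec = iteration_spec(model, iteration, settings)
    space_size = enumerate_design_space(spec).count
    states = build_pam_states(model, settings.pams)

    design_sets: dict[str, list[DesignSet]] = {}
    variants: dict[tuple[str, ...], tuple] = {}
    for si, st in enumerate(states):
        state_spec = build_design_spec(
            st.model, spec.sites, spec.n_min, spec.n_max, settings.weights
        )
        # the reference sequence is the wild type of the input model
        state_spec.native_sequence = dict(spec.native_sequence)
        sets, _report = run_repeats(
            st.model,
            state_spec,
            schedule=settings.schedule,
            n_traj=settings.n_traj,
            n_repeats=settings.n_repeats,
            keep=settings.keep,
            base_seed=settings.base_seed + si * 10_000_000,
            state_id=st.pam,
            config=settings.config,
        )
        design_sets[st.pam] = sets
        for s in sets:
            for rec in s.records:
                variants.setdefault(rec.sequence, rec.mutations)

    repack = [s.site for s in spec.repack_sites]
    summaries = [
        evaluate_variant(muts, states, repack_sites=repack,
                         weights=settings.weights, config=settings.config)
        for muts in variants.values()
    ]
    ranked = rank_variants(summaries, settings.mean_cut, settings.mad_cut)
    return IterationResult(
        iteration=iteration,
        spec=spec,
        feasible_space_size=space_size,
        design_sets=design_sets,
        summaries=ranked,
    )
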