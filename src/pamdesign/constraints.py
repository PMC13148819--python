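"""Design constraints: RESFILE parsing, automatic design-site selection,
and exhaustive enumeration of the constrained sequence space.

The RESFILE dialect is a plain-text, one-directive-per-line format:

    # comment
    <chain> <number> NATRO            # keep native identity and conformation
    <chain> <number> NATAA            # repack only (identity fixed)
    <chain> <number> PIKAA <letters>  # designable, allowed one-letter codes

Residues not mentioned default to fixed-native.  Mutation counts are
always measured against a reference (wild-type) sequence, so a site
constrained to a single non-native identity contributes one mutation to
every design — the convention under which an "exactly 3 mutations"
design run on a fixed-His background produces triple mutants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import templates as T
from .energy import ScoreWeights

__all__ = [
    "SiteConstraint",
    "DesignSpec",
    "SiteSelection",
    "ResfileError",
    "EnumerationCapError",
    "parse_resfile",
    "build_design_spec",
    "select_design_sites",
    "enumerate_design_space",
    "DesignSpace",
]

MODES = ("fixed-native", "repack-only", "design")


class ResfileError(ValueError):
    pass


class EnumerationCapError(ValueError):
    def __init__(self, estimate: int, cap: int):
        super().__init__(
            f"constrained sequence space has {estimate} members, "
            f"exceeding the enumeration cap of {cap}"
        )
        self.estimate = estimate
        self.cap = cap


@dataclass(frozen=True)
class SiteConstraint:
    chain: str
    number: int
    mode: str
    allowed: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown site mode {self.mode!r}")
        if self.mode == "design" and not self.allowed:
            raise ValueError("design mode requires a non-empty allowed set")

    @property
    def site(self) -> tuple[str, int]:
        return (self.chain, self.number)


@dataclass
class DesignSpec:
    """Per-site constraints plus the mutation-count range and weights."""

    sites: list[SiteConstraint]
    n_min: int
    n_max: int
    native_sequence: dict[tuple[str, int], str]
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    feasible_warning: str | None = field(default=None)

    def __post_init__(self):
        if not (0 <= self.n_min <= self.n_max):
            raise ValueError(f"invalid mutation-count range [{self.n_min}, {self.n_max}]")
        seen = set()
        for s in self.sites:
            if s.site in seen:
                raise ValueError(f"duplicate site constraint for {s.site}")
            seen.add(s.site)
        # capacity check: can the feasible set be non-empty?
        max_muts = 0
        forced = 0
        for s in self.design_sites:
            native = self.native_sequence[s.site]
            non_native = [a for a in s.allowed if a != native]
            if non_native:
                max_muts += 1
            if native not in s.allowed:
                forced += 1
        if self.n_min > max_muts or forced > self.n_max:
            self.feasible_warning = (
                f"mutation-count range [{self.n_min}, {self.n_max}] may be infeasible: "
                f"{max_muts} sites offer non-native identities, {forced} force a mutation"
            )

    @property
    def design_sites(self) -> list[SiteConstraint]:
        return [s for s in self.sites if s.mode == "design"]

    @property
    def repack_sites(self) -> list[SiteConstraint]:
        return [s for s in self.sites if s.mode == "repack-only"]

    def mutation_count(self, sequence: tuple[str, ...]) -> int:
        return sum(
            1
            for s, letter in zip(self.design_sites, sequence)
            if letter != self.native_sequence[s.site]
        )


@dataclass
class SiteSelection:
    mutable: list[tuple[str, int]]
    repackable: list[tuple[str, int]]

    def to_tsv(self) -> str:
        lines = ["chain\tnumber\tcategory"]
        for c, n in self.mutable:
            lines.append(f"{c}\t{n}\tmutable")
        for c, n in self.repackable:
            lines.append(f"{c}\t{n}\trepackable")
        return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# RESFILE parsing
# --------------------------------------------------------------------------

def parse_resfile(path) -> list[SiteConstraint]:
    with open(path) as fh:
        lines = fh.readlines()
    out: list[SiteConstraint] = []
    seen: set[tuple[str, int]] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ResfileError(f"line {lineno}: expected '<chain> <number> <directive>'")
        chain, num_s, directive = fields[0], fields[1], fields[2].upper()
        try:
            number = int(num_s)
        except ValueError:
            raise ResfileError(f"line {lineno}: residue number {num_s!r} is not an integer")
        if (chain, number) in seen:
            raise ResfileError(f"line {lineno}: duplicate directive for site {chain} {number}")
        seen.add((chain, number))
        if directive == "NATRO":
            out.append(SiteConstraint(chain, number, "fixed-native"))
        elif directive == "NATAA":
            out.append(SiteConstraint(chain, number, "repack-only"))
        elif directive == "PIKAA":
            if len(fields) < 4:
                raise ResfileError(f"line {lineno}: PIKAA requires a set of one-letter codes")
            letters = fields[3].upper()
            bad = [a for a in letters if a not in T.AA_1TO3]
            if bad:
                raise ResfileError(f"line {lineno}: unknown amino-acid code(s) {bad}")
            out.append(SiteConstraint(chain, number, "design", frozenset(letters)))
        else:
            raise ResfileError(f"line {lineno}: unknown directive {directive!r}")
    return out


def build_design_spec(
    model,
    constraints: list[SiteConstraint],
    n_min: int,
    n_max: int,
    weights: ScoreWeights | None = None,
) -> DesignSpec:
    """Bind parsed constraints to a model, taking the model's current
    protein sequence as the wild-type reference for mutation counting."""
    native = {}
    for s in constraints:
        try:
            res = model.get(s.chain, s.number)
        except KeyError:
            raise KeyError(f"RESFILE site {s.chain} {s.number} not present in the model")
        if res.polymer != "protein":
            raise TypeError(f"RESFILE site {s.chain} {s.number} is not a protein residue")
        native[s.site] = T.AA_3TO1[res.name]
    return DesignSpec(
        sites=list(constraints),
        n_min=n_min,
        n_max=n_max,
        native_sequence=native,
        weights=weights or ScoreWeights(),
    )


# --------------------------------------------------------------------------
# design-site selection
# --------------------------------------------------------------------------

def _side_chain_coords(res) -> np.ndarray:
    pts = [a.pos for a in res.atoms if not a.is_backbone]
    return np.array(pts) if pts else np.empty((0, 3))


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0:
        return np.inf
    d = a[:, None, :] - b[None, :, :]
    return float(np.sqrt(np.einsum("ijk,ijk->ij", d, d)).min())


def _pam_region_residues(model):
    """PAM nucleotides, their complement partners, and the flank
    nucleotides up/downstream on both strands (where present)."""
    pam = model.pam
    region = []
    for chain, numbers in ((pam.nts_chain, pam.nts_numbers), (pam.ts_chain, pam.ts_numbers)):
        lo, hi = min(numbers), max(numbers)
        for n in range(lo - pam.flank, hi + pam.flank + 1):
            if model.has(chain, n):
                region.append(model.get(chain, n))
    return region


def select_design_sites(
    model,
    focus: tuple[str, int],
    d_side: float = 4.5,
    d_pam: float = 6.0,
    flank: int | None = None,
) -> SiteSelection:
    """Classify protein residues into mutable and repackable sets.

    Mutable: the focus residue; residues whose side chains come within
    ``d_side`` of the focus side chain; and residues whose side chains
    come within ``d_pam`` of the sugar-phosphate (main-chain) atoms of
    the PAM region (PAM, complement, and flanking nucleotides on both
    strands).  Repackable: residues whose side chains come within
    ``d_side`` of any mutable side chain, excluding the mutable set.
    Distances are closed ("within" means <=).
    """
    if model.pam is None:
        raise ValueError("model carries no PAM annotation; cannot select design sites")
    if flank is not None:
        model = model  # annotation flank override
        pam_flank = flank
    else:
        pam_flank = model.pam.flank
    focus_res = model.get(*focus)

    saved_flank = model.pam.flank
    model.pam.flank = pam_flank
    try:
        region = _pam_region_residues(model)
    finally:
        model.pam.flank = saved_flank
    pam_backbone = [a.pos for r in region for a in r.atoms if a.is_backbone]
    pam_backbone = np.array(pam_backbone) if pam_backbone else np.empty((0, 3))
    focus_side = _side_chain_coords(focus_res)

    protein = [r for r in model.residues() if r.polymer == "protein"]
    mutable: set[tuple[str, int]] = {focus}
    for r in protein:
        side = _side_chain_coords(r)
        if r is not focus_res and _min_dist(side, focus_side) <= d_side:
            mutable.add((r.chain_id, r.number))
        if _min_dist(side, pam_backbone) <= d_pam:
            mutable.add((r.chain_id, r.number))

    mutable_side = [
        _side_chain_coords(model.get(c, n)) for c, n in mutable
    ]
    mutable_side = (
        np.concatenate([s for s in mutable_side if len(s)]) if any(len(s) for s in mutable_side)
        else np.empty((0, 3))
    )
    repackable: set[tuple[str, int]] = set()
    for r in protein:
        key = (r.chain_id, r.number)
        if key in mutable:
            continue
        if _min_dist(_side_chain_coords(r), mutable_side) <= d_side:
            repackable.add(key)

    return SiteSelection(sorted(mutable), sorted(repackable))


# --------------------------------------------------------------------------
# exhaustive enumeration
# --------------------------------------------------------------------------

class DesignSpace:
    """Iterator over the feasible constrained sequence space.

    ``count`` is exact and computed up front (generating-function pass);
    iteration yields each feasible assignment exactly once as a tuple of
    one-letter identities in design-site order.
    """

    def __init__(self, spec: DesignSpec, cap: int = 10**7):
        self.spec = spec
        self.sites = spec.design_sites
        self.native = [spec.native_sequence[s.site] for s in self.sites]
        self.choices = []
        for s, nat in zip(self.sites, self.native):
            natives = [nat] if nat in s.allowed else []
            others = sorted(a for a in s.allowed if a != nat)
            self.choices.append((natives, others))
        # polynomial in z: coefficient of z^k = number of assignments with
        # k substitutions
        poly = np.array([1], dtype=object)
        for natives, others in self.choices:
            term = np.array([len(natives), len(others)], dtype=object)
            poly = np.convolve(poly, term)
        self.count_by_muts = poly
        lo, hi = spec.n_min, min(spec.n_max, len(poly) - 1)
        self.count = int(sum(poly[lo : hi + 1])) if hi >= lo else 0
        if self.count > cap:
            raise EnumerationCapError(self.count, cap)

    def __len__(self):
        return self.count

    def __iter__(self):
        n_min, n_max = self.spec.n_min, self.spec.n_max
        n_sites = len(self.choices)
        # max substitutions attainable from site index i onward
        rest_max = [0] * (n_sites + 1)
        for i in range(n_sites - 1, -1, -1):
            rest_max[i] = rest_max[i + 1] + (1 if self.choices[i][1] else 0)
        # min substitutions forced from site i onward
        rest_min = [0] * (n_sites + 1)
        for i in range(n_sites - 1, -1, -1):
            rest_min[i] = rest_min[i + 1] + (0 if self.choices[i][0] else 1)

        def rec(i, muts, prefix):
            if muts + rest_min[i] > n_max or muts + rest_max[i] < n_min:
                return
            if i == n_sites:
                yield tuple(prefix)
                return
            natives, others = self.choices[i]
            for a in natives:
                prefix.append(a)
                yield from rec(i + 1, muts, prefix)
                prefix.pop()
            for a in others:
                prefix.append(a)
                yield from rec(i + 1, muts + 1, prefix)
                prefix.pop()

        return rec(0, 0, [])

    def to_tsv(self) -> str:
        header = "\t".join(f"{s.chain}{s.number}" for s in self.sites)
        lines = [header]
        for seq in self:
            lines.append("\t".join(seq))
        return "\n".join(lines) + "\n"


def enumerate_design_space(spec: DesignSpec, cap: int = 10**7) -> DesignSpace:
    return DesignSpace(spec, cap=cap)
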