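# Methods

`pamdesign` implements a constrained, rotamer-based redesign workflow
for the protein side of a protein–DNA interface, aimed at the problem of
relaxing the PAM (protospacer-adjacent motif) specificity of a Cas
nuclease such as SaCas9.  This note records the model, the numerical
choices, and the limits of what the packaged tests demonstrate.

## The design score

A design state is one side-chain rotamer (identity + conformer) per
mobile site on a fixed backbone.  States are scored by

```
E_total = E_non-bind + w_bind·E_bind + w_evo·E_evo
          + w_OOR·N_OOR + w_exist·X_exist
```

* `E_bind` sums pair interactions between protein atoms and nucleic-acid
  atoms (DNA and, by default, RNA; a config switch restricts the binding
  scope to DNA).  `E_non-bind` sums every other admissible pair.  We use
  interface cross-terms rather than bound-minus-separated energies; the
  two are identical under rigid separation, and cross-terms are cheaper
  and exactly decomposable.
* `E_evo` is an optional per-site evolutionary profile term.  It is
  disabled (identically zero) by default, as is typical for redesign of
  an existing protein; the weight and interface exist so a profile can
  be supplied.
* `N_OOR` is the integer distance of the design's substitution count
  `n_mut` from the user range `[N_mut,min, N_mut,max]`: `N_min − n_mut`
  below the range, `n_mut − N_max` above it, zero inside.
* `X_exist` is 1 iff the design's sequence is identical to one already
  saved in the reserved set, 0 otherwise.
* Default weights: `w_bind = w_evo = 1`, `w_OOR = w_exist = 1000`.  The
  penalty weights are deliberately enormous relative to the physical
  energy scale of the packaged fixtures (|E_phys| < 500 surrogate
  units), so a single constraint violation dominates any physical
  preference and the annealer is driven into the feasible, novel subset
  of sequence space whenever it is non-empty.

**Mutation counting.**  `n_mut` is always measured against a *wild-type
reference sequence*, not against the allowed sets.  A site constrained
to a single non-native identity (e.g. His at a position whose wild type
is Arg) therefore contributes one substitution to every design.  This is
the only convention under which an "exactly 3 substitutions" run on a
fixed-His background yields triple mutants, and it reproduces the
expected combinatorics: with non-native option counts (1,1,3,2,1,1,2) at
seven sites plus the forced His, the exactly-three space has
e₂(1,1,3,2,1,1,2) = 50 members.

## The surrogate energy function

The physical terms are a deliberately simple heavy-atom surrogate; no
published force field is reproduced and absolute values (reported in
"surrogate energy units") are meaningless outside this package.  Only
signs, orderings, and the constraint arithmetic built on top are used by
the workflow, and only those are tested.

* **van der Waals**: 12-6 form `ε[(r_min/r)¹² − 2(r_min/r)⁶]` with
  `r_min` the sum of element radii (C 1.70, N 1.55, O 1.52, S 1.80,
  P 1.80 Å) and `ε` the geometric mean of per-element well depths;
  capped at +10 per pair to keep clashes finite; zero beyond 8 Å.
* **Electrostatics**: `q_a·q_b·332/(4r²)` — a distance-dependent
  dielectric of 4r — over a small embedded charge table (Arg NH1/NH2
  +0.5, Lys NZ +1.0, Asp/Glu carboxylate oxygens −0.5 each, phosphate
  OP1/OP2 −0.6 each); zero beyond 10 Å.  Histidine is neutral by
  default; a config switch puts +0.25 on each ring nitrogen, reflecting
  its titratability near physiological pH.
* **Hydrogen bonds**: for donor/acceptor heavy-atom pairs at
  2.6–3.4 Å, `−1.0 · w_dist · w_ang` with `w_dist` a triangular window
  peaking at 3.0 Å and `w_ang` a triangular window (width 60°) around a
  120° donor–acceptor–antecedent angle; full weight when the acceptor
  has no antecedent atom.  When both atoms are amphoteric the more
  favorable orientation is used.
* **Bonded exclusions**: 1-2 and 1-3 pairs are skipped, 1-4 pairs scaled
  by 0.5, everything farther interacts fully.  Bond topology comes from
  per-residue templates plus peptide C–N and nucleic O3'–P links.
  Side chains of *different* residues are never within three bonds of
  each other, so rotamer–rotamer pair tables need no exclusions.

The decomposition is exact: the vectorized implementation agrees with an
independent scalar O(N²) double loop to 1e-9, and all terms are
invariant under rigid motion to 1e-6.

## Rotamers

The library is an embedded chi-grid: sp3 chis sampled at {−60, 60,
180}°, terminal sp2 chis (carboxylate/amide flips, aromatic rings, the
guanidinium plane) at {0, 90}°, capped at 81 conformers per identity
(only Lys reaches the cap; Arg has 54).  Proline gets two
ring-consistent pucker conformers whose (chi1, chi2) close the CD–N
bond to ~1e-3 Å; cysteine is treated as free (no disulfide detection).
Conformers are built by exact internal-coordinate (NeRF) placement from
the site's own N/CA/C triad, so backbone atoms are shared bit-exactly
and realized chi dihedrals reproduce the grid to machine precision.
This coarse grid is not a statistical rotamer library; it is adequate
for exercising the constraint and search machinery, which is this
package's subject, and it keeps the artifact fully self-contained.

## Search

SAMC (simulated annealing Monte Carlo) with Metropolis acceptance on
`E_total`.  Schedule: geometric cooling from T = 30 to 0.3 score units
with factor 0.85 per stage (29 stages), 500·(number of mobile sites)
moves per stage.  Move set: with probability 0.5 a random designable
site proposes a uniformly random (identity, conformer) from its allowed
set; otherwise a random mobile site proposes a conformer swap within its
current identity.  Initialization is the native sequence (or the first
allowed identity where the native is excluded) at each site's
lowest-self-energy rotamer.  The RNG is a counter-based Philox generator
keyed by the trajectory seed; no global state is touched, and identical
inputs reproduce trajectories bit-exactly.

Energies are precomputed into tables — a fixed-environment constant,
per-site self energies (conformer vs. environment, split into binding
and non-binding channels), and site-pair coupling tables — so a move
evaluation is a handful of array lookups.  Sites whose Cα atoms are more
than 26 Å apart (10 Å interaction cutoff plus twice the maximal
side-chain reach) are provably uncoupled and their tables are dropped.

A trajectory returns the lowest-`E_total` feasible *and* novel state it
visited; if it never visits one it signals exhaustion rather than
raising.  `run_design` runs trajectories sequentially with seeds
`base_seed + i`, adds each returned sequence to the reserved set before
the next trajectory, retries an exhausted trajectory once with 3× steps,
and stops early when the space is used up — which is what makes
"1000 trajectories" cheap on a nine-member space.  `X_exist` is
evaluated against the reserved set frozen at trajectory start; a
trajectory's own visited states are not reserved.

`run_repeats` executes independent `run_design` blocks with disjoint
seed ranges and keeps the repeats with the lowest best energy (default:
3 of 10).  Convergence is reported, not adjudicated: per-sequence
recurrence counts across repeats and the spread of kept best energies.

**The exhaustive oracle** evaluates every feasible sequence at its exact
best rotamer assignment: the site-coupling graph is split into connected
components; singleton components take the per-site argmin and larger
components are enumerated exhaustively (up to 10⁵ combinations per
component, refusing with a size report beyond that).  On every packaged
small-space fixture the seeded search recovers the oracle's optimum
sequence and energy exactly and its design-set union equals the full
enumeration.

## Multi-PAM objective

PAM states are built by threading each 6-mer (and its complement) onto
the annotated PAM window — idealized base recipes rebuilt from the
existing C2'/O4'/C1' sugar frame, so all states share every non-PAM
coordinate bit-exactly.  The default panel varies position 3 over
A/C/G/T on a TTNGGT background.  A variant produced in *any* state is
evaluated on *all* states (union, not intersection); its per-state
binding energy uses the exact best repack of the mutated + repackable
sites (the component-wise oracle, not an ensemble average), which keeps
evaluation deterministic.  Aggregation: mean μ and MAD
`(1/n)Σ|e_bind^i − μ|`; ranking sorts ascending by μ with MAD and then
the mutation list as tie-breakers, after optional strict `μ < mean_cut`
and `MAD < mad_cut` filters.  Mean total energy is reported as a
diagnostic only.

The three-iteration driver reconstructs each stage's constraints from
the distance-rule site selection: (1) a nine-identity scan at the focus
site with 0–1 substitutions; (2) focus fixed to His, all other mutable
sites over all twenty identities, exactly two substitutions; (3) focus
fixed to His plus seven favorable-identity sets, exactly three
substitutions.  Candidate triage for structural plausibility is an
automated clash filter plus the reported tables; expert visual
inspection is not automated.

## Site selection

Mutable sites: the focus residue; protein residues with any side-chain
atom within 4.5 Å of the focus side chain; and protein residues with any
side-chain atom within 6 Å of the sugar-phosphate ("main-chain") atoms
of the PAM region — the PAM, its complement, and 3 flanking nucleotides
on both strands.  Repackable sites: side chains within 4.5 Å of any
mutable side chain, minus the mutable set.  "Within" is closed (≤);
glycine contributes no side-chain atoms and can only enter as the focus.
Repackable sites are computed against the native side-chain coordinates
of the input.  The implementation is verified against an independent
all-pairs distance scan on randomized fixtures.

## Synthetic fixtures

The generator emulates the geometry the workflow needs, at desk scale:

* **DNA duplex**: an idealized, helically symmetric B-form template
  (rise 3.38 Å, twist 36°/bp) derived once by least squares against
  standard bond lengths/angles with the O3'(i)–P(i+1) link enforced
  under the helix symmetry, then frozen into the package.  Bases are
  placed from the sugar frame with a fixed anti glycosidic torsion
  calibrated so Watson–Crick partners approach to ~3.3 Å without steric
  interpenetration.  Consecutive C1' atoms sit 5.2 Å apart; paired C1'
  atoms 11.5 Å.
* **Peptide**: an ideal right-handed α-helix (φ, ψ = −57°, −47°) packed
  against the PAM face of the duplex, side chains grown at their
  lowest-energy rotamers in N→C order.  The default 10-residue peptide
  reuses the author residue numbering and wild-type identities of the
  SaCas9 PAM-interacting sites (K37, E782, T787, N803, K822, Y882, N968,
  E993, R1015, T1019), so the packaged iteration RESFILEs apply to the
  fixture verbatim.  The placement contract — at least three side chains
  within 6 Å of PAM backbone atoms — is checked at build time.
* Coordinate jitter (seeded Gaussian) and randomized sequences provide
  fixture diversity for property tests.

**What the fixtures do not emulate**: a real Cas9 fold, base-specific
major-groove readout (the toy helix approaches the phosphate backbone,
so per-PAM binding differences are small and largely
variant-independent), sgRNA structure, solvation, or backbone
flexibility.  Passing tests therefore demonstrate the correctness of
the constraint handling, search, bookkeeping and aggregation machinery —
not the biophysical accuracy of any energy value.  In particular,
published binding energies for SaCas9 variants (UEU-scale numbers) are
outside the scope of the surrogate by design.

## Numerical choices and degenerate inputs

* Ties in rotamer placement and search break toward the lowest rotamer
  index / earliest trajectory; sorting is stable, so output order is
  reproducible.
* Structure repair iterates clash re-placement to a fixed point (≤10
  rounds), which makes it idempotent; the clash criterion (interatomic
  distance < 0.8× the vdW-radius sum, ignoring pairs within three
  bonds) matches the energy function's exclusion rules.
* Enumeration counts come from a generating-function pass (exact integer
  polynomial), so the feasibility cap (default 10⁷) is enforced without
  materializing the cartesian product; an infeasible range is flagged on
  the spec, not fatal.
* Empty feasible spaces surface as an exhaustion signal from
  trajectories and an empty design set, not an exception; an empty
  energy decomposition input or an empty MAD input is an error.
* PDB output writes 3-decimal coordinates; round-tripping is exact at
  that precision.

## Known limitations

* The chi-grid rotamer library has no backbone-dependent statistics and
  no continuous minimization; off-grid native conformers are
  unreachable.
* The duplicate penalty guarantees uniqueness only within one
  `run_design` call's reserved set (plus whatever the caller seeds it
  with).
* The iteration driver requires the focus/numbered sites to exist in the
  model; it does not remap numbering.
* Proline closure and the fused rings of tryptophan are approximate at
  the 0.01 Å level of the templates; ring-closure bonds are respected in
  the topology but not re-minimized.
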