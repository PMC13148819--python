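# pamdesign

Constrained, rotamer-based redesign of PAM-interacting residues on
protein–DNA complexes, with a multi-PAM (mean + MAD) binding objective.

CRISPR–Cas nucleases only cut next to a protospacer-adjacent motif
(PAM); SaCas9's NNGRRT requirement, for example, sharply limits the
genomic sites it can target.  One route to relaxing such specificity is
computational: redesign the PAM-interacting residues on the crystal
structure of the protein–sgRNA–DNA complex so that the predicted
binding energy becomes strong *and uniform* across a panel of PAM
variants.  `pamdesign` implements that workflow end to end for
structural bioinformaticians who want a self-contained, deterministic,
testable implementation:

* a protein/DNA/RNA complex model with PDB I/O, structure repair,
  fixed-backbone point mutants, and threading of alternative PAM
  sequences onto the existing sugar-phosphate backbone;
* an embedded chi-grid rotamer library;
* a surrogate pairwise energy function decomposed into binding
  (protein ↔ nucleic acid) and non-binding parts;
* simulated-annealing Monte Carlo (SAMC) sequence search under two
  hard constraints, scored by

  `E_total = E_non-bind + w_bind·E_bind + w_evo·E_evo + w_OOR·N_OOR + w_exist·X_exist`

  where `N_OOR` penalizes designs whose substitution count leaves the
  requested range `[N_mut,min, N_mut,max]` and `X_exist` penalizes
  regenerating an already-saved sequence (both weights default to
  1000, so violations dominate any physical energy difference);
* RESFILE-style per-site constraints (`NATRO` / `NATAA` / `PIKAA`),
  automatic mutable/repackable site selection by interface distance
  rules, and exact enumeration of constrained sequence spaces;
* a multi-PAM driver that evaluates every designed variant on every PAM
  state and ranks by the mean binding energy μ and the mean absolute
  deviation `MAD = (1/n)·Σ|e_bind^i − μ|` (MAD = 0 means identical
  affinity across PAMs — the relaxation objective);
* a deterministic synthetic fixture generator (idealized B-DNA duplex +
  α-helical peptide with an annotated PAM window) so every stage is
  testable without downloading structures.

The energy function is an intentionally simple surrogate; its absolute
values carry no meaning outside this package (see `docs/methods.md`).
The workflow machinery — constraints, uniqueness, search, enumeration,
aggregation — is the point, and it is tested against independent
brute-force oracles throughout.

## Worked example

Generate the packaged toy complex — a 10-residue helical peptide whose
residue numbering mirrors the SaCas9 PAM-interacting sites, packed
against a 14-bp duplex carrying a TTGGGT PAM — then run a
single-mutant scan at the focus residue 1015 (nine allowed identities,
0–1 substitutions, duplicate penalty on):

```
$ pamdesign fixture toy.pdb --seed 0
wrote toy.pdb (38 residues, PAM TTGGGT)

$ pamdesign design --pdb toy.pdb --resfile src/pamdesign/data/iteration1.resfile \
      --min-muts 0 --max-muts 1 --n-traj 1000 --seed 0
# design pdb=toy.pdb resfile=src/pamdesign/data/iteration1.resfile min_muts=0 max_muts=1 n_traj=1000 seed=0 penalize_identical_seqs=True
rank	mutations	n_mut	non_bind	bind	total	trajectory	seed
1	R1015K	1	-138.934411	-46.297068	-185.231480	0	0
2	WT	0	-135.496872	-45.918744	-181.415615	1	1
3	R1015Q	1	-134.932072	-42.361920	-177.293992	2	2
4	R1015H	1	-134.683794	-42.361920	-177.045714	3	3
5	R1015Y	1	-133.950632	-42.361920	-176.312553	4	4
6	R1015N	1	-133.948840	-42.361920	-176.310760	5	5
7	R1015C	1	-133.090904	-42.361920	-175.452824	6	6
8	R1015S	1	-132.900073	-42.361920	-175.261994	7	7
9	R1015T	1	-132.787174	-42.361920	-175.149094	8	8
```

Although 1000 trajectories were requested, the run stops after the
space is exhausted: with only nine allowed identities at one site the
duplicate penalty guarantees at most nine unique designs, each row a
distinct sequence inside the substitution range.  `non_bind`, `bind`
and `total` are surrogate energy units — more negative is more
favorable; here every single mutant except R1015K binds the DNA less
tightly than wild type, and the search ranks them accordingly.

Enumerating the third-iteration combination space (focus fixed to His
and counted as a substitution, seven favorable-identity sets, exactly
three substitutions total):

```
$ pamdesign enumerate --pdb toy.pdb --resfile src/pamdesign/data/iteration3.resfile \
      --min-muts 3 --max-muts 3 --count-only
count	50
```

The same operations are available as a library:

```python
from pamdesign.fixtures import default_toy_complex, iteration_resfile_path
from pamdesign.constraints import build_design_spec, parse_resfile
from pamdesign.samc import run_design
from pamdesign.multistate import build_pam_states, evaluate_variant

model = default_toy_complex()
spec = build_design_spec(model, parse_resfile(iteration_resfile_path(1)), 0, 1)
designs = run_design(model, spec, n_traj=1000, base_seed=0)

states = build_pam_states(model)           # TTAGGT / TTCGGT / TTGGGT / TTTGGT
summary = evaluate_variant(designs.records[0].mutations, states)
print(summary.mutation_string, summary.mu, summary.mad)
```

## Layout

```
src/pamdesign/
  structure.py    complex model, PDB I/O, repair, mutants, PAM threading
  rotamers.py     chi-grid library and conformer placement
  energy.py       surrogate pair terms, decomposition, penalties, score
  constraints.py  RESFILE dialect, site selection, exact enumeration
  samc.py         annealing search, design sets, exhaustive oracle
  multistate.py   PAM states, mean/MAD aggregation, iteration driver
  fixtures.py     synthetic duplex + peptide fixture generator
  cli.py          `pamdesign` command-line interface
  data/           packaged iteration RESFILEs
```
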