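import numpy as np
import pytest

from pamdesign.structure import (
    EmptyStructureError,
    PDBFormatError,
    RepairError,
    build_mutant,
    build_pam_variant,
    read_pdb,
    repair_structure,
    write_pdb,
)
from pamdesign.energy import decompose
from oracle_utils import count_clashes


def atoms_equal(res_a, res_b):
    if [a.name for a in res_a.atoms] != [a.name for a in res_b.atoms]:
        return False
    return all(
        np.array_equal(a.pos, b.pos) for a, b in zip(res_a.atoms, res_b.atoms)
    )


def untouched_bit_identical(before, after, touched):
    """Every residue not named in ``touched`` is bit-identical."""
    for r0, r1 in zip(before.residues(), after.residues()):
        key = (r0.chain_id, r0.number)
        if key in touched:
            continue
        if not atoms_equal(r0, r1):
            return False
    return True


# --------------------------------------------------------------------------
# PDB I/O
# --------------------------------------------------------------------------

class TestReadWrite:
    def test_fixture_chain_and_residue_counts(self, toy, toy_pdb):
        model = read_pdb(toy_pdb)
        assert sorted(model.chains) == ["A", "B", "C"]
        assert model.n_residues() == toy.n_residues()

    def test_author_numbering_preserved(self, toy_pdb):
        model = read_pdb(toy_pdb)
        assert [r.number for r in model.chains["A"]] == [
            37, 782, 787, 803, 822, 882, 968, 993, 1015, 1019,
        ]

    def test_round_trip_equality(self, toy, toy_pdb, tmp_path):
        model = read_pdb(toy_pdb)
        assert toy.equals(model)
        again = tmp_path / "again.pdb"
        write_pdb(model, again)
        assert read_pdb(again).equals(model)

    def test_written_pdb_is_standard(self, toy_pdb):
        gemmi = pytest.importorskip("gemmi")
        st = gemmi.read_structure(str(toy_pdb))
        assert [c.name for c in st[0]] == ["A", "B", "C"]
        assert sum(len(c) for c in st[0]) == 38

    def test_water_hetatm_dropped(self, toy_pdb, tmp_path):
        text = toy_pdb.read_text().replace("END\n", "")
        text += (
            "HETATM 9991  O   HOH W   1      99.000  99.000  99.000  1.00  0.00           O\n"
            "END\n"
        )
        p = tmp_path / "wet.pdb"
        p.write_text(text)
        assert read_pdb(p).equals(read_pdb(toy_pdb))
        kept = read_pdb(p, keep_hetero=True)
        assert kept.n_residues() == read_pdb(toy_pdb).n_residues() + 1

    def test_truncated_atom_line_reports_line_number(self, tmp_path):
        p = tmp_path / "trunc.pdb"
        p.write_text("ATOM      1  N   ALA A   1      11.000\n")
        with pytest.raises(PDBFormatError, match="line 1"):
            read_pdb(p)

    def test_duplicate_residue_rejected(self, tmp_path):
        lines = [
            "ATOM      1  N   ALA A   1      11.000  12.000  13.000  1.00  0.00           N",
            "ATOM      2  N   GLY A   2      12.000  12.000  13.000  1.00  0.00           N",
            "ATOM      3  CA  ALA A   1      13.000  12.000  13.000  1.00  0.00           C",
        ]
        p = tmp_path / "dup.pdb"
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(PDBFormatError, match=r"duplicate residue A/1"):
            read_pdb(p)

    def test_empty_structure_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(EmptyStructureError):
            read_pdb(p)

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(IOError):
            read_pdb(tmp_path / "nope.pdb")


# --------------------------------------------------------------------------
# repair
# --------------------------------------------------------------------------

class TestRepair:
    def test_completes_missing_side_chain_atoms(self, toy):
        # LEU has 8 heavy atoms; strip it to N/CA/C/O/CB and repair
        model = build_mutant(toy, [("A", 803, "L")])
        res = model.get("A", 803)
        res.atoms = [a for a in res.atoms if a.is_backbone or a.name == "CB"]
        repaired = repair_structure(model)
        assert len(repaired.get("A", 803).atoms) == 8

    def test_clean_input_is_noop(self, toy):
        assert repair_structure(toy).equals(toy)

    def test_idempotent(self, toy):
        model = build_mutant(toy, [("A", 803, "L")])
        model.get("A", 803).atoms = [
            a for a in model.get("A", 803).atoms if a.is_backbone
        ]
        once = repair_structure(model)
        assert repair_structure(once).equals(once)

    def test_engineered_clash_strictly_decreases(self, toy):
        model = toy.copy()
        res = model.get("A", 968)
        # drag the ASN side chain into the neighbouring residue
        target = model.get("A", 993).atom("CA").pos
        delta = target - res.atom("CB").pos
        for a in res.atoms:
            if not a.is_backbone:
                a.pos = a.pos + delta
        before = count_clashes(model)
        assert before > 0
        after = count_clashes(repair_structure(model))
        assert after < before

    def test_missing_backbone_is_repair_error(self, toy):
        model = toy.copy()
        res = model.get("A", 882)
        res.atoms = [a for a in res.atoms if a.name != "CA"]
        with pytest.raises(RepairError, match="882"):
            repair_structure(model)

    def test_nucleic_coordinates_untouched(self, toy):
        model = build_mutant(toy, [("A", 803, "W")])  # bulky, may clash
        repaired = repair_structure(model)
        for cid in ("B", "C"):
            for r0, r1 in zip(model.chains[cid], repaired.chains[cid]):
                assert atoms_equal(r0, r1)


# --------------------------------------------------------------------------
# mutants
# --------------------------------------------------------------------------

class TestBuildMutant:
    def test_arg_to_ala_atom_count_and_locality(self, toy):
        out = build_mutant(toy, [("A", 1015, "A")])
        res = out.get("A", 1015)
        assert sorted(a.name for a in res.atoms) == ["C", "CA", "CB", "N", "O"]
        assert untouched_bit_identical(toy, out, {("A", 1015)})

    def test_empty_mutation_list_is_identity(self, toy):
        assert build_mutant(toy, []).equals(toy)

    def test_unknown_address_raises(self, toy):
        with pytest.raises(KeyError):
            build_mutant(toy, [("A", 4242, "A")])

    def test_amino_acid_at_nucleotide_site_is_type_error(self, toy):
        with pytest.raises(TypeError):
            build_mutant(toy, [("B", 1, "W")])

    def test_backbone_fixed(self, toy):
        out = build_mutant(toy, [("A", 968, "R")])
        r0, r1 = toy.get("A", 968), out.get("A", 968)
        for name in ("N", "CA", "C", "O"):
            assert np.array_equal(r0.atom(name).pos, r1.atom(name).pos)

    def test_asn_to_arg_near_phosphate_strengthens_binding(self, toy):
        # a basic side chain reaching the PAM phosphates must lower the
        # protein-DNA binding term
        parent = decompose(toy).bind
        mutant = decompose(build_mutant(toy, [("A", 968, "R")])).bind
        assert mutant < parent


# --------------------------------------------------------------------------
# PAM threading
# --------------------------------------------------------------------------

class TestBuildPamVariant:
    def test_current_pam_is_identity(self, toy):
        assert build_pam_variant(toy, toy.pam_sequence()).equals(toy)

    def test_single_base_swap_touches_exactly_two_residues(self, toy):
        out = build_pam_variant(toy, "TTAGGT")
        changed = [
            (r0.chain_id, r0.number)
            for r0, r1 in zip(toy.residues(), out.residues())
            if not atoms_equal(r0, r1)
        ]
        # NTS position 3 and its target-strand partner
        assert changed == [("B", 7), ("C", 8)]
        for key in changed:
            r0, r1 = toy.get(*key), out.get(*key)
            bb0 = [a for a in r0.atoms if a.is_backbone]
            bb1 = [a for a in r1.atoms if a.is_backbone]
            assert all(np.array_equal(a.pos, b.pos) for a, b in zip(bb0, bb1))

    def test_four_pam_models_identical_outside_pam(self, toy):
        pams = ("TTAGGT", "TTCGGT", "TTGGGT", "TTTGGT")
        models = [build_pam_variant(toy, p) for p in pams]
        pam_keys = {("B", n) for n in toy.pam.nts_numbers}
        pam_keys |= {("C", n) for n in toy.pam.ts_numbers}
        for m in models[1:]:
            for r0, r1 in zip(models[0].residues(), m.residues()):
                if (r0.chain_id, r0.number) in pam_keys:
                    continue
                assert atoms_equal(r0, r1)

    def test_there_and_back_restores_identities_and_backbone(self, toy):
        back = build_pam_variant(build_pam_variant(toy, "TTTGGT"), "TTGGGT")
        assert back.pam_sequence() == "TTGGGT"
        for r0, r1 in zip(toy.residues(), back.residues()):
            assert r0.name == r1.name
            bb0 = [a for a in r0.atoms if a.is_backbone]
            bb1 = [a for a in r1.atoms if a.is_backbone]
            assert all(np.array_equal(a.pos, b.pos) for a, b in zip(bb0, bb1))

    def test_missing_annotation_is_config_error(self, toy):
        bare = toy.copy()
        bare.pam = None
        with pytest.raises(ValueError, match="annotation"):
            build_pam_variant(bare, "TTAGGT")

    def test_non_acgt_rejected(self, toy):
        with pytest.raises(ValueError):
            build_pam_variant(toy, "TTXGGT")
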