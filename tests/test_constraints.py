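import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pamdesign.constraints import (
    DesignSpec,
    EnumerationCapError,
    ResfileError,
    SiteConstraint,
    build_design_spec,
    enumerate_design_space,
    parse_resfile,
    select_design_sites,
)
from pamdesign.fixtures import default_toy_complex, iteration_resfile_path
from pamdesign.geometry import rotation_about_axis
from oracle_utils import brute_force_enumeration, brute_force_site_selection


def spec_from(sites, n_min, n_max, native):
    """DesignSpec straight from (number, allowed) pairs and a native map."""
    cons = [SiteConstraint("A", n, "design", frozenset(a)) for n, a in sites]
    return DesignSpec(sites=cons, n_min=n_min, n_max=n_max,
                      native_sequence={("A", n): nat for n, nat in native.items()})


# --------------------------------------------------------------------------
# RESFILE parsing
# --------------------------------------------------------------------------

class TestResfile:
    def test_single_mutant_scan_file(self):
        cons = parse_resfile(iteration_resfile_path(1))
        assert len(cons) == 1
        (c,) = cons
        assert c.mode == "design" and c.site == ("A", 1015)
        assert c.allowed == frozenset("CHKNQRSTY") and len(c.allowed) == 9

    def test_empty_file_means_all_fixed(self, tmp_path):
        p = tmp_path / "empty.resfile"
        p.write_text("# nothing but comments\n\n")
        assert parse_resfile(p) == []

    def test_all_three_directives(self, tmp_path):
        p = tmp_path / "mix.resfile"
        p.write_text("A 5 NATRO\nA 6 NATAA\nA 7 PIKAA HKR\n")
        modes = [c.mode for c in parse_resfile(p)]
        assert modes == ["fixed-native", "repack-only", "design"]

    @pytest.mark.parametrize(
        "content,match",
        [
            ("A 5 PIKAA H\nA 5 NATAA\n", "duplicate"),
            ("A 5 WOBBLE\n", "unknown directive"),
            ("A 5 PIKAA\n", "PIKAA requires"),
            ("A 5 PIKAA HZX\n", "unknown amino-acid"),
            ("A five NATRO\n", "not an integer"),
        ],
    )
    def test_parse_errors_carry_line_numbers(self, tmp_path, content, match):
        p = tmp_path / "bad.resfile"
        p.write_text(content)
        with pytest.raises(ResfileError, match=match):
            parse_resfile(p)

    def test_binding_to_model_checks_residues(self, toy):
        with pytest.raises(KeyError):
            build_design_spec(toy, [SiteConstraint("A", 4242, "design", frozenset("H"))], 0, 1)
        with pytest.raises(TypeError):
            build_design_spec(toy, [SiteConstraint("B", 1, "design", frozenset("H"))], 0, 1)


# --------------------------------------------------------------------------
# enumeration
# --------------------------------------------------------------------------

class TestEnumeration:
    def test_single_site_scan_gives_nine(self, toy):
        spec = build_design_spec(toy, parse_resfile(iteration_resfile_path(1)), 0, 1)
        space = enumerate_design_space(spec)
        assert space.count == 9
        seqs = list(space)
        assert len(seqs) == 9 and len(set(seqs)) == 9
        assert ("R",) in seqs  # the native is admitted by the 0-1 range

    def test_triple_mutant_combination_space_is_fifty(self, toy):
        spec = build_design_spec(toy, parse_resfile(iteration_resfile_path(3)), 3, 3)
        space = enumerate_design_space(spec)
        assert space.count == 50
        assert len(set(space)) == 50

    def test_fixed_background_double_mutants_product_rule(self):
        # 26 sites x all 20 identities on a forced-substitution background:
        # exactly-2 counting admits 26 * 19 combinations
        native = {1015: "R"}
        sites = [(1015, "H")]
        for k in range(26):
            native[k] = "A"
            sites.append((k, "ACDEFGHIKLMNPQRSTVWY"))
        spec = spec_from(sites, 2, 2, native)
        assert enumerate_design_space(spec).count == 26 * 19

    def test_all_native_zero_range_single_sequence(self, toy):
        spec = build_design_spec(toy, parse_resfile(iteration_resfile_path(3)), 0, 0)
        # 1015 is forced to H, so a 0-0 range is infeasible; with the
        # focus relaxed the native sequence is the only member
        assert spec.feasible_warning is not None
        assert enumerate_design_space(spec).count == 0
        cons = [SiteConstraint("A", 37, "design", frozenset("KR"))]
        spec2 = build_design_spec(toy, cons, 0, 0)
        assert list(enumerate_design_space(spec2)) == [("K",)]

    def test_cap_refused_with_size_estimate(self):
        sites = [(k, "ACDEFGHIKL") for k in range(6)]
        native = {k: "A" for k in range(6)}
        spec = spec_from(sites, 0, 6, native)
        with pytest.raises(EnumerationCapError) as err:
            enumerate_design_space(spec, cap=1000)
        assert err.value.estimate == 10**6

    @given(
        st.lists(
            st.tuples(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
                      st.sets(st.sampled_from("ACDEFGHIK"), min_size=1, max_size=4)),
            min_size=1, max_size=5,
        ),
        st.integers(0, 3),
        st.integers(0, 3),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_cartesian_product_filter(self, site_data, n_min, spread):
        n_max = n_min + spread
        sites = [(k, "".join(sorted(allowed))) for k, (_nat, allowed) in enumerate(site_data)]
        native = {k: nat for k, (nat, _allowed) in enumerate(site_data)}
        spec = spec_from(sites, n_min, n_max, native)
        space = enumerate_design_space(spec)
        expected = brute_force_enumeration(spec)
        got = list(space)
        assert len(got) == len(set(got)) == space.count
        assert set(got) == expected


# --------------------------------------------------------------------------
# design-site selection
# --------------------------------------------------------------------------

class TestSiteSelection:
    def test_matches_brute_force_scan(self, toy):
        sel = select_design_sites(toy, ("A", 1015))
        mut, rep = brute_force_site_selection(toy, ("A", 1015))
        assert sel.mutable == mut
        assert sel.repackable == rep

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_fixtures(self, seed):
        from pamdesign.fixtures import random_fixture

        model = random_fixture(seed)
        focus = ("A", model.chains["A"][len(model.chains["A"]) // 2].number)
        sel = select_design_sites(model, focus)
        mut, rep = brute_force_site_selection(model, focus)
        assert sel.mutable == mut and sel.repackable == rep

    def test_lists_are_disjoint_and_protein_only(self, toy):
        sel = select_design_sites(toy, ("A", 1015))
        assert not set(sel.mutable) & set(sel.repackable)
        for c, _n in sel.mutable + sel.repackable:
            assert c == "A"

    def test_remote_residue_in_neither_list(self, toy):
        from pamdesign.structure import AtomRecord, Residue
        from pamdesign.rotamers import build_side_chain

        model = toy.copy()
        n = np.array([60.0, 60.0, 0.0])
        ca = n + np.array([1.458, 0, 0])
        c = ca + np.array([0.55, 1.42, 0])
        res = Residue("A", 5000, "", "SER", "protein")
        for name, pos in (("N", n), ("CA", ca), ("C", c), ("O", c + np.array([0.6, 1.0, 0]))):
            res.atoms.append(AtomRecord(name, name[0], pos, True))
        for name, elem, pos in build_side_chain(n, ca, c, "SER", (-60.0,)):
            res.atoms.append(AtomRecord(name, elem, pos, False))
        model.chains["A"] = model.chains["A"] + [res]
        sel = select_design_sites(model, ("A", 1015))
        assert ("A", 5000) not in sel.mutable
        assert ("A", 5000) not in sel.repackable

    def test_monotone_in_cutoffs(self, toy):
        small = select_design_sites(toy, ("A", 1015), d_side=3.0, d_pam=4.0)
        large = select_design_sites(toy, ("A", 1015), d_side=6.0, d_pam=8.0)
        assert set(small.mutable) <= set(large.mutable)
        assert set(small.mutable) | set(small.repackable) <= (
            set(large.mutable) | set(large.repackable)
        )

    def test_invariant_under_rigid_motion(self, toy):
        moved = toy.copy()
        R = rotation_about_axis(np.array([0.3, 1.0, 0.2]), 119.0)
        t = np.array([-7.0, 2.0, 13.0])
        for res in moved.residues():
            for a in res.atoms:
                a.pos = R @ a.pos + t
        sel0 = select_design_sites(toy, ("A", 1015))
        sel1 = select_design_sites(moved, ("A", 1015))
        assert sel0.mutable == sel1.mutable
        assert sel0.repackable == sel1.repackable

    def test_missing_annotation_is_config_error(self, toy):
        bare = toy.copy()
        bare.pam = None
        with pytest.raises(ValueError, match="annotation"):
            select_design_sites(bare, ("A", 1015))
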