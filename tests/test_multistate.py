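import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pamdesign.energy import decompose
from pamdesign.multistate import (
    IterationSettings,
    MultiStateSummary,
    build_pam_states,
    evaluate_variant,
    iteration_spec,
    mad,
    rank_variants,
    run_iteration_protocol,
)
from pamdesign.constraints import enumerate_design_space, select_design_sites
from pamdesign.samc import AnnealSchedule


def summary(name_muts, e_bind):
    return MultiStateSummary(variant=name_muts, e_bind=e_bind)


def var(*muts):
    return tuple((("A", num), nat, new) for num, nat, new in muts)


class TestMad:
    def test_identical_values_give_zero(self):
        assert mad([-500.0] * 4) == 0.0

    def test_closed_form_example(self):
        assert mad([-514, -510, -512, -508]) == pytest.approx(2.0)

    def test_single_value_is_zero(self):
        assert mad([3.7]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mad([])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=12),
           st.floats(-1e3, 1e3), st.floats(-20, 20))
    @settings(max_examples=200, derandomize=True)
    def test_shift_invariance_and_scale_covariance(self, values, shift, scale):
        base = mad(values)
        assert mad([v + shift for v in values]) == pytest.approx(base, abs=1e-9)
        assert mad([scale * v for v in values]) == pytest.approx(
            abs(scale) * base, abs=1e-6 * max(1.0, abs(scale))
        )

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=10))
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_definition(self, values):
        mu = sum(values) / len(values)
        brute = sum(abs(v - mu) for v in values) / len(values)
        assert mad(values) == pytest.approx(brute, abs=1e-9)


class TestSummary:
    def test_mu_and_mad_recompute_from_components(self):
        s = summary((), {"TTAGGT": -505.0, "TTCGGT": -507.0, "TTGGGT": -509.0,
                         "TTTGGT": -507.0})
        vals = list(s.e_bind.values())
        assert s.mu == pytest.approx(sum(vals) / 4, abs=1e-9)
        assert s.mad == pytest.approx(mad(vals), abs=1e-9)

    def test_constant_offset_shifts_mu_not_mad(self):
        base = {"TTAGGT": -505.0, "TTCGGT": -507.0, "TTGGGT": -509.0, "TTTGGT": -507.0}
        s0 = summary((), base)
        s1 = summary((), {k: v + 12.5 for k, v in base.items()})
        assert s1.mu == pytest.approx(s0.mu + 12.5, abs=1e-9)
        assert s1.mad == pytest.approx(s0.mad, abs=1e-12)


class TestRanking:
    def test_lower_mean_binding_ranks_first(self):
        # the printed mean/MAD pairs of the two PAM-relaxed triple mutants:
        # KRH (mu -513.75, MAD 0.61) must precede KKH (mu -513.12, MAD 0.67)
        krh = summary(var((782, "E", "K"), (968, "N", "R"), (1015, "R", "H")),
                      {"p": -513.75})
        krh.mu, krh.mad = -513.75, 0.61
        kkh = summary(var((782, "E", "K"), (968, "N", "K"), (1015, "R", "H")),
                      {"p": -513.12})
        kkh.mu, kkh.mad = -513.12, 0.67
        ranked = rank_variants([kkh, krh])
        assert ranked[0] is krh and ranked[1] is kkh

    def test_threshold_filter_passes_borderline_variant(self):
        s = summary(var((803, "N", "W"), (1015, "R", "H")), {"p": -507.76})
        s.mu, s.mad = -507.76, 0.80
        kept = rank_variants([s], mean_cut=-507.61, mad_cut=0.82)
        assert kept == [s]
        dropped = rank_variants([s], mean_cut=-507.80, mad_cut=0.82)
        assert dropped == []

    def test_empty_input_empty_output(self):
        assert rank_variants([]) == []

    def test_total_order_and_idempotence(self):
        rng = np.random.default_rng(0)
        pool = []
        for k in range(25):
            s = summary(var((37, "K", "R")), {"p": 0.0})
            s.mu = float(rng.choice([-510.0, -508.0, -506.0]))
            s.mad = float(rng.choice([0.5, 0.7]))
            pool.append(s)
        once = rank_variants(pool)
        assert sorted(map(id, once)) == sorted(map(id, pool))
        assert rank_variants(once) == once
        keys = [(s.mu, s.mad, s.mutation_string) for s in once]
        assert keys == sorted(keys)


@pytest.fixture(scope="module")
def two_states(small_toy):
    return build_pam_states(small_toy, ("TTGGGT", "TTAGGT"))


class TestEvaluateVariant:
    def test_native_matches_plain_decomposition(self, small_toy, two_states):
        s = evaluate_variant((), two_states[:1])
        assert s.e_bind["TTGGGT"] == pytest.approx(decompose(two_states[0].model).bind,
                                                   abs=1e-9)

    def test_deterministic(self, two_states):
        v = var((6, "R", "K"))
        a = evaluate_variant(v, two_states)
        b = evaluate_variant(v, two_states)
        assert a.e_bind == b.e_bind and a.mu == b.mu and a.mad == b.mad

    def test_inconsistent_states_rejected(self, small_toy, two_states):
        broken = build_pam_states(small_toy, ("TTGGGT", "TTAGGT"))
        atom = broken[1].model.chains["A"][0].atoms[0]
        atom.pos = atom.pos + 0.5
        with pytest.raises(ValueError, match="differ outside the PAM"):
            evaluate_variant((), broken)

    def test_states_share_everything_but_the_pam(self, toy):
        states = build_pam_states(toy)
        assert [s.pam for s in states] == ["TTAGGT", "TTCGGT", "TTGGGT", "TTTGGT"]
        pam_keys = {("B", n) for n in toy.pam.nts_numbers}
        pam_keys |= {("C", n) for n in toy.pam.ts_numbers}
        ref = states[0].model
        for st_ in states[1:]:
            for r0, r1 in zip(ref.residues(), st_.model.residues()):
                if (r0.chain_id, r0.number) in pam_keys:
                    continue
                assert r0.name == r1.name
                assert all(
                    np.array_equal(a.pos, b.pos) for a, b in zip(r0.atoms, r1.atoms)
                )


class TestIterationProtocol:
    def test_invalid_iteration_rejected(self, toy):
        with pytest.raises(ValueError):
            run_iteration_protocol(toy, 4)

    def test_iteration_specs_reproduce_design_space_sizes(self, toy):
        settings_ = IterationSettings()
        spec1 = iteration_spec(toy, 1, settings_)
        assert enumerate_design_space(spec1).count == 9
        spec2 = iteration_spec(toy, 2, settings_)
        m = len(select_design_sites(toy, ("A", 1015)).mutable) - 1
        assert enumerate_design_space(spec2).count == 19 * m
        spec3 = iteration_spec(toy, 3, settings_)
        assert enumerate_design_space(spec3).count == 50

    def test_single_mutant_scan_protocol_desk_scale(self, toy):
        settings_ = IterationSettings(
            pams=("TTGGGT", "TTAGGT"),
            n_traj=12,
            n_repeats=2,
            keep=1,
            base_seed=0,
        )
        result = run_iteration_protocol(toy, 1, settings_)
        assert result.feasible_space_size == 9
        assert 1 <= len(result.summaries) <= 9
        mus = [s.mu for s in result.summaries]
        assert mus == sorted(mus)
        for s in result.summaries:
            assert set(s.e_bind) == {"TTGGGT", "TTAGGT"}
            assert s.mad >= 0.0
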