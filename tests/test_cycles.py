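"""Unit and property tests for the thermodynamic-cycle algebra."""
import numpy as np
import pytest

from mutcycle.cycles import (
    WT,
    DDGTable,
    MutationSet,
    MutationSpec,
    compose_path,
    ddg_from_legs,
    is_correlated,
    nonadditivity,
    propagate,
    triple_box,
)
from mutcycle.errors import DuplicateEdgeError, MissingEdgeError, NoPathError
from mutcycle.estimators import FreeEnergyEstimate

from conftest import make_specs, random_consistent_table


def est(value, unc=0.0):
    return FreeEnergyEstimate(value, unc)


class TestMutationSpec:
    @pytest.mark.parametrize(
        "code, position, wt, mut, chain",
        [
            ("L37A", 37, "L", "A", ""),
            ("G79S", 79, "G", "S", ""),
            ("B:N118D", 118, "N", "D", "B"),
        ],
    )
    def test_parse_render_round_trip(self, code, position, wt, mut, chain):
        spec = MutationSpec.from_code(code)
        assert (spec.position, spec.wt_res, spec.mut_res, spec.chain) == (
            position, wt, mut, chain,
        )
        assert spec.code == code

    @pytest.mark.parametrize("bad", ["L37", "37A", "L37L", "X37A", "L37B37", ""])
    def test_malformed_codes_rejected(self, bad):
        with pytest.raises(ValueError):
            MutationSpec.from_code(bad)

    def test_charge_change_flag(self):
        assert MutationSpec.from_code("N118D").is_charge_changing
        assert MutationSpec.from_code("K16M").is_charge_changing
        assert not MutationSpec.from_code("L37A").is_charge_changing
        assert not MutationSpec.from_code("D21E").is_charge_changing  # both negative


class TestMutationSet:
    def test_label_is_order_independent(self):
        a, b = make_specs("L37A", "G79S")
        assert MutationSet([a, b]) == MutationSet([b, a])
        assert MutationSet([b, a]).label == "L37A+G79S"
        assert hash(MutationSet([a, b])) == hash(MutationSet([b, a]))

    def test_wild_type_is_empty(self):
        assert MutationSet.from_code("").label == ""
        assert len(WT) == 0

    def test_one_mutation_per_site(self):
        with pytest.raises(ValueError, match="same site"):
            MutationSet(make_specs("L37A", "L37V"))

    def test_add_returns_new_state(self):
        a, b = make_specs("L37A", "G79S")
        state = MutationSet([a]).add(b)
        assert a in state and b in state
        assert len(MutationSet([a])) == 1  # original untouched


class TestDdgFromLegs:
    def test_subtraction_with_quadrature(self):
        out = ddg_from_legs(est(4.0, 0.3), est(1.0, 0.4))
        assert out.value == pytest.approx(3.0)
        assert out.uncertainty == pytest.approx(0.5)
        assert not out.offset_relative

    def test_zero_unfolded_leg_is_identity(self):
        out = ddg_from_legs(est(2.5, 0.1), est(0.0, 0.0))
        assert out.value == 2.5 and out.uncertainty == pytest.approx(0.1)

    def test_missing_unfolded_leg_flags_offset(self):
        out = ddg_from_legs(est(2.5, 0.1))
        assert out.offset_relative

    def test_unfolded_offsets_cancel_in_delta(self):
        """Tables differing by a per-single-mutation unfolded offset give
        identical couplings: the unfolded-state-cancellation assumption."""
        rng = np.random.default_rng(99)
        specs = make_specs("L37A", "G79S", "N118A")
        for _ in range(20):
            _, energies = random_consistent_table(rng, specs)
            offsets = {s: rng.uniform(-5, 5) for s in specs}
            shifted = {
                state: g + sum(offsets[m] for m in state.mutations)
                for state, g in energies.items()
            }
            t0 = DDGTable.from_state_energies(energies)
            t1 = DDGTable.from_state_energies(shifted)
            a, b, c = specs
            for ref in (WT, MutationSet([c])):
                d0 = nonadditivity(t0, a, b, ref).delta
                d1 = nonadditivity(t1, a, b, ref).delta
                assert d0 == pytest.approx(d1, abs=1e-9)


class TestNonadditivity:
    def test_perfectly_additive_pair_gives_zero(self):
        a, b = make_specs("L37A", "G79S")
        table = DDGTable()
        table.add(WT, MutationSet([a]), est(2.0))
        table.add(WT, MutationSet([b]), est(3.0))
        table.add(WT, MutationSet([a, b]), est(5.0))
        res = nonadditivity(table, a, b)
        assert res.delta == 0.0

    def test_value_and_quadrature_uncertainty(self):
        a, b = make_specs("L37A", "G79S")
        table = DDGTable()
        table.add(WT, MutationSet([a]), est(2.0, 0.5))
        table.add(WT, MutationSet([b]), est(3.0, 0.5))
        table.add(WT, MutationSet([a, b]), est(9.0, 0.5))
        res = nonadditivity(table, a, b)
        assert res.delta == pytest.approx(4.0)
        assert res.uncertainty == pytest.approx(np.sqrt(0.75))

    def test_missing_edge_error_names_the_key(self):
        a, b = make_specs("L37A", "G79S")
        table = DDGTable()
        table.add(WT, MutationSet([a]), est(2.0))
        table.add(WT, MutationSet([a, b]), est(5.0))
        with pytest.raises(MissingEdgeError, match=r"\(WT, G79S\)"):
            nonadditivity(table, a, b)

    def test_pair_symmetry_is_exact(self):
        rng = np.random.default_rng(5)
        specs = make_specs("L37A", "G79S", "N118D")
        table, _ = random_consistent_table(rng, specs)
        a, b, _ = specs
        assert nonadditivity(table, a, b).delta == nonadditivity(table, b, a).delta

    def test_planted_coupling_recovered_exactly(self):
        from mutcycle.synthetic import emit_ddg_table, generate_landscape

        model = generate_landscape(5, 2, 0, seed=31)
        pair = sorted(next(iter(model.pair_couplings)), key=lambda m: m.sort_key)
        c = model.pair_couplings[frozenset(pair)]
        table = emit_ddg_table(model, pairs=[tuple(pair)], noise_sd=0.0)
        assert nonadditivity(table, *pair).delta == pytest.approx(c, abs=1e-12)


class TestComposePath:
    def test_direct_edge_passes_through_unchanged(self, consistent_table):
        table, energies, (a, b, c) = consistent_table
        direct = table.get(WT, MutationSet([a]))
        out = compose_path(table, WT, MutationSet([a]))
        assert out.estimate is direct

    def test_all_pathways_agree_on_consistent_tables(self):
        """Free energy is a state function: every chain between two states
        of a consistent table sums to the same ΔΔG."""
        rng = np.random.default_rng(17)
        specs = make_specs("L37A", "G79S", "N118D")
        for _ in range(30):
            table, energies = random_consistent_table(rng, specs)
            a, b, _ = specs
            target = MutationSet([a, b])
            out = compose_path(table, WT, target)
            assert out.max_discrepancy < 1e-10
            assert out.estimate.value == pytest.approx(
                energies[target] - energies[WT], abs=1e-10
            )

    def test_two_step_chain_matches_direct_edge(self):
        a, b = make_specs("L37A", "G79S")
        sa, sab = MutationSet([a]), MutationSet([a, b])
        table = DDGTable()
        table.add(WT, sa, est(1.0, 0.1))
        table.add(sa, sab, est(2.0, 0.2))
        out = compose_path(table, WT, sab)
        assert out.estimate.value == pytest.approx(3.0)
        assert out.estimate.uncertainty == pytest.approx(np.hypot(0.1, 0.2))

    def test_reverse_traversal_negates_edge(self):
        a, b = make_specs("L37A", "G79S")
        sa, sb = MutationSet([a]), MutationSet([b])
        sab = MutationSet([a, b])
        table = DDGTable()
        table.add(sa, sab, est(2.0))
        table.add(sb, sab, est(5.0))
        # sa -> sab -> sb must give 2.0 - 5.0
        out = compose_path(table, sa, sb)
        assert out.estimate.value == pytest.approx(-3.0)

    def test_no_path_raises(self):
        a, b, c = make_specs("L37A", "G79S", "N118D")
        table = DDGTable()
        table.add(WT, MutationSet([a]), est(1.0))
        table.add(MutationSet([b]), MutationSet([b, c]), est(1.0))
        with pytest.raises(NoPathError):
            compose_path(table, MutationSet([a]), MutationSet([b, c]))

    def test_identical_states_compose_to_zero(self, consistent_table):
        table, _, _ = consistent_table
        out = compose_path(table, WT, WT)
        assert out.estimate.value == 0.0


class TestTripleBox:
    def test_decomposition_equals_direct_form(self):
        """The triple-box decomposition is an exact consequence of state-
        function additivity: check both routes on random consistent tables."""
        rng = np.random.default_rng(8)
        specs = make_specs("L37A", "G79S", "N118D")
        a, b, c = specs
        for _ in range(200):
            table, _ = random_consistent_table(rng, specs)
            direct = triple_box(table, a, b, c, form="direct")
            decomp = triple_box(table, a, b, c, form="decomposition")
            assert abs(direct.delta - decomp.delta) < 1e-10

    def test_uniform_third_mutation_leaves_coupling_unchanged(self):
        """When introducing C costs the same ΔΔG in every background, all
        C terms cancel and δ_C^AB = δ_WT^AB."""
        a, b, c = make_specs("L37A", "G79S", "P117L")
        g = {}
        rng = np.random.default_rng(3)
        base = {
            (): 0.0,
            ("a",): 1.7,
            ("b",): -2.3,
            ("a", "b"): 4.1,
        }
        cost_c = 0.9
        for mask, val in base.items():
            members = [{"a": a, "b": b}[k] for k in mask]
            g[MutationSet(members)] = val
            g[MutationSet(members + [c])] = val + cost_c
        table = DDGTable.from_state_energies(g)
        res = triple_box(table, a, b, c)
        d_wt = nonadditivity(table, a, b)
        assert res.delta == pytest.approx(d_wt.delta, abs=1e-12)

    def test_fully_additive_landscape_gives_zero(self):
        a, b, c = make_specs("L37A", "G79S", "N118A")
        singles = {a: 1.0, b: -2.0, c: 0.5}
        g = {}
        for mask in range(8):
            members = [s for i, s in enumerate((a, b, c)) if mask & (1 << i)]
            g[MutationSet(members)] = sum(singles[m] for m in members)
        table = DDGTable.from_state_energies(g)
        assert triple_box(table, a, b, c).delta == pytest.approx(0.0, abs=1e-12)

    def test_missing_edges_named(self):
        a, b, c = make_specs("L37A", "G79S", "N118D")
        table = DDGTable()
        table.add(WT, MutationSet([a]), est(1.0))
        with pytest.raises(MissingEdgeError):
            triple_box(table, a, b, c, form="direct")

    def test_decomposition_fallback_when_c_reference_absent(self):
        """With only WT-rooted and C-introduction edges (no C-referenced
        double-mutant cycle) the auto form still returns δ_C^AB."""
        rng = np.random.default_rng(23)
        specs = make_specs("L37A", "G79S", "N118D")
        a, b, c = specs
        _, energies = random_consistent_table(rng, specs)
        table = DDGTable()
        for ref_members, tgt_members in [
            ((), (a,)), ((), (b,)), ((), (a, b)), ((), (c,)),
            ((a,), (a, c)), ((b,), (b, c)), ((a, b), (a, b, c)),
        ]:
            ref, tgt = MutationSet(ref_members), MutationSet(tgt_members)
            table.add(ref, tgt, est(energies[tgt] - energies[ref]))
        expected = (
            energies[MutationSet([a, b, c])]
            - energies[MutationSet([a, c])]
            - energies[MutationSet([b, c])]
            + energies[MutationSet([c])]
        )
        res = triple_box(table, a, b, c)
        assert res.delta == pytest.approx(expected, abs=1e-10)
        decomp = triple_box(table, a, b, c, form="decomposition")
        assert decomp.delta == pytest.approx(expected, abs=1e-10)
        assert "delta_wt_ab" in decomp.breakdown


class TestPropagate:
    def test_single_component_unchanged(self):
        out = propagate([est(1.5, 0.3)])
        assert out.value == 1.5 and out.uncertainty == pytest.approx(0.3)

    def test_two_half_uncertainties_combine_to_sqrt_half(self):
        out = propagate([est(1.0, 0.5), est(2.0, 0.5)], [1, 1])
        assert out.uncertainty == pytest.approx(0.7071, abs=1e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            propagate([est(1.0)], [1, -1])

    def test_matches_monte_carlo_propagation(self):
        rng = np.random.default_rng(15)
        for _ in range(5):
            values = rng.uniform(-5, 5, 4)
            uncs = rng.uniform(0.1, 2.0, 4)
            signs = rng.choice([-1, 1], 4)
            out = propagate(
                [est(v, u) for v, u in zip(values, uncs)], list(signs)
            )
            draws = (
                signs[None, :] * rng.normal(values, uncs, size=(100_000, 4))
            ).sum(axis=1)
            assert out.value == pytest.approx((signs * values).sum())
            assert out.uncertainty == pytest.approx(draws.std(), rel=0.02)


class TestTable:
    def test_duplicate_edge_rejected(self):
        a = MutationSpec.from_code("L37A")
        table = DDGTable()
        table.add(WT, MutationSet([a]), est(1.0))
        with pytest.raises(DuplicateEdgeError):
            table.add(WT, MutationSet([a]), est(2.0))

    def test_target_must_strictly_contain_reference(self):
        a, b = make_specs("L37A", "G79S")
        table = DDGTable()
        with pytest.raises(ValueError, match="strictly contain"):
            table.add(MutationSet([a]), MutationSet([b]), est(1.0))


def test_is_correlated_threshold():
    from mutcycle.cycles import CouplingResult

    a, b = make_specs("L37A", "G79S")
    strong = CouplingResult((a, b), WT, delta=6.85, uncertainty=1.44)
    weak = CouplingResult((a, b), WT, delta=0.4, uncertainty=0.3)
    noisy = CouplingResult((a, b), WT, delta=2.0, uncertainty=1.5)
    assert is_correlated(strong)
    assert not is_correlated(weak)
    assert not is_correlated(noisy)  # |δ| < 2σ
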