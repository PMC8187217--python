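"""Decomposition layer: bipartition enumeration, essential decompositions,
assembly with matching, refusals, and the driver against the null-space
oracle."""
import numpy as np
import pytest

from crndecomp import (
    Decomposition,
    RefusalError,
    UndecomposableError,
    complex_balance_point,
    enumerate_reaction_bipartitions,
    essential_decompositions,
    generate_fixture,
    irreducible_component,
    master_equation_residual,
    parse_network,
    solve_by_decomposition,
    solve_master_direct,
    total_variation,
)
from crndecomp.decompose import (
    Decomposition,
    SolveContext,
    assemble_stationary,
    solve_complex_balanced,
    solve_motif,
)
from crndecomp.config import DEFAULT


class TestBipartitions:
    @pytest.mark.parametrize("n_reactions,expected", [(1, 1), (2, 3), (3, 7)])
    def test_ordered_count(self, n_reactions, expected):
        lines = "\n".join(f"A{i} -> B{i} ; rate=1" for i in range(n_reactions))
        g = parse_network(lines)
        assert sum(1 for _ in enumerate_reaction_bipartitions(g)) == expected

    def test_double_motif_hub_has_255_ordered_and_the_canonical_split(self, double_motif_hub):
        g = double_motif_hub.network
        assert sum(1 for _ in enumerate_reaction_bipartitions(g)) == 255
        target = {frozenset(range(4)), frozenset(range(4, 8))}
        hits = [
            (a, b)
            for a, b in enumerate_reaction_bipartitions(g, unordered=True)
            if {a, b} == target
        ]
        assert len(hits) == 1

    def test_unordered_halves(self, double_motif_hub):
        ordered = sum(1 for _ in enumerate_reaction_bipartitions(double_motif_hub.network))
        unordered = sum(
            1
            for _ in enumerate_reaction_bipartitions(
                double_motif_hub.network, unordered=True
            )
        )
        assert unordered == (ordered + 1) // 2


class TestEssentialDecompositions:
    def test_double_motif_hub_contains_the_motif_split(self, double_motif_hub):
        decomps = essential_decompositions(double_motif_hub.network, max_parts=2)
        targets = [set(d.part_indices) for d in decomps]
        assert {frozenset(range(4)), frozenset(range(4, 8))} in targets

    def test_gene_expression_only_trivial(self):
        g = generate_fixture("gene_expression").network
        decomps = essential_decompositions(g, max_parts=3)
        assert [set(d.part_indices) for d in decomps] == [
            {frozenset(range(4))}
        ]

    def test_disjoint_union_natural_split_found(self):
        bundle = generate_fixture("disjoint_union", seed=2)
        decomps = essential_decompositions(bundle.network, max_parts=2)
        assert {frozenset(range(4)), frozenset(range(4, 8))} in [
            set(d.part_indices) for d in decomps
        ]

    def test_finer_decompositions_ranked_first(self, double_motif_hub):
        decomps = essential_decompositions(double_motif_hub.network, max_parts=3)
        sizes = [len(d.part_indices) for d in decomps]
        assert sizes == sorted(sizes, reverse=True)


class TestComplexBalance:
    def test_birth_death_point(self):
        g = generate_fixture("birth_death", rates=(3.0, 2.0)).network
        point = complex_balance_point(g)
        assert point["S2"] == pytest.approx(1.5)

    def test_triple_exchange_point_ratio(self):
        bundle = generate_fixture("triple_exchange", rates=(2.0, 0.5))
        point = complex_balance_point(bundle.network)
        assert point["S5"] / point["S3"] == pytest.approx(
            bundle.truth["complex_balance_ratio"]
        )

    def test_deficiency_one_network_has_no_point(self, double_motif_hub):
        assert complex_balance_point(double_motif_hub.network.subnetwork(range(4))) is None


class TestAssembly:
    def test_double_motif_hub_assembles_to_oracle(self, double_motif_hub):
        g = double_motif_hub.network
        comp = irreducible_component(g, None, (2, 1, 1))
        oracle = solve_master_direct(g, None, comp)
        dist, report = solve_by_decomposition(g, None, comp)
        assert report["method"] == "decomposition"
        assert set(report["decomposition"]["solver_tags"]) == {"motif"}
        assert total_variation(dist, oracle) < 1e-10
        assert dist.residual < 1e-9

    def test_disjoint_union_is_outer_product(self):
        bundle = generate_fixture("disjoint_union", seed=4)
        g = bundle.network
        comp = irreducible_component(g, None, (2, 1, 1, 2))
        dist, _ = solve_by_decomposition(g, None, comp)
        # marginal product check: p(x) = p_AB(x_AB) * p_CD(x_CD)
        g1, g2 = g.subnetwork(range(4)), g.subnetwork(range(4, 8))
        c1 = irreducible_component(g1, None, (2, 1))
        c2 = irreducible_component(g2, None, (1, 2))
        d1 = solve_master_direct(g1, None, c1)
        d2 = solve_master_direct(g2, None, c2)
        for state, p in zip(comp.states, dist.probs):
            expected = d1.prob(state[:2]) * d2.prob(state[2:])
            assert p == pytest.approx(expected, abs=1e-12)

    def test_glued_mixed_star(self):
        bundle = generate_fixture("glued_mixed", seed=9)
        comp = irreducible_component(bundle.network, None, (1, 1, 1, 1))
        oracle = solve_master_direct(bundle.network, None, comp)
        dist, report = solve_by_decomposition(bundle.network, None, comp)
        assert report["method"] == "decomposition"
        assert total_variation(dist, oracle) < 1e-10

    def test_autocatalytic_join_decomposes_into_motifs_and_poisson(self):
        bundle = generate_fixture("autocatalytic_join", seed=4)
        assert bundle.truth["matched"]
        comp = irreducible_component(bundle.network, None, (1, 1, 1, 1, 1))
        oracle = solve_master_direct(bundle.network, None, comp)
        dist, report = solve_by_decomposition(bundle.network, None, comp)
        assert report["method"] == "decomposition"
        assert "complex_balanced" in report["decomposition"]["solver_tags"]
        assert total_variation(dist, oracle) < 1e-9

    def test_autocatalytic_family_solved_by_motif_solver(self):
        bundle = generate_fixture("autocatalytic_motif", seed=3, ms=(1, 2, 3))
        comp = irreducible_component(bundle.network, None, (5, 2))
        oracle = solve_master_direct(bundle.network, None, comp)
        dist, report = solve_by_decomposition(bundle.network, None, comp)
        assert report["decomposition"]["solver_tags"] == ["motif"]
        assert total_variation(dist, oracle) < 1e-10

    def test_motif_birth_death_infinite_component(self):
        bundle = generate_fixture("motif_birth_death", seed=5)
        comp = irreducible_component(bundle.network, None, (0, 0), (45, 45))
        assert comp.truncated
        dist, report = solve_by_decomposition(bundle.network, None, comp)
        assert report["summability"] == "summable"
        truth = irreducible_component(bundle.network, None, (0, 0), (45, 45))
        from crndecomp import explicit_from_product

        closed_form = explicit_from_product(truth, bundle.truth["functions"])
        assert total_variation(dist, closed_form) < 1e-12


class TestRefusal:
    def _parts(self, network, context):
        p1 = solve_motif(network.subnetwork(range(4)), None, context)
        p2 = solve_motif(network.subnetwork(range(4, 8)), None, context)
        dec = Decomposition(
            network, (frozenset(range(4)), frozenset(range(4, 8)))
        )
        return dec, [p1, p2]

    def test_matched_double_motif_assembles(self):
        bundle = generate_fixture("double_motif_shared_slow", seed=6)
        g = bundle.network
        comp = irreducible_component(g, None, (2, 1, 1))
        context = SolveContext(g, None, comp, DEFAULT)
        dec, parts = self._parts(g, context)
        dist = assemble_stationary(g, None, comp, dec, parts)
        oracle = solve_master_direct(g, None, comp)
        assert total_variation(dist, oracle) < 1e-10

    def test_perturbed_rate_refuses_and_naive_product_is_wrong(self):
        bundle = generate_fixture("double_motif_shared_slow", seed=6)
        rates = list(bundle.truth["rates"])
        rates[7] *= 1.5  # breaks proportionality of the shared-species factors
        g = generate_fixture("double_motif_shared_slow", rates=tuple(rates)).network
        comp = irreducible_component(g, None, (2, 1, 1))
        context = SolveContext(g, None, comp, DEFAULT)
        dec, parts = self._parts(g, context)
        with pytest.raises(RefusalError):
            assemble_stationary(g, None, comp, dec, parts)
        naive = assemble_stationary(g, None, comp, dec, parts, force=True)
        assert master_equation_residual(g, None, naive) > 1e-3

    def test_open_motif_branches_parameter_mismatch_is_undecomposable(self):
        bundle = generate_fixture("open_motif_branches", seed=7)
        rates = list(bundle.truth["rates"])
        rates[9] *= 2.0
        g = generate_fixture("open_motif_branches", rates=tuple(rates)).network
        comp = irreducible_component(g, None, (0, 0, 0), (5, 25, 25))
        with pytest.raises(UndecomposableError):
            solve_by_decomposition(g, None, comp)

    def test_driver_falls_back_to_direct_on_finite_mismatch(self):
        bundle = generate_fixture("double_motif_shared_slow", seed=6)
        rates = list(bundle.truth["rates"])
        rates[7] *= 1.5
        g = generate_fixture("double_motif_shared_slow", rates=tuple(rates)).network
        comp = irreducible_component(g, None, (2, 1, 1))
        dist, report = solve_by_decomposition(g, None, comp)
        assert report["method"] == "direct_fallback"
        assert report["refusals"] > 0
        oracle = solve_master_direct(g, None, comp)
        assert total_variation(dist, oracle) < 1e-12


class TestRateIndependence:
    def test_star_unions_assemble_for_every_rate_draw(self):
        """Disjoint motifs glued on a hub species assemble for every rate
        draw and every partner kinetics (rate-independent product form)."""
        from crndecomp import KineticsSpec, hill_type_I

        for seed in range(8):
            bundle = generate_fixture("motif_chain", seed=seed, length=2)
            kin = (
                KineticsSpec({"A1": hill_type_I(1, 2.0)})
                if seed % 2
                else None
            )
            comp = irreducible_component(bundle.network, kin, (2, 1, 1))
            dist, report = solve_by_decomposition(bundle.network, kin, comp)
            assert report["method"] == "decomposition"
            oracle = solve_master_direct(bundle.network, kin, comp)
            assert total_variation(dist, oracle) < 1e-9
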