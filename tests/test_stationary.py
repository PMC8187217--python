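"""Stationary layer: direct solves, generalized balance, product-form
families, factorization, proportionality and summability."""
import math

import numpy as np
import pytest

from crndecomp import (
    BalancePartition,
    KineticsSpec,
    ProductFormFunction,
    check_generalized_balance,
    explicit_from_product,
    factorize_product_form,
    generate_fixture,
    hill_type_I,
    irreducible_component,
    master_equation_residual,
    motif_product_form,
    parse_network,
    poisson_product_form,
    proportionality_match,
    random_rates,
    ratio_test_summability,
    solve_master_direct,
    total_variation,
)
from crndecomp.errors import ClosureError
from crndecomp.fixtures import _motif_reactions
from crndecomp.network import ReactionNetwork
from crndecomp.stationary import StationaryDistribution

from conftest import binomial_probs


class TestDirectSolve:
    def test_symmetric_exchange_is_binomial(self, simple_exchange):
        """Detailed balance on the 1-D chain gives Binomial(N, 1/2)."""
        comp = irreducible_component(simple_exchange, None, (6, 0))
        dist = solve_master_direct(simple_exchange, None, comp)
        expected = binomial_probs(6, 0.5)
        assert np.allclose(dist.probs, expected, atol=1e-12)
        assert dist.residual < 1e-12
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_asymmetric_exchange_is_binomial_p(self):
        g = parse_network("S1 <-> S2 ; rates=3,1")
        comp = irreducible_component(g, None, (5, 0))
        dist = solve_master_direct(g, None, comp)
        # x1 counts survivors of the slow direction: p = k2/(k1+k2)
        assert np.allclose(dist.probs, binomial_probs(5, 0.25), atol=1e-12)

    def test_singleton_component_point_mass(self):
        g = parse_network("2 S1 -> S1 + S2 ; rate=1")
        comp = irreducible_component(g, None, (0, 3))
        dist = solve_master_direct(g, None, comp)
        assert dist.probs.tolist() == [1.0]

    def test_open_component_rejected(self):
        g = generate_fixture("source_chain").network
        comp = irreducible_component(g, None, (1, 0, 0, 0))
        with pytest.raises(ClosureError):
            solve_master_direct(g, None, comp)

    def test_residual_small_on_fixture_sweep(self):
        for seed in range(5):
            bundle = generate_fixture("motif_chain", seed=seed, length=2)
            comp = irreducible_component(bundle.network, None, (2, 1, 1))
            dist = solve_master_direct(bundle.network, None, comp)
            assert dist.residual < 1e-10
            assert abs(dist.probs.sum() - 1.0) < 1e-12


class TestGeneralizedBalance:
    def test_double_motif_hub_per_part_partition(self, double_motif_hub):
        g = double_motif_hub.network
        comp = irreducible_component(g, None, (1, 1, 1))
        dist = explicit_from_product(comp, double_motif_hub.truth["functions"])
        partition = BalancePartition.per_part(g, [range(4), range(4, 8)])
        ok, residual = check_generalized_balance(g, None, dist, partition)
        assert ok and residual < 1e-9

    def test_balance_implies_stationarity(self, double_motif_hub):
        """A generalized-balance pass certifies a master-equation pass."""
        g = double_motif_hub.network
        comp = irreducible_component(g, None, (2, 0, 0))
        dist = explicit_from_product(comp, double_motif_hub.truth["functions"])
        partition = BalancePartition.per_part(g, [range(4), range(4, 8)])
        ok, _ = check_generalized_balance(g, None, dist, partition)
        assert ok
        assert master_equation_residual(g, None, dist) < 1e-9

    def test_complex_indexed_partition_on_birth_death(self):
        g = generate_fixture("birth_death", rates=(2.0, 1.0)).network
        comp = irreducible_component(g, None, (0,), (40,))
        dist = poisson_product_form([2.0], comp)
        ok, residual = check_generalized_balance(
            g, None, dist, BalancePartition.complex_indexed(g)
        )
        assert ok, residual

    def test_complex_indexed_partition_on_cycle(self):
        """Complex-balanced (not detailed-balanced) 3-cycle: the Poisson form
        passes the per-complex balance equations."""
        g = parse_network("A -> B ; rate=1\nB -> C ; rate=1\nC -> A ; rate=1")
        comp = irreducible_component(g, None, (3, 0, 0))
        dist = poisson_product_form([1.0, 1.0, 1.0], comp)
        ok, residual = check_generalized_balance(
            g, None, dist, BalancePartition.complex_indexed(g)
        )
        assert ok, residual
        # but it is NOT reaction (detailed) balanced: the pairing cannot even
        # be formed for an irreversible cycle
        with pytest.raises(Exception):
            BalancePartition.reaction_balanced(g)

    def test_wrong_distribution_fails(self):
        g = parse_network("S1 <-> S2 ; rates=3,1")
        comp = irreducible_component(g, None, (4, 0))
        uniform = StationaryDistribution(
            component=comp, probs=np.full(len(comp), 1 / len(comp))
        )
        ok, residual = check_generalized_balance(
            g, None, uniform, BalancePartition.reaction_balanced(g)
        )
        assert not ok and residual > 1e-3

    def test_reaction_vector_partition_on_motif(self, double_motif_hub):
        g = double_motif_hub.network.subnetwork(range(4))
        comp = irreducible_component(g, None, (3, 1))
        dist = solve_master_direct(g, None, comp)
        ok, residual = check_generalized_balance(
            g, None, dist, BalancePartition.reaction_vector_balanced(g)
        )
        assert ok, residual


class TestPoissonForms:
    def test_unit_rates_give_binomial(self, simple_exchange):
        comp = irreducible_component(simple_exchange, None, (5, 0))
        dist = poisson_product_form([1.0, 1.0], comp)
        assert np.allclose(dist.probs, binomial_probs(5, 0.5), atol=1e-14)

    def test_singleton_point_mass(self):
        g = parse_network("2 S1 -> S1 + S2 ; rate=1")
        comp = irreducible_component(g, None, (0, 2))
        dist = poisson_product_form([0.7, 1.3], comp)
        assert dist.probs.tolist() == [1.0]

    def test_hill_factor_closed_form(self):
        """With θ = Hill-I(1, k): f(x) = c^x ∏_{l≤x} (k+l)/l."""
        c, k = 1.7, 2.5
        fn = ProductFormFunction.poisson(c, hill_type_I(1, k))
        for x in range(6):
            expected = c**x * math.prod((k + l) / l for l in range(1, x + 1))
            assert fn.f(x) == pytest.approx(expected)


class TestMotifForm:
    def test_equal_rates_reduce_to_factorials(self):
        f1, f2 = motif_product_form(2.0, 2.0, 2.0, 2.0)
        for x in range(6):
            assert f1.f(x) == pytest.approx(1 / math.factorial(x))
            assert f2.f(x) == pytest.approx(1 / math.factorial(x))

    def test_printed_value(self):
        f1, _ = motif_product_form(1.0, 2.0, 3.0, 4.0)
        assert f1.f(2) == pytest.approx(1.5)

    def test_matches_null_space_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            k = random_rates(rng, 4)
            g = ReactionNetwork.build(_motif_reactions("S1", "S2", k))
            comp = irreducible_component(g, None, (4, 2))
            oracle = solve_master_direct(g, None, comp)
            f1, f2 = motif_product_form(*k)
            assembled = explicit_from_product(comp, {"S1": f1, "S2": f2})
            assert total_variation(oracle, assembled) < 1e-10

    def test_general_kinetics_matches_oracle(self):
        rng = np.random.default_rng(12)
        kin = KineticsSpec({"S1": hill_type_I(2, 1.5), "S2": hill_type_I(1, 3.0)})
        for _ in range(5):
            k = random_rates(rng, 4)
            g = ReactionNetwork.build(_motif_reactions("S1", "S2", k))
            comp = irreducible_component(g, kin, (4, 2))
            oracle = solve_master_direct(g, kin, comp)
            f1, f2 = motif_product_form(
                *k, theta1=kin.theta("S1"), theta2=kin.theta("S2")
            )
            assembled = explicit_from_product(comp, {"S1": f1, "S2": f2})
            assert total_variation(oracle, assembled) < 1e-10

    def test_mass_action_theta_equals_default_path(self):
        from crndecomp import tabulated

        ident = tabulated(range(1, 30))
        k = (1.0, 2.0, 3.0, 4.0)
        f_default, _ = motif_product_form(*k)
        f_theta, _ = motif_product_form(*k, theta1=ident, theta2=ident)
        for x in range(10):
            assert f_default.f(x) == pytest.approx(f_theta.f(x))

    def test_d_degree_of_freedom(self):
        """Tilting by d is invisible on a conservative component."""
        k = (1.0, 2.0, 3.0, 4.0)
        g = ReactionNetwork.build(_motif_reactions("S1", "S2", k))
        comp = irreducible_component(g, None, (4, 1))
        dists = []
        for d in (0.5, 1.0, 3.0):
            f1, f2 = motif_product_form(*k, d=d)
            dists.append(explicit_from_product(comp, {"S1": f1, "S2": f2}))
        assert total_variation(dists[0], dists[1]) < 1e-12
        assert total_variation(dists[1], dists[2]) < 1e-12

    def test_detailed_balance_specialization(self):
        """κ3 = ακ1, κ4 = ακ2 collapses the motif factor to Poisson type
        (the (κ2/κ1)-rate form; the (κ1/κ2)-rate form is the same function
        up to a d-tilt)."""
        alpha, k1, k2 = 1.7, 2.0, 3.0
        f1, _ = motif_product_form(k1, k2, alpha * k1, alpha * k2)
        assert proportionality_match(
            ProductFormFunction.poisson(k2 / k1), f1, range(8)
        ) == pytest.approx(1.0)
        tilted = ProductFormFunction.poisson(k1 / k2).tilted((k2 / k1) ** 2)
        assert proportionality_match(tilted, f1, range(8)) == pytest.approx(1.0)


class TestFactorization:
    def test_binomial_factorizes_and_reconstructs(self, simple_exchange):
        """The binomial line factorizes exactly; on a conservation line the
        per-species functions are gauge-dependent, so the reconstruction —
        not the fitted tables — is the meaningful check."""
        comp = irreducible_component(simple_exchange, None, (5, 0))
        dist = solve_master_direct(simple_exchange, None, comp)
        result = factorize_product_form(dist)
        assert result is not None and result.ok
        for state, p in zip(comp.states, dist.probs):
            logp = (
                result.tables[0][(state[0],)]
                + result.tables[1][(state[1],)]
                + result.constants[0]
            )
            assert math.exp(logp) == pytest.approx(p, rel=1e-10)

    def test_identified_factor_on_full_grid(self):
        """Without a conservation law the fitted factors are identified up to
        f(0)=1 and recover the generating factors exactly."""
        from crndecomp import IrreducibleComponent

        states = [(a, b) for a in range(5) for b in range(5)]
        f_a = ProductFormFunction.poisson(1.0)
        f_b = ProductFormFunction.poisson(2.0)
        weights = np.array([f_a.f(a) * f_b.f(b) for a, b in states])
        weights /= weights.sum()
        comp = IrreducibleComponent(
            species=("A", "B"),
            states=tuple(states),
            closed=True,
            truncated=False,
            seed_state=(0, 0),
        )
        dist = StationaryDistribution(component=comp, probs=weights)
        result = factorize_product_form(dist)
        assert result is not None and result.ok
        assert proportionality_match(
            f_a, result.function_for("A"), range(5)
        ) == pytest.approx(1.0)
        assert proportionality_match(
            f_b, result.function_for("B"), range(5)
        ) == pytest.approx(1.0)

    def test_correlated_distribution_refused(self):
        """A deliberately non-product π has no factorization."""
        states = [(a, b) for a in range(4) for b in range(4)]
        weights = np.array([math.exp(-2.0 * (a - b) ** 2) for a, b in states])
        weights /= weights.sum()
        from crndecomp import IrreducibleComponent

        comp = IrreducibleComponent(
            species=("A", "B"),
            states=tuple(states),
            closed=True,
            truncated=False,
            seed_state=(0, 0),
        )
        dist = StationaryDistribution(component=comp, probs=weights)
        assert factorize_product_form(dist) is None

    def test_singleton_support_trivially_factorizes(self):
        from crndecomp import IrreducibleComponent

        comp = IrreducibleComponent(
            species=("A", "B"),
            states=((1, 2),),
            closed=True,
            truncated=False,
            seed_state=(1, 2),
        )
        dist = StationaryDistribution(component=comp, probs=np.array([1.0]))
        result = factorize_product_form(dist)
        assert result is not None and result.max_residual < 1e-14

    def test_block_grouping_on_double_motif_hub(self, double_motif_hub):
        """Coarser block factorization also holds when the full product does."""
        comp = irreducible_component(double_motif_hub.network, None, (1, 1, 0))
        dist = solve_master_direct(double_motif_hub.network, None, comp)
        result = factorize_product_form(dist, grouping=[("S1", "S2"), ("S3",)])
        assert result is not None and result.ok


class TestProportionality:
    def test_scalar_multiple(self):
        f = ProductFormFunction.poisson(1.3)
        h = f.tilted(1.0)  # same ratios
        assert proportionality_match(f, h, range(6)) == pytest.approx(1.0)

    def test_factorial_vs_poisson_one(self):
        f = ProductFormFunction(lambda x: 1.0 / x)
        assert proportionality_match(
            f, ProductFormFunction.poisson(1.0), range(6)
        ) == pytest.approx(1.0)

    def test_distinct_rates_refused(self):
        f = ProductFormFunction.poisson(1.0)
        h = ProductFormFunction.poisson(2.0)
        assert proportionality_match(f, h, range(6)) is None


class TestSummability:
    def test_finite_component_summable(self, simple_exchange):
        comp = irreducible_component(simple_exchange, None, (3, 0))
        fns = [ProductFormFunction.poisson(1.0)] * 2
        assert ratio_test_summability(fns, comp) == "summable"

    def test_poisson_summable(self):
        assert ratio_test_summability([ProductFormFunction.poisson(5.0)]) == "summable"

    def test_constant_ratio_two_divergent(self):
        fn = ProductFormFunction(lambda x: 2.0)
        assert ratio_test_summability([fn]) == "divergent"

    def test_ratio_tending_to_one_inconclusive(self):
        fn = ProductFormFunction(lambda x: 1.0 + 1.0 / x)
        assert ratio_test_summability([fn]) == "inconclusive"

    def test_table_function_inconclusive(self):
        fn = ProductFormFunction.from_log_table([0.0, -1.0, -2.5])
        assert ratio_test_summability([fn]) == "inconclusive"
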