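"""Cumomer enumeration, conversions, ODE assembly, and oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cumoflux import (
    FluxSet,
    IsotopomerDistribution,
    build_cumomer_system,
    enumerate_cumomers,
    isotopomers_to_cumomer,
    load_network,
)
from cumoflux.cumomer import cumomers_to_isotopomers

from conftest import integrate_oracle, toy_network


def chain_model(n_carbons: int, name="M"):
    text = f"""
pools:
  - {{name: {name}, compartment: cytosol, n_carbons: {n_carbons}, pool_size: 1.0}}
sources: [{{name: S, n_carbons: {n_carbons}}}]
sinks: [OUT]
reactions:
  - {{name: R_in, stoich: "S -> {name}", atoms: "{'abcdefg'[:n_carbons]} -> {'abcdefg'[:n_carbons]}", flux_role: free}}
  - {{name: R_out, stoich: "{name} -> OUT", atoms: "{'abcdefg'[:n_carbons]} -> {'abcdefg'[:n_carbons]}"}}
perfusion: {{feed_rate_ml_h: 0.0}}
"""
    return load_network(text)


class TestEnumerate:
    @pytest.mark.parametrize(
        "n,max_order,bonded,expected",
        [
            (5, 3, True, 12),  # 5 + 4 + 3 connected sets on a chain
            (5, 3, False, 25),  # 5 + 10 + 10 subsets
            (3, 3, True, 6),  # 3 + 2 + 1
            (3, 3, False, 7),  # all non-empty subsets
            (2, 5, True, 3),  # order capped at n_carbons
        ],
    )
    def test_chain_counts(self, n, max_order, bonded, expected):
        model = chain_model(n)
        idx = enumerate_cumomers(model, max_order, bonded=bonded)
        assert len(idx) == expected

    def test_branched_skeleton_counts_connected_sets(self, db1):
        model, _, _ = db1
        idx = enumerate_cumomers(model, 3, bonded=True)
        cit = [e for e in idx if e[0] == "CIT"]
        # citrate tree: 6 singletons, 5 edges, and sum-over-vertices
        # C(deg, 2) = 1 + 3 + 1 = 5 connected triples
        assert len(cit) == 16
        by_order = {}
        for _, pos in cit:
            by_order[len(pos)] = by_order.get(len(pos), 0) + 1
        assert by_order == {1: 6, 2: 5, 3: 5}

    def test_index_is_deterministic_and_sorted(self, db1):
        model, _, _ = db1
        a = enumerate_cumomers(model, 3, bonded=True)
        b = enumerate_cumomers(model, 3, bonded=True)
        assert a.entries == b.entries
        orders = {}
        for pool, pos in a.entries:
            orders.setdefault(pool, []).append(len(pos))
        for pool, seq in orders.items():
            assert seq == sorted(seq), f"{pool} orders not ascending"


class TestIsotopomerCumomer:
    def test_worked_second_order_example(self):
        # 4-carbon pool: p{1,3} sums the four isotopomers labeled at 1 and 3
        m = np.zeros(16)
        m[0b0101] = 0.1  # {1,3}
        m[0b0111] = 0.2  # {1,2,3}
        m[0b1101] = 0.05  # {1,3,4}
        m[0b1111] = 0.15  # {1,2,3,4}
        m[0] = 0.5
        dist = IsotopomerDistribution("M", 4, m)
        assert isotopomers_to_cumomer(dist, (1, 3)) == pytest.approx(0.50)

    def test_empty_set_is_one(self):
        dist = IsotopomerDistribution("M", 2, [0.25, 0.25, 0.25, 0.25])
        assert isotopomers_to_cumomer(dist, ()) == pytest.approx(1.0)

    def test_fully_labeled(self):
        m = np.zeros(8)
        m[7] = 1.0
        dist = IsotopomerDistribution("M", 3, m)
        for pos in [(1,), (2, 3), (1, 2, 3)]:
            assert isotopomers_to_cumomer(dist, pos) == pytest.approx(1.0)

    def test_invalid_position_raises(self):
        dist = IsotopomerDistribution("M", 2, [1, 0, 0, 0])
        with pytest.raises(IndexError):
            isotopomers_to_cumomer(dist, (3,))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_moebius_roundtrip_and_monotonicity(self, seed):
        """Cumomer <-> isotopomer conversion round-trips, and supersets
        never exceed subsets (p is an 'at least' probability)."""
        rng = np.random.default_rng(seed)
        m = rng.dirichlet(np.ones(8))
        dist = IsotopomerDistribution("M", 3, m)
        cum = {}
        import itertools

        for r in range(1, 4):
            for pos in itertools.combinations((1, 2, 3), r):
                cum[pos] = isotopomers_to_cumomer(dist, pos)
        back = cumomers_to_isotopomers("M", 3, cum)
        np.testing.assert_allclose(back.fractions, m, atol=1e-12)
        for s, ps in cum.items():
            for t, pt in cum.items():
                if set(s) <= set(t):
                    assert pt <= ps + 1e-12


class TestBuildSystem:
    def test_db1_system_size_regression(self, db1_system):
        # same order of magnitude as the published ~210-equation system;
        # exact count frozen as a regression constant for this preset
        assert db1_system.n_states == 223

    def test_single_pool_influx_rate(self):
        """One 1-carbon pool, [A]=2 mM, flux 4 from a fully labeled source:
        dp/dt at p=0 is (4*1 - 4*0)/2 = +2/h."""
        text = """
pools: [{name: A, compartment: cytosol, n_carbons: 1, pool_size: 2.0}]
sources: [{name: S, n_carbons: 1, label: [{fraction: 1.0, positions: [1]}]}]
sinks: [OUT]
reactions:
  - {name: R1, stoich: "S -> A", atoms: "a -> a", flux_role: free}
  - {name: R2, stoich: "A -> OUT", atoms: "a -> a"}
perfusion: {feed_rate_ml_h: 0.0}
"""
        model, fluxes = toy_network(text, {"R1": 4.0})
        system = build_cumomer_system(model, fluxes)
        dydt = system.rhs(np.zeros(system.n_states))
        j = system.index.index_of("A", (1,))
        assert dydt[j] == pytest.approx(2.0)

    def test_condensation_term_is_product_of_fragments(self):
        """C2 + C4 -> C6 with both substrate fragments at 0.5 gives an
        influx term of 0.25 on the spanning cumomer."""
        text = """
pools:
  - {name: A, compartment: cytosol, n_carbons: 2, pool_size: 1.0}
  - {name: B, compartment: cytosol, n_carbons: 4, pool_size: 1.0}
  - {name: C, compartment: cytosol, n_carbons: 6, pool_size: 1.0}
sources: [{name: SA, n_carbons: 2}, {name: SB, n_carbons: 4}]
sinks: [OUT]
reactions:
  - {name: RA, stoich: "SA -> A", atoms: "ab -> ab", flux_role: free}
  - {name: RB, stoich: "SB -> B", atoms: "abcd -> abcd", flux_role: free}
  - {name: RC, stoich: "A + B -> C", atoms: "ab + cdef -> abcdef"}
  - {name: RD, stoich: "C -> OUT", atoms: "abcdef -> abcdef"}
perfusion: {feed_rate_ml_h: 0.0}
"""
        model, fluxes = toy_network(text, {"RA": 1.0, "RB": 1.0})
        system = build_cumomer_system(model, fluxes, max_order=3)
        y = np.zeros(system.n_states)
        y[system.index.index_of("A", (2,))] = 0.5
        y[system.index.index_of("B", (1,))] = 0.5
        j = system.index.index_of("C", (2, 3))  # spans A{2} x B{1}
        dydt = system.rhs(y)
        assert dydt[j] == pytest.approx(1.0 * 0.5 * 0.5)  # F * product / [C]

    def test_unbalanced_fluxes_rejected(self, db1):
        model, _, _ = db1
        bad = FluxSet({name: 1.0 for name in model.reactions})
        for t in model.transports:
            bad[t] = 1.0
        with pytest.raises(Exception, match="balanc"):
            build_cumomer_system(model, bad)

    def test_cascade_jacobian_sparsity(self, db1_system):
        """Order-n states never depend on states of order > n."""
        S = db1_system.jac_sparsity().tocoo()
        orders = db1_system.order_of_state
        assert (orders[S.row] >= orders[S.col]).all()


class TestOracleEquivalence:
    def test_trajectories_match_full_isotopomer_oracle(self, toy):
        """Bonded-cumomer trajectories equal the projections of the
        brute-force isotopomer system within 1e-6 at 50 time points."""
        from cumoflux import simulate

        name, model, fluxes = toy
        t_grid = np.linspace(0.0, 8.0, 50)
        oracle, Y = integrate_oracle(model, fluxes, t_grid)
        system = build_cumomer_system(model, fluxes, max_order=3, bonded=True)
        traj = simulate(model, fluxes, t_grid, system=system, rtol=1e-10, atol=1e-12)
        for j, (pool, pos) in enumerate(system.index.entries):
            proj = np.array([oracle.cumomer(Y[k], pool, pos) for k in range(len(t_grid))])
            np.testing.assert_allclose(
                traj.cumomers[:, j], proj, atol=1e-6,
                err_msg=f"{name}: {pool}{pos}",
            )

    def test_fully_labeled_limit(self):
        """With fully labeled boundary input, every cumomer -> 1."""
        from cumoflux import simulate

        text = """
pools:
  - {name: A, compartment: cytosol, n_carbons: 2, pool_size: 0.5}
  - {name: B, compartment: cytosol, n_carbons: 2, pool_size: 0.5}
sources: [{name: S, n_carbons: 2, label: [{fraction: 1.0, positions: [1, 2]}]}]
sinks: [OUT]
reactions:
  - {name: R1, stoich: "S -> A", atoms: "ab -> ab", flux_role: free}
  - {name: R2, stoich: "A -> B", atoms: "ab -> ba"}
  - {name: R3, stoich: "B -> OUT", atoms: "ab -> ab"}
perfusion: {feed_rate_ml_h: 0.0}
"""
        model, fluxes = toy_network(text, {"R1": 2.0})
        traj = simulate(model, fluxes, np.linspace(0, 50, 6))
        assert np.allclose(traj.cumomers[-1], 1.0, atol=1e-6)

    def test_unlabeled_limit_and_range(self, toy):
        """Unlabeled sources keep every fraction at 0; all fractions stay
        in [0,1] along labeled trajectories."""
        from cumoflux import simulate

        name, model, fluxes = toy
        unlabeled = type(model)(
            pools=model.pools,
            sources=model.sources,
            sinks=model.sinks,
            reactions=model.reactions,
            transports=model.transports,
            protocol=model.protocol,
            source_labels={k: () for k in model.source_labels},
        )
        traj0 = simulate(unlabeled, fluxes, np.linspace(0, 5, 11))
        assert np.abs(traj0.cumomers).max() < 1e-10
        traj = simulate(model, fluxes, np.linspace(0, 5, 11))
        assert traj.cumomers.min() >= -1e-9 and traj.cumomers.max() <= 1 + 1e-9

    def test_monotonicity_supersets(self, toy):
        """p_{S u T} <= p_S at every output time point."""
        from cumoflux import simulate

        name, model, fluxes = toy
        system = build_cumomer_system(model, fluxes)
        traj = simulate(model, fluxes, np.linspace(0, 6, 13), system=system)
        lookup = system.index.lookup
        for (pool, pos), j in lookup.items():
            for (pool2, pos2), j2 in lookup.items():
                if pool2 == pool and set(pos) < set(pos2):
                    assert (
                        traj.cumomers[:, j2] <= traj.cumomers[:, j] + 1e-7
                    ).all()

    def test_zero_fluxes_keep_state_constant(self):
        text = """
pools: [{name: A, compartment: cytosol, n_carbons: 1, pool_size: 1.0}]
sources: [{name: S, n_carbons: 1, label: [{fraction: 1.0, positions: [1]}]}]
sinks: [OUT]
reactions:
  - {name: R1, stoich: "S -> A", atoms: "a -> a", flux_role: free}
  - {name: R2, stoich: "A -> OUT", atoms: "a -> a"}
perfusion: {feed_rate_ml_h: 0.0}
"""
        model, fluxes = toy_network(text, {"R1": 0.0})
        system = build_cumomer_system(model, fluxes)
        y0 = np.full(system.n_states, 0.3)
        assert np.abs(system.rhs(y0)).max() == 0.0
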