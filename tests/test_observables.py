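"""Multiplets, positional enrichments, MIDs and natural-abundance
corrections — including brute-force cross-checks over all isotopomers."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cumoflux import FluxSet, IsotopomerDistribution, build_cumomer_system, load_network
from cumoflux.cumomer import isotopomers_to_cumomer
from cumoflux.observables import (
    MIDVector,
    MultipletSpec,
    StateView,
    mass_isotopomer_distribution,
    multiplet_fractions,
    natural_abundance_adjust,
    positional_enrichment,
)

from conftest import toy_network


def three_carbon_view(dist: IsotopomerDistribution):
    """StateView over a 3-carbon pool populated from an isotopomer
    distribution (full-order system so every subset is present)."""
    text = """
pools: [{name: M, compartment: cytosol, n_carbons: 3, pool_size: 1.0}]
sources: [{name: S, n_carbons: 3}]
sinks: [OUT]
reactions:
  - {name: R1, stoich: "S -> M", atoms: "abc -> abc", flux_role: free}
  - {name: R2, stoich: "M -> OUT", atoms: "abc -> abc"}
perfusion: {feed_rate_ml_h: 0.0}
"""
    model, fluxes = toy_network(text, {"R1": 1.0})
    system = build_cumomer_system(model, fluxes, max_order=3, bonded=False)
    y = np.zeros(system.n_states)
    for pos, j in system.index.lookup.items():
        y[j] = isotopomers_to_cumomer(dist, pos[1])
    return system, y


class TestMultiplets:
    def test_uniform_full_labeling(self):
        m = np.zeros(8)
        m[7] = 1.0
        system, y = three_carbon_view(IsotopomerDistribution("M", 3, m))
        comp = multiplet_fractions(StateView(system, y), MultipletSpec("M", 2))
        assert comp["total"] == pytest.approx(1.0)
        assert comp["s"] == pytest.approx(0.0)
        assert comp["d21"] == pytest.approx(0.0)
        assert comp["d23"] == pytest.approx(0.0)
        assert comp["dd"] == pytest.approx(1.0)

    def test_pure_singlet(self):
        # only position 2 labeled: total = singlet
        m = np.zeros(8)
        m[0b010] = 0.3
        m[0] = 0.7
        system, y = three_carbon_view(IsotopomerDistribution("M", 3, m))
        comp = multiplet_fractions(StateView(system, y), MultipletSpec("M", 2))
        assert comp["total"] == pytest.approx(0.3)
        assert comp["s"] == pytest.approx(0.3)
        assert comp["dd"] == pytest.approx(0.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_isotopomer_enumeration(self, seed):
        """Multiplets from cumomers equal the brute-force sums over all 8
        isotopomers, and components sum to the positional enrichment."""
        rng = np.random.default_rng(seed)
        m = rng.dirichlet(np.ones(8))
        dist = IsotopomerDistribution("M", 3, m)
        system, y = three_carbon_view(dist)
        view = StateView(system, y)
        for k in (1, 2, 3):
            comp = multiplet_fractions(view, MultipletSpec("M", k))
            neighbors = {1: (2,), 2: (1, 3), 3: (2,)}[k]
            # brute force: group isotopomers labeled at k by neighbor labels
            brute = {}
            for v in range(8):
                if not v >> (k - 1) & 1:
                    continue
                labeled = tuple(sorted(j for j in neighbors if v >> (j - 1) & 1))
                brute[labeled] = brute.get(labeled, 0.0) + m[v]
            total = sum(brute.values())
            assert comp["total"] == pytest.approx(total, abs=1e-12)
            assert comp["s"] == pytest.approx(brute.get((), 0.0), abs=1e-12)
            # completeness: components sum to the positional enrichment
            parts = sum(v for kk, v in comp.items() if kk != "total")
            assert parts == pytest.approx(comp["total"], abs=1e-12)

    def test_positional_enrichment_identities(self):
        rng = np.random.default_rng(11)
        m = rng.dirichlet(np.ones(8))
        system, y = three_carbon_view(IsotopomerDistribution("M", 3, m))
        view = StateView(system, y)
        for k in (1, 2, 3):
            pe = positional_enrichment(view, "M", k)
            comp = multiplet_fractions(view, MultipletSpec("M", k))
            parts = sum(v for kk, v in comp.items() if kk != "total")
            assert pe == pytest.approx(parts, abs=1e-12)
        with pytest.raises(IndexError):
            positional_enrichment(view, "M", 4)

    def test_missing_order_is_informative(self, db1, db1_system):
        view = StateView(db1_system, np.zeros(db1_system.n_states))
        with pytest.raises(KeyError, match="order"):
            view.get("GLU", (1, 2, 3, 4))

    def test_linearity_superposition(self):
        """Cumomer -> multiplet maps are linear in the state."""
        rng = np.random.default_rng(5)
        m1 = rng.dirichlet(np.ones(8))
        m2 = rng.dirichlet(np.ones(8))
        s1, y1 = three_carbon_view(IsotopomerDistribution("M", 3, m1))
        _, y2 = three_carbon_view(IsotopomerDistribution("M", 3, m2))
        lam = 0.37
        mix = lam * y1 + (1 - lam) * y2
        spec = MultipletSpec("M", 2)
        c_mix = multiplet_fractions(StateView(s1, mix), spec)
        c1 = multiplet_fractions(StateView(s1, y1), spec)
        c2 = multiplet_fractions(StateView(s1, y2), spec)
        for key in c_mix:
            assert c_mix[key] == pytest.approx(
                lam * c1[key] + (1 - lam) * c2[key], abs=1e-12
            )


class TestMID:
    def test_independent_two_carbon_binomial(self):
        m = np.array([0.25, 0.25, 0.25, 0.25])  # p1=p2=0.5 independent
        dist = IsotopomerDistribution("M", 2, m)
        mid = mass_isotopomer_distribution(dist, "M")
        np.testing.assert_allclose(mid.fractions, [0.25, 0.5, 0.25], atol=1e-12)

    def test_fully_labeled(self):
        m = np.zeros(8)
        m[7] = 1.0
        mid = mass_isotopomer_distribution(IsotopomerDistribution("M", 3, m), "M")
        np.testing.assert_allclose(mid.fractions, [0, 0, 0, 1], atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_mean_mass_equals_sum_of_positional_enrichments(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.dirichlet(np.ones(32))
        dist = IsotopomerDistribution("M", 5, m)
        mid = mass_isotopomer_distribution(dist, "M")
        pe_sum = sum(isotopomers_to_cumomer(dist, (k,)) for k in range(1, 6))
        assert mid.mean_mass == pytest.approx(pe_sum, abs=1e-10)
        assert mid.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_from_full_order_cumomer_state(self):
        rng = np.random.default_rng(3)
        m = rng.dirichlet(np.ones(8))
        dist = IsotopomerDistribution("M", 3, m)
        system, y = three_carbon_view(dist)
        mid = mass_isotopomer_distribution(StateView(system, y), "M")
        ref = mass_isotopomer_distribution(dist, "M")
        np.testing.assert_allclose(mid.fractions, ref.fractions, atol=1e-10)

    def test_truncated_state_rejected(self, db1, db1_system):
        view = StateView(db1_system, np.zeros(db1_system.n_states))
        with pytest.raises(ValueError, match="full"):
            mass_isotopomer_distribution(view, "CIT")


class TestPPPLactateMultiplets:
    """Steady-state lactate multiplets under [1,2-13C2]glucose — the
    pentose-phosphate-pathway probe.  Intact C1-C2 transfer through
    glycolysis gives the dominant 2,3-doublets; the oxidative PPP strips
    C1 and produces the C3 singlet.  Values are regression-pinned from
    the full-order steady state and cross-checked against long-time
    integration of the bonded system."""

    def test_pinned_values_and_integration_crosscheck(self):
        from cumoflux.cumomer import build_cumomer_system, build_full_order_system
        from cumoflux.simulate import simulate, steady_state
        from cumoflux.synthetic import db1_preset

        model, fluxes, _ = db1_preset("glc_12")
        full = build_full_order_system(model, fluxes)
        y = steady_state(model, fluxes, system=full)
        view = StateView(full, y[: full.n_states])
        c2 = multiplet_fractions(view, MultipletSpec("LAC_c", 2))
        c3 = multiplet_fractions(view, MultipletSpec("LAC_c", 3))
        # regression constants (frozen from this model's steady state)
        assert c3["s"] == pytest.approx(0.0117, abs=2e-4)
        assert c3["d32"] == pytest.approx(0.4372, abs=2e-3)
        assert c2["s"] == pytest.approx(0.0087, abs=2e-4)
        assert c2["d23"] == pytest.approx(0.4183, abs=2e-3)
        assert c2["dd"] == pytest.approx(0.0189, abs=5e-4)
        # doublets dominate singlets: intact C2-C3 pairs from [1,2] glucose
        assert c3["d32"] > 20 * c3["s"]
        # cross-check: bonded-system long-time integration agrees
        bonded = build_cumomer_system(model, fluxes)
        traj = simulate(model, fluxes, np.linspace(0, 300, 4), system=bonded)
        j = bonded.index.index_of("LAC_c", (2, 3))
        p23_ss = view.get("LAC_c", (2, 3))
        assert traj.cumomers[-1, j] == pytest.approx(p23_ss, abs=1e-5)


class TestNaturalAbundance:
    def test_add_remove_roundtrip(self):
        mid = MIDVector("M", (1, 2, 3, 4), [0.5, 0.3, 0.15, 0.05, 0.0])
        added = natural_abundance_adjust(mid, 4, "add")
        back = natural_abundance_adjust(added, 4, "remove")
        np.testing.assert_allclose(back.fractions, mid.fractions, atol=1e-10)

    def test_unlabeled_two_carbon_m1(self):
        mid = MIDVector("M", (1, 2), [1.0, 0.0, 0.0])
        out = natural_abundance_adjust(mid, 2, "add")
        assert out.fractions[1] == pytest.approx(2 * 0.011 * 0.989, rel=1e-9)

    def test_remove_from_m0_only_is_stable(self):
        # unchanged up to renormalization (clipped negatives leave a
        # sub-0.1% remainder in M2); the >2% clipped M1 sets the flag
        mid = MIDVector("M", (1, 2, 3), [1.0, 0.0, 0.0, 0.0])
        out = natural_abundance_adjust(mid, 3, "remove")
        assert out.fractions[0] == pytest.approx(1.0, abs=1e-3)
        assert out.warning is not None

    def test_normalization_preserved(self):
        rng = np.random.default_rng(0)
        f = rng.dirichlet(np.ones(6))
        mid = MIDVector("M", tuple(range(1, 6)), f)
        for d in ("add", "remove"):
            out = natural_abundance_adjust(mid, 5, d)
            assert out.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_bad_direction(self):
        mid = MIDVector("M", (1,), [1.0, 0.0])
        with pytest.raises(ValueError):
            natural_abundance_adjust(mid, 1, "sideways")
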