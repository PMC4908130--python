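"""Shared fixtures: the DB-1 preset (session-scoped, it is expensive to
rebuild) and a family of small closed toy networks used to cross-check
the cumomer engine against the brute-force isotopomer oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cumoflux import FluxSet, complete_flux_set, load_network
from cumoflux.synthetic import db1_free_fluxes, db1_preset

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def db1():
    model, fluxes, protocol = db1_preset("glc_16")
    return model, fluxes, protocol


@pytest.fixture(scope="session")
def db1_system(db1):
    from cumoflux import build_cumomer_system

    model, fluxes, _ = db1
    return build_cumomer_system(model, fluxes, max_order=3, bonded=True)


@pytest.fixture(scope="session")
def db1_free():
    return db1_free_fluxes()


def toy_network(yaml_text: str, free: dict):
    """Load a toy config and complete its flux set."""
    model = load_network(yaml_text)
    fluxes = complete_flux_set(model, FluxSet(free))
    return model, fluxes


# -- toy zoo ---------------------------------------------------------------
# All are closed (no medium pools, no perfusion), <= 12 total carbons, and
# driven by labeled/unlabeled boundary sources.

TOY_CHAIN = """
pools:
  - {name: A, compartment: cytosol, n_carbons: 2, pool_size: 1.0}
  - {name: B, compartment: cytosol, n_carbons: 2, pool_size: 2.0}
  - {name: C, compartment: cytosol, n_carbons: 2, pool_size: 0.5}
sources:
  - {name: SRC, n_carbons: 2, label: [{fraction: 0.8, positions: [1]}]}
sinks: [OUT]
reactions:
  - {name: R1, stoich: "SRC -> A", atoms: "ab -> ab", flux_role: free}
  - {name: R2, stoich: "A -> B", atoms: "ab -> ba"}
  - {name: R3, stoich: "B -> C", atoms: "ab -> ab"}
  - {name: R4, stoich: "C -> OUT", atoms: "ab -> ab"}
perfusion: {feed_rate_ml_h: 0.0}
"""

TOY_CONDENSATION = """
pools:
  - {name: A, compartment: cytosol, n_carbons: 2, pool_size: 1.0}
  - {name: B, compartment: cytosol, n_carbons: 1, pool_size: 0.5}
  - {name: C, compartment: cytosol, n_carbons: 3, pool_size: 1.5}
sources:
  - {name: SA, n_carbons: 2, label: [{fraction: 0.6, positions: [1, 2]}]}
  - {name: SB, n_carbons: 1, label: [{fraction: 0.5, positions: [1]}]}
sinks: [OUT]
reactions:
  - {name: RA, stoich: "SA -> A", atoms: "ab -> ab", flux_role: free}
  - {name: RB, stoich: "SB -> B", atoms: "a -> a", flux_role: free}
  - {name: RC, stoich: "A + B -> C", atoms: "ab + c -> acb"}
  - {name: RD, stoich: "C -> OUT", atoms: "abc -> abc"}
perfusion: {feed_rate_ml_h: 0.0}
"""

TOY_SYMMETRIC = """
pools:
  - {name: S, compartment: cytosol, n_carbons: 2, pool_size: 1.0, symmetric: true}
  - {name: D, compartment: cytosol, n_carbons: 2, pool_size: 0.7}
sources:
  - {name: SRC, n_carbons: 2, label: [{fraction: 0.9, positions: [1]}]}
sinks: [OUT]
reactions:
  - {name: R1, stoich: "SRC -> S", atoms: "ab -> ab", flux_role: free}
  - {name: R2, stoich: "S -> D", atoms: "ab -> ab"}
  - {name: R3, stoich: "D -> OUT", atoms: "ab -> ab"}
perfusion: {feed_rate_ml_h: 0.0}
"""

TOY_CLEAVAGE = """
pools:
  - {name: H, compartment: cytosol, n_carbons: 4, pool_size: 1.0}
  - {name: P, compartment: cytosol, n_carbons: 2, pool_size: 0.4}
  - {name: Q, compartment: cytosol, n_carbons: 2, pool_size: 0.6}
sources:
  - {name: SRC, n_carbons: 4, label: [{fraction: 0.7, positions: [1, 4]},
                                      {fraction: 0.1, positions: [2]}]}
sinks: [OUT]
reactions:
  - {name: R1, stoich: "SRC -> H", atoms: "abcd -> abcd", flux_role: free}
  - {name: R2, stoich: "H -> P + Q", atoms: "abcd -> ba + cd"}
  - {name: R3, stoich: "P -> OUT", atoms: "ab -> ab"}
  - {name: R4, stoich: "Q -> OUT", atoms: "ab -> ab"}
perfusion: {feed_rate_ml_h: 0.0}
"""

TOY_EXCHANGE = """
pools:
  - {name: A, compartment: cytosol, n_carbons: 3, pool_size: 1.0}
  - {name: B, compartment: cytosol, n_carbons: 3, pool_size: 2.0}
sources:
  - {name: SRC, n_carbons: 3, label: [{fraction: 0.75, positions: [1, 3]}]}
  - {name: DIL, n_carbons: 3}
sinks: [OUT]
reactions:
  - {name: R1, stoich: "SRC -> A", atoms: "abc -> abc", flux_role: free}
  - {name: R2, stoich: "A -> B", atoms: "abc -> cab"}
  - {name: RX, stoich: "DIL -> B", atoms: "abc -> abc", reversible: true,
     flux_role: free}
  - {name: R3, stoich: "B -> OUT", atoms: "abc -> abc"}
perfusion: {feed_rate_ml_h: 0.0}
"""

TOY_LOOP = """
pools:
  - {name: A, compartment: cytosol, n_carbons: 2, pool_size: 0.8}
  - {name: B, compartment: cytosol, n_carbons: 2, pool_size: 1.2}
sources:
  - {name: SRC, n_carbons: 2, label: [{fraction: 1.0, positions: [2]}]}
sinks: [OUT]
reactions:
  - {name: R1, stoich: "SRC -> A", atoms: "ab -> ab", flux_role: free}
  - {name: R2, stoich: "A -> B", atoms: "ab -> ba", reversible: true,
     flux_role: free}
  - {name: R3, stoich: "B -> OUT", atoms: "ab -> ab"}
perfusion: {feed_rate_ml_h: 0.0}
"""

TOY_SPECS = {
    "chain": (TOY_CHAIN, {"R1": 3.0}),
    "condensation": (TOY_CONDENSATION, {"RA": 2.0, "RB": 2.0}),
    "symmetric": (TOY_SYMMETRIC, {"R1": 4.0}),
    "cleavage": (TOY_CLEAVAGE, {"R1": 2.5}),
    "exchange": (TOY_EXCHANGE, {"R1": 2.0, "RX": (1.0, 1.5)}),
    "loop": (TOY_LOOP, {"R1": 3.0, "R2": (3.0, 2.0)}),
}


@pytest.fixture(params=sorted(TOY_SPECS))
def toy(request):
    text, free = TOY_SPECS[request.param]
    model, fluxes = toy_network(text, free)
    return request.param, model, fluxes


def integrate_oracle(model, fluxes, t_grid):
    """Integrate the brute-force full-isotopomer system on a time grid."""
    from scipy.integrate import solve_ivp

    from cumoflux import build_full_isotopomer_system

    oracle = build_full_isotopomer_system(model, fluxes)
    sol = solve_ivp(
        oracle.rhs,
        (t_grid[0], t_grid[-1]),
        oracle.initial_state(),
        method="BDF",
        t_eval=t_grid,
        rtol=1e-10,
        atol=1e-12,
    )
    assert sol.success
    return oracle, sol.y.T
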