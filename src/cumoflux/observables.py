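"""Observable layer: positional enrichments, NMR fine-structure multiplets,
and mass-isotopomer distributions derived from cumomer states.

The 13C resonance of carbon k splits according to which *bonded* neighbors
also carry 13C.  With neighbor set B(k), the multiplet component for the
exact neighbor-labeling subset A <= B(k) follows by inclusion-exclusion
over bonded cumomers:

    comp(A) = sum_{C >= A, C <= B(k)} (-1)^{|C|-|A|} p_{ {k} u C }

so for B(k)={j,l}: singlet = p{k} - p{jk} - p{kl} + p{jkl},
doublet(k,j) = p{jk} - p{jkl}, and the doublet-of-doublets = p{jkl}.
Components always sum to the positional enrichment p{k}.

Mass-isotopomer distributions need the complete subset lattice of the
fragment (full-order / fragmented-cumomer information); a bonded order-3
state is rejected for larger fragments rather than silently truncated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .cumomer import (
    CumomerSystem,
    IsotopomerDistribution,
    boundary_cumomer,
    isotopomers_to_cumomer,
)

__all__ = [
    "StateView",
    "MultipletSpec",
    "MIDVector",
    "multiplet_fractions",
    "positional_enrichment",
    "mass_isotopomer_distribution",
    "natural_abundance_adjust",
]

NATURAL_ABUNDANCE_13C = 0.011


class StateView:
    """Read access to cumomer fractions of a system state (or trajectory).

    ``y`` may be a state vector or an (nt, n_states) trajectory matrix;
    lookups then return arrays.  Boundary species resolve to their
    prescribed label.
    """

    def __init__(self, system: CumomerSystem, y: np.ndarray):
        self.system = system
        self.y = np.asarray(y, dtype=float)

    def get(self, pool: str, positions):
        positions = tuple(sorted(positions))
        n = self.system.n_states
        if not positions:
            return (
                1.0 if self.y.ndim == 1 else np.ones(self.y.shape[0])
            )
        key = (pool, positions)
        if key in self.system.index.lookup:
            j = self.system.index.lookup[key]
            return self.y[..., j]
        model = self.system.model
        if model.is_boundary(pool):
            v = boundary_cumomer(model.boundary_label(pool), positions)
            return v if self.y.ndim == 1 else np.full(self.y.shape[0], v)
        raise KeyError(
            f"cumomer {pool}{positions} is not tracked by this system "
            f"(max order {self.system.max_order}, bonded={self.system.bonded}); "
            "rebuild with a higher order or bonded=False"
        )


@dataclass(frozen=True)
class MultipletSpec:
    """Observed carbon ``position`` of ``pool`` with its coupled neighbors.

    ``neighbors`` defaults to all bonded neighbors of the position.  The
    component naming convention follows NMR practice: 's' (singlet),
    'd<k><j>' (doublet from coupling to neighbor j), 'dd'/'t' (all
    neighbors labeled), and 'total' (= positional enrichment).
    """

    pool: str
    position: int
    neighbors: tuple[int, ...] = ()

    def resolved_neighbors(self, system_or_model) -> tuple[int, ...]:
        if self.neighbors:
            return self.neighbors
        model = getattr(system_or_model, "model", system_or_model)
        return model.pools[self.pool].neighbors[self.position]


@dataclass
class MIDVector:
    """Mass-isotopomer fractions M0..Mn of a pool or fragment."""

    pool: str
    fragment: tuple[int, ...]
    fractions: np.ndarray
    warning: str | None = None

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)

    @property
    def mean_mass(self) -> float:
        return float(np.dot(np.arange(len(self.fractions)), self.fractions))

    def normalized(self) -> "MIDVector":
        f = np.clip(self.fractions, 0.0, None)
        return MIDVector(self.pool, self.fragment, f / f.sum(), self.warning)


def _component_name(position: int, labeled: tuple[int, ...], n_neighbors: int) -> str:
    if not labeled:
        return "s"
    if len(labeled) == n_neighbors and n_neighbors > 1:
        return "dd" if n_neighbors == 2 else "t"
    return "d" + "".join(f"{position}{j}" for j in labeled)


def multiplet_fractions(state: StateView, spec: MultipletSpec) -> dict:
    """Fine-structure multiplet components of one carbon resonance.

    Returns a mapping with one entry per neighbor-labeling subset plus
    'total'; values are fractions of the pool (multiply by the pool
    concentration for mM).  Requires bonded cumomers up to order
    |neighbors|+1.
    """
    k = spec.position
    B = spec.resolved_neighbors(state.system)
    out = {}
    for r in range(len(B) + 1):
        for A in itertools.combinations(B, r):
            comp = 0.0
            for rr in range(len(B) + 1):
                for C in itertools.combinations(B, rr):
                    if set(A) <= set(C):
                        sgn = (-1) ** (len(C) - len(A))
                        comp = comp + sgn * state.get(spec.pool, (k, *C))
            out[_component_name(k, A, len(B))] = comp
    out["total"] = state.get(spec.pool, (k,))
    return out


def positional_enrichment(state: StateView, pool: str, position: int):
    """Order-1 cumomer fraction p{position} of the pool."""
    n = state.system.model.n_carbons(pool)
    if not (1 <= position <= n):
        raise IndexError(f"position {position} outside 1..{n} for {pool}")
    return state.get(pool, (position,))


def mass_isotopomer_distribution(state, pool: str, fragment=None) -> MIDVector:
    """MID of a pool (or contiguous fragment of it).

    ``state`` is a :class:`StateView` over a full-order system or an
    :class:`IsotopomerDistribution`.  M_k sums the isotopomers with
    exactly k labels inside the fragment; a truncated bonded state is
    rejected for fragments larger than its maximum order.
    """
    if isinstance(state, IsotopomerDistribution):
        n = state.n_carbons
        fragment = tuple(fragment) if fragment else tuple(range(1, n + 1))
        mid = np.zeros(len(fragment) + 1)
        for v in range(2**n):
            k = sum(1 for p in fragment if v >> (p - 1) & 1)
            mid[k] += state.fractions[v]
        return MIDVector(state.pool, fragment, mid).normalized()

    model = state.system.model
    n = model.n_carbons(pool)
    fragment = tuple(fragment) if fragment else tuple(range(1, n + 1))
    if len(fragment) > state.system.max_order or (
        state.system.bonded and len(fragment) > 1 and not model.is_boundary(pool)
    ):
        raise ValueError(
            f"MID of a {len(fragment)}-carbon fragment needs the complete "
            f"subset lattice up to order {len(fragment)}; this system is "
            f"bonded/truncated (order {state.system.max_order}) — build with "
            "build_full_order_system"
        )
    if np.asarray(state.y).ndim != 1:
        raise ValueError("MID extraction expects a single state vector")
    # Moebius inversion on the fragment's subset lattice:
    # m_exact(S) = sum_{T >= S} (-1)^{|T|-|S|} p_T  (within the fragment)
    nf = len(fragment)
    mid = [0.0] * (nf + 1)
    for v in range(2**nf):
        S = tuple(fragment[i] for i in range(nf) if v >> i & 1)
        m = 0.0
        for w in range(2**nf):
            if (w & v) == v:
                T = tuple(fragment[i] for i in range(nf) if w >> i & 1)
                m = m + (-1) ** (len(T) - len(S)) * state.get(pool, T)
        mid[len(S)] = mid[len(S)] + m
    return MIDVector(pool, fragment, np.clip(np.array(mid), 0.0, None)).normalized()


def _binomial_kernel(n: int, p: float) -> np.ndarray:
    from scipy.stats import binom

    return binom.pmf(np.arange(n + 1), n, p)


def natural_abundance_adjust(
    mid: MIDVector, n_carbons: int | None = None, direction: str = "add"
) -> MIDVector:
    """Apply or remove the 1.1%-per-carbon natural 13C background.

    'add' convolves with the binomial natural-abundance kernel of the
    fragment; 'remove' deconvolves (triangular solve), clipping small
    negatives and renormalizing.  A deconvolution residual below -0.02
    sets a warning flag on the result rather than raising.
    """
    if direction not in ("add", "remove"):
        raise ValueError("direction must be 'add' or 'remove'")
    n = n_carbons if n_carbons is not None else len(mid.fragment)
    kern = _binomial_kernel(n, NATURAL_ABUNDANCE_13C)
    m = np.asarray(mid.fractions, dtype=float)
    size = len(m)
    # lower-triangular convolution matrix C[i, j] = kern[i-j]
    C = np.zeros((size, size))
    for j in range(size):
        for i in range(j, size):
            if i - j <= n:
                C[i, j] = kern[i - j]
    if direction == "add":
        out = C @ m
        return MIDVector(mid.pool, mid.fragment, out / out.sum())
    sol = np.linalg.solve(C, m)
    warning = None
    if sol.min() < -0.02:
        warning = f"deconvolution produced negative fraction {sol.min():.3g}"
    sol = np.clip(sol, 0.0, None)
    return MIDVector(mid.pool, mid.fragment, sol / sol.sum(), warning)
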