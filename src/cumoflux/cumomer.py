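"""Cumomer enumeration and balance-ODE assembly.

A *cumomer* of a metabolite M at position set S is the set of isotopomers
labeled at least at S; its fraction p_S is the probability that all
positions in S carry 13C.  *Bonded* cumomers restrict S to sets connected
along the carbon bond graph — exactly the joint-labeling information that
13C NMR fine structure can resolve.  The balance of each cumomer is

    [M] dp_S/dt  =  sum_j F_j * prod_s p^(s)_{sigma_j^-1(S)}  -  (sum_j F_j) p_S,

where the sum runs over unidirectional influxes j into M, and the pullback
sigma_j^-1 distributes S over the substrate(s) of step j; condensation
steps contribute the product of the per-substrate fragment cumomer
fractions (labeling of distinct substrate molecules is independent).  The
form above uses the total *influx* in the decay term, which is exact for
both constant balanced pools and pools whose size changes in time.

The assembled :class:`CumomerSystem` is a flat term table suitable for
fast vectorised evaluation:

    dy[target] += sign * F[flux] * y_ext[f1] * y_ext[f2] * y_ext[f3] * const
    dy /= pool_size[target]

with y_ext = concat(y, [1.0]) so unused factor slots point at a constant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .network import FluxSet, NetworkModel, NetworkError

__all__ = [
    "CumomerIndex",
    "CumomerSystem",
    "IsotopomerDistribution",
    "enumerate_cumomers",
    "isotopomers_to_cumomer",
    "build_cumomer_system",
    "build_full_isotopomer_system",
    "boundary_cumomer",
]

MAX_FACTORS = 3  # enough for any bimolecular condensation + padding


# --------------------------------------------------------------------------
# enumeration
# --------------------------------------------------------------------------

def _connected_subsets(neighbors: dict[int, tuple[int, ...]], max_size: int):
    """All connected vertex subsets of size 1..max_size, as sorted tuples."""
    found: set[tuple[int, ...]] = set()
    for start in neighbors:
        frontier = [frozenset([start])]
        while frontier:
            s = frontier.pop()
            tup = tuple(sorted(s))
            if tup in found:
                continue
            found.add(tup)
            if len(s) < max_size:
                for v in s:
                    for w in neighbors[v]:
                        if w not in s:
                            frontier.append(s | {w})
    return sorted(found, key=lambda t: (len(t), t))


@dataclass
class CumomerIndex:
    """Deterministic, sorted index of cumomer states.

    Entries are (pool name, positions) with positions a sorted 1-based
    tuple, grouped by ascending order within each pool's declaration
    order.  ``bonded`` records whether the index was built restricted to
    backbone-connected sets.
    """

    entries: list[tuple[str, tuple[int, ...]]]
    bonded: bool
    lookup: dict[tuple[str, tuple[int, ...]], int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.lookup:
            self.lookup = {e: i for i, e in enumerate(self.entries)}

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def index_of(self, pool: str, positions) -> int:
        return self.lookup[(pool, tuple(sorted(positions)))]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(p, "{" + ",".join(map(str, s)) + "}", len(s)) for p, s in self.entries],
            columns=["pool", "positions", "order"],
        )


def _state_pools(model: NetworkModel) -> list[str]:
    """Pools whose labeling is a state variable (clamped pools are boundary)."""
    return [n for n in model.pools if n not in model.protocol.clamped]


def enumerate_cumomers(
    model: NetworkModel, max_order: int, bonded: bool = True
) -> CumomerIndex:
    """Enumerate cumomer states up to ``max_order`` for every state pool.

    With ``bonded=True`` only position sets connected along each pool's
    bond graph are kept (the NMR-visible set); otherwise all subsets.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    entries: list[tuple[str, tuple[int, ...]]] = []
    for name in _state_pools(model):
        pool = model.pools[name]
        k = min(max_order, pool.n_carbons)
        if bonded:
            subsets = [s for s in _connected_subsets(pool.neighbors, k)]
        else:
            subsets = [
                t
                for n in range(1, k + 1)
                for t in itertools.combinations(range(1, pool.n_carbons + 1), n)
            ]
            subsets.sort(key=lambda t: (len(t), t))
        entries.extend((name, s) for s in subsets)
    # canonical order: pool declaration order, then order, then lexicographic
    pool_rank = {n: i for i, n in enumerate(model.pools)}
    entries.sort(key=lambda e: (pool_rank[e[0]], len(e[1]), e[1]))
    return CumomerIndex(entries=entries, bonded=bonded)


# --------------------------------------------------------------------------
# isotopomer <-> cumomer conversions
# --------------------------------------------------------------------------

@dataclass
class IsotopomerDistribution:
    """Vector of 2^N isotopomer fractions; bit i-1 of the index set means
    position i is labeled."""

    pool: str
    n_carbons: int
    fractions: np.ndarray

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (2**self.n_carbons,):
            raise ValueError("fractions must have length 2^N")
        if (self.fractions < -1e-12).any():
            raise ValueError("isotopomer fractions must be >= 0")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("isotopomer fractions must sum to 1")


def _mask(positions) -> int:
    m = 0
    for p in positions:
        m |= 1 << (p - 1)
    return m


def isotopomers_to_cumomer(dist: IsotopomerDistribution, positions) -> float:
    """Cumomer fraction p_S = sum of isotopomers labeled at least at S."""
    positions = tuple(positions)
    for p in positions:
        if not (1 <= p <= dist.n_carbons):
            raise IndexError(f"position {p} outside 1..{dist.n_carbons}")
    m = _mask(positions)
    idx = np.arange(2**dist.n_carbons)
    return float(dist.fractions[(idx & m) == m].sum())


def cumomers_to_isotopomers(
    pool: str, n_carbons: int, cumomer_of: dict[tuple[int, ...], float]
) -> IsotopomerDistribution:
    """Moebius inversion: recover isotopomer fractions from the complete
    set of cumomer fractions (all 2^N subsets; the empty set is 1)."""
    n = n_carbons
    p = np.zeros(2**n)
    for subset_mask in range(2**n):
        positions = tuple(i + 1 for i in range(n) if subset_mask >> i & 1)
        p[subset_mask] = 1.0 if not positions else cumomer_of[positions]
    # m_S = sum_{T >= S} (-1)^{|T|-|S|} p_T  — do a fast superset Moebius
    m = p.copy()
    for bit in range(n):
        step = 1 << bit
        for v in range(2**n):
            if not v & step:
                m[v] -= m[v | step]
    m = np.clip(m, 0.0, None)
    s = m.sum()
    if s > 0:
        m /= s
    return IsotopomerDistribution(pool=pool, n_carbons=n, fractions=m)


def boundary_cumomer(label, positions) -> float:
    """Cumomer fraction of a boundary species from its isotopomer mixture.

    ``label`` is a tuple of (fraction, labeled positions); unlisted mass is
    unlabeled.  p_S is the total fraction of species labeled at least at S.
    """
    s = set(positions)
    if not s:
        return 1.0
    return float(sum(f for f, pos in label if s.issubset(pos)))


# --------------------------------------------------------------------------
# elementary unidirectional steps
# --------------------------------------------------------------------------

@dataclass
class Step:
    """One unidirectional atom-mapped flux-carrying transition."""

    name: str  # flux-vector entry name, e.g. "CS", "ANA__rev", "T_LAC__out"
    substrates: tuple[str, ...]
    products: tuple[str, ...]  # tracked product names ('' marks sink slots)
    # per product occurrence: tuple of (substrate occurrence, carbon) or None
    product_origin: tuple[tuple[tuple[int, int], ...] | None, ...]
    flux: float
    kind: str = "reaction"  # reaction | transport_in | transport_out | feed
    transport: str | None = None


def expand_steps(model: NetworkModel) -> list[Step]:
    """Expand reactions, transports and perfusion feed into the structural
    list of unidirectional steps.

    The step list depends only on the model (both directions are always
    emitted for reversible reactions and transports), so a system built
    from it can be re-valued for new flux sets without re-assembly; see
    :func:`step_values`.
    """
    steps: list[Step] = []
    for r in model.reactions.values():
        steps.append(
            Step(r.name, r.substrates, r.products, r.atom_map.product_origin, 0.0)
        )
        if r.reversible:
            inv = r.atom_map.inverse()
            steps.append(
                Step(
                    r.name + "__rev",
                    inv.substrates,
                    inv.products,
                    inv.product_origin,
                    0.0,
                )
            )
    for t in model.transports.values():
        nc = model.pools[t.species_out].n_carbons
        ident = (tuple((0, c) for c in range(nc)),)
        kind_in = "transport_in" if t.kinetics == "michaelis-menten" else "reaction"
        kind_out = "transport_out" if t.kinetics == "michaelis-menten" else "reaction"
        steps.append(
            Step(
                t.name + "__in",
                (t.species_out,),
                (t.species_in,),
                ident,
                0.0,
                kind=kind_in,
                transport=t.name,
            )
        )
        steps.append(
            Step(
                t.name + "__out",
                (t.species_in,),
                (t.species_out,),
                ident,
                0.0,
                kind=kind_out,
                transport=t.name,
            )
        )
    # perfusion feed into tracked (non-clamped) medium pools
    prot = model.protocol
    for sp, (conc, label) in prot.feed_composition.items():
        if sp in prot.clamped or sp not in model.pools:
            continue
        nc = model.pools[sp].n_carbons
        steps.append(
            Step(
                "feed_" + sp,
                ("__feed_" + sp,),
                (sp,),
                (tuple((0, c) for c in range(nc)),),
                0.0,
                kind="feed",
            )
        )
    return steps


def step_values(model: NetworkModel, steps: list[Step], fluxes: FluxSet) -> np.ndarray:
    """Flux value vector for a structural step list.

    Reversible pairs split as forward = exchange + max(net, 0) and
    backward = exchange + max(-net, 0).  Michaelis–Menten transport
    entries are zero here (the simulator fills them from concentrations);
    feed entries come from the perfusion protocol.
    """
    prot = model.protocol
    vals = np.zeros(len(steps))
    for i, st in enumerate(steps):
        if st.kind == "feed":
            sp = st.products[0]
            conc = prot.feed_composition[sp][0]
            vals[i] = prot.feed_rate_ml_h * conc / prot.cell_volume_ml
            continue
        if st.kind in ("transport_in", "transport_out"):
            continue  # dynamic, set at runtime
        rev = st.name.endswith("__rev")
        base = st.name[: -len("__rev")] if rev else st.name
        if st.transport is not None:
            base = st.transport
            rev = st.name.endswith("__out")
        if base not in fluxes:
            raise NetworkError(f"no flux value for {base!r}")
        net, exch = fluxes[base]
        fwd_val = exch + max(net, 0.0)
        bwd_val = exch + max(-net, 0.0)
        if (
            base in model.reactions
            and not model.reactions[base].reversible
            and bwd_val > 0
        ):
            raise NetworkError(
                f"reaction {base} carries reverse flux but is irreversible"
            )
        vals[i] = bwd_val if rev else fwd_val
    return vals


# --------------------------------------------------------------------------
# cumomer system assembly
# --------------------------------------------------------------------------

@dataclass
class CumomerSystem:
    """Assembled cumomer balance ODE system (term-table form)."""

    model: NetworkModel
    index: CumomerIndex
    max_order: int
    bonded: bool
    flux_names: list[str]
    flux_values: np.ndarray  # base values (dynamic entries overwritten at runtime)
    # term table
    t_target: np.ndarray
    t_flux: np.ndarray
    t_sign: np.ndarray
    t_fac: np.ndarray  # (n_terms, MAX_FACTORS) indices into extended state
    t_const: np.ndarray
    pool_of_state: list[str]
    pool_size: np.ndarray  # base sizes; dynamic pools overwritten at runtime
    order_of_state: np.ndarray
    dynamic_flux: dict[str, int] = field(default_factory=dict)  # flux name -> idx

    @property
    def n_states(self) -> int:
        return len(self.index)

    def rhs(self, y: np.ndarray, flux_values=None, pool_size=None) -> np.ndarray:
        """Evaluate dp/dt for cumomer fractions y."""
        f = self.flux_values if flux_values is None else flux_values
        m = self.pool_size if pool_size is None else pool_size
        y_ext = np.empty(len(y) + 1)
        y_ext[:-1] = y
        y_ext[-1] = 1.0
        contrib = (
            self.t_sign
            * f[self.t_flux]
            * self.t_const
            * y_ext[self.t_fac[:, 0]]
            * y_ext[self.t_fac[:, 1]]
            * y_ext[self.t_fac[:, 2]]
        )
        out = np.zeros(len(y))
        np.add.at(out, self.t_target, contrib)
        return out / m

    def jacobian(self, y: np.ndarray, flux_values=None, pool_size=None):
        """Sparse Jacobian of rhs with respect to the cumomer states."""
        from scipy import sparse

        f = self.flux_values if flux_values is None else flux_values
        m = self.pool_size if pool_size is None else pool_size
        y_ext = np.empty(len(y) + 1)
        y_ext[:-1] = y
        y_ext[-1] = 1.0
        rows, cols, vals = [], [], []
        coef = self.t_sign * f[self.t_flux] * self.t_const
        facs = self.t_fac
        n = len(y)
        for k in range(MAX_FACTORS):
            fk = facs[:, k]
            live = fk < n
            if not live.any():
                continue
            other = coef.copy()
            for j in range(MAX_FACTORS):
                if j != k:
                    other = other * y_ext[facs[:, j]]
            rows.append(self.t_target[live])
            cols.append(fk[live])
            vals.append(other[live])
        J = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
        return sparse.diags(1.0 / m) @ J

    def jac_sparsity(self):
        from scipy import sparse

        n = self.n_states
        rows, cols = [], []
        for k in range(MAX_FACTORS):
            fk = self.t_fac[:, k]
            live = fk < n
            rows.append(self.t_target[live])
            cols.append(fk[live])
        return sparse.coo_matrix(
            (
                np.ones(sum(len(r) for r in rows)),
                (np.concatenate(rows), np.concatenate(cols)),
            ),
            shape=(n, n),
        ).tocsr()

    def state_value(self, y: np.ndarray, pool: str, positions) -> float:
        """Cumomer fraction of (pool, positions) in state vector y; boundary
        species are evaluated from their prescribed label."""
        positions = tuple(sorted(positions))
        if not positions:
            return 1.0
        key = (pool, positions)
        if key in self.index.lookup:
            return float(y[self.index.lookup[key]])
        if self.model.is_boundary(pool):
            return boundary_cumomer(self.model.boundary_label(pool), positions)
        raise KeyError(f"cumomer {pool}{positions} not in system (order too low?)")


def _product_variants(model: NetworkModel, pool_name: str):
    """Position permutations over which to average for symmetric products.

    Returns a list of (weight, perm) with perm mapping product position ->
    equivalent position (1-based).
    """
    pool = model.pools.get(pool_name)
    if pool is not None and pool.symmetric:
        ident = tuple(range(1, pool.n_carbons + 1))
        return [(0.5, ident), (0.5, pool.symmetry_map)]
    n = model.n_carbons(pool_name) if pool_name in model.pools else 0
    return [(1.0, tuple(range(1, n + 1)))]


def build_cumomer_system(
    model: NetworkModel,
    fluxes: FluxSet,
    max_order: int = 3,
    bonded: bool = True,
    *,
    check_balance: bool = True,
) -> CumomerSystem:
    """Assemble the cumomer balance ODEs for a network and flux set.

    The state index starts from :func:`enumerate_cumomers` and is closed
    under atom-map pullback, so every referenced precursor cumomer is
    itself a state (pullbacks never increase the order, preserving the
    cascade structure).  Symmetric products average over the symmetry
    orbit; condensations multiply per-substrate fragment fractions.
    """
    if check_balance:
        from .network import flux_balance_residual

        resid = flux_balance_residual(model, fluxes)
        scale = max(1.0, max(abs(v[0]) + v[1] for v in fluxes.values()))
        if resid > 1e-6 * scale:
            raise NetworkError(
                f"flux set is not balanced (residual {resid:.3g}); "
                "run complete_flux_set first"
            )
    steps = expand_steps(model)
    values = step_values(model, steps, fluxes)
    base = enumerate_cumomers(model, max_order, bonded)
    entries = set(base.entries)

    # producing steps per pool: list of (step_idx, product_occurrence)
    producers: dict[str, list[tuple[int, int]]] = {}
    for si, st in enumerate(steps):
        for pi, prod in enumerate(st.products):
            if st.product_origin[pi] is None:
                continue
            if prod in model.pools and prod not in model.protocol.clamped:
                producers.setdefault(prod, []).append((si, pi))

    for name in _state_pools(model):
        if name not in producers and model.pools[name].compartment != "medium":
            raise NetworkError(
                f"pool {name} has no producing flux; its cumomer balance is undefined"
            )

    # closure: pull every needed state back through every producing step
    TermSpec = tuple  # (target_key, step_idx, [(species, positions)], weight)
    term_specs: list[tuple] = []
    worklist = list(base.entries)
    seen = set(worklist)
    while worklist:
        pool, positions = worklist.pop()
        for si, pi in producers.get(pool, ()):  # each producing occurrence
            st = steps[si]
            origin = st.product_origin[pi]
            for weight, perm in _product_variants(model, pool):
                by_sub: dict[int, list[int]] = {}
                for p in positions:
                    s, c = origin[perm[p - 1] - 1]
                    by_sub.setdefault(s, []).append(c + 1)
                factors: list[tuple[str, tuple[int, ...]]] = []
                for s, pos in sorted(by_sub.items()):
                    sub = st.substrates[s]
                    factors.append((sub, tuple(sorted(pos))))
                term_specs.append(((pool, positions), si, factors, weight))
                for sub, pos in factors:
                    if (
                        sub in model.pools
                        and sub not in model.protocol.clamped
                        and (sub, pos) not in seen
                    ):
                        seen.add((sub, pos))
                        worklist.append((sub, pos))
                        entries.add((sub, pos))

    pool_rank = {n: i for i, n in enumerate(model.pools)}
    ordered = sorted(entries, key=lambda e: (pool_rank[e[0]], len(e[1]), e[1]))
    index = CumomerIndex(entries=ordered, bonded=bonded)
    n = len(index)

    flux_names = [st.name for st in steps]
    flux_values = values
    dynamic = {
        st.name: i for i, st in enumerate(steps) if st.kind in ("transport_in", "transport_out")
    }

    tt, tf, ts, tc = [], [], [], []
    tfac = []

    def emit(target, flux_idx, sign, fac_idx, const):
        tt.append(target)
        tf.append(flux_idx)
        ts.append(sign)
        fac = list(fac_idx)[:MAX_FACTORS] + [n] * (MAX_FACTORS - len(fac_idx))
        tfac.append(fac)
        tc.append(const)

    for (pool, positions), si, factors, weight in term_specs:
        target = index.lookup[(pool, positions)]
        fac_idx: list[int] = []
        const = weight
        for sub, pos in factors:
            if sub.startswith("__feed_"):
                sp = sub[len("__feed_"):]
                const *= boundary_cumomer(
                    model.protocol.feed_composition[sp][1], pos
                )
            elif sub in model.pools and sub not in model.protocol.clamped:
                fac_idx.append(index.lookup[(sub, pos)])
            else:  # clamped medium pool or declared source: constant label
                const *= boundary_cumomer(model.boundary_label(sub), pos)
        if len(fac_idx) > MAX_FACTORS:
            raise NetworkError("condensation with more than 3 tracked substrates")
        emit(target, si, +1.0, fac_idx, const)
        emit(target, si, -1.0, [target], weight)

    pool_size = np.array([model.pools[p].pool_size for p, _ in index.entries])
    system = CumomerSystem(
        model=model,
        index=index,
        max_order=max_order,
        bonded=bonded,
        flux_names=flux_names,
        flux_values=flux_values,
        t_target=np.array(tt, dtype=np.intp),
        t_flux=np.array(tf, dtype=np.intp),
        t_sign=np.array(ts),
        t_fac=np.array(tfac, dtype=np.intp),
        t_const=np.array(tc),
        pool_of_state=[p for p, _ in index.entries],
        pool_size=pool_size,
        order_of_state=np.array([len(s) for _, s in index.entries]),
        dynamic_flux=dynamic,
    )
    system._steps = steps  # kept for the simulator (concentration balances)
    return system


def build_full_order_system(model: NetworkModel, fluxes: FluxSet, **kw) -> CumomerSystem:
    """Unrestricted cumomer system up to each pool's full carbon count —
    the 'fragmented cumomer' mode carrying complete MID information."""
    max_n = max(p.n_carbons for p in model.pools.values())
    return build_cumomer_system(model, fluxes, max_order=max_n, bonded=False, **kw)


# --------------------------------------------------------------------------
# full isotopomer oracle
# --------------------------------------------------------------------------

class FullIsotopomerSystem:
    """Brute-force ODE system over every 2^N isotopomer of every pool.

    Serves as the independent oracle for the cumomer engine: projections
    of its trajectories through :func:`isotopomers_to_cumomer` must agree
    with the cumomer system to integrator tolerance.  Guarded to small
    networks.
    """

    SIZE_GUARD = 100_000

    def __init__(self, model: NetworkModel, fluxes: FluxSet):
        total = sum(2 ** p.n_carbons for p in model.pools.values())
        if total > self.SIZE_GUARD:
            raise NetworkError(
                f"full isotopomer system would need {total} states "
                f"(guard {self.SIZE_GUARD}); use the cumomer engine instead"
            )
        self.model = model
        self.steps = expand_steps(model)
        self.values = step_values(model, self.steps, fluxes)
        self.pools = _state_pools(model)
        self.offset: dict[str, int] = {}
        off = 0
        for p in self.pools:
            self.offset[p] = off
            off += 2 ** model.pools[p].n_carbons
        self.n_states = off
        self.pool_size = np.concatenate(
            [
                np.full(2 ** model.pools[p].n_carbons, model.pools[p].pool_size)
                for p in self.pools
            ]
        )
        self._compile()

    def _boundary_dist(self, species: str) -> np.ndarray:
        if species.startswith("__feed_"):
            label = self.model.protocol.feed_composition[species[len("__feed_"):]][1]
            nc = self.model.pools[species[len("__feed_"):]].n_carbons
        else:
            label = self.model.boundary_label(species)
            nc = self.model.n_carbons(species)
        m = np.zeros(2**nc)
        rest = 1.0
        for frac, pos in label:
            m[_mask(pos)] += frac
            rest -= frac
        m[0] += rest
        return m

    def _compile(self):
        """Precompute, per producing occurrence, the gather indices mapping
        product patterns to per-substrate marginal patterns."""
        self.emitters = []  # (step_idx, product, weight, per-substrate info)
        for si, st in enumerate(self.steps):
            for pi, prod in enumerate(st.products):
                origin = st.product_origin[pi]
                if origin is None or prod not in self.offset:
                    continue
                npc = self.model.pools[prod].n_carbons
                for weight, perm in _product_variants(self.model, prod):
                    by_sub: dict[int, list[tuple[int, int]]] = {}
                    for ppos in range(1, npc + 1):
                        s, c = origin[perm[ppos - 1] - 1]
                        by_sub.setdefault(s, []).append((ppos, c))
                    subinfo = []
                    vidx = np.arange(2**npc)
                    for s, pairs in sorted(by_sub.items()):
                        sub = st.substrates[s]
                        sub_positions = [c for _, c in pairs]  # 0-based carbons
                        # gather index: bits of product pattern at mapped slots
                        gather = np.zeros(2**npc, dtype=np.intp)
                        for bit, (ppos, _c) in enumerate(pairs):
                            gather |= ((vidx >> (ppos - 1)) & 1) << bit
                        subinfo.append((sub, tuple(sub_positions), gather))
                    self.emitters.append((si, prod, weight, subinfo))

    def _marginal(self, dist: np.ndarray, nc: int, carbons: tuple[int, ...]):
        """Marginal distribution of ``dist`` over the given 0-based carbons."""
        out = np.zeros(2 ** len(carbons))
        idx = np.arange(len(dist))
        key = np.zeros(len(dist), dtype=np.intp)
        for bit, c in enumerate(carbons):
            key |= ((idx >> c) & 1) << bit
        np.add.at(out, key, dist)
        return out

    def initial_state(self) -> np.ndarray:
        y = np.zeros(self.n_states)
        for p in self.pools:
            y[self.offset[p]] = 1.0  # fully unlabeled
        return y

    def rhs(self, t: float, y: np.ndarray, flux_values=None) -> np.ndarray:
        f = flux_values if flux_values is not None else self.values
        dy = np.zeros_like(y)
        for si, prod, weight, subinfo in self.emitters:
            F = f[si] * weight
            if F == 0:
                continue
            npc = self.model.pools[prod].n_carbons
            term = np.ones(2**npc)
            for sub, carbons, gather in subinfo:
                if sub in self.offset:
                    nc = self.model.pools[sub].n_carbons
                    dist = y[self.offset[sub]: self.offset[sub] + 2**nc]
                else:
                    dist = self._boundary_dist(sub)
                    nc = int(np.log2(len(dist)))
                marg = self._marginal(dist, nc, carbons)
                term = term * marg[gather]
            sl = slice(self.offset[prod], self.offset[prod] + 2**npc)
            dy[sl] += F * term - F * y[sl]
        return dy / self.pool_size

    def distribution(self, y: np.ndarray, pool: str) -> IsotopomerDistribution:
        nc = self.model.pools[pool].n_carbons
        frac = y[self.offset[pool]: self.offset[pool] + 2**nc].copy()
        frac = np.clip(frac, 0.0, None)
        frac /= frac.sum()
        return IsotopomerDistribution(pool=pool, n_carbons=nc, fractions=frac)

    def cumomer(self, y: np.ndarray, pool: str, positions) -> float:
        nc = self.model.pools[pool].n_carbons
        m = _mask(positions)
        idx = np.arange(2**nc)
        frac = y[self.offset[pool]: self.offset[pool] + 2**nc]
        return float(frac[(idx & m) == m].sum())


def build_full_isotopomer_system(
    model: NetworkModel, fluxes: FluxSet
) -> FullIsotopomerSystem:
    """Construct the brute-force full-isotopomer oracle (size-guarded)."""
    return FullIsotopomerSystem(model, fluxes)
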