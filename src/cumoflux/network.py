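"""Compartmented metabolic networks with carbon atom-transition maps.

A :class:`NetworkModel` declares metabolite pools (carbon counts, pool
sizes, bond graphs), reactions with explicit carbon atom maps, transport
processes across the medium/cytosol and cytosol/mitochondrion boundaries,
and the perfusion protocol of a bioreactor experiment.  Reactions are
written in the field-standard letter notation, e.g.::

    stoich: "ACoA_m + OAA_m -> CIT"
    atoms:  "ab + cdef -> fedbac"

where each substrate carbon receives a letter (left to right, 1-based
within each molecule) and the product strings state which substrate carbon
lands on each product position.  Cleavage and condensation are expressed
naturally; every product carbon must come from exactly one substrate
carbon and carbon is conserved up to declared sink products (e.g. CO2).

Reversible reactions carry a non-negative *exchange* flux on top of the
net flux; a :class:`FluxSet` holds (net, exchange) pairs in mmol/L-cell/h.
`complete_flux_set` solves the stoichiometric steady-state balance for the
derived net fluxes given the free/fixed ones.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "MetabolitePool",
    "AtomMap",
    "ReactionSpec",
    "TransportSpec",
    "PerfusionProtocol",
    "FluxSet",
    "NetworkModel",
    "ValidationReport",
    "NetworkError",
    "load_network",
    "validate_network",
    "complete_flux_set",
]


class NetworkError(ValueError):
    """Raised for schema violations, broken references or atom-map errors."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

COMPARTMENTS = ("medium", "cytosol", "mitochondrion")


@dataclass(frozen=True)
class MetabolitePool:
    """A metabolite pool: total (labeled+unlabeled) concentration [M].

    ``bonds`` is the carbon skeleton as an edge list of 1-based position
    pairs; it defaults to the linear chain 1-2-...-n.  ``symmetric`` pools
    declare a 2-fold rotational symmetry via ``symmetry_map`` (position i
    of the molecule is chemically equivalent to ``symmetry_map[i-1]``), as
    for succinate and fumarate.
    """

    name: str
    compartment: str
    n_carbons: int
    pool_size: float
    symmetric: bool = False
    symmetry_map: tuple[int, ...] = ()
    bonds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.n_carbons < 1:
            raise NetworkError(f"pool {self.name}: n_carbons must be >= 1")
        if self.pool_size <= 0:
            raise NetworkError(f"pool {self.name}: pool_size must be > 0")
        if self.compartment not in COMPARTMENTS:
            raise NetworkError(
                f"pool {self.name}: unknown compartment {self.compartment!r}"
            )
        if not self.bonds:
            object.__setattr__(
                self,
                "bonds",
                tuple((i, i + 1) for i in range(1, self.n_carbons)),
            )
        for i, j in self.bonds:
            if not (1 <= i <= self.n_carbons and 1 <= j <= self.n_carbons):
                raise NetworkError(f"pool {self.name}: bond ({i},{j}) out of range")
        if self.symmetric:
            if not self.symmetry_map:
                # default: end-to-end flip of the chain
                object.__setattr__(
                    self,
                    "symmetry_map",
                    tuple(range(self.n_carbons, 0, -1)),
                )
            perm = self.symmetry_map
            if sorted(perm) != list(range(1, self.n_carbons + 1)):
                raise NetworkError(f"pool {self.name}: symmetry_map is not a permutation")
            edges = {frozenset(b) for b in self.bonds}
            mapped = {frozenset((perm[i - 1], perm[j - 1])) for i, j in self.bonds}
            if edges != mapped:
                raise NetworkError(
                    f"pool {self.name}: symmetric flag inconsistent with bond graph"
                )

    @property
    def neighbors(self) -> dict[int, tuple[int, ...]]:
        adj: dict[int, list[int]] = {i: [] for i in range(1, self.n_carbons + 1)}
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return {k: tuple(sorted(v)) for k, v in adj.items()}


@dataclass(frozen=True)
class AtomMap:
    """Carbon transitions of one reaction.

    ``product_origin[p][k]`` gives, for the k-th carbon (0-based) of the
    p-th product occurrence, the pair ``(s, c)``: substrate occurrence s,
    carbon c (0-based).  Sink products (untracked, e.g. CO2) appear with
    ``product_origin[p] is None``.
    """

    substrates: tuple[str, ...]
    products: tuple[str, ...]
    product_origin: tuple[tuple[tuple[int, int], ...] | None, ...]

    def inverse(self) -> "AtomMap":
        """Atom map of the reverse reaction (only if carbon-complete)."""
        if any(o is None for o in self.product_origin):
            raise NetworkError("cannot invert an atom map with sink products")
        n_sub_carbons: dict[int, int] = {}
        for orig in self.product_origin:
            for s, c in orig:  # type: ignore[union-attr]
                n_sub_carbons[s] = max(n_sub_carbons.get(s, -1), c)
        origin: list[list[tuple[int, int]]] = [
            [(-1, -1)] * (n + 1) for n in (n_sub_carbons[s] for s in sorted(n_sub_carbons))
        ]
        for p, orig in enumerate(self.product_origin):
            for k, (s, c) in enumerate(orig):  # type: ignore[union-attr]
                origin[s][c] = (p, k)
        return AtomMap(
            substrates=self.products,
            products=self.substrates,
            product_origin=tuple(tuple(o) for o in origin),
        )


@dataclass
class ReactionSpec:
    """A (possibly reversible) atom-mapped reaction.

    flux_role: 'free' (fitted), 'fixed' (held), or 'derived' (solved from
    the steady-state balance).  Reversible reactions are net + exchange
    pairs with exchange >= 0.
    """

    name: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    atom_map: AtomMap
    flux_role: str = "derived"
    reversible: bool = False

    def __post_init__(self):
        if self.flux_role not in ("free", "fixed", "derived"):
            raise NetworkError(f"reaction {self.name}: bad flux_role {self.flux_role!r}")


@dataclass
class TransportSpec:
    """Facilitative transport of one species across a boundary.

    kinetics 'michaelis-menten' uses the reversible saturable form
    J = Jmax (Me/Km - Mi/Km) / (1 + Me/Km + Mi/Km); 'balancing' means the
    transporter is non-limiting and the flux takes whatever value balances
    the intracellular pool (its net value is then a derived flux).
    """

    name: str
    species_out: str  # pool on the outer side (medium / cytosol)
    species_in: str  # pool on the inner side (cytosol / mitochondrion)
    jmax: float = 0.0
    km: float = 1.0
    kinetics: str = "balancing"

    def __post_init__(self):
        if self.kinetics not in ("michaelis-menten", "balancing"):
            raise NetworkError(f"transport {self.name}: bad kinetics {self.kinetics!r}")
        if self.kinetics == "michaelis-menten":
            if self.jmax <= 0 or self.km <= 0:
                raise NetworkError(f"transport {self.name}: Jmax and Km must be > 0")


@dataclass
class PerfusionProtocol:
    """Bioreactor perfusion: cell/medium volumes, feed, clamps, tracer.

    ``feed_composition`` maps medium species name to (concentration mM,
    label), where label is a list of (fraction, positions) isotopomer
    specs, e.g. [1,6-13C2]glucose at 99% enrichment is
    ``[(0.99, (1, 6))]`` with the remainder unlabeled.  Clamped species are
    held at their feed concentration (feed rate adjusted implicitly).
    """

    cell_volume_ml: float = 1.0
    medium_volume_ml: float = 120.0
    feed_rate_ml_h: float = 24.0
    feed_composition: dict[str, tuple[float, tuple[tuple[float, tuple[int, ...]], ...]]] = field(
        default_factory=dict
    )
    clamped: tuple[str, ...] = ()

    def __post_init__(self):
        if self.medium_volume_ml <= 0 or self.cell_volume_ml <= 0:
            raise NetworkError("volumes must be positive")
        if self.feed_rate_ml_h < 0:
            raise NetworkError("feed_rate must be >= 0")
        for sp in self.clamped:
            if sp not in self.feed_composition:
                raise NetworkError(f"clamped species {sp} missing from feed_composition")

    @property
    def r_ie(self) -> float:
        """Cell-to-media volume ratio (dimensionless)."""
        return self.cell_volume_ml / self.medium_volume_ml


class FluxSet(dict):
    """Mapping reaction/transport name -> (net, exchange) flux pair.

    Values may be set as a scalar (net only) or a (net, exchange) tuple;
    they are stored as tuples.  Units: mmol/L-cell/h.
    """

    def __init__(self, values: Mapping | Iterable | None = None, **kw):
        super().__init__()
        if values:
            for k, v in dict(values).items():
                self[k] = v
        for k, v in kw.items():
            self[k] = v

    def __setitem__(self, key, value):
        if np.isscalar(value):
            value = (float(value), 0.0)
        else:
            net, exch = value
            value = (float(net), float(exch))
        if value[1] < 0:
            raise NetworkError(f"flux {key}: exchange flux must be >= 0")
        super().__setitem__(key, value)

    def net(self, name: str) -> float:
        return self[name][0]

    def exchange(self, name: str) -> float:
        return self[name][1]

    def copy(self) -> "FluxSet":
        return FluxSet(self)

    def to_frame(self):
        import pandas as pd

        rows = [(k, v[0], v[1]) for k, v in self.items()]
        return pd.DataFrame(rows, columns=["name", "net", "exchange"])


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass
class NetworkModel:
    """A validated compartmented network ready for cumomer-system assembly."""

    pools: dict[str, MetabolitePool]
    sources: dict[str, int]  # boundary source name -> n_carbons (label via protocol or unlabeled)
    sinks: set[str]
    reactions: dict[str, ReactionSpec]
    transports: dict[str, TransportSpec]
    protocol: PerfusionProtocol
    source_labels: dict[str, tuple[tuple[float, tuple[int, ...]], ...]] = field(
        default_factory=dict
    )
    metadata: dict = field(default_factory=dict)

    # -- species categories ------------------------------------------------
    @property
    def medium_pools(self) -> list[str]:
        return [n for n, p in self.pools.items() if p.compartment == "medium"]

    @property
    def intracellular_pools(self) -> list[str]:
        return [n for n, p in self.pools.items() if p.compartment != "medium"]

    def is_boundary(self, name: str) -> bool:
        """Boundary species have externally prescribed labeling."""
        return name in self.sources or name in self.protocol.clamped

    def n_carbons(self, name: str) -> int:
        if name in self.pools:
            return self.pools[name].n_carbons
        if name in self.sources:
            return self.sources[name]
        raise NetworkError(f"unknown species {name!r}")

    def boundary_label(self, name: str) -> tuple[tuple[float, tuple[int, ...]], ...]:
        """Isotopomer mixture for a boundary species (default: unlabeled)."""
        if name in self.protocol.feed_composition:
            return tuple(self.protocol.feed_composition[name][1])
        return tuple(self.source_labels.get(name, ()))


# --------------------------------------------------------------------------
# parsing
# --------------------------------------------------------------------------

_ARROW = re.compile(r"\s*(?:->|=>|<->|<=>)\s*")


def _parse_side(side: str) -> list[str]:
    names = [t.strip() for t in side.split("+")]
    if any(not n for n in names):
        raise NetworkError(f"empty species name in {side!r}")
    return names


def _parse_reaction(name: str, stoich: str, atoms: str, n_carbons) -> AtomMap:
    """Parse letter-notation atom maps against the stoichiometry string."""
    try:
        lhs, rhs = _ARROW.split(stoich)
    except ValueError:
        raise NetworkError(f"reaction {name}: bad stoich {stoich!r}") from None
    subs, prods = _parse_side(lhs), _parse_side(rhs)
    try:
        alhs, arhs = _ARROW.split(atoms)
    except ValueError:
        raise NetworkError(f"reaction {name}: bad atoms {atoms!r}") from None
    sub_atoms = [a.strip() for a in alhs.split("+")]
    prod_atoms = [a.strip() for a in arhs.split("+")]
    if len(sub_atoms) != len(subs) or len(prod_atoms) != len(prods):
        raise NetworkError(f"reaction {name}: atoms do not match stoich")

    letter_src: dict[str, tuple[int, int]] = {}
    for s, (spname, letters) in enumerate(zip(subs, sub_atoms)):
        nc = n_carbons(spname)
        if nc is None:
            raise NetworkError(f"reaction {name}: unknown metabolite {spname!r}")
        if len(letters) != nc:
            raise NetworkError(
                f"reaction {name}: {spname} has {nc} carbons, atoms give {len(letters)}"
            )
        for c, ch in enumerate(letters):
            if ch in letter_src:
                raise NetworkError(
                    f"reaction {name}: substrate letter {ch!r} used twice"
                )
            letter_src[ch] = (s, c)

    origin: list[tuple[tuple[int, int], ...] | None] = []
    used: set[str] = set()
    for p, (prname, letters) in enumerate(zip(prods, prod_atoms)):
        nc = n_carbons(prname)
        if nc is None:
            raise NetworkError(f"reaction {name}: unknown metabolite {prname!r}")
        if nc == 0:  # sink product: letters recorded but not tracked
            for ch in letters:
                if ch not in letter_src:
                    raise NetworkError(f"reaction {name}: unmapped letter {ch!r}")
                used.add(ch)
            origin.append(None)
            continue
        if len(letters) != nc:
            raise NetworkError(
                f"reaction {name}: {prname} has {nc} carbons, atoms give {len(letters)}"
            )
        row = []
        for ch in letters:
            if ch not in letter_src:
                raise NetworkError(f"reaction {name}: unmapped product letter {ch!r}")
            if ch in used:
                raise NetworkError(
                    f"reaction {name}: substrate carbon {ch!r} mapped to two products"
                )
            used.add(ch)
            row.append(letter_src[ch])
        origin.append(tuple(row))
    if used != set(letter_src):
        missing = sorted(set(letter_src) - used)
        raise NetworkError(
            f"reaction {name}: substrate carbons {missing} not mapped to any product"
        )
    return AtomMap(tuple(subs), tuple(prods), tuple(origin))


def _parse_label(spec) -> tuple[tuple[float, tuple[int, ...]], ...]:
    """Parse a label mixture: list of {fraction, positions} or 'U' for uniform."""
    if not spec:
        return ()
    out = []
    for item in spec:
        frac = float(item["fraction"])
        pos = item["positions"]
        pos = tuple(int(p) for p in pos)
        out.append((frac, pos))
    total = sum(f for f, _ in out)
    if total > 1.0 + 1e-9:
        raise NetworkError("label fractions sum to more than 1")
    return tuple(out)


def load_network(config) -> NetworkModel:
    """Load a network from a YAML file path, a YAML string, or a dict."""
    if isinstance(config, (str, Path)) and "\n" not in str(config):
        path = Path(config)
        if not path.exists():
            raise NetworkError(f"config file not found: {path}")
        doc = yaml.safe_load(path.read_text())
    elif isinstance(config, str):
        doc = yaml.safe_load(config)
    else:
        doc = config
    if not isinstance(doc, dict):
        raise NetworkError("network config must be a mapping")

    for key in ("pools",):
        if key not in doc:
            raise NetworkError(f"missing required config key {key!r}")

    pools: dict[str, MetabolitePool] = {}
    for p in doc["pools"]:
        try:
            pool = MetabolitePool(
                name=p["name"],
                compartment=p.get("compartment", "cytosol"),
                n_carbons=int(p["n_carbons"]),
                pool_size=float(p["pool_size"]),
                symmetric=bool(p.get("symmetric", False)),
                symmetry_map=tuple(p.get("symmetry_map", ())),
                bonds=tuple(tuple(b) for b in p.get("bonds", ())),
            )
        except KeyError as e:
            raise NetworkError(f"pool entry missing key {e.args[0]!r}") from None
        if pool.name in pools:
            raise NetworkError(f"duplicate pool {pool.name}")
        pools[pool.name] = pool

    sources = {s["name"]: int(s["n_carbons"]) for s in doc.get("sources", [])}
    source_labels = {
        s["name"]: _parse_label(s.get("label")) for s in doc.get("sources", [])
    }
    sinks = set(doc.get("sinks", []))

    def n_carbons(name: str):
        if name in pools:
            return pools[name].n_carbons
        if name in sources:
            return sources[name]
        if name in sinks:
            return 0
        return None

    reactions: dict[str, ReactionSpec] = {}
    for r in doc.get("reactions", []):
        try:
            name, stoich, atoms = r["name"], r["stoich"], r["atoms"]
        except KeyError as e:
            raise NetworkError(f"reaction entry missing key {e.args[0]!r}") from None
        amap = _parse_reaction(name, stoich, atoms, n_carbons)
        # sources may only appear as substrates, sinks only as products
        for sp in amap.substrates:
            if sp in sinks:
                raise NetworkError(f"reaction {name}: sink {sp} used as substrate")
        for sp in amap.products:
            if sp in sources:
                raise NetworkError(f"reaction {name}: source {sp} used as product")
        if name in reactions:
            raise NetworkError(f"duplicate reaction {name}")
        reactions[name] = ReactionSpec(
            name=name,
            substrates=amap.substrates,
            products=amap.products,
            atom_map=amap,
            flux_role=r.get("flux_role", "derived"),
            reversible=bool(r.get("reversible", False)),
        )

    transports: dict[str, TransportSpec] = {}
    for t in doc.get("transports", []):
        tr = TransportSpec(
            name=t["name"],
            species_out=t["out"],
            species_in=t["in"],
            jmax=float(t.get("jmax", 0.0)),
            km=float(t.get("km", 1.0)),
            kinetics=t.get("kinetics", "balancing"),
        )
        for sp in (tr.species_out, tr.species_in):
            if sp not in pools:
                raise NetworkError(f"transport {tr.name}: unknown pool {sp!r}")
        if pools[tr.species_out].n_carbons != pools[tr.species_in].n_carbons:
            raise NetworkError(f"transport {tr.name}: carbon counts differ")
        transports[tr.name] = tr

    prot = doc.get("perfusion", {})
    feed = {}
    for sp, entry in (prot.get("feed_composition") or {}).items():
        if sp not in pools or pools[sp].compartment != "medium":
            raise NetworkError(f"feed species {sp!r} is not a medium pool")
        feed[sp] = (float(entry["concentration"]), _parse_label(entry.get("label")))
    protocol = PerfusionProtocol(
        cell_volume_ml=float(prot.get("cell_volume_ml", 1.0)),
        medium_volume_ml=float(prot.get("medium_volume_ml", 120.0)),
        feed_rate_ml_h=float(prot.get("feed_rate_ml_h", 24.0)),
        feed_composition=feed,
        clamped=tuple(prot.get("clamped", ())),
    )
    for sp in protocol.clamped:
        if sp not in pools:
            raise NetworkError(f"clamped species {sp!r} is not a declared pool")

    model = NetworkModel(
        pools=pools,
        sources=sources,
        sinks=sinks,
        reactions=reactions,
        transports=transports,
        protocol=protocol,
        source_labels=source_labels,
        metadata=doc.get("metadata", {}),
    )
    report = validate_network(model)
    if report.violations:
        raise NetworkError("invalid network:\n  " + "\n  ".join(report.violations))
    return model


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def validate_network(model: NetworkModel) -> ValidationReport:
    """Report atom-map conservation violations, dangling pools, missing
    transports for compartment-crossing reactions, and symmetry issues."""
    rep = ValidationReport()

    produced: set[str] = set()
    consumed: set[str] = set()
    for r in model.reactions.values():
        # carbon conservation: every substrate carbon mapped exactly once
        n_sub = sum(model.n_carbons(s) for s in r.substrates if s not in model.sinks)
        n_prod = 0
        for p, orig in zip(r.products, r.atom_map.product_origin):
            n_prod += model.n_carbons(p) if orig is not None else 0
        mapped = sum(
            len(o) for o in r.atom_map.product_origin if o is not None
        )
        dropped = n_sub - mapped
        if dropped < 0 or mapped != n_prod:
            rep.violations.append(
                f"reaction {r.name}: carbon not conserved "
                f"({n_sub} substrate vs {n_prod} tracked product carbons)"
            )
        consumed.update(s for s in r.substrates if s in model.pools)
        produced.update(p for p in r.products if p in model.pools)
        # compartment crossings must be explicit transports
        comps = {
            model.pools[s].compartment
            for s in (*r.substrates, *r.products)
            if s in model.pools
        }
        if "medium" in comps and len(comps) > 1:
            rep.violations.append(
                f"reaction {r.name}: crosses the medium boundary without a transport"
            )
        if r.reversible:
            try:
                r.atom_map.inverse()
            except NetworkError:
                rep.violations.append(
                    f"reaction {r.name}: reversible but atom map is not invertible "
                    "(has sink products)"
                )
    for t in model.transports.values():
        produced.add(t.species_in)
        produced.add(t.species_out)
        consumed.add(t.species_in)
        consumed.add(t.species_out)

    for name, pool in model.pools.items():
        if pool.compartment == "medium":
            continue
        if name not in produced and name not in consumed:
            rep.warnings.append(f"pool {name}: disconnected (no producer or consumer)")
        elif name not in produced:
            rep.violations.append(f"pool {name}: dangling (no producer)")
        elif name not in consumed:
            rep.violations.append(f"pool {name}: dangling (no consumer)")

    # symmetry consistency is enforced at construction; re-check here for
    # models built programmatically
    for pool in model.pools.values():
        if pool.symmetric:
            perm = pool.symmetry_map
            edges = {frozenset(b) for b in pool.bonds}
            mapped = {frozenset((perm[i - 1], perm[j - 1])) for i, j in pool.bonds}
            if edges != mapped:
                rep.violations.append(
                    f"pool {pool.name}: symmetry_map does not preserve the bond graph"
                )
    return rep


# --------------------------------------------------------------------------
# flux completion
# --------------------------------------------------------------------------

def _stoich_entries(model: NetworkModel):
    """Yield (flux_name, pool, coefficient) for net fluxes over balanced pools.

    Medium pools are boundary for the balance (their dynamics are governed
    by the perfusion equations, not the steady-state constraint).
    """
    balanced = set(model.intracellular_pools)
    for r in model.reactions.values():
        for s in r.substrates:
            if s in balanced:
                yield r.name, s, -1.0
        for p, orig in zip(r.products, r.atom_map.product_origin):
            if orig is not None and p in balanced:
                yield r.name, p, +1.0
    for t in model.transports.values():
        # transport net flux defined positive out -> in
        if t.species_out in balanced:
            yield t.name, t.species_out, -1.0
        if t.species_in in balanced:
            yield t.name, t.species_in, +1.0


def complete_flux_set(
    model: NetworkModel, free_fluxes: FluxSet, *, tol: float = 1e-9
) -> FluxSet:
    """Solve the steady-state carbon balance for all derived net fluxes.

    ``free_fluxes`` must give net values for every free/fixed reaction (and
    may give exchanges for reversible ones).  Returns a full FluxSet; the
    production/consumption balance of every intracellular pool holds to
    ``tol * max|flux|``.  Raises if the system is underdetermined or a
    derived unidirectional flux goes negative.
    """
    names_all = list(model.reactions) + list(model.transports)
    known: dict[str, float] = {}
    for name in names_all:
        role = (
            model.reactions[name].flux_role
            if name in model.reactions
            else ("free" if name in free_fluxes else "derived")
        )
        if name in free_fluxes and not np.isnan(free_fluxes.net(name)):
            known[name] = free_fluxes.net(name)
        elif role in ("free", "fixed") and name in model.reactions:
            raise NetworkError(f"missing value for {role} flux {name!r}")

    unknown = [n for n in names_all if n not in known]
    pools = model.intracellular_pools
    pool_idx = {p: i for i, p in enumerate(pools)}
    A = np.zeros((len(pools), len(unknown)))
    b = np.zeros(len(pools))
    uidx = {n: j for j, n in enumerate(unknown)}
    for fname, pool, coeff in _stoich_entries(model):
        i = pool_idx[pool]
        if fname in uidx:
            A[i, uidx[fname]] += coeff
        else:
            b[i] -= coeff * known[fname]

    if unknown:
        rank = np.linalg.matrix_rank(A)
        if rank < len(unknown):
            # identify which unknowns are unresolved
            _, _, vt = np.linalg.svd(A)
            null = vt[rank:]
            loose = [unknown[j] for j in range(len(unknown)) if np.abs(null[:, j]).max() > 1e-8]
            raise NetworkError(
                f"flux system underdetermined: {len(unknown) - rank} extra degree(s) "
                f"of freedom among {loose}"
            )
        x, res, _, _ = np.linalg.lstsq(A, b, rcond=None)
    else:
        x = np.zeros(0)

    out = FluxSet()
    for name in names_all:
        net = known.get(name, None)
        if net is None:
            net = float(x[uidx[name]])
        exch = free_fluxes.exchange(name) if name in free_fluxes else 0.0
        out[name] = (net, exch)

    # verify balance and feasibility
    scale = max(1.0, max(abs(v[0]) for v in out.values()))
    resid = np.zeros(len(pools))
    for fname, pool, coeff in _stoich_entries(model):
        resid[pool_idx[pool]] += coeff * out.net(fname)
    bad = np.abs(resid) > tol * scale
    if bad.any():
        names = [pools[i] for i in np.flatnonzero(bad)]
        raise NetworkError(
            f"no steady-state flux solution: pools {names} unbalanced "
            f"(residual {np.abs(resid).max():.3g}); check free flux values"
        )
    for name, (net, exch) in out.items():
        irreversible = name in model.reactions and not model.reactions[name].reversible
        if irreversible and net < -tol * scale and name not in known:
            raise NetworkError(
                f"derived flux {name} is negative ({net:.4g}) but the reaction "
                "is irreversible: flux set infeasible"
            )
    return out


def flux_balance_residual(model: NetworkModel, fluxes: FluxSet) -> float:
    """Max absolute net production-consumption imbalance over balanced pools."""
    pools = model.intracellular_pools
    pool_idx = {p: i for i, p in enumerate(pools)}
    resid = np.zeros(len(pools))
    for fname, pool, coeff in _stoich_entries(model):
        resid[pool_idx[pool]] += coeff * fluxes.net(fname)
    return float(np.abs(resid).max()) if len(resid) else 0.0
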