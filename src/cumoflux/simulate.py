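"""Integration of the coupled concentration and cumomer balance ODEs.

The chemical state comprises the *dynamic* pools — medium species that are
not clamped (they accumulate or wash out under perfusion) and any
intracellular pool attached to a Michaelis–Menten transporter (its
concentration adjusts to the transport gradient).  All other pools are at
metabolic steady state with constant size; their labeling still evolves.

Medium amounts are carried per liter-cell (amount = C_medium * V_m/V_c) so
that all balances share the mmol/L-cell/h flux unit; outputs convert back
to medium mM.  Clamped species are held at the feed concentration with the
feed label, tracking the implied feed adjustment rather than simulating
the feedback controller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .cumomer import CumomerSystem, build_cumomer_system
from .network import FluxSet, NetworkModel

__all__ = ["transport_flux", "simulate", "steady_state", "Trajectory", "SimulationError"]


class SimulationError(RuntimeError):
    pass


def transport_flux(me: float, mi: float, jmax: float, km: float) -> float:
    """Reversible saturable facilitative transport (net flux, out -> in).

    J = Jmax * (Me/Km - Mi/Km) / (1 + Me/Km + Mi/Km).  Antisymmetric in
    (Me, Mi), bounded by |J| < Jmax, and linear (Jmax/Km) at low
    concentrations.
    """
    if km <= 0:
        raise ValueError("Km must be positive")
    me = np.asarray(me, dtype=float)
    mi = np.asarray(mi, dtype=float)
    out = jmax * (me / km - mi / km) / (1.0 + me / km + mi / km)
    return out if out.ndim else float(out)


def _unidirectional(c: float, other: float, jmax: float, km: float) -> float:
    """One directional component Jmax*(C/Km)/D of the reversible carrier."""
    return jmax * (c / km) / (1.0 + c / km + other / km)


# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time courses of cumomer fractions and dynamic concentrations."""

    t: np.ndarray
    cumomers: np.ndarray  # (nt, n_states)
    concentrations: np.ndarray  # (nt, n_dynamic)
    system: CumomerSystem
    dynamic_pools: list[str]
    _medium_scale: dict[str, float]

    def cumomer(self, pool: str, positions) -> np.ndarray:
        positions = tuple(sorted(positions))
        if not positions:
            return np.ones_like(self.t)
        if (pool, positions) in self.system.index.lookup:
            return self.cumomers[:, self.system.index.lookup[(pool, positions)]]
        if self.system.model.is_boundary(pool):
            from .cumomer import boundary_cumomer

            v = boundary_cumomer(self.system.model.boundary_label(pool), positions)
            return np.full_like(self.t, v)
        raise KeyError(f"cumomer {pool}{positions} not tracked")

    def concentration(self, pool: str) -> np.ndarray:
        """Concentration in mM (medium pools in medium mM)."""
        model = self.system.model
        if pool in self.dynamic_pools:
            col = self.concentrations[:, self.dynamic_pools.index(pool)]
            return col * self._medium_scale.get(pool, 1.0)
        if pool in model.protocol.clamped:
            return np.full_like(self.t, model.protocol.feed_composition[pool][0])
        return np.full_like(self.t, model.pools[pool].pool_size)

    def final_state(self) -> np.ndarray:
        return np.concatenate([self.cumomers[-1], self.concentrations[-1]])

    def to_frame(self):
        import pandas as pd

        rows = []
        for j, (pool, pos) in enumerate(self.system.index.entries):
            name = f"{pool}[{','.join(map(str, pos))}]"
            for ti, tv in enumerate(self.t):
                rows.append((tv, name, self.cumomers[ti, j]))
        for pool in self.dynamic_pools:
            conc = self.concentration(pool)
            for ti, tv in enumerate(self.t):
                rows.append((tv, f"conc:{pool}", conc[ti]))
        return pd.DataFrame(rows, columns=["time_h", "variable", "value"])


class _Engine:
    """Bundles a CumomerSystem with the dynamic-concentration machinery."""

    def __init__(self, model: NetworkModel, system: CumomerSystem):
        self.model = model
        self.system = system
        self.steps = system._steps
        prot = model.protocol
        self.r_me = prot.cell_volume_ml / prot.medium_volume_ml  # medium mM per state unit

        # only medium species have dynamic concentrations; intracellular
        # pools are constant-size (the cumomer balance formalism), with
        # carrier kinetics evaluated at their declared concentration
        self.dynamic_pools = [
            n
            for n in model.pools
            if n not in prot.clamped and model.pools[n].compartment == "medium"
        ]
        self.dp_idx = {n: i for i, n in enumerate(self.dynamic_pools)}
        self.medium_scale = {
            n: self.r_me
            for n in self.dynamic_pools
            if model.pools[n].compartment == "medium"
        }

        # per-dynamic-pool (flux index, sign) for the chemical balance
        self.conc_terms: list[list[tuple[int, float]]] = [[] for _ in self.dynamic_pools]
        fidx = {name: i for i, name in enumerate(system.flux_names)}
        for st in self.steps:
            i = fidx[st.name]
            for s in st.substrates:
                if s in self.dp_idx:
                    self.conc_terms[self.dp_idx[s]].append((i, -1.0))
            for p, orig in zip(st.products, st.product_origin):
                if orig is not None and p in self.dp_idx:
                    self.conc_terms[self.dp_idx[p]].append((i, +1.0))
        # feed removal rate (1/h) for medium pools
        self.removal = prot.feed_rate_ml_h / prot.medium_volume_ml

        # Michaelis-Menten transports; jmax/km looked up per call so that
        # fitted transport parameters take effect without re-assembly
        self.mm = []
        for t in model.transports.values():
            if t.kinetics != "michaelis-menten":
                continue
            self.mm.append(
                (
                    fidx[t.name + "__in"],
                    fidx[t.name + "__out"],
                    t.species_out,
                    t.species_in,
                    t.name,
                )
            )

        # state -> dynamic pool column (or -1)
        self.state_dyn = np.array(
            [self.dp_idx.get(p, -1) for p in system.pool_of_state], dtype=np.intp
        )
        self.n = system.n_states
        self.d = len(self.dynamic_pools)

    def conc_mM(self, pool: str, conc: np.ndarray) -> float:
        if pool in self.dp_idx:
            return conc[self.dp_idx[pool]] * self.medium_scale.get(pool, 1.0)
        if pool in self.model.protocol.clamped:
            return self.model.protocol.feed_composition[pool][0]
        return self.model.pools[pool].pool_size

    def flux_and_sizes(self, conc: np.ndarray):
        f = self.system.flux_values.copy()
        for i_in, i_out, sp_out, sp_in, tname in self.mm:
            tr = self.model.transports[tname]
            c_out = self.conc_mM(sp_out, conc)
            c_in = self.conc_mM(sp_in, conc)
            f[i_in] = _unidirectional(c_out, c_in, tr.jmax, tr.km)
            f[i_out] = _unidirectional(c_in, c_out, tr.jmax, tr.km)
        sizes = self.system.pool_size.copy()
        live = self.state_dyn >= 0
        sizes[live] = np.maximum(conc[self.state_dyn[live]], 1e-9)
        return f, sizes

    def dconc(self, conc: np.ndarray, f: np.ndarray) -> np.ndarray:
        out = np.zeros(self.d)
        for j, terms in enumerate(self.conc_terms):
            for i, sign in terms:
                out[j] += sign * f[i]
            pool = self.dynamic_pools[j]
            if pool in self.medium_scale:  # perfusion removal
                out[j] -= self.removal * conc[j]
        return out

    def rhs(self, t, y):
        cum, conc = y[: self.n], y[self.n:]
        f, sizes = self.flux_and_sizes(conc)
        dcum = self.system.rhs(cum, f, sizes)
        return np.concatenate([dcum, self.dconc(conc, f)])

    def jac(self, t, y):
        from scipy import sparse

        cum, conc = y[: self.n], y[self.n:]
        f, sizes = self.flux_and_sizes(conc)
        Jcc = self.system.jacobian(cum, f, sizes).tolil()
        # concentration columns by finite differences (few columns)
        base = self.rhs(t, y)
        cols = np.zeros((self.n + self.d, self.d))
        for j in range(self.d):
            h = max(1e-6, 1e-6 * abs(conc[j]))
            yp = y.copy()
            yp[self.n + j] += h
            cols[:, j] = (self.rhs(t, yp) - base) / h
        J = sparse.lil_matrix((self.n + self.d, self.n + self.d))
        J[: self.n, : self.n] = Jcc
        J[:, self.n:] = cols
        return J.tocsr()

    def jac_sparsity(self):
        from scipy import sparse

        S = sparse.lil_matrix((self.n + self.d, self.n + self.d))
        S[: self.n, : self.n] = self.system.jac_sparsity()
        S[:, self.n:] = 1.0
        return S.tocsr()

    def initial_conc(self) -> np.ndarray:
        """Medium species start at their declared (pre-label) levels.

        The preset declares the bioreactor's operating state: the label
        switch happens on a running reactor, so medium lactate starts at
        its perfusion steady level (unlabeled), not at zero.
        """
        conc = np.zeros(self.d)
        for j, pool in enumerate(self.dynamic_pools):
            c0 = self.model.pools[pool].pool_size
            conc[j] = c0 / self.medium_scale.get(pool, 1.0)
        return conc


def _get_engine(model: NetworkModel, system: CumomerSystem) -> _Engine:
    eng = getattr(system, "_engine", None)
    if eng is None:
        eng = _Engine(model, system)
        system._engine = eng
    return eng


def simulate(
    model: NetworkModel,
    fluxes: FluxSet,
    t_grid,
    *,
    system: CumomerSystem | None = None,
    max_order: int = 3,
    bonded: bool = True,
    initial: np.ndarray | None = None,
    initial_conc: dict | None = None,
    method: str = "BDF",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_step: float = np.inf,
) -> Trajectory:
    """Integrate the labeling dynamics over ``t_grid`` (hours).

    ``method`` is any stiff scipy solver name (default BDF with an
    analytic Jacobian) or ``"rk4"`` for a fixed-step classical
    Runge–Kutta integration with step ``max_step``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("empty time grid")
    if system is None:
        system = build_cumomer_system(model, fluxes, max_order=max_order, bonded=bonded)
    eng = _get_engine(model, system)

    y0 = np.zeros(eng.n + eng.d)
    if initial is not None:
        y0[: len(initial)] = initial
    conc0 = eng.initial_conc()
    if initial_conc:
        for pool, c in initial_conc.items():
            conc0[eng.dp_idx[pool]] = c / eng.medium_scale.get(pool, 1.0)
    y0[eng.n:] = conc0

    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    if method.lower() == "rk4":
        step = max_step if np.isfinite(max_step) else (t1 - t0) / 2000.0
        ys = _rk4(eng.rhs, y0, t_grid, step)
    else:
        kw = {"jac": eng.jac} if method in ("BDF", "Radau", "LSODA") else {}
        sol = solve_ivp(
            eng.rhs,
            (t0, t1),
            y0,
            method=method,
            t_eval=t_grid,
            rtol=rtol,
            atol=atol,
            max_step=max_step,
            **kw,
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed at t={sol.t[-1] if len(sol.t) else t0:.3g} h: "
                f"{sol.message}"
            )
        ys = sol.y.T
    if (ys[:, : eng.n] < -1e-6).any() or (ys[:, : eng.n] > 1 + 1e-6).any():
        worst = ys[:, : eng.n].min(), ys[:, : eng.n].max()
        raise SimulationError(f"cumomer fractions left [0,1]: range {worst}")
    return Trajectory(
        t=t_grid,
        cumomers=np.clip(ys[:, : eng.n], 0.0, 1.0),
        concentrations=ys[:, eng.n:],
        system=system,
        dynamic_pools=eng.dynamic_pools,
        _medium_scale=eng.medium_scale,
    )


def _rk4(rhs, y0, t_grid, step):
    ys = [y0.copy()]
    y = y0.copy()
    t = t_grid[0]
    for t_next in t_grid[1:]:
        while t < t_next - 1e-12:
            h = min(step, t_next - t)
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h / 2 * k1)
            k3 = rhs(t + h / 2, y + h / 2 * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        ys.append(y.copy())
    return np.array(ys)


# --------------------------------------------------------------------------

def steady_state(
    model: NetworkModel,
    fluxes: FluxSet,
    *,
    system: CumomerSystem | None = None,
    max_order: int = 3,
    bonded: bool = True,
) -> np.ndarray:
    """Algebraic isotopic steady state, solved order by order.

    The chemical steady state of the dynamic pools is found first (feed
    removal balancing export for medium species); the cumomer cascade is
    then linear within each order and solved by sparse elimination.
    Returns the full state vector [cumomers, dynamic concentrations].
    """
    from scipy import sparse
    from scipy.sparse.linalg import spsolve

    if system is None:
        system = build_cumomer_system(model, fluxes, max_order=max_order, bonded=bonded)
    eng = _get_engine(model, system)

    conc = eng.initial_conc()
    if eng.d:
        # iterate medium pools to their perfusion steady state
        for _ in range(200):
            f, _ = eng.flux_and_sizes(conc)
            dc = eng.dconc(conc, f)
            if np.abs(dc).max() < 1e-10 * max(1.0, np.abs(conc).max()):
                break
            # damped fixed-point on the chemical balance
            conc = np.maximum(conc + 0.05 * dc, 0.0)
        else:
            # fall back to a root solve per pool via relaxation ODE
            from scipy.optimize import fsolve

            def res(c):
                f, _ = eng.flux_and_sizes(np.maximum(c, 0.0))
                return eng.dconc(np.maximum(c, 0.0), f)

            conc = np.maximum(fsolve(res, conc, full_output=False), 0.0)
            if np.abs(res(conc)).max() > 1e-8:
                raise SimulationError("no chemical steady state found")

    f, sizes = eng.flux_and_sizes(conc)
    n = system.n_states
    y = np.zeros(n)
    orders = system.order_of_state
    y_ext = np.empty(n + 1)
    y_ext[-1] = 1.0
    for order in range(1, int(orders.max()) + 1):
        sel = np.flatnonzero(orders == order)
        if not len(sel):
            continue
        pos = {int(s): i for i, s in enumerate(sel)}
        A = sparse.lil_matrix((len(sel), len(sel)))
        b = np.zeros(len(sel))
        y_ext[:-1] = y
        for ti in range(len(system.t_target)):
            tgt = int(system.t_target[ti])
            if orders[tgt] != order:
                continue
            coef = system.t_sign[ti] * f[system.t_flux[ti]] * system.t_const[ti]
            facs = [int(x) for x in system.t_fac[ti] if x < n]
            same = [x for x in facs if orders[x] == order]
            lower = [x for x in facs if orders[x] < order]
            val = coef * np.prod([y[x] for x in lower]) if lower else coef
            if same:
                A[pos[tgt], pos[same[0]]] += val
            else:
                b[pos[tgt]] -= val
        try:
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # singularity handled below
                sol = spsolve(A.tocsc(), b)
        except Exception as e:  # singular within-order system
            raise SimulationError(
                f"singular steady-state system at order {order}: {e}"
            ) from e
        if not np.all(np.isfinite(sol)):
            raise SimulationError(
                f"singular steady-state system at order {order} "
                "(zero-outflux pool?)"
            )
        y[sel] = sol
    return np.concatenate([np.clip(y, 0.0, 1.0), conc])
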