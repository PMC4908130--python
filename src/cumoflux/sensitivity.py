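"""Dynamic isotopomer control analysis and cost-function sensitivity.

The dynamic isotopomer control coefficient of state (or observable) pi
with respect to parameter F is the normalized sensitivity

    ICC_F(pi; t) = (d pi / pi) / (dF / F) = (d pi/dF) * F / pi(t),

computed either by central finite differences at +-1% parameter
perturbations (rebalancing the derived fluxes each time), or by forward
sensitivity equations: s = d z/dF obeys the linear time-varying system

    ds/dt = A(z(t)) s + df/dF|_z ,

solved along the baseline trajectory — one extra system of the same size
per parameter, doubling the number of differential equations.

The MSE sensitivity of a fitted parameter is the relative change of the
minimized weighted mean squared error E under a 5% one-at-a-time
perturbation:  S_i = max_{+-} [E(p_i ± 0.05 p_i) - E(p_i)] / (0.05 E).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .cumomer import step_values
from .estimation import Dataset, FitProblem, Parameter, objective
from .network import FluxSet, NetworkModel, complete_flux_set
from .simulate import simulate, steady_state, Trajectory

__all__ = [
    "SensitivityTrace",
    "dynamic_control_coefficients",
    "steady_state_control_coefficient",
    "mse_sensitivity",
]

PI_FLOOR = 1e-6  # below this, normalized coefficients are masked (NaN)


@dataclass
class SensitivityTrace:
    parameter: str
    observable: str
    t: np.ndarray
    values: np.ndarray  # NaN where the denominator is below the floor
    method: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": self.parameter,
                "observable": self.observable,
                "time_h": self.t,
                "value": self.values,
            }
        )


class _ParamApplier:
    """Applies one Parameter value onto a (model, base free fluxes) pair
    and refreshes a system's flux values, including flux rebalancing."""

    def __init__(self, model: NetworkModel, base_free: FluxSet, system):
        self.model = model
        self.base_free = base_free
        self.system = system

    def value_of(self, p: Parameter) -> float:
        if p.kind == "flux_net":
            return self.base_free.net(p.target)
        if p.kind == "flux_exchange":
            t = p.target[0] if isinstance(p.target, tuple) else p.target
            return self.base_free.exchange(t)
        if p.kind == "transport_jmax":
            return self.model.transports[p.target].jmax
        if p.kind == "transport_km":
            return self.model.transports[p.target].km
        if p.kind == "pool_size":
            return self.model.pools[p.target].pool_size
        raise ValueError(f"unsupported parameter kind {p.kind!r} for sensitivity")

    def set(self, p: Parameter, value: float):
        free = self.base_free.copy()
        if p.kind == "flux_net":
            free[p.target] = (value, free.exchange(p.target))
        elif p.kind == "flux_exchange":
            targets = p.target if isinstance(p.target, tuple) else (p.target,)
            for t in targets:
                free[t] = (free.net(t), value)
        elif p.kind == "transport_jmax":
            self.model.transports[p.target].jmax = value
        elif p.kind == "transport_km":
            self.model.transports[p.target].km = value
        elif p.kind == "pool_size":
            object.__setattr__(self.model.pools[p.target], "pool_size", value)
            idx = [
                i
                for i, pl in enumerate(self.system.pool_of_state)
                if pl == p.target
            ]
            self.system.pool_size[idx] = value
        full = complete_flux_set(self.model, free)
        self.system.flux_values = step_values(self.model, self.system._steps, full)
        return full


def _as_parameter(p) -> Parameter:
    if isinstance(p, Parameter):
        return p
    raise TypeError("parameters must be estimation.Parameter instances")


def dynamic_control_coefficients(
    model: NetworkModel,
    base_free: FluxSet,
    parameters,
    observables: dict,
    t_grid,
    *,
    method: str = "forward-ode",
    max_order: int = 3,
    bonded: bool = True,
    rel_step: float = 0.01,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    system=None,
) -> list[SensitivityTrace]:
    """Time courses of normalized control coefficients.

    ``observables`` maps name -> callable(Trajectory) -> array; the
    coefficients are d ln(observable) / d ln(parameter).  ``method`` is
    'forward-ode' (augmented sensitivity system) or 'finite-difference'
    (central differences at ±``rel_step``), the latter serving as the
    independent cross-check of the former.
    """
    from .cumomer import build_cumomer_system

    t_grid = np.asarray(t_grid, dtype=float)
    # labeling starts at t=0; anchor the integration there even when the
    # requested output grid does not include it
    prepend = t_grid[0] > 0
    sim_grid = np.concatenate([[0.0], t_grid]) if prepend else t_grid
    sl = slice(1, None) if prepend else slice(None)
    parameters = [_as_parameter(p) for p in parameters]
    if system is None:
        full = complete_flux_set(model, base_free)
        system = build_cumomer_system(model, full, max_order=max_order, bonded=bonded)
    app = _ParamApplier(model, base_free, system)

    traces: list[SensitivityTrace] = []
    if method == "finite-difference":
        for p in parameters:
            p0 = app.value_of(p)
            if p0 <= 0:
                raise ValueError(f"parameter {p.name} must be positive")
            curves = {}
            for fac in (1.0, 1.0 + rel_step, 1.0 - rel_step):
                app.set(p, p0 * fac)
                traj = simulate(
                    model, None, sim_grid, system=system, rtol=rtol, atol=atol
                )
                curves[fac] = {
                    k: np.asarray(f(traj))[sl] for k, f in observables.items()
                }
            app.set(p, p0)
            for name in observables:
                base = curves[1.0][name]
                dO = (curves[1.0 + rel_step][name] - curves[1.0 - rel_step][name]) / (
                    2 * rel_step
                )
                icc = np.where(np.abs(base) > PI_FLOOR, dO / np.where(
                    np.abs(base) > PI_FLOOR, base, 1.0), np.nan)
                traces.append(
                    SensitivityTrace(p.name, name, t_grid, icc, "finite-difference")
                )
        return traces
    if method != "forward-ode":
        raise ValueError("method must be 'forward-ode' or 'finite-difference'")

    # ---- forward sensitivity: baseline with dense output, then the
    # linear time-varying sensitivity system per parameter
    app.set(parameters[0], app.value_of(parameters[0]))  # ensure baseline values
    eng_traj = simulate(model, None, sim_grid, system=system, rtol=rtol, atol=atol)
    eng = system._engine
    nz = eng.n + eng.d

    sol = solve_ivp(
        eng.rhs,
        (sim_grid[0], sim_grid[-1]),
        np.concatenate([eng_traj.cumomers[0], eng_traj.concentrations[0]]),
        method="BDF",
        dense_output=True,
        rtol=rtol,
        atol=atol,
        jac=eng.jac,
    )
    if not sol.success:
        raise RuntimeError("baseline integration failed")
    zfun = sol.sol

    for p in parameters:
        p0 = app.value_of(p)
        h = rel_step * p0

        def dfdp(z):
            app.set(p, p0 + h)
            rp = eng.rhs(0.0, z)
            app.set(p, p0 - h)
            rm = eng.rhs(0.0, z)
            app.set(p, p0)
            return (rp - rm) / (2 * h)

        def srhs(t, s):
            z = zfun(t)
            return eng.jac(t, z) @ s + dfdp(z)

        def sjac(t, s):
            return eng.jac(t, zfun(t))

        ssol = solve_ivp(
            srhs,
            (sim_grid[0], sim_grid[-1]),
            np.zeros(nz),
            method="BDF",
            t_eval=sim_grid,
            rtol=max(rtol, 1e-8),
            atol=max(atol, 1e-10),
            jac=sjac,
        )
        if not ssol.success:
            raise RuntimeError(f"sensitivity integration failed for {p.name}")
        S = ssol.y.T  # (nt, nz) = dz/dp

        # observable sensitivities via a directional derivative along S
        base_curves = {k: np.asarray(f(eng_traj)) for k, f in observables.items()}
        scale = np.abs(S).max() or 1.0
        eps = 1e-4 / scale

        def shifted(sign):
            t2 = Trajectory(
                t=sim_grid,
                cumomers=eng_traj.cumomers + sign * eps * S[:, : eng.n],
                concentrations=eng_traj.concentrations + sign * eps * S[:, eng.n:],
                system=system,
                dynamic_pools=eng.dynamic_pools,
                _medium_scale=eng.medium_scale,
            )
            return {k: np.asarray(f(t2)) for k, f in observables.items()}

        plus, minus = shifted(+1), shifted(-1)
        for name in observables:
            dO = (plus[name] - minus[name]) / (2 * eps)  # dO/dp
            base = base_curves[name]
            icc = np.where(
                np.abs(base) > PI_FLOOR,
                dO * p0 / np.where(np.abs(base) > PI_FLOOR, base, 1.0),
                np.nan,
            )
            traces.append(
                SensitivityTrace(p.name, name, t_grid, icc[sl], "forward-ode")
            )
    return traces


def steady_state_control_coefficient(
    model: NetworkModel,
    base_free: FluxSet,
    parameter: Parameter,
    response,
    *,
    rel_step: float = 0.01,
    max_order: int = 3,
    bonded: bool = True,
    system=None,
) -> float:
    """Classical control coefficient C_p^R = (d ln R / d ln p) at steady
    state, by central log-differences.  ``response`` is a callable taking
    (system, steady-state vector) and returning a positive scalar;
    a zero/negative response is masked as NaN."""
    from .cumomer import build_cumomer_system

    if system is None:
        full = complete_flux_set(model, base_free)
        system = build_cumomer_system(model, full, max_order=max_order, bonded=bonded)
    app = _ParamApplier(model, base_free, system)
    p0 = app.value_of(parameter)

    def R(v):
        app.set(parameter, v)
        y = steady_state(model, None, system=system)
        return float(response(system, y))

    r_plus = R(p0 * (1 + rel_step))
    r_minus = R(p0 * (1 - rel_step))
    app.set(parameter, p0)
    if r_plus <= PI_FLOOR or r_minus <= PI_FLOOR:
        return float("nan")
    return float(
        (np.log(r_plus) - np.log(r_minus))
        / (np.log(1 + rel_step) - np.log(1 - rel_step))
    )


def mse_sensitivity(
    problem: FitProblem,
    dataset: Dataset,
    fitted_values,
    index: int,
    *,
    rel_step: float = 0.05,
) -> dict:
    """Relative MSE change per relative parameter change at the fit.

    S_i = max over ± of [E(p_i ± rel_step*p_i) - E(p_i)] / (rel_step * E);
    the raw |delta E| is reported alongside.  E = 0 (a perfect fit) is
    masked as NaN.
    """
    values = np.asarray(fitted_values, dtype=float)
    e0 = objective(problem, values, dataset)
    if e0 <= 0:
        return {"S": float("nan"), "delta_E": 0.0, "E0": e0}
    deltas = []
    for sign in (+1, -1):
        v = values.copy()
        v[index] = values[index] * (1 + sign * rel_step)
        deltas.append(objective(problem, v, dataset) - e0)
    d = max(deltas)
    return {"S": float(d / (rel_step * e0)), "delta_E": float(d), "E0": float(e0)}
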