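"""Flux and transport-parameter estimation from labeling data.

A :class:`FitProblem` binds a network model, the free parameters (net
fluxes, exchange fluxes, transport Jmax/Km, initial concentrations), the
observable definitions, and a :class:`Dataset` of measured curves.  The
cost is the weighted mean squared error

    E = (1/N) sum_i (sim_i - obs_i)^2 / sigma_i^2 ,

minimized with the simplex (Nelder-Mead) or quasi-Newton (L-BFGS-B)
algorithm over log-transformed parameters, with seeded log-uniform
multi-starts.  Parameter uncertainties come from Monte Carlo: synthetic
datasets are regenerated at the fitted parameters with the experimental
noise level and refit; the spread of the refitted parameters gives the
standard deviations and percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cumomer import build_cumomer_system, step_values
from .network import FluxSet, NetworkError, NetworkModel, complete_flux_set
from .simulate import SimulationError, Trajectory, simulate, steady_state

__all__ = [
    "Dataset",
    "Parameter",
    "FitProblem",
    "FitResult",
    "objective",
    "fit",
    "goodness_of_fit",
    "monte_carlo_errors",
]

PENALTY = 1e8


@dataclass
class Dataset:
    """Observations: one row per (observable, time) with value and sigma.

    ``frame`` columns: observable (str), time_h (float; NaN marks steady
    state), value (float), sigma (float > 0).  ``meta`` records tracer,
    clamp levels, seed, and anything else worth keeping with the data.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        need = {"observable", "time_h", "value", "sigma"}
        missing = need - set(self.frame.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        if (self.frame["sigma"] <= 0).any():
            raise ValueError("all sigmas must be > 0")

    def __len__(self):
        return len(self.frame)

    @property
    def structure_token(self) -> int:
        """Hash of the (observable, time) layout — predictions depend only
        on this, not on the measured values."""
        tok = getattr(self, "_structure_token", None)
        if tok is None:
            tok = hash(
                tuple(zip(self.frame["observable"], self.frame["time_h"].fillna(-1.0)))
            )
            self._structure_token = tok
        return tok

    @property
    def times(self) -> np.ndarray:
        t = self.frame["time_h"].dropna().unique()
        return np.sort(t)

    @property
    def is_steady(self) -> bool:
        return self.frame["time_h"].isna().all()

    def filter_endpoint(self, min_value: float = 0.5) -> "Dataset":
        """Drop observables whose end-point value is below ``min_value``
        (mM) — the low signal-to-noise curves excluded from fitting."""
        f = self.frame
        keep = []
        for name, g in f.groupby("observable"):
            g2 = g.dropna(subset=["time_h"])
            endpoint = (
                g2.sort_values("time_h")["value"].iloc[-1] if len(g2) else g["value"].max()
            )
            if endpoint >= min_value:
                keep.append(name)
        return Dataset(f[f["observable"].isin(keep)].reset_index(drop=True), dict(self.meta))


@dataclass
class Parameter:
    """One fitted parameter and how it maps onto the model.

    kind: 'flux_net' | 'flux_exchange' | 'transport_jmax' | 'transport_km'
    | 'pool_size' | 'initial_conc'.  ``target`` names the
    reaction/transport/pool; for 'flux_exchange' it may be a tuple (one
    parameter driving several exchanges, e.g. both legs of the
    malate-aspartate shuttle).  'pool_size' fits a constant pool
    concentration; 'initial_conc' the t=0 level of a dynamic species.
    """

    name: str
    kind: str
    target: str | tuple[str, ...]
    bounds: tuple[float, float]
    init: float

    def __post_init__(self):
        lo, hi = self.bounds
        if not (0 < lo < hi):
            raise ValueError(f"parameter {self.name}: bounds must be 0 < lo < hi")
        if not (lo <= self.init <= hi):
            raise ValueError(f"parameter {self.name}: init outside bounds")


@dataclass
class FitResult:
    params: dict[str, float]
    objective: float
    residuals: np.ndarray
    n_obs: int
    n_params: int
    converged: bool
    n_fev: int
    algorithm: str
    seed: int | None
    at_bounds: list[str] = field(default_factory=list)
    start_objectives: list[float] = field(default_factory=list)
    mc_sd: dict[str, float] | None = None
    mc_interval: dict[str, tuple[float, float]] | None = None
    mc_samples: pd.DataFrame | None = None
    message: str = ""

    @property
    def chi2(self) -> float:
        return float(np.sum(self.residuals**2))

    def to_dict(self) -> dict:
        out = {
            "params": self.params,
            "objective": self.objective,
            "chi2": self.chi2,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "n_fev": self.n_fev,
            "algorithm": self.algorithm,
            "seed": self.seed,
            "at_bounds": self.at_bounds,
        }
        if self.mc_sd is not None:
            out["mc_sd"] = self.mc_sd
            out["mc_interval"] = {k: list(v) for k, v in self.mc_interval.items()}
        return out


class FitProblem:
    """Simulation-backed least-squares problem over named parameters.

    ``observables`` maps observable name -> callable(Trajectory) -> array
    aligned with the trajectory time grid.  The cumomer system is
    assembled once; parameter updates only re-derive the flux values.
    """

    def __init__(
        self,
        model: NetworkModel,
        base_fluxes: FluxSet,
        parameters: list[Parameter],
        observables: dict,
        *,
        max_order: int = 3,
        bonded: bool = True,
        rtol: float = 1e-6,
        atol: float = 1e-9,
        method: str = "BDF",
    ):
        self.model = model
        self.base_fluxes = base_fluxes.copy()
        self.parameters = list(parameters)
        self.observables = observables
        self.rtol, self.atol = rtol, atol
        self.method = method
        full = complete_flux_set(model, base_fluxes)
        self.system = build_cumomer_system(model, full, max_order=max_order, bonded=bonded)
        self._cache: dict[tuple, np.ndarray] = {}

    # -- parameter mapping -------------------------------------------------
    def apply(self, values) -> dict:
        """Push parameter values into model/fluxes; returns simulate kwargs."""
        free = self.base_fluxes.copy()
        initial_conc: dict[str, float] = {}
        for p, v in zip(self.parameters, values):
            v = float(v)
            if p.kind == "flux_net":
                free[p.target] = (v, free.exchange(p.target) if p.target in free else 0.0)
            elif p.kind == "flux_exchange":
                targets = p.target if isinstance(p.target, tuple) else (p.target,)
                for t in targets:
                    net = free.net(t) if t in free else np.nan
                    free[t] = (net, v)
            elif p.kind == "transport_jmax":
                self.model.transports[p.target].jmax = v
            elif p.kind == "transport_km":
                self.model.transports[p.target].km = v
            elif p.kind == "pool_size":
                object.__setattr__(self.model.pools[p.target], "pool_size", v)
                self.system.pool_size[self._pool_states(p.target)] = v
            elif p.kind == "initial_conc":
                initial_conc[p.target] = v
            else:
                raise ValueError(f"unknown parameter kind {p.kind!r}")
        full = complete_flux_set(self.model, free)
        self.system.flux_values = step_values(self.model, self.system._steps, full)
        return {"initial_conc": initial_conc}

    def init_values(self) -> np.ndarray:
        return np.array([p.init for p in self.parameters])

    def _pool_states(self, pool: str) -> np.ndarray:
        cache = getattr(self, "_pool_state_cache", None)
        if cache is None:
            cache = self._pool_state_cache = {}
        if pool not in cache:
            cache[pool] = np.array(
                [i for i, p in enumerate(self.system.pool_of_state) if p == pool],
                dtype=np.intp,
            )
        return cache[pool]

    # -- prediction --------------------------------------------------------
    def predict(self, values, dataset: Dataset) -> np.ndarray:
        """Model values for every dataset row (order preserved)."""
        key = (tuple(np.asarray(values, dtype=float)), dataset.structure_token)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        kw = self.apply(values)
        frame = dataset.frame
        out = np.empty(len(frame))
        t_rows = frame["time_h"].notna()
        if t_rows.any():
            t_grid = np.unique(frame.loc[t_rows, "time_h"].to_numpy(dtype=float))
            if t_grid[0] > 0:
                t_grid = np.concatenate([[0.0], t_grid])
            traj = simulate(
                self.model,
                None,
                t_grid,
                system=self.system,
                rtol=self.rtol,
                atol=self.atol,
                method=self.method,
                **kw,
            )
            tpos = {t: i for i, t in enumerate(t_grid)}
            curves = {
                name: np.asarray(fn(traj)) for name, fn in self.observables.items()
            }
            for i, row in enumerate(frame.itertuples(index=False)):
                if not np.isnan(row.time_h):
                    out[i] = curves[row.observable][tpos[row.time_h]]
        if (~t_rows).any():
            y = steady_state(self.model, None, system=self.system)
            traj_ss = _single_point_trajectory(self.system, y)
            curves = {
                name: np.asarray(fn(traj_ss)) for name, fn in self.observables.items()
            }
            for i, row in enumerate(frame.itertuples(index=False)):
                if np.isnan(row.time_h):
                    out[i] = np.atleast_1d(curves[row.observable])[-1]
        if len(self._cache) > 256:
            self._cache.clear()
        self._cache[key] = out
        return out

    def residuals(self, values, dataset: Dataset) -> np.ndarray:
        sim = self.predict(values, dataset)
        f = dataset.frame
        return (sim - f["value"].to_numpy()) / f["sigma"].to_numpy()


def _single_point_trajectory(system, y) -> Trajectory:
    eng = system._engine
    return Trajectory(
        t=np.array([np.inf]),
        cumomers=y[None, : eng.n],
        concentrations=y[None, eng.n:],
        system=system,
        dynamic_pools=eng.dynamic_pools,
        _medium_scale=eng.medium_scale,
    )


# --------------------------------------------------------------------------

def objective(problem: FitProblem, values, dataset: Dataset) -> float:
    """Weighted mean squared error; simulation failures return a large
    penalty (flagged by magnitude) so optimizers can retreat."""
    if dataset is None or len(dataset) == 0:
        raise ValueError("dataset is empty")
    try:
        r = problem.residuals(values, dataset)
    except (NetworkError, SimulationError, FloatingPointError):
        return PENALTY
    if not np.all(np.isfinite(r)):
        return PENALTY
    return float(np.mean(r**2))


def _to_internal(values, parameters):
    return np.log(np.asarray(values, dtype=float))


def _from_internal(x, parameters):
    return np.exp(np.asarray(x, dtype=float))


def fit(
    problem: FitProblem,
    dataset: Dataset,
    *,
    algorithm: str = "simplex",
    n_starts: int = 8,
    seed: int | None = 0,
    maxfev: int = 400,
    polish_maxfev: int = 800,
    start_values: np.ndarray | None = None,
    fd_eps: float = 3e-4,
) -> FitResult:
    """Minimize the weighted MSE with seeded multi-starts.

    Starts are log-uniform within the parameter bounds; the best start is
    polished with a tighter tolerance.  ``algorithm``: 'simplex'
    (Nelder-Mead) or 'quasi-newton' (L-BFGS-B), both in log-parameter
    space.  Non-convergence flags the result instead of raising.
    """
    from scipy.optimize import minimize

    rng = np.random.default_rng(seed)
    lo = np.log([p.bounds[0] for p in problem.parameters])
    hi = np.log([p.bounds[1] for p in problem.parameters])
    bounds = list(zip(lo, hi))

    def f(x):
        return objective(problem, np.exp(x), dataset)

    method = {"simplex": "Nelder-Mead", "quasi-newton": "L-BFGS-B"}.get(algorithm)
    if method is None:
        raise ValueError(f"unknown algorithm {algorithm!r}")

    if start_values is not None:
        starts = [_to_internal(start_values, problem.parameters)]
    else:
        starts = [lo + rng.random(len(lo)) * (hi - lo) for _ in range(max(1, n_starts))]

    def options(budget, tight):
        if method == "Nelder-Mead":
            out = {"maxfev": budget}
            if tight:
                out.update(fatol=1e-12, xatol=1e-8)
            return out
        # finite-difference step sized above the integrator noise floor
        return {"maxfun": budget, "eps": fd_eps, "ftol": 1e-13, "gtol": 1e-10}

    best = None
    start_objs = []
    nfev = 0
    single = len(starts) == 1 and polish_maxfev <= 0
    for x0 in starts:
        res = minimize(
            f, x0, method=method, bounds=bounds, options=options(maxfev, single)
        )
        nfev += res.nfev
        start_objs.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    # polish the winner
    res = best
    if polish_maxfev > 0:
        res = minimize(
            f, best.x, method=method, bounds=bounds,
            options=options(polish_maxfev, True),
        )
        nfev += res.nfev
        if res.fun > best.fun:
            res = best

    values = np.exp(res.x)
    names = [p.name for p in problem.parameters]
    at_bounds = [
        p.name
        for p, v in zip(problem.parameters, values)
        if v <= p.bounds[0] * 1.001 or v >= p.bounds[1] * 0.999
    ]
    try:
        residuals = problem.residuals(values, dataset)
    except (NetworkError, SimulationError):
        residuals = np.full(len(dataset), np.nan)
    return FitResult(
        params=dict(zip(names, map(float, values))),
        objective=float(res.fun),
        residuals=residuals,
        n_obs=len(dataset),
        n_params=len(names),
        converged=bool(res.fun < PENALTY and np.all(np.isfinite(values))),
        n_fev=nfev,
        algorithm=algorithm,
        seed=seed,
        at_bounds=at_bounds,
        start_objectives=start_objs,
        message=str(getattr(res, "message", "")),
    )


def goodness_of_fit(result: FitResult, dataset: Dataset) -> dict:
    """Chi-square statistic against the per-observation sigmas.

    chi2 = sum(residual^2 / sigma^2) (residuals are already
    sigma-scaled), dof = N_obs - N_params.  Verdict 'consistent' when
    chi2/dof lies in [0.5, 1.5] — the documented convention for a
    correctly specified noise model.
    """
    if dataset.frame["sigma"].isna().any():
        raise ValueError("goodness of fit requires sigma for every observation")
    chi2 = result.chi2
    dof = result.n_obs - result.n_params
    red = chi2 / dof if dof > 0 else np.nan
    verdict = "consistent" if 0.5 <= red <= 1.5 else (
        "overdispersed" if red > 1.5 else "underdispersed"
    )
    return {"chi2": chi2, "dof": dof, "chi2_per_dof": red, "verdict": verdict}


def monte_carlo_errors(
    problem: FitProblem,
    dataset: Dataset,
    fit_result: FitResult,
    *,
    n_reps: int = 20,
    seed: int = 0,
    maxfev: int = 300,
    stages: list[tuple[str, int]] | None = None,
    refit_start: np.ndarray | None = None,
    max_failures: float = 0.2,
) -> FitResult:
    """Monte Carlo parameter errors at the experimental noise level.

    Synthetic replicates are generated from the model at the fitted
    parameters with Gaussian noise of the dataset's sigmas, then refit.
    ``stages`` optionally chains optimizers per refit, e.g.
    [("quasi-newton", 150), ("simplex", 300)].  ``refit_start`` sets the
    refit starting point (default: the fitted values); passing the same
    anchor that produced the original estimate makes every replicate run
    the *identical* estimator, so the spread is calibrated against the
    estimate's own noise sensitivity.  Returns a copy of the fit result
    with per-parameter SDs, 2.5-97.5 percentile intervals and the raw
    samples attached.  Aborts if more than ``max_failures`` of the refits
    fail.
    """
    rng = np.random.default_rng(seed)
    values0 = np.array([fit_result.params[p.name] for p in problem.parameters])
    clean = problem.predict(values0, dataset)
    sigma = dataset.frame["sigma"].to_numpy()
    if stages is None:
        stages = [(fit_result.algorithm, maxfev)]
    start0 = values0 if refit_start is None else np.asarray(refit_start, float)
    samples = []
    failures = 0
    for rep in range(n_reps):
        noisy = dataset.frame.copy()
        noisy["value"] = clean + rng.normal(0.0, sigma)
        ds = Dataset(noisy, dict(dataset.meta))
        start = start0
        r = None
        for algorithm, budget in stages:
            r = fit(
                problem,
                ds,
                algorithm=algorithm,
                start_values=start,
                maxfev=budget,
                polish_maxfev=0,
                seed=None,
            )
            start = np.array([r.params[p.name] for p in problem.parameters])
        if not r.converged or not np.isfinite(r.objective) or r.objective >= PENALTY:
            failures += 1
            continue
        samples.append([r.params[p.name] for p in problem.parameters])
    if failures > max_failures * n_reps:
        raise RuntimeError(
            f"{failures}/{n_reps} Monte Carlo refits failed; "
            "check identifiability or noise model"
        )
    names = [p.name for p in problem.parameters]
    df = pd.DataFrame(samples, columns=names)
    sd = {n: float(df[n].std(ddof=1)) for n in names}
    ivl = {
        n: (float(df[n].quantile(0.025)), float(df[n].quantile(0.975))) for n in names
    }
    out = replace(fit_result)
    out.mc_sd = sd
    out.mc_interval = ivl
    out.mc_samples = df
    return out
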