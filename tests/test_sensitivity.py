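"""Dynamic control coefficients, steady-state control coefficients, and
MSE sensitivity."""

import numpy as np
import pandas as pd
import pytest

from cumoflux import FluxSet, load_network
from cumoflux.estimation import Dataset, Parameter
from cumoflux.sensitivity import (
    dynamic_control_coefficients,
    mse_sensitivity,
    steady_state_control_coefficient,
)

WASHIN = """
pools: [{name: A, compartment: cytosol, n_carbons: 1, pool_size: 2.0}]
sources: [{name: S, n_carbons: 1, label: [{fraction: 1.0, positions: [1]}]}]
sinks: [OUT]
reactions:
  - {name: R1, stoich: "S -> A", atoms: "a -> a", flux_role: free}
  - {name: R2, stoich: "A -> OUT", atoms: "a -> a"}
perfusion: {feed_rate_ml_h: 0.0}
"""

MIXING = """
pools: [{name: A, compartment: cytosol, n_carbons: 1, pool_size: 1.0}]
sources:
  - {name: HOT, n_carbons: 1, label: [{fraction: 1.0, positions: [1]}]}
  - {name: COLD, n_carbons: 1}
sinks: [OUT]
reactions:
  - {name: R_hot, stoich: "HOT -> A", atoms: "a -> a", flux_role: free}
  - {name: R_cold, stoich: "COLD -> A", atoms: "a -> a", flux_role: free}
  - {name: R_out, stoich: "A -> OUT", atoms: "a -> a"}
perfusion: {feed_rate_ml_h: 0.0}
"""


def washin_setup():
    model = load_network(WASHIN)
    base = FluxSet({"R1": 3.0})
    p = Parameter("F", "flux_net", "R1", (0.1, 50.0), 3.0)
    obs = {"A1": lambda tr: tr.cumomer("A", (1,))}
    return model, base, p, obs


class TestDynamicICC:
    def test_washin_limits(self):
        """pi = 1 - exp(-Ft/M): ICC = (Ft/M) e^{-Ft/M} / (1 - e^{-Ft/M}),
        which -> 1 as t -> 0+ and -> 0 as t -> inf."""
        model, base, p, obs = washin_setup()
        t = np.array([0.01, 0.5, 1.0, 2.0, 4.0])
        traces = dynamic_control_coefficients(
            model, base, [p], obs, t, method="finite-difference"
        )
        icc = traces[0].values
        x = 3.0 * t / 2.0
        expected = x * np.exp(-x) / (1.0 - np.exp(-x))
        # tolerance floor reflects integrator noise amplified by the 1%
        # central difference
        np.testing.assert_allclose(icc, expected, atol=5e-3)
        assert icc[0] == pytest.approx(1.0, abs=0.01)
        assert icc[-1] < 0.05

    def test_forward_ode_matches_finite_difference_toy(self):
        model, base, p, obs = washin_setup()
        t = np.linspace(0.1, 4.0, 9)
        fd = dynamic_control_coefficients(
            model, base, [p], obs, t, method="finite-difference"
        )[0].values
        fo = dynamic_control_coefficients(
            model, base, [p], obs, t, method="forward-ode"
        )[0].values
        mask = np.abs(fd) > 1e-3
        np.testing.assert_allclose(fo[mask], fd[mask], rtol=1e-3)

    def test_forward_ode_matches_finite_difference_db1(self, db1):
        """Cross-validation of the two sensitivity methods on the preset,
        for a TCA-scale flux and the full nine-observable set."""
        from cumoflux.synthetic import db1_free_fluxes, db1_observables

        model, _, _ = db1
        free = db1_free_fluxes()
        obs = db1_observables(model)
        p = Parameter("F_tca", "flux_net", "IDH", (2.0, 40.0), 10.9)
        t = np.arange(0.5, 6.01, 0.5)
        fd = dynamic_control_coefficients(
            model, free, [p], obs, t, method="finite-difference"
        )
        fo = dynamic_control_coefficients(
            model, free, [p], obs, t, method="forward-ode"
        )
        fd_map = {tr.observable: tr.values for tr in fd}
        for tr in fo:
            a, b = fd_map[tr.observable], tr.values
            mask = np.isfinite(a) & np.isfinite(b) & (np.abs(a) > 1e-3)
            if mask.any():
                np.testing.assert_allclose(
                    b[mask], a[mask], rtol=1e-3, err_msg=tr.observable
                )

    def test_untouched_parameter_gives_zero_trace(self):
        """A flux with no path to the observable leaves the trace at 0."""
        model = load_network(MIXING)
        base = FluxSet({"R_hot": 1.0, "R_cold": 1.0})
        # observable on the labeled source flux only: vary an isolated flux
        # by adding a bypass branch that never touches pool A
        text = MIXING.replace(
            "sinks: [OUT]",
            """sinks: [OUT]
""",
        )
        model2 = load_network(
            text.replace(
                'reactions:',
                '''reactions:
  - {name: R_iso, stoich: "COLD -> OUT", atoms: "a -> a", flux_role: free}''',
            )
        )
        base2 = FluxSet({"R_hot": 1.0, "R_cold": 1.0, "R_iso": 2.0})
        p = Parameter("iso", "flux_net", "R_iso", (0.1, 10.0), 2.0)
        obs = {"A1": lambda tr: tr.cumomer("A", (1,))}
        traces = dynamic_control_coefficients(
            model2, base2, [p], obs, np.linspace(0.2, 3, 6),
            method="finite-difference",
        )
        assert np.nanmax(np.abs(traces[0].values)) < 1e-9

    def test_masking_below_floor(self):
        model, base, p, obs = washin_setup()
        # at t=0 the enrichment is 0 -> coefficient undefined, masked NaN
        traces = dynamic_control_coefficients(
            model, base, [p], obs, np.array([0.0, 1.0]),
            method="finite-difference",
        )
        assert np.isnan(traces[0].values[0])
        assert np.isfinite(traces[0].values[1])


class TestSteadyStateCC:
    def test_two_source_mixing_is_flux_share(self):
        """Enrichment = F_hot/(F_hot + F_cold); at 50/50 the control
        coefficient of the labeled flux is 0.5."""
        model = load_network(MIXING)
        base = FluxSet({"R_hot": 2.0, "R_cold": 2.0})
        p = Parameter("hot", "flux_net", "R_hot", (0.1, 10.0), 2.0)

        def response(system, y):
            j = system.index.index_of("A", (1,))
            return y[j]

        c = steady_state_control_coefficient(model, base, p, response)
        assert c == pytest.approx(0.5, abs=1e-4)

    def test_saturated_terminal_pool_is_zero(self):
        """A pool fed only by one fully labeled source saturates at 1;
        its steady enrichment has no flux control."""
        model, base, p, obs = washin_setup()

        def response(system, y):
            return y[system.index.index_of("A", (1,))]

        c = steady_state_control_coefficient(model, base, p, response)
        assert c == pytest.approx(0.0, abs=1e-8)

    def test_matches_manual_log_difference(self):
        model = load_network(MIXING)
        base = FluxSet({"R_hot": 1.0, "R_cold": 3.0})
        p = Parameter("hot", "flux_net", "R_hot", (0.1, 10.0), 1.0)

        def response(system, y):
            return y[system.index.index_of("A", (1,))]

        c = steady_state_control_coefficient(model, base, p, response)
        # analytic: R = F/(F + 3), dlnR/dlnF = 3/(F+3) = 0.75 at F=1
        assert c == pytest.approx(0.75, abs=1e-4)


class _QuadraticStub:
    """Minimal FitProblem stand-in with E(p) = E0 (1 + ((p-p0)/p0)^2)."""

    def __init__(self, p0=2.0, e0=0.5):
        self.p0, self.e0 = p0, e0

    def residuals(self, values, dataset):
        p = values[0]
        e = self.e0 * (1.0 + ((p - self.p0) / self.p0) ** 2)
        return np.sqrt(np.full(len(dataset), e))


class TestMSESensitivity:
    def _dataset(self, n=4):
        return Dataset(
            pd.DataFrame(
                {"observable": "x", "time_h": np.arange(n) + 1.0,
                 "value": 0.0, "sigma": 1.0}
            )
        )

    def test_quadratic_toy_gives_rel_step(self):
        """E = E0 (1 + ((p-p0)/p0)^2) at p = p0: the documented convention
        yields S = rel_step (0.05)."""
        stub = _QuadraticStub()
        out = mse_sensitivity(stub, self._dataset(), [stub.p0], 0)
        assert out["S"] == pytest.approx(0.05, rel=1e-9)

    def test_no_effect_parameter_is_zero(self):
        class Flat:
            def residuals(self, values, dataset):
                return np.full(len(dataset), 0.3)

        out = mse_sensitivity(Flat(), self._dataset(), [1.0], 0)
        assert out["S"] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_fit_masked(self):
        class Perfect:
            def residuals(self, values, dataset):
                return np.zeros(len(dataset))

        out = mse_sensitivity(Perfect(), self._dataset(), [1.0], 0)
        assert np.isnan(out["S"])

    def test_nonnegative_at_minimum(self):
        stub = _QuadraticStub()
        out = mse_sensitivity(stub, self._dataset(), [stub.p0], 0)
        assert out["S"] >= 0.0

    def test_db1_tca_ranks_above_pc(self, db1):
        """On a noisy DB-1 synthetic fit at the truth, the MSE is far more
        sensitive to the TCA cycle flux than to pyruvate carboxylase."""
        from cumoflux.estimation import FitProblem
        from cumoflux.synthetic import (
            SyntheticExperiment,
            db1_free_fluxes,
            db1_observables,
            db1_parameters,
            generate_timecourses,
        )

        model, fluxes, _ = db1
        obs = db1_observables(model)
        ds = generate_timecourses(
            SyntheticExperiment(
                model, fluxes, obs, sigma=0.01, seed=8,
                times=np.arange(0.5, 6.01, 0.5),
            )
        )
        problem = FitProblem(model, db1_free_fluxes(), db1_parameters(), obs)
        truth = problem.init_values()
        names = [p.name for p in problem.parameters]
        s_tca = mse_sensitivity(problem, ds, truth, names.index("F_tca"))["S"]
        s_pc = mse_sensitivity(problem, ds, truth, names.index("F_pc"))["S"]
        assert s_tca > 5 * s_pc
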