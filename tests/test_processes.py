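"""O-U propagation, Fokker-Planck solver, Langevin ensemble, dichotomous system."""

import numpy as np
import pytest
from scipy.integrate import quad

from infolength import (
    GaussianState,
    Grid1D,
    PDFTrajectory,
    fp_solve,
    gaussian_to_grid,
    langevin_simulate,
    ou_propagate,
    probability_current,
)
from infolength.processes import (
    ProcessSpec,
    dichotomous_solve,
    ou_state_derivatives,
)


def grid_moments(grid, dens):
    m = np.trapezoid(grid.x * dens, dx=grid.dx)
    v = np.trapezoid((grid.x - m) ** 2 * dens, dx=grid.dx)
    return m, v


class TestOUPropagate:
    def test_t0_returns_init(self, default_spec, default_init):
        out = ou_propagate(default_spec, default_init, [0.0])[0]
        assert out.y == default_init.y and out.beta == default_init.beta

    def test_stationary_limit(self, default_spec, default_init):
        out = ou_propagate(default_spec, default_init, [20.0])[0]
        assert out.beta == pytest.approx(default_spec.beta_s, abs=1e-8)
        assert out.variance == pytest.approx(0.5, abs=1e-8)

    def test_ramp_lag(self):
        # v = u t: the mean tracks u t with asymptotic lag u/gamma
        spec = ProcessSpec(gamma=1.0, D=0.5, u=1.0)
        out = ou_propagate(spec, GaussianState(0.0, 1.0), [20.0])[0]
        assert out.y - 1.0 * 20.0 == pytest.approx(-1.0, abs=1e-8)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            GaussianState(0.0, -1.0)

    def test_time_dependent_coefficients_vs_quadrature(self):
        # oracle: the explicit decay-kernel quadrature formulas for y and sigma^2
        gamma = lambda t: 1.0 + 0.5 * np.sin(t)  # noqa: E731
        Dfun = lambda t: 0.5 + 0.2 * np.cos(t)   # noqa: E731
        vfun = lambda t: 0.3 * t                 # noqa: E731
        spec = ProcessSpec(gamma=gamma, D=Dfun, v=vfun)
        init = GaussianState(2.0, 0.8)
        t_end = 2.5

        def Lam(a, b):
            return quad(gamma, a, b, epsabs=1e-12)[0]

        y_ref = init.y * np.exp(-Lam(0, t_end)) + quad(
            lambda s: np.exp(-Lam(s, t_end)) * gamma(s) * vfun(s),
            0, t_end, epsabs=1e-12,
        )[0]
        var_ref = init.variance * np.exp(-2 * Lam(0, t_end)) + quad(
            lambda s: np.exp(-2 * Lam(s, t_end)) * 2 * Dfun(s),
            0, t_end, epsabs=1e-12,
        )[0]
        out = ou_propagate(spec, init, [t_end])[0]
        assert out.y == pytest.approx(y_ref, abs=1e-8)
        assert out.variance == pytest.approx(var_ref, abs=1e-8)

    def test_state_derivatives_match_finite_difference(self, default_spec, default_init):
        h = 1e-6
        states = ou_propagate(default_spec, default_init, [1.0 - h, 1.0, 1.0 + h])
        _, _, ydot, sigdot = ou_state_derivatives(default_spec, states[1])
        assert ydot == pytest.approx((states[2].y - states[0].y) / (2 * h), abs=1e-6)
        assert sigdot == pytest.approx(
            (states[2].sigma - states[0].sigma) / (2 * h), abs=1e-6
        )


class TestFokkerPlanck:
    def test_no_dynamics_is_identity(self, unit_grid):
        p0 = gaussian_to_grid(GaussianState(0.0, 0.5), unit_grid)
        sol = fp_solve(p0, np.linspace(0, 1, 5), drift=lambda x, t: 0.0 * x, D=0.0)
        assert np.abs(sol.traj.densities - p0.p).max() < 1e-14

    def test_ou_moments_match_propagator(self, default_spec, default_init):
        grid = Grid1D(-10.0, 15.0, 4096)
        p0 = gaussian_to_grid(default_init, grid)
        times = np.array([0.0, 0.5, 1.0, 2.0])
        sol = fp_solve(p0, times, spec=default_spec, max_step=1e-3)
        states = ou_propagate(default_spec, default_init, times)
        for k, s in enumerate(states):
            m, v = grid_moments(grid, sol.traj.densities[k])
            assert abs(m - s.y) / max(abs(s.y), 1.0) < 1e-4
            assert abs(v - s.variance) / s.variance < 1e-4
        assert sol.mass_errors.max() < 1e-8
        assert sol.min_density > -1e-12

    def test_stationary_state_is_fixed_point(self):
        spec = ProcessSpec(gamma=0.5, D=1.0, v=0.0)
        grid = Grid1D(-14.0, 14.0, 8192)
        p_s = gaussian_to_grid(GaussianState(0.0, spec.beta_s), grid)
        sol = fp_solve(p_s, np.linspace(0, 1, 5), spec=spec, max_step=1e-3)
        assert np.abs(sol.traj.densities - p_s.p).max() < 1e-6
        assert np.abs(sol.currents).max() < 1e-6

    def test_mass_conserved_every_step(self, default_spec, default_init, default_grid):
        p0 = gaussian_to_grid(default_init, default_grid)
        sol = fp_solve(p0, np.linspace(0, 1, 101), spec=default_spec, max_step=1e-3)
        assert sol.mass_errors.max() < 1e-8

    def test_unstable_step_reported(self):
        # pure advection with a coarse step drives the density negative
        grid = Grid1D(-5.0, 5.0, 256)
        p0 = gaussian_to_grid(GaussianState(0.0, 2.0), grid)
        with pytest.raises(FloatingPointError, match="step"):
            fp_solve(
                p0, [0.0, 2.0], drift=lambda x, t: -50.0 * x, D=0.0, max_step=0.5
            )


class TestProbabilityCurrent:
    def test_equilibrium_detailed_balance(self):
        spec = ProcessSpec(gamma=0.5, D=1.0)
        grid = Grid1D(-14.0, 14.0, 8192)
        p_s = gaussian_to_grid(GaussianState(0.0, spec.beta_s), grid)
        J = probability_current(p_s, spec.drift, float(spec.D), t=0.0)
        assert np.abs(J).max() < 1e-6

    def test_transient_gaussian_current_identity(self, default_spec, default_init):
        # J = [-(betadot/2beta)(x - y) + ydot] p along the Gaussian transient
        grid = Grid1D(-10.0, 15.0, 4096)
        s = ou_propagate(default_spec, default_init, [0.5])[0]
        pdf = gaussian_to_grid(s, grid)
        J = probability_current(pdf, default_spec.drift, float(default_spec.D), t=0.5)
        y, sig, ydot, sigdot = ou_state_derivatives(default_spec, s)
        betadot_over_2beta = -sigdot / sig
        J_ref = (-betadot_over_2beta * (grid.x - y) + ydot) * pdf.p
        assert np.abs(J - J_ref).max() < 1e-4

    def test_odd_current_for_symmetric_density_odd_drift(self, unit_grid):
        pdf = gaussian_to_grid(GaussianState(0.0, 0.5), unit_grid)
        J = probability_current(pdf, lambda x, t: -(x**3), 0.0)
        assert np.abs(J + J[::-1]).max() < 1e-12


class TestLangevin:
    def test_noiseless_paths_deterministic(self):
        spec = ProcessSpec(gamma=1.0, D=0.0)
        res = langevin_simulate(
            spec, 200, lambda rng, n: np.full(n, 5.0), np.linspace(0, 1, 5), seed=3
        )
        assert res.var.max() < 1e-20
        assert res.mean[-1] == pytest.approx(5 * np.exp(-1), rel=1e-3)

    def test_moments_within_four_standard_errors(self, default_spec, default_init):
        times = np.linspace(0, 1, 6)
        res = langevin_simulate(
            default_spec, 20000, default_init, times, seed=11,
            grid=Grid1D(-10, 15, 256),
        )
        exact = ou_propagate(default_spec, default_init, times)
        for k, s in enumerate(exact):
            assert abs(res.mean[k] - s.y) < 4 * res.sem[k] + 1e-12
            se_var = s.variance * np.sqrt(2 / res.n_paths)
            assert abs(res.var[k] - s.variance) < 4 * se_var + 2e-3

    def test_stationary_variance(self, default_spec):
        res = langevin_simulate(
            default_spec, 20000, GaussianState(0.0, default_spec.beta_s),
            np.linspace(0, 3, 4), seed=5,
        )
        se = 0.5 * np.sqrt(2 / res.n_paths)
        assert abs(res.var[-1] - 0.5) < 4 * se

    def test_seed_reproducibility(self, default_spec, default_init):
        times = np.linspace(0, 0.5, 3)
        a = langevin_simulate(default_spec, 500, default_init, times, seed=9)
        b = langevin_simulate(default_spec, 500, default_init, times, seed=9)
        assert np.array_equal(a.mean, b.mean)


@pytest.fixture(scope="module")
def setup():
    spec = ProcessSpec(gamma=1.0, D=0.5)
    grid = Grid1D(-8.0, 11.0, 768)
    beta_s = spec.beta_s
    P1_0 = 0.5 * gaussian_to_grid(GaussianState(0.0, beta_s), grid).p
    P2_0 = 0.5 * gaussian_to_grid(GaussianState(4.0, beta_s), grid).p
    return spec, grid, P1_0, P2_0


class TestDichotomous:
    def test_decoupled_matches_single_component_fp(self, setup):
        spec, grid, P1_0, P2_0 = setup
        times = np.linspace(0, 1, 11)
        sol = dichotomous_solve(P1_0, P2_0, grid, times, r=0.0, spec=spec,
                                max_step=1e-3)
        p0 = gaussian_to_grid(GaussianState(4.0, spec.beta_s), grid)
        ref = fp_solve(p0, times, spec=spec, max_step=1e-3)
        assert np.abs(2 * sol.P2 - ref.traj.densities).max() < 1e-6

    def test_component_masses_conserved(self, setup):
        spec, grid, P1_0, P2_0 = setup
        times = np.linspace(0, 2, 21)
        sol = dichotomous_solve(P1_0, P2_0, grid, times, r=1.0, spec=spec,
                                max_step=2e-3)
        assert sol.mass_errors_1.max() < 1e-8
        assert sol.mass_errors_2.max() < 1e-8

    def test_total_obeys_ou_equation(self, setup):
        # with equal drifts the total density is the analytic O-U mixture
        spec, grid, P1_0, P2_0 = setup
        times = np.linspace(0, 2, 21)
        sol = dichotomous_solve(P1_0, P2_0, grid, times, r=1.0, spec=spec,
                                max_step=1e-3)
        states = ou_propagate(spec, GaussianState(4.0, spec.beta_s), times)
        stat = gaussian_to_grid(GaussianState(0.0, spec.beta_s), grid).p
        worst = 0.0
        for k, s in enumerate(states):
            mix = 0.5 * stat + 0.5 * s.density(grid.x)
            worst = max(worst, np.trapezoid(np.abs(sol.P[k] - mix), dx=grid.dx))
        assert worst < 1e-3

    def test_asymmetric_masses_rejected(self, setup):
        spec, grid, P1_0, P2_0 = setup
        with pytest.raises(ValueError, match="mass"):
            dichotomous_solve(0.8 * P1_0, P2_0, grid, [0.0, 0.1], r=1.0, spec=spec)
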