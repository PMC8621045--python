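"""Information rate Gamma, information length L, and their invariances."""

import numpy as np
import pytest

from infolength import (
    GaussianState,
    Grid1D,
    PDFTrajectory,
    gaussian_to_grid,
    information_length,
    information_rate_gaussian,
    information_rate_numeric,
    invariance_check,
    ou_propagate,
    parametric_rate_and_bounds,
    small_dt_equivalence,
)
from infolength.info_geom import InfoSeries, ParametricModel, gaussian_parametric_model
from infolength.processes import ProcessSpec, ou_state_derivatives


def gaussian_traj(y_fn, beta_fn, times, grid):
    states = [GaussianState(y_fn(t), beta_fn(t), t=t) for t in times]
    return PDFTrajectory.from_states(states, grid)


def exact_ou_info(spec, init, times):
    states = ou_propagate(spec, init, times)
    y = np.array([s.y for s in states])
    beta = np.array([s.beta for s in states])
    der = np.array([ou_state_derivatives(spec, s) for s in states])
    betadot = -der[:, 3] / der[:, 1] ** 3
    return information_rate_gaussian(times, y, beta, ydot=der[:, 2], betadot=betadot)


class TestNumericRate:
    def test_stationary_gamma_zero(self, unit_grid):
        times = np.linspace(0, 1, 11)
        p = gaussian_to_grid(GaussianState(0.0, 0.5), unit_grid).p
        traj = PDFTrajectory(times, unit_grid, np.tile(p, (11, 1)))
        info = information_rate_numeric(traj)
        assert np.all(info.gamma < 1e-12)
        assert np.all(info.L < 1e-12)

    def test_mean_sweep_constant_sigma(self, unit_grid):
        # y(t) = t at sigma = 0.5: Gamma = |ydot|/sigma = 2
        times = np.arange(0.0, 1.0 + 5e-4, 1e-3)
        traj = gaussian_traj(lambda t: t, lambda t: 2.0, times, unit_grid)
        info = information_rate_numeric(traj)
        assert np.max(np.abs(info.gamma - 2.0)) / 2.0 < 5e-3

    def test_matches_gaussian_closed_form_on_ou(
        self, default_spec, default_init, default_grid
    ):
        times = np.arange(0.0, 1.0 + 5e-4, 1e-3)
        states = ou_propagate(default_spec, default_init, times)
        traj = PDFTrajectory.from_states(states, default_grid)
        num = information_rate_numeric(traj)
        ref = exact_ou_info(default_spec, default_init, times)
        sel = (times >= 0.1)
        rel = np.abs(num.gamma[sel] - ref.gamma[sel]) / ref.gamma[sel]
        assert rel.max() < 5e-3

    def test_gamma_stencil_second_order(self, default_spec, default_init, default_grid):
        # halving the time step changes Gamma by < 0.3%
        vals = []
        for dt in (2e-3, 1e-3):
            times = np.arange(0.5, 1.5 + dt / 2, dt)
            states = ou_propagate(default_spec, default_init, times)
            traj = PDFTrajectory.from_states(states, default_grid)
            info = information_rate_numeric(traj)
            vals.append(info.gamma[len(times) // 2])
        assert abs(vals[0] - vals[1]) / vals[1] < 3e-3

    def test_nonuniform_times_rejected(self, unit_grid):
        times = np.array([0.0, 0.1, 0.25, 0.3])
        p = gaussian_to_grid(GaussianState(0.0, 0.5), unit_grid).p
        traj = PDFTrajectory(times, unit_grid, np.tile(p, (4, 1)))
        with pytest.raises(ValueError, match="varies"):
            information_rate_numeric(traj)


class TestGaussianRate:
    def test_mean_motion(self):
        # constant sigma=0.5, ydot=1: Gamma = 2 exactly
        times = np.linspace(0, 1, 101)
        info = information_rate_gaussian(
            times, lambda t: t, lambda t: 2.0,
            ydot=np.ones_like(times), betadot=np.zeros_like(times),
        )
        assert np.allclose(info.gamma, 2.0, atol=1e-12)

    def test_pure_variance_decay(self):
        # sigma(t) = sigma0 e^{-t}: Gamma = sqrt(2) for all t
        times = np.linspace(0, 1, 101)
        beta = 0.5 * np.exp(2 * times)
        betadot = np.exp(2 * times)
        info = information_rate_gaussian(
            times, np.zeros_like(times), beta,
            ydot=np.zeros_like(times), betadot=betadot,
        )
        assert np.allclose(info.gamma, np.sqrt(2), atol=1e-12)

    def test_static_zero(self):
        times = np.linspace(0, 1, 51)
        info = information_rate_gaussian(times, lambda t: 1.0, lambda t: 3.0)
        assert np.all(info.gamma < 1e-9)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            information_rate_gaussian(
                np.linspace(0, 1, 11), lambda t: 0.0, lambda t: 0.5 - t
            )


class TestInformationLength:
    def test_zero_rate_zero_length(self):
        times = np.linspace(0, 1, 11)
        series = information_length(InfoSeries(times, np.zeros(11)))
        assert np.all(series.L == 0.0)

    def test_mean_sweep_total(self):
        # d<x> = 3 at sigma = 1: L = 3
        times = np.linspace(0, 3, 3001)
        info = information_rate_gaussian(
            times, times, np.full_like(times, 0.5),
            ydot=np.ones_like(times), betadot=np.zeros_like(times),
        )
        assert info.L_final == pytest.approx(3.0, rel=1e-10)

    def test_variance_e_fold(self):
        # sigma0 -> sigma0 e over any duration: L = sqrt(2)
        times = np.linspace(0, 2, 2001)
        beta = 0.5 * np.exp(-times)  # sigma grows by factor e over t in [0,2]
        betadot = -0.5 * np.exp(-times)
        info = information_rate_gaussian(
            times, np.zeros_like(times), beta,
            ydot=np.zeros_like(times), betadot=betadot,
        )
        assert info.L_final == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_L_nondecreasing_and_saturates(self, default_spec, default_init):
        times = np.linspace(0, 20, 4001)
        info = exact_ou_info(default_spec, default_init, times)
        assert np.all(np.diff(info.L) >= -1e-15)
        assert info.gamma[-1] < 1e-7
        assert info.L[-1] - info.L[-200] < 1e-6


class TestSmallDtEquivalence:
    def test_stationary_trivial(self, default_spec, unit_grid):
        p_s = gaussian_to_grid(GaussianState(0.0, default_spec.beta_s), unit_grid)
        rep = small_dt_equivalence(lambda t: p_s, 1.0, [1e-2, 1e-3], gamma_sq=0.0)
        assert rep.gamma_sq == 0.0

    def test_ou_ratio_converges_first_order(self, default_spec, default_grid):
        init = GaussianState(5.0, default_spec.beta_s)

        def pdf_at(t):
            return gaussian_to_grid(
                ou_propagate(default_spec, init, [t])[0], default_grid
            )

        s = ou_propagate(default_spec, init, [1.0])[0]
        _, sig, yd, sd = ou_state_derivatives(default_spec, s)
        g2 = (2 * sd**2 + yd**2) / sig**2
        rep = small_dt_equivalence(pdf_at, 1.0, [1e-2, 3e-3, 1e-3], gamma_sq=g2)
        errs = np.abs(rep.ratio - 1)
        assert np.all(np.diff(errs) < 0)           # monotone convergence to 1
        assert rep.fitted_order == pytest.approx(1.0, abs=0.3)
        assert np.all(rep.asymmetry < 1e-2)        # K symmetric to O(dt^2)


class TestParametricBounds:
    def test_mean_only_equality(self):
        times = np.linspace(0, 1, 21)
        model = gaussian_parametric_model(
            times, times, np.full_like(times, 2.0),
            ydot=np.ones_like(times), betadot=np.zeros_like(times),
        )
        rep = parametric_rate_and_bounds(model)
        # |ydot|/sigma = Gamma exactly when only the mean moves
        assert np.allclose(rep.single_bounds[:, 0], rep.gamma_param, rtol=1e-12)
        assert rep.sum_bound_holds and rep.single_bounds_hold

    def test_strict_inequality_with_variance_motion(self, default_spec, default_init):
        times = np.linspace(0.1, 1.0, 19)
        states = ou_propagate(default_spec, default_init, times)
        y = np.array([s.y for s in states])
        beta = np.array([s.beta for s in states])
        der = np.array([ou_state_derivatives(default_spec, s) for s in states])
        betadot = -der[:, 3] / der[:, 1] ** 3
        model = gaussian_parametric_model(times, y, beta, ydot=der[:, 2], betadot=betadot)
        rep = parametric_rate_and_bounds(model)
        assert rep.sum_bound_holds and rep.single_bounds_hold
        assert np.all(rep.single_bounds[:, 0] < rep.gamma_param)  # strict for the mean

    def test_zero_velocity_trivial(self):
        times = np.linspace(0, 1, 5)
        model = gaussian_parametric_model(
            times, np.ones_like(times), np.ones_like(times),
            ydot=np.zeros_like(times), betadot=np.zeros_like(times),
        )
        rep = parametric_rate_and_bounds(model)
        assert np.all(rep.bound_sum == 0.0)

    def test_non_psd_metric_rejected(self):
        times = np.linspace(0, 1, 3)
        model = ParametricModel(
            times, np.ones((3, 2)), metric=lambda lam: np.diag([1.0, -1.0])
        )
        with pytest.raises(ValueError, match="positive semi-definite"):
            parametric_rate_and_bounds(model)


@pytest.fixture()
def state_at(default_spec, default_init):
    return lambda t: ou_propagate(default_spec, default_init, [t])[0]


class TestCoordinateInvariance:
    def test_shift_exact(self, state_at, default_grid):
        times = np.linspace(0.2, 1.0, 5)
        rep = invariance_check(
            state_at, lambda x: x + 5.0, lambda x: np.ones_like(x), times,
            default_grid,
        )
        assert rep.max_rel_err_gamma < 1e-10

    def test_linear_scale_exact(self, state_at, default_grid):
        times = np.linspace(0.2, 1.0, 5)
        rep = invariance_check(
            state_at, lambda x: 2 * x, lambda x: np.full_like(x, 2.0), times,
            default_grid,
        )
        assert rep.max_rel_err_gamma < 1e-10

    def test_cubic_transform_within_one_percent(self, state_at, default_grid):
        times = np.linspace(0.1, 5.0, 50)
        rep = invariance_check(
            state_at, lambda x: x + x**3, lambda x: 1 + 3 * x**2, times,
            default_grid,
        )
        assert rep.max_rel_err_gamma < 0.01
        assert rep.rel_err_L < 0.01

    def test_non_monotone_rejected(self, state_at, default_grid):
        with pytest.raises(ValueError, match="monotone"):
            invariance_check(
                state_at, lambda x: x**2, lambda x: 2 * x,
                np.linspace(0.2, 1.0, 3), default_grid,
            )
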