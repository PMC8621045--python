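"""Information rate and information length of an evolving density.

The information rate

    Gamma(t)^2 = ∫ p (∂t ln p)^2 dx = 4 ∫ (∂t sqrt(p))^2 dx

measures how fast a time-dependent PDF traverses statistically
distinguishable states; its time integral L(t) = ∫ Gamma dt' is the
information length.  The amplitude (sqrt-p) form is used numerically because
it stays finite where the density vanishes.

For the Gaussian family with mean y(t) and inverse temperature beta(t)
(variance sigma^2 = 1/(2 beta)) the rate has the closed form

    Gamma^2 = 2 beta ydot^2 + betadot^2 / (2 beta^2)
            = (2 sigmadot^2 + ydot^2) / sigma^2,

which doubles as the Fisher-metric quadratic form with g_yy = 2 beta,
g_bb = 1/(2 beta^2) for the parameter path lambda = (y, beta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .grids import GaussianState, Grid1D, GridPDF, gaussian_to_grid

__all__ = [
    "PDFTrajectory",
    "InfoSeries",
    "information_rate_numeric",
    "information_rate_gaussian",
    "information_length",
    "small_dt_equivalence",
    "ParametricModel",
    "gaussian_parametric_model",
    "parametric_rate_and_bounds",
    "invariance_check",
]


@dataclass
class PDFTrajectory:
    """Snapshots of one density on a shared grid at near-uniform times."""

    times: np.ndarray
    grid: Grid1D
    densities: np.ndarray  # shape (n_times, n_points)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("need at least 2 snapshots")
        if self.densities.shape != (len(self.times), self.grid.n_points):
            raise ValueError("density array shape mismatch")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        mass = np.trapezoid(self.densities, dx=self.grid.dx, axis=1)
        if np.max(np.abs(mass - 1.0)) > 1e-6:
            raise ValueError("snapshots are not normalized")

    @property
    def dt(self) -> float:
        """Mean time step; raises if the spacing varies by more than 1%
        (the finite-difference stencils assume a uniform step)."""
        steps = np.diff(self.times)
        if len(self.times) < 3:
            raise ValueError("need at least 3 snapshots for time derivatives")
        if (steps.max() - steps.min()) > 0.01 * steps.mean():
            raise ValueError("time step varies by more than 1% (stencil validity)")
        return float(steps.mean())

    @classmethod
    def from_states(
        cls, states: Sequence[GaussianState], grid: Grid1D
    ) -> "PDFTrajectory":
        dens = np.stack([gaussian_to_grid(s, grid).p for s in states])
        return cls(np.array([s.t for s in states]), grid, dens)

    def snapshot(self, k: int) -> GridPDF:
        return GridPDF(self.grid, self.densities[k], t=float(self.times[k]),
                       normalize=True)


@dataclass
class InfoSeries:
    """Gamma(t), E = Gamma^2 and the cumulative information length L(t)."""

    times: np.ndarray
    gamma: np.ndarray
    L: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if np.any(self.gamma < 0):
            raise ValueError("Gamma must be non-negative")

    @property
    def E(self) -> np.ndarray:
        return self.gamma**2

    @property
    def tau(self) -> np.ndarray:
        """Characteristic information time 1/Gamma (inf where Gamma = 0)."""
        with np.errstate(divide="ignore"):
            return np.where(self.gamma > 0, 1.0 / self.gamma, np.inf)

    @property
    def L_final(self) -> float:
        if self.L is None:
            raise ValueError("L not filled; call information_length first")
        return float(self.L[-1])


def _dt_central(arr: np.ndarray, dt: float) -> np.ndarray:
    """Second-order time derivative along axis 0 (one-sided at the ends)."""
    out = np.empty_like(arr)
    out[1:-1] = (arr[2:] - arr[:-2]) / (2 * dt)
    out[0] = (-3 * arr[0] + 4 * arr[1] - arr[2]) / (2 * dt)
    out[-1] = (3 * arr[-1] - 4 * arr[-2] + arr[-3]) / (2 * dt)
    return out


def information_rate_numeric(traj: PDFTrajectory) -> InfoSeries:
    """Gamma(t) from snapshots via the amplitude form ``4 ∫ (∂t sqrt p)^2 dx``."""
    q = np.sqrt(traj.densities)
    qdot = _dt_central(q, traj.dt)
    gamma_sq = 4.0 * np.trapezoid(qdot**2, dx=traj.grid.dx, axis=1)
    series = InfoSeries(traj.times, np.sqrt(np.clip(gamma_sq, 0.0, None)))
    return information_length(series)


def information_rate_gaussian(
    times: np.ndarray,
    y: np.ndarray | Callable[[float], float],
    beta: np.ndarray | Callable[[float], float],
    ydot: np.ndarray | None = None,
    betadot: np.ndarray | None = None,
    cross_check_tol: float = 1e-10,
) -> InfoSeries:
    """Closed-form Gamma for a Gaussian path ``(y(t), beta(t))``.

    ``y`` and ``beta`` may be callables (sampled on ``times``) or arrays.
    Derivatives are taken by second-order finite differences unless supplied.
    Both printed forms of the rate are evaluated and cross-checked.
    """
    times = np.asarray(times, dtype=float)
    yv = np.array([y(t) for t in times]) if callable(y) else np.asarray(y, float)
    bv = (
        np.array([beta(t) for t in times])
        if callable(beta)
        else np.asarray(beta, float)
    )
    if np.any(bv <= 0):
        raise ValueError("beta must stay positive")
    dt = np.diff(times)
    if (dt.max() - dt.min()) > 0.01 * dt.mean():
        raise ValueError("time step varies by more than 1%")
    h = float(dt.mean())
    yd = _dt_central(yv, h) if ydot is None else np.asarray(ydot, float)
    bd = _dt_central(bv, h) if betadot is None else np.asarray(betadot, float)

    gamma_sq = 2 * bv * yd**2 + bd**2 / (2 * bv**2)
    # equivalent (sigma) form: [2 sigmadot^2 + ydot^2] / sigma^2
    sigma = 1.0 / np.sqrt(2 * bv)
    sigmadot = -bd / (2 * bv) * sigma  # d/dt (2 beta)^{-1/2}
    gamma_sq_alt = (2 * sigmadot**2 + yd**2) / sigma**2
    scale = np.maximum(gamma_sq, 1e-30)
    if np.max(np.abs(gamma_sq - gamma_sq_alt) / scale) > cross_check_tol:
        raise AssertionError("the two closed forms of Gamma^2 disagree")
    series = InfoSeries(times, np.sqrt(np.clip(gamma_sq, 0.0, None)))
    return information_length(series)


def information_length(series: InfoSeries) -> InfoSeries:
    """Fill ``L(t)`` as the cumulative trapezoid integral of Gamma."""
    t, g = series.times, series.gamma
    L = np.concatenate([[0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * np.diff(t))])
    series.L = L
    return series


# ---------------------------------------------------------------------------
# Small-dt equivalence of divergences and the information rate


@dataclass(frozen=True)
class SmallDtReport:
    """Convergence of ``2 K[p(t+dt)|p(t)] / dt^2`` to ``Gamma^2``."""

    t: float
    dts: np.ndarray
    ratio: np.ndarray          # (2 K_forward / dt^2) / Gamma^2
    asymmetry: np.ndarray      # |K_forward - K_backward| / K_forward
    fitted_order: float        # slope of log|ratio-1| vs log dt
    gamma_sq: float


def small_dt_equivalence(
    pdf_at: Callable[[float], GridPDF],
    t: float,
    dt_list: Sequence[float],
    gamma_sq: float | None = None,
) -> SmallDtReport:
    """Check that the relative entropy of adjacent snapshots recovers Gamma^2.

    ``pdf_at`` must return the density at an arbitrary time (an analytic or
    re-solvable trajectory).  If ``gamma_sq`` is not given it is estimated
    from the amplitude form at a step ten times finer than the smallest dt.
    """
    from .distances import kl_divergence

    dts = np.sort(np.asarray(dt_list, dtype=float))[::-1]
    base = pdf_at(t)
    if gamma_sq is None:
        h = dts[-1] / 10.0
        qm, qp = np.sqrt(pdf_at(t - h).p), np.sqrt(pdf_at(t + h).p)
        gamma_sq = 4.0 * base.integrate(((qp - qm) / (2 * h)) ** 2)
    ratios, asym = [], []
    for dt in dts:
        ahead = pdf_at(t + dt)
        kf = kl_divergence(ahead, base)
        kb = kl_divergence(base, ahead)
        if gamma_sq <= 0:
            ratios.append(np.nan)
        else:
            ratios.append(2 * kf / dt**2 / gamma_sq)
        asym.append(abs(kf - kb) / kf if kf > 0 else 0.0)
    ratios = np.array(ratios)
    if gamma_sq > 0 and np.all(np.abs(ratios - 1) > 0):
        order = float(
            np.polyfit(np.log(dts), np.log(np.abs(ratios - 1)), 1)[0]
        )
    else:
        order = np.nan
    return SmallDtReport(t, dts, ratios, np.array(asym), order, float(gamma_sq))


# ---------------------------------------------------------------------------
# Parametric (Fisher-metric) form and Cramér-Rao-type bounds


@dataclass
class ParametricModel:
    """A parameter path with its Fisher metric and fluctuation covariance.

    ``metric(lmbda)`` and ``cov(lmbda)`` return (k, k) matrices at one
    parameter point; ``cov`` defaults to the inverse metric (the Cramér-Rao
    saturation, exact for the Gaussian family's natural estimators).
    """

    times: np.ndarray
    lambdas: np.ndarray        # (n_times, k)
    metric: Callable[[np.ndarray], np.ndarray]
    cov: Callable[[np.ndarray], np.ndarray] | None = None
    lambdadots: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.lambdas = np.atleast_2d(np.asarray(self.lambdas, float))
        if self.lambdadots is None:
            h = float(np.mean(np.diff(self.times)))
            self.lambdadots = _dt_central(self.lambdas, h)


def gaussian_parametric_model(
    times: np.ndarray,
    y: np.ndarray,
    beta: np.ndarray,
    ydot: np.ndarray | None = None,
    betadot: np.ndarray | None = None,
) -> ParametricModel:
    """Gaussian family with lambda = (y, beta); g = diag(2b, 1/(2b^2))."""

    def metric(lmbda: np.ndarray) -> np.ndarray:
        b = lmbda[1]
        return np.diag([2 * b, 1.0 / (2 * b**2)])

    lams = np.column_stack([y, beta])
    dots = (
        None
        if ydot is None or betadot is None
        else np.column_stack([ydot, betadot])
    )
    return ParametricModel(times, lams, metric, lambdadots=dots)


@dataclass(frozen=True)
class ParametricBoundsReport:
    times: np.ndarray
    gamma_param: np.ndarray
    bound_sum: np.ndarray          # Eq-style aggregate fluctuation bound
    single_bounds: np.ndarray      # (n, k): |lamdot_a| / rms fluctuation
    sum_bound_holds: bool
    single_bounds_hold: bool


def parametric_rate_and_bounds(
    model: ParametricModel, tol: float = 1e-9
) -> ParametricBoundsReport:
    """Gamma from the Fisher metric, plus the fluctuation-normalized bounds.

    Verifies ``sum_a lamdot_a^2 / <dlam_a^2> <= Gamma^2`` and, per parameter,
    ``|lamdot_a| / <dlam_a^2>^{1/2} <= Gamma``.
    """
    n, k = model.lambdas.shape
    g2 = np.empty(n)
    bsum = np.empty(n)
    single = np.empty((n, k))
    for i in range(n):
        lam, dot = model.lambdas[i], model.lambdadots[i]
        g = model.metric(lam)
        w = np.linalg.eigvalsh(g)
        if w.min() < -1e-12 * max(1.0, w.max()):
            raise ValueError("Fisher metric is not positive semi-definite")
        g2[i] = dot @ g @ dot
        C = np.linalg.inv(g) if model.cov is None else model.cov(lam)
        dvar = np.diag(C)
        bsum[i] = np.sum(dot**2 / dvar)
        single[i] = np.abs(dot) / np.sqrt(dvar)
    gamma = np.sqrt(np.clip(g2, 0.0, None))
    scale = np.maximum(g2, 1.0)
    return ParametricBoundsReport(
        model.times,
        gamma,
        bsum,
        single,
        bool(np.all(bsum <= g2 + tol * scale)),
        bool(np.all(single <= gamma[:, None] + tol * np.maximum(gamma[:, None], 1.0))),
    )


# ---------------------------------------------------------------------------
# Invariance under time-independent coordinate transformations


@dataclass(frozen=True)
class InvarianceReport:
    times: np.ndarray
    gamma_x: np.ndarray
    gamma_y: np.ndarray
    L_x: float
    L_y: float
    max_rel_err_gamma: float
    rel_err_L: float


def invariance_check(
    state_at: Callable[[float], GaussianState],
    h: Callable[[np.ndarray], np.ndarray],
    h_prime: Callable[[np.ndarray], np.ndarray],
    times: Sequence[float],
    grid: Grid1D,
    dt: float = 1e-3,
    n_y: int = 65536,
    n_dense: int = 400000,
) -> InvarianceReport:
    """Compare Gamma computed in x-coordinates and under ``y = h(x)``.

    ``h`` must be strictly monotone and time-independent; the transformed
    density is ``p_y(y) = p_x(h^{-1}(y)) / |h'(h^{-1}(y))|`` sampled on a
    uniform y-grid.  Gamma at each requested time uses a local central
    difference of the amplitude with half-width ``dt``; L integrates Gamma
    over ``times`` by the trapezoid rule in both coordinate systems.
    """
    times = np.asarray(times, dtype=float)
    x_dense = np.linspace(grid.x_min, grid.x_max, n_dense)
    hx = np.asarray(h(x_dense), dtype=float)
    dh = np.diff(hx)
    if np.all(dh > 0):
        sign = 1.0
    elif np.all(dh < 0):
        sign = -1.0
        hx = hx[::-1]
        x_dense = x_dense[::-1]
    else:
        raise ValueError("transform h is not strictly monotone on the grid")
    ygrid = Grid1D(float(hx[0]), float(hx[-1]), n_y)
    x_inv = np.interp(ygrid.x, hx, x_dense)
    jac = np.abs(np.asarray(h_prime(x_inv), dtype=float))

    def gamma_from_triplet(dens_m, dens_p, dxg):
        qdot = (np.sqrt(dens_p) - np.sqrt(dens_m)) / (2 * dt)
        return float(np.sqrt(4 * np.trapezoid(qdot**2, dx=dxg)))

    gx, gy = [], []
    for t in times:
        sm, sp = state_at(t - dt), state_at(t + dt)
        gx.append(gamma_from_triplet(sm.density(grid.x), sp.density(grid.x), grid.dx))
        py_m = sm.density(x_inv) / jac
        py_p = sp.density(x_inv) / jac
        gy.append(gamma_from_triplet(py_m, py_p, ygrid.dx))
    del sign  # orientation already absorbed by the |h'| Jacobian
    gx, gy = np.array(gx), np.array(gy)
    Lx = float(np.trapezoid(gx, times))
    Ly = float(np.trapezoid(gy, times))
    rel = np.abs(gy - gx) / np.maximum(gx, 1e-300)
    return InvarianceReport(
        times, gx, gy, Lx, Ly, float(rel.max()),
        abs(Ly - Lx) / max(Lx, 1e-300),
    )
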