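"""Trajectory generators for the (non-autonomous) Ornstein-Uhlenbeck system.

The model is the overdamped Langevin equation

    dx/dt = -gamma(t) (x - v(t)) + xi,   <xi(t) xi(t')> = 2 D(t) delta(t-t'),

whose density obeys the Fokker-Planck equation

    dp/dt = -d/dx (f p) + D d2p/dx2 = -dJ/dx,   J = f p - D dp/dx.

Four routes to trajectories are provided: the exact Gaussian propagator
(closed forms for constant coefficients, high-accuracy integration of the
exact moment ODEs otherwise), a conservative finite-volume Fokker-Planck
solver (Chang-Cooper face weights, Crank-Nicolson stepping, zero-flux
boundaries), an Euler-Maruyama Monte-Carlo simulator, and a two-component
system coupled by dichotomous (telegraph) switching at rate r, whose total
density obeys the same O-U Fokker-Planck equation when the two drifts agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded

from .grids import GaussianState, Grid1D, GridPDF
from .info_geom import PDFTrajectory

__all__ = [
    "ProcessSpec",
    "ou_propagate",
    "ou_state_derivatives",
    "fp_solve",
    "FPSolution",
    "langevin_simulate",
    "LangevinResult",
    "dichotomous_solve",
    "DichotomousSolution",
    "probability_current",
]

_NUM_DERIV_H = 1e-6


def _as_fn(value) -> Callable[[float], float]:
    if callable(value):
        return value
    return lambda t, _v=float(value): _v


@dataclass
class ProcessSpec:
    """Coefficients gamma(t) > 0, D(t) >= 0 and force v(t) of the O-U model.

    Each coefficient may be a constant or a callable of time.  ``u`` is a
    convenience for the linear ramp ``v(t) = u t``.  The drift is
    ``f(x, t) = -gamma(t) (x - v(t))`` and the confining potential
    ``V(x, t) = gamma(t) (x - v(t))^2 / 2``.
    """

    gamma: float | Callable[[float], float] = 1.0
    D: float | Callable[[float], float] = 0.5
    v: float | Callable[[float], float] = 0.0
    u: float | None = None

    def __post_init__(self) -> None:
        if self.u is not None:
            if callable(self.v) or float(self.v) != 0.0:
                raise ValueError("give either a ramp rate u or a force v, not both")

    # -- coefficient access -------------------------------------------------
    def gamma_at(self, t: float) -> float:
        g = _as_fn(self.gamma)(t)
        if g <= 0:
            raise ValueError(f"gamma(t={t}) = {g} must be positive")
        return g

    def D_at(self, t: float) -> float:
        d = _as_fn(self.D)(t)
        if d < 0:
            raise ValueError(f"D(t={t}) = {d} must be non-negative")
        return d

    def v_at(self, t: float) -> float:
        if self.u is not None:
            return self.u * t
        return _as_fn(self.v)(t)

    def vdot_at(self, t: float) -> float:
        if self.u is not None:
            return self.u
        if not callable(self.v):
            return 0.0
        return (self.v(t + _NUM_DERIV_H) - self.v(t - _NUM_DERIV_H)) / (2 * _NUM_DERIV_H)

    def gammadot_at(self, t: float) -> float:
        if not callable(self.gamma):
            return 0.0
        return (
            self.gamma(t + _NUM_DERIV_H) - self.gamma(t - _NUM_DERIV_H)
        ) / (2 * _NUM_DERIV_H)

    @property
    def constant_coefficients(self) -> bool:
        return not (callable(self.gamma) or callable(self.D))

    @property
    def beta_s(self) -> float:
        """Stationary inverse temperature gamma/(2D) (constant coefficients)."""
        if not self.constant_coefficients:
            raise ValueError("beta_s requires constant gamma and D")
        if self.D == 0:
            raise ValueError("beta_s undefined for D = 0")
        return float(self.gamma) / (2.0 * float(self.D))

    # -- fields -------------------------------------------------------------
    def drift(self, x: np.ndarray, t: float) -> np.ndarray:
        return -self.gamma_at(t) * (x - self.v_at(t))

    def potential(self, x: np.ndarray, t: float) -> np.ndarray:
        return 0.5 * self.gamma_at(t) * (x - self.v_at(t)) ** 2

    def potential_rate(self, x: np.ndarray, t: float) -> np.ndarray:
        """Explicit time derivative of the potential at fixed x."""
        dx = x - self.v_at(t)
        return 0.5 * self.gammadot_at(t) * dx**2 - self.gamma_at(t) * self.vdot_at(t) * dx


# ---------------------------------------------------------------------------
# Exact Gaussian propagation


def ou_propagate(
    spec: ProcessSpec, init: GaussianState, times: Sequence[float]
) -> list[GaussianState]:
    """Exact Gaussian states of the O-U process at the requested times.

    Constant-coefficient cases use the printed closed forms; otherwise the
    exact first/second-moment ODEs are integrated to tight tolerance.
    """
    times = np.asarray(times, dtype=float)
    t0 = init.t
    if np.any(times < t0 - 1e-12):
        raise ValueError("times must not precede the initial state")
    if init.beta <= 0:
        raise ValueError("beta0 must be positive")

    if spec.constant_coefficients and (
        spec.u is not None or not callable(spec.v)
    ):
        g, D = float(spec.gamma), float(spec.D)
        tau = times - t0
        decay = np.exp(-g * tau)
        var = init.variance * decay**2 + (D / g) * (1 - decay**2)
        if spec.u is not None:
            u = spec.u
            # means relative to an initial time t0: shift the ramp phase
            y = (
                (init.y - spec.u * t0) * decay
                + u * tau
                - (u / g) * (1 - decay)
                + spec.u * t0
            )
        else:
            v0 = float(spec.v)
            y = v0 + (init.y - v0) * decay
        return [
            GaussianState(float(yi), 1.0 / (2.0 * vi), t=float(ti))
            for yi, vi, ti in zip(y, var, times)
        ]

    def rhs(t: float, s: np.ndarray) -> list[float]:
        g = spec.gamma_at(t)
        return [-g * (s[0] - spec.v_at(t)), -2 * g * s[1] + 2 * spec.D_at(t)]

    t_end = float(times.max())
    sol = solve_ivp(
        rhs,
        (t0, t_end if t_end > t0 else t0 + 1e-12),
        [init.y, init.variance],
        t_eval=np.maximum(times, t0),
        method="DOP853",
        rtol=1e-11,
        atol=1e-13,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"moment integration failed: {sol.message}")
    return [
        GaussianState(float(y), 1.0 / (2.0 * max(v, 1e-300)), t=float(t))
        for t, y, v in zip(times, sol.y[0], sol.y[1])
    ]


def ou_state_derivatives(
    spec: ProcessSpec, state: GaussianState
) -> tuple[float, float, float, float]:
    """Exact (y, sigma, ydot, sigmadot) at a propagated state.

    The O-U moment equations ``ydot = -gamma (y - v)`` and
    ``d(sigma^2)/dt = -2 gamma sigma^2 + 2 D`` hold along every trajectory,
    so the derivatives follow from the state itself.
    """
    t = state.t
    g = spec.gamma_at(t)
    ydot = -g * (state.y - spec.v_at(t))
    var = state.variance
    dvar = -2 * g * var + 2 * spec.D_at(t)
    sigma = float(np.sqrt(var))
    return state.y, sigma, float(ydot), float(dvar / (2 * sigma))


# ---------------------------------------------------------------------------
# Conservative Fokker-Planck solver


def _chang_cooper_delta(w: np.ndarray) -> np.ndarray:
    """Exponentially fitted face weight; limits 1/2 (diffusive) and 0/1 (upwind)."""
    # weight of the left (upstream for w>0) node, chosen so that the discrete
    # zero-flux state reproduces p_{i+1}/p_i = exp(w) exactly
    delta = np.empty_like(w)
    small = np.abs(w) < 1e-8
    delta[small] = 0.5 + w[small] / 12.0
    ws = w[~small]
    delta[~small] = 1.0 + 1.0 / np.expm1(ws) - 1.0 / ws
    return delta


def _fp_matrix(
    x: np.ndarray, dx: float, f_face: np.ndarray, D: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tridiagonal generator A of dp/dt = A p (flux form, zero-flux ends).

    Returns (lower, diag, upper) such that
    ``(A p)[i] = lower[i-1] p[i-1] + diag[i] p[i] + upper[i] p[i+1]``.
    """
    if D > 0:
        w = f_face * dx / D
        delta = _chang_cooper_delta(w)
        a = f_face * delta + D / dx        # coefficient of p_left in the face flux
        b = f_face * (1 - delta) - D / dx  # coefficient of p_right
    else:
        a = np.where(f_face > 0, f_face, 0.0)
        b = np.where(f_face < 0, f_face, 0.0)
    n = len(x)
    diag = np.zeros(n)
    lower = a / dx                  # A[i, i-1] for i = 1..n-1
    upper = -b / dx                 # A[i, i+1] for i = 0..n-2
    diag[0] = -a[0] / dx
    diag[-1] = b[-1] / dx
    diag[1:-1] = (b[:-1] - a[1:]) / dx
    return lower, diag, upper


@dataclass
class FPSolution:
    """Output of :func:`fp_solve`: snapshots, currents, conservation log."""

    traj: PDFTrajectory
    currents: np.ndarray
    mass_errors: np.ndarray
    min_density: float
    clipped: float = 0.0

    def snapshot(self, k: int) -> GridPDF:
        return self.traj.snapshot(k)


def fp_solve(
    p0: GridPDF,
    times: Sequence[float],
    drift: Callable[[np.ndarray, float], np.ndarray] | None = None,
    D: float | Callable[[float], float] = 0.0,
    spec: ProcessSpec | None = None,
    max_step: float = 1e-3,
    boundary_warn: float = 1e-12,
) -> FPSolution:
    """Solve the 1-D Fokker-Planck equation on the grid of ``p0``.

    Conservative finite-volume discretization with Chang-Cooper face
    weighting and Crank-Nicolson time stepping; the discrete node mass
    ``sum(p) dx`` is conserved to round-off and the zero-flux (reflecting)
    boundaries are immaterial as long as boundary densities stay negligible.

    Either a ``spec`` (drift ``-gamma (x - v)`` and its ``D``) or an explicit
    ``drift(x, t)`` with a diffusion amplitude ``D`` must be given.
    """
    if spec is not None:
        drift = spec.drift
        D = spec.D
    if drift is None:
        raise ValueError("provide a drift function or a ProcessSpec")
    D_fn = _as_fn(D)

    times = np.asarray(times, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two output times")
    grid = p0.grid
    x, dx = grid.x, grid.dx
    x_face = 0.5 * (x[:-1] + x[1:])

    if max(p0.p[0], p0.p[-1]) > boundary_warn:
        import warnings

        warnings.warn(
            "initial boundary density exceeds 1e-12; reflecting walls may bias the solution",
            stacklevel=2,
        )

    p = p0.p.copy()
    nt, n = len(times), grid.n_points
    out = np.empty((nt, n))
    currents = np.empty((nt, n))
    mass_errors = np.empty(nt)
    min_density = float(p.min())
    clipped = 0.0

    def record(k: int, t: float) -> None:
        out[k] = p
        currents[k] = probability_current_values(x, dx, p, drift(x, t), D_fn(t))
        mass_errors[k] = abs(np.trapezoid(p, dx=dx) - 1.0)

    record(0, float(times[0]))
    ab = np.zeros((3, n))
    for k in range(1, nt):
        t_a, t_b = float(times[k - 1]), float(times[k])
        span = t_b - t_a
        n_sub = max(1, int(np.ceil(span / max_step)))
        h = span / n_sub
        t = t_a
        for _ in range(n_sub):
            tm = t + 0.5 * h
            Dm = D_fn(tm)
            f_face = np.asarray(drift(x_face, tm), dtype=float)
            if not np.all(np.isfinite(f_face)):
                raise FloatingPointError(f"drift not finite at t={tm}")
            lower, diag, upper = _fp_matrix(x, dx, f_face, Dm)
            # explicit half step:  rhs = (I + h/2 A) p
            rhs = p + 0.5 * h * (
                diag * p
                + np.concatenate([[0.0], lower * p[:-1]])
                + np.concatenate([upper * p[1:], [0.0]])
            )
            # implicit half step: (I - h/2 A) p_new = rhs, banded solve
            ab[0, 1:] = -0.5 * h * upper
            ab[1, :] = 1.0 - 0.5 * h * diag
            ab[2, :-1] = -0.5 * h * lower
            p = solve_banded((1, 1), ab, rhs)
            t += h
        mn = float(p.min())
        min_density = min(min_density, mn)
        if mn < 0:
            if mn < -1e-9:
                raise FloatingPointError(
                    f"Fokker-Planck step h={h:.3e} produced density {mn:.3e}; "
                    "reduce max_step"
                )
            clipped = max(clipped, -mn)
            p = np.clip(p, 0.0, None)
        record(k, t_b)

    traj = PDFTrajectory(times, grid, out)
    return FPSolution(traj, currents, mass_errors, min_density, clipped)


def probability_current_values(
    x: np.ndarray, dx: float, p: np.ndarray, f: np.ndarray, D: float
) -> np.ndarray:
    dpdx = np.gradient(p, dx, edge_order=2)
    return f * p - D * dpdx


def probability_current(
    pdf: GridPDF,
    f: Callable[[np.ndarray, float], np.ndarray] | np.ndarray,
    D: float,
    t: float = 0.0,
) -> np.ndarray:
    """Probability current ``J = f p - D dp/dx`` on the grid of ``pdf``."""
    fv = f(pdf.x, t) if callable(f) else np.asarray(f, dtype=float)
    return probability_current_values(pdf.x, pdf.grid.dx, pdf.p, fv, D)


# ---------------------------------------------------------------------------
# Euler-Maruyama Monte Carlo


@dataclass
class LangevinResult:
    times: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    sem: np.ndarray
    traj: PDFTrajectory | None
    n_paths: int
    paths: np.ndarray | None = None


def langevin_simulate(
    spec: ProcessSpec,
    n_paths: int,
    init: GaussianState | Callable[[np.random.Generator, int], np.ndarray],
    times: Sequence[float],
    seed: int,
    grid: Grid1D | None = None,
    dt: float | None = None,
    keep_paths: bool = False,
) -> LangevinResult:
    """Euler-Maruyama ensemble of the Langevin equation.

    The per-step noise has variance ``2 D dt``.  Empirical densities are
    histograms on ``grid`` (bin edges at node midpoints).  The generator is
    seeded from ``(seed, 0)`` so runs are bit-reproducible.
    """
    if n_paths < 100:
        raise ValueError("need at least 100 paths")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng([int(seed), 0])
    if isinstance(init, GaussianState):
        x = init.y + init.sigma * rng.standard_normal(n_paths)
        t0 = init.t
    else:
        x = np.asarray(init(rng, n_paths), dtype=float)
        t0 = float(times[0])
    if dt is None:
        g_max = max(spec.gamma_at(float(t)) for t in np.linspace(times[0], times[-1], 32))
        dt = min(1e-3, 0.01 / g_max)

    nt = len(times)
    mean = np.empty(nt)
    var = np.empty(nt)
    dens = np.empty((nt, grid.n_points)) if grid is not None else None
    saved = np.empty((nt, n_paths)) if keep_paths else None
    edges = None
    if grid is not None:
        xg = grid.x
        edges = np.concatenate(
            [[xg[0] - grid.dx / 2], 0.5 * (xg[:-1] + xg[1:]), [xg[-1] + grid.dx / 2]]
        )

    def record(k: int) -> None:
        mean[k] = x.mean()
        var[k] = x.var()
        if dens is not None:
            counts, _ = np.histogram(x, bins=edges)
            d = counts / (n_paths * grid.dx)
            norm = np.trapezoid(d, dx=grid.dx)
            dens[k] = d / norm if norm > 0 else d
        if saved is not None:
            saved[k] = x

    t = t0
    record(0)
    for k in range(1, nt):
        target = float(times[k])
        while t < target - 1e-12:
            h = min(dt, target - t)
            drift = spec.drift(x, t)
            noise = np.sqrt(2 * spec.D_at(t) * h) * rng.standard_normal(n_paths)
            x = x + drift * h + noise
            t += h
        record(k)

    sem = np.sqrt(var / n_paths)
    traj = PDFTrajectory(times, grid, dens) if dens is not None and nt >= 3 else None
    return LangevinResult(times, mean, var, sem, traj, n_paths, saved)


# ---------------------------------------------------------------------------
# Dichotomous-noise coupled two-component system


@dataclass
class DichotomousSolution:
    """Two coupled component densities and their total."""

    times: np.ndarray
    grid: Grid1D
    P1: np.ndarray
    P2: np.ndarray
    mass_errors_1: np.ndarray
    mass_errors_2: np.ndarray

    @property
    def P(self) -> np.ndarray:
        return self.P1 + self.P2

    def component_trajectory(self, which: int) -> PDFTrajectory:
        """Normalized (mass-1) trajectory of one component, ``2 P_i``."""
        dens = {1: self.P1, 2: self.P2}[which]
        mass = np.trapezoid(dens, dx=self.grid.dx, axis=1)
        return PDFTrajectory(self.times, self.grid, dens / mass[:, None])

    def total_trajectory(self) -> PDFTrajectory:
        return PDFTrajectory(self.times, self.grid, self.P)


def dichotomous_solve(
    P1_0: np.ndarray,
    P2_0: np.ndarray,
    grid: Grid1D,
    times: Sequence[float],
    r: float,
    spec: ProcessSpec | None = None,
    f1: Callable[[np.ndarray, float], np.ndarray] | None = None,
    f2: Callable[[np.ndarray, float], np.ndarray] | None = None,
    D: float | None = None,
    max_step: float = 2e-3,
) -> DichotomousSolution:
    """Two Fokker-Planck components exchanging mass at switching rate ``r``.

        dP1/dt = -d(f1 P1)/dx + D d2P1/dx2 + r (P2 - P1)
        dP2/dt = -d(f2 P2)/dx + D d2P2/dx2 + r (P1 - P2)

    Both components must start with mass 1/2 (the symmetric configuration in
    which each mass is conserved).  With ``f1 = f2`` the total ``P1 + P2``
    obeys the single-component O-U Fokker-Planck equation.
    """
    if r < 0:
        raise ValueError("switching rate r must be non-negative")
    if spec is not None:
        f1 = f1 or spec.drift
        f2 = f2 or spec.drift
        D = float(spec.D) if D is None else D
    if f1 is None or f2 is None or D is None:
        raise ValueError("provide a ProcessSpec or explicit drifts and D")

    times = np.asarray(times, dtype=float)
    x, dx, n = grid.x, grid.dx, grid.n_points
    m1 = float(np.trapezoid(P1_0, dx=dx))
    m2 = float(np.trapezoid(P2_0, dx=dx))
    if abs(m1 - 0.5) > 1e-8 or abs(m2 - 0.5) > 1e-8:
        raise ValueError("each component must start with mass 1/2")

    x_face = 0.5 * (x[:-1] + x[1:])
    nt = len(times)
    P1 = np.empty((nt, n))
    P2 = np.empty((nt, n))
    e1 = np.empty(nt)
    e2 = np.empty(nt)
    p1, p2 = np.asarray(P1_0, float).copy(), np.asarray(P2_0, float).copy()

    def record(k: int) -> None:
        P1[k], P2[k] = p1, p2
        e1[k] = abs(np.trapezoid(p1, dx=dx) - 0.5)
        e2[k] = abs(np.trapezoid(p2, dx=dx) - 0.5)

    record(0)
    # interleaved unknown vector (P1_0, P2_0, P1_1, P2_1, ...): bandwidth 2
    ab = np.zeros((5, 2 * n))
    rhs = np.empty(2 * n)
    for k in range(1, nt):
        span = float(times[k] - times[k - 1])
        n_sub = max(1, int(np.ceil(span / max_step)))
        h = span / n_sub
        t = float(times[k - 1])
        for _ in range(n_sub):
            tm = t + 0.5 * h
            trid = [
                _fp_matrix(x, dx, np.asarray(f(x_face, tm), float), D)
                for f in (f1, f2)
            ]
            Ap = []
            for (lo, di, up), p in zip(trid, (p1, p2)):
                Ap.append(
                    di * p
                    + np.concatenate([[0.0], lo * p[:-1]])
                    + np.concatenate([up * p[1:], [0.0]])
                )
            Ap[0] += r * (p2 - p1)
            Ap[1] += r * (p1 - p2)
            rhs[0::2] = p1 + 0.5 * h * Ap[0]
            rhs[1::2] = p2 + 0.5 * h * Ap[1]

            c = 0.5 * h
            ab[:] = 0.0
            for comp, (lo, di, up) in enumerate(trid):
                idx = np.arange(comp, 2 * n, 2)
                ab[2, idx] = 1.0 - c * (di - r)
                # spatial neighbours sit two slots away in the interleaved order
                ab[0, idx[1:]] = -c * up
                ab[4, idx[:-1]] = -c * lo
            # exchange couples the two components at the same node (offset 1)
            ab[1, 1::2] = -c * r   # P1 row, P2 column
            ab[3, 0::2] = -c * r   # P2 row, P1 column
            sol = solve_banded((2, 2), ab, rhs)
            p1, p2 = sol[0::2].copy(), sol[1::2].copy()
            t += h
        mn = min(p1.min(), p2.min())
        if mn < -1e-9:
            raise FloatingPointError(
                f"dichotomous step h={h:.3e} produced density {mn:.3e}"
            )
        p1, p2 = np.clip(p1, 0.0, None), np.clip(p2, 0.0, None)
        record(k)

    return DichotomousSolution(times, grid, P1, P2, e1, e2)
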