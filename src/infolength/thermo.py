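"""Non-equilibrium thermodynamic functionals of a density trajectory.

Given a trajectory p(x,t) generated by drift f and diffusion D, this module
computes the entropy budget

    Sdot = Sdot_T - Sdot_m,
    Sdot_T = ∫ J^2/(D p) dx >= 0   (total entropy production rate),
    Sdot_m = ∫ J f / D dx          (entropy flow to the environment),

the first law ``Udot = Wdot - Qdot`` with U = <V>, Wdot = <dV/dt>,
Qdot = ∫ J f dx = D Sdot_m, the non-equilibrium free energy F = U - D S
(D acts as the effective temperature, k_B = 1) with the non-negative
dissipated power Wdot_D = Wdot - Fdot = D Sdot_T, and the relative entropy
K[p|p_s] to the frozen-parameter stationary state, whose excess free energy
is F - F_s = D K.

Everything exists in two routes: a numeric pipeline driven by grid
quadrature on snapshots, and closed forms for Gaussian (O-U) trajectories.
The two routes are kept independent so they can cross-check each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .distances import kl_divergence
from .grids import GaussianState, GridPDF, gaussian_entropy, gaussian_to_grid
from .info_geom import PDFTrajectory, _dt_central, information_rate_numeric
from .processes import (
    FPSolution,
    ProcessSpec,
    ou_propagate,
    ou_state_derivatives,
    probability_current_values,
)

__all__ = [
    "ThermoSeries",
    "thermo_gaussian",
    "thermo_numeric",
    "stationary_state",
    "stationary_free_energy",
    "gamma_identities",
    "micro_free_energy_checks",
    "inequality_suite",
]

#: entropy-production integrand is evaluated only where p exceeds this
P_FLOOR = 1e-14


@dataclass
class ThermoSeries:
    """Per-time thermodynamic functionals along one trajectory."""

    times: np.ndarray
    S: np.ndarray
    Sdot: np.ndarray
    ST_dot: np.ndarray
    Sm_dot: np.ndarray
    Qdot: np.ndarray
    U: np.ndarray
    Wdot: np.ndarray
    W: np.ndarray
    F: np.ndarray | None = None
    Fdot: np.ndarray | None = None
    WD_dot: np.ndarray | None = None
    K_s: np.ndarray | None = None
    dK_dt: np.ndarray | None = None
    Wirr_dot: np.ndarray | None = None
    gamma: np.ndarray | None = None
    sigma: np.ndarray | None = None
    c_fluct: np.ndarray | None = None
    residuals: dict = field(default_factory=dict)


def _cumtrapz(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(t))])


# ---------------------------------------------------------------------------
# Closed-form Gaussian pipeline


def thermo_gaussian(
    spec: ProcessSpec,
    states: Sequence[GaussianState] | None = None,
    init: GaussianState | None = None,
    times: Sequence[float] | None = None,
    with_stationary: bool | None = None,
) -> ThermoSeries:
    """Exact thermodynamic series along a Gaussian O-U trajectory.

    Either precomputed ``states`` or ``(init, times)`` must be given.  The
    stationary-reference block (K_s, its rate, irreversible work) requires
    constant gamma and D and is included automatically in that case.
    """
    if states is None:
        if init is None or times is None:
            raise ValueError("need states or (init, times)")
        states = ou_propagate(spec, init, times)
    t = np.array([s.t for s in states])
    n = len(states)
    y = np.empty(n); sig = np.empty(n); yd = np.empty(n); sd = np.empty(n)
    for i, s in enumerate(states):
        y[i], sig[i], yd[i], sd[i] = ou_state_derivatives(spec, s)
    beta = 1.0 / (2 * sig**2)
    D = np.array([spec.D_at(float(tk)) for tk in t])
    if np.any(D <= 0):
        raise ValueError("thermo closed forms require D > 0")
    g = np.array([spec.gamma_at(float(tk)) for tk in t])
    v = np.array([spec.v_at(float(tk)) for tk in t])
    vdot = np.array([spec.vdot_at(float(tk)) for tk in t])
    gdot = np.array([spec.gammadot_at(float(tk)) for tk in t])

    S = 0.5 * (1 + np.log(np.pi / beta))
    Sdot = sd / sig
    ST_dot = (sd**2 + yd**2) / D
    Sm_dot = ST_dot - Sdot
    Qdot = D * Sm_dot
    U = 0.5 * g * (sig**2 + (y - v) ** 2)
    Wdot = 0.5 * gdot * (sig**2 + (y - v) ** 2) - g * vdot * (y - v)
    W = _cumtrapz(Wdot, t)
    gamma_info = np.sqrt((2 * sd**2 + yd**2) / sig**2)
    series = ThermoSeries(
        t, S, Sdot, ST_dot, Sm_dot, Qdot, U, Wdot, W,
        gamma=gamma_info, sigma=sig, c_fluct=sig * gamma_info,
    )
    D_const = not callable(spec.D)
    if D_const:
        Dc = float(spec.D)
        series.F = U - Dc * S
        series.Fdot = Wdot - Dc * ST_dot
        series.WD_dot = Dc * ST_dot
    if with_stationary is None:
        with_stationary = spec.constant_coefficients and float(spec.D) > 0
    if with_stationary:
        beta_s = spec.beta_s
        series.K_s = (
            0.5 * (np.log(beta / beta_s) - 1.0)
            + beta_s * ((y - v) ** 2 + 1.0 / (2 * beta))
        )
        series.dK_dt = -ST_dot + Wdot / D    # valid while beta_s (hence F_s) is frozen
        series.Wirr_dot = D * ST_dot + D * series.dK_dt
    return series


def free_energy_series(
    traj: PDFTrajectory | FPSolution | ThermoSeries, spec: ProcessSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(F, Fdot, WD_dot) of a trajectory; F = U - D S with D the effective
    temperature.  A time-varying D has no single effective temperature and
    raises rather than silently misreporting."""
    if callable(spec.D):
        raise ValueError(
            "free energy F = U - D*S assumes a constant D (effective temperature); "
            "time-varying D is not supported"
        )
    series = traj if isinstance(traj, ThermoSeries) else thermo_numeric(traj, spec)
    return series.F, series.Fdot, series.WD_dot


def stationary_state(spec: ProcessSpec, t: float = 0.0) -> GaussianState:
    """Frozen-parameter stationary Gaussian, centered on v(t) with beta_s."""
    return GaussianState(spec.v_at(t), spec.beta_s, t=t)


def stationary_free_energy(spec: ProcessSpec, t: float = 0.0) -> float:
    """F_s = -D ln Z for the frozen O-U potential."""
    D, g = float(spec.D), spec.gamma_at(t)
    return float(-0.5 * D * np.log(2 * np.pi * D / g))


# ---------------------------------------------------------------------------
# Numeric pipeline on grid snapshots


def thermo_numeric(
    traj: PDFTrajectory | FPSolution,
    spec: ProcessSpec,
    with_stationary: bool | None = None,
) -> ThermoSeries:
    """Thermodynamic series from grid snapshots by quadrature.

    Currents use ``J = f p - D dp/dx`` (re-derived unless an
    :class:`FPSolution` already carries them); scalar time derivatives use
    second-order finite differences on the trajectory's time grid.
    Free-energy outputs require a constant D; a time-varying D raises.
    """
    currents = None
    if isinstance(traj, FPSolution):
        currents = traj.currents
        traj = traj.traj
    t = traj.times
    x, dx = traj.grid.x, traj.grid.dx
    dens = traj.densities
    nt = len(t)
    D_vals = np.array([spec.D_at(float(tk)) for tk in t])
    if np.any(D_vals <= 0):
        raise ValueError("entropy production undefined for D = 0 with nonzero current")

    if currents is None:
        currents = np.stack(
            [
                probability_current_values(
                    x, dx, dens[k], spec.drift(x, float(t[k])), D_vals[k]
                )
                for k in range(nt)
            ]
        )

    S = np.empty(nt); ST = np.empty(nt); Sm = np.empty(nt)
    U = np.empty(nt); Wd = np.empty(nt); Qd = np.empty(nt)
    sigma = np.empty(nt)
    for k in range(nt):
        p = dens[k]
        tk = float(t[k])
        mask = p > P_FLOOR
        S[k] = -np.trapezoid(np.where(mask, p * np.log(np.where(mask, p, 1.0)), 0.0), dx=dx)
        J = currents[k]
        integ = np.where(mask, J**2 / (D_vals[k] * np.where(mask, p, 1.0)), 0.0)
        ST[k] = np.trapezoid(integ, dx=dx)
        f = spec.drift(x, tk)
        Qd[k] = np.trapezoid(J * f, dx=dx)
        Sm[k] = Qd[k] / D_vals[k]
        V = spec.potential(x, tk)
        U[k] = np.trapezoid(V * p, dx=dx)
        Wd[k] = np.trapezoid(spec.potential_rate(x, tk) * p, dx=dx)
        mean = np.trapezoid(x * p, dx=dx)
        sigma[k] = np.sqrt(np.trapezoid((x - mean) ** 2 * p, dx=dx))

    h = traj.dt
    Sdot = _dt_central(S, h)
    Udot = _dt_central(U, h)
    W = _cumtrapz(Wd, t)
    info = information_rate_numeric(traj)
    series = ThermoSeries(
        t, S, Sdot, ST, Sm, Qd, U, Wd, W,
        gamma=info.gamma, sigma=sigma, c_fluct=sigma * info.gamma,
    )
    series.residuals["entropy_decomposition"] = float(
        np.max(np.abs(Sdot - (ST - Sm)))
    )
    series.residuals["first_law"] = float(np.max(np.abs(Udot - (Wd - Qd))))

    if callable(spec.D):
        series.residuals["free_energy_skipped"] = "time-varying D"
        return series
    Dc = float(spec.D)
    series.F = U - Dc * S
    series.Fdot = _dt_central(series.F, h)
    series.WD_dot = Wd - series.Fdot
    series.residuals["dissipated_power"] = float(
        np.max(np.abs(series.WD_dot - Dc * ST))
    )
    if with_stationary is None:
        with_stationary = spec.constant_coefficients and Dc > 0
    if with_stationary:
        beta_s = spec.beta_s
        K = np.empty(nt)
        for k in range(nt):
            ps = gaussian_to_grid(
                GaussianState(spec.v_at(float(t[k])), beta_s), traj.grid
            )
            K[k] = kl_divergence(traj.snapshot(k), ps)
        series.K_s = K
        series.dK_dt = _dt_central(K, h)
        series.Wirr_dot = Dc * ST + Dc * series.dK_dt
        Fs = stationary_free_energy(spec)
        series.residuals["excess_free_energy"] = float(
            np.max(np.abs(series.F - Fs - Dc * K))
        )
    return series


# ---------------------------------------------------------------------------
# Gamma-based identities and bounds (closed-form Gaussian route)


@dataclass(frozen=True)
class IdentityReport:
    times: np.ndarray
    eq_rate_split_rel: np.ndarray      # Gamma^2 = (D/sigma^2) ST_dot + Sdot^2
    eq_speed_rel: np.ndarray           # c = sigma Gamma = sqrt(D ST_dot + sigma^2 Sdot^2)
    proportionality_rel: np.ndarray    # Gamma^2 vs D ST_dot / sigma^2 (exact iff sigmadot=0)
    L_mean_rule: float | None          # L = |Delta<x>|/sigma when sigmadot = 0
    max_rate_split_rel: float
    max_speed_rel: float


def gamma_identities(
    spec: ProcessSpec,
    init: GaussianState,
    times: Sequence[float],
) -> IdentityReport:
    """Residuals of the exact Gamma/thermodynamics identities on a Gaussian path."""
    series = thermo_gaussian(spec, init=init, times=times, with_stationary=False)
    t = series.times
    D = np.array([spec.D_at(float(tk)) for tk in t])
    g2 = series.gamma**2
    rhs = D * series.ST_dot / series.sigma**2 + series.Sdot**2
    scale = np.maximum(g2, 1e-30)
    split = np.abs(g2 - rhs) / scale
    c_rhs = np.sqrt(D * series.ST_dot + series.sigma**2 * series.Sdot**2)
    speed = np.abs(series.c_fluct - c_rhs) / np.maximum(series.c_fluct, 1e-30)
    prop = np.abs(g2 - D * series.ST_dot / series.sigma**2) / scale

    L_rule = None
    sd = series.Sdot * series.sigma  # sigmadot
    if np.max(np.abs(sd)) < 1e-12:
        states = ou_propagate(spec, init, times)
        L = _cumtrapz(series.gamma, t)[-1]
        L_rule = float(
            abs(L - abs(states[-1].y - states[0].y) / series.sigma[0])
        )
    return IdentityReport(
        t, split, speed, prop, L_rule, float(split.max()), float(speed.max())
    )


@dataclass(frozen=True)
class MicroFreeEnergyReport:
    power_rel: float        # <d(mu)/dt> vs Wdot
    gamma_rel: float        # <(d mu/dt - dV/dt)^2> vs D^2 Gamma^2
    entropy_rel: float      # -∫ mu pdot dx vs D ST_dot


def micro_free_energy_checks(
    traj: PDFTrajectory | FPSolution, spec: ProcessSpec
) -> MicroFreeEnergyReport:
    """Numeric residuals of the microscopic free-energy identities.

    mu = V + D ln p is the microscopic free energy; the checks are
    ``<dmu/dt> = Wdot``, ``<(dmu/dt - dV/dt)^2> = D^2 Gamma^2`` and
    ``-∫ mu pdot dx = D ST_dot``, all evaluated at interior times.
    """
    series = thermo_numeric(traj, spec, with_stationary=False)
    if isinstance(traj, FPSolution):
        traj = traj.traj
    t, dens, dx, x = traj.times, traj.densities, traj.grid.dx, traj.grid.x
    h = traj.dt
    pdot = _dt_central(dens, h)
    Dv = np.array([spec.D_at(float(tk)) for tk in t])
    g2 = series.gamma**2
    pr, gr, er = [], [], []
    for k in range(1, len(t) - 1):
        p = dens[k]
        mask = p > P_FLOOR
        tk = float(t[k])
        dVdt = spec.potential_rate(x, tk)
        mu_dot = dVdt + Dv[k] * np.where(mask, pdot[k] / np.where(mask, p, 1.0), 0.0)
        lhs = np.trapezoid(mu_dot * p, dx=dx)
        pr.append(abs(lhs - series.Wdot[k]) / max(abs(series.Wdot[k]), 1.0))
        fluct = np.trapezoid(
            np.where(mask, pdot[k] ** 2 / np.where(mask, p, 1.0), 0.0), dx=dx
        )
        gr.append(
            abs(Dv[k] ** 2 * fluct - Dv[k] ** 2 * g2[k])
            / max(Dv[k] ** 2 * g2[k], 1e-30)
        )
        V = spec.potential(x, tk)
        mu = np.where(mask, V + Dv[k] * np.log(np.where(mask, p, 1.0)), 0.0)
        lhs3 = -np.trapezoid(np.where(mask, mu * pdot[k], 0.0), dx=dx)
        er.append(
            abs(lhs3 - Dv[k] * series.ST_dot[k]) / max(Dv[k] * series.ST_dot[k], 1e-12)
        )
    return MicroFreeEnergyReport(float(max(pr)), float(max(gr)), float(max(er)))


@dataclass(frozen=True)
class InequalityReport:
    times: np.ndarray
    margin_entropy: np.ndarray    # Gamma/sqrt(2) - |Sdot|
    margin_heat: np.ndarray       # Gamma sigma sqrt(ydot^2 + g^2 s^2/2) - |Qdot|
    margin_production: np.ndarray # Gamma sigma sqrt(ydot^2 + sdot^2/2) - D ST_dot
    all_hold: bool
    saturation_production: np.ndarray  # relative gap of the ST bound


def inequality_suite(
    spec: ProcessSpec,
    init: GaussianState,
    times: Sequence[float],
    tol: float = 1e-12,
) -> InequalityReport:
    """Schwartz-inequality bounds on Sdot, Qdot and ST_dot for an O-U path.

    The production bound saturates exactly when sigmadot = 0 or ydot = 0.
    """
    states = ou_propagate(spec, init, times)
    t = np.array([s.t for s in states])
    y = np.empty_like(t); sig = np.empty_like(t)
    yd = np.empty_like(t); sd = np.empty_like(t)
    for i, s in enumerate(states):
        y[i], sig[i], yd[i], sd[i] = ou_state_derivatives(spec, s)
    D = np.array([spec.D_at(float(tk)) for tk in t])
    g = np.array([spec.gamma_at(float(tk)) for tk in t])
    gamma_info = np.sqrt((2 * sd**2 + yd**2) / sig**2)
    Sdot = sd / sig
    DST = sd**2 + yd**2
    Qdot = DST - D * Sdot

    m1 = gamma_info / np.sqrt(2) - np.abs(Sdot)
    m2 = gamma_info * sig * np.sqrt(yd**2 + g**2 * sig**2 / 2) - np.abs(Qdot)
    m3 = gamma_info * sig * np.sqrt(yd**2 + sd**2 / 2) - DST
    scale = np.maximum.reduce([gamma_info**2, np.ones_like(t)])
    holds = bool(
        np.all(m1 >= -tol * scale) and np.all(m2 >= -tol * scale)
        and np.all(m3 >= -tol * scale)
    )
    sat = m3 / np.maximum(DST, 1e-30)
    return InequalityReport(t, m1, m2, m3, holds, sat)
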