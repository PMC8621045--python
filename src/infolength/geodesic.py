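"""Minimum-information-length geodesics of the Gaussian statistical manifold.

For Gaussian densities with mean y and inverse temperature beta (variance
sigma^2 = 1/(2 beta)), the information-rate line element

    Gamma^2 dt^2 = [2 sigmadot^2 + ydot^2] / sigma^2 dt^2
                 = 2 (dz^2 + dsigma^2) / sigma^2,   z = y / sqrt(2),

is twice the Poincaré upper-half-plane metric in (z, sigma).  Paths of
minimum L = ∫ Gamma dt are therefore hyperbolic geodesics — arcs of circles
centered on the sigma = 0 axis, traversed at constant Gamma — and the
closed-form solution is

    beta(t) = (4 c^2 / alpha) cosh^2(theta),  theta = (sqrt(alpha)/2)(t - A),
    y(t)    = sqrt(2) [z_c + s R tanh(theta)],
    Gamma   = sqrt(alpha/2),   beta ydot = c,   R = Gamma / (2 |c|),

with the circle invariant (z - z_c)^2 + sigma^2 = R^2.  Vertical geodesics
(c = 0, pure variance change) have beta(t) = beta0 exp(+-sqrt(alpha) t) and
L = sqrt(2) |ln(sigma_F/sigma_0)|.

Given constant damping gamma, the controls that realize a geodesic follow by
inverting the O-U moment dynamics:

    v(t) = y + ydot / gamma,     D(t) = gamma sigma^2 + sigma sigmadot,

feasible whenever the right-hand side of D stays non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids import GaussianState

__all__ = [
    "GeodesicBC",
    "GeodesicSolution",
    "ControlProtocol",
    "solve_geodesic",
    "geodesic_path",
    "hyperbolic_length",
    "synthesize_controls",
    "verify_minimality",
    "InfeasibleProtocolError",
]

#: |c| below this multiple of sqrt(alpha) selects the vertical-geodesic branch
VERTICAL_TOL = 1e-12


class InfeasibleProtocolError(ValueError):
    """The geodesic demands a negative noise amplitude for the given gamma."""


@dataclass(frozen=True)
class GeodesicBC:
    """Endpoint conditions (y0, beta0) at t0 and (yF, betaF) at tF."""

    y0: float
    beta0: float
    yF: float
    betaF: float
    t0: float = 0.0
    tF: float = 1.0

    def __post_init__(self) -> None:
        if self.beta0 <= 0 or self.betaF <= 0:
            raise ValueError("beta must be positive at both endpoints")
        if not self.tF > self.t0:
            raise ValueError("tF must exceed t0")

    @property
    def sigma0(self) -> float:
        return 1.0 / np.sqrt(2 * self.beta0)

    @property
    def sigmaF(self) -> float:
        return 1.0 / np.sqrt(2 * self.betaF)


def hyperbolic_length(bc: GeodesicBC) -> float:
    """L_geo = sqrt(2) arccosh[1 + (dz^2 + dsigma^2)/(2 sigma0 sigmaF)]."""
    dz = (bc.yF - bc.y0) / np.sqrt(2)
    ds = bc.sigmaF - bc.sigma0
    arg = 1.0 + (dz**2 + ds**2) / (2 * bc.sigma0 * bc.sigmaF)
    return float(np.sqrt(2) * np.arccosh(arg))


@dataclass(frozen=True)
class GeodesicSolution:
    """Constants and circle data of a solved geodesic."""

    bc: GeodesicBC
    L: float
    Gamma: float
    alpha: float
    c: float
    A: float | None          # time of the sigma apex (c != 0 branch)
    B: float | None
    z_c: float | None
    R: float | None
    s: int                   # sign of c
    degenerate: bool = False # identical endpoints: zero-length solution

    @property
    def vertical(self) -> bool:
        return self.c == 0.0 and not self.degenerate

    def state(self, t: float) -> GaussianState:
        return geodesic_path(self, [t])[0]

    def y_sigma_dot(self, t: np.ndarray):
        """(y, sigma, ydot, sigmadot) arrays along the geodesic."""
        t = np.asarray(t, dtype=float)
        bc = self.bc
        if self.degenerate:
            z = np.zeros_like(t)
            return bc.y0 + z, bc.sigma0 + z, z, z
        if self.vertical:
            k = np.log(bc.sigmaF / bc.sigma0) / (bc.tF - bc.t0)
            sig = bc.sigma0 * np.exp(k * (t - bc.t0))
            return bc.y0 + 0 * t, sig, 0 * t, k * sig
        half = 0.5 * np.sqrt(self.alpha)
        th = half * (t - self.A)
        sech = 1.0 / np.cosh(th)
        sig = self.R * sech
        y = np.sqrt(2) * (self.z_c + self.s * self.R * np.tanh(th))
        ydot = np.sqrt(2) * self.s * self.R * half * sech**2
        sigdot = -self.R * half * sech * np.tanh(th)
        return y, sig, ydot, sigdot


def solve_geodesic(bc: GeodesicBC) -> GeodesicSolution:
    """Constructive geodesic solver via the half-plane circle.

    Maps the endpoints to (z, sigma) = (y/sqrt(2), sigma); if z0 != zF the
    unique circle centered on the real axis through both points gives the
    center, radius and hyperbolic length, from which all constants
    (c, alpha, A, B) follow in closed form.  z0 = zF selects the vertical
    (pure variance change) branch.
    """
    z0, zF = bc.y0 / np.sqrt(2), bc.yF / np.sqrt(2)
    s0, sF = bc.sigma0, bc.sigmaF
    T = bc.tF - bc.t0

    if abs(zF - z0) < 1e-14 * max(1.0, abs(z0)) and abs(sF - s0) < 1e-14 * s0:
        return GeodesicSolution(bc, 0.0, 0.0, 0.0, 0.0, None, None, None,
                                None, 0, degenerate=True)

    L = hyperbolic_length(bc)
    Gamma = L / T
    alpha = 2 * Gamma**2

    if abs(zF - z0) < VERTICAL_TOL * max(np.sqrt(alpha), 1.0):
        return GeodesicSolution(bc, L, Gamma, alpha, 0.0, None, None, None,
                                None, 0)

    z_c = (z0**2 + s0**2 - zF**2 - sF**2) / (2 * (z0 - zF))
    R = float(np.hypot(z0 - z_c, s0))
    s = 1 if zF > z0 else -1
    c = s * Gamma / (2 * R)
    # theta at t0 from tanh(theta0) = (z0 - z_c)/(s R)
    th0 = float(np.arctanh(np.clip((z0 - z_c) / (s * R), -1 + 1e-16, 1 - 1e-16)))
    A = bc.t0 - th0 / (0.5 * np.sqrt(alpha))
    B = float(np.sqrt(2) * (z_c + s * R))
    return GeodesicSolution(bc, L, Gamma, alpha, float(c), float(A), B,
                            float(z_c), R, s)


def geodesic_path(sol: GeodesicSolution, times: Sequence[float]) -> list[GaussianState]:
    """Gaussian states along the geodesic at the requested times."""
    t = np.asarray(times, dtype=float)
    y, sig, _, _ = sol.y_sigma_dot(t)
    return [
        GaussianState(float(yi), 1.0 / (2 * si**2), t=float(ti))
        for yi, si, ti in zip(y, sig, t)
    ]


@dataclass
class ControlProtocol:
    """Time-dependent controls (D(t), v(t)) at fixed damping gamma."""

    sol: GeodesicSolution
    gamma: float
    D_min: float
    gamma_min: float

    def v(self, t):
        y, _, ydot, _ = self.sol.y_sigma_dot(np.asarray(t, dtype=float))
        return y + ydot / self.gamma

    def D(self, t):
        _, sig, _, sigdot = self.sol.y_sigma_dot(np.asarray(t, dtype=float))
        return self.gamma * sig**2 + sig * sigdot


def synthesize_controls(
    sol: GeodesicSolution, gamma: float = 1.0, n_check: int = 2001
) -> ControlProtocol:
    """Controls D(t) >= 0 and v(t) that drive the O-U process along ``sol``.

    Inverts the exact moment dynamics at constant gamma.  If the geodesic
    would require negative diffusion, raises
    :class:`InfeasibleProtocolError` naming the minimal feasible gamma
    (``max_t(-sigmadot/sigma)``).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    tt = np.linspace(sol.bc.t0, sol.bc.tF, n_check)
    _, sig, _, sigdot = sol.y_sigma_dot(tt)
    gamma_min = float(np.max(-sigdot / sig))
    D = gamma * sig**2 + sig * sigdot
    D_min = float(D.min())
    if D_min < 0:
        raise InfeasibleProtocolError(
            f"geodesic requires D(t) < 0 for gamma={gamma}; "
            f"need gamma > {gamma_min:.6g}"
        )
    return ControlProtocol(sol, gamma, D_min, gamma_min)


@dataclass(frozen=True)
class MinimalityReport:
    L_geo: float
    perturbed_lengths: np.ndarray
    min_excess: float
    reparam_L: float
    reparam_action: float      # ∫ E dt of the reparametrized track
    geodesic_action: float     # ∫ E dt of the constant-speed geodesic


def _discrete_length(t: np.ndarray, y: np.ndarray, sig: np.ndarray) -> float:
    """Trapezoid ∫ Gamma dt for a sampled Gaussian path (midpoint form)."""
    dy, dsig = np.diff(y), np.diff(sig)
    smid = 0.5 * (sig[1:] + sig[:-1])
    return float(np.sum(np.sqrt(2 * dsig**2 + dy**2) / smid))


def verify_minimality(
    sol: GeodesicSolution,
    n_perturbations: int = 200,
    seed: int = 0,
    amplitude: float = 0.05,
    n_t: int = 2001,
) -> MinimalityReport:
    """Variational check: endpoint-preserving perturbations never shorten L.

    Random smooth sine-mode perturbations of (y(t), sigma(t)) are applied and
    each perturbed discrete length compared against L_geo.  A time
    reparametrization of the geodesic track keeps L but raises the action
    ∫ E dt (the Cauchy-Schwarz equality case singles out constant Gamma).
    """
    rng = np.random.default_rng([int(seed), 17])
    bc = sol.bc
    t = np.linspace(bc.t0, bc.tF, n_t)
    y, sig, _, _ = sol.y_sigma_dot(t)
    s_unit = np.linspace(0.0, 1.0, n_t)
    lengths = np.empty(n_perturbations)
    for i in range(n_perturbations):
        dy = np.zeros(n_t)
        dsig = np.zeros(n_t)
        for mode in range(1, 4):
            dy += rng.normal(0, amplitude) * np.sin(np.pi * mode * s_unit)
            dsig += rng.normal(0, amplitude) * np.sin(np.pi * mode * s_unit)
        sig_pert = sig + dsig
        if np.any(sig_pert <= 1e-6):
            sig_pert = np.clip(sig_pert, 1e-6, None)
        lengths[i] = _discrete_length(t, y + dy, sig_pert)
    # same geometric track traversed at non-uniform speed: at uniform times t
    # visit the geodesic state at warped arc fraction w(s).  L is unchanged
    # while the action ∫ E dt exceeds L^2/T (Cauchy-Schwarz equality case).
    T = bc.tF - bc.t0
    warp = s_unit + 0.15 * np.sin(np.pi * s_unit) ** 2
    warp /= warp[-1]
    yw, sw, _, _ = sol.y_sigma_dot(bc.t0 + T * warp)
    Lw = _discrete_length(t, yw, sw)
    dyw, dsw = np.diff(yw), np.diff(sw)
    smid = 0.5 * (sw[1:] + sw[:-1])
    dt = np.diff(t)
    action_w = float(np.sum((2 * dsw**2 + dyw**2) / smid**2 / dt))
    return MinimalityReport(
        sol.L,
        lengths,
        float(lengths.min() - sol.L),
        Lw,
        action_w,
        sol.Gamma**2 * T,
    )
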