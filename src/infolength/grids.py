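"""Grid-based probability densities and Gaussian states.

A :class:`GridPDF` is a normalized density sampled on a uniform 1-D grid; it is
the common currency of every numeric operation in the package.  A
:class:`GaussianState` carries the closed-form side: a mean ``y`` and an inverse
temperature ``beta`` with variance ``sigma**2 = 1/(2*beta)`` (units ``k_B = 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Grid1D",
    "GridPDF",
    "GaussianState",
    "GridMismatchError",
    "GridTooNarrowError",
    "gaussian_to_grid",
    "moments",
    "differential_entropy",
    "gaussian_entropy",
]

#: densities below this are treated as true zeros (0*log 0 := 0)
ZERO_TOL = 1e-300


class GridMismatchError(ValueError):
    """Two densities do not live on the same grid."""


class GridTooNarrowError(ValueError):
    """The grid does not cover enough of the distribution's mass."""


@dataclass(frozen=True)
class Grid1D:
    """Uniform 1-D grid on ``[x_min, x_max]`` with ``n_points`` nodes."""

    x_min: float
    x_max: float
    n_points: int

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min:
            raise ValueError("x_max must exceed x_min")
        if self.n_points < 16:
            raise ValueError("need at least 16 grid nodes")

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / (self.n_points - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n_points)

    def same_as(self, other: "Grid1D") -> bool:
        return (
            self.n_points == other.n_points
            and np.isclose(self.x_min, other.x_min, rtol=0, atol=1e-12)
            and np.isclose(self.x_max, other.x_max, rtol=0, atol=1e-12)
        )


@dataclass
class GridPDF:
    """A normalized probability density on a :class:`Grid1D`.

    ``p`` must be non-negative and integrate to one (trapezoid rule) within
    1e-8 unless ``normalize=True`` is passed, in which case the density is
    rescaled once at construction.
    """

    grid: Grid1D
    p: np.ndarray
    t: float | None = None
    normalize: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.grid.n_points,):
            raise ValueError("density shape does not match the grid")
        if np.any(self.p < 0):
            if self.p.min() < -1e-12:
                raise ValueError(f"negative density (min {self.p.min():.3e})")
            self.p = np.clip(self.p, 0.0, None)
        mass = float(np.trapezoid(self.p, dx=self.grid.dx))
        if self.normalize:
            if mass <= 0:
                raise ValueError("cannot normalize a zero density")
            self.p = self.p / mass
        elif abs(mass - 1.0) > 1e-8:
            raise ValueError(f"density not normalized: integral = {mass!r}")

    @property
    def x(self) -> np.ndarray:
        return self.grid.x

    @property
    def q(self) -> np.ndarray:
        """Amplitude ``q = sqrt(p)`` (well-defined where the density vanishes)."""
        return np.sqrt(self.p)

    def integrate(self, values: np.ndarray) -> float:
        """Trapezoid quadrature of ``values`` over the grid."""
        return float(np.trapezoid(values, dx=self.grid.dx))

    def expect(self, values: np.ndarray) -> float:
        """Ensemble average of node values against this density."""
        return self.integrate(values * self.p)


@dataclass(frozen=True)
class GaussianState:
    """Gaussian PDF parameters: mean ``y`` and inverse temperature ``beta``.

    Variance is ``1/(2*beta)``; ``beta`` plays the role of an inverse
    temperature with ``k_B = 1``.
    """

    y: float
    beta: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("beta must be positive")

    @property
    def variance(self) -> float:
        return 1.0 / (2.0 * self.beta)

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.variance))

    def density(self, x: np.ndarray) -> np.ndarray:
        return np.sqrt(self.beta / np.pi) * np.exp(-self.beta * (x - self.y) ** 2)

    def at_time(self, t: float) -> "GaussianState":
        return replace(self, t=t)


def default_grid(states, n_points: int = 2048, n_sigma: float = 8.0) -> Grid1D:
    """Grid covering every state's mean within ``n_sigma`` standard deviations."""
    states = list(states)
    lo = min(s.y - n_sigma * s.sigma for s in states)
    hi = max(s.y + n_sigma * s.sigma for s in states)
    return Grid1D(lo, hi, n_points)


def gaussian_to_grid(state: GaussianState, grid: Grid1D) -> GridPDF:
    """Sample a Gaussian state on a grid and renormalize.

    Raises :class:`GridTooNarrowError` unless the grid spans at least
    ``[y - 6*sigma, y + 6*sigma]`` (truncation would bias the integrals
    otherwise).
    """
    lo, hi = state.y - 6 * state.sigma, state.y + 6 * state.sigma
    if grid.x_min > lo or grid.x_max < hi:
        raise GridTooNarrowError(
            f"grid [{grid.x_min}, {grid.x_max}] does not cover [{lo:.4g}, {hi:.4g}]"
        )
    return GridPDF(grid, state.density(grid.x), t=state.t, normalize=True)


def moments(pdf: GridPDF) -> tuple[float, float, float]:
    """Mean, variance and fourth central moment by trapezoid quadrature."""
    x = pdf.x
    mean = pdf.expect(x)
    dx = x - mean
    var = pdf.expect(dx**2)
    m4 = pdf.expect(dx**4)
    return mean, var, m4


def differential_entropy(pdf: GridPDF) -> float:
    """Differential entropy ``-∫ p ln p dx`` with the 0*ln 0 = 0 convention."""
    p = pdf.p
    integrand = np.zeros_like(p)
    mask = p > ZERO_TOL
    integrand[mask] = -p[mask] * np.log(p[mask])
    return pdf.integrate(integrand)


def gaussian_entropy(state: GaussianState) -> float:
    """Closed-form Gaussian entropy ``S = (1 + ln(pi/beta)) / 2``."""
    return 0.5 * (1.0 + np.log(np.pi / state.beta))
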