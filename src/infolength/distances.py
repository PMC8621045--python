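"""Distances between two probability densities on a shared grid.

Four two-PDF distances are provided: the Wootters (Hilbert-space angle)
distance, the Kullback-Leibler divergence (relative entropy), its symmetrized
Jensen form, and the squared Euclidean (L2) norm.  The squared-norm convention
is canonical for ``l2_distance``; the rooted variant is exposed separately.

Closed-form Gaussian expressions are included as independent cross-checks for
the grid quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ZERO_TOL, GaussianState, GridMismatchError, GridPDF

__all__ = [
    "DistanceReport",
    "wootters_distance",
    "kl_divergence",
    "jensen_divergence",
    "l2_distance",
    "l2_distance_rooted",
    "all_distances",
    "gaussian_kl",
    "gaussian_bhattacharyya",
    "gaussian_wootters",
    "gaussian_l2",
]


def _check_shared(p1: GridPDF, p2: GridPDF) -> None:
    if not p1.grid.same_as(p2.grid):
        raise GridMismatchError("densities live on different grids")


def kl_divergence(p1: GridPDF, p2: GridPDF) -> float:
    """Relative entropy ``K(p1|p2) = ∫ p1 ln(p1/p2) dx``.

    Nodes with ``p1 = 0`` contribute zero; if ``p1`` has support where ``p2``
    vanishes the divergence is ``+inf``.
    """
    _check_shared(p1, p2)
    a, b = p1.p, p2.p
    support = a > ZERO_TOL
    if np.any(support & (b <= ZERO_TOL)):
        return float("inf")
    integrand = np.zeros_like(a)
    integrand[support] = a[support] * np.log(a[support] / b[support])
    val = p1.integrate(integrand)
    # Gibbs' inequality guarantees K >= 0; quadrature roundoff may dip epsilon-negative
    return 0.0 if -1e-10 < val < 0.0 else val


def jensen_divergence(p1: GridPDF, p2: GridPDF) -> float:
    """Symmetrized Kullback-Leibler divergence ``(K(p1|p2)+K(p2|p1))/2``."""
    return 0.5 * (kl_divergence(p1, p2) + kl_divergence(p2, p1))


def wootters_distance(p1: GridPDF, p2: GridPDF) -> float:
    """Hilbert-space angle ``arccos ∫ sqrt(p1 p2) dx`` in ``[0, pi/2]``."""
    _check_shared(p1, p2)
    inner = p1.integrate(np.sqrt(p1.p * p2.p))
    return float(np.arccos(np.clip(inner, 0.0, 1.0)))


def l2_distance(p1: GridPDF, p2: GridPDF) -> float:
    """Squared Euclidean norm ``∫ (p1-p2)^2 dx`` (squared convention)."""
    _check_shared(p1, p2)
    return p1.integrate((p1.p - p2.p) ** 2)


def l2_distance_rooted(p1: GridPDF, p2: GridPDF) -> float:
    """Square root of :func:`l2_distance`, for users preferring a true norm."""
    return float(np.sqrt(l2_distance(p1, p2)))


@dataclass(frozen=True)
class DistanceReport:
    """All four distances between one pair of densities."""

    wootters: float
    kl_forward: float
    kl_backward: float
    jensen: float
    l2: float


def all_distances(p1: GridPDF, p2: GridPDF) -> DistanceReport:
    kf = kl_divergence(p1, p2)
    kb = kl_divergence(p2, p1)
    return DistanceReport(
        wootters=wootters_distance(p1, p2),
        kl_forward=kf,
        kl_backward=kb,
        jensen=0.5 * (kf + kb),
        l2=l2_distance(p1, p2),
    )


# ---------------------------------------------------------------------------
# Gaussian closed forms (independent oracles for the grid quadrature)

def gaussian_kl(s1: GaussianState, s2: GaussianState) -> float:
    """``K(N(y1,σ1²) | N(y2,σ2²)) = ln(σ2/σ1) + (σ1² + Δy²)/(2σ2²) − 1/2``."""
    v1, v2 = s1.variance, s2.variance
    return float(
        0.5 * np.log(v2 / v1) + (v1 + (s1.y - s2.y) ** 2) / (2 * v2) - 0.5
    )


def gaussian_bhattacharyya(s1: GaussianState, s2: GaussianState) -> float:
    """Bhattacharyya coefficient ``∫ sqrt(p1 p2) dx`` for two Gaussians."""
    v1, v2 = s1.variance, s2.variance
    pref = np.sqrt(2 * np.sqrt(v1 * v2) / (v1 + v2))
    return float(pref * np.exp(-((s1.y - s2.y) ** 2) / (4 * (v1 + v2))))


def gaussian_wootters(s1: GaussianState, s2: GaussianState) -> float:
    return float(np.arccos(np.clip(gaussian_bhattacharyya(s1, s2), 0.0, 1.0)))


def gaussian_l2(s1: GaussianState, s2: GaussianState) -> float:
    """Squared L2 distance between two Gaussians via Gaussian product integrals."""

    def cross(va: float, vb: float, dy: float) -> float:
        return float(
            np.exp(-(dy**2) / (2 * (va + vb))) / np.sqrt(2 * np.pi * (va + vb))
        )

    v1, v2, dy = s1.variance, s2.variance, s1.y - s2.y
    return cross(v1, v1, 0.0) + cross(v2, v2, 0.0) - 2 * cross(v1, v2, dy)
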