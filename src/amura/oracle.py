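"""Brute-force quadrature oracles for the single-shell return probabilities.

Given an arbitrary strictly positive ADC function ``D(u)`` on the unit
sphere, the apparent measures are defined by radial Gaussian integrals
that reduce to (see docs/methods.md for the derivation):

* RTOP: ``sqrt(pi)/4 * (4 pi^2 tau)^-3/2 * Int_S D(u)^-3/2 dS``
* RTPP: ``(4 pi tau D(r0))^-1/2`` at the maximum-diffusion direction r0
* RTAP: ``(8 pi^2 tau)^-1 * Int_0^2pi D(theta')^-1 dtheta'`` on the
  equator normal to r0

This module evaluates those integrals directly — product Gauss-Legendre
x trapezoid quadrature on the sphere, dense-grid + simplex-polished
maximization, trapezoid rule on the equator — with grid-doubling until
convergence.  It never touches spherical harmonics, so agreement with
the SH implementation in :mod:`amura.measures` is evidence rather than
tautology.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.optimize import minimize

from .tessellation import fibonacci_sphere

__all__ = [
    "quad_rtop",
    "quad_rtpp",
    "quad_rtap",
    "find_max_direction",
    "sphere_surface_integral",
    "map_correlation",
    "tensor_adc",
    "multi_tensor_adc",
]

ADCFunction = Callable[[np.ndarray], np.ndarray]
"""Maps (..., 3) unit vectors to ADC values in mm^2/s."""


def tensor_adc(D: np.ndarray) -> ADCFunction:
    """ADC of a single Gaussian compartment: u^T D u."""
    D = np.asarray(D, dtype=float)

    def fn(u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        return np.einsum("...i,ij,...j->...", u, D, u)

    return fn


def multi_tensor_adc(
    tensors: list[np.ndarray], fractions: list[float], b: float
) -> ADCFunction:
    """Apparent ADC of a tensor mixture at b: -ln(sum_i f_i e^{-b u^T D_i u})/b.

    Unlike a single compartment this depends on the probing b-value, which
    is exactly the "apparent" character of single-shell measures.
    """
    Ds = [np.asarray(D, dtype=float) for D in tensors]
    fs = np.asarray(fractions, dtype=float)

    def fn(u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        E = sum(
            f * np.exp(-b * np.einsum("...i,ij,...j->...", u, D, u))
            for f, D in zip(fs, Ds)
        )
        return -np.log(E) / b

    return fn


def sphere_surface_integral(
    fn: ADCFunction,
    n_grid: int = 32,
    rtol: float = 1e-6,
    max_refinements: int = 8,
) -> float:
    """Int_S fn(u) dS by Gauss-Legendre in cos(theta) x trapezoid in phi.

    The grid is doubled until the relative change drops below ``rtol``.
    """
    prev = None
    n = n_grid
    for _ in range(max_refinements + 1):
        x, w = np.polynomial.legendre.leggauss(n)  # x = cos(theta)
        phi = np.linspace(0.0, 2.0 * np.pi, 2 * n, endpoint=False)
        sin_t = np.sqrt(1.0 - x ** 2)
        u = np.empty((n, 2 * n, 3))
        u[..., 0] = sin_t[:, None] * np.cos(phi)[None, :]
        u[..., 1] = sin_t[:, None] * np.sin(phi)[None, :]
        u[..., 2] = x[:, None]
        vals = fn(u)
        total = float((w @ vals.sum(axis=1)) * (2.0 * np.pi / (2 * n)))
        if prev is not None and abs(total - prev) <= rtol * abs(total):
            return total
        prev = total
        n *= 2
    raise RuntimeError(
        f"sphere integral did not converge: last two values {prev}, {total}"
    )


def find_max_direction(fn: ADCFunction, n_grid: int = 20000) -> tuple[np.ndarray, float]:
    """Global maximum of fn on the sphere: dense Fibonacci grid + local polish.

    The grid argmax is refined with a Nelder-Mead simplex on spherical
    angles (a 2-D search; derivative-free so any callable works).
    """
    grid = fibonacci_sphere(n_grid)
    vals = fn(grid)
    u0 = grid[int(np.argmax(vals))]
    theta0 = np.arccos(np.clip(u0[2], -1, 1))
    phi0 = np.arctan2(u0[1], u0[0])

    def neg(angles):
        t, p = angles
        u = np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])
        return -float(fn(u))

    res = minimize(neg, [theta0, phi0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14})
    t, p = res.x
    u = np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])
    return u, -res.fun


def quad_rtop(
    adc_fn: ADCFunction,
    tau: float,
    n_grid: int = 32,
    rtol: float = 1e-6,
) -> float:
    """RTOP in mm^-3 by direct surface quadrature of D^-3/2."""
    integral = sphere_surface_integral(
        lambda u: adc_fn(u) ** -1.5, n_grid=n_grid, rtol=rtol
    )
    return np.sqrt(np.pi) / 4.0 * (4.0 * np.pi ** 2 * tau) ** -1.5 * integral


def quad_rtpp(adc_fn: ADCFunction, tau: float, n_grid: int = 20000) -> float:
    """RTPP in mm^-1: (4 pi tau D_max)^-1/2 with D_max found numerically."""
    _, d_max = find_max_direction(adc_fn, n_grid)
    return (4.0 * np.pi * tau * d_max) ** -0.5


def quad_rtap(
    adc_fn: ADCFunction,
    tau: float,
    n_grid: int = 20000,
    n_equator: int = 256,
    rtol: float = 1e-10,
    max_refinements: int = 10,
) -> float:
    """RTAP in mm^-2: equator line integral of 1/D normal to the maximum.

    The equator integral uses the trapezoid rule (spectrally accurate for
    periodic integrands) with doubling until converged.
    """
    r0, _ = find_max_direction(adc_fn, n_grid)
    # orthonormal frame spanning the plane normal to r0
    helper = np.array([1.0, 0.0, 0.0])
    if abs(r0 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(r0, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(r0, e1)

    prev = None
    n = n_equator
    for _ in range(max_refinements + 1):
        th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        u = np.cos(th)[:, None] * e1 + np.sin(th)[:, None] * e2
        integral = float(np.mean(1.0 / adc_fn(u)) * 2.0 * np.pi)
        if prev is not None and abs(integral - prev) <= rtol * abs(integral):
            return integral / (8.0 * np.pi ** 2 * tau)
        prev = integral
        n *= 2
    raise RuntimeError(
        f"equator integral did not converge: last two values {prev}, {integral}"
    )


def map_correlation(
    map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Pearson correlation between two scalar maps over in-mask voxels."""
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must share a shape")
    keep = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        keep &= np.asarray(mask, bool).ravel()
    a, b = a[keep], b[keep]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        import warnings

        warnings.warn("zero variance or too few voxels for correlation", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
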