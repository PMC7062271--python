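"""Unit-sphere point sets: icosphere tessellations and Fibonacci lattices."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import trimesh


@lru_cache(maxsize=8)
def icosphere_vertices(subdivisions: int = 4) -> np.ndarray:
    """Vertices of a subdivided icosahedron on the unit sphere.

    ``10 * 4**subdivisions + 2`` vertices; subdivision 4 gives 2562.
    """
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(mesh.vertices, dtype=float)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def antipodal_reduce(points: np.ndarray) -> np.ndarray:
    """Keep one representative per antipodal pair (upper hemisphere).

    A point survives if z > 0, or z == 0 and y > 0, or z == y == 0 and
    x > 0 (lexicographic tie-break on the equator).
    """
    p = np.asarray(points, dtype=float)
    eps = 1e-12
    keep = (p[:, 2] > eps) | (
        (np.abs(p[:, 2]) <= eps)
        & ((p[:, 1] > eps) | ((np.abs(p[:, 1]) <= eps) & (p[:, 0] > eps)))
    )
    return p[keep]


@lru_cache(maxsize=8)
def hemisphere_tessellation(subdivisions: int = 4) -> np.ndarray:
    """Antipodally reduced icosphere: the search grid for maximum-diffusion
    directions.  Subdivision 4 yields 1281 hemisphere points (~2 degree
    nearest-neighbour spacing), well beyond what an order-6 SH expansion
    can localize."""
    return antipodal_reduce(icosphere_vertices(subdivisions))


def fibonacci_sphere(n: int) -> np.ndarray:
    """Spherical Fibonacci lattice: n approximately uniform unit vectors."""
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def max_nearest_neighbor_angle(points: np.ndarray) -> float:
    """Largest nearest-neighbour angular gap (degrees) of an antipodal set."""
    p = np.asarray(points, dtype=float)
    dots = np.abs(p @ p.T)
    np.fill_diagonal(dots, -1.0)
    nn = np.arccos(np.clip(dots.max(axis=1), -1.0, 1.0))
    return float(np.degrees(nn.max()))
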