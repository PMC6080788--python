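"""Brute-force geometric oracles, independent of the Qhull pipeline.

These reference implementations are deliberately slow and simple. Vertex
membership is decided by linear programming (a point is a hull vertex iff it
is not a convex combination of the remaining points); edge membership by
projecting out the edge direction and testing whether the projected edge
point is a strict corner of the 2-D shadow (all other projected points fit
in an open half-plane). Both tests use exact definitions rather than any
triangulation, so edges interior to coplanar hull faces are never reported.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import linprog


def is_vertex_bruteforce(points: np.ndarray, i: int) -> bool:
    """LP feasibility test: is point ``i`` a strict hull vertex?

    The point is a vertex iff no convex combination of the remaining points
    reproduces it (lambda >= 0, sum lambda = 1, sum lambda x_k = x_i is
    infeasible).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    others = np.delete(points, i, axis=0)
    a_eq = np.vstack([others.T, np.ones(n - 1)])
    b_eq = np.concatenate([points[i], [1.0]])
    res = linprog(
        c=np.zeros(n - 1),
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=[(0, None)] * (n - 1),
        method="highs",
    )
    return not res.success


def hull_vertices_bruteforce(points: np.ndarray, tol: float = 1e-9) -> set[int]:
    """Indices of strict convex-hull vertices via an LP feasibility test."""
    points = np.asarray(points, dtype=float)
    return {i for i in range(len(points)) if is_vertex_bruteforce(points, i)}


def _orthonormal_complement(u: np.ndarray) -> np.ndarray:
    """Two orthonormal vectors spanning the plane orthogonal to unit u."""
    pivot = np.zeros(3)
    pivot[int(np.argmin(np.abs(u)))] = 1.0
    e1 = np.cross(u, pivot)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return np.vstack([e1, e2])


def is_hull_edge_bruteforce(
    points: np.ndarray, i: int, j: int, tol: float = 1e-9
) -> bool:
    """Whether segment (i, j) is an edge of the hull polygon.

    The segment is an edge iff a supporting plane contains both endpoints
    with every other point strictly on one side; equivalently, after
    projecting along the segment direction, the shared projected endpoint is
    a strict corner of the 2-D point shadow (maximum angular gap > pi).
    """
    points = np.asarray(points, dtype=float)
    u = points[j] - points[i]
    norm = np.linalg.norm(u)
    if norm == 0:
        return False
    u = u / norm
    basis = _orthonormal_complement(u)
    rel = np.delete(points, [i, j], axis=0) - points[i]
    shadow = rel @ basis.T
    radii = np.linalg.norm(shadow, axis=1)
    scale = max(radii.max(initial=0.0), norm)
    near = radii <= tol * scale
    if near.any():
        # a third point collinear with the segment: degenerate input
        raise ValueError("degenerate input: third point on the edge line")
    angles = np.sort(np.arctan2(shadow[:, 1], shadow[:, 0]))
    if len(angles) == 0:
        return True
    gaps = np.diff(angles, append=angles[0] + 2.0 * np.pi)
    return float(gaps.max()) > np.pi + tol


def hull_edges_bruteforce(
    points: np.ndarray, vertices: set[int] | None = None, tol: float = 1e-9
) -> set[frozenset]:
    """All hull polygon edges, as frozensets of point indices."""
    if vertices is None:
        vertices = hull_vertices_bruteforce(points, tol)
    edges = set()
    for i, j in combinations(sorted(vertices), 2):
        if is_hull_edge_bruteforce(points, i, j, tol):
            edges.add(frozenset((i, j)))
    return edges


def local_density_bruteforce(
    points: np.ndarray, cb_coord: np.ndarray, radius: float
) -> int:
    """O(N) recount of C-alpha/C-beta points within ``radius`` (inclusive)."""
    d = np.linalg.norm(np.asarray(points, dtype=float) - cb_coord, axis=1)
    return int(np.sum(d <= radius))


def isolated_sphere_area(vdw_radius: float, probe_radius: float) -> float:
    """Closed-form SASA of one isolated atom: 4 pi (r + p)^2."""
    r = vdw_radius + probe_radius
    return 4.0 * np.pi * r * r
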