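"""Convex-polygon helpers shared by arena handling, zone logic and the simulator.

All arena cross-sections used here (trapezoid behavior tank, square circadian
arena, rectangular zones) are convex, so containment and projection reduce to
half-plane tests. Vertices must be given in counter-clockwise order.
"""

from __future__ import annotations

import numpy as np


def polygon_is_simple(vertices: np.ndarray) -> bool:
    """True if no two non-adjacent edges intersect (O(n^2) segment test)."""
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    if n < 3:
        return False
    edges = [(v[i], v[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            if _segments_intersect(*edges[i], *edges[j]):
                return False
    return True


def _segments_intersect(p1, p2, p3, p4) -> bool:
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(p3, p4, p1)
    d2 = cross(p3, p4, p2)
    d3 = cross(p1, p2, p3)
    d4 = cross(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def ensure_ccw(vertices: np.ndarray) -> np.ndarray:
    """Return the vertex list in counter-clockwise order (shoelace sign)."""
    v = np.asarray(vertices, dtype=float)
    area2 = np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
    return v if area2 >= 0 else v[::-1].copy()


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area (absolute value)."""
    v = np.asarray(vertices, dtype=float)
    return 0.5 * abs(
        np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
    )


def polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon."""
    v = ensure_ccw(vertices)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-300:  # degenerate: fall back to vertex mean
        return v.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def _edge_normals(vertices: np.ndarray):
    """Inward normals and offsets for a CCW convex polygon.

    A point p is inside iff n_i . p >= c_i for every edge i.
    """
    v = ensure_ccw(vertices)
    e = np.roll(v, -1, axis=0) - v
    # inward normal of a CCW edge is (-ey, ex)
    normals = np.stack([-e[:, 1], e[:, 0]], axis=1)
    lengths = np.linalg.norm(normals, axis=1)
    normals = normals / lengths[:, None]
    offsets = np.einsum("ij,ij->i", normals, v)
    return normals, offsets


def points_in_convex_polygon(points: np.ndarray, vertices: np.ndarray,
                             tol: float = 1e-9) -> np.ndarray:
    """Vectorized containment test for a convex polygon (boundary counts)."""
    normals, offsets = _edge_normals(vertices)
    pts = np.atleast_2d(points)
    slack = pts @ normals.T - offsets[None, :]
    return np.all(slack >= -tol, axis=1)


def clip_to_convex_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Project points onto the polygon by clipping against violated half-planes.

    Exact for a single violated edge; for corner cases the sequential clip
    converges to a boundary point after a few sweeps.
    """
    normals, offsets = _edge_normals(vertices)
    pts = np.array(np.atleast_2d(points), dtype=float)
    for _ in range(3):
        slack = pts @ normals.T - offsets[None, :]
        if np.all(slack >= -1e-12):
            break
        for i in range(len(normals)):
            viol = slack[:, i] < -1e-12
            if viol.any():
                pts[viol] -= slack[viol, i][:, None] * normals[i][None, :]
                slack = pts @ normals.T - offsets[None, :]
    return pts


def point_segment_distance(points: np.ndarray, a, b) -> np.ndarray:
    """Perpendicular distance from points to segment a-b (vectorized)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pts = np.atleast_2d(points).astype(float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        raise ValueError("degenerate segment: endpoints coincide")
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab[None, :]
    return np.linalg.norm(pts - proj, axis=1)
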