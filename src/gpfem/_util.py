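"""Small numeric helpers shared across modules."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def point_in_mesh(mesh, points: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Even-odd ray-parity containment test for a watertight triangle mesh.

    Casts +Z rays and counts triangle crossings with pure numpy (no spatial
    index needed).  Points are nudged by a tiny deterministic offset so rays
    avoid triangle edges/vertices of structured meshes.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles  # (m, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    eps = 1e-7 * max(1.0, float(np.abs(mesh.bounds).max()))
    offset = np.array([1.234567e-1, 7.654321e-2, 0.0]) * eps
    inside = np.zeros(len(points), dtype=bool)

    # precompute 2D edge data for the xy projection
    ax, ay = a[:, 0], a[:, 1]
    bx, by = b[:, 0], b[:, 1]
    cx, cy = c[:, 0], c[:, 1]
    d00 = (bx - ax) * (cy - ay) - (cx - ax) * (by - ay)  # signed area*2
    keep = np.abs(d00) > 1e-14
    ax, ay, bx, by, cx, cy = (v[keep] for v in (ax, ay, bx, by, cx, cy))
    az, bz, cz = a[keep, 2], b[keep, 2], c[keep, 2]
    d00 = d00[keep]

    for start in range(0, len(points), chunk):
        p = points[start : start + chunk] + offset
        px, py, pz = p[:, 0:1], p[:, 1:2], p[:, 2:3]
        # barycentric coordinates of the xy projection
        w0 = ((bx - px) * (cy - py) - (cx - px) * (by - py)) / d00
        w1 = ((cx - px) * (ay - py) - (ax - px) * (cy - py)) / d00
        w2 = 1.0 - w0 - w1
        hit = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        z_hit = w0 * az + w1 * bz + w2 * cz
        above = hit & (z_hit > pz)
        inside[start : start + chunk] = (above.sum(axis=1) % 2).astype(bool)
    return inside


def angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    c = float(np.dot(unit(v1), unit(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def angle_in_plane_deg(v1, v2, plane_normal) -> float:
    """Angle between projections of two vectors onto a plane, in [0, 180]."""
    n = unit(plane_normal)
    p1 = np.asarray(v1, float) - np.dot(v1, n) * n
    p2 = np.asarray(v2, float) - np.dot(v2, n) * n
    if np.linalg.norm(p1) < 1e-9 or np.linalg.norm(p2) < 1e-9:
        raise ValueError("projection onto plane is degenerate (near-zero length)")
    return angle_deg(p1, p2)
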