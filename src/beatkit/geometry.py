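"""Polyline geometry primitives shared by the midline and flow modules.

All polylines are (N, 2) float arrays of (x, y) pixel coordinates, 0-based,
x rightward, y downward. Physical lengths are obtained by multiplying pixel
distances by the pixel width at the reporting boundary, never inside these
helpers.
"""
from __future__ import annotations

import numpy as np


def polyline_lengths(points: np.ndarray) -> np.ndarray:
    """Per-edge Euclidean lengths of a polyline, shape (N-1,)."""
    d = np.diff(np.asarray(points, dtype=float), axis=0)
    return np.hypot(d[:, 0], d[:, 1])


def cumulative_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length at each vertex, starting at 0, shape (N,)."""
    seg = polyline_lengths(points)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to `n` points equally spaced in arc length.

    Endpoints are preserved exactly.
    """
    points = np.asarray(points, dtype=float)
    s = cumulative_arclength(points)
    if s[-1] <= 0:
        raise ValueError("polyline has zero length")
    target = np.linspace(0.0, s[-1], n)
    x = np.interp(target, s, points[:, 0])
    y = np.interp(target, s, points[:, 1])
    out = np.column_stack([x, y])
    out[0] = points[0]
    out[-1] = points[-1]
    return out


def interp_along(points: np.ndarray, arc: np.ndarray, at: np.ndarray) -> np.ndarray:
    """Interpolate polyline positions at arbitrary arc positions `at`."""
    at = np.asarray(at, dtype=float)
    x = np.interp(at, arc, points[:, 0])
    y = np.interp(at, arc, points[:, 1])
    return np.column_stack([x, y])


def point_polyline_distance(p: np.ndarray, polyline: np.ndarray) -> float:
    """Exact minimum distance from point `p` to a polyline."""
    p = np.asarray(p, dtype=float)
    a = np.asarray(polyline[:-1], dtype=float)
    b = np.asarray(polyline[1:], dtype=float)
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.hypot(*(p - proj).T)))


def points_polyline_distance(pts: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Minimum distance from each of `pts` (M, 2) to a polyline, shape (M,)."""
    pts = np.asarray(pts, dtype=float)
    a = polyline[:-1]
    ab = polyline[1:] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    # (M, E) parameter of the foot point on each edge
    t = np.clip(
        ((pts[:, None, :] - a[None, :, :]) * ab[None, :, :]).sum(-1) / denom[None, :],
        0.0,
        1.0,
    )
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]
    d = np.hypot(*(pts[:, None, :] - proj).transpose(2, 0, 1))
    return d.min(axis=1)


def nearest_points_on_polyline(pts: np.ndarray, polyline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest point (foot) on a polyline for each of `pts` (M, 2).

    Returns ``(distances (M,), feet (M, 2))``.
    """
    pts = np.asarray(pts, dtype=float)
    a = polyline[:-1]
    ab = polyline[1:] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip(
        ((pts[:, None, :] - a[None, :, :]) * ab[None, :, :]).sum(-1) / denom[None, :],
        0.0,
        1.0,
    )
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]
    d = np.hypot(*(pts[:, None, :] - proj).transpose(2, 0, 1))
    best = d.argmin(axis=1)
    rows = np.arange(len(pts))
    return d[rows, best], proj[rows, best]


def _orient(p, q, r):
    return (q[..., 0] - p[..., 0]) * (r[..., 1] - p[..., 1]) - (
        q[..., 1] - p[..., 1]
    ) * (r[..., 0] - p[..., 0])


def segments_intersect(p1, p2, q1, q2) -> bool:
    """Proper or improper intersection test for two closed segments."""
    d1 = _orient(q1, q2, p1)
    d2 = _orient(q1, q2, p2)
    d3 = _orient(p1, p2, q1)
    d4 = _orient(p1, p2, q2)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return True

    def on_seg(a, b, c):
        return (
            min(a[0], b[0]) <= c[0] <= max(a[0], b[0])
            and min(a[1], b[1]) <= c[1] <= max(a[1], b[1])
        )

    if d1 == 0 and on_seg(q1, q2, p1):
        return True
    if d2 == 0 and on_seg(q1, q2, p2):
        return True
    if d3 == 0 and on_seg(p1, p2, q1):
        return True
    if d4 == 0 and on_seg(p1, p2, q2):
        return True
    return False


def polyline_is_simple(points: np.ndarray) -> bool:
    """True when no two non-adjacent edges of the polyline intersect."""
    points = np.asarray(points, dtype=float)
    n_edges = len(points) - 1
    for i in range(n_edges):
        for j in range(i + 2, n_edges):
            if segments_intersect(points[i], points[i + 1], points[j], points[j + 1]):
                return False
    return True


def line_polyline_intersections(
    origin: np.ndarray, direction: np.ndarray, polyline: np.ndarray
) -> np.ndarray:
    """Signed distances t along `direction` where the infinite line through
    `origin` crosses the polyline. Returns a (possibly empty) sorted array.
    """
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    a = polyline[:-1]
    e = polyline[1:] - a
    # o + t d = a + u e ; solve 2x2 per edge via cross products
    denom = d[0] * e[:, 1] - d[1] * e[:, 0]
    ok = np.abs(denom) > 1e-12
    ao = a - o
    t = np.where(ok, (ao[:, 0] * e[:, 1] - ao[:, 1] * e[:, 0]) / np.where(ok, denom, 1.0), np.nan)
    u = np.where(ok, (ao[:, 0] * d[1] - ao[:, 1] * d[0]) / np.where(ok, denom, 1.0), np.nan)
    hit = ok & (u >= 0.0) & (u <= 1.0)
    return np.sort(t[hit])


def smooth_polyline(points: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing with reflected ends; endpoints are pinned.

    Reflection keeps the operation symmetric under polyline reversal, which
    the orientation-equivariance contract of the pipeline relies on.
    """
    points = np.asarray(points, dtype=float)
    if len(points) <= window:
        return points.copy()
    half = window // 2
    padded = np.concatenate(
        [points[1 : half + 1][::-1], points, points[-half - 1 : -1][::-1]], axis=0
    )
    kernel = np.ones(window) / window
    out = np.column_stack(
        [np.convolve(padded[:, k], kernel, mode="valid") for k in (0, 1)]
    )
    out[0] = points[0]
    out[-1] = points[-1]
    return out
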