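"""Superior-valve morphometry: leaflet elongation and valve-cell counting.

The superior AV valve leaflet is traced per plane of a confocal z-stack;
its length is the polyline arc length, and the maximum over planes is
thresholded into a binary elongation call (the criterion the elongation
percentages are built from). Valve cells detected in every plane are
deduplicated by linking detections of the same nucleus across adjacent
planes before counting.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .geometry import cumulative_arclength


@dataclass
class LeafletTrace:
    """Per-plane polylines tracing the superior leaflet, attachment to tip."""

    polylines: list  # list of (N_i, 2) pixel-coordinate arrays
    planes: list  # plane index per polyline
    pixel_width: float
    z_step: float

    def __post_init__(self):
        if len(self.polylines) != len(self.planes):
            raise ValidationError("one plane index per polyline required")
        for poly in self.polylines:
            if np.asarray(poly).shape[0] < 2:
                raise ValidationError("leaflet polylines need at least 2 points")
        if not self.pixel_width > 0 or not self.z_step > 0:
            raise ValidationError("pixel_width and z_step must be positive")


@dataclass
class NucleusDetections:
    """Detected nucleus centers as (x, y, plane) rows."""

    points: np.ndarray
    pixel_width: float
    z_step: float

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.size and (self.points.ndim != 2 or self.points.shape[1] != 3):
            raise ValidationError("detections must be (N, 3) rows of x, y, plane")


@dataclass
class ElongationCall:
    max_leaflet_length: float  # um
    elongated: bool
    threshold_used: float  # um


def leaflet_length(trace: LeafletTrace) -> tuple[np.ndarray, float]:
    """Per-plane leaflet lengths (um) and their maximum over planes.

    An empty trace yields an empty array and maximum 0 (no leaflet seen in
    any plane).
    """
    if len(trace.polylines) == 0:
        return np.array([]), 0.0
    lengths = np.array(
        [cumulative_arclength(np.asarray(p, dtype=float))[-1] * trace.pixel_width
         for p in trace.polylines]
    )
    return lengths, float(lengths.max())


def classify_elongated(length_um: float, threshold_um: float = 10.0) -> ElongationCall:
    """Binary elongation call at a recorded length threshold."""
    if not threshold_um > 0:
        raise ValidationError("elongation threshold must be positive")
    return ElongationCall(
        max_leaflet_length=float(length_um),
        elongated=bool(length_um >= threshold_um),
        threshold_used=float(threshold_um),
    )


def count_valve_cells(
    detections: NucleusDetections,
    link_radius_um: float = 3.0,
    max_plane_gap: int = 1,
    per_plane_sum: bool = False,
) -> int:
    """Number of distinct valve cells after linking detections across planes.

    Detections are linked greedily: walking the planes in order, each
    detection extends the nearest open chain whose last point lies within
    ``link_radius_um`` in xy and at most ``max_plane_gap`` planes below;
    otherwise it starts a new chain. The count is the number of chains.
    ``per_plane_sum`` returns the undeduplicated per-plane total instead.
    """
    pts = detections.points
    if len(pts) == 0:
        return 0
    if per_plane_sum:
        return len(pts)
    order = np.lexsort((pts[:, 0], pts[:, 1], pts[:, 2]))
    pts = pts[order]
    chains: list[list[float]] = []  # last (x, y, plane) per chain
    radius_px = link_radius_um / detections.pixel_width
    for x, y, plane in pts:
        best, best_d = None, np.inf
        for ci, (cx, cy, cplane) in enumerate(chains):
            gap = plane - cplane
            if gap < 1 or gap > max_plane_gap:
                continue
            d = np.hypot(x - cx, y - cy)
            if d <= radius_px and d < best_d:
                best, best_d = ci, d
        if best is None:
            chains.append([x, y, plane])
        else:
            chains[best] = [x, y, plane]
    return len(chains)


def count_cells_connected_components(
    detections: NucleusDetections,
    link_radius_um: float = 3.0,
    max_plane_gap: int = 1,
) -> int:
    """Brute-force count: connected components of the proximity graph.

    Two detections are connected when their xy distance is within the link
    radius and their plane gap is at most ``max_plane_gap``. Used as the
    independent oracle for the greedy chain count on well-separated nuclei.
    """
    pts = detections.points
    n = len(pts)
    if n == 0:
        return 0
    radius_px = link_radius_um / detections.pixel_width
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(pts[i, 2] - pts[j, 2]) <= max_plane_gap and np.hypot(
                *(pts[i, :2] - pts[j, :2])
            ) <= radius_px:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def elongation_table(
    calls_group_a: list[ElongationCall], calls_group_b: list[ElongationCall]
) -> np.ndarray:
    """2x2 contingency table [[elongated, not], ...] for two groups."""
    if len(calls_group_a) == 0 or len(calls_group_b) == 0:
        raise ValidationError("both groups must be non-empty")
    table = np.zeros((2, 2), dtype=int)
    for row, calls in enumerate((calls_group_a, calls_group_b)):
        e = sum(c.elongated for c in calls)
        table[row] = (e, len(calls) - e)
    return table
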