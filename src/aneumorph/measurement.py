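"""Aneurysm size: 3D maximum dome diameter (MaxLen) and its 2D counterpart.

MaxLen is the maximum Euclidean distance between two vertices of the
isolated dome mesh — the computerized 3D size. The in-plane diameter is
the largest distance within a planar cross-section of the dome surface and
emulates a manual caliper measurement on a single 2D viewing plane; it can
never exceed MaxLen, which is the geometric source of the systematic
undersizing of manual relative to computerized measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist

from aneumorph.errors import ValidationError
from aneumorph.mesh_geometry import SurfaceMesh


@dataclass
class SizeMeasurement:
    """One scalar size with the endpoints that realize it."""

    case_id: str
    method: str  # "computerized_3d" | "in_plane_2d"
    value_mm: float
    endpoints: np.ndarray  # (2, 3) world mm
    plane: tuple | None = None  # (point, normal) for in_plane_2d

    def __post_init__(self) -> None:
        self.endpoints = np.asarray(self.endpoints, dtype=float).reshape(2, 3)
        if self.value_mm <= 0:
            raise ValidationError(f"size must be positive, got {self.value_mm}")
        realized = float(np.linalg.norm(self.endpoints[0] - self.endpoints[1]))
        if abs(realized - self.value_mm) > 1e-6 * max(1.0, self.value_mm):
            raise ValidationError("value_mm does not match endpoint distance")


def categorize_size(size_mm: float) -> str:
    """Clinical size category: small (< 3 mm), medium (3-7 mm), large (> 7 mm)."""
    if size_mm <= 0:
        raise ValidationError("size must be positive")
    if size_mm < 3.0:
        return "small"
    if size_mm <= 7.0:
        return "medium"
    return "large"


def category_shares(counts) -> np.ndarray:
    """Percentage share of each size category, rounded to whole percent
    (the convention of clinical demographics tables)."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0 or np.any(counts < 0):
        raise ValidationError("counts must be non-negative with a positive total")
    return np.round(100.0 * counts / counts.sum())


def _dome_points(dome) -> np.ndarray:
    if isinstance(dome, SurfaceMesh):
        return dome.vertices
    if hasattr(dome, "mesh"):
        return dome.mesh.vertices
    return np.asarray(dome, dtype=float).reshape(-1, 3)


def _exhaustive_diameter(points: np.ndarray, ids: np.ndarray) -> tuple[float, int, int]:
    """Max pairwise distance by full O(n^2) scan; ties -> lowest (i, j) pair."""
    best = -1.0
    bi = bj = 0
    # chunk rows to bound memory on large domes
    n = len(points)
    step = max(1, int(4e7 // max(n, 1)))
    for lo in range(0, n, step):
        d = cdist(points[lo : lo + step], points)
        k = int(np.argmax(d))
        val = float(d.flat[k])
        if val > best:
            i_loc, j = divmod(k, n)
            bi, bj = lo + i_loc, j
            best = val
    i, j = int(ids[bi]), int(ids[bj])
    return best, min(i, j), max(i, j)


def max_diameter(dome, case_id: str = "", backend: str = "hull") -> SizeMeasurement:
    """MaxLen: maximum pairwise Euclidean distance over dome vertices.

    Two backends are provided and agree exactly: ``"exhaustive"`` scans all
    vertex pairs; ``"hull"`` first reduces to convex-hull vertices (the
    diameter of a finite point set is attained between extreme points) and
    scans those. Endpoint ties are broken by the lowest index pair.
    """
    points = _dome_points(dome)
    if len(points) < 2:
        raise ValidationError(f"need >= 2 vertices for a diameter, got {len(points)}")
    if backend not in ("hull", "exhaustive"):
        raise ValidationError(f"unknown backend {backend!r}")
    ids = np.arange(len(points))
    if backend == "hull" and len(points) > 4:
        try:
            hull = ConvexHull(points)
            ids = np.sort(hull.vertices)
            points = points[ids]
        except QhullError:
            pass  # degenerate (coplanar/collinear) set: fall back to all points
    value, i, j = _exhaustive_diameter(points, ids)
    pts = _dome_points(dome)
    return SizeMeasurement(
        case_id=case_id,
        method="computerized_3d",
        value_mm=value,
        endpoints=np.stack([pts[i], pts[j]]),
    )


def in_plane_diameter(dome, plane, case_id: str = "") -> SizeMeasurement:
    """Largest distance within the dome-surface/plane cross-section.

    The cross-section polyline points are the triangle/plane intersection
    segment endpoints; because they lie on the surface (hence inside the
    convex hull of the vertices) the result never exceeds MaxLen.
    """
    mesh = dome.mesh if hasattr(dome, "mesh") else dome
    if not isinstance(mesh, SurfaceMesh):
        raise ValidationError("in_plane_diameter needs a mesh, not a bare point set")
    point, normal = (np.asarray(x, dtype=float) for x in plane)
    norm = np.linalg.norm(normal)
    if norm == 0:
        raise ValidationError("plane normal must be non-zero")
    normal = normal / norm
    import trimesh.intersections

    segments = trimesh.intersections.mesh_plane(
        mesh.to_trimesh(), plane_normal=normal, plane_origin=point
    )
    if len(segments) == 0:
        raise ValidationError("plane does not intersect the dome surface")
    section = np.unique(np.asarray(segments).reshape(-1, 3), axis=0)
    if len(section) < 2:
        raise ValidationError("degenerate cross-section")
    value, i, j = _exhaustive_diameter(section, np.arange(len(section)))
    return SizeMeasurement(
        case_id=case_id,
        method="in_plane_2d",
        value_mm=value,
        endpoints=np.stack([section[i], section[j]]),
        plane=(point, normal),
    )
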