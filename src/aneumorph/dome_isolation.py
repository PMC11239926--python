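"""Isolate the aneurysm dome from the ROI mesh with a closed neck curve.

The neck of a saccular aneurysm is annotated as an ordered sequence of
anchor points on the surface; consecutive anchors are joined by shortest
edge-graph paths and the concatenation is closed (last anchor back to the
first). Removing the realized curve splits the ROI surface into components,
and the component geodesically closest to the annotated aneurysm centre is
the dome. Any separating cycle is accepted — no particular neck shape is
assumed.

Curve vertices are assigned to the dome side, so the maximum dome diameter
can never be truncated below the neck by the partition itself.

For phantoms whose ground truth carries an analytic neck plane,
:func:`auto_neck_curve_from_plane` synthesizes the annotation so the full
pipeline can run unattended.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra

from aneumorph.errors import NonSeparatingCurveError, ValidationError
from aneumorph.mesh_geometry import RoiMesh, SurfaceMesh, nearest_vertex

logger = logging.getLogger("aneumorph")


@dataclass
class NeckCurve:
    """A closed curve of mesh vertices separating dome from vessel.

    ``anchor_ids`` are the annotated vertices in order; ``vertex_path`` is
    the realized closed cycle after geodesic projection (no repeated
    vertices, last implicitly connects to first).
    """

    anchor_ids: np.ndarray
    vertex_path: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.anchor_ids = np.asarray(self.anchor_ids, dtype=np.int64)
        self.vertex_path = np.asarray(self.vertex_path, dtype=np.int64)
        if len(self.anchor_ids) < 3:
            raise ValidationError(f"a closed curve needs >= 3 anchors, got {len(self.anchor_ids)}")


@dataclass
class DomeMesh:
    """Isolated aneurysm dome with provenance into its ROI mesh."""

    mesh: SurfaceMesh
    dome_vertex_ids: np.ndarray  # ROI indices on the dome side (curve included)
    vessel_vertex_ids: np.ndarray
    curve: NeckCurve
    ia_center: np.ndarray

    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices


def _lexicographic_shortest_path(
    graph, vertices: np.ndarray, start: int, goal: int
) -> list[int]:
    """Lexicographically smallest shortest path start -> goal on the edge graph.

    Runs Dijkstra from the goal, then walks greedily from the start always
    taking the lowest-index neighbour that stays on a shortest path.
    """
    dist = dijkstra(graph, directed=False, indices=goal)
    if not np.isfinite(dist[start]):
        raise ValidationError(
            f"anchors {start} and {goal} lie on different connected components"
        )
    path = [start]
    current = start
    indptr, indices, data = graph.indptr, graph.indices, graph.data
    rel_tol = 1e-9
    while current != goal:
        nbrs = indices[indptr[current] : indptr[current + 1]]
        wts = data[indptr[current] : indptr[current + 1]]
        on_path = np.abs(wts + dist[nbrs] - dist[current]) <= rel_tol * (1.0 + dist[current])
        candidates = nbrs[on_path]
        current = int(candidates.min())
        path.append(current)
    return path


def project_closed_curve(mesh: SurfaceMesh, anchor_vertex_ids) -> NeckCurve:
    """Join ordered anchors by shortest edge-graph paths into a closed curve.

    Ties between equally short paths are broken by the lexicographically
    smallest vertex sequence. Self-intersections of the concatenated walk
    are collapsed to the first occurrence with a warning.
    """
    anchors = np.asarray(anchor_vertex_ids, dtype=np.int64)
    if len(anchors) < 3:
        raise ValidationError(f"a closed curve needs >= 3 anchors, got {len(anchors)}")
    if anchors.min() < 0 or anchors.max() >= mesh.n_vertices:
        raise ValidationError("anchor vertex index out of range")
    if np.any(anchors == np.roll(anchors, -1)):
        raise ValidationError("consecutive anchors must be distinct")
    graph = mesh.edge_graph()
    walk: list[int] = []
    for a, b in zip(anchors, np.roll(anchors, -1)):
        seg = _lexicographic_shortest_path(graph, mesh.vertices, int(a), int(b))
        walk.extend(seg[:-1])  # drop segment end; next segment starts there
    seen: set[int] = set()
    cycle: list[int] = []
    duplicates = 0
    for v in walk:
        if v in seen:
            duplicates += 1
            continue
        seen.add(v)
        cycle.append(v)
    if duplicates:
        logger.warning("neck curve self-intersects; collapsed %d duplicate vertices", duplicates)
    return NeckCurve(anchor_ids=anchors, vertex_path=np.asarray(cycle, dtype=np.int64))


def partition_by_curve(mesh: SurfaceMesh, curve: NeckCurve) -> list[np.ndarray]:
    """Connected components of the mesh after removing the curve vertices.

    Returns the component vertex sets (each sorted), largest first then by
    smallest contained index. Raises if the curve does not separate.
    """
    if curve.vertex_path.max(initial=-1) >= mesh.n_vertices:
        raise ValidationError("curve vertex index out of range for this mesh")
    keep = np.ones(mesh.n_vertices, dtype=bool)
    keep[curve.vertex_path] = False
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[keep] = np.arange(int(keep.sum()))
    # component structure comes from the edge graph: keep only edges whose
    # endpoints both survive curve removal
    e = mesh.edges()
    e = e[keep[e[:, 0]] & keep[e[:, 1]]]
    n = int(keep.sum())
    g = sp.coo_matrix((np.ones(len(e)), (remap[e[:, 0]], remap[e[:, 1]])), shape=(n, n))
    n_comp, labels = connected_components(g + g.T, directed=False)
    if n_comp < 2:
        raise NonSeparatingCurveError("curve does not separate the mesh (1 component)")
    kept_ids = np.flatnonzero(keep)
    comps = [np.sort(kept_ids[labels == c]) for c in range(n_comp)]
    comps.sort(key=lambda c: (-len(c), int(c[0])))
    return comps


def isolate_dome(roi: RoiMesh, curve: NeckCurve, ia_center=None) -> DomeMesh:
    """Label the curve-separated component closest to the IA centre as dome.

    Closeness is the mean edge-graph geodesic distance from the vertex
    nearest the annotated centre; curve vertices join the dome side. The
    dome submesh keeps faces whose three vertices are all on the dome side.
    """
    if ia_center is None:
        ia_center = roi.ia_center
    if ia_center is None:
        raise ValidationError("no IA centre available: pass ia_center explicitly")
    ia_center = np.asarray(ia_center, dtype=float)
    comps = partition_by_curve(roi, curve)
    source = nearest_vertex(roi, ia_center)
    g = roi.edge_graph()
    dist = dijkstra(g, directed=False, indices=source)
    means = np.array([np.mean(dist[c]) for c in comps])
    best = float(np.min(means))
    tied = np.flatnonzero(means == best)
    if len(tied) > 1:
        logger.warning("dome labelling tie between %d components; taking the largest", len(tied))
        idx = int(tied[np.argmax([len(comps[t]) for t in tied])])
    else:
        idx = int(tied[0])
    dome_ids = np.sort(np.concatenate([comps[idx], curve.vertex_path]))
    all_ids = np.arange(roi.n_vertices)
    vessel_ids = np.setdiff1d(all_ids, dome_ids, assume_unique=False)
    remap = -np.ones(roi.n_vertices, dtype=np.int64)
    remap[dome_ids] = np.arange(len(dome_ids))
    keep = np.all(remap[roi.faces] >= 0, axis=1)
    dome_mesh = SurfaceMesh(
        vertices=roi.vertices[dome_ids],
        faces=remap[roi.faces[keep]],
        parent_vertex_ids=dome_ids,
    )
    return DomeMesh(
        mesh=dome_mesh,
        dome_vertex_ids=dome_ids,
        vessel_vertex_ids=vessel_ids,
        curve=curve,
        ia_center=ia_center,
    )


def auto_neck_curve_from_plane(roi: SurfaceMesh, neck_plane, n_anchors: int = 12) -> NeckCurve:
    """Synthesize a neck annotation from an analytic neck plane.

    Anchors are, per angular sector around the plane normal, the vertex
    closest to the plane; they are ordered by angle and projected with
    :func:`project_closed_curve`. Intended for phantoms whose ground truth
    records the dome/vessel boundary as a plane.
    """
    point, normal = (np.asarray(x, dtype=float) for x in neck_plane)
    normal = normal / np.linalg.norm(normal)
    signed = (roi.vertices - point) @ normal
    if np.all(signed > 0) or np.all(signed < 0):
        raise ValidationError("neck plane does not intersect the mesh")
    # in-plane basis for angular ordering
    seed = np.array([1.0, 0.0, 0.0])
    if abs(normal @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, seed)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    rel = roi.vertices - point
    theta = np.arctan2(rel @ v, rel @ u)
    bins = np.floor((theta + np.pi) / (2 * np.pi) * n_anchors).astype(int).clip(0, n_anchors - 1)
    anchors = []
    for b in range(n_anchors):
        members = np.flatnonzero(bins == b)
        if len(members) == 0:
            continue
        anchors.append(int(members[np.argmin(np.abs(signed[members]))]))
    anchors = [a for i, a in enumerate(anchors) if a != anchors[i - 1]]
    if len(anchors) < 3:
        raise ValidationError("could not place 3 distinct anchors near the neck plane")
    return project_closed_curve(roi, anchors)


# ---------------------------------------------------------------------------
# Curve annotation files


def read_curve_anchors(path: str | Path, mesh: SurfaceMesh) -> np.ndarray:
    """Read neck anchors from JSON: a list of vertex indices, or of world
    [x, y, z] coordinates snapped to the nearest vertex."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, list) or not data:
        raise ValidationError("curve file must be a non-empty JSON list")
    if all(isinstance(x, (int, np.integer)) for x in data):
        return np.asarray(data, dtype=np.int64)
    return np.asarray([nearest_vertex(mesh, np.asarray(p, dtype=float)) for p in data])
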