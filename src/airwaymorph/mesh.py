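"""Surface-mesh foundation: STL I/O, volume, closest-point queries, distance maps.

Meshes are carried as :class:`trimesh.Trimesh` objects throughout the
package; coordinates are millimetres in the package-wide frame (+x right,
+y anterior, +z cranial, see :mod:`airwaymorph.transforms`).  STL itself is
unitless — millimetres are assumed on load and stated in every output.

Nearest-point-on-surface queries are served by :class:`SurfaceIndex`, an
exact engine combining vectorised point-triangle distances with a k-d tree
candidate prune; its results equal exhaustive search (tested on small
meshes).
"""

from __future__ import annotations

import os
import struct
from typing import Iterable

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, MeshFormatError, NonWatertightError
from .transforms import RigidTransform

__all__ = [
    "load_mesh",
    "save_mesh",
    "make_mesh",
    "mesh_volume",
    "boundary_edge_count",
    "SurfaceIndex",
    "surface_distance_map",
    "distance_summary",
    "transform_mesh",
    "fill_planar_boundaries",
]


# ---------------------------------------------------------------------------
# I/O


def make_mesh(vertices, faces) -> trimesh.Trimesh:
    """Build a Trimesh without any automatic processing (order preserved)."""
    return trimesh.Trimesh(
        vertices=np.asarray(vertices, dtype=float),
        faces=np.asarray(faces, dtype=np.int64),
        process=False,
    )


def _validate_stl_bytes(path: str) -> None:
    size = os.path.getsize(path)
    if size < 15:  # smaller than the shortest valid ASCII solid
        raise MeshFormatError(f"{path}: {size} bytes is too short for an STL file")
    with open(path, "rb") as fh:
        head = fh.read(84)
    if head[:5].lower() == b"solid" and b"facet" not in head:
        # could still be binary starting with 'solid'; fall through to count check
        pass
    if len(head) == 84 and head[:5].lower() != b"solid":
        (n_facets,) = struct.unpack("<I", head[80:84])
        expected = 84 + 50 * n_facets
        if size < expected:
            raise MeshFormatError(
                f"{path}: binary STL declares {n_facets} facets "
                f"(expected {expected} bytes) but file ends at byte {size}"
            )


def load_mesh(path: str, file_format: str = "stl") -> trimesh.Trimesh:
    """Load a surface mesh (ASCII or binary STL), units assumed mm.

    Raises
    ------
    MeshFormatError
        If the file is missing, truncated, unparseable or has zero faces.
    """
    if not os.path.exists(path):
        raise MeshFormatError(f"{path}: file does not exist")
    if file_format.lower() == "stl":
        _validate_stl_bytes(path)
    try:
        # STL duplicates vertices per facet; processing welds them so
        # watertightness and volume are recoverable
        mesh = trimesh.load_mesh(path, file_type=file_format, process=True)
    except MeshFormatError:
        raise
    except Exception as exc:  # trimesh raises a zoo of types for bad input
        raise MeshFormatError(f"{path}: unreadable {file_format} file ({exc})") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshFormatError(f"{path}: no triangular faces found")
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path: str, binary: bool = True) -> None:
    """Write an STL file (binary by default; coordinates in mm)."""
    mesh.export(path, file_type="stl" if binary else "stl_ascii")


# ---------------------------------------------------------------------------
# Volume / watertightness


def boundary_edge_count(mesh: trimesh.Trimesh) -> int:
    """Number of edges referenced by exactly one face (0 for a closed surface)."""
    edges = mesh.edges_sorted
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int(np.sum(counts == 1))


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Signed enclosed volume (mm^3) by the divergence theorem.

    Positive for an outward-oriented watertight surface.  Raises
    :class:`NonWatertightError` (reporting the boundary edge count) when the
    surface is open.
    """
    if not mesh.is_watertight:
        n_open = boundary_edge_count(mesh)
        raise NonWatertightError(
            f"mesh is not watertight ({n_open} boundary edges)", boundary_edges=n_open
        )
    v = mesh.vertices
    t = v[mesh.faces]
    # sum of signed tetrahedron volumes against the origin
    return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)


def transform_mesh(mesh: trimesh.Trimesh, transform: RigidTransform) -> trimesh.Trimesh:
    """Return a copy of the mesh under a rigid transform."""
    return make_mesh(transform.apply(mesh.vertices), mesh.faces)


# ---------------------------------------------------------------------------
# Closest point on surface


def _closest_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Pairwise closest point on triangle (Ericson's region method, vectorised).

    ``points``: (n, 3); ``tri``: (n, 3, 3) — one triangle per point.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    def assign(mask, values):
        mask = mask & ~done
        out[mask] = values[mask]
        done[mask] = True

    assign((d1 <= 0) & (d2 <= 0), a)  # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)  # vertex B
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)[:, None]
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + t_ab * ab)  # edge AB
    assign((d6 >= 0) & (d5 <= d6), c)  # vertex C
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)[:, None]
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + t_ac * ac)  # edge AC
    den_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_bc = np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0)[:, None]
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + t_bc * (c - b))  # edge BC
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)[:, None]
        w = np.where(denom != 0, vc / denom, 1 / 3)[:, None]
    assign(np.ones(len(points), dtype=bool), a + v * ab + w * ac)  # interior
    return out


class SurfaceIndex:
    """Exact nearest-point-on-surface queries against a triangle mesh.

    A k-d tree over triangle centroids supplies an upper bound from the
    nearest few candidates; every triangle whose centroid ball could beat
    that bound is then checked exactly, so the result equals exhaustive
    search.
    """

    #: below this face count the prune is skipped entirely
    EXHAUSTIVE_LIMIT = 64

    def __init__(self, mesh: trimesh.Trimesh):
        if len(mesh.faces) == 0:
            raise DegenerateGeometryError("cannot index an empty mesh")
        self.mesh = mesh
        tri = mesh.vertices[mesh.faces].astype(float)
        face_id = np.arange(len(tri))
        # split oversized triangles (e.g. end-cap fans) for the index only, so
        # the candidate ball radius stays small; geometry is unchanged
        self._orig_tri = tri
        diag = float(np.linalg.norm(np.ptp(mesh.vertices, axis=0)))
        tri, face_id = self._split_large(tri, face_id, target=max(diag / 32.0, 1e-9))
        self._tri = tri
        self._face_id = face_id
        self._centroids = self._tri.mean(axis=1)
        self._radius = np.linalg.norm(
            self._tri - self._centroids[:, None, :], axis=2
        ).max(axis=1)
        self._max_radius = float(self._radius.max())
        self._tree = cKDTree(self._centroids)

    @staticmethod
    def _split_large(tri: np.ndarray, face_id: np.ndarray, target: float, rounds: int = 8):
        for _ in range(rounds):
            radius = np.linalg.norm(tri - tri.mean(axis=1, keepdims=True), axis=2).max(
                axis=1
            )
            big = radius > target
            if not big.any():
                break
            a, b, c = tri[big, 0], tri[big, 1], tri[big, 2]
            ab, bc, ca = (a + b) / 2, (b + c) / 2, (c + a) / 2
            children = np.concatenate(
                [
                    np.stack([a, ab, ca], axis=1),
                    np.stack([ab, b, bc], axis=1),
                    np.stack([ca, bc, c], axis=1),
                    np.stack([ab, bc, ca], axis=1),
                ]
            )
            tri = np.concatenate([tri[~big], children])
            face_id = np.concatenate([face_id[~big], np.tile(face_id[big], 4)])
        return tri, face_id

    def query(self, points: np.ndarray, chunk: int = 4096):
        """Return (closest_points, distances, triangle_ids) for (n, 3) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(pts)
        closest = np.empty((n, 3))
        dist = np.empty(n)
        tid = np.empty(n, dtype=np.int64)
        for lo in range(0, n, chunk):
            sl = slice(lo, min(lo + chunk, n))
            c, d, t = self._query_chunk(pts[sl])
            closest[sl], dist[sl], tid[sl] = c, d, t
        return closest, dist, tid

    def _query_chunk(self, pts: np.ndarray):
        n_faces = len(self._orig_tri)
        if n_faces <= self.EXHAUSTIVE_LIMIT:
            cand = np.tile(np.arange(n_faces), len(pts))
            owner = np.repeat(np.arange(len(pts)), n_faces)
            return self._reduce(pts, owner, cand)
        k = min(4, len(self._tri))
        _, idx = self._tree.query(pts, k=k)
        cand0 = self._tri[idx.reshape(-1)]
        p_rep = np.repeat(pts, k, axis=0)
        cp0 = _closest_on_triangles(p_rep, cand0)
        d0 = np.linalg.norm(cp0 - p_rep, axis=1).reshape(len(pts), k)
        upper = d0.min(axis=1)
        # every sub-triangle whose centroid lies within upper + its max radius
        # could contain a closer point; the global max radius bounds them all
        balls = self._tree.query_ball_point(pts, upper + self._max_radius + 1e-12)
        owner = np.repeat(np.arange(len(pts)), [len(b) for b in balls])
        cand = np.concatenate([np.asarray(b, dtype=np.int64) for b in balls])
        # collapse sub-triangles back to (point, original face) pairs
        keys = owner * np.int64(n_faces) + self._face_id[cand]
        keys = np.unique(keys)
        return self._reduce(pts, keys // n_faces, keys % n_faces)

    def _reduce(self, pts, owner, cand):
        cp = _closest_on_triangles(pts[owner], self._orig_tri[cand])
        d = np.linalg.norm(cp - pts[owner], axis=1)
        n = len(pts)
        best = np.full(n, np.inf)
        best_i = np.zeros(n, dtype=np.int64)
        # stable per-owner argmin
        order = np.lexsort((d, owner))
        owner_s, d_s = owner[order], d[order]
        first = np.ones(len(owner_s), dtype=bool)
        first[1:] = owner_s[1:] != owner_s[:-1]
        best[owner_s[first]] = d_s[first]
        best_i[owner_s[first]] = order[first]
        return cp[best_i], best, cand[best_i]


def surface_distance_map(
    mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh
) -> np.ndarray:
    """Unsigned distance (mm) from each vertex of ``mesh_a`` to the surface of
    ``mesh_b`` — the colorimetric-map quantity used to inspect registrations."""
    if len(mesh_a.vertices) == 0 or len(mesh_b.faces) == 0:
        raise DegenerateGeometryError("surface_distance_map requires non-empty meshes")
    _, dist, _ = SurfaceIndex(mesh_b).query(mesh_a.vertices)
    return dist


def distance_summary(distances: Iterable[float]) -> dict:
    d = np.asarray(list(distances), dtype=float)
    return {
        "mean": float(d.mean()),
        "p95": float(np.percentile(d, 95)),
        "max": float(d.max()),
    }


# ---------------------------------------------------------------------------
# Boundary capping (used after plane cuts)


def _weld_vertices(mesh: trimesh.Trimesh, decimals: int = 7) -> trimesh.Trimesh:
    """Merge coincident vertices (plane cuts duplicate them) and drop
    degenerate faces so boundary loops come out manifold."""
    key = np.round(mesh.vertices, decimals)
    _, first, inverse = np.unique(
        key, axis=0, return_index=True, return_inverse=True
    )
    faces = inverse[mesh.faces]
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 2] != faces[:, 0])
    )
    return make_mesh(mesh.vertices[first], faces[ok])


def _directed_boundary_edges(mesh: trimesh.Trimesh) -> np.ndarray:
    edges = mesh.edges  # directed, per-face
    edges_sorted = np.sort(edges, axis=1)
    _, inv, counts = np.unique(
        edges_sorted, axis=0, return_inverse=True, return_counts=True
    )
    return edges[counts[inv] == 1]


def fill_planar_boundaries(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Close every boundary loop with a centroid fan, preserving winding.

    Cap triangles traverse each boundary edge opposite to the adjacent face,
    so a consistently outward-wound open mesh stays outward once closed.
    Loops are assumed star-shaped about their centroid (true for the planar
    cuts this package produces).
    """
    mesh = _weld_vertices(mesh)
    directed = _directed_boundary_edges(mesh)
    if len(directed) == 0:
        return mesh
    succ = dict(map(tuple, directed))
    if len(succ) != len(directed):
        raise DegenerateGeometryError("non-manifold boundary: repeated edge start")
    vertices = [mesh.vertices]
    faces = [mesh.faces]
    n_v = len(mesh.vertices)
    remaining = dict(succ)
    while remaining:
        start = next(iter(remaining))
        loop = [start]
        nxt = remaining.pop(start)
        while nxt != start:
            loop.append(nxt)
            nxt = remaining.pop(nxt)
        loop_v = mesh.vertices[loop]
        centroid = loop_v.mean(axis=0)
        vertices.append(centroid[None, :])
        # fan (centroid, b, a) reverses each directed boundary edge (a, b)
        a = np.asarray(loop)
        b = np.asarray(loop[1:] + [loop[0]])
        cap = np.column_stack([np.full(len(a), n_v), b, a])
        faces.append(cap)
        n_v += 1
    return make_mesh(np.vstack(vertices), np.vstack(faces))
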