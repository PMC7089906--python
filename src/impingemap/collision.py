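"""Mesh-mesh surface intersection built on Möller-Trumbore.

Two triangle surfaces cross where an edge of one pierces a triangle of
the other.  Every unique edge of mesh A (posed by a rigid transform) is
therefore tested as a bounded segment against the triangles of mesh B,
and symmetrically, using the Möller-Trumbore ray-triangle formulation
with the ray parameter restricted to the segment, ``0 <= t <= 1``.

A broad phase prunes edge-triangle pairs with a kd-tree over triangle
centroids (an edge whose midpoint is farther from a triangle's centroid
than the two bounding radii combined cannot touch it).  The contract is
exact equality with the exhaustive all-pairs test, which is available via
``exhaustive=True`` and pinned by tests.

This is a *surface crossing* notion: a mesh entirely inside another
without its surface crossing reports no intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .mesh_core import TriMesh

#: Möller-Trumbore determinant below which a segment is treated as
#: parallel to the triangle plane (dimensionless).
PARALLEL_EPS = 1e-12

#: Boundary points closer than this (mm) are merged.
DEDUP_TOL = 1e-9

#: Fixed, irrational-component ray direction for parity containment tests
#: (avoids hitting mesh edges/vertices exactly on structured meshes).
_PARITY_DIR = np.array([0.57735026919, 0.62361024384, 0.52573111212])
_PARITY_DIR = _PARITY_DIR / np.linalg.norm(_PARITY_DIR)


@dataclass
class IntersectionResult:
    """Outcome of a mesh-mesh surface intersection test.

    ``boundary_points`` sample the intersection curve (one point per
    segment-triangle crossing, deduplicated); ``crossed_faces_*`` are the
    faces that straddle the curve and ``crossed_vertices_*`` the vertices
    incident to a crossed edge (or belonging to a pierced face).
    """

    intersects: bool
    boundary_points: np.ndarray
    crossed_faces_a: set = field(default_factory=set)
    crossed_faces_b: set = field(default_factory=set)
    crossed_vertices_a: set = field(default_factory=set)
    crossed_vertices_b: set = field(default_factory=set)


# --------------------------------------------------------------------------
# Möller-Trumbore
# --------------------------------------------------------------------------

def ray_triangle(origin, direction, triangle, eps: float = PARALLEL_EPS):
    """Möller-Trumbore ray-triangle intersection.

    Returns ``(t, u, v)`` with ``t >= 0`` the ray parameter and
    ``(u, v)`` the barycentric coordinates, or ``None`` when the ray
    misses or runs parallel to the triangle plane (|det| < ``eps``).
    """
    o = np.asarray(origin, dtype=np.float64)
    d = np.asarray(direction, dtype=np.float64)
    if np.linalg.norm(d) == 0:
        raise ContractError("ray direction must be non-zero")
    tri = np.asarray(triangle, dtype=np.float64)
    e1 = tri[1] - tri[0]
    e2 = tri[2] - tri[0]
    p = np.cross(d, e2)
    det = np.dot(e1, p)
    if abs(det) < eps:
        return None
    inv = 1.0 / det
    s = o - tri[0]
    u = np.dot(s, p) * inv
    if u < 0.0 or u > 1.0:
        return None
    q = np.cross(s, e1)
    v = np.dot(d, q) * inv
    if v < 0.0 or u + v > 1.0:
        return None
    t = np.dot(e2, q) * inv
    if t < 0.0:
        return None
    return float(t), float(u), float(v)


def _segments_vs_triangles(p0, p1, t0, t1, t2, eps=PARALLEL_EPS):
    """Vectorised Möller-Trumbore for paired segments and triangles.

    All inputs are (N, 3).  Returns (hit_mask, t) where hits require
    ``0 <= t <= 1`` (bounded segments, not rays).
    """
    d = p1 - p0
    e1 = t1 - t0
    e2 = t2 - t0
    p = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) >= eps
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    s = p0 - t0
    u = np.einsum("ij,ij->i", s, p) * inv
    q = np.cross(s, e1)
    v = np.einsum("ij,ij->i", d, q) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    hit = ok & (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0) & (t >= 0.0) & (t <= 1.0)
    return hit, t


# --------------------------------------------------------------------------
# Broad phase
# --------------------------------------------------------------------------

def _aabb_overlap(lo_a, hi_a, lo_b, hi_b, margin=0.0):
    return bool(np.all(lo_a <= hi_b + margin) and np.all(lo_b <= hi_a + margin))


def _candidate_pairs(mid, half, tree, tri_radius, box_lo, box_hi):
    """Edge indices x triangle indices that could touch.

    ``mid``/``half`` describe the edge bounding spheres, ``tree`` is the
    kd-tree over the opposing triangle centroids with bounding radii
    ``tri_radius``.  Edges outside the opposing AABB (inflated by the
    maximum reach) are discarded before querying.
    """
    max_r = float(tri_radius.max()) if len(tri_radius) else 0.0
    reach = half + max_r + 1e-9
    near = np.all((mid >= box_lo - reach[:, None]) &
                  (mid <= box_hi + reach[:, None]), axis=1)
    idx = np.flatnonzero(near)
    if idx.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    lists = tree.query_ball_point(mid[idx], r=reach[idx])
    e_out, t_out = [], []
    for i, lst in zip(idx, lists):
        if lst:
            e_out.append(np.full(len(lst), i, dtype=np.int64))
            t_out.append(np.asarray(lst, dtype=np.int64))
    if not e_out:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return np.concatenate(e_out), np.concatenate(t_out)


def _edges_cross_mesh(edge_v0, edge_v1, mesh_t: TriMesh, exhaustive: bool,
                      first_hit_only: bool = False):
    """Crossings of the given edge segments against the triangles of
    ``mesh_t`` (in mesh_t's frame).

    Returns (edge_idx, tri_idx, points) arrays of the crossing pairs.
    """
    empty = (np.empty(0, np.int64), np.empty(0, np.int64), np.zeros((0, 3)))
    if mesh_t.n_faces == 0 or len(edge_v0) == 0:
        return empty
    if exhaustive:
        ne, nt = len(edge_v0), mesh_t.n_faces
        ei = np.repeat(np.arange(ne, dtype=np.int64), nt)
        ti = np.tile(np.arange(nt, dtype=np.int64), ne)
    else:
        mid = 0.5 * (edge_v0 + edge_v1)
        half = 0.5 * np.linalg.norm(edge_v1 - edge_v0, axis=1)
        lo, hi = mesh_t.bounds
        ei, ti = _candidate_pairs(mid, half, mesh_t.centroid_tree,
                                  mesh_t.face_bound_radius, lo, hi)
    if ei.size == 0:
        return empty
    hits_e, hits_t, pts = [], [], []
    tri = mesh_t.triangles
    chunk = 2_000_000
    for s in range(0, ei.size, chunk):
        e = ei[s:s + chunk]
        t = ti[s:s + chunk]
        p0 = edge_v0[e]
        p1 = edge_v1[e]
        hit, tpar = _segments_vs_triangles(p0, p1, tri[t, 0], tri[t, 1], tri[t, 2])
        if hit.any():
            h = np.flatnonzero(hit)
            hits_e.append(e[h])
            hits_t.append(t[h])
            pts.append(p0[h] + tpar[h][:, None] * (p1[h] - p0[h]))
            if first_hit_only:
                break
    if not hits_e:
        return empty
    return np.concatenate(hits_e), np.concatenate(hits_t), np.vstack(pts)


# --------------------------------------------------------------------------
# Public operations
# --------------------------------------------------------------------------

def _dedup(points, tol=DEDUP_TOL):
    if len(points) == 0:
        return np.zeros((0, 3))
    key = np.round(points / tol)
    _, first = np.unique(key, axis=0, return_index=True)
    return points[np.sort(first)]


def mesh_intersect(mesh_a: TriMesh, transform_a, mesh_b: TriMesh,
                   exhaustive: bool = False) -> IntersectionResult:
    """Surface intersection of ``mesh_a`` (posed by ``transform_a``,
    a 4x4 rigid transform) with the static ``mesh_b``.

    Results are expressed in mesh_b's (world) frame.
    """
    T = np.asarray(transform_a, dtype=np.float64)
    empty = IntersectionResult(False, np.zeros((0, 3)))
    if mesh_a.n_faces == 0 or mesh_b.n_faces == 0:
        return empty

    va = mesh_a.vertices @ T[:3, :3].T + T[:3, 3]
    lo_a, hi_a = va.min(axis=0), va.max(axis=0)
    lo_b, hi_b = mesh_b.bounds
    if not exhaustive and not _aabb_overlap(lo_a, hi_a, lo_b, hi_b, margin=1e-9):
        return empty

    # direction 1: edges of A against triangles of B (B frame)
    ea = mesh_a.edges_unique
    e1_idx, t1_idx, pts1 = _edges_cross_mesh(va[ea[:, 0]], va[ea[:, 1]],
                                             mesh_b, exhaustive)

    # direction 2: edges of B against triangles of A, tested in A's local
    # frame so A's cached kd-tree can be reused; points mapped back by T.
    Tinv = np.linalg.inv(T)
    vb = mesh_b.vertices @ Tinv[:3, :3].T + Tinv[:3, 3]
    eb = mesh_b.edges_unique
    e2_idx, t2_idx, pts2 = _edges_cross_mesh(vb[eb[:, 0]], vb[eb[:, 1]],
                                             mesh_a, exhaustive)
    if len(pts2):
        pts2 = pts2 @ T[:3, :3].T + T[:3, 3]

    points = _dedup(np.vstack([pts1, pts2]) if (len(pts1) or len(pts2))
                    else np.zeros((0, 3)))
    if len(points) == 0:
        return empty

    crossed_faces_a: set = set()
    crossed_vertices_a: set = set()
    crossed_faces_b: set = set()
    crossed_vertices_b: set = set()

    if e1_idx.size:
        ce = np.unique(e1_idx)
        for f in mesh_a.edge_faces[ce].ravel():
            if f >= 0:
                crossed_faces_a.add(int(f))
        crossed_vertices_a.update(int(v) for v in ea[ce].ravel())
        ct = np.unique(t1_idx)
        crossed_faces_b.update(int(f) for f in ct)
        crossed_vertices_b.update(int(v) for v in mesh_b.faces[ct].ravel())
    if e2_idx.size:
        ce = np.unique(e2_idx)
        for f in mesh_b.edge_faces[ce].ravel():
            if f >= 0:
                crossed_faces_b.add(int(f))
        crossed_vertices_b.update(int(v) for v in eb[ce].ravel())
        ct = np.unique(t2_idx)
        crossed_faces_a.update(int(f) for f in ct)
        crossed_vertices_a.update(int(v) for v in mesh_a.faces[ct].ravel())

    return IntersectionResult(True, points, crossed_faces_a, crossed_faces_b,
                              crossed_vertices_a, crossed_vertices_b)


def meshes_cross(mesh_a: TriMesh, transform_a, mesh_b: TriMesh) -> bool:
    """Boolean fast path of :func:`mesh_intersect` (early exit)."""
    T = np.asarray(transform_a, dtype=np.float64)
    if mesh_a.n_faces == 0 or mesh_b.n_faces == 0:
        return False
    va = mesh_a.vertices @ T[:3, :3].T + T[:3, 3]
    lo_b, hi_b = mesh_b.bounds
    if not _aabb_overlap(va.min(axis=0), va.max(axis=0), lo_b, hi_b, margin=1e-9):
        return False
    ea = mesh_a.edges_unique
    e_idx, _, _ = _edges_cross_mesh(va[ea[:, 0]], va[ea[:, 1]], mesh_b,
                                    exhaustive=False, first_hit_only=True)
    if e_idx.size:
        return True
    Tinv = np.linalg.inv(T)
    vb = mesh_b.vertices @ Tinv[:3, :3].T + Tinv[:3, 3]
    eb = mesh_b.edges_unique
    e_idx, _, _ = _edges_cross_mesh(vb[eb[:, 0]], vb[eb[:, 1]], mesh_a,
                                    exhaustive=False, first_hit_only=True)
    return bool(e_idx.size)


def check_pi(stem: TriMesh, transform, liner: TriMesh) -> bool:
    """Prosthetic impingement: does the stem/neck surface cross the liner
    surface at the given pose?"""
    return meshes_cross(stem, transform, liner)


def contains_points(mesh: TriMesh, points, transform=None) -> np.ndarray:
    """Ray-parity point-in-mesh test for a closed mesh.

    ``transform`` optionally poses the mesh; points are given in the
    world frame.  Uses a fixed irrational ray direction, counting
    Möller-Trumbore crossings with ``t > 0``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if mesh.n_faces == 0:
        return np.zeros(len(pts), dtype=bool)
    if transform is not None:
        Tinv = np.linalg.inv(np.asarray(transform, dtype=np.float64))
        pts = pts @ Tinv[:3, :3].T + Tinv[:3, 3]
    tri = mesh.triangles
    inside = np.zeros(len(pts), dtype=bool)
    d = _PARITY_DIR
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    p = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) >= PARALLEL_EPS
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    for i, o in enumerate(pts):
        s = o - tri[:, 0]
        u = np.einsum("ij,ij->i", s, p) * inv
        q = np.cross(s, e1)
        v = np.einsum("ij,j->i", q, d) * inv
        t = np.einsum("ij,ij->i", e2, q) * inv
        hit = ok & (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0) & (t > 0.0)
        inside[i] = bool(hit.sum() % 2)
    return inside
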