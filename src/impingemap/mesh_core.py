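"""Triangle-mesh data model and I/O.

All geometry in this package lives on indexed triangle surfaces in
millimetres.  STL input carries no connectivity (each facet repeats its
corner coordinates), so vertices are welded on load; the adjacency built
here is what the collision and region-growing stages operate on.

Colour-annotated output uses PLY, because STL cannot carry per-face
colour.  The palette maps the four impingement-severity names plus the
``non_impinged`` background colour to RGB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import trimesh

from .errors import ContractError, InputError, ValidationError

#: Default vertex-welding tolerance (mm).  STL facets duplicate corner
#: coordinates bit-exactly, so any tolerance well below the mesh edge
#: length works; 1e-6 mm is far below CT-derived mesh resolution.
DEFAULT_WELD_TOLERANCE = 1e-6

#: Area (mm^2) below which a facet is considered degenerate.
DEGENERATE_AREA = 1e-10

#: Colour names used by impingement maps, most to least severe, plus the
#: background.
COLOR_NAMES = ("red", "yellow", "green", "blue", "non_impinged")

#: Default palette (RGB, uchar).
DEFAULT_PALETTE = {
    "red": (255, 0, 0),
    "yellow": (255, 255, 0),
    "green": (0, 255, 0),
    "blue": (0, 0, 255),
    "non_impinged": (128, 128, 128),
}


class TriMesh:
    """Indexed triangle surface with cached adjacency.

    Parameters
    ----------
    vertices : (n, 3) float array, millimetres.
    faces : (m, 3) int array of vertex indices.
    validate : check the structural invariants (indices in range,
        non-degenerate triangles).  Skipped internally for rigid copies,
        which cannot break them.
    """

    def __init__(self, vertices, faces, validate: bool = True):
        self.vertices = np.ascontiguousarray(vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64).reshape(-1, 3)
        if validate:
            self._validate()

    def _validate(self) -> None:
        if self.n_faces and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise ValidationError("face references a vertex index out of range")
        if self.n_faces:
            f = self.faces
            repeated = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            if repeated.any():
                raise ValidationError(
                    f"face {int(np.flatnonzero(repeated)[0])} repeats a vertex"
                )
            bad = self.face_areas < DEGENERATE_AREA
            if bad.any():
                raise ValidationError(
                    f"face {int(np.flatnonzero(bad)[0])} has (near-)zero area"
                )

    # ----- basic quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @cached_property
    def triangles(self):
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    @cached_property
    def _cross(self):
        t = self.triangles
        return np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])

    @cached_property
    def face_areas(self):
        return 0.5 * np.linalg.norm(self._cross, axis=1)

    @cached_property
    def face_normals(self):
        n = self._cross.copy()
        lens = np.linalg.norm(n, axis=1)
        lens[lens == 0] = 1.0
        return n / lens[:, None]

    @cached_property
    def face_centroids(self):
        return self.triangles.mean(axis=1)

    @cached_property
    def bounds(self):
        """(2, 3) axis-aligned bounding box (min row, max row)."""
        if self.n_vertices == 0:
            return np.zeros((2, 3))
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    # ----- connectivity -----------------------------------------------------

    @cached_property
    def _tm(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @cached_property
    def edges_unique(self):
        """(E, 2) sorted vertex index pairs, one row per undirected edge."""
        if self.n_faces == 0:
            return np.zeros((0, 2), dtype=np.int64)
        return np.asarray(self._tm.edges_unique, dtype=np.int64)

    @cached_property
    def edge_faces(self):
        """(E, 2) faces sharing each unique edge; -1 pads boundary edges."""
        out = np.full((len(self.edges_unique), 2), -1, dtype=np.int64)
        if self.n_faces == 0:
            return out
        inv = self._tm.edges_unique_inverse
        efa = self._tm.edges_face
        fill = np.zeros(len(self.edges_unique), dtype=np.int64)
        for j in range(len(inv)):
            e = inv[j]
            if fill[e] < 2:
                out[e, fill[e]] = efa[j]
                fill[e] += 1
        return out

    @cached_property
    def face_adjacency(self):
        """(K, 2) pairs of faces sharing an edge."""
        if self.n_faces == 0:
            return np.zeros((0, 2), dtype=np.int64)
        return np.asarray(self._tm.face_adjacency, dtype=np.int64)

    @cached_property
    def adjacency_list(self):
        """list of int arrays: edge-neighbouring faces of each face."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_faces)]
        for a, b in self.face_adjacency:
            nbrs[a].append(b)
            nbrs[b].append(a)
        return [np.array(x, dtype=np.int64) for x in nbrs]

    @cached_property
    def vertex_faces(self):
        """list of int arrays: faces incident to each vertex."""
        vf: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for fid, face in enumerate(self.faces):
            for v in face:
                vf[v].append(fid)
        return [np.array(x, dtype=np.int64) for x in vf]

    @cached_property
    def is_watertight(self) -> bool:
        if self.n_faces == 0:
            return False
        return bool(self._tm.is_watertight)

    @cached_property
    def median_edge_length(self) -> float:
        if len(self.edges_unique) == 0:
            return 0.0
        e = self.edges_unique
        return float(np.median(np.linalg.norm(
            self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)))

    # ----- collision support (cached broad-phase data) ----------------------

    @cached_property
    def edge_segments(self):
        """(p0, p1) endpoint arrays of the unique edges."""
        e = self.edges_unique
        return self.vertices[e[:, 0]], self.vertices[e[:, 1]]

    @cached_property
    def centroid_tree(self):
        from scipy.spatial import cKDTree

        return cKDTree(self.face_centroids) if self.n_faces else None

    @cached_property
    def face_bound_radius(self):
        """Per-face distance from centroid to its farthest corner."""
        d = self.triangles - self.face_centroids[:, None, :]
        return np.linalg.norm(d, axis=2).max(axis=1)

    # ----- transforms -------------------------------------------------------

    def transformed(self, matrix) -> "TriMesh":
        """Return a rigidly transformed copy (4x4 homogeneous matrix)."""
        m = np.asarray(matrix, dtype=np.float64)
        v = self.vertices @ m[:3, :3].T + m[:3, 3]
        return TriMesh(v, self.faces, validate=False)

    def mirrored(self, axis: int = 1) -> "TriMesh":
        """Mirror about the coordinate plane normal to ``axis``.

        Triangle winding is reversed so outward normals stay outward.
        """
        v = self.vertices.copy()
        v[:, axis] *= -1.0
        f = self.faces[:, ::-1].copy()
        return TriMesh(v, f, validate=False)

    def __eq__(self, other):
        return (
            isinstance(other, TriMesh)
            and self.vertices.shape == other.vertices.shape
            and self.faces.shape == other.faces.shape
            and np.array_equal(self.vertices, other.vertices)
            and np.array_equal(self.faces, other.faces)
        )

    def __repr__(self):
        return f"TriMesh({self.n_vertices} vertices, {self.n_faces} faces)"


def empty_mesh() -> TriMesh:
    """A mesh with no faces (useful to disable a collision partner)."""
    return TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64), validate=False)


@dataclass
class FaceColorMap:
    """Per-face colour assignment; unassigned faces are ``non_impinged``.

    ``assignments`` maps face id -> colour name.  Every face of the target
    mesh therefore has exactly one colour, the default being the
    background colour.
    """

    n_faces: int
    assignments: dict = field(default_factory=dict)

    def __post_init__(self):
        for fid, name in self.assignments.items():
            if not (0 <= fid < self.n_faces):
                raise ContractError(f"colour assigned to invalid face id {fid}")
            if name not in COLOR_NAMES:
                raise ContractError(f"unknown colour name {name!r}")

    def color_name(self, fid: int) -> str:
        return self.assignments.get(fid, "non_impinged")

    def to_rgb(self, palette=None):
        """(n_faces, 3) uint8 RGB array."""
        palette = palette or DEFAULT_PALETTE
        rgb = np.tile(np.array(palette["non_impinged"], dtype=np.uint8),
                      (self.n_faces, 1))
        for fid, name in self.assignments.items():
            rgb[fid] = palette[name]
        return rgb


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def _weld(vertices, faces, tol):
    """Merge vertices whose coordinates coincide within ``tol``."""
    if tol > 0:
        quant = np.round(vertices / tol)
    else:
        quant = vertices
    _, first, inverse = np.unique(quant, axis=0, return_index=True,
                                  return_inverse=True)
    return vertices[first], inverse[faces]


def load_mesh(path, weld_tolerance: float = DEFAULT_WELD_TOLERANCE) -> TriMesh:
    """Read a surface mesh (binary or ASCII STL, or PLY) and weld it.

    Raises :class:`InputError` if the file is unreadable and
    :class:`ValidationError` for empty or degenerate geometry.
    """
    path = Path(path)
    try:
        raw = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:  # parser errors vary by format
        raise InputError(f"could not read mesh file {path}: {exc}") from exc
    vertices = np.asarray(raw.vertices, dtype=np.float64)
    faces = np.asarray(raw.faces, dtype=np.int64)
    if len(faces) == 0:
        raise ValidationError(f"mesh file {path} contains no faces")
    tri = vertices[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    bad = areas < DEGENERATE_AREA
    if bad.any():
        raise ValidationError(
            f"mesh file {path}: facet {int(np.flatnonzero(bad)[0])} has zero area")
    v, f = _weld(vertices, faces, weld_tolerance)
    return TriMesh(v, f)


def save_colored_mesh(mesh: TriMesh, colors: FaceColorMap, path,
                      palette=None) -> None:
    """Write ``mesh`` as binary PLY with per-face uchar RGB colours."""
    if colors.n_faces != mesh.n_faces:
        raise ContractError(
            f"colour map covers {colors.n_faces} faces, mesh has {mesh.n_faces}")
    rgba = np.concatenate(
        [colors.to_rgb(palette),
         np.full((mesh.n_faces, 1), 255, dtype=np.uint8)], axis=1)
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    tm.visual.face_colors = rgba
    tm.export(str(path), file_type="ply")


def load_colored_mesh(path, palette=None):
    """Inverse of :func:`save_colored_mesh`: (TriMesh, FaceColorMap)."""
    palette = palette or DEFAULT_PALETTE
    path = Path(path)
    try:
        tm = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:
        raise InputError(f"could not read mesh file {path}: {exc}") from exc
    mesh = TriMesh(np.asarray(tm.vertices, dtype=np.float64),
                   np.asarray(tm.faces, dtype=np.int64))
    rgb = np.asarray(tm.visual.face_colors)[:, :3]
    by_rgb = {tuple(v): k for k, v in palette.items()}
    assignments = {}
    for fid in range(mesh.n_faces):
        key = tuple(int(c) for c in rgb[fid])
        if key not in by_rgb:
            raise ValidationError(f"face {fid} colour {key} not in palette")
        name = by_rgb[key]
        if name != "non_impinged":
            assignments[fid] = name
    return mesh, FaceColorMap(mesh.n_faces, assignments)


def face_area(mesh: TriMesh, face_ids) -> float:
    """Total area (mm^2) of the given faces; the empty set has area 0."""
    ids = np.fromiter(face_ids, dtype=np.int64) if not isinstance(
        face_ids, np.ndarray) else face_ids.astype(np.int64)
    if ids.size == 0:
        return 0.0
    if ids.min() < 0 or ids.max() >= mesh.n_faces:
        raise ContractError("face id out of range")
    return float(mesh.face_areas[ids].sum())
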