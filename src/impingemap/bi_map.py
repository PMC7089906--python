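"""Bony-impingement mapping: detection, region growing, severity colours.

Within each posture's conical clearance angle (CCA), the cone aperture is
divided into ordered fractions (default 25/50/75/100 %).  Bone-to-bone
impingement (BTBI) intersects the bony femur with the pelvis; implant-to-
bone impingement (ITBI) intersects the prosthetic stem with the pelvis.
Every aperture/azimuth sample that crosses contributes its straddling
faces plus the region-grown impinged patches; a face keeps the smallest
fraction (most severe category) at which it was ever flagged.

Because smaller cones are subsets of larger ones, the face set flagged
within fraction ``f`` is nested inside the set for any larger fraction;
the collapsed per-face category is therefore exactly the smallest
fraction at which the face impinges.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .collision import contains_points, mesh_intersect
from .errors import ContractError
from .kinematics import (HipModel, SweepParams, conical_positions,
                         posture_axis, posture_transform)
from .mesh_core import TriMesh

logger = logging.getLogger(__name__)

MODE_BTBI = "BTBI"
MODE_ITBI = "ITBI"
MODE_COMBINED = "combined"


@dataclass(frozen=True)
class CCACategories:
    """Ordered severity bands as fractions of the per-posture CCA."""

    fractions: tuple = (0.25, 0.50, 0.75, 1.00)
    colors: tuple = ("red", "yellow", "green", "blue")

    def __post_init__(self):
        f = self.fractions
        if len(f) != len(self.colors):
            raise ContractError("fractions and colors must have the same length")
        if not all(0 < a <= 1 for a in f) or any(b <= a for a, b in zip(f, f[1:])):
            raise ContractError("fractions must be strictly increasing in (0, 1]")


def categorize(cca: float, categories: CCACategories) -> list[float]:
    """Aperture thresholds ``fraction * cca`` for each severity band."""
    if cca < 0:
        raise ContractError("cca must be non-negative")
    return [f * cca for f in categories.fractions]


@dataclass(frozen=True)
class Cluster:
    """An edge-connected set of faces produced by region growing."""

    faces: frozenset
    role: str | None = None


@dataclass
class ImpingementMap:
    """Per-face severity categories (the ITFs) on one bone.

    ``itf`` maps face id -> category index (0 = most severe fraction);
    ``provenance`` records which (activity, posture index) flagged each
    face.
    """

    bone: str
    mode: str
    itf: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    n_categories: int = 4

    def add(self, fid: int, category: int, source) -> None:
        cur = self.itf.get(fid)
        if cur is None or category < cur:
            self.itf[fid] = category
        self.provenance.setdefault(fid, set()).add(source)

    def itf_at_category(self, category: int) -> set:
        """Pre-collapse ITF set for a band: faces flagged at or before it."""
        return {f for f, c in self.itf.items() if c <= category}

    def faces_with_category(self, category: int) -> set:
        return {f for f, c in self.itf.items() if c == category}


# --------------------------------------------------------------------------
# Region growing
# --------------------------------------------------------------------------

def region_grow(mesh: TriMesh, crossed_vertices) -> list[Cluster]:
    """Seed/child region growing bounded by the intersection curve.

    A face is a *seed* iff none of its vertices is crossed; growth
    proceeds over shared edges between seed faces and stops at the
    boundary, so faces straddling the intersection curve belong to no
    cluster (the grown region is slightly smaller than the true patch).
    """
    crossed = set(int(v) for v in crossed_vertices)
    if crossed and (min(crossed) < 0 or max(crossed) >= mesh.n_vertices):
        raise ContractError("crossed vertex id out of range")
    faces = mesh.faces
    seed = np.ones(mesh.n_faces, dtype=bool)
    if crossed:
        mask = np.isin(faces, np.fromiter(crossed, dtype=np.int64))
        seed = ~mask.any(axis=1)
    adjacency = mesh.adjacency_list
    unvisited = seed.copy()
    clusters = []
    for start in range(mesh.n_faces):
        if not unvisited[start]:
            continue
        comp = []
        queue = deque([start])
        unvisited[start] = False
        while queue:
            f = queue.popleft()
            comp.append(f)
            for g in adjacency[f]:
                if unvisited[g]:
                    unvisited[g] = False
                    queue.append(g)
        clusters.append(Cluster(frozenset(int(f) for f in comp)))
    return clusters


def select_impinged(clusters, mesh: TriMesh, other: TriMesh, other_transform,
                    mesh_transform=None) -> set:
    """Face ids of the clusters lying inside the opposing body.

    A cluster is probed at the centroid of its largest face, offset
    inward (against the outward face normal) by one tenth of the median
    edge length, and tested against the opposing closed mesh by ray
    parity.  If the opposing mesh is open, falls back to flagging every
    boundary-adjacent cluster that is smaller than its neighbour across
    the boundary, with a warning.
    """
    clustered = set()
    for c in clusters:
        clustered |= c.faces
    if len(clustered) == mesh.n_faces:
        raise ContractError("select_impinged requires a non-empty crossing")

    if other.is_watertight:
        eps = 0.1 * mesh.median_edge_length
        pts = []
        for c in clusters:
            ids = np.fromiter(c.faces, dtype=np.int64)
            fid = ids[np.argmax(mesh.face_areas[ids])]
            p = mesh.face_centroids[fid] - eps * mesh.face_normals[fid]
            if mesh_transform is not None:
                m = np.asarray(mesh_transform)
                p = p @ m[:3, :3].T + m[:3, 3]
            pts.append(p)
        inside = contains_points(other, np.array(pts), transform=other_transform)
        out: set = set()
        for c, flag in zip(clusters, inside):
            if flag:
                out |= set(c.faces)
        return out

    logger.warning(
        "opposing mesh is not closed; selecting impinged clusters by the "
        "smaller-than-neighbour area heuristic")
    boundary = sorted(set(range(mesh.n_faces)) - clustered)
    face_cluster = {}
    for ci, c in enumerate(clusters):
        for f in c.faces:
            face_cluster[f] = ci
    adjacency = mesh.adjacency_list
    # group boundary faces into connected strips, collect touching clusters
    remaining = set(boundary)
    neighbour_sets = []
    while remaining:
        comp_clusters = set()
        queue = deque([remaining.pop()])
        while queue:
            f = queue.popleft()
            for g in adjacency[f]:
                g = int(g)
                if g in remaining:
                    remaining.discard(g)
                    queue.append(g)
                elif g in face_cluster:
                    comp_clusters.add(face_cluster[g])
        neighbour_sets.append(comp_clusters)
    areas = [float(mesh.face_areas[np.fromiter(c.faces, dtype=np.int64)].sum())
             for c in clusters]
    out = set()
    for group in neighbour_sets:
        if len(group) < 2:
            continue
        biggest = max(areas[ci] for ci in group)
        for ci in group:
            if areas[ci] < biggest:
                out |= set(clusters[ci].faces)
    return out


# --------------------------------------------------------------------------
# The STEP-2 sweep
# --------------------------------------------------------------------------

def _category_of(alpha: float, thresholds) -> int:
    for j, thr in enumerate(thresholds):
        if alpha <= thr + 1e-9:
            return j
    raise ContractError("alpha above the largest category threshold")


def map_bi(model: HipModel, profiles, categories: CCACategories,
           params: SweepParams, mode: str) -> dict:
    """Impingement maps for one mode, keyed by bone name.

    BTBI intersects femur vs pelvis and returns maps for both bones;
    ITBI intersects stem vs pelvis and returns the pelvis map only.
    """
    if mode not in (MODE_BTBI, MODE_ITBI):
        raise ContractError(f"mode must be {MODE_BTBI!r} or {MODE_ITBI!r}")
    moving_name = "femur" if mode == MODE_BTBI else "stem"
    moving: TriMesh = getattr(model, moving_name)
    pelvis = model.pelvis
    n_cat = len(categories.fractions)
    maps = {"pelvis": ImpingementMap("pelvis", mode, n_categories=n_cat)}
    if mode == MODE_BTBI:
        maps["femur"] = ImpingementMap("femur", mode, n_categories=n_cat)

    grow_cache: dict = {}

    def grown(mesh_name, mesh, crossed_vertices):
        key = (mesh_name, frozenset(crossed_vertices))
        if key not in grow_cache:
            grow_cache[key] = region_grow(mesh, crossed_vertices)
        return grow_cache[key]

    for profile in profiles:
        if len(profile.postures) != len(profile.cca):
            raise ContractError("malformed CCA profile")
        for i, (posture, cca) in enumerate(zip(profile.postures, profile.cca)):
            source = (profile.activity, i)
            T = posture_transform(posture, model)
            axis = posture_axis(posture, model)
            thresholds = categorize(cca, categories)
            n_steps = int(np.floor(cca / params.dt_alpha + 1e-9))
            for j in range(n_steps + 1):
                alpha = params.dt_alpha * j
                cat = _category_of(alpha, thresholds)
                cones = (conical_positions(axis, alpha, params.dt_con,
                                           model.hip_center)
                         if alpha > 0 else [np.eye(4)])
                for C in cones:
                    pose = C @ T
                    res = mesh_intersect(moving, pose, pelvis)
                    if not res.intersects:
                        continue
                    fids = set(res.crossed_faces_b)
                    clusters = grown("pelvis", pelvis,
                                     frozenset(res.crossed_vertices_b))
                    fids |= select_impinged(clusters, pelvis, moving, pose)
                    for f in fids:
                        maps["pelvis"].add(f, cat, source)
                    if mode == MODE_BTBI:
                        fids_f = set(res.crossed_faces_a)
                        clusters_f = grown("femur", moving,
                                           frozenset(res.crossed_vertices_a))
                        fids_f |= select_impinged(clusters_f, moving, pelvis,
                                                  np.eye(4), mesh_transform=pose)
                        for f in fids_f:
                            maps["femur"].add(f, cat, source)
    return maps


def filter_itbi(itbi: ImpingementMap, btbi: ImpingementMap) -> ImpingementMap:
    """Remove infeasible ITBI faces: pelvis ITFs common to both analyses.

    Stem regions seated in the femoral canal are covered by bone, so a
    pelvis contact predicted by both the stem and the bony femur cannot
    be produced by exposed implant; those faces revert to non-impinged
    in the ITBI map.  The BTBI map is unchanged.
    """
    if itbi.bone != btbi.bone:
        raise ContractError("ITBI/BTBI maps must be on the same bone")
    common = set(itbi.itf) & set(btbi.itf)
    return ImpingementMap(
        bone=itbi.bone, mode=itbi.mode,
        itf={f: c for f, c in itbi.itf.items() if f not in common},
        provenance={f: set(s) for f, s in itbi.provenance.items()
                    if f not in common},
        n_categories=itbi.n_categories,
    )


def combine_maps(itbi: ImpingementMap, btbi: ImpingementMap) -> ImpingementMap:
    """Merge two maps on the same bone, keeping the more severe category."""
    if itbi.bone != btbi.bone:
        raise ContractError("maps must be on the same bone")
    itf = dict(btbi.itf)
    for f, c in itbi.itf.items():
        if f not in itf or c < itf[f]:
            itf[f] = c
    provenance: dict = {}
    for src in (itbi, btbi):
        for f, s in src.provenance.items():
            provenance.setdefault(f, set()).update(s)
    return ImpingementMap(bone=itbi.bone, mode=MODE_COMBINED, itf=itf,
                          provenance=provenance,
                          n_categories=max(itbi.n_categories, btbi.n_categories))
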