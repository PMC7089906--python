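"""Outputs: colour-coded PLY meshes, area tables and pre/post reductions.

Three representation styles are supported: ITBI (pelvis only), BTBI
(pelvis and femur) and combined (pelvis carrying the merged map plus the
femur BTBI map).  Areas are summed per severity category; the pre- versus
post-operative comparison reports the percentage reduction of each
coloured area, which may legitimately be negative when the later geometry
carries bone absent from the earlier one.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bi_map import (MODE_BTBI, MODE_COMBINED, MODE_ITBI, CCACategories,
                     ImpingementMap, combine_maps)
from .errors import ContractError
from .kinematics import HipModel
from .mesh_core import FaceColorMap, TriMesh, face_area, save_colored_mesh

logger = logging.getLogger(__name__)


@dataclass
class AreaReport:
    """Coloured surface area per severity category (mm^2).

    When paired with a post-operative report, ``reduction_pct`` holds
    ``100 * (pre - post) / pre`` per category, or ``None`` where the
    pre-operative area is zero.
    """

    categories: tuple
    areas: dict
    pre: dict | None = None
    post: dict | None = None
    reduction_pct: dict | None = None


def color_map_from_impingement(imap: ImpingementMap, n_faces: int,
                               categories: CCACategories) -> FaceColorMap:
    return FaceColorMap(n_faces, {
        fid: categories.colors[cat] for fid, cat in imap.itf.items()})


def render_maps(model: HipModel, maps: dict, style: str, out_dir,
                categories: CCACategories | None = None,
                palette=None, mirror_back: bool = False) -> list[Path]:
    """Write the colour-coded PLY files for one representation style.

    ``maps`` is a mapping mode -> bone -> :class:`ImpingementMap` (the
    ITBI entry is expected to be already feasibility-filtered).  Returns
    the written paths: one pelvis file for ITBI, pelvis + femur for BTBI
    and for combined.
    """
    categories = categories or CCACategories()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def bone_mesh(name: str) -> TriMesh:
        mesh: TriMesh = getattr(model, name)
        return mesh.mirrored() if mirror_back else mesh

    def write(bone: str, imap: ImpingementMap, tag: str) -> Path:
        mesh = bone_mesh(bone)
        colors = color_map_from_impingement(imap, mesh.n_faces, categories)
        path = out / f"{bone}_{tag}.ply"
        save_colored_mesh(mesh, colors, path, palette)
        return path

    if style == MODE_ITBI:
        if MODE_ITBI not in maps or "pelvis" not in maps[MODE_ITBI]:
            raise ContractError("ITBI style requires an ITBI pelvis map")
        return [write("pelvis", maps[MODE_ITBI]["pelvis"], "itbi")]
    if style == MODE_BTBI:
        if MODE_BTBI not in maps or not {"pelvis", "femur"} <= set(maps[MODE_BTBI]):
            raise ContractError("BTBI style requires pelvis and femur maps")
        return [write("pelvis", maps[MODE_BTBI]["pelvis"], "btbi"),
                write("femur", maps[MODE_BTBI]["femur"], "btbi")]
    if style == MODE_COMBINED:
        if not (MODE_ITBI in maps and MODE_BTBI in maps):
            raise ContractError("combined style requires ITBI and BTBI maps")
        merged = combine_maps(maps[MODE_ITBI]["pelvis"], maps[MODE_BTBI]["pelvis"])
        return [write("pelvis", merged, "combined"),
                write("femur", maps[MODE_BTBI]["femur"], "combined")]
    raise ContractError(f"unknown representation style {style!r}")


def area_report(mesh: TriMesh, imap: ImpingementMap,
                categories: CCACategories) -> AreaReport:
    """Sum of face areas per severity category."""
    areas = {}
    for j, name in enumerate(categories.colors):
        ids = [f for f, c in imap.itf.items() if c == j]
        areas[name] = face_area(mesh, ids)
    return AreaReport(categories=tuple(categories.colors), areas=areas)


def reduction(pre: AreaReport, post: AreaReport) -> AreaReport:
    """Percentage reduction of each coloured area from pre to post."""
    if pre.categories != post.categories:
        raise ContractError("area reports use different category sets")
    red = {}
    for name in pre.categories:
        p, q = pre.areas[name], post.areas[name]
        if p > 0:
            red[name] = 100.0 * (p - q) / p
            if red[name] < 0:
                logger.warning(
                    "negative reduction for %s area (pre %.3f mm^2, post %.3f "
                    "mm^2): the later geometry carries extra surface", name, p, q)
        else:
            red[name] = None
    return AreaReport(categories=pre.categories, areas=dict(post.areas),
                      pre=dict(pre.areas), post=dict(post.areas),
                      reduction_pct=red)


# --------------------------------------------------------------------------
# CSV schemas
# --------------------------------------------------------------------------

def write_areas_csv(rows, path) -> None:
    """``rows``: iterable of (bone, mode, category, area_mm2)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bone", "mode", "category", "area_mm2"])
        for row in rows:
            w.writerow(list(row))


def read_areas_csv(path) -> dict:
    """(bone, mode, category) -> area_mm2."""
    out = {}
    with open(path, newline="") as fh:
        for r in csv.DictReader(fh):
            out[(r["bone"], r["mode"], r["category"])] = float(r["area_mm2"])
    return out


def write_reduction_csv(rows, path) -> None:
    """``rows``: iterable of (bone, mode, category, pre, post, reduction_pct)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bone", "mode", "category", "pre_mm2", "post_mm2",
                    "reduction_pct"])
        for bone, mode, cat, pre, post, red in rows:
            w.writerow([bone, mode, cat, pre, post,
                        "" if red is None else red])
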