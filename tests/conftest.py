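import math

import numpy as np
import pytest
import trimesh

import impingemap as im

# Coarse fixture meshes keep the sweeps fast while staying well below the
# angular tolerance of the analytic oracles (see mesh_angle_slack).
FIXTURE_EDGE = 2.5


@pytest.fixture(scope="session")
def default_spec():
    return im.FixtureSpec(mesh_edge_length=FIXTURE_EDGE)


@pytest.fixture(scope="session")
def default_model(default_spec):
    return im.make_hip_fixture(default_spec)


def blue_band_spec():
    """Bump engineered to first contact at 15 deg, inside the top band of
    a CCA of about 17 deg (rim contact at 16.1 deg)."""
    gamma = 15.0 + math.degrees(math.asin(12.0 / 40.0))
    return im.FixtureSpec(
        cup_radius=25, rim_opening_half_angle=30, head_radius=12,
        neck_radius=6, neck_length=50, femur_radius=9,
        bump=im.bump_at(gamma, 40.0, 3.0), mesh_edge_length=FIXTURE_EDGE)


def red_bump_spec():
    """Bump already in contact with the bone proxy at the neutral posture."""
    return im.FixtureSpec(
        cup_radius=25, rim_opening_half_angle=30, head_radius=12,
        neck_radius=6, neck_length=50, femur_radius=9,
        bump=im.bump_at(10.0, 40.0, 3.0), mesh_edge_length=FIXTURE_EDGE)


@pytest.fixture(scope="session")
def band_spec():
    return blue_band_spec()


@pytest.fixture(scope="session")
def band_model(band_spec):
    return im.make_hip_fixture(band_spec)


@pytest.fixture(scope="session")
def band_profile(band_model):
    params = im.SweepParams(dt_alpha=1.0, n_alpha=31, dt_con=10.0)
    cca, capped = im.compute_cca(band_model, im.Posture(), params)
    return im.CCAProfile("neutral", [im.Posture()], [cca], [capped]), params


@pytest.fixture(scope="session")
def band_maps(band_model, band_profile):
    profile, params = band_profile
    return im.map_bi(band_model, [profile], im.CCACategories(), params, "BTBI")


def icosphere_mesh(radius=10.0, subdivisions=2, center=(0, 0, 0)) -> im.TriMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return im.TriMesh(np.asarray(tm.vertices) + np.asarray(center, float),
                      np.asarray(tm.faces))


def point_mesh_distance(points, mesh: im.TriMesh) -> np.ndarray:
    """Min distance from each point to the mesh surface (brute force)."""
    pts = np.atleast_2d(points)
    out = np.empty(len(pts))
    tri = mesh.triangles
    for i, p in enumerate(pts):
        closest = trimesh.triangles.closest_point(tri, np.tile(p, (len(tri), 1)))
        out[i] = np.linalg.norm(closest - p, axis=1).min()
    return out


def write_cube_stl(path):
    trimesh.creation.box(extents=(1, 1, 1)).export(str(path))
    return path


ZERO_AREA_STL = """solid degenerate
facet normal 0 0 1
  outer loop
    vertex 0 0 0
    vertex 1 0 0
    vertex 0 1 0
  endloop
endfacet
facet normal 0 0 1
  outer loop
    vertex 0 0 0
    vertex 1 0 0
    vertex 2 0 0
  endloop
endfacet
endsolid degenerate
"""
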