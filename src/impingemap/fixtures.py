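"""Parametric hip fixtures with closed-form contact angles.

These synthetic geometries stand in for patient data in tests and
examples: a spherical-cap liner with a circular rim, a ball-plus-neck
stem proxy, a cylindrical bone-proxy femur sleeve, and a pelvis made of
a plate well clear of the motion plus an optional spherical prominence
("bump") near the rim.  All bodies are concentric with the hip centre at
the origin, the neutral femoral axis pointing along -z and the cup
opening facing -z, so first-contact tilt angles have closed forms:

* rim contact of the neck cylinder (radius ``r_n``) with the rim circle
  (cup radius ``R``, opening half-angle ``beta`` from the -z axis):
  the distance from a liner point at polar angle ``psi`` off the tilted
  neck axis to that axis is ``R * sin(psi)``, minimised on the rim where
  ``psi = beta - theta``; contact therefore occurs at

      theta* = beta - asin(r_n / R)

* bump reach of a cylinder of radius ``r`` (bone proxy or neck) against
  a spherical bump of radius ``r_b`` centred at distance ``h`` from the
  hip centre, at angle ``gamma`` from -z:

      theta_b = gamma - asin((r + r_b) / h)

Both formulas are validated against dense brute-force pose sweeps with
exhaustive mesh intersection in the test suite before being trusted as
oracles.  Mesh discretisation only shrinks the surfaces (chords lie
inside arcs), so meshed contact occurs at or slightly above the analytic
angle; the corresponding angular slack is :func:`mesh_angle_slack`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
import yaml

from .errors import ContractError, ValidationError
from .kinematics import HipModel
from .mesh_core import TriMesh

#: Sentinel returned by :func:`analytic_bump_reach` when no tilt of the
#: chosen body can touch the bump.
UNREACHABLE = float("inf")


@dataclass(frozen=True)
class BumpSpec:
    """A spherical bony prominence on the pelvis.

    ``direction``: unit vector from the hip centre to the bump centre;
    ``height``: distance (mm) from the hip centre to the bump centre;
    ``radius``: bump sphere radius (mm).
    """

    direction: tuple
    height: float
    radius: float

    def center(self):
        d = np.asarray(self.direction, dtype=np.float64)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValidationError("bump direction must be non-zero")
        return d / n * self.height


def bump_at(gamma_deg: float, height: float, radius: float,
            azimuth_deg: float = 0.0) -> BumpSpec:
    """Bump placed at polar angle ``gamma_deg`` from the neutral femoral
    axis (-z), at the given conical azimuth (0 = towards +x)."""
    g = math.radians(gamma_deg)
    p = math.radians(azimuth_deg)
    d = (math.sin(g) * math.cos(p), -math.sin(g) * math.sin(p), -math.cos(g))
    return BumpSpec(direction=d, height=height, radius=radius)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic hip (all lengths in mm, angles deg)."""

    cup_radius: float = 25.0
    rim_opening_half_angle: float = 45.0
    head_radius: float = 14.0
    neck_radius: float = 6.0
    neck_length: float = 50.0
    femur_radius: float = 9.0
    bump: BumpSpec | None = None
    bump_on: str = "pelvis"
    mesh_edge_length: float = 2.0
    random_seed: int = 0

    def __post_init__(self):
        if not (0 < self.neck_radius < self.head_radius < self.cup_radius):
            raise ValidationError(
                "fixture requires neck_radius < head_radius < cup_radius")
        if not (0 < self.rim_opening_half_angle < 90):
            raise ValidationError("rim_opening_half_angle must be in (0, 90) deg")
        if self.mesh_edge_length <= 0:
            raise ValidationError("mesh_edge_length must be positive")
        if self.neck_length <= self.cup_radius:
            raise ValidationError("neck must extend beyond the cup radius")
        if not (self.neck_radius < self.femur_radius):
            raise ValidationError("femur_radius must exceed neck_radius")
        if self.bump_on != "pelvis":
            raise ContractError("bumps are supported on the pelvis proxy only")


# --------------------------------------------------------------------------
# Mesh generators (shared-vertex grids; outward winding fixed via trimesh)
# --------------------------------------------------------------------------

def _as_trimesh_fixed(vertices, faces) -> TriMesh:
    tm = trimesh.Trimesh(np.asarray(vertices, float), np.asarray(faces, np.int64),
                         process=False)
    if tm.is_watertight:
        tm.fix_normals()
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def spherical_cap_band(radius: float, theta_min_deg: float, theta_max_deg: float,
                       edge: float) -> TriMesh:
    """Open spherical band at ``radius`` with polar angle (from -z) in
    [theta_min, theta_max]."""
    t0, t1 = math.radians(theta_min_deg), math.radians(theta_max_deg)
    n_t = max(2, math.ceil(radius * (t1 - t0) / edge))
    smax = max(math.sin(t0), math.sin(t1),
               1.0 if t0 <= math.pi / 2 <= t1 else 0.0)
    n_p = max(12, math.ceil(2 * math.pi * radius * smax / edge))
    thetas = np.linspace(t0, t1, n_t + 1)
    phis = np.linspace(0, 2 * math.pi, n_p, endpoint=False)
    st, ct = np.sin(thetas), np.cos(thetas)
    verts = np.empty(((n_t + 1) * n_p, 3))
    for i in range(n_t + 1):
        verts[i * n_p:(i + 1) * n_p, 0] = radius * st[i] * np.cos(phis)
        verts[i * n_p:(i + 1) * n_p, 1] = radius * st[i] * np.sin(phis)
        verts[i * n_p:(i + 1) * n_p, 2] = -radius * ct[i]
    faces = []
    for i in range(n_t):
        for j in range(n_p):
            a = i * n_p + j
            b = i * n_p + (j + 1) % n_p
            c = (i + 1) * n_p + (j + 1) % n_p
            d = (i + 1) * n_p + j
            faces.append((a, b, c))
            faces.append((a, c, d))
    return TriMesh(verts, np.array(faces, dtype=np.int64))


def capped_cylinder(radius: float, z_top: float, z_bot: float,
                    edge: float) -> TriMesh:
    """Closed cylinder along z from ``z_bot`` to ``z_top``."""
    if z_top <= z_bot:
        raise ContractError("z_top must exceed z_bot")
    n_p = max(12, math.ceil(2 * math.pi * radius / edge))
    n_z = max(1, math.ceil((z_top - z_bot) / edge))
    phis = np.linspace(0, 2 * math.pi, n_p, endpoint=False)
    zs = np.linspace(z_top, z_bot, n_z + 1)
    verts = []
    for z in zs:
        for p in phis:
            verts.append((radius * math.cos(p), radius * math.sin(p), z))
    top_c = len(verts)
    verts.append((0.0, 0.0, z_top))
    bot_c = len(verts)
    verts.append((0.0, 0.0, z_bot))
    faces = []
    for i in range(n_z):
        for j in range(n_p):
            a = i * n_p + j
            b = i * n_p + (j + 1) % n_p
            c = (i + 1) * n_p + (j + 1) % n_p
            d = (i + 1) * n_p + j
            faces.append((a, c, b))
            faces.append((a, d, c))
    for j in range(n_p):
        faces.append((top_c, j, (j + 1) % n_p))
        base = n_z * n_p
        faces.append((bot_c, base + (j + 1) % n_p, base + j))
    return _as_trimesh_fixed(np.array(verts), np.array(faces, dtype=np.int64))


def icosphere(radius: float, edge: float) -> TriMesh:
    """Closed sphere with approximately the requested edge length."""
    sub = int(np.clip(math.ceil(math.log2(max(1.05 * radius / edge, 1.0))), 1, 5))
    tm = trimesh.creation.icosphere(subdivisions=sub, radius=radius)
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def _plate(cup_radius: float) -> TriMesh:
    """Pelvis plate: a coarse closed box parked superior to the cup,
    clear of every swept femur pose."""
    tm = trimesh.creation.box(extents=(3 * cup_radius, 3 * cup_radius,
                                       0.4 * cup_radius))
    tm = tm.subdivide().subdivide()
    tm.apply_translation((0.0, 0.0, 1.6 * cup_radius))
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def _concat(a: TriMesh, b: TriMesh) -> TriMesh:
    v = np.vstack([a.vertices, b.vertices])
    f = np.vstack([a.faces, b.faces + a.n_vertices])
    return TriMesh(v, f)


# --------------------------------------------------------------------------
# Fixture assembly and analytic oracles
# --------------------------------------------------------------------------

#: Angular extent of the liner band above the rim; the neck only ever
#: first contacts at the rim, so the band need not reach the cup pole.
LINER_BAND_DEG = 60.0


def make_hip_fixture(spec: FixtureSpec) -> HipModel:
    """Assemble the synthetic :class:`HipModel` (deterministic)."""
    e = spec.mesh_edge_length
    beta = spec.rim_opening_half_angle
    liner = spherical_cap_band(spec.cup_radius, beta,
                               min(beta + LINER_BAND_DEG, 175.0), e)
    head = icosphere(spec.head_radius, e)
    neck = capped_cylinder(spec.neck_radius, 0.0, -spec.neck_length, e)
    stem = _concat(head, neck)
    femur = capped_cylinder(spec.femur_radius, -spec.head_radius,
                            -spec.neck_length, e)
    pelvis = _plate(spec.cup_radius)
    if spec.bump is not None:
        bump = icosphere(spec.bump.radius, min(e, spec.bump.radius * 0.6))
        bump = TriMesh(bump.vertices + spec.bump.center(), bump.faces)
        pelvis = _concat(pelvis, bump)
    return HipModel(
        pelvis=pelvis, femur=femur, stem=stem, liner=liner,
        hip_center=np.zeros(3),
        femur_axis_point=np.array([0.0, 0.0, -spec.neck_length]),
        side="right",
    )


def analytic_rim_contact(spec: FixtureSpec, azimuth: float = 0.0) -> float:
    """Closed-form tilt (deg, from the neutral axis) at which the neck
    cylinder first touches the liner rim circle.

    Independent of ``azimuth`` for this axisymmetric geometry; the
    argument is kept so tests can assert that symmetry.
    """
    arg = spec.neck_radius / spec.cup_radius
    theta = spec.rim_opening_half_angle - math.degrees(math.asin(arg))
    if theta <= 0:
        raise ContractError(
            "neck already impinges at the neutral posture; no positive clearance")
    return theta


def analytic_bump_reach(spec: FixtureSpec, body: str = "femur") -> float:
    """Closed-form tilt (deg) at which the chosen body (bone-proxy
    ``'femur'`` sleeve or prosthetic ``'stem'`` neck) first touches the
    pelvis bump, or :data:`UNREACHABLE`.

    A value <= 0 means the bump is already in contact at zero aperture.
    """
    if spec.bump is None:
        raise ContractError("fixture has no bump")
    if body == "femur":
        r_cyl = spec.femur_radius
        span = (spec.head_radius, spec.neck_length)
    elif body == "stem":
        r_cyl = spec.neck_radius
        span = (0.0, spec.neck_length)
    else:
        raise ContractError(f"unknown body {body!r}")
    r = r_cyl + spec.bump.radius
    h = spec.bump.height
    if r >= h:
        raise ContractError("bump overlaps the hip centre region")
    c = spec.bump.center()
    gamma = math.degrees(math.acos(np.clip(-c[2] / h, -1.0, 1.0)))
    half = math.degrees(math.asin(r / h))
    reach = gamma - half
    foot = h * math.cos(math.radians(half))
    margin = spec.bump.radius
    if reach > 90.0 or not (span[0] + margin <= foot <= span[1] - margin):
        return UNREACHABLE
    return reach


def mesh_angle_slack(spec: FixtureSpec) -> float:
    """Upper bound (deg) on how far meshing can delay the rim contact.

    Chords of the rim circle and of the neck polygon both lie inside
    their arcs by at most the sagitta ``s ~= L^2 / (8 r)`` for edge
    length ``L``; the contact angle shifts by at most the combined
    sagitta divided by the rate of approach ``sqrt(R^2 - r_n^2)``.
    """
    L = spec.mesh_edge_length
    sag_rim = L ** 2 / (8 * spec.cup_radius * math.sin(
        math.radians(spec.rim_opening_half_angle)))
    sag_neck = L ** 2 / (8 * spec.neck_radius)
    rate = math.sqrt(spec.cup_radius ** 2 - spec.neck_radius ** 2)
    return math.degrees((sag_rim + sag_neck) / rate)


# --------------------------------------------------------------------------
# On-disk fixtures for the CLI
# --------------------------------------------------------------------------

def write_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Write STL files plus a ready-to-run YAML config; returns the config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = make_hip_fixture(spec)
    for name in ("pelvis", "femur", "stem", "liner"):
        mesh: TriMesh = getattr(model, name)
        trimesh.Trimesh(mesh.vertices, mesh.faces, process=False).export(
            str(out / f"{name}.stl"))
    config = {
        "meshes": {name: str(out / f"{name}.stl")
                   for name in ("pelvis", "femur", "stem", "liner")},
        "hip_center": [0.0, 0.0, 0.0],
        "femur_axis_point": [0.0, 0.0, -float(spec.neck_length)],
        "side": "right",
        "sweep": {"dt_pos": 5.0, "dt_alpha": 1.0, "n_alpha": 61, "dt_con": 10.0},
        "output_dir": str(out / "results"),
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    return config


def load_fixture_spec(path) -> FixtureSpec:
    data = yaml.safe_load(Path(path).read_text()) or {}
    bump = data.pop("bump", None)
    if bump is not None:
        bump = BumpSpec(direction=tuple(bump["direction"]),
                        height=float(bump["height"]),
                        radius=float(bump["radius"]))
    return FixtureSpec(bump=bump, **{k: v for k, v in data.items()})
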