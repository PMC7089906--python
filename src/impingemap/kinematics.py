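"""Hip joint kinematics: postures, activity discretisation and conical motion.

Coordinate convention (right hip, pelvis-fixed anatomical frame):

* ``x`` antero-posterior (positive anterior),
* ``y`` medio-lateral,
* ``z`` superior-inferior (positive superior; the neutral femoral axis
  points roughly inferior, i.e. towards negative ``z``).

The joint is modelled as a pure ball joint: every posture is a rotation
about the hip centre, composed in the fixed order
flexion (about ``y``) -> abduction (about ``x``) -> axial rotation (about
the current femoral axis).  Left hips are handled by mirroring the input
meshes about the sagittal (``x``-``z``) plane so all internal maths can
assume a right hip.

Extension is encoded as negative flexion, adduction as negative
abduction, and external rotation as negative (internal-positive)
rotation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .errors import ContractError, ValidationError
from .mesh_core import TriMesh

_ANGLE_LO, _ANGLE_HI = -90.0, 150.0


def _unit(v):
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0:
        raise ContractError("zero-length vector where a direction is required")
    return v / n


def rotation_about(axis, angle_deg: float, center) -> np.ndarray:
    """4x4 rigid transform: rotation by ``angle_deg`` about ``axis``
    through ``center``."""
    R = Rotation.from_rotvec(np.radians(angle_deg) * _unit(axis)).as_matrix()
    T = np.eye(4)
    T[:3, :3] = R
    c = np.asarray(center, dtype=np.float64)
    T[:3, 3] = c - R @ c
    return T


def apply_transform(T, points):
    """Apply a 4x4 homogeneous transform to an (n, 3) array or a point."""
    p = np.asarray(points, dtype=np.float64)
    return p @ np.asarray(T)[:3, :3].T + np.asarray(T)[:3, 3]


@dataclass(frozen=True)
class Posture:
    """Hip joint angles in degrees.

    ``flexion`` (negative = extension), ``abduction`` (negative =
    adduction), ``rotation`` (positive = internal, negative = external).
    """

    flexion: float = 0.0
    abduction: float = 0.0
    rotation: float = 0.0

    def __post_init__(self):
        for name in ("flexion", "abduction", "rotation"):
            a = getattr(self, name)
            if not math.isfinite(a) or not (_ANGLE_LO <= a <= _ANGLE_HI):
                raise ValidationError(
                    f"{name}={a} outside the sane range [{_ANGLE_LO}, {_ANGLE_HI}] deg")

    def as_array(self):
        return np.array([self.flexion, self.abduction, self.rotation])


@dataclass(frozen=True)
class Activity:
    """A hip motion given by its start and end postures."""

    name: str
    initial: Posture
    final: Posture

    def __post_init__(self):
        if np.allclose(self.initial.as_array(), self.final.as_array()):
            raise ValidationError(f"activity {self.name!r} has zero range")


@dataclass(frozen=True)
class SweepParams:
    """Resolutions of the three nested sweeps.

    ``dt_pos``: posture step along an activity (deg).
    ``dt_alpha``: aperture-angle step of the clearance search (deg).
    ``n_alpha``: number of aperture samples; the search is capped at
    ``dt_alpha * (n_alpha - 1)``.
    ``dt_con``: azimuthal step of the conical motion (deg, must divide 360).
    """

    dt_pos: float = 5.0
    dt_alpha: float = 1.0
    n_alpha: int = 61
    dt_con: float = 10.0

    def __post_init__(self):
        if self.dt_pos <= 0 or self.dt_alpha <= 0 or self.dt_con <= 0:
            raise ValidationError("sweep resolutions must be positive")
        if self.n_alpha < 2:
            raise ValidationError("n_alpha must be at least 2")
        n = 360.0 / self.dt_con
        if abs(n - round(n)) > 1e-9:
            raise ValidationError("dt_con must divide 360 evenly")

    @property
    def max_alpha(self) -> float:
        return self.dt_alpha * (self.n_alpha - 1)


@dataclass
class HipModel:
    """All geometry of one hip in a common frame, implants at planned pose."""

    pelvis: TriMesh
    femur: TriMesh
    stem: TriMesh
    liner: TriMesh
    hip_center: np.ndarray
    femur_axis_point: np.ndarray
    side: str = "right"

    def __post_init__(self):
        self.hip_center = np.asarray(self.hip_center, dtype=np.float64)
        self.femur_axis_point = np.asarray(self.femur_axis_point, dtype=np.float64)
        if np.allclose(self.hip_center, self.femur_axis_point):
            raise ValidationError("hip_center and femur_axis_point coincide")
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def neutral_axis(self):
        """Unit vector from hip centre towards the distal femoral axis point."""
        return _unit(self.femur_axis_point - self.hip_center)

    def mirrored(self) -> "HipModel":
        """Mirror about the sagittal plane (flips the side label)."""
        def mp(p):
            q = np.array(p, dtype=np.float64)
            q[1] *= -1.0
            return q

        return HipModel(
            pelvis=self.pelvis.mirrored(),
            femur=self.femur.mirrored(),
            stem=self.stem.mirrored(),
            liner=self.liner.mirrored(),
            hip_center=mp(self.hip_center),
            femur_axis_point=mp(self.femur_axis_point),
            side="left" if self.side == "right" else "right",
        )


# --------------------------------------------------------------------------
# Loop 1: activity discretisation
# --------------------------------------------------------------------------

def discretize_activity(activity: Activity, dt_pos: float) -> list[Posture]:
    """Discretise a motion into postures by simultaneous linear interpolation.

    The largest-moving angle component changes by ``dt_pos`` per step;
    both endpoints are always included (the final posture is appended
    when the range is not an integer multiple of ``dt_pos``).
    """
    if dt_pos <= 0:
        raise ContractError("dt_pos must be positive")
    a0 = activity.initial.as_array()
    a1 = activity.final.as_array()
    max_range = float(np.abs(a1 - a0).max())
    if max_range == 0:
        raise ContractError(f"activity {activity.name!r} has zero range")
    n_steps = int(math.floor(max_range / dt_pos + 1e-9))
    ts = [k * dt_pos / max_range for k in range(n_steps + 1)]
    if ts[-1] < 1.0 - 1e-9:
        ts.append(1.0)
    else:
        ts[-1] = 1.0
    return [Posture(*(a0 + t * (a1 - a0))) for t in ts]


# --------------------------------------------------------------------------
# Posture transform
# --------------------------------------------------------------------------

def posture_transform(posture: Posture, model: HipModel) -> np.ndarray:
    """4x4 rigid transform placing the femur (and stem) at ``posture``.

    Pure rotation about the hip centre: flexion about the medio-lateral
    axis, then abduction about the antero-posterior axis, then axial
    rotation about the femoral axis as carried by the first two
    rotations.  The zero posture is the identity.
    """
    c = model.hip_center
    R1 = Rotation.from_rotvec(np.radians(posture.flexion) * np.array([0.0, 1.0, 0.0]))
    R2 = Rotation.from_rotvec(np.radians(posture.abduction) * np.array([1.0, 0.0, 0.0]))
    axis = (R2 * R1).apply(model.neutral_axis)
    R3 = Rotation.from_rotvec(np.radians(posture.rotation) * _unit(axis))
    R = (R3 * R2 * R1).as_matrix()
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = c - R @ c
    return T


def posture_axis(posture: Posture, model: HipModel) -> np.ndarray:
    """Unit femoral axis direction at ``posture``."""
    T = posture_transform(posture, model)
    return _unit(apply_transform(T, model.femur_axis_point) - model.hip_center)


# --------------------------------------------------------------------------
# Loop 3: conical motion
# --------------------------------------------------------------------------

def _perpendicular(u):
    """A deterministic unit vector perpendicular to ``u``."""
    basis = np.eye(3)
    k = int(np.argmin(np.abs(u)))
    w = basis[k] - np.dot(basis[k], u) * u
    return _unit(w)


def conical_positions(posture_axis, alpha: float, dt_con: float,
                      hip_center) -> list[np.ndarray]:
    """Rigid transforms realising one ring of the conical motion.

    Transform ``k`` tilts the femur about the hip centre so that its axis
    makes angle ``alpha`` with ``posture_axis`` at azimuth ``k * dt_con``;
    there are ``360 / dt_con`` of them.  ``alpha = 0`` yields identities.
    """
    if alpha < 0:
        raise ContractError("alpha must be non-negative")
    n = 360.0 / dt_con
    if dt_con <= 0 or abs(n - round(n)) > 1e-9:
        raise ContractError("dt_con must be positive and divide 360 evenly")
    n = int(round(n))
    u = _unit(posture_axis)
    c = np.asarray(hip_center, dtype=np.float64)
    if alpha == 0:
        return [np.eye(4) for _ in range(n)]
    e1 = _perpendicular(u)
    e2 = np.cross(u, e1)
    a = np.radians(alpha)
    out = []
    for k in range(n):
        phi = np.radians(k * dt_con)
        d = np.cos(a) * u + np.sin(a) * (np.cos(phi) * e1 + np.sin(phi) * e2)
        w = _unit(np.cross(u, d))
        R = Rotation.from_rotvec(a * w).as_matrix()
        T = np.eye(4)
        T[:3, :3] = R
        T[:3, 3] = c - R @ c
        out.append(T)
    return out


# --------------------------------------------------------------------------
# Activity files and the packaged default activity set
# --------------------------------------------------------------------------

def default_activities() -> list[Activity]:
    """The four hypothetical motions commonly checked intra-operatively.

    Extension to 10 deg, flexion to 90 deg, external rotation to 25 deg at
    10 deg extension, and internal rotation to 35 deg at 90 deg flexion.
    """
    return [
        Activity("Extn", Posture(0, 0, 0), Posture(-10, 0, 0)),
        Activity("Flex", Posture(0, 0, 0), Posture(90, 0, 0)),
        Activity("ER_Ext", Posture(-10, 0, 0), Posture(-10, 0, -25)),
        Activity("IR_Flex", Posture(90, 0, 0), Posture(90, 0, 35)),
    ]


def load_activities(path) -> list[Activity]:
    """Read activities from a YAML or JSON list of
    ``{name, initial: {flexion, abduction, rotation}, final: {...}}``."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    out = []
    for item in data:
        out.append(Activity(
            name=str(item["name"]),
            initial=Posture(**{k: float(v) for k, v in item["initial"].items()}),
            final=Posture(**{k: float(v) for k, v in item["final"].items()}),
        ))
    return out


def save_activities(activities, path) -> None:
    data = [
        {
            "name": a.name,
            "initial": {"flexion": a.initial.flexion, "abduction": a.initial.abduction,
                        "rotation": a.initial.rotation},
            "final": {"flexion": a.final.flexion, "abduction": a.final.abduction,
                      "rotation": a.final.rotation},
        }
        for a in activities
    ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
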