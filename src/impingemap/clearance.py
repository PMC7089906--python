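"""Per-posture conical clearance angle (CCA) search.

For every posture of a discretised activity, a hypothetical conical
motion of the femur is constructed about the femoral axis at that
posture.  The aperture angle is swept from zero upwards on a grid
``alpha_J = dt_alpha * (J - 1)``; at each aperture every azimuthal
position of the cone is checked for prosthetic impingement (stem/neck
surface against liner surface).  The first aperture at which any
position impinges is the CCA of the posture — the search starts at
``alpha = 0``, so a CCA of 0 encodes impingement of the posture itself.
If the full grid is clear the CCA is capped at ``dt_alpha * (n_alpha - 1)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

from .collision import check_pi
from .kinematics import (Activity, HipModel, Posture, SweepParams,
                         conical_positions, discretize_activity,
                         posture_axis, posture_transform)


@dataclass
class CCAProfile:
    """Per-posture conical clearance angles for one activity."""

    activity: str
    postures: list
    cca: list
    capped: list

    def __post_init__(self):
        if not (len(self.postures) == len(self.cca) == len(self.capped)):
            raise ValueError("profile lists must have equal length")


def compute_cca(model: HipModel, posture: Posture,
                params: SweepParams) -> tuple[float, bool]:
    """CCA of one posture: (angle in degrees, capped flag).

    ``capped`` is true exactly when the returned angle equals the grid
    maximum ``dt_alpha * (n_alpha - 1)``.
    """
    T = posture_transform(posture, model)
    axis = posture_axis(posture, model)
    max_alpha = params.max_alpha
    for j in range(params.n_alpha):
        alpha = params.dt_alpha * j
        if alpha == 0:
            # all conical positions coincide at zero aperture
            if check_pi(model.stem, T, model.liner):
                return 0.0, max_alpha == 0.0
            continue
        for C in conical_positions(axis, alpha, params.dt_con, model.hip_center):
            if check_pi(model.stem, C @ T, model.liner):
                return alpha, alpha == max_alpha
    return max_alpha, True


def compute_profile(model: HipModel, activity: Activity,
                    params: SweepParams) -> CCAProfile:
    """CCA for every posture of the discretised activity, in order."""
    postures = discretize_activity(activity, params.dt_pos)
    cca, capped = [], []
    for p in postures:
        a, c = compute_cca(model, p, params)
        cca.append(a)
        capped.append(c)
    return CCAProfile(activity.name, postures, cca, capped)


def write_profiles_csv(profiles, path) -> None:
    """CSV behind the per-posture CCA summaries (box-plot data)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["activity", "posture_index", "flexion_deg", "abduction_deg",
                    "rotation_deg", "cca_deg", "capped"])
        for prof in profiles:
            for i, (p, a, c) in enumerate(zip(prof.postures, prof.cca, prof.capped)):
                w.writerow([prof.activity, i, p.flexion, p.abduction, p.rotation,
                            a, int(c)])


def read_profiles_csv(path) -> list[CCAProfile]:
    rows_by_activity: dict[str, list] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows_by_activity.setdefault(row["activity"], []).append(row)
    out = []
    for name, rows in rows_by_activity.items():
        rows.sort(key=lambda r: int(r["posture_index"]))
        out.append(CCAProfile(
            activity=name,
            postures=[Posture(float(r["flexion_deg"]), float(r["abduction_deg"]),
                              float(r["rotation_deg"])) for r in rows],
            cca=[float(r["cca_deg"]) for r in rows],
            capped=[bool(int(r["capped"])) for r in rows],
        ))
    return out
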