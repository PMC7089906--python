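# Methods

## Model and coordinate conventions

All geometry lives in a right-handed patient-like frame centred on the
hip joint:

* the **hip centre** (centre of the prosthetic head) is the origin of
  every rotation;
* **x** points antero-posteriorly, **y** medio-laterally, **z**
  superiorly;
* the neutral femoral axis runs from the hip centre towards the knee,
  i.e. along **−z**; the acetabular cup opens towards **−z** as well.

Left hips are mirrored about the x–z plane (y → −y, with triangle
winding reversed so normals stay outward) on load, analysed as right
hips, and mirrored back before any mesh is written. This keeps one set
of sign conventions throughout the analysis.

A **posture** is (flexion, abduction, rotation) in degrees, applied in
that order: flexion about the y axis, abduction about the (new) x axis,
axial rotation about the current femoral axis. All rotations fix the
hip centre. An **activity** is a linear interpolation between an
initial and a final posture, discretised every `Δt_POS` degrees of the
largest component range, with the final posture appended when the range
is not a multiple of the step. The default activity set covers
extension 0→−10°, flexion 0→90°, external rotation at −10° extension
(0→−25°) and internal rotation at 90° flexion (0→35°).

## Conical clearance angle (CCA)

For each posture the femur (with stem) is tilted away from its current
axis over a cone of aperture α. Apertures are swept as
`α_J = Δt_α · (J − 1)`, J = 1…N_α; at each aperture the tilted axis is
placed at `360 / Δt_CON` equally spaced conical azimuths (azimuth 0
tilts towards +x, increasing azimuths towards −y). The tilt transform
is the minimal rotation carrying the posture axis onto the tilted axis,
so α is exactly the angle between the two axes.

The **CCA** of a posture is the smallest swept aperture at which the
stem crosses the liner (prosthetic impingement, PI) at any azimuth,
evaluated in increasing α with early exit. `CCA = 0` means the posture
itself already impinges. If no aperture up to the grid maximum
`Δt_α · (N_α − 1)` impinges, the CCA is reported as that maximum with a
`capped` flag.

Defaults mirror a practical planning resolution: `Δt_POS = 5°`,
`Δt_α = 1°`, `N_α = 61` (max 60°), `Δt_CON = 10°` (36 azimuths).
Coarser grids only ever delay the detected first contact, so reported
CCAs are conservative within one `Δt_α` plus the meshing slack
described below.

## Impingement detection

Surface crossing is decided by segment–triangle intersection: every
edge of mesh A (as a bounded segment) is tested against the triangles
of mesh B with the Möller–Trumbore algorithm (determinant cut-off
1e-12), and symmetrically B against A. Two closed surfaces that touch
or overlap in a volume always have crossing edges at the intersection
curve; a mesh entirely inside another (no surface crossing) is *not*
reported as impingement, which matches the physical reading of a
surface contact event and cannot occur for the swept first-contact
search (contact is detected at the first crossing aperture).

A broad phase accelerates the test: a k-d tree over the static mesh's
triangle centroids is queried per edge with radius
`edge half-length + max triangle circumradius`, after an
axis-aligned-bounding-box pre-reject. The accelerated result is, by
contract, **identical** to the exhaustive all-pairs test (`exhaustive=True`
keeps the reference path available), and the test suite enforces field-level
equality on random mesh pairs. Intersection points are deduplicated at
1e-9 mm.

Within each posture's CCA, every swept sample (aperture multiples of
`Δt_α` up to the CCA, all azimuths) is checked for

* **BTBI** — bony femur vs pelvis (maps on both bones), and
* **ITBI** — prosthetic stem vs pelvis (map on the pelvis).

## Region growing and patch selection

The faces whose vertices are touched by crossing edges form the
intersection band. **Seed faces** are faces with no crossed vertex;
clusters are connected components of seed faces over shared mesh edges
(breadth-first search). Faces straddling the intersection curve belong
to no cluster but are always included in the impinged set at the
sample's severity category.

To decide which clusters are the impinged patches, each cluster is
probed at the centroid of its largest face, offset inward by one tenth
of the median edge length, and tested for containment in the opposing
closed mesh by ray parity. If the opposing mesh is open, a fallback
flags boundary-adjacent clusters smaller than their neighbour across
the intersection curve and logs a warning.

## Severity categories and maps

The CCA of the flagging posture is split into ordered fractions
(default 25/50/75/100 %, colours red/yellow/green/blue). A sample at
aperture α contributes its faces at the first band with
`α ≤ fraction · CCA`. Each face keeps the smallest (most severe)
category over all activities, postures, apertures and azimuths; the
flagging (activity, posture) pairs are kept as provenance. Because a
smaller cone is a subset of a larger one, the pre-collapse face set of
band f is nested in that of any band f′ > f; the collapsed per-face
category loses no information, and the nesting invariant is asserted in
the tests.

**ITBI feasibility filter:** pelvis faces flagged by both the stem
(ITBI) and the bony femur (BTBI) are removed from the ITBI map — where
the bone collides, the corresponding stem region is seated inside the
femoral canal and cannot touch the pelvis directly.

Three representation styles are rendered: ITBI (pelvis), BTBI (pelvis
and femur) and combined (pelvis with the category-wise minimum of both
maps, plus the femur BTBI map). Colours are written as per-face RGB in
binary PLY; areas per colour are summed from triangle areas, and the
pre/post comparison reports `100 · (pre − post) / pre` per colour
(undefined when pre = 0; negative values are legitimate and logged when
the later geometry carries extra surface).

## Fixtures and their analytic oracles

The parametric fixture is an idealised, axisymmetric hip: a spherical
liner band of radius `R_c` whose rim opens at half-angle β from −z, a
ball head plus cylindrical neck (radius `r_n`, length `L`) as the stem,
a wider cylindrical sleeve (radius `r_f`) as the bony femur, and a
pelvis made of a plate parked clear of all motion plus an optional
spherical "bump" (radius `r_b`, centre at distance `h` from the hip
centre, polar angle γ). It emulates the *topology* of the clinical
problem — rim-limited prosthetic clearance and an osteophyte-like bony
prominence — not patient anatomy.

Closed forms used as oracles:

* rim contact of the neck with the liner rim:
  `θ* = β − asin(r_n / R_c)`;
* bump first contact of a cylinder of radius r:
  `θ_b = γ − asin((r + r_b) / h)`, `UNREACHABLE` when the contact point
  falls outside the cylinder's axial span or beyond 90°.

Both formulas are themselves re-validated by dense brute-force pose
sweeps in the test suite before being used to judge the pipeline.
Meshing uses chords that lie strictly inside the smooth surfaces, so
meshed contact occurs at or slightly after the analytic angle; the
bound `mesh_angle_slack ≈ (sagitta_rim + sagitta_neck) / sqrt(R_c² − r_n²)`
(sagitta `L²/8r` for edge length L) is added to `Δt_α` as the
acceptance tolerance.

Placing the bump at `γ = θ_target + asin((r_f + r_b)/h)` engineers a
first contact at exactly `θ_target`, which is how the category-placement
checks construct a "blue-band" bump (contact in (0.75·CCA, CCA]) and a
"red" bump (contact at zero aperture).

## Numerical choices

* Möller–Trumbore determinant cut-off 1e-12 (parallel rejection);
  segment parameter accepted on [0, 1].
* Intersection-point deduplication at 1e-9 mm.
* Vertex welding on load at 1e-6 mm (configurable); zero-area facets
  (area < 1e-10 mm²) are rejected naming the facet.
* Ray-parity containment uses a fixed irrational direction to avoid
  edge-grazing degeneracies.
* All sweeps are deterministic; the only random seed in the package
  belongs to nothing at runtime (fixture generation is deterministic
  too; the `random_seed` field is reserved).

## Design decisions left open by the source material

* Impingement is defined as *surface crossing*; full containment
  without crossing does not occur in the incremental sweeps and is
  reported as no contact.
* Faces straddling the intersection curve are counted as impinged at
  the flagging category even though region growing excludes them from
  clusters (the grown patch is otherwise slightly smaller than the true
  one).
* The ITBI feasibility filter is implemented as an exact set difference
  on pelvis faces flagged by both analyses.
* The conical azimuth basis (azimuth 0 towards +x, increasing towards
  −y) is fixed so results are reproducible across runs and sides.

## Limitations

* No patient data: clinical-scale numbers (cohort statistics, per-case
  reduction percentages from planning workstations) are out of scope;
  validation is against closed-form fixtures and independent numerical
  oracles.
* Rigid bones, fixed hip centre, no soft tissue, no translation or
  micro-separation of the joint.
* First-contact detection is grid-limited: a feature thinner than the
  aperture/azimuth grid spacing could be skipped between samples.
* Meshes must be oriented, manifold surfaces; the pelvis/femur/stem are
  expected closed for parity-based patch selection (an area heuristic
  with a warning covers open opposing meshes).
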