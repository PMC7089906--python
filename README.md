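# impingemap

Pre-operative mapping of bone-to-bone and implant-to-bone impingement
for total hip arthroplasty planning.

Given surface meshes of the pelvis, the (prosthesis-carrying) femur, the
prosthetic stem and the acetabular liner, plus a set of activities
(ranges of hip motion), `impingemap` answers two questions for every
posture along each activity:

1. **How much extra motion is available before the prosthesis impinges?**
   For each posture the femur is swept over cones of increasing aperture
   about its current axis; the smallest aperture at which the stem first
   touches the liner is the **conical clearance angle (CCA)** of that
   posture.
2. **Which bony surfaces collide inside that clearance cone?**
   Every swept position inside the CCA is checked for bone-to-bone
   impingement (BTBI, femur vs pelvis) and implant-to-bone impingement
   (ITBI, stem vs pelvis). Each impinged surface patch is extracted by
   region growing from the mesh intersection curve and coloured by the
   fraction of the CCA at which it is first hit: **red** (≤ 25 % of the
   CCA — essentially unavoidable), **yellow** (≤ 50 %), **green**
   (≤ 75 %) and **blue** (≤ 100 %). The colour-coded meshes are written
   as PLY files and the coloured areas tabulated, so two candidate plans
   (e.g. before/after an osteophyte resection) can be compared by their
   per-colour area reduction.

The package operates on triangle meshes only; no patient imaging, no
statistical models. Synthetic parametric fixtures with closed-form
contact angles are included so every part of the pipeline can be
verified without clinical data.

## Worked example

Generate a synthetic hip and run the full analysis:

```bash
impinge-map fixtures --out demo
impinge-map run --config demo/config.yaml
```

`demo/results/` then contains `cca_profile.csv` (per-posture CCA for
each activity), `pelvis_itbi.ply`, `pelvis_btbi.ply`, `femur_btbi.ply`,
`pelvis_combined.ply`, `femur_combined.ply` (colour-coded meshes),
`areas.csv` and `manifest.json`.

The same pipeline from Python, on a fixture whose bump is engineered to
first touch at 15.0° inside a CCA of about 17°:

```python
import math
import impingemap as im

gamma = 15.0 + math.degrees(math.asin(12.0 / 40.0))
spec = im.FixtureSpec(
    cup_radius=25, rim_opening_half_angle=30, head_radius=12,
    neck_radius=6, neck_length=50, femur_radius=9,
    bump=im.bump_at(gamma, 40.0, 3.0), mesh_edge_length=2.5)
model = im.make_hip_fixture(spec)

params = im.SweepParams(dt_alpha=1.0, n_alpha=31, dt_con=10.0)
cca, capped = im.compute_cca(model, im.Posture(), params)
print(cca)                                        # 17.0
print(im.analytic_rim_contact(spec))              # 16.114...
print(im.analytic_bump_reach(spec, "femur"))      # 15.0

prof = im.CCAProfile("neutral", [im.Posture()], [cca], [capped])
maps = im.map_bi(model, [prof], im.CCACategories(), params, "BTBI")
print(set(maps["pelvis"].itf.values()))           # {3}  -> blue only
```

The bump's first contact (15.0°) lies in the (0.75·CCA, CCA] band, so
every flagged pelvis face is blue — and only blue.

Comparing two runs (pre vs post):

```bash
impinge-map compare demo/results demo2/results --out reduction.csv
```

## Package layout

| module | contents |
| --- | --- |
| `impingemap.mesh_core` | mesh container, STL/PLY I/O, welding, colour maps, areas |
| `impingemap.kinematics` | postures, activities, conical sweep transforms |
| `impingemap.collision` | Möller–Trumbore kernel, mesh intersection, containment |
| `impingemap.clearance` | per-posture CCA search and profiles |
| `impingemap.bi_map` | BTBI/ITBI detection, region growing, severity maps |
| `impingemap.reporting` | coloured PLY output, area tables, reductions |
| `impingemap.fixtures` | parametric synthetic hips with analytic contact angles |
| `impingemap.cli` | `impinge-map run / fixtures / compare` |

See `docs/methods.md` for the model, conventions, parameters and
numerical choices.
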