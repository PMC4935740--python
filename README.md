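# zygonav

Navigation planning for secondary zygoma (malar bone) reduction surgery.

In secondary facial-fracture repair the fracture lines have fused: once the
zygoma is osteotomized and freed there are few anatomical clues left for
putting it back in the right place. One solution is to plan the reduction
virtually on CT-derived surface models and use an optical navigation system
to steer the fragment. `zygonav` implements the geometry underneath such a
workflow:

* estimate the rigid **reduction transform** `T` that carries the
  dislocated zygoma onto its planned (reduced) position, by matching the
  two surface point clouds with an iterative-closest-point (ICP)
  registration;
* turn surface marks chosen *intraoperatively* on the dislocated bone into
  **free navigation reference points (FNRPs)** — the image-space targets
  `P_R = T P_D` each mark must reach when the fragment is correctly
  reduced;
* **back-calculate** screw holes planned on the reduced model onto the
  still-dislocated bone, `P_D = T⁻¹ P_R`, so plates pre-bent on a
  fabrication model can be drilled for before reduction;
* simulate the **probing procedure** (touching a mark with a tracked probe
  and reading its offset from the FNRP) and recover the fragment pose from
  three or more probed marks;
* evaluate outcomes the way model-surgery studies report them: per-hole
  **drilling deviation** (Euclidean distance from plan, mm) and **global
  reduction error** (geometric-center displacement plus per-axis Euler
  rotation of planned vs. achieved zygoma, after registering the images on
  un-operated bone).

The flexibility is the point: because `T` is known, *any* point on the
fragment can become a navigation reference during surgery, instead of
relying on marks fixed at planning time that the intraoperative situation
(fragile bone, soft-tissue exposure) may invalidate.

A synthetic phantom generator (stylized ellipsoid skull with a malar-like
protrusion, known ground-truth dislocation, seeded pick/probe/drill noise)
makes the whole pipeline testable without any imaging data; see
`docs/methods.md` for the model and its limitations.

## Worked example

```python
import numpy as np
from zygonav import (PhantomSpec, make_phantom, compute_reduction_transform,
                     generate_fnrps, back_calculate_holes,
                     simulate_probe_readings, pose_from_probes,
                     summarize_table1)
from zygonav.datasets import load_drilling_deviations

ph = make_phantom(PhantomSpec(seed=42))
plan = compute_reduction_transform(ph.zygoma_dislocated_cloud(),
                                   ph.zygoma_planned_cloud())
print("reduction transform:", plan.t_dr)

fnrps = generate_fnrps(plan, ph.marks_dislocated)
for f in fnrps:
    print(f"{f.name}: mark {np.round(f.mark_dislocated, 2)} "
          f"-> FNRP {np.round(f.reference_reduced, 2)}")

readings = simulate_probe_readings(fnrps, plan.t_dr, sigma=0.3, seed=0)
for r in readings:
    print(f"probe {r.fnrp_name}: {r.distance:.3f} mm from its FNRP")
```

prints

```
reduction transform: RigidTransform(t=(8.475, 5.919, 1.313) mm, euler=(5.208, -3.441, -4.738) deg)
m_suture: mark [ 55.82 -54.55   8.4 ] -> FNRP [ 59.25 -53.57   8.07]
m_orbital: mark [ 52.58 -67.34  -6.95] -> FNRP [ 56.08 -64.68  -8.54]
m_buttress: mark [ 46.25 -47.76 -35.56] -> FNRP [ 53.2  -42.27 -35.58]
probe m_suture: 0.200 mm from its FNRP
probe m_orbital: 0.196 mm from its FNRP
probe m_buttress: 0.528 mm from its FNRP
```

The estimated transform is the phantom's ground-truth dislocation, inverted
(here ~7° of rotation and ~10 mm of translation); each FNRP is where the
corresponding mark must sit after reduction; the probe distances are the
residual offsets under 0.3 mm probe-tip noise with the fragment at the
planned pose. `back_calculate_holes(plan, ph.holes_reduced)` maps the
twelve planned screw holes back onto the dislocated bone the same way.

The package also ships the drilling-deviation and reduction-error tables
from a six-reduction model-surgery study as example data:

```python
print(summarize_table1(load_drilling_deviations()).round(3).to_string(index=False))
```

```
     statistic  value
site_1_mean_mm  0.880
site_2_mean_mm  0.840
site_3_mean_mm  0.768
site_4_mean_mm  1.154
site_5_mean_mm  0.786
site_6_mean_mm  1.114
 grand_mean_mm  0.924
   grand_sd_mm  0.380
```

i.e. a mean drilling deviation of 0.924 ± 0.380 mm over 72 screw holes.

`LandmarkTransform`, `IterativeClosestPoint` and `ReductionPlanner` expose
the same operations as scikit-learn-style estimators
(`fit`/`transform`/`inverse_transform`, `get_params`), and the `zygonav`
console script provides one subcommand per pipeline stage (`phantom`,
`register`, `plan`, `fnrp`, `backcalc`, `probe`, `evaluate`, `summarize`).

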