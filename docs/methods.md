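# Methods

## The model

All motion of bone is modeled as a proper rigid transform of 3-space,
stored as a 4×4 homogeneous matrix `T = [R t; 0 1]` with `R ∈ SO(3)` and
`t` in millimetres, acting on column vectors (`p' = T p`). Three such
transforms matter in the workflow:

1. the **reduction transform** `T` from the dislocated to the planned
   zygoma configuration, estimated by surface registration;
2. the **patient-to-image registration** that lets a tracked probe be
   expressed in image coordinates (a landmark fit refined by surface
   points); and
3. the **residual error transform** between planned and achieved zygoma
   after surgery.

Given `T`, a surface mark `P_D` picked on the dislocated bone has the
reference position `P_R = T P_D` (its FNRP), and a screw hole planned at
`P_R` on the reduced model is drilled at `P_D = T⁻¹ P_R`. These two maps
are exact mutual inverses; the package treats that round trip as a hard
invariant (tested to 1e−9 mm over random transforms and points).

### Registration

* **Landmark fit**: the closed-form least-squares rigid fit (SVD of the
  weighted cross-covariance of the centered pairs, with the determinant
  sign-corrected so reflections are never returned). Requires ≥3
  non-collinear pairs; collinear sources are rejected with the degenerate
  direction named, because rotation about the line is unidentifiable.
  The reported `rms_error` is the fiducial registration error. Tests
  certify optimality against an independent rotation-space search
  (random-quaternion seeding plus an adaptive perturbation walk) that
  agrees with the closed form to better than 1e−6 mm RMS.

* **ICP**: classic point-to-point. Per iteration: nearest-neighbour
  correspondences via a kD-tree (ties resolved to the lowest target
  index for determinism), optional distance gating and worst-fraction
  trimming, a closed-form rigid update on the correspondences, and the
  post-update RMS recorded in `rms_trace`. Untrimmed, the trace is
  provably non-increasing and is asserted as such. Convergence is
  declared when the RMS changes by less than 1e−6 mm (default), capped at
  100 iterations; both are configurable (`IcpParams`). Point-to-plane
  variants are deliberately out of scope — the clouds here are dense
  samples of the same surface, where point-to-point suffices.

  ICP converges only locally. The reduction transform should therefore be
  estimated from a coarse initial overlap — in practice the planner has
  already roughly reduced the fragment on screen; in the synthetic
  pipeline a three-landmark fit plays that role (`init=` parameter).
  Dislocations up to ~10° / 8 mm typically converge even from identity on
  the phantom, but this is not guaranteed and a stalled fit is reported
  (high RMS, plan rejected against `rms_threshold`, default 1 mm).

### Euler angles

Per-axis rotation errors are reported as extrinsic, fixed-axis X-Y-Z
angles in degrees (`R = Rz(rz)·Ry(ry)·Rx(rx)`). The convention is
arbitrary but documented; for the sub-1° rotations these reports deal in,
all common conventions agree to well under 0.001°, so only the
convention-independent magnitudes should be compared across systems. Near
gimbal lock (|ry| = 90°) the decomposition sets `rz = 0`, lets `rx`
absorb the free angle, and flags the result.

### Error evaluation

* **Drilling deviation**: Euclidean distance between a drilled-and-
  registered hole and its planned position, tabulated per fracture site
  (6 sites × 12 holes in the bundled reference table) with site means and
  a grand mean ± SD.
* **Global reduction error**: postop image is first registered to the
  preop plan by ICP on the *fixed* (un-operated) region only; the
  residual rigid transform between achieved and planned zygoma clouds is
  then estimated, and the report carries the distance between the two
  geometric centers plus the Euler angles of the residual rotation.
  "Geometric center" is the unweighted vertex centroid of the labeled
  region (an area-weighted option exists); centers are
  rigid-equivariant, so this choice only matters for unevenly meshed
  regions.
* **Summary statistics** default to the population (÷n) standard
  deviation computed over *absolute* values, matching how small-n
  surgical error tables are conventionally reported; the sample (n−1)
  denominator is available via `ddof=1`. Signed rotations are reported
  per case, but only absolute-value summaries are comparable across
  cases, since the sign depends on axis conventions that differ between
  navigation systems. For the bundled reference errors, the y-axis SD
  recomputes to 0.543° from the shipped per-case values under every
  standard convention; the package reports its own recomputation.

## The phantom

`make_phantom` builds a stylized skull: an icosphere (subdivision 4, 2562
vertices) scaled to semi-axes (70, 90, 65) mm — about the half-width,
half-length and half-height of an adult skull — with the zygoma
represented by the cone of vertices within 35° of a left-anterior-inferior
direction, given an 8 mm radial "malar" protrusion. Faces wholly inside
the patch are labeled `zygoma` (~230 vertices), the rest `fixed`; rim
vertices are duplicated so the regions share none, which both emulates the
widened fracture gap and keeps the fixed region bit-identical when the
fragment moves.

The ground-truth dislocation is a rotation about the fragment centroid
(≤10° by default) plus a translation (≤8 mm) — the scale of displacement
seen in zygoma fractures needing formal reduction; both bounds are
configurable, and the validation of large-dislocation recovery uses
15°/10 mm. Three fiducials (nasion-like midline point, two suture-like
points) sit on the fixed region; three marks and 12 screw holes (3 plates
× 4 screws) sit near the zygomatico-frontal, infra-orbital and buttress
aspects of the patch.

Noise model: isotropic Gaussian throughout — fiducial picks σ = 0.3 mm,
probe tips σ = 0.3 mm (typical optical-tracker point-pick accuracy), and
drilled holes σ = 0.579 mm, chosen so the implied Maxwell mean distance
`2σ√(2/π)` equals the 0.924 mm mean drilling deviation of the bundled
reference table. An optional constant probe depth bias (a tip resting
proud of a deep screw hole) is off by default. Every simulator takes an
explicit seed and is deterministic given it.

**What the phantom does not model**: real skull geometry and mesh
artifacts from CT segmentation, anisotropic or spatially correlated
tracker error, soft-tissue deflection of the probe, partial-overlap
clouds (the two zygoma clouds are exact copies of the same vertex set, so
noiseless ICP can reach machine precision — real segmentations would
plateau at the surface-discrepancy level), and plate/screw mechanics.
Passing tests therefore certify the *geometry and software*, not
clinical accuracy.

## Numerical choices

* Rigidity validation at 1e−9 (orthonormality drift and |det−1|);
  composition re-orthonormalizes by SVD projection only when drift
  exceeds that.
* STL is read through trimesh with per-facet vertices merged at 1e−6 mm;
  binary and ASCII dialects are both read and written. STL has no region
  field, so labels live in a JSON sidecar of face-index ranges.
* Transform files store 17 significant digits, so write→read round trips
  are bit-exact in double precision.
* Problem sizes used in the validation suite — 2562-vertex phantoms,
  ~230-point zygoma clouds, 100–200 Monte-Carlo replicates, 50 synthetic
  tables — were chosen as the smallest at which the Monte-Carlo
  statistics are stable; the full suite runs in a few seconds.

## Known limitations

* Point-to-point ICP with identity initialization can stall on smooth,
  near-symmetric surfaces at misalignments beyond a few millimetres /
  degrees; supply a landmark-based coarse fit (the CLI `register`
  command does exactly this before refining).
* The pose recovered from three probed marks is sensitive to mark
  collinearity; marks should be spread over the fragment (the generator
  places them near the three fixation sites for this reason), and exact
  collinearity is a hard error.
* `global_error` assumes the postop scan is already roughly aligned with
  the preop scan (same scanner frame, patient roughly repositioned); a
  grossly different frame needs a coarse pre-alignment first.
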