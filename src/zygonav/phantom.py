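"""Synthetic skull phantom with a known ground-truth zygoma dislocation.

The geometry is deliberately stylized: an ellipsoid shell (semi-axes sized
like an adult skull) with a malar-like radial protrusion standing in for the
zygoma.  The method under test is purely geometric — rigid registration and
transform algebra — so anatomical fidelity is unnecessary for correctness;
what matters is a labeled two-region mesh pair related by a known rigid
transform, plus realistic pick/probe/drill noise.  Do not read anything
anatomical into the shapes.

Frame convention: right-handed, x = left, y = posterior, z = superior,
origin at the ellipsoid center, millimetres.

The zygoma region's faces share no vertices with the fixed region (boundary
vertices are duplicated), emulating the widened fracture gap of a freed
fragment and keeping the fixed region bit-identical between the planned and
dislocated meshes.

All randomness flows through one ``numpy`` generator seeded per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh as _trimesh

from .exceptions import DegenerateGeometryError, ValidationError
from .geometry import PointSet, RigidTransform, geometric_center
from .io import TriMesh
from .planning import Fnrp, ProbeReading, probe

__all__ = [
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "sample_surface_points",
    "simulate_probe_readings",
    "simulate_drilling",
    "synthetic_deviation_table",
    "DRILL_SIGMA_DEFAULT",
]

#: Drill-scatter sigma (mm) whose Maxwell mean 2*sigma*sqrt(2/pi) equals the
#: 0.924 mm mean drilling deviation observed in the six-reduction
#: model-surgery study the error model emulates.
DRILL_SIGMA_DEFAULT = float(0.924 / (2.0 * np.sqrt(2.0 / np.pi)))


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValidationError("zero direction vector")
    return v / n


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic skull.

    ``subdivisions`` controls icosphere resolution (4 -> 2562 vertices);
    ``zygoma_direction``/``zygoma_angle_deg`` define the malar patch as the
    cone of unit-sphere vertices within that angle of the direction;
    ``bump_height_mm`` is the radial protrusion at the patch center.
    ``max_rotation_deg``/``max_translation_mm`` bound the ground-truth
    dislocation; sigmas are isotropic Gaussian noise levels for fiducial
    picking, probe tips, and drilled holes.  ``probe_depth_bias_mm`` models
    a probe tip resting above the true surface point (default off).
    """

    subdivisions: int = 4
    semi_axes: tuple[float, float, float] = (70.0, 90.0, 65.0)
    zygoma_direction: tuple[float, float, float] = (0.80, -0.55, -0.22)
    zygoma_angle_deg: float = 35.0
    bump_height_mm: float = 8.0
    max_rotation_deg: float = 10.0
    max_translation_mm: float = 8.0
    fiducial_sigma: float = 0.3
    probe_sigma: float = 0.3
    drill_sigma: float = DRILL_SIGMA_DEFAULT
    probe_depth_bias_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("fiducial_sigma", "probe_sigma", "drill_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.zygoma_angle_deg <= 0:
            raise DegenerateGeometryError("zygoma patch has zero extent")
        if self.max_rotation_deg < 0 or self.max_translation_mm < 0:
            raise ValidationError("dislocation bounds must be >= 0")


@dataclass
class Phantom:
    """A planned/dislocated mesh pair with ground truth and planning inputs.

    ``t_true`` maps the dislocated zygoma onto its planned (reduced)
    position — the ground truth that registration must recover.
    ``landmarks`` are fiducials on the fixed skull (nasion-like plus two
    suture-like points); ``marks_dislocated`` are the three candidate
    surface marks on the dislocated fragment; ``holes_reduced`` are the 12
    screw-hole positions (3 plates x 4 screws) planned in the reduced
    configuration.
    """

    spec: PhantomSpec
    planned: TriMesh
    dislocated: TriMesh
    t_true: RigidTransform
    landmarks: PointSet
    marks_dislocated: PointSet
    holes_reduced: PointSet

    def zygoma_planned_cloud(self) -> np.ndarray:
        return self.planned.region_vertices("zygoma")

    def zygoma_dislocated_cloud(self) -> np.ndarray:
        return self.dislocated.region_vertices("zygoma")

    def noisy_fiducials(self, seed: int) -> PointSet:
        """Fiducial picks with isotropic Gaussian pick noise."""
        rng = np.random.default_rng(seed)
        noisy = self.landmarks.coordinates + rng.normal(
            0.0, self.spec.fiducial_sigma, size=(len(self.landmarks), 3))
        return PointSet(noisy, names=self.landmarks.names)


def _pick_region_vertex(unit_dirs: np.ndarray, candidates: np.ndarray,
                        direction, used: set[int]) -> int:
    """Index (into the full vertex array) of the unused candidate vertex
    whose unit-sphere direction is closest to *direction*."""
    d = _unit(direction)
    scores = unit_dirs[candidates] @ d
    for i in np.argsort(-scores, kind="stable"):
        idx = int(candidates[i])
        if idx not in used:
            used.add(idx)
            return idx
    raise DegenerateGeometryError("ran out of candidate vertices")


def make_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Build the phantom deterministically from its spec (and its seed)."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)

    sphere = _trimesh.creation.icosphere(subdivisions=spec.subdivisions,
                                         radius=1.0)
    unit_dirs = np.asarray(sphere.vertices, dtype=float)
    faces = np.asarray(sphere.faces, dtype=np.int64)
    verts = unit_dirs * np.asarray(spec.semi_axes)

    d = _unit(spec.zygoma_direction)
    ang = np.arccos(np.clip(unit_dirs @ d, -1.0, 1.0))
    theta = np.deg2rad(spec.zygoma_angle_deg)
    in_patch = ang < theta

    # malar protrusion: radial bump, smooth to zero at the patch rim
    bump = np.zeros(len(verts))
    bump[in_patch] = spec.bump_height_mm * np.cos(
        0.5 * np.pi * ang[in_patch] / theta) ** 2
    radial = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    verts = verts + radial * bump[:, None]

    zyg_face = in_patch[faces].all(axis=1)
    if not zyg_face.any():
        raise DegenerateGeometryError("zygoma patch contains no whole faces")

    # Split shared boundary vertices so the regions are vertex-disjoint.
    fixed_faces = faces[~zyg_face]
    zyg_faces = faces[zyg_face].copy()
    zyg_vert_ids = np.unique(zyg_faces)
    shared = np.intersect1d(zyg_vert_ids, np.unique(fixed_faces))
    if len(shared):
        dup = verts[shared]
        remap = dict(zip(shared.tolist(),
                         range(len(verts), len(verts) + len(shared))))
        verts = np.vstack([verts, dup])
        flat = zyg_faces.ravel()
        for k, v in remap.items():
            flat[flat == k] = v
        zyg_faces = flat.reshape(-1, 3)

    all_faces = np.vstack([fixed_faces, zyg_faces])
    labels = np.array(["fixed"] * len(fixed_faces)
                      + ["zygoma"] * len(zyg_faces), dtype=object)
    planned = TriMesh(verts.copy(), all_faces, labels)

    zyg_idx = planned.region_vertex_indices("zygoma")
    if len(zyg_idx) < 30:  # too sparse for a stable surface registration
        raise DegenerateGeometryError(
            f"zygoma region has only {len(zyg_idx)} vertices; "
            "increase subdivisions or patch angle")

    # Ground-truth dislocation: rotation about the zygoma centroid plus a
    # translation, both bounded by the spec.
    angle = rng.uniform(0.0, spec.max_rotation_deg)
    axis = _unit(rng.normal(size=3))
    from scipy.spatial.transform import Rotation as _R
    rot = _R.from_rotvec(np.deg2rad(angle) * axis).as_matrix()
    center = verts[zyg_idx].mean(axis=0)
    t_vec = rng.normal(size=3)
    t_vec = _unit(t_vec) * rng.uniform(0.0, spec.max_translation_mm)
    # dislocation D moves planned -> dislocated; ground truth is its inverse
    dislocation = RigidTransform.from_rotation_translation(
        rot, center - rot @ center + t_vec)
    dislocated = planned.transformed(dislocation, region="zygoma")
    t_true = dislocation.inverse()

    # Fiducials on the fixed skull (anterior midline + two suture-like).
    fixed_idx = planned.region_vertex_indices("fixed")
    used: set[int] = set()
    fid_dirs = [(0.0, -1.0, 0.15), (0.72, -0.40, 0.45), (-0.72, -0.40, 0.45)]
    fid_idx = [_pick_region_vertex(unit_dirs, fixed_idx[fixed_idx < len(unit_dirs)],
                                   fd, used) for fd in fid_dirs]
    landmarks = PointSet(planned.vertices[fid_idx],
                         names=["nasion", "zf_left", "zf_right"])

    # Marks and screw holes on the zygoma patch, near the three fixation
    # sites (suture-ward, orbital-rim-ward, buttress-ward sub-directions).
    zyg_unit_idx = zyg_idx[zyg_idx < len(unit_dirs)]
    site_dirs = [d + 0.35 * np.array([0.0, 0.0, 1.0]),
                 d + 0.35 * np.array([-0.3, -0.3, 0.3]),
                 d + 0.35 * np.array([0.0, 0.1, -1.0])]
    used = set()
    mark_idx = [_pick_region_vertex(unit_dirs, zyg_unit_idx, sd, used)
                for sd in site_dirs]
    marks_planned = planned.vertices[mark_idx]
    marks_dislocated = PointSet(dislocation.apply(marks_planned),
                                names=["m_suture", "m_orbital", "m_buttress"])

    hole_idx: list[int] = []
    for sd in site_dirs:
        jitter_dirs = [sd + 0.06 * rng.normal(size=3) for _ in range(4)]
        hole_idx.extend(_pick_region_vertex(unit_dirs, zyg_unit_idx, jd, used)
                        for jd in jitter_dirs)
    holes_reduced = PointSet(planned.vertices[hole_idx],
                             names=[f"hole{i + 1}" for i in range(12)])

    return Phantom(spec=spec, planned=planned, dislocated=dislocated,
                   t_true=t_true, landmarks=landmarks,
                   marks_dislocated=marks_dislocated,
                   holes_reduced=holes_reduced)


def sample_surface_points(mesh: TriMesh, n: int, seed: int,
                          regions: list[str] | None = None) -> np.ndarray:
    """Sample *n* points uniformly by area over the mesh (or the named
    regions) — the synthetic analogue of picking random surface points for
    fine alignment."""
    if n < 1:
        raise ValidationError("need n >= 1 sample points")
    if regions:
        faces = np.vstack([mesh.region_faces(r) for r in regions])
    else:
        faces = mesh.faces
    tri = mesh.vertices[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    if areas.sum() <= 0:
        raise DegenerateGeometryError("zero-area sampling region")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(faces), size=n, p=areas / areas.sum())
    u, v = rng.random((2, n))
    flip = u + v > 1.0
    u[flip], v[flip] = 1.0 - u[flip], 1.0 - v[flip]
    t = tri[pick]
    return t[:, 0] + u[:, None] * (t[:, 1] - t[:, 0]) + v[:, None] * (t[:, 2] - t[:, 0])


def simulate_probe_readings(fnrps: list[Fnrp], current_pose: RigidTransform,
                            sigma: float, seed: int,
                            depth_bias: float = 0.0) -> list[ProbeReading]:
    """Probe every FNRP's mark with the fragment at *current_pose*.

    The probed position is the mark's dislocated coordinate moved by
    *current_pose*, plus isotropic Gaussian tip noise (sigma, mm) and an
    optional constant depth bias along +z (a tip resting proud of a deep
    hole).  ``current_pose`` equal to the plan's reduction transform and
    sigma 0 gives zero distances.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    readings = []
    for f in fnrps:
        pos = current_pose.apply(f.mark_dislocated)
        pos = pos + rng.normal(0.0, sigma, size=3) if sigma > 0 else pos
        if depth_bias:
            pos = pos + np.array([0.0, 0.0, depth_bias])
        readings.append(probe(f, pos))
    return readings


def simulate_drilling(planned_holes: PointSet, sigma: float,
                      seed: int) -> PointSet:
    """Drilled-and-registered hole positions: planned plus isotropic
    Gaussian scatter (hand tremor, handpiece vibration, bit wander)."""
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    coords = planned_holes.coordinates if isinstance(planned_holes, PointSet) \
        else np.atleast_2d(np.asarray(planned_holes, dtype=float))
    rng = np.random.default_rng(seed)
    noisy = coords + (rng.normal(0.0, sigma, size=coords.shape)
                      if sigma > 0 else 0.0)
    names = planned_holes.names if isinstance(planned_holes, PointSet) else None
    return PointSet(noisy, names=names)


def synthetic_deviation_table(sigma: float = DRILL_SIGMA_DEFAULT,
                              n_sites: int = 6, holes_per_site: int = 12,
                              seed: int = 0):
    """Simulate a drilling-deviation table: *n_sites* fracture sites with
    *holes_per_site* holes each, deviations drawn from the isotropic drill
    noise model (Maxwell-distributed distances)."""
    from .errors import DeviationTable, drilling_deviation

    rng = np.random.default_rng(seed)
    recs = []
    for s in range(1, n_sites + 1):
        planned = rng.uniform(-50.0, 50.0, size=(holes_per_site, 3))
        drilled = planned + rng.normal(0.0, sigma, size=planned.shape)
        for h in range(holes_per_site):
            recs.append((s, h + 1, drilling_deviation(drilled[h], planned[h])))
    import pandas as pd
    return DeviationTable(pd.DataFrame(recs,
                                       columns=["site", "hole", "deviation_mm"]))
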