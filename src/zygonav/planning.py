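"""Reduction planning with free navigation reference points (FNRPs).

The core of the toolkit.  A dislocated zygoma fragment and its planned
(reduced) position are related by a rigid reduction transform ``T`` estimated
by matching the two surface point clouds with ICP.  Any surface mark ``P_D``
chosen intraoperatively on the dislocated bone then has a known target
position ``P_R = T P_D`` — its free navigation reference point — and,
conversely, a screw hole planned at ``P_R`` on the reduced model is drilled
at ``P_D = T^{-1} P_R`` on the still-dislocated bone.  Probing a mark with a
tracked pointer and comparing against its FNRP measures the residual
malposition of the fragment; three or more non-collinear marks pin down the
full 3-D pose.

Marks must be selected and registered *before* the fragment is freed:
reduction breaks the fragment-to-skull relationship on which the
registration rests.  :class:`ReductionPlan` enforces this ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import ConvergenceError, PlanStateError, ValidationError
from .geometry import PointSet, RigidTransform
from .registration import (IcpParams, RegistrationResult, icp, landmark_fit,
                           _as_coords)

__all__ = [
    "ReductionPlan",
    "Fnrp",
    "ProbeReading",
    "compute_reduction_transform",
    "generate_fnrps",
    "back_calculate_holes",
    "probe",
    "pose_from_probes",
    "read_fnrps",
    "write_fnrps",
    "ReductionPlanner",
]


@dataclass(frozen=True)
class Fnrp:
    """A surface mark on the dislocated bone and its reference position
    after the planned reduction."""

    name: str
    mark_dislocated: np.ndarray   # P_D, mm
    reference_reduced: np.ndarray  # P_R = T P_D, mm


@dataclass(frozen=True)
class ProbeReading:
    """Offset of a probed mark from its FNRP: distance is the Euclidean
    norm of the offset vector (mm)."""

    fnrp_name: str
    probed_position: np.ndarray
    offset_vector: np.ndarray
    distance: float


@dataclass
class ReductionPlan:
    """A fitted dislocated-to-reduced transform plus its diagnostics.

    ``reduced`` flips once the fragment is freed; registering marks after
    that is rejected, because the mark-to-image registration is no longer
    valid.
    """

    t_dr: RigidTransform
    fit_diagnostics: RegistrationResult
    rms_threshold: float = 1.0
    dislocated_region: str = "zygoma"
    planned_region: str = "zygoma"
    reduced: bool = False
    _marks: list[Fnrp] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.fit_diagnostics.rms_error > self.rms_threshold:
            raise ValidationError(
                f"reduction fit RMS {self.fit_diagnostics.rms_error:.3f} mm "
                f"exceeds threshold {self.rms_threshold} mm")

    @property
    def fnrps(self) -> list[Fnrp]:
        return list(self._marks)

    def register_marks(self, marks) -> list[Fnrp]:
        """Bind surface marks to the plan, generating their FNRPs; only
        allowed before :meth:`begin_reduction`."""
        if self.reduced:
            raise PlanStateError(
                "cannot register marks after reduction has begun; "
                "the mark registration is only valid on the un-freed fragment")
        new = generate_fnrps(self, marks)
        self._marks.extend(new)
        return new

    def begin_reduction(self) -> None:
        self.reduced = True


def compute_reduction_transform(dislocated, planned,
                                params: IcpParams | None = None,
                                rms_threshold: float = 1.0,
                                init: RigidTransform | None = None) -> ReductionPlan:
    """Estimate the rigid dislocated-to-reduced transform by ICP between the
    two zygoma surface clouds.

    Both clouds must sample the same bone surface (the dislocated fragment
    and its virtually reduced copy).  ICP refines from *init* when given —
    for large dislocations supply a coarse seed (e.g. a three-landmark fit,
    the analogue of roughly overlapping the fragments on screen first),
    since plain ICP only converges locally.  Non-convergent ICP raises
    :class:`ConvergenceError`; a converged fit whose RMS exceeds
    *rms_threshold* is rejected as not sampling the same surface.
    """
    res = icp(dislocated, planned, init=init, params=params)
    if not res.converged:
        raise ConvergenceError(
            f"reduction-transform ICP did not converge in {res.iterations} "
            f"iterations (final RMS {res.rms_error:.4f} mm)")
    return ReductionPlan(t_dr=res.transform, fit_diagnostics=res,
                         rms_threshold=rms_threshold)


def generate_fnrps(plan: ReductionPlan, marks) -> list[Fnrp]:
    """Map marks on the dislocated bone to their FNRPs, ``P_R = T P_D``.

    At least three marks are needed to confirm a 3-D pose; fewer than three
    produces a warning, an empty set is an error.
    """
    if isinstance(marks, PointSet):
        coords, names = marks.coordinates, marks.names
    else:
        coords, names = _as_coords(marks, "marks"), None
    if len(coords) == 0:
        raise ValidationError("no marks given")
    if len(coords) < 3:
        import warnings
        warnings.warn(
            f"only {len(coords)} mark(s): at least three FNRPs are needed to "
            "confirm the 3-D position of the fragment", stacklevel=2)
    if names is None:
        names = [f"mark{i + 1}" for i in range(len(coords))]
    refs = plan.t_dr.apply(coords)
    return [Fnrp(n, p.copy(), r.copy()) for n, p, r in zip(names, coords, refs)]


def back_calculate_holes(plan: ReductionPlan, holes_reduced) -> PointSet:
    """Map screw holes planned on the reduced model back onto the dislocated
    bone, ``P_D = T^{-1} P_R`` — the drilling targets before reduction."""
    if isinstance(holes_reduced, PointSet):
        coords, names = holes_reduced.coordinates, holes_reduced.names
    else:
        coords, names = _as_coords(holes_reduced, "holes"), None
    if len(coords) == 0:
        raise ValidationError("no screw holes given")
    return PointSet(plan.t_dr.inverse().apply(coords), names=names)


def probe(fnrp: Fnrp, probed) -> ProbeReading:
    """Compare a probed mark position against its FNRP."""
    p = np.asarray(probed, dtype=float).reshape(3)
    if not np.all(np.isfinite(p)):
        raise ValidationError("probed position must be finite")
    offset = p - fnrp.reference_reduced
    return ProbeReading(fnrp_name=fnrp.name, probed_position=p,
                        offset_vector=offset,
                        distance=float(np.linalg.norm(offset)))


def pose_from_probes(fnrps: list[Fnrp], probed) -> RegistrationResult:
    """Estimate the fragment's current pose from probed mark positions.

    Fits the rigid map from the marks' dislocated coordinates to their
    probed positions (>= 3 non-collinear marks).  If the fragment sits at
    the planned reduction, the estimate equals the plan's transform; the
    residual relative to it quantifies the remaining malposition.  Collinear
    marks leave rotation about their line unidentifiable and raise.
    """
    if len(fnrps) < 3:
        raise ValidationError(
            f"pose estimation needs >= 3 probed marks, got {len(fnrps)}")
    src = np.array([f.mark_dislocated for f in fnrps])
    tgt = _as_coords(probed, "probed positions")
    if len(tgt) != len(src):
        raise ValidationError(
            f"{len(tgt)} probed positions for {len(src)} marks")
    return landmark_fit(src, tgt)


def write_fnrps(fnrps: list[Fnrp], path) -> None:
    """Write FNRPs as tabular text: name, dislocated mark, reduced reference."""
    with open(path, "w") as fh:
        fh.write("name\txd\tyd\tzd\txr\tyr\tzr\n")
        for f in fnrps:
            vals = (*f.mark_dislocated, *f.reference_reduced)
            fh.write(f.name + "\t" + "\t".join(f"{v:.17g}" for v in vals) + "\n")


def read_fnrps(path) -> list[Fnrp]:
    from .io import _floats, _parse_table

    rows = _parse_table(path, ["name", "xd", "yd", "zd", "xr", "yr", "zr"])
    out = []
    for r in rows:
        vals = _floats(r[1:], path, f"FNRP {r[0]!r}")
        out.append(Fnrp(r[0], np.array(vals[:3]), np.array(vals[3:])))
    return out


class ReductionPlanner(BaseEstimator):
    """The FNRP planning pipeline as a transformer.

    ``fit(X, y)`` estimates the reduction transform from the dislocated
    zygoma cloud ``X`` to the planned cloud ``y`` by ICP.
    ``transform(marks)`` returns FNRP reference positions (``P_R = T P_D``);
    ``inverse_transform(holes)`` back-calculates planned screw holes onto
    the dislocated bone (``P_D = T^{-1} P_R``).

    Attributes
    ----------
    plan_ : ReductionPlan
    transform_ : RigidTransform
        The fitted reduction transform.
    rms_error_ : float
        Final ICP correspondence RMS (mm).
    """

    def __init__(self, max_iterations: int = 100, convergence_tol: float = 1e-6,
                 trim_fraction: float = 0.0,
                 max_correspondence_distance: float = np.inf,
                 subsample_cap: int | None = None, seed: int | None = None,
                 rms_threshold: float = 1.0,
                 init: RigidTransform | None = None):
        self.max_iterations = max_iterations
        self.convergence_tol = convergence_tol
        self.trim_fraction = trim_fraction
        self.max_correspondence_distance = max_correspondence_distance
        self.subsample_cap = subsample_cap
        self.seed = seed
        self.rms_threshold = rms_threshold
        self.init = init

    def fit(self, X, y):
        params = IcpParams(
            max_iterations=self.max_iterations,
            convergence_tol=self.convergence_tol,
            trim_fraction=self.trim_fraction,
            max_correspondence_distance=self.max_correspondence_distance,
            subsample_cap=self.subsample_cap,
            seed=self.seed,
        )
        self.plan_ = compute_reduction_transform(
            X, y, params=params, rms_threshold=self.rms_threshold,
            init=self.init)
        self.transform_ = self.plan_.t_dr
        self.rms_error_ = self.plan_.fit_diagnostics.rms_error
        return self

    def _check_fitted(self):
        if not hasattr(self, "plan_"):
            raise ValidationError("ReductionPlanner is not fitted")

    def transform(self, X):
        """FNRP generation: map dislocated-bone marks to reduced positions."""
        self._check_fitted()
        return self.transform_.apply(_as_coords(X, "marks"))

    def inverse_transform(self, X):
        """Back-calculation: map reduced-frame holes to the dislocated bone."""
        self._check_fitted()
        return self.transform_.inverse().apply(_as_coords(X, "holes"))
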