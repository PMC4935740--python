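"""Rigid registration: closed-form paired-landmark fit and iterative
closest point (ICP).

The navigation workflow uses registration twice: a coarse patient-to-image
alignment from three anatomical fiducials (nasion and the two
zygomatico-frontal sutures) refined by ~20 random surface points, and the
estimation of the dislocated-to-reduced transform of the zygoma itself by
matching the two surface point clouds with ICP.

The landmark fit is the Kabsch/Horn closed-form least-squares solution with
proper-rotation (determinant) correction; ICP is the classic point-to-point
variant alternating nearest-neighbour correspondence (kD-tree) with the
closed-form update, with optional worst-fraction trimming and a maximum
correspondence distance for outlier rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .exceptions import ConvergenceError, DegenerateGeometryError, ValidationError
from .geometry import PointSet, RigidTransform
from .io import TriMesh

__all__ = [
    "RegistrationResult",
    "IcpParams",
    "landmark_fit",
    "icp",
    "fine_alignment",
    "LandmarkTransform",
    "IterativeClosestPoint",
]

#: Second singular value below this fraction of the first marks the source
#: configuration as collinear.
COLLINEARITY_RTOL = 1e-9


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of a rigid registration.

    Attributes
    ----------
    transform : estimated rigid map from source to target frame.
    rms_error : root-mean-square residual (mm) over the points used in the
        fit — the fiducial registration error for a landmark fit, the final
        correspondence RMS for ICP.
    iterations : number of iterations performed (1 for a closed-form fit).
    converged : whether the RMS change fell below tolerance.
    rms_trace : per-iteration RMS values (mm); non-increasing for untrimmed
        point-to-point ICP.
    seed : subsampling seed actually used, if any.
    """

    transform: RigidTransform
    rms_error: float
    iterations: int = 1
    converged: bool = True
    rms_trace: tuple[float, ...] = ()
    seed: int | None = None


@dataclass(frozen=True)
class IcpParams:
    """ICP tuning knobs.

    max_correspondence_distance is in mm (``inf`` disables gating);
    trim_fraction in [0, 0.5) discards that proportion of the worst
    correspondences each iteration; subsample_cap bounds the number of
    source points used (seeded random choice) to keep large clouds cheap.
    """

    max_iterations: int = 100
    convergence_tol: float = 1e-6
    trim_fraction: float = 0.0
    max_correspondence_distance: float = np.inf
    subsample_cap: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.trim_fraction < 0.5):
            raise ValidationError("trim_fraction must be in [0, 0.5)")
        if self.convergence_tol <= 0:
            raise ValidationError("convergence_tol must be positive")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")


def _as_coords(obj, what: str) -> np.ndarray:
    if isinstance(obj, TriMesh):
        pts = obj.vertices
    elif isinstance(obj, PointSet):
        pts = obj.coordinates
    else:
        pts = np.asarray(obj, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        pts = np.atleast_2d(pts)
    if pts.ndim != 2 or (pts.size and pts.shape[1] != 3):
        raise ValidationError(f"{what} must be (N, 3) points, got {pts.shape}")
    return np.asarray(pts, dtype=float)


def landmark_fit(source, target, weights=None) -> RegistrationResult:
    """Closed-form least-squares rigid fit of paired points.

    Minimizes ``sum_i w_i || T s_i - t_i ||^2`` over rigid T via SVD of the
    weighted cross-covariance, forcing a proper rotation (det +1) by sign
    correction so reflection-requiring noise configurations resolve to the
    best rotation.  Requires at least 3 non-collinear source points.

    Returns a :class:`RegistrationResult` whose ``rms_error`` is the
    (unweighted) fiducial registration error after the fit.
    """
    s = _as_coords(source, "source landmarks")
    t = _as_coords(target, "target landmarks")
    if len(s) != len(t):
        raise ValidationError(
            f"landmark counts differ: {len(s)} source vs {len(t)} target")
    if len(s) < 3:
        raise ValidationError(
            f"a rigid fit needs at least 3 landmark pairs, got {len(s)}")
    if weights is None:
        w = np.ones(len(s))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(s),) or (w < 0).any() or w.sum() <= 0:
            raise ValidationError("weights must be non-negative, same length, not all zero")
    w = w / w.sum()

    cs = w @ s
    ct = w @ t
    s0 = s - cs
    t0 = t - ct
    _, sv, svt = np.linalg.svd(s0 * np.sqrt(w)[:, None])
    if sv[1] <= COLLINEARITY_RTOL * max(sv[0], 1.0):
        direction = svt[0] if sv[0] > 0 else np.zeros(3)
        raise DegenerateGeometryError(
            "source landmarks are collinear along direction "
            f"({direction[0]:.3f}, {direction[1]:.3f}, {direction[2]:.3f}); "
            "rotation about this line is unidentifiable")

    h = (t0 * w[:, None]).T @ s0  # 3x3 cross-covariance
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, 1.0, d]) @ vt
    trans = ct - r @ cs
    transform = RigidTransform.from_rotation_translation(r, trans)
    res = transform.apply(s) - t
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return RegistrationResult(transform=transform, rms_error=rms)


def _rms(residuals: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))


def icp(source, target, init: RigidTransform | None = None,
        params: IcpParams | None = None) -> RegistrationResult:
    """Point-to-point ICP from *source* onto *target*.

    Each iteration: transform the source, find nearest-neighbour
    correspondences in the target via a kD-tree (ties broken toward the
    lowest target index), optionally gate by distance and trim the worst
    fraction, update with the closed-form landmark fit, and record the RMS
    over the current correspondences after the update.  Stops when the RMS
    change drops below ``convergence_tol`` or after ``max_iterations``.
    The returned transform includes *init*.
    """
    params = params or IcpParams()
    src = _as_coords(source, "source cloud")
    tgt = _as_coords(target, "target cloud")
    if len(src) == 0:
        raise ValidationError("source cloud is empty")
    if len(tgt) < 3:
        raise ValidationError(f"target needs >= 3 points, got {len(tgt)}")

    seed_used = None
    if params.subsample_cap is not None and len(src) > params.subsample_cap:
        seed_used = params.seed if params.seed is not None else 0
        rng = np.random.default_rng(seed_used)
        src = src[rng.choice(len(src), params.subsample_cap, replace=False)]

    tree = cKDTree(tgt)
    t = init if init is not None else RigidTransform.identity()
    trace: list[float] = []
    converged = False
    n_keep_min = 3

    for _ in range(params.max_iterations):
        moved = t.apply(src)
        dist, idx = tree.query(moved)
        sel = np.flatnonzero(dist <= params.max_correspondence_distance)
        if len(sel) < n_keep_min:
            raise ConvergenceError(
                f"only {len(sel)} correspondences within "
                f"{params.max_correspondence_distance} mm; need >= {n_keep_min}")
        if params.trim_fraction > 0.0:
            n_keep = max(n_keep_min,
                         int(np.ceil((1.0 - params.trim_fraction) * len(sel))))
            order = np.argsort(dist[sel], kind="stable")
            sel = sel[order[:n_keep]]
        step = landmark_fit(moved[sel], tgt[idx[sel]])
        t = step.transform @ t
        rms = _rms(t.apply(src[sel]) - tgt[idx[sel]])
        trace.append(rms)
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) < params.convergence_tol:
            converged = True
            break

    return RegistrationResult(transform=t, rms_error=trace[-1],
                              iterations=len(trace), converged=converged,
                              rms_trace=tuple(trace), seed=seed_used)


def fine_alignment(coarse: RegistrationResult, surface_points,
                   target_mesh: TriMesh, params: IcpParams | None = None,
                   regions: list[str] | None = None) -> RegistrationResult:
    """Refine a coarse landmark fit with surface points against fixed
    anatomy.

    *surface_points* are probed positions (>= 4) on un-operated regions of
    the skull; the target is the mesh restricted to *regions* when given
    (e.g. the frontal/maxillary/naso-orbital patches), else the whole mesh.
    ICP is seeded with the coarse transform; the result's ``rms_error`` is
    the final surface-fit RMS.
    """
    pts = _as_coords(surface_points, "surface points")
    if len(pts) < 4:
        raise ValidationError(
            f"fine alignment needs >= 4 surface points, got {len(pts)}")
    if regions:
        tgt = np.concatenate([target_mesh.region_vertices(r) for r in regions])
    else:
        tgt = target_mesh.vertices
    return icp(pts, tgt, init=coarse.transform, params=params)


# ---------------------------------------------------------------------------
# Estimator front-ends


class LandmarkTransform(BaseEstimator):
    """Paired-landmark rigid alignment as a transformer.

    ``fit(X, y)`` estimates the rigid map from source points ``X`` (n, 3) to
    target points ``y`` (n, 3); ``transform(X)`` applies it.

    Attributes
    ----------
    transform_ : RigidTransform
    rms_error_ : float
        Fiducial registration error (mm).
    """

    def fit(self, X, y):
        res = landmark_fit(X, y)
        self.transform_ = res.transform
        self.rms_error_ = res.rms_error
        self.result_ = res
        return self

    def transform(self, X):
        self._check_fitted()
        return self.transform_.apply(_as_coords(X, "X"))

    def inverse_transform(self, X):
        self._check_fitted()
        return self.transform_.inverse().apply(_as_coords(X, "X"))

    def _check_fitted(self):
        if not hasattr(self, "transform_"):
            raise ValidationError("LandmarkTransform is not fitted")


class IterativeClosestPoint(BaseEstimator):
    """Point-to-point ICP as a transformer.

    ``fit(X, y)`` registers source cloud ``X`` onto target cloud (or mesh)
    ``y``; ``transform(X)`` maps points through the estimated transform.

    Parameters mirror :class:`IcpParams`; ``init`` is an optional coarse
    :class:`RigidTransform` seed.

    Attributes
    ----------
    transform_ : RigidTransform
    rms_error_ : float
    rms_trace_ : tuple of float
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, max_iterations: int = 100, convergence_tol: float = 1e-6,
                 trim_fraction: float = 0.0,
                 max_correspondence_distance: float = np.inf,
                 subsample_cap: int | None = None, seed: int | None = None,
                 init: RigidTransform | None = None):
        self.max_iterations = max_iterations
        self.convergence_tol = convergence_tol
        self.trim_fraction = trim_fraction
        self.max_correspondence_distance = max_correspondence_distance
        self.subsample_cap = subsample_cap
        self.seed = seed
        self.init = init

    def _params(self) -> IcpParams:
        return IcpParams(
            max_iterations=self.max_iterations,
            convergence_tol=self.convergence_tol,
            trim_fraction=self.trim_fraction,
            max_correspondence_distance=self.max_correspondence_distance,
            subsample_cap=self.subsample_cap,
            seed=self.seed,
        )

    def fit(self, X, y):
        res = icp(X, y, init=self.init, params=self._params())
        self.transform_ = res.transform
        self.rms_error_ = res.rms_error
        self.rms_trace_ = res.rms_trace
        self.n_iter_ = res.iterations
        self.converged_ = res.converged
        self.result_ = res
        return self

    def transform(self, X):
        if not hasattr(self, "transform_"):
            raise ValidationError("IterativeClosestPoint is not fitted")
        return self.transform_.apply(_as_coords(X, "X"))
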