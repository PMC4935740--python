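"""Rigid SE(3) transform algebra in millimetres and degrees.

The navigation workflow treats bone as rigid: every motion of a zygoma
fragment — the planned reduction, the simulated dislocation, the residual
malposition measured after surgery — is a proper rigid transform stored as a
4x4 homogeneous matrix acting on column vectors, ``p' = T p``.  This module
provides the transform type, composition/inversion/application, the
Euler-angle decomposition used to report per-axis rotation errors, and
geometric centers of point sets and mesh regions.

Conventions
-----------
* Units are millimetres (translations, coordinates) and degrees (angles).
* Euler angles are extrinsic, fixed-axis X-Y-Z: the rotation block factors
  as ``Rz(rz) @ Ry(ry) @ Rx(rx)``.
* The frame is right-handed; the phantom generator uses x = left,
  y = posterior, z = superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DegenerateGeometryError, ValidationError

__all__ = [
    "RigidTransform",
    "EulerAngles",
    "PointSet",
    "geometric_center",
]

#: Tolerance for the orthonormality / unit-determinant test of a rotation block.
RIGIDITY_TOL = 1e-9


def _check_rotation(r: np.ndarray, tol: float = RIGIDITY_TOL) -> float:
    """Return the orthonormality drift ``max(|R^T R - I|)``; raise if not a
    proper rotation within *tol*."""
    drift = float(np.abs(r.T @ r - np.eye(3)).max())
    if drift > tol:
        raise ValidationError(
            f"matrix rotation block is not orthonormal (drift {drift:.3e} > {tol:.0e})"
        )
    det = float(np.linalg.det(r))
    if abs(det - 1.0) > max(tol, 1e-9):
        raise ValidationError(
            f"rotation block has determinant {det:.12f}; reflections are not rigid motions"
        )
    return drift


def _orthonormalize(r: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) via SVD (nearest orthogonal matrix)."""
    u, _, vt = np.linalg.svd(r)
    out = u @ vt
    if np.linalg.det(out) < 0:  # keep it proper
        u[:, -1] *= -1.0
        out = u @ vt
    return out


@dataclass(frozen=True)
class EulerAngles:
    """Rotation about the fixed x, y and z axes, in degrees (extrinsic X-Y-Z).

    ``gimbal_lock`` flags a decomposition taken at ``|ry| = 90 deg`` where only
    the sum/difference of rx and rz is observable; by convention rx absorbs
    the free angle and rz is set to 0.
    """

    rx: float
    ry: float
    rz: float
    gimbal_lock: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.rx, self.ry, self.rz)

    def __iter__(self):
        return iter(self.as_tuple())


class RigidTransform:
    """A proper rigid motion of 3-space as a 4x4 homogeneous matrix.

    Parameters
    ----------
    matrix : (4, 4) array-like
        Homogeneous matrix with orthonormal rotation block (det +1) and
        bottom row ``[0, 0, 0, 1]``.
    reorthonormalize : bool
        If True, project a slightly drifted rotation block back onto SO(3)
        instead of rejecting it (used internally by :meth:`compose`).
    """

    __slots__ = ("_m",)

    def __init__(self, matrix, *, reorthonormalize: bool = False):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"rigid transform must be 4x4, got shape {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValidationError("rigid transform contains non-finite entries")
        if np.abs(m[3] - np.array([0.0, 0.0, 0.0, 1.0])).max() > RIGIDITY_TOL:
            raise ValidationError(f"bottom row must be [0, 0, 0, 1], got {m[3]}")
        r = m[:3, :3]
        if reorthonormalize:
            drift = float(np.abs(r.T @ r - np.eye(3)).max())
            if drift > RIGIDITY_TOL:
                r = _orthonormalize(r)
                m = m.copy()
                m[:3, :3] = r
        _check_rotation(r)
        m = m.copy()
        m[3] = (0.0, 0.0, 0.0, 1.0)
        m.flags.writeable = False
        self._m = m

    # -- constructors ------------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation, translation) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @classmethod
    def from_translation(cls, translation) -> "RigidTransform":
        return cls.from_rotation_translation(np.eye(3), translation)

    @classmethod
    def from_euler(cls, angles: "EulerAngles | Sequence[float]",
                   translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build ``Rz(rz) Ry(ry) Rx(rx)`` (extrinsic X-Y-Z, degrees) plus a
        translation."""
        rx, ry, rz = (angles.as_tuple() if isinstance(angles, EulerAngles)
                      else tuple(float(a) for a in angles))
        a, b, c = np.deg2rad([rx, ry, rz])
        ca, sa = np.cos(a), np.sin(a)
        cb, sb = np.cos(b), np.sin(b)
        cc, sc = np.cos(c), np.sin(c)
        r = np.array([
            [cc * cb, cc * sb * sa - sc * ca, cc * sb * ca + sc * sa],
            [sc * cb, sc * sb * sa + cc * ca, sc * sb * ca - cc * sa],
            [-sb, cb * sa, cb * ca],
        ])
        return cls.from_rotation_translation(r, translation)

    # -- accessors ---------------------------------------------------------

    @property
    def matrix(self) -> np.ndarray:
        return self._m

    @property
    def rotation(self) -> np.ndarray:
        return self._m[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self._m[:3, 3]

    # -- algebra -----------------------------------------------------------

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying *other* first, then *self*."""
        if not isinstance(other, RigidTransform):
            raise ValidationError("compose expects a RigidTransform")
        return RigidTransform(self._m @ other._m, reorthonormalize=True)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        """Analytic inverse ``[R^T, -R^T t]``."""
        r = self.rotation.T
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = -r @ self.translation
        return RigidTransform(m)

    def apply(self, points) -> np.ndarray:
        """Map points (shape ``(3,)`` or ``(N, 3)``, or a :class:`PointSet`)
        through the transform.  An empty set maps to an empty set."""
        if isinstance(points, PointSet):
            return PointSet(self.apply(points.coordinates), names=points.names)
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        if p.size and p.shape[1] != 3:
            raise ValidationError(f"points must be (N, 3), got shape {p.shape}")
        if p.size == 0:
            out = np.empty((0, 3))
        else:
            out = p @ self.rotation.T + self.translation
        return out[0] if single else out

    # -- decomposition -----------------------------------------------------

    def to_euler(self) -> EulerAngles:
        """Decompose the rotation block into extrinsic X-Y-Z angles (degrees).

        Near gimbal lock (|cos ry| < 1e-9) the returned angles use the
        convention rz = 0 with rx absorbing the free angle, and
        ``gimbal_lock`` is set.
        """
        r = self.rotation
        sb = -float(r[2, 0])
        sb = min(1.0, max(-1.0, sb))
        cb = float(np.hypot(r[2, 1], r[2, 2]))
        if cb < 1e-9:
            ry = 90.0 if sb > 0 else -90.0
            # r[0,1] = sin(rx -/+ rz), r[1,1] = cos(rx -/+ rz); set rz = 0
            if sb > 0:
                rx = float(np.degrees(np.arctan2(r[0, 1], r[1, 1])))
            else:
                rx = float(np.degrees(np.arctan2(-r[0, 1], r[1, 1])))
            return EulerAngles(rx, ry, 0.0, gimbal_lock=True)
        ry = float(np.degrees(np.arctan2(sb, cb)))
        rx = float(np.degrees(np.arctan2(r[2, 1], r[2, 2])))
        rz = float(np.degrees(np.arctan2(r[1, 0], r[0, 0])))
        return EulerAngles(rx, ry, rz)

    # -- misc --------------------------------------------------------------

    def almost_equals(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return bool(np.abs(self._m - other._m).max() <= tol)

    def __repr__(self) -> str:
        t = self.translation
        e = self.to_euler()
        return (f"RigidTransform(t=({t[0]:.3f}, {t[1]:.3f}, {t[2]:.3f}) mm, "
                f"euler=({e.rx:.3f}, {e.ry:.3f}, {e.rz:.3f}) deg)")


class PointSet:
    """Named 3-D points in millimetres.

    Coordinates are an ``(N, 3)`` float array; names, when given, must be
    unique and match the number of points.
    """

    __slots__ = ("coordinates", "names")

    def __init__(self, coordinates, names: Sequence[str] | None = None):
        c = np.asarray(coordinates, dtype=float)
        if c.size == 0:
            c = c.reshape(0, 3)
        c = np.atleast_2d(c)
        if c.shape[1] != 3:
            raise ValidationError(f"coordinates must be (N, 3), got {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValidationError("point coordinates must be finite")
        if names is not None:
            names = list(names)
            if len(names) != len(c):
                raise ValidationError(
                    f"{len(names)} names for {len(c)} points")
            if len(set(names)) != len(names):
                raise ValidationError("point names must be unique within a set")
        self.coordinates = c
        self.names = names

    def __len__(self) -> int:
        return len(self.coordinates)

    def __iter__(self) -> Iterable[np.ndarray]:
        return iter(self.coordinates)

    def __getitem__(self, key):
        if isinstance(key, str):
            if self.names is None:
                raise KeyError("point set has no names")
            return self.coordinates[self.names.index(key)]
        return self.coordinates[key]

    def subset(self, indices) -> "PointSet":
        idx = np.asarray(indices)
        names = [self.names[i] for i in idx] if self.names is not None else None
        return PointSet(self.coordinates[idx], names=names)

    def __repr__(self) -> str:
        return f"PointSet(n={len(self)}, named={self.names is not None})"


def geometric_center(obj, region: str | None = None, *,
                     area_weighted: bool = False) -> np.ndarray:
    """Geometric center of a point set or labeled mesh region.

    By default this is the unweighted arithmetic mean of the vertex
    coordinates; with ``area_weighted=True`` a mesh region's center is the
    surface-area-weighted mean of its face centroids.  The displacement
    component of the global reduction error is the distance between two such
    centers.
    """
    from .io import TriMesh  # local import to avoid a cycle

    if isinstance(obj, TriMesh):
        if area_weighted:
            faces = obj.region_faces(region) if region is not None else obj.faces
            if len(faces) == 0:
                raise DegenerateGeometryError("region has no faces")
            tri = obj.vertices[faces]
            centroids = tri.mean(axis=1)
            areas = 0.5 * np.linalg.norm(
                np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
            if areas.sum() <= 0:
                raise DegenerateGeometryError("region has zero total area")
            return (centroids * areas[:, None]).sum(axis=0) / areas.sum()
        pts = obj.region_vertices(region) if region is not None else obj.vertices
    elif isinstance(obj, PointSet):
        pts = obj.coordinates
    else:
        pts = np.atleast_2d(np.asarray(obj, dtype=float))
    if pts.size == 0:
        raise DegenerateGeometryError("cannot take the center of an empty set")
    return pts.mean(axis=0)
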