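"""Shared fixtures and independent oracles.

The brute-force rigid fit here is deliberately independent of the package's
closed-form solution: it searches rotation space directly (random unit
quaternions plus shrinking local perturbations) and uses only centroid
alignment for the translation, so it can certify the closed-form optimum.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from zygonav import PhantomSpec, RigidTransform, make_phantom


@pytest.fixture(scope="session")
def phantom():
    """Default synthetic skull with a known dislocation (fixed seed)."""
    return make_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def still_phantom():
    """Phantom with zero dislocation (ground truth = identity)."""
    return make_phantom(PhantomSpec(seed=11, max_rotation_deg=0.0,
                                    max_translation_mm=0.0))


def random_rigid(rng, max_angle_deg: float = 180.0,
                 max_translation: float = 50.0) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    r = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform.from_rotation_translation(r, t)


def rotation_angle_deg(t: RigidTransform) -> float:
    """Magnitude of the rotation of *t*, degrees."""
    return float(np.degrees(np.linalg.norm(
        Rotation.from_matrix(t.rotation).as_rotvec())))


def pose_error(estimate: RigidTransform, truth: RigidTransform,
               at_point) -> tuple[float, float]:
    """(translation error at *at_point* in mm, rotation error in degrees)
    of the discrepancy transform estimate o truth^-1."""
    d = estimate @ truth.inverse()
    p = np.asarray(at_point, dtype=float)
    trans = float(np.linalg.norm(d.apply(truth.apply(p)) - truth.apply(p)))
    return trans, rotation_angle_deg(d)


def _rms_for_rotations(rots: np.ndarray, s0: np.ndarray,
                       t0: np.ndarray) -> np.ndarray:
    """RMS of centroid-aligned residuals for a batch of rotation matrices."""
    mapped = np.einsum("kij,nj->kni", rots, s0)
    res = mapped - t0[None]
    return np.sqrt(np.mean(np.sum(res**2, axis=2), axis=1))


def brute_force_rigid_rms(source: np.ndarray, target: np.ndarray,
                          seed: int = 0, n_samples: int = 4000,
                          batch: int = 96) -> float:
    """Best achievable RMS of a rigid fit, by direct search over rotations.

    Random unit quaternions seed the search; an adaptive-step random walk
    (expand on improvement, shrink on failure) polishes the best one down to
    ~1e-8 rad.  The translation for each candidate rotation is the
    centroid-aligning one (the least-squares optimum for fixed rotation).
    """
    s = np.asarray(source, dtype=float)
    t = np.asarray(target, dtype=float)
    s0 = s - s.mean(axis=0)
    t0 = t - t.mean(axis=0)
    rng = np.random.default_rng(seed)

    q = rng.normal(size=(n_samples, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    rots = Rotation.from_quat(q).as_matrix()
    rms = _rms_for_rotations(rots, s0, t0)
    best_i = int(np.argmin(rms))
    best_rot = Rotation.from_quat(q[best_i])
    best_rms = float(rms[best_i])

    scale = 0.5  # radians
    while scale > 1e-9:
        perturb = Rotation.from_rotvec(rng.normal(scale=scale, size=(batch, 3)))
        cand = perturb * best_rot
        rms = _rms_for_rotations(cand.as_matrix(), s0, t0)
        i = int(np.argmin(rms))
        if rms[i] < best_rms:
            best_rms = float(rms[i])
            best_rot = cand[i]
            scale *= 1.5
        else:
            scale *= 0.6
        scale = min(scale, 1.0)
    return best_rms
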