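"""Exact SO(3)/SE(3) primitives.

Rotations are plain 3x3 ``numpy`` arrays satisfying ``R^T R = I`` and
``det(R) = 1``; rigid motions are ``(rotation, translation)`` pairs.  All
angles are radians internally; degrees appear only at user-facing
interfaces (cryo-ET convention).

The twist vector of a relative pose ``(omega, p)`` is ``(log(omega)^vee, p)``:
the rotational part is the axis-angle vector (the matrix logarithm mapped to
R^3 by the vee operator), the translational part is the neighbor position in
the query's canonical frame.  Its norms are the angular distance on SO(3)
and the Euclidean inter-particle distance.

Conventions
-----------
* Axis-angle: angle in ``[0, pi]``; at angle pi the axis sign is fixed so
  that the first nonzero component is positive.
* ``log_so3`` uses first-order skew extraction near angle 0 and the
  symmetric-part construction ``(R + I)/2`` near angle pi, where the
  antisymmetric part degenerates.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = [
    "ORTHOGONALITY_TOL",
    "RigidMotion",
    "angular_distance",
    "compose",
    "exp_so3",
    "hat",
    "invert",
    "is_rotation",
    "log_so3",
    "project_to_so3",
    "random_rotation",
    "relative_pose",
    "swing_twist",
    "twist_from_pair",
    "validate_rotation",
    "vee",
]

ORTHOGONALITY_TOL = 1e-10

# angle above which the antisymmetric-part axis extraction is abandoned in
# favour of the symmetric-part construction
_NEAR_PI = np.pi - 1e-4
_NEAR_ZERO = 1e-8


class RigidMotion(NamedTuple):
    """An element of SE(3): a rotation followed by a translation."""

    rotation: np.ndarray
    translation: np.ndarray


def is_rotation(m: np.ndarray, tol: float = ORTHOGONALITY_TOL) -> bool:
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        return False
    if not np.allclose(m.T @ m, np.eye(3), atol=tol, rtol=0.0):
        return False
    return bool(abs(np.linalg.det(m) - 1.0) <= max(tol, 1e-9))


def validate_rotation(m: np.ndarray, tol: float = ORTHOGONALITY_TOL) -> np.ndarray:
    """Return ``m`` as a float array, raising ``ValueError`` naming the
    violated invariant (orthogonality or unit determinant) otherwise."""
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"rotation must be a 3x3 matrix, got shape {m.shape}")
    if not np.allclose(m.T @ m, np.eye(3), atol=tol, rtol=0.0):
        raise ValueError("matrix is not orthogonal (R^T R != I)")
    det = np.linalg.det(m)
    if abs(det - 1.0) > max(tol, 1e-9):
        raise ValueError(f"matrix determinant is {det:.6f}, not +1")
    return m


def hat(v: np.ndarray) -> np.ndarray:
    """Skew-symmetric embedding of a 3-vector: ``hat(v) w = v x w``."""
    x, y, z = np.asarray(v, dtype=float)
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def vee(m: np.ndarray) -> np.ndarray:
    """Inverse of :func:`hat` on skew-symmetric matrices."""
    return np.array([m[2, 1], m[0, 2], m[1, 0]])


def exp_so3(zeta: np.ndarray) -> np.ndarray:
    """Matrix exponential of ``hat(zeta)`` via the Rodrigues formula."""
    zeta = np.asarray(zeta, dtype=float)
    theta = np.linalg.norm(zeta)
    k = hat(zeta)
    if theta < 1e-8:
        # second-order series; exact to double precision at this scale
        return np.eye(3) + k + 0.5 * (k @ k)
    a = np.sin(theta) / theta
    b = (1.0 - np.cos(theta)) / theta**2
    return np.eye(3) + a * k + b * (k @ k)


def _axis_near_pi(r: np.ndarray) -> np.ndarray:
    """Rotation axis near angle pi from the symmetric part:
    ``(R + R^T)/2 = cos(t) I + (1 - cos(t)) a a^T``, so ``a a^T`` is
    recovered with a well-conditioned ``1 - cos(t) ~ 2`` denominator.  The
    dominant diagonal entry gives the best-conditioned component; the rest
    follow from the off-diagonal products."""
    cos_theta = (np.trace(r) - 1.0) / 2.0
    b = ((r + r.T) / 2.0 - cos_theta * np.eye(3)) / (1.0 - cos_theta)
    k = int(np.argmax(np.diag(b)))
    axis = np.empty(3)
    axis[k] = np.sqrt(max(b[k, k], 0.0))
    for i in range(3):
        if i != k:
            axis[i] = b[i, k] / axis[k]
    axis /= np.linalg.norm(axis)
    # deterministic sign: first component of magnitude > tol positive
    for c in axis:
        if abs(c) > 1e-12:
            if c < 0:
                axis = -axis
            break
    return axis


def log_so3(r: np.ndarray) -> np.ndarray:
    """Axis-angle vector ``log(r)^vee`` with norm in ``[0, pi]``.

    Stable over the whole group: the rotation angle comes from
    ``atan2(||antisymmetric part||, (trace - 1)/2)`` and the axis from the
    antisymmetric part away from pi, or from the symmetric-part
    construction near pi.
    """
    r = np.asarray(r, dtype=float)
    s = vee((r - r.T) / 2.0)  # sin(theta) * axis
    sin_theta = np.linalg.norm(s)
    cos_theta = (np.trace(r) - 1.0) / 2.0
    theta = np.arctan2(sin_theta, cos_theta)
    if theta < _NEAR_ZERO:
        return s  # first-order: log(R) ~ (R - R^T)/2
    if theta > _NEAR_PI:
        axis = _axis_near_pi(r)
        if sin_theta > 1e-12 and np.dot(axis, s) < 0:
            axis = -axis
        return theta * axis
    return theta / sin_theta * s


def project_to_so3(m: np.ndarray) -> np.ndarray:
    """Nearest rotation (orthogonal Procrustes): ``U V^T`` from the SVD of
    ``m``, with the sign of the last column of ``U`` flipped if needed so
    that the determinant is +1.  Idempotent on rotations."""
    m = np.asarray(m, dtype=float)
    u, sv, vt = np.linalg.svd(m)
    if sv[-1] <= 1e-12 * max(sv[0], 1.0):
        raise ValueError("matrix is rank-deficient; no unique nearest rotation")
    r = u @ vt
    if np.linalg.det(r) < 0:
        u = u.copy()
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def compose(a: RigidMotion, b: RigidMotion) -> RigidMotion:
    """Group product ``a * b`` of rigid motions."""
    return RigidMotion(a.rotation @ b.rotation, a.rotation @ b.translation + a.translation)


def invert(a: RigidMotion) -> RigidMotion:
    return RigidMotion(a.rotation.T, -(a.rotation.T @ a.translation))


def relative_pose(query: RigidMotion, neighbor: RigidMotion) -> RigidMotion:
    """Pose of ``neighbor`` in the canonical frame of ``query``:
    ``(w1^T w2, w1^T (p2 - p1))``.

    Invariant under left-composition of both inputs with a common rigid
    motion, which is what makes downstream descriptors rotationally
    invariant.
    """
    w1 = validate_rotation(query.rotation)
    w2 = validate_rotation(neighbor.rotation)
    p1 = np.asarray(query.translation, dtype=float)
    p2 = np.asarray(neighbor.translation, dtype=float)
    return RigidMotion(w1.T @ w2, w1.T @ (p2 - p1))


def twist_from_pair(query: RigidMotion, neighbor: RigidMotion) -> tuple[np.ndarray, np.ndarray]:
    """Twist vector ``(zeta, trans)`` of the relative pose of a pair.

    ``||trans||`` is the Euclidean inter-particle distance and ``||zeta||``
    the angular distance between the two orientations.  A particle paired
    with itself (zero-distance pair) is rejected.
    """
    rel = relative_pose(query, neighbor)
    if np.linalg.norm(rel.translation) < 1e-12:
        raise ValueError("zero-distance pair: a particle cannot be its own neighbor")
    return log_so3(rel.rotation), rel.translation


def angular_distance(r1: np.ndarray, r2: np.ndarray) -> float:
    """Geodesic (angular) distance on SO(3): ``||log(r1^T r2)^vee||`` in
    ``[0, pi]``.  Symmetric and bi-invariant."""
    return float(np.linalg.norm(log_so3(np.asarray(r1).T @ np.asarray(r2))))


def swing_twist(r: np.ndarray, axis: np.ndarray) -> tuple[float, np.ndarray]:
    """Decompose ``r = cone_part @ R(axis, in_plane_angle)``.

    ``in_plane_angle`` in ``(-pi, pi]`` is the twist of ``r`` about
    ``axis``; ``cone_part`` carries no twist about ``axis``.  Computed via
    the quaternion projection of the rotation onto the axis.  In the
    gimbal-degenerate case (``r`` maps ``axis`` to ``-axis``) the twist is
    undefined; by convention the angle is reported as 0 and the cone part
    is ``r`` itself.
    """
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise ValueError("axis must be unit-norm")
    r = np.asarray(r, dtype=float)
    zeta = log_so3(r)
    theta = np.linalg.norm(zeta)
    # quaternion (w, xyz) of r
    w = np.cos(theta / 2.0)
    xyz = np.sin(theta / 2.0) * (zeta / theta) if theta > 1e-12 else np.zeros(3)
    proj = np.dot(xyz, axis)
    norm = np.hypot(w, proj)
    if norm < 1e-9:
        # r takes axis to -axis: any twist angle is consistent
        return 0.0, r.copy()
    tw, tproj = w / norm, proj / norm
    in_plane = 2.0 * np.arctan2(tproj, tw)
    if in_plane <= -np.pi:
        in_plane += 2.0 * np.pi
    elif in_plane > np.pi:
        in_plane -= 2.0 * np.pi
    cone = r @ exp_so3(-in_plane * axis)
    return float(in_plane), cone


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform random rotation (QR-based)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    return q
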