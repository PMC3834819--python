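"""Rigid-body geometry primitives.

Rotations are plain 3x3 orthonormal matrices (det +1); a :class:`RigidTransform`
is the affine map ``x -> R x + t``.  All angles at the API surface are degrees;
all lengths are angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "dihedral",
    "superpose",
    "screw_decompose",
    "nerf",
    "rotation_about_axis",
]

_ORTHO_TOL = 1e-8


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis through the origin."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    x, y, z = axis / n
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if self.validate:
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
                raise ValueError("rotation matrix is not orthonormal")
            if np.linalg.det(R) < 0:
                raise ValueError("rotation matrix has negative determinant")

    # -- constructors ------------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_axis_angle(
        axis: np.ndarray, angle_deg: float, point: np.ndarray | None = None
    ) -> "RigidTransform":
        """Rotation about an axis through ``point`` (origin if omitted)."""
        R = rotation_about_axis(axis, angle_deg)
        if point is None:
            t = np.zeros(3)
        else:
            p = np.asarray(point, dtype=float)
            t = p - R @ p
        return RigidTransform(R, t)

    @staticmethod
    def screw(
        axis: np.ndarray,
        angle_deg: float,
        rise: float,
        point: np.ndarray | None = None,
    ) -> "RigidTransform":
        """Rotation about the axis line combined with translation along it."""
        axis = np.asarray(axis, dtype=float)
        a = axis / np.linalg.norm(axis)
        rt = RigidTransform.from_axis_angle(a, angle_deg, point)
        return RigidTransform(rt.rotation, rt.translation + rise * a)

    # -- algebra -----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies *other* first, then *self*."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=tol)
            and np.allclose(self.translation, 0.0, atol=tol)
        )

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-8) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=tol)
            and np.allclose(self.translation, other.translation, atol=tol)
        )


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid superposition of a mobile onto a reference set."""

    rmsd: float
    n_atom_pairs: int
    transform: RigidTransform
    atom_pair_list: tuple = ()


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def _collinear(points: np.ndarray, tol: float = 1e-8) -> bool:
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return bool(s[1] <= tol * max(s[0], 1.0))


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Optimal least-squares rigid superposition (Kabsch algorithm).

    Returns the transform mapping *mobile* onto *reference* and the minimized
    coordinate RMSD.  Selections must be equal length, order-matched and
    contain at least three non-collinear points.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(
            f"selection length mismatch: mobile {P.shape} vs reference {Q.shape}"
        )
    if len(P) < 3:
        raise ValueError("superposition needs at least 3 atom pairs")
    if _collinear(P) or _collinear(Q):
        raise ValueError("degenerate (collinear) selection")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    rt = RigidTransform(R, t)
    diff = rt.apply(P) - Q
    rmsd = float(np.sqrt((diff * diff).sum() / len(P)))
    return SuperpositionResult(rmsd=rmsd, n_atom_pairs=len(P), transform=rt)


def screw_decompose(rt: RigidTransform):
    """Decompose a rigid transform into screw parameters.

    Returns ``(axis, angle_deg, rise, point)`` where *axis* is a unit vector,
    *angle_deg* the signed rotation about it in (-180, 180], *rise* the
    translation component along the axis, and *point* a point on the screw
    axis (minimum-norm solution, perpendicular offset from the origin).

    For a (near-)pure translation the direction of the translation is used as
    the axis and the angle is 0.
    """
    R = rt.rotation
    t = rt.translation
    # rotation angle from the trace; axis from the antisymmetric part
    cos_a = (np.trace(R) - 1.0) / 2.0
    cos_a = min(1.0, max(-1.0, cos_a))
    angle = np.arccos(cos_a)
    if angle < 1e-12:
        n = np.linalg.norm(t)
        axis = t / n if n > 0 else np.array([0.0, 0.0, 1.0])
        return axis, 0.0, float(t @ axis), np.zeros(3)
    if np.pi - angle < 1e-8:
        # 180 degrees: axis from the symmetric part
        M = (R + np.eye(3)) / 2.0
        # columns of M are proportional to axis * axis components
        i = int(np.argmax(np.diag(M)))
        axis = M[:, i] / np.sqrt(M[i, i])
        axis = axis / np.linalg.norm(axis)
    else:
        w = np.array(
            [R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]
        )
        axis = w / (2.0 * np.sin(angle))
    rise = float(t @ axis)
    # orient so that the rise is non-negative by convention of the caller;
    # here keep axis as derived and return signed values consistently.
    t_perp = t - rise * axis
    point, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    angle_deg = float(np.degrees(angle))
    return axis, angle_deg, rise, point


def nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to atoms a-b-c.

    Natural extension reference frame: ``bond`` = |c-d|, ``angle_deg`` =
    angle(b, c, d), ``torsion_deg`` = dihedral(a, b, c, d).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
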