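"""Rigid-transform algebra for oligomer geometry.

A rigid transform here is the pair (R, t) acting on coordinates as
``x -> R @ x + t`` with R a proper rotation (det = +1).  Every rigid motion
with a nonzero rotation angle is equivalently a *screw motion* (Chasles):
rotation by an angle about an axis line plus a translation (the *rise*)
along that same axis.  The screw form is what assembly classification
consumes: the angle gives the rotation order of a filament or ring, the
rise gives the helical pitch per repeat, and the sign relation between the
two gives the handedness.

Conventions
-----------
* The canonical screw angle lies in (0, 180] degrees.
* With the angle positive about ``+axis``, a positive rise is a
  right-handed screw and a negative rise a left-handed one.
* At exactly 180 degrees the axis direction (hence the sign of the rise)
  is ambiguous; the rise is then reported as a magnitude with handedness
  ``"none"`` and ``axis_sign_ambiguous`` set.
* A transform whose rotation angle is numerically zero is *not* a screw
  (no rotation order exists); ``screw_decompose`` rejects it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "ScrewParameters",
    "DegenerateGeometryError",
    "PureTranslationError",
    "NotATwoFoldError",
    "superpose",
    "compose",
    "invert",
    "screw_decompose",
    "screw_recompose",
    "symmetrize_c2",
]


class DegenerateGeometryError(ValueError):
    """Point set too small or collinear for a unique superposition."""


class PureTranslationError(ValueError):
    """Transform has no rotation component; report the translation instead."""


class NotATwoFoldError(ValueError):
    """Transform is too far from an exact C2 to be symmetrized."""


_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, acting as ``x -> R x + t`` (Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(r)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite transform components")
        if abs(np.linalg.det(r) - 1.0) > 1e-6:
            raise ValueError(f"rotation determinant {np.linalg.det(r):.6g} != +1")
        if np.max(np.abs(r.T @ r - np.eye(3))) > 1e-6:
            raise ValueError("rotation matrix is not orthonormal")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec_deg(
        cls, axis, angle_deg: float, point=(0.0, 0.0, 0.0), rise: float = 0.0
    ) -> "RigidTransform":
        """Screw motion: rotate ``angle_deg`` about the line through
        ``point`` along ``axis``, then translate ``rise`` along the axis."""
        u = np.asarray(axis, dtype=float)
        n = np.linalg.norm(u)
        if n == 0:
            raise ValueError("zero rotation axis")
        u = u / n
        p = np.asarray(point, dtype=float)
        r = Rotation.from_rotvec(np.deg2rad(angle_deg) * u).as_matrix()
        t = p - r @ p + rise * u
        return cls(r, t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) coordinate array (or a single 3-vector)."""
        c = np.asarray(coords, dtype=float)
        return c @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"]), np.array(d["translation"]))


@dataclass(frozen=True)
class ScrewParameters:
    """Chasles form of a rigid transform.

    Attributes
    ----------
    axis : unit 3-vector of the screw axis direction.
    axis_point : a point on the axis line (the one closest to the origin), Å.
    angle_deg : canonical rotation angle in (0, 180].
    rise : signed translation along ``axis``, Å (magnitude only when
        ``axis_sign_ambiguous``).
    handedness : ``"right"``, ``"left"`` or ``"none"``.
    axis_sign_ambiguous : True when angle is exactly 180° (axis direction,
        hence rise sign, is conventional).
    """

    axis: np.ndarray
    axis_point: np.ndarray
    angle_deg: float
    rise: float
    handedness: str
    axis_sign_ambiguous: bool = field(default=False)

    def __post_init__(self) -> None:
        u = np.asarray(self.axis, dtype=float).reshape(3)
        if abs(np.linalg.norm(u) - 1.0) > 1e-6:
            raise ValueError("screw axis is not a unit vector")
        object.__setattr__(self, "axis", u)
        object.__setattr__(
            self, "axis_point", np.asarray(self.axis_point, dtype=float).reshape(3)
        )
        if self.handedness not in ("right", "left", "none"):
            raise ValueError(f"bad handedness {self.handedness!r}")

    def to_dict(self) -> dict:
        return {
            "axis": self.axis.tolist(),
            "axis_point": self.axis_point.tolist(),
            "angle_deg": float(self.angle_deg),
            "rise": float(self.rise),
            "handedness": self.handedness,
            "axis_sign_ambiguous": bool(self.axis_sign_ambiguous),
        }


def superpose(moving: np.ndarray, fixed: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch) of ``moving`` onto ``fixed``.

    Reflections are forbidden (the det = −1 branch of the SVD is corrected),
    preserving protein chirality.  Returns the optimal transform and the
    RMSD of the residuals after applying it.

    Raises
    ------
    DegenerateGeometryError
        If fewer than 3 point pairs are given or the points are collinear
        (the rotation would not be unique).
    """
    a = np.asarray(moving, dtype=float)
    b = np.asarray(fixed, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ or are not (N, 3): {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 point pairs, got {n}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # collinearity: second singular value of the centred cloud ~ 0
    sv = np.linalg.svd(a0, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("moving points are (near-)collinear")
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cb - r @ ca
    resid = a @ r.T + t - b
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidTransform(r, t), rmsd


def compose(outer: RigidTransform, inner: RigidTransform) -> RigidTransform:
    """Composition applying ``inner`` first: ``x -> R_o (R_i x + t_i) + t_o``."""
    r = outer.rotation @ inner.rotation
    t = outer.rotation @ inner.translation + outer.translation
    # re-orthonormalize drift from repeated products
    u, _, vt = np.linalg.svd(r)
    return RigidTransform(u @ vt, t)


def invert(t: RigidTransform) -> RigidTransform:
    return RigidTransform(t.rotation.T, -(t.rotation.T @ t.translation))


def transform_power(g: RigidTransform, k: int) -> RigidTransform:
    """``g`` composed with itself ``k`` times (k >= 0)."""
    out = RigidTransform.identity()
    for _ in range(int(k)):
        out = compose(g, out)
    return out


def screw_decompose(t: RigidTransform, rise_tolerance: float = 0.5) -> ScrewParameters:
    """Chasles decomposition of a rigid transform into screw parameters.

    The rotation axis and angle come from the rotation matrix; the rise is
    the translation component along the axis; the axis point solves
    ``(I − R) p = t_perp`` in the plane normal to the axis (the returned
    point is the axis point closest to the origin).

    Handedness: ``right`` if rise > 0 under the canonical positive angle,
    ``left`` if rise < 0, ``none`` when |rise| < ``rise_tolerance`` or the
    angle is exactly 180° (axis sign ambiguous).

    Raises
    ------
    PureTranslationError
        If the rotation angle is numerically zero — report the translation
        on its own instead; no rotation order exists.
    """
    rotvec = Rotation.from_matrix(t.rotation).as_rotvec()
    angle = float(np.linalg.norm(rotvec))  # in [0, pi]
    if angle < 1e-6:
        raise PureTranslationError(
            f"rotation angle {np.rad2deg(angle):.2e} deg ~ 0: pure translation "
            f"{t.translation}; no screw axis exists"
        )
    u = rotvec / angle
    angle_deg = float(np.rad2deg(angle))
    rise = float(u @ t.translation)

    ambiguous = abs(angle_deg - 180.0) < 1e-9
    if ambiguous:
        # axis sign is a convention at a half-turn; fix it and report |rise|
        rise = abs(rise)
        handedness = "none"
    elif abs(rise) < rise_tolerance:
        handedness = "none"
    else:
        handedness = "right" if rise > 0 else "left"

    # axis point: solve (I - R) p = t - rise*u restricted to the axis-normal
    # plane; lstsq gives the minimum-norm solution, i.e. the point on the
    # axis closest to the origin.
    t_perp = t.translation - rise * u if not ambiguous else t.translation - (u @ t.translation) * u
    a = np.eye(3) - t.rotation
    p, *_ = np.linalg.lstsq(a, t_perp, rcond=None)
    p = p - (p @ u) * u

    return ScrewParameters(
        axis=u,
        axis_point=p,
        angle_deg=angle_deg,
        rise=rise if not ambiguous else float(rise),
        handedness=handedness,
        axis_sign_ambiguous=ambiguous,
    )


def screw_recompose(s: ScrewParameters) -> RigidTransform:
    """Exact transform of the screw motion described by ``s``."""
    return RigidTransform.from_rotvec_deg(
        s.axis, s.angle_deg, point=s.axis_point, rise=s.rise
    )


def symmetrize_c2(
    t: RigidTransform,
    angle_window_deg: float = 15.0,
    max_rise: float = 5.0,
) -> tuple[RigidTransform, float, float]:
    """Project an approximate two-fold onto the nearest exact C2.

    Crystal dimer interfaces are never numerically exact two-folds; this
    forces the angle to 180° and the rise to 0 while keeping the fitted
    axis line, and reports how far the input was from exact C2.

    Returns ``(exact_c2, deviation_deg, residual_rise)`` where
    ``deviation_deg = |180 − input angle|`` and ``residual_rise`` is the
    magnitude of the input's translation along its own axis.

    Raises
    ------
    NotATwoFoldError
        If the input angle is more than ``angle_window_deg`` from 180° or
        its axial rise exceeds ``max_rise`` Å.
    """
    s = screw_decompose(t, rise_tolerance=0.0)
    deviation = abs(180.0 - s.angle_deg)
    residual_rise = abs(s.rise)
    if deviation > angle_window_deg or residual_rise > max_rise:
        raise NotATwoFoldError(
            f"angle {s.angle_deg:.2f} deg / rise {s.rise:.2f} A is outside the "
            f"approximate-C2 window (180 +/- {angle_window_deg} deg, |rise| <= {max_rise} A)"
        )
    exact = RigidTransform.from_rotvec_deg(s.axis, 180.0, point=s.axis_point, rise=0.0)
    return exact, float(deviation), float(residual_rise)
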