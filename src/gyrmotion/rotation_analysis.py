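"""Interpretable descriptors of relative domain motion.

A relative reorientation of one rigid body with respect to another is
summarised by its rotation angle kappa, the orientation of the rotation
axis (as a unit vector and as polar angles Omega/phi), the location of the
screw axis in space, and the translation component along that axis.  The
procedure mirrors the classical two-step protocol: superimpose two
structures on the anchor domain, then superimpose the mobile domains and
decompose the resulting transform.

Conventions
-----------
* kappa is canonical in [0, 180] degrees; the axis sign is chosen to make
  that so.  Axis *lines* (unsigned) are what gets compared to reference
  axes such as the dimer dyad.
* Omega is the inclination of the axis from the polar direction (the
  crystal b axis when a cell is known, +z otherwise) and phi the azimuth in
  the perpendicular plane, measured from the a (or x) direction towards c
  (or y); the unit vector is always reported alongside so the convention is
  auditable.
* Rotations below ``DEGENERATE_KAPPA_DEG`` leave the axis location
  numerically undefined; descriptors are then flagged degenerate and carry
  a conventional axis of +z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import InvalidRotationError
from .structure_io import DomainDefinition, Structure, pair_atoms
from .superpose import RigidTransform, kabsch

__all__ = [
    "DEGENERATE_KAPPA_DEG",
    "AxisAngle",
    "ScrewDecomposition",
    "RotationDescriptor",
    "matrix_to_axis_angle",
    "axis_angle_to_matrix",
    "polar_angles",
    "screw_decomposition",
    "relative_domain_rotation",
    "angle_between_axes",
]

#: below this rotation angle the axis position is considered undefined
DEGENERATE_KAPPA_DEG = 0.1


class AxisAngle(NamedTuple):
    kappa_deg: float
    axis_unit: np.ndarray
    degenerate: bool


def _require_rotation(r: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise InvalidRotationError(f"expected 3x3 matrix, got shape {r.shape}")
    err = np.abs(r.T @ r - np.eye(3)).max()
    det = np.linalg.det(r)
    if err > tol or abs(det - 1.0) > tol:
        raise InvalidRotationError(
            f"not a proper rotation: |R^T R - I| = {err:.2e}, det = {det:.6f}"
        )
    return r


def _quaternion_from_matrix(r: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) via Shepperd's method (numerically
    stable for all angles including near 180 degrees)."""
    t = np.trace(r)
    candidates = [t, r[0, 0], r[1, 1], r[2, 2]]
    i = int(np.argmax(candidates))
    if i == 0:
        s = math.sqrt(max(1.0 + t, 0.0)) * 2.0
        q = np.array([0.25 * s,
                      (r[2, 1] - r[1, 2]) / s,
                      (r[0, 2] - r[2, 0]) / s,
                      (r[1, 0] - r[0, 1]) / s])
    elif i == 1:
        s = math.sqrt(max(1.0 + r[0, 0] - r[1, 1] - r[2, 2], 0.0)) * 2.0
        q = np.array([(r[2, 1] - r[1, 2]) / s,
                      0.25 * s,
                      (r[0, 1] + r[1, 0]) / s,
                      (r[0, 2] + r[2, 0]) / s])
    elif i == 2:
        s = math.sqrt(max(1.0 - r[0, 0] + r[1, 1] - r[2, 2], 0.0)) * 2.0
        q = np.array([(r[0, 2] - r[2, 0]) / s,
                      (r[0, 1] + r[1, 0]) / s,
                      0.25 * s,
                      (r[1, 2] + r[2, 1]) / s])
    else:
        s = math.sqrt(max(1.0 - r[0, 0] - r[1, 1] + r[2, 2], 0.0)) * 2.0
        q = np.array([(r[1, 0] - r[0, 1]) / s,
                      (r[0, 2] + r[2, 0]) / s,
                      (r[1, 2] + r[2, 1]) / s,
                      0.25 * s])
    q /= np.linalg.norm(q)
    if q[0] < 0:  # canonical hemisphere: kappa in [0, 180]
        q = -q
    return q


def matrix_to_axis_angle(r: np.ndarray) -> AxisAngle:
    """Decompose a proper rotation into (kappa in degrees, unit axis).

    kappa lies in [0, 180].  For kappa below the degeneracy tolerance the
    axis is reported as +z with the degenerate flag set; at kappa = 180 the
    axis is defined only up to sign.
    """
    r = _require_rotation(r)
    q = _quaternion_from_matrix(r)
    vec_norm = float(np.linalg.norm(q[1:]))
    kappa = math.degrees(2.0 * math.atan2(vec_norm, q[0]))
    if kappa < DEGENERATE_KAPPA_DEG or vec_norm < 1e-12:
        return AxisAngle(kappa, np.array([0.0, 0.0, 1.0]), True)
    return AxisAngle(kappa, q[1:] / vec_norm, False)


def axis_angle_to_matrix(axis_unit: np.ndarray, kappa_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    u = np.asarray(axis_unit, dtype=float)
    n = np.linalg.norm(u)
    if n == 0:
        raise ValueError("axis must be non-zero")
    u = u / n
    k = math.radians(kappa_deg)
    cross = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return math.cos(k) * np.eye(3) + math.sin(k) * cross + (1 - math.cos(k)) * np.outer(u, u)


def polar_angles(
    axis_unit: np.ndarray,
    cell: tuple[float, ...] | None = None,
) -> tuple[float, float]:
    """(Omega, phi) in degrees for an axis direction.

    With a unit cell, the polar direction is the Cartesian b axis and the
    azimuth is measured from a towards c; without one, polar = +z and
    azimuth from +x towards +y.
    """
    u = np.asarray(axis_unit, dtype=float)
    u = u / np.linalg.norm(u)
    if cell is not None:
        import gemmi

        mat = np.array(gemmi.UnitCell(*cell).orth.mat.tolist())
        pole = mat[:, 1] / np.linalg.norm(mat[:, 1])
        e1 = mat[:, 0] - (mat[:, 0] @ pole) * pole
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(pole, e1)
    else:
        pole = np.array([0.0, 0.0, 1.0])
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = np.array([0.0, 1.0, 0.0])
    omega = math.degrees(math.acos(np.clip(u @ pole, -1.0, 1.0)))
    phi = math.degrees(math.atan2(u @ e2, u @ e1)) % 360.0
    return omega, phi


@dataclass
class ScrewDecomposition:
    axis_unit: np.ndarray
    axis_point: np.ndarray
    kappa_deg: float
    screw_translation: float
    degenerate: bool = False


def screw_decomposition(
    t: RigidTransform,
    reference_point: np.ndarray | None = None,
) -> ScrewDecomposition:
    """Split a rigid transform into rotation about a located axis plus a
    translation along that axis (Chasles decomposition).

    The translation is projected onto the rotation axis (the screw pitch);
    the perpendicular remainder fixes the axis position by solving
    (I - R) x = t_perp, whose minimum-norm solution is perpendicular to the
    axis.  ``axis_point`` is then slid along the axis to the point closest
    to ``reference_point`` (origin by default).  Rotations below the
    degeneracy tolerance return a flagged result with the raw translation
    magnitude as screw translation.
    """
    ref = np.zeros(3) if reference_point is None else np.asarray(reference_point, dtype=float)
    kappa, axis, degenerate = matrix_to_axis_angle(t.rotation)
    if degenerate:
        return ScrewDecomposition(
            axis_unit=axis,
            axis_point=ref.copy(),
            kappa_deg=kappa,
            screw_translation=float(np.linalg.norm(t.translation)),
            degenerate=True,
        )
    pitch = float(axis @ t.translation)
    t_perp = t.translation - pitch * axis
    x0, *_ = np.linalg.lstsq(np.eye(3) - t.rotation, t_perp, rcond=None)
    x0 = x0 - (x0 @ axis) * axis  # enforce perpendicularity to the axis
    axis_point = x0 + ((ref - x0) @ axis) * axis
    return ScrewDecomposition(
        axis_unit=axis,
        axis_point=axis_point,
        kappa_deg=kappa,
        screw_translation=pitch,
        degenerate=False,
    )


@dataclass
class RotationDescriptor:
    """Full account of one relative domain motion."""

    kappa_deg: float
    axis_unit: np.ndarray
    axis_point: np.ndarray
    screw_translation: float
    omega_phi: tuple[float, float]
    degenerate: bool = False
    source_pair: tuple[str, str, str, str] | None = None  # (ref id, mob id, anchor, mobile)

    def __post_init__(self) -> None:
        self.axis_unit = np.asarray(self.axis_unit, dtype=float)
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        if abs(np.linalg.norm(self.axis_unit) - 1.0) > 1e-9:
            raise ValueError("axis_unit must be a unit vector")

    def to_transform(self) -> RigidTransform:
        """Reconstruct the rigid transform this descriptor summarises."""
        r = axis_angle_to_matrix(self.axis_unit, self.kappa_deg)
        t = (np.eye(3) - r) @ self.axis_point + self.screw_translation * self.axis_unit
        return RigidTransform(r, t)

    def to_dict(self) -> dict:
        omega, phi = self.omega_phi
        return {
            "kappa_deg": round(self.kappa_deg, 4),
            "axis_unit": [round(v, 6) for v in self.axis_unit],
            "axis_point": [round(v, 4) for v in self.axis_point],
            "screw_translation_A": round(self.screw_translation, 4),
            "omega_deg": round(omega, 2),
            "phi_deg": round(phi, 2),
            "degenerate": self.degenerate,
            "source_pair": self.source_pair,
        }


def descriptor_from_transform(
    t: RigidTransform,
    *,
    reference_point: np.ndarray | None = None,
    cell: tuple[float, ...] | None = None,
    source_pair: tuple[str, str, str, str] | None = None,
) -> RotationDescriptor:
    screw = screw_decomposition(t, reference_point=reference_point)
    return RotationDescriptor(
        kappa_deg=screw.kappa_deg,
        axis_unit=screw.axis_unit,
        axis_point=screw.axis_point,
        screw_translation=screw.screw_translation,
        omega_phi=polar_angles(screw.axis_unit, cell),
        degenerate=screw.degenerate,
        source_pair=source_pair,
    )


def relative_domain_rotation(
    ref: Structure,
    mob: Structure,
    anchor: DomainDefinition,
    mobile: DomainDefinition,
) -> RotationDescriptor:
    """Reorientation of ``mobile`` relative to ``anchor`` between two states.

    Step 1: superimpose ``mob`` onto ``ref`` using the anchor-domain atoms.
    Step 2: superimpose the reference mobile domain onto the anchored mobile
    domain; the resulting transform — the motion carrying the reference
    domain into its position in ``mob`` — is decomposed into a screw
    descriptor.  The axis point reported is the point on the screw axis
    closest to the mobile-domain centroid.
    """
    anchor_pairs = pair_atoms(ref, mob, anchor)
    # kabsch maps ref -> mob; its inverse brings mob into the ref frame
    anchored_mob = kabsch(anchor_pairs).transform.inverse().apply_to_structure(mob)
    mobile_pairs = pair_atoms(ref, anchored_mob, mobile)
    motion = kabsch(mobile_pairs).transform
    centroid = mobile_pairs.coords_a.mean(axis=0)
    return descriptor_from_transform(
        motion,
        reference_point=centroid,
        cell=ref.cell,
        source_pair=(ref.id, mob.id, anchor.name, mobile.name),
    )


def angle_between_axes(u: np.ndarray, v: np.ndarray) -> float:
    """Acute angle in degrees between two axis *lines* (sign-blind)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("axes must be non-zero vectors")
    u = u / nu
    v = v / nv
    if u @ v < 0:
        v = -v  # same line, aligned direction
    # atan2 form is accurate near both 0 and 90 degrees
    return math.degrees(math.atan2(np.linalg.norm(np.cross(u, v)), u @ v))
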