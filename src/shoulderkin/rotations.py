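"""Rotation matrices and intrinsic Euler-sequence decomposition.

This module is the mathematical core of the pipeline: it builds proper
rotation matrices from intrinsic Euler angle triples, decomposes rotations
back into the two sequences used for shoulder kinematics, and computes the
rotation relating a child anatomical frame to its parent.

Two intrinsic (body-fixed) sequences are supported:

* ``YXZ`` (Y-X'-Z''): the ISB-recommended sequence for scapulothoracic
  orientation.
* ``XZY`` (X-Z'-Y''): used for glenohumeral orientation, preferred over
  Y-X'-Y'' because the latter is ill-conditioned at low humeral elevation.

Everything here follows the right-hand rule; the clinical sign reversals
(e.g. "+" upward rotation) live exclusively in :mod:`shoulderkin.angles`.
Angles cross the module boundary in degrees; trigonometry is in radians.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EulerSequence",
    "RawEulerTriple",
    "InvalidRotationError",
    "GIMBAL_TOL_DEG",
    "check_rotation",
    "rot_x",
    "rot_y",
    "rot_z",
    "compose_euler",
    "decompose",
    "relative_rotation",
]

#: |middle angle| within this many degrees of 90 deg raises the gimbal flag
#: (1e-3 rad; far tighter than any anatomical configuration in scope).
GIMBAL_TOL_DEG = math.degrees(1e-3)

_ORTHO_TOL = 1e-6  # acceptance tolerance for inputs claiming to be rotations


class InvalidRotationError(ValueError):
    """Raised when a matrix is not a proper rotation within tolerance."""


class EulerSequence(enum.Enum):
    """Intrinsic Euler sequences accepted by :func:`decompose`."""

    YXZ = "YXZ"
    XZY = "XZY"


@dataclass(frozen=True)
class RawEulerTriple:
    """Three intrinsic Euler angles in degrees, right-hand-rule signs.

    ``a2`` is confined to the principal branch [-90, 90].  When
    ``gimbal_flag`` is set the decomposition is non-unique; by convention
    ``a3`` is reported as 0 and ``a1`` absorbs the free rotation.
    """

    a1: float
    a2: float
    a3: float
    sequence: EulerSequence
    gimbal_flag: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a1, self.a2, self.a3)


def check_rotation(m: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    """Validate that ``m`` is a proper rotation; return it as float array.

    Raises :class:`InvalidRotationError` if ``m`` is not 3x3, not orthonormal
    to ``tol`` per element, or has determinant differing from +1 by more
    than ``tol``.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3) or not np.all(np.isfinite(m)):
        raise InvalidRotationError("rotation must be a finite 3x3 matrix")
    if np.max(np.abs(m.T @ m - np.eye(3))) > tol:
        raise InvalidRotationError("matrix is not orthonormal within tolerance")
    if abs(np.linalg.det(m) - 1.0) > tol:
        raise InvalidRotationError("matrix is not proper (det != +1)")
    return m


def rot_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_AXIS_ROT = {"X": rot_x, "Y": rot_y, "Z": rot_z}


def compose_euler(
    seq: EulerSequence, a1: float, a2: float, a3: float
) -> np.ndarray:
    """Compose the intrinsic rotation R = R_axis1(a1) @ R_axis2(a2) @ R_axis3(a3).

    Angles are in degrees.  For intrinsic sequences the matrix product in
    the fixed frame is taken in the listed order.
    """
    angles = (a1, a2, a3)
    if not all(math.isfinite(a) for a in angles):
        raise ValueError("Euler angles must be finite")
    seq = EulerSequence(seq)
    r = np.eye(3)
    for axis, ang in zip(seq.value, angles):
        r = r @ _AXIS_ROT[axis](ang)
    return r


def _wrap_deg(a: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    a = math.remainder(a, 360.0)  # in [-180, 180]
    return a if a != -180.0 else 180.0


def decompose(m: np.ndarray, seq: EulerSequence) -> RawEulerTriple:
    """Decompose a proper rotation into an intrinsic Euler triple (degrees).

    The middle angle is taken on the principal branch [-90, 90].  Within
    :data:`GIMBAL_TOL_DEG` of gimbal lock (|a2| = 90 deg) the first and third
    rotations are indistinguishable; ``a3`` is pinned to 0, ``a1`` carries the
    combined rotation, and ``gimbal_flag`` is set.
    """
    m = check_rotation(m)
    seq = EulerSequence(seq)
    if seq is EulerSequence.YXZ:
        # R = Ry(a1) Rx(a2) Rz(a3):
        #   m[1,2] = -sin(a2); m[0,2] = sin(a1)cos(a2); m[2,2] = cos(a1)cos(a2)
        #   m[1,0] = cos(a2)sin(a3); m[1,1] = cos(a2)cos(a3)
        s2 = -m[1, 2]
        a2 = math.degrees(math.asin(min(1.0, max(-1.0, s2))))
        if 90.0 - abs(a2) < GIMBAL_TOL_DEG:
            # a1 and a3 degenerate; with a3 := 0,
            #   m[0,0] = cos(a1 -/+ a3'), m[0,1] = +/- sin(a1 -/+ a3')
            if s2 > 0:
                a1 = math.degrees(math.atan2(m[0, 1], m[0, 0]))
            else:
                a1 = math.degrees(math.atan2(-m[0, 1], m[0, 0]))
            return RawEulerTriple(_wrap_deg(a1), a2, 0.0, seq, True)
        a1 = math.degrees(math.atan2(m[0, 2], m[2, 2]))
        a3 = math.degrees(math.atan2(m[1, 0], m[1, 1]))
    else:
        # R = Rx(a1) Rz(a2) Ry(a3):
        #   m[0,1] = -sin(a2); m[2,1] = sin(a1)cos(a2); m[1,1] = cos(a1)cos(a2)
        #   m[0,2] = cos(a2)sin(a3); m[0,0] = cos(a2)cos(a3)
        s2 = -m[0, 1]
        a2 = math.degrees(math.asin(min(1.0, max(-1.0, s2))))
        if 90.0 - abs(a2) < GIMBAL_TOL_DEG:
            if s2 > 0:
                a1 = math.degrees(math.atan2(m[2, 0], m[1, 0]))
            else:
                a1 = math.degrees(math.atan2(-m[2, 0], -m[1, 0]))
            return RawEulerTriple(_wrap_deg(a1), a2, 0.0, seq, True)
        a1 = math.degrees(math.atan2(m[2, 1], m[1, 1]))
        a3 = math.degrees(math.atan2(m[0, 2], m[0, 0]))
    return RawEulerTriple(_wrap_deg(a1), a2, _wrap_deg(a3), seq, False)


def relative_rotation(parent_basis: np.ndarray, child_basis: np.ndarray) -> np.ndarray:
    """Rotation expressing the child basis in parent coordinates.

    Both arguments are 3x3 matrices whose *columns* are the frame axes in a
    common (lab) coordinate system.  ``relative_rotation(B, B)`` is the
    identity for any valid basis ``B``.
    """
    parent_basis = check_rotation(parent_basis)
    child_basis = check_rotation(child_basis)
    return parent_basis.T @ child_basis
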