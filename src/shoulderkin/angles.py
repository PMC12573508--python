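"""Clinically signed scapulothoracic and glenohumeral joint angles.

Scapulothoracic orientation (scapula relative to torso) is decomposed with
the ISB-recommended intrinsic Y-X'-Z'' sequence; glenohumeral orientation
(humerus relative to scapula) with X-Z'-Y'', which avoids the instability of
Y-X'-Y'' at low humeral elevation.  Raw right-hand-rule angles are then
mapped to the clinical conventions:

========================  ==========  ==============================
DOF                        raw angle   clinical sign
========================  ==========  ==============================
protraction                +a1 (Y)     + = protraction
upward rotation            -a2 (X')    + = upward (sign reversed)
posterior tilt             +a3 (Z'')   + = posterior tilt
elevation                  -a1 (X)     + = upward (sign reversed)
plane of elevation         +a2 (Z')    + = anterior
internal rotation          +a3 (Y'')   + = internal
========================  ==========  ==============================

The two sign reversals trade the right-hand rule for intuitive reading:
upward scapular rotation and humeral elevation are positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .frames import AnatomicalFrame
from .rotations import EulerSequence, decompose, relative_rotation

__all__ = [
    "ST_DOFS",
    "GH_DOFS",
    "ScapulothoracicAngles",
    "GlenohumeralAngles",
    "PosePair",
    "scapulothoracic_angles",
    "glenohumeral_angles",
    "pose_difference",
]

ST_DOFS = ("upward_rotation", "protraction", "posterior_tilt")
GH_DOFS = ("elevation", "anterior_plane", "internal_rotation")


def _wrap(a: float) -> float:
    a = math.remainder(a, 360.0)
    return a if a != -180.0 else 180.0


@dataclass(frozen=True)
class ScapulothoracicAngles:
    """Scapula-in-torso angles (degrees), clinical signs."""

    upward_rotation: float
    protraction: float
    posterior_tilt: float
    gimbal_flag: bool = False

    joint = "scapulothoracic"
    dofs = ST_DOFS

    def as_dict(self) -> dict[str, float]:
        return {d: getattr(self, d) for d in self.dofs}


@dataclass(frozen=True)
class GlenohumeralAngles:
    """Humerus-in-scapula angles (degrees), clinical signs."""

    elevation: float
    anterior_plane: float
    internal_rotation: float
    gimbal_flag: bool = False

    joint = "glenohumeral"
    dofs = GH_DOFS

    def as_dict(self) -> dict[str, float]:
        return {d: getattr(self, d) for d in self.dofs}


def scapulothoracic_angles(
    torso: AnatomicalFrame, scapula: AnatomicalFrame
) -> ScapulothoracicAngles:
    """Decompose the scapula-in-torso rotation (Y-X'-Z'') into clinical angles."""
    raw = decompose(
        relative_rotation(torso.basis, scapula.basis), EulerSequence.YXZ
    )
    return ScapulothoracicAngles(
        upward_rotation=-raw.a2,
        protraction=raw.a1,
        posterior_tilt=raw.a3,
        gimbal_flag=raw.gimbal_flag,
    )


def glenohumeral_angles(
    scapula: AnatomicalFrame, humerus: AnatomicalFrame
) -> GlenohumeralAngles:
    """Decompose the humerus-in-scapula rotation (X-Z'-Y'') into clinical angles."""
    raw = decompose(
        relative_rotation(scapula.basis, humerus.basis), EulerSequence.XZY
    )
    return GlenohumeralAngles(
        elevation=-raw.a1,
        anterior_plane=raw.a2,
        internal_rotation=raw.a3,
        gimbal_flag=raw.gimbal_flag,
    )


def pose_difference(upright, supine) -> dict[str, float]:
    """Per-DOF upright minus supine difference, wrapped to (-180, 180]."""
    if type(upright) is not type(supine):
        raise ValueError(
            f"cannot difference {type(upright).__name__} against "
            f"{type(supine).__name__}"
        )
    return {
        d: _wrap(getattr(upright, d) - getattr(supine, d)) for d in upright.dofs
    }


@dataclass(frozen=True)
class PosePair:
    """One patient's supine and upright angles for both joints, plus deltas."""

    patient_id: str
    supine_st: ScapulothoracicAngles
    supine_gh: GlenohumeralAngles
    upright_st: ScapulothoracicAngles
    upright_gh: GlenohumeralAngles

    @property
    def delta(self) -> dict[str, float]:
        d = pose_difference(self.upright_st, self.supine_st)
        d.update(pose_difference(self.upright_gh, self.supine_gh))
        return d

    @property
    def gimbal_flag(self) -> bool:
        return any(
            a.gimbal_flag
            for a in (self.supine_st, self.supine_gh, self.upright_st, self.upright_gh)
        )

    def angles(self, pose: str, joint: str):
        key = {
            ("supine", "scapulothoracic"): self.supine_st,
            ("supine", "glenohumeral"): self.supine_gh,
            ("upright", "scapulothoracic"): self.upright_st,
            ("upright", "glenohumeral"): self.upright_gh,
        }
        return key[(pose, joint)]
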