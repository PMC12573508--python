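"""Anatomical coordinate frames from named bony landmarks.

Builds the torso, scapula, and humerus frames used for supine-vs-upright
shoulder pose analysis.  All frames share the orientation convention
+X anterior, +Y superior, +Z lateral (toward the affected side), with a
right-handed orthonormal basis stored column-wise.

The torso frame is sternum-based (origin at the sternal notch) rather than
the ISB T8/PX frame, because clinical supine CT often truncates the distal
sternum.  For the supine pose the truncated distal-sternum landmark is first
replaced by a *synthetic xiphoid*: a point constructed in the plane of
{sternal notch, distal sternum, C7} such that the opening angle between the
superior-inferior axis and the sternal-notch-to-C7 vector equals the upright
opening angle theta_u.  This makes the supine and upright torso axes
consistent (theta_cs = theta_u) despite the missing xiphoid.

Left shoulders are mirrored across a configurable plane (default the input
x-z plane) before construction, so a single right-side sign convention
serves both sides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .rotations import check_rotation

__all__ = [
    "LANDMARK_NAMES",
    "TORSO_LANDMARKS",
    "SCAPULA_LANDMARKS",
    "DegenerateLandmarkError",
    "CorrectionInfeasibleError",
    "LandmarkSet",
    "AnatomicalFrame",
    "TorsoAxisCorrection",
    "opening_angle",
    "corrected_supine_axis",
    "build_torso_frame",
    "build_scapula_frame",
    "build_humerus_frame",
    "frame_axis_sensitivity",
]

#: Landmark vocabulary accepted by the pipeline (coordinates in mm).
LANDMARK_NAMES = (
    "sternal_notch",
    "distal_sternum",
    "xiphoid",
    "c7_spinous",
    "glenosphere_center",
    "inferior_angle",
    "trigonum_spinae",
    "lesser_tuberosity",
)

TORSO_LANDMARKS = ("sternal_notch", "c7_spinous")  # plus xiphoid OR distal_sternum
SCAPULA_LANDMARKS = ("glenosphere_center", "inferior_angle", "trigonum_spinae")

_MIN_TRIANGLE_AREA_MM2 = 1.0

_MIRROR_AXIS = {"xy": 2, "xz": 1, "yz": 0}


class DegenerateLandmarkError(ValueError):
    """Landmarks too close to collinear/coincident to define a frame."""


class CorrectionInfeasibleError(ValueError):
    """No in-plane synthetic xiphoid satisfies the requested opening angle."""


def _point(p) -> np.ndarray:
    p = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(p)):
        raise ValueError("landmark coordinates must be finite")
    return p


def _unit(v: np.ndarray, context: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateLandmarkError(f"{context} has near-zero length")
    return v / n


def _triangle_area(a, b, c) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(b - a, c - a)))


@dataclass(frozen=True)
class LandmarkSet:
    """Named 3D landmarks (mm) for one patient/pose.

    ``points`` maps names from :data:`LANDMARK_NAMES` to length-3 arrays.
    ``pose_label`` is ``"supine"`` or ``"upright"``; ``side`` is ``"right"``
    or ``"left"``.
    """

    pose_label: str
    side: str
    points: Mapping[str, np.ndarray]
    patient_id: str = ""

    def __post_init__(self):
        if self.pose_label not in ("supine", "upright"):
            raise ValueError(f"unknown pose_label {self.pose_label!r}")
        if self.side not in ("right", "left"):
            raise ValueError(f"unknown side {self.side!r}")
        pts = {}
        for name, xyz in dict(self.points).items():
            if name not in LANDMARK_NAMES:
                raise ValueError(
                    f"unknown landmark {name!r}; allowed: {', '.join(LANDMARK_NAMES)}"
                )
            pts[name] = _point(xyz)
        object.__setattr__(self, "points", pts)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise KeyError(
                f"landmark {name!r} missing (present: {sorted(self.points)})"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def require(self, names, frame: str) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise KeyError(
                f"{frame} frame requires landmark(s) {missing}; "
                f"present: {sorted(self.points)}"
            )

    def mirrored(self, plane: str = "xz") -> "LandmarkSet":
        """Reflect all landmarks across a coordinate plane (for left sides)."""
        axis = _MIRROR_AXIS[plane]
        pts = {}
        for name, p in self.points.items():
            q = p.copy()
            q[axis] = -q[axis]
            pts[name] = q
        return LandmarkSet(self.pose_label, "right", pts, self.patient_id)


@dataclass(frozen=True)
class AnatomicalFrame:
    """Origin (mm) plus right-handed basis; columns are +X, +Y, +Z axes."""

    body: str
    origin: np.ndarray
    basis: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", _point(self.origin))
        object.__setattr__(self, "basis", check_rotation(self.basis, tol=1e-9))

    @property
    def x(self) -> np.ndarray:  # anterior
        return self.basis[:, 0]

    @property
    def y(self) -> np.ndarray:  # superior
        return self.basis[:, 1]

    @property
    def z(self) -> np.ndarray:  # lateral
        return self.basis[:, 2]


@dataclass(frozen=True)
class TorsoAxisCorrection:
    """Result of the supine superior-inferior axis correction."""

    theta_u: float
    theta_cs: float
    synthetic_xiphoid: np.ndarray = field(repr=False)
    si_axis: np.ndarray = field(repr=False)


def opening_angle(xiphoid, sternal_notch, c7) -> float:
    """Torso opening angle (degrees) between xiphoid->SN and SN->C7 vectors."""
    xiphoid, sternal_notch, c7 = map(_point, (xiphoid, sternal_notch, c7))
    v1 = _unit(sternal_notch - xiphoid, "xiphoid to sternal notch")
    v2 = _unit(c7 - sternal_notch, "sternal notch to C7")
    # atan2 form is exact near 0 and 180 deg where arccos loses precision
    return math.degrees(math.atan2(np.linalg.norm(np.cross(v1, v2)), float(v1 @ v2)))


def corrected_supine_axis(
    sternal_notch, distal_sternum, c7, theta_u: float
) -> TorsoAxisCorrection:
    """Construct the synthetic xiphoid and corrected supine torso axis.

    The synthetic xiphoid lies in the plane of the three supine landmarks,
    at the distal-sternum distance from the sternal notch, placed so the
    supine opening angle theta_cs equals the upright angle ``theta_u``.  Of
    the two in-plane solutions the one angularly closest to the original
    truncated-sternum direction is returned.
    """
    sn, ds, c7 = map(_point, (sternal_notch, distal_sternum, c7))
    if not 0.0 < theta_u < 180.0:
        raise CorrectionInfeasibleError(
            f"theta_u must lie in (0, 180) degrees, got {theta_u}"
        )
    if _triangle_area(sn, ds, c7) < _MIN_TRIANGLE_AREA_MM2:
        raise DegenerateLandmarkError(
            "sternal notch, distal sternum and C7 are nearly collinear"
        )
    c = _unit(c7 - sn, "sternal notch to C7")
    d0 = ds - sn
    dist = np.linalg.norm(d0)
    d0 = d0 / dist
    # in-plane unit vector orthogonal to c, oriented toward the sternum side
    e2 = d0 - (d0 @ c) * c
    e2 = _unit(e2, "in-plane complement")
    # SN->xiphoid direction d must satisfy angle(-d, c) = theta_u,
    # i.e. d.c = -cos(theta_u); two in-plane solutions +/- e2
    phi = math.radians(180.0 - theta_u)
    d = math.cos(phi) * c + math.sin(phi) * e2  # e2 side is closer to d0
    if not math.isfinite(d @ c):  # pragma: no cover - guarded upstream
        raise CorrectionInfeasibleError("no in-plane solution")
    synthetic = sn + dist * d
    theta_cs = opening_angle(synthetic, sn, c7)
    return TorsoAxisCorrection(
        theta_u=float(theta_u),
        theta_cs=theta_cs,
        synthetic_xiphoid=synthetic,
        si_axis=-d,
    )


def build_torso_frame(
    sternal_notch, xiphoid, c7, side: str = "right"
) -> AnatomicalFrame:
    """Torso frame: origin at the sternal notch.

    +Y points from the (possibly synthetic) xiphoid to the sternal notch;
    +Z is the midline-plane normal, signed so that +X = Y x Z points
    anteriorly (positive dot with the C7-to-sternal-notch direction);
    +X completes the right-handed triad.
    """
    sn, xp, c7 = map(_point, (sternal_notch, xiphoid, c7))
    if _triangle_area(sn, xp, c7) < _MIN_TRIANGLE_AREA_MM2:
        raise DegenerateLandmarkError("torso landmarks are nearly collinear")
    y = _unit(sn - xp, "xiphoid to sternal notch")
    n = _unit(np.cross(xp - sn, c7 - sn), "torso plane normal")  # n is ±Z, ⊥ y
    x = np.cross(y, n)
    anterior_ref = sn - c7
    if float(x @ anterior_ref) < 0.0:
        n, x = -n, -x
    basis = np.column_stack([x, y, n])
    return AnatomicalFrame("torso", sn, basis)


def build_scapula_frame(
    glenosphere_center,
    inferior_angle,
    trigonum_spinae,
    side: str = "right",
    anterior_hint=None,
) -> AnatomicalFrame:
    """Scapula frame: origin at the glenosphere center.

    +Z runs from the trigonum spinae to the glenosphere center (lateral);
    +X is the scapular-plane normal pointing anteriorly; +Y = Z x X points
    superiorly.  The plane normal has two orientations; the one with
    positive dot product against ``anterior_hint`` (the torso +X axis when
    available) is chosen.  Without a hint, the sign is resolved assuming the
    inferior angle lies inferior to the glenosphere-trigonum line with the
    normal (GC - trigonum) x (IA - trigonum) pointing anteriorly, the
    configuration of a right scapula viewed from lateral.
    """
    gc, ia, ts = map(_point, (glenosphere_center, inferior_angle, trigonum_spinae))
    if _triangle_area(gc, ia, ts) < _MIN_TRIANGLE_AREA_MM2:
        raise DegenerateLandmarkError("scapula landmarks are nearly collinear")
    z = _unit(gc - ts, "trigonum to glenosphere center")
    n = np.cross(gc - ts, ia - ts)
    n = _unit(n - (n @ z) * z, "scapular plane normal")  # exactly ⊥ z
    if anterior_hint is not None:
        if float(n @ _point(anterior_hint)) < 0.0:
            n = -n
    x = n
    y = np.cross(z, x)
    basis = np.column_stack([x, y, z])
    return AnatomicalFrame("scapula", gc, basis)


def build_humerus_frame(
    glenosphere_center,
    shaft_axis,
    lesser_tuberosity,
    side: str = "right",
) -> AnatomicalFrame:
    """Humerus frame: origin at the glenosphere center.

    +Y is the (superiorly oriented) shaft axis from the cylinder fit; +X is
    the component of the glenosphere-center-to-lesser-tuberosity vector
    orthogonal to +Y (Gram-Schmidt); +Z = X x Y is lateral.
    """
    gc = _point(glenosphere_center)
    lt = _point(lesser_tuberosity)
    y = np.asarray(shaft_axis, dtype=float).reshape(3)
    if abs(np.linalg.norm(y) - 1.0) > 1e-6:
        raise ValueError("shaft_axis must be a unit vector")
    y = y / np.linalg.norm(y)
    v = lt - gc
    v = _unit(v, "glenosphere center to lesser tuberosity")
    if math.degrees(math.acos(min(1.0, abs(float(v @ y))))) < 1.0:
        raise DegenerateLandmarkError(
            "lesser tuberosity nearly parallel to the shaft axis"
        )
    x = _unit(v - (v @ y) * y, "anterior axis")
    z = np.cross(x, y)
    basis = np.column_stack([x, y, z])
    return AnatomicalFrame("humerus", gc, basis)


def frame_axis_sensitivity(
    builder: Callable[..., AnatomicalFrame],
    landmarks: dict[str, np.ndarray],
    perturbation_mm: float,
    n_samples: int = 200,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> dict[str, float]:
    """Worst-case axis deviation (degrees) under bounded landmark noise.

    Each landmark is independently perturbed by a uniformly random vector of
    length <= ``perturbation_mm`` (emulating marker-placement error) and the
    frame rebuilt; returns the maximum observed angular change of each axis
    over ``n_samples`` draws.
    """
    rng = np.random.default_rng(rng)
    base = builder(**landmarks, **kwargs)
    worst = {"x": 0.0, "y": 0.0, "z": 0.0}
    names = list(landmarks)
    for _ in range(n_samples):
        pert = {}
        for name in names:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            pert[name] = landmarks[name] + u * rng.uniform(0.0, perturbation_mm)
        f = builder(**pert, **kwargs)
        for ax in worst:
            d = float(np.clip(getattr(base, ax) @ getattr(f, ax), -1.0, 1.0))
            worst[ax] = max(worst[ax], math.degrees(math.acos(d)))
    return worst
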