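"""End-to-end per-patient analysis: landmarks -> frames -> joint angles.

The supine torso frame is built through the synthetic-xiphoid correction
(using the upright opening angle theta_u) whenever the supine landmark set
carries a truncated ``distal_sternum`` instead of a ``xiphoid``.  The
humeral shaft axis comes from the cylinder fit, oriented superiorly by
pointing from the shaft-cloud centroid toward the glenosphere center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import (
    GlenohumeralAngles,
    PosePair,
    ScapulothoracicAngles,
    glenohumeral_angles,
    scapulothoracic_angles,
)
from .frames import (
    SCAPULA_LANDMARKS,
    AnatomicalFrame,
    LandmarkSet,
    build_humerus_frame,
    build_scapula_frame,
    build_torso_frame,
    corrected_supine_axis,
    opening_angle,
)
from .shaft import CylinderFit, ShaftPointCloud, fit_cylinder

__all__ = ["PoseResult", "analyze_pose", "analyze_patient", "upright_opening_angle"]


@dataclass(frozen=True)
class PoseResult:
    """Frames, shaft fit and joint angles for one patient pose."""

    pose_label: str
    torso: AnatomicalFrame
    scapula: AnatomicalFrame
    humerus: AnatomicalFrame
    shaft_fit: CylinderFit
    st: ScapulothoracicAngles
    gh: GlenohumeralAngles
    theta_u: float | None = None
    theta_cs: float | None = None


def upright_opening_angle(upright: LandmarkSet) -> float:
    """theta_u from the upright xiphoid, sternal notch and C7 landmarks."""
    upright.require(("xiphoid", "sternal_notch", "c7_spinous"), "torso (upright)")
    return opening_angle(
        upright["xiphoid"], upright["sternal_notch"], upright["c7_spinous"]
    )


def analyze_pose(
    landmarks: LandmarkSet,
    shaft_cloud: ShaftPointCloud,
    theta_u: float | None = None,
    mirror_plane: str = "xz",
) -> PoseResult:
    """Build the three anatomical frames for one pose and decompose angles.

    For a supine set without a ``xiphoid`` landmark, ``theta_u`` (the upright
    opening angle) is required and the torso frame uses the corrected
    superior-inferior axis.  Left-side landmark sets are mirrored across
    ``mirror_plane`` first, so right-side sign conventions apply throughout.
    """
    cloud_pts = shaft_cloud.points
    if landmarks.side == "left":
        landmarks = landmarks.mirrored(mirror_plane)
        axis = {"xy": 2, "xz": 1, "yz": 0}[mirror_plane]
        cloud_pts = cloud_pts.copy()
        cloud_pts[:, axis] = -cloud_pts[:, axis]
        shaft_cloud = ShaftPointCloud(cloud_pts, shaft_cloud.provenance)

    landmarks.require(("sternal_notch", "c7_spinous"), "torso")
    theta_cs = None
    if "xiphoid" in landmarks:
        xiphoid = landmarks["xiphoid"]
    else:
        landmarks.require(("distal_sternum",), "torso (corrected)")
        if theta_u is None:
            raise ValueError(
                "supine landmark set has no xiphoid: theta_u (the upright "
                "opening angle) is required for the axis correction"
            )
        corr = corrected_supine_axis(
            landmarks["sternal_notch"],
            landmarks["distal_sternum"],
            landmarks["c7_spinous"],
            theta_u,
        )
        xiphoid = corr.synthetic_xiphoid
        theta_cs = corr.theta_cs
    torso = build_torso_frame(
        landmarks["sternal_notch"], xiphoid, landmarks["c7_spinous"]
    )

    landmarks.require(SCAPULA_LANDMARKS, "scapula")
    scapula = build_scapula_frame(
        landmarks["glenosphere_center"],
        landmarks["inferior_angle"],
        landmarks["trigonum_spinae"],
        anterior_hint=torso.x,
    )

    landmarks.require(("lesser_tuberosity",), "humerus")
    gc = landmarks["glenosphere_center"]
    hint = gc - shaft_cloud.points.mean(axis=0)
    fit = fit_cylinder(shaft_cloud, superior_hint=hint)
    humerus = build_humerus_frame(gc, fit.axis_dir, landmarks["lesser_tuberosity"])

    return PoseResult(
        pose_label=landmarks.pose_label,
        torso=torso,
        scapula=scapula,
        humerus=humerus,
        shaft_fit=fit,
        st=scapulothoracic_angles(torso, scapula),
        gh=glenohumeral_angles(scapula, humerus),
        theta_u=theta_u,
        theta_cs=theta_cs,
    )


def analyze_patient(
    patient_id: str,
    supine: LandmarkSet,
    upright: LandmarkSet,
    supine_cloud: ShaftPointCloud,
    upright_cloud: ShaftPointCloud,
    theta_u: float | None = None,
    mirror_plane: str = "xz",
) -> tuple[PosePair, PoseResult, PoseResult]:
    """Analyze both poses of one patient and pair the results.

    ``theta_u`` defaults to the value computed from the upright landmarks.
    """
    if theta_u is None and "xiphoid" not in supine:
        theta_u = upright_opening_angle(
            upright.mirrored(mirror_plane) if upright.side == "left" else upright
        )
    res_sup = analyze_pose(supine, supine_cloud, theta_u, mirror_plane)
    res_up = analyze_pose(upright, upright_cloud, theta_u, mirror_plane)
    pair = PosePair(
        patient_id=patient_id,
        supine_st=res_sup.st,
        supine_gh=res_sup.gh,
        upright_st=res_up.st,
        upright_gh=res_up.gh,
    )
    return pair, res_sup, res_up
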