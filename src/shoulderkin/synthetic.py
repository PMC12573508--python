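"""Forward-kinematics synthetic cohorts with known ground-truth joint angles.

The generator inverts the analysis: given prescribed clinical joint angles
it poses canonical bone templates so that the landmark-based frame
constructions and Euler decompositions recover exactly those angles.  With
zero landmark noise the full pipeline reproduces the ground truth to
numerical precision, which is the module's central guarantee and the basis
of the end-to-end tests.

A synthetic patient carries, per pose (supine and upright):

* torso landmarks — the supine set has a *truncated distal sternum* instead
  of the xiphoid, deliberately rotated in the midline plane by a
  configurable angle so the synthetic-xiphoid correction is exercised
  non-trivially;
* scapula and humerus landmarks posed by the intrinsic Euler rotations that
  encode the ground-truth angles;
* a cortical-surface shaft point cloud (cylinder of configurable radius,
  length, and circumferential arc) for the cylinder fit;
* the true upright opening angle theta_u.

Cohort-level defaults mirror the study conditions this package targets:
7 patients per cohort, per-DOF upright-minus-supine offsets of
patient-specific sign and magnitude (mean -9.3 deg, SD 12.9 deg scapular
upward rotation; +13.2 +/- 17.6 deg humeral elevation; -15.4 +/- 26.6 deg
internal rotation), landmark noise at the few-mm optical-marker scale, and
~50 mm shaft clouds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import LandmarkSet, build_torso_frame
from .rotations import EulerSequence, compose_euler
from .shaft import ShaftPointCloud

__all__ = [
    "DOF_NAMES",
    "SyntheticCohortSpec",
    "SyntheticPatient",
    "generate_patient",
    "generate_cohort",
    "cohort_truth_table",
]

DOF_NAMES = (
    "upward_rotation",
    "protraction",
    "posterior_tilt",
    "elevation",
    "anterior_plane",
    "internal_rotation",
)

# Canonical templates (mm).  Torso landmarks live in the midline (z = 0)
# plane of a local frame with x anterior, y superior; scapula and humerus
# landmarks are expressed in their own anatomical frames so that the frame
# builders return exactly the posed frame.
_TORSO_TEMPLATE = {
    "sternal_notch": np.array([0.0, 0.0, 0.0]),
    "xiphoid": np.array([15.0, -120.0, 0.0]),
    "c7_spinous": np.array([-60.0, 25.0, 0.0]),
}
_SCAPULA_TEMPLATE = {
    "glenosphere_center": np.array([0.0, 0.0, 0.0]),
    "trigonum_spinae": np.array([0.0, 0.0, -110.0]),
    "inferior_angle": np.array([0.0, -120.0, -60.0]),
}
_LESSER_TUBEROSITY = np.array([25.0, -40.0, 0.0])
#: glenosphere center expressed in torso-frame coordinates
_SCAPULA_OFFSET = np.array([-40.0, -20.0, 170.0])
#: distal truncated-sternum landmark distance from the sternal notch
_STERNUM_TRUNC_DIST = 80.0

_GIMBAL_GUARD_DEG = 85.0

# Study-condition defaults: supine resting posture means/SDs and
# upright-minus-supine offsets per DOF (degrees).
_DEFAULT_SUPINE_MEANS = {
    "upward_rotation": 10.0,
    "protraction": 30.0,
    "posterior_tilt": -10.0,
    "elevation": 35.0,
    "anterior_plane": 20.0,
    "internal_rotation": 25.0,
}
_DEFAULT_SUPINE_SDS = {d: 6.0 for d in DOF_NAMES}
_DEFAULT_DELTA_MEANS = {
    "upward_rotation": -9.3,
    "protraction": -2.0,
    "posterior_tilt": 4.0,
    "elevation": 13.2,
    "anterior_plane": 5.0,
    "internal_rotation": -15.4,
}
_DEFAULT_DELTA_SDS = {
    "upward_rotation": 12.9,
    "protraction": 11.0,
    "posterior_tilt": 9.0,
    "elevation": 17.6,
    "anterior_plane": 8.0,
    "internal_rotation": 26.6,
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic supine/upright cohort."""

    n_patients: int = 7
    seed: int = 0
    supine_means: dict = field(default_factory=lambda: dict(_DEFAULT_SUPINE_MEANS))
    supine_sds: dict = field(default_factory=lambda: dict(_DEFAULT_SUPINE_SDS))
    delta_means: dict = field(default_factory=lambda: dict(_DEFAULT_DELTA_MEANS))
    delta_sds: dict = field(default_factory=lambda: dict(_DEFAULT_DELTA_SDS))
    landmark_noise_sd: float = 0.0  # mm, isotropic per landmark
    shaft_radius: float = 12.0  # mm
    shaft_length: float = 50.0  # mm
    shaft_arc: float = 360.0  # degrees of circumferential coverage
    shaft_noise_sd: float = 0.0  # mm
    shaft_points: int = 400
    sternum_truncation_angle: float = 8.0  # deg, in-plane offset of distal sternum
    side: str = "right"

    def validate(self) -> None:
        problems = []
        if self.n_patients < 1:
            problems.append("n_patients must be >= 1")
        for label, d in (
            ("supine_sds", self.supine_sds),
            ("delta_sds", self.delta_sds),
        ):
            if any(v < 0 for v in d.values()):
                problems.append(f"{label} must be non-negative")
        for label, d in (
            ("supine_means", self.supine_means),
            ("supine_sds", self.supine_sds),
            ("delta_means", self.delta_means),
            ("delta_sds", self.delta_sds),
        ):
            missing = set(DOF_NAMES) - set(d)
            if missing:
                problems.append(f"{label} missing DOFs {sorted(missing)}")
        if self.landmark_noise_sd < 0 or self.shaft_noise_sd < 0:
            problems.append("noise SDs must be non-negative")
        if self.shaft_length <= 0:
            problems.append("shaft_length must be positive")
        if not 10.0 <= self.shaft_arc <= 360.0:
            problems.append("shaft_arc must lie in [10, 360] degrees")
        if self.side not in ("right", "left"):
            problems.append("side must be 'right' or 'left'")
        if problems:
            raise ValueError("invalid cohort spec: " + "; ".join(problems))


@dataclass(frozen=True)
class SyntheticPatient:
    """Landmarks, shaft clouds and ground-truth angles for one patient."""

    patient_id: str
    ground_truth: dict  # {"supine": {dof: deg}, "upright": {dof: deg}}
    landmarks: dict  # {"supine": LandmarkSet, "upright": LandmarkSet}
    shaft_clouds: dict  # {"supine": ShaftPointCloud, "upright": ShaftPointCloud}
    theta_u: float

    @property
    def true_delta(self) -> dict[str, float]:
        return {
            d: self.ground_truth["upright"][d] - self.ground_truth["supine"][d]
            for d in DOF_NAMES
        }


def _raw_st(truth: dict) -> tuple[float, float, float]:
    # clinical -> raw right-hand-rule YXZ triple
    return truth["protraction"], -truth["upward_rotation"], truth["posterior_tilt"]


def _raw_gh(truth: dict) -> tuple[float, float, float]:
    return -truth["elevation"], truth["anterior_plane"], truth["internal_rotation"]


def _check_truth(truth: dict) -> None:
    for pose, angs in truth.items():
        missing = set(DOF_NAMES) - set(angs)
        if missing:
            raise ValueError(f"{pose} truth missing DOFs {sorted(missing)}")
        for mid in ("upward_rotation", "anterior_plane"):
            if abs(angs[mid]) > _GIMBAL_GUARD_DEG:
                raise ValueError(
                    f"{pose} {mid} = {angs[mid]:.1f} deg is within the gimbal "
                    f"guard (|angle| must be <= {_GIMBAL_GUARD_DEG} deg)"
                )


def _random_rigid(rng: np.random.Generator, base: np.ndarray, spread_deg: float):
    angles = rng.uniform(-spread_deg, spread_deg, size=3)
    r = (
        compose_euler(EulerSequence.YXZ, angles[0], angles[1], angles[2]) @ base
    )
    t = rng.uniform(-100.0, 100.0, size=3)
    return r, t


def _cylinder_points(spec: SyntheticCohortSpec, rng: np.random.Generator):
    """Shaft-surface samples in humerus-frame coordinates (distal of the GC)."""
    n = spec.shaft_points
    half_arc = np.radians(spec.shaft_arc) / 2.0
    ang = rng.uniform(-half_arc, half_arc, size=n)
    y = rng.uniform(-70.0 - spec.shaft_length, -70.0, size=n)
    pts = np.column_stack(
        [spec.shaft_radius * np.cos(ang), y, spec.shaft_radius * np.sin(ang)]
    )
    if spec.shaft_noise_sd > 0:
        pts = pts + rng.normal(scale=spec.shaft_noise_sd, size=pts.shape)
    return pts


def generate_patient(
    spec: SyntheticCohortSpec,
    truth: dict,
    rng: np.random.Generator,
    patient_id: str = "P01",
) -> SyntheticPatient:
    """Pose the bone templates so the pipeline recovers ``truth`` exactly.

    ``truth`` maps each pose ("supine", "upright") to clinical angles for
    all six DOFs.  Randomness (whole-body placement, shaft sampling,
    landmark noise) is drawn from ``rng`` in a fixed order: supine placement,
    supine shaft cloud, upright placement, upright shaft cloud, then
    landmark noise pose by pose.
    """
    spec.validate()
    _check_truth(truth)

    # upright opening angle from the torso template (pose-invariant)
    tt = _TORSO_TEMPLATE
    v1 = tt["sternal_notch"] - tt["xiphoid"]
    v2 = tt["c7_spinous"] - tt["sternal_notch"]
    theta_u = float(
        np.degrees(
            np.arctan2(np.linalg.norm(np.cross(v1, v2)), float(v1 @ v2))
        )
    )

    poses = {}
    clouds = {}
    base_supine = compose_euler(EulerSequence.YXZ, 0.0, -90.0, 0.0)  # lying
    for pose, base in (("supine", base_supine), ("upright", np.eye(3))):
        r_body, t_body = _random_rigid(rng, base, spread_deg=10.0)
        world = {
            name: r_body @ p + t_body for name, p in _TORSO_TEMPLATE.items()
        }
        torso = build_torso_frame(
            world["sternal_notch"], world["xiphoid"], world["c7_spinous"]
        )
        if pose == "supine":
            # replace the xiphoid with a truncated distal-sternum landmark,
            # rotated in the midline plane so the correction does real work
            xi_dir = world["xiphoid"] - world["sternal_notch"]
            xi_dir /= np.linalg.norm(xi_dir)
            normal = np.cross(
                world["xiphoid"] - world["sternal_notch"],
                world["c7_spinous"] - world["sternal_notch"],
            )
            normal /= np.linalg.norm(normal)
            ang = np.radians(spec.sternum_truncation_angle)
            ds_dir = (
                np.cos(ang) * xi_dir
                + np.sin(ang) * np.cross(normal, xi_dir)
            )
            world["distal_sternum"] = (
                world["sternal_notch"] + _STERNUM_TRUNC_DIST * ds_dir
            )
            del world["xiphoid"]

        st_raw = compose_euler(EulerSequence.YXZ, *_raw_st(truth[pose]))
        b_scap = torso.basis @ st_raw
        o_scap = torso.origin + torso.basis @ _SCAPULA_OFFSET
        for name, p in _SCAPULA_TEMPLATE.items():
            world[name] = o_scap + b_scap @ p

        gh_raw = compose_euler(EulerSequence.XZY, *_raw_gh(truth[pose]))
        b_hum = b_scap @ gh_raw
        world["lesser_tuberosity"] = o_scap + b_hum @ _LESSER_TUBEROSITY
        cyl_local = _cylinder_points(spec, rng)
        clouds[pose] = ShaftPointCloud(
            (o_scap + cyl_local @ b_hum.T),
            provenance=f"synthetic shaft, pose={pose}",
        )
        poses[pose] = world

    for pose in ("supine", "upright"):
        world = poses[pose]
        if spec.landmark_noise_sd > 0:
            for name in sorted(world):
                world[name] = world[name] + rng.normal(
                    scale=spec.landmark_noise_sd, size=3
                )
        poses[pose] = LandmarkSet(pose, spec.side, world, patient_id)

    return SyntheticPatient(
        patient_id=patient_id,
        ground_truth={p: dict(truth[p]) for p in truth},
        landmarks=poses,
        shaft_clouds=clouds,
        theta_u=theta_u,
    )


def generate_cohort(spec: SyntheticCohortSpec) -> list[SyntheticPatient]:
    """Generate a reproducible cohort; per-patient truth ~ Normal(spec means, SDs).

    Draws are clipped into the gimbal guard so the forward model is always
    well posed.  Given the same spec (including seed) the cohort is
    bit-identical.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    patients = []
    for i in range(spec.n_patients):
        truth = {"supine": {}, "upright": {}}
        for dof in DOF_NAMES:
            supine = rng.normal(spec.supine_means[dof], spec.supine_sds[dof])
            delta = rng.normal(spec.delta_means[dof], spec.delta_sds[dof])
            upright = supine + delta
            if dof in ("upward_rotation", "anterior_plane"):
                g = _GIMBAL_GUARD_DEG
                supine = float(np.clip(supine, -g, g))
                upright = float(np.clip(upright, -g, g))
            truth["supine"][dof] = float(supine)
            truth["upright"][dof] = float(upright)
        patients.append(
            generate_patient(spec, truth, rng, patient_id=f"P{i + 1:02d}")
        )
    return patients


def cohort_truth_table(patients: list[SyntheticPatient]):
    """Long-format ground-truth table (patient_id, pose, dof, angle_deg)."""
    import pandas as pd

    rows = []
    for p in patients:
        for pose in ("supine", "upright"):
            for dof in DOF_NAMES:
                rows.append(
                    {
                        "patient_id": p.patient_id,
                        "pose": pose,
                        "dof": dof,
                        "angle_deg": p.ground_truth[pose][dof],
                    }
                )
    return pd.DataFrame(rows)
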