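"""Readers and writers for landmark sets, shaft clouds, and result tables.

Formats (all plain text; full column documentation in docs/FORMATS.md):

* Landmark JSON — one patient/pose per file::

      {"patient_id": "P01", "pose": "supine", "side": "right",
       "landmarks": {"sternal_notch": [x, y, z], ...}}   # mm

* Landmark CSV — long format, any number of patients/poses:
  ``patient_id,pose,side,landmark,x_mm,y_mm,z_mm``.
* Shaft cloud — CSV with ``x_mm,y_mm,z_mm`` columns, or ASCII PLY
  (vertex positions only, read via trimesh).
* Tidy angle CSV — ``patient_id,joint,dof,pose,angle_deg,gimbal_flag``.
* ICC ratings CSV — rows = targets, columns = raters, numeric cells.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .angles import GH_DOFS, ST_DOFS, PosePair
from .frames import LANDMARK_NAMES, LandmarkSet
from .shaft import CylinderFit, ShaftPointCloud

__all__ = [
    "read_landmarks_json",
    "write_landmarks_json",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_shaft_cloud",
    "write_shaft_cloud_csv",
    "cylinder_fit_report",
    "pose_pairs_to_tidy",
    "tidy_to_pose_pairs",
    "read_icc_ratings",
]

_LM_COLUMNS = ["patient_id", "pose", "side", "landmark", "x_mm", "y_mm", "z_mm"]


def read_landmarks_json(path) -> LandmarkSet:
    data = json.loads(Path(path).read_text())
    try:
        points = {k: np.asarray(v, dtype=float) for k, v in data["landmarks"].items()}
        return LandmarkSet(
            pose_label=data["pose"],
            side=data["side"],
            points=points,
            patient_id=str(data.get("patient_id", "")),
        )
    except KeyError as e:
        raise ValueError(f"{path}: missing required key {e}") from None


def write_landmarks_json(lms: LandmarkSet, path) -> None:
    data = {
        "patient_id": lms.patient_id,
        "pose": lms.pose_label,
        "side": lms.side,
        "landmarks": {k: list(map(float, v)) for k, v in lms.points.items()},
    }
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


def read_landmarks_csv(path) -> list[LandmarkSet]:
    """Read the long-format landmark CSV; one LandmarkSet per (patient, pose)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_LM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    unknown = set(df["landmark"]) - set(LANDMARK_NAMES)
    if unknown:
        raise ValueError(
            f"{path}: unknown landmark(s) {sorted(unknown)}; "
            f"allowed: {', '.join(LANDMARK_NAMES)}"
        )
    out = []
    for (pid, pose, side), grp in df.groupby(
        ["patient_id", "pose", "side"], sort=True
    ):
        points = {
            row.landmark: np.array([row.x_mm, row.y_mm, row.z_mm])
            for row in grp.itertuples()
        }
        out.append(LandmarkSet(pose, side, points, str(pid)))
    return out


def write_landmarks_csv(sets: list[LandmarkSet], path) -> None:
    rows = [
        {
            "patient_id": s.patient_id,
            "pose": s.pose_label,
            "side": s.side,
            "landmark": name,
            "x_mm": p[0],
            "y_mm": p[1],
            "z_mm": p[2],
        }
        for s in sets
        for name, p in sorted(s.points.items())
    ]
    pd.DataFrame(rows, columns=_LM_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_shaft_cloud(path, provenance: str = "") -> ShaftPointCloud:
    """Read a shaft point cloud from CSV (x_mm,y_mm,z_mm) or PLY vertices."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        import trimesh

        geom = trimesh.load(str(path), process=False)
        pts = np.asarray(geom.vertices, dtype=float)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        missing = {"x_mm", "y_mm", "z_mm"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    return ShaftPointCloud(pts, provenance or str(path))


def write_shaft_cloud_csv(cloud: ShaftPointCloud, path) -> None:
    pd.DataFrame(cloud.points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def cylinder_fit_report(fit: CylinderFit) -> dict:
    """JSON-serializable summary of a cylinder fit."""
    return {
        "axis_point_mm": list(map(float, fit.axis_point)),
        "axis_dir": list(map(float, fit.axis_dir)),
        "radius_mm": fit.radius,
        "rms_residual_mm": fit.rms_residual,
        "iterations": fit.iterations,
        "converged": fit.converged,
    }


def pose_pairs_to_tidy(pairs: list[PosePair]) -> pd.DataFrame:
    """Tidy per-patient angle table (patient_id, joint, dof, pose, angle_deg)."""
    rows = []
    for p in pairs:
        for pose in ("supine", "upright"):
            for joint, dofs in (
                ("scapulothoracic", ST_DOFS),
                ("glenohumeral", GH_DOFS),
            ):
                a = p.angles(pose, joint)
                for dof in dofs:
                    rows.append(
                        {
                            "patient_id": p.patient_id,
                            "joint": joint,
                            "dof": dof,
                            "pose": pose,
                            "angle_deg": getattr(a, dof),
                            "gimbal_flag": a.gimbal_flag,
                        }
                    )
    return pd.DataFrame(rows)


def tidy_to_pose_pairs(df: pd.DataFrame) -> list[PosePair]:
    """Rebuild PosePairs from the tidy angle table."""
    from .angles import GlenohumeralAngles, ScapulothoracicAngles

    pairs = []
    for pid, grp in df.groupby("patient_id", sort=True):
        parts = {}
        for (pose, joint), sub in grp.groupby(["pose", "joint"]):
            vals = dict(zip(sub["dof"], sub["angle_deg"]))
            flag = bool(sub["gimbal_flag"].any())
            cls = (
                ScapulothoracicAngles
                if joint == "scapulothoracic"
                else GlenohumeralAngles
            )
            parts[(pose, joint)] = cls(**vals, gimbal_flag=flag)
        try:
            pairs.append(
                PosePair(
                    patient_id=str(pid),
                    supine_st=parts[("supine", "scapulothoracic")],
                    supine_gh=parts[("supine", "glenohumeral")],
                    upright_st=parts[("upright", "scapulothoracic")],
                    upright_gh=parts[("upright", "glenohumeral")],
                )
            )
        except KeyError as e:
            raise ValueError(f"patient {pid}: missing angle block {e}") from None
    return pairs


def read_icc_ratings(path) -> np.ndarray:
    """ICC ratings CSV: first column = target id, remaining columns = raters."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need a target column plus >= 2 rater columns")
    return df.iloc[:, 1:].to_numpy(dtype=float)
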