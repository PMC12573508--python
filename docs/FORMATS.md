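# File formats

All files are plain text. Coordinates are millimetres; angles are degrees.

## Landmark JSON (one patient/pose per file)

```json
{
 "patient_id": "P01",
 "pose": "supine",
 "side": "right",
 "landmarks": {
  "sternal_notch": [0.0, 0.0, 0.0],
  "distal_sternum": [10.0, -80.0, 0.0],
  "c7_spinous": [-60.0, 20.0, 0.0]
 }
}
```

`pose` ∈ {supine, upright}; `side` ∈ {right, left}. Landmark names must be
from: `sternal_notch`, `distal_sternum`, `xiphoid`, `c7_spinous`,
`glenosphere_center`, `inferior_angle`, `trigonum_spinae`,
`lesser_tuberosity`. A supine set normally has `distal_sternum` (truncated
sternum) and no `xiphoid`; an upright set has `xiphoid`.

## Landmark CSV (long format, many patients/poses)

Columns: `patient_id,pose,side,landmark,x_mm,y_mm,z_mm`. Floats are
written with 17 significant digits so read/write round-trips exactly.

## Shaft point cloud

* CSV with columns `x_mm,y_mm,z_mm` (one cortical-surface point per row), or
* ASCII PLY, vertex positions only.

The `angles` subcommand looks for `shaft_<patient_id>_<pose>.csv` in
`--shaft-dir`. Cylinder-fit reports are JSON with keys `axis_point_mm`,
`axis_dir`, `radius_mm`, `rms_residual_mm`, `iterations`, `converged`.

## Tidy angle CSV (`angles` output / `cohort` input)

Columns: `patient_id,joint,dof,pose,angle_deg,gimbal_flag` with
`joint` ∈ {scapulothoracic, glenohumeral};
`dof` ∈ {upward_rotation, protraction, posterior_tilt} or
{elevation, anterior_plane, internal_rotation}.

## Cohort summary CSV (`cohort` output)

One row per joint/DOF: `joint,dof,n,supine_mean,supine_sd,upright_mean,
upright_sd,delta_mean,delta_sd,delta_min,delta_max,t_stat,df,p_value,
significance`. Deltas are upright − supine. `significance` is `*` for
p ≤ .05, `^` for p ≤ .10, empty otherwise.

## ICC ratings CSV (`icc` input)

First column: target identifier (e.g. torso id). Remaining columns: one
per rater/session, numeric ratings, no missing cells.

## Ground-truth CSV (`simulate` output)

Columns: `patient_id,pose,dof,angle_deg` — the generating clinical angles.

## Provenance headers

CSV outputs of the CLI begin with a single comment line
`# shoulderkin <version> config_sha=<12-hex> <config JSON>`; readers skip
lines starting with `#`.
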