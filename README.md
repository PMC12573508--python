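# shoulderkin

Supine-vs-upright shoulder joint-angle analysis for reverse total shoulder
arthroplasty (rTSA) planning research.

Preoperative planning for rTSA is based on supine CT, but patients live —
and move — upright. The scapula and humerus sit differently in the two
poses, so glenohumeral relationships measured on the planning CT can differ
by more than typical implant-parameter increments from the upright reality.
`shoulderkin` implements the full measurement chain needed to quantify that
difference from named bony landmarks, together with a forward-kinematics
synthetic-cohort generator with known ground truth so every stage is
testable end to end.

## What it computes

**Anatomical frames.** Right-handed orthonormal frames (+X anterior, +Y
superior, +Z lateral) built from landmarks:

* *Torso* — origin at the sternal notch; +Y from the xiphoid to the
  sternal notch; +Z normal to the {sternal notch, xiphoid, C7} midline
  plane. Because supine CT usually truncates the distal sternum, the supine
  +Y axis is first corrected with a **synthetic xiphoid**: a point placed
  in the midline plane so that the supine opening angle θ_cs between the
  superior–inferior axis and the sternal-notch→C7 vector equals the angle
  θ_u measured upright (θ_cs = θ_u exactly, by construction).
* *Scapula* — origin at the glenosphere center; +Z from trigonum spinae to
  glenosphere center; +X the scapular-plane normal (anterior); +Y = Z × X.
* *Humerus* — origin at the glenosphere center; +Y the shaft axis from a
  least-squares **cylinder fit** to ~50 mm of cortical-surface points;
  +X toward the lesser tuberosity (orthogonalized); +Z = X × Y.

**Joint angles.** Intrinsic Euler decompositions with clinical signs:
scapulothoracic rotation R = Rᵧ(protraction)·Rₓ′(−upward rotation)·R_z″(posterior tilt)
(ISB Y-X′-Z″), and glenohumeral R = Rₓ(−elevation)·R_z′(plane)·Rᵧ″(internal rotation)
(X-Z′-Y″, which stays well-conditioned at low elevation). Upward rotation
and elevation reverse the right-hand rule so that "+" reads as *up*.

**Cohort statistics.** Per-DOF upright-minus-supine deltas, two-sided
paired t-tests (t = d̄/(s_d/√n), significance p ≤ .05, marginal p ≤ .10),
per-patient delta ranges, and single-measure absolute-agreement ICC(A,1)
from the two-way ANOVA mean squares for landmarking reliability.

## Worked example

```python
from shoulderkin import (SyntheticCohortSpec, generate_cohort,
                         analyze_patient, summarize_cohort)

spec = SyntheticCohortSpec(n_patients=7, seed=11, landmark_noise_sd=1.0)
pairs = []
for p in generate_cohort(spec):
    pair, supine, upright = analyze_patient(
        p.patient_id,
        p.landmarks["supine"], p.landmarks["upright"],
        p.shaft_clouds["supine"], p.shaft_clouds["upright"],
    )
    pairs.append(pair)

table = summarize_cohort(pairs)
cols = ["joint", "dof", "delta_mean", "delta_sd", "delta_min", "delta_max",
        "p_value", "significance"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:7.2f}"))
```

prints

```
          joint               dof  delta_mean  delta_sd  delta_min  delta_max  p_value significance
scapulothoracic   upward_rotation       -3.44      8.81     -16.18       5.28     0.34
scapulothoracic       protraction       -4.38     13.38     -24.32      18.64     0.42
scapulothoracic    posterior_tilt        6.81      5.92      -0.85      13.80     0.02            *
   glenohumeral         elevation        4.29     10.02     -10.83      20.06     0.30
   glenohumeral    anterior_plane       -2.04      9.32     -12.15      10.44     0.58
   glenohumeral internal_rotation      -16.02     10.01     -30.44      -1.79     0.01            *
```

Each row is one rotational degree of freedom: `delta_mean ± delta_sd` is
the cohort upright-minus-supine change in degrees recovered by the full
landmark pipeline (here under 1 mm landmark noise), `delta_min/max` the
per-patient extremes, and `*`/`^` mark p ≤ .05 / p ≤ .10 on the paired
t-test. With seven patients and patient-specific offsets of either sign,
individual DOFs reach significance only when the programmed offset is
large relative to its spread — exactly the behaviour such small paired
cohorts show.

The same workflow is available from the shell:

```bash
shoulderkin simulate --out-dir data --n-patients 7 --seed 11 --landmark-noise-sd 1
shoulderkin angles --landmarks data/landmarks.csv --shaft-dir data --out angles.csv
shoulderkin cohort --angles angles.csv --out summary.csv
shoulderkin icc --ratings ratings.csv --model two_way_mixed
```

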