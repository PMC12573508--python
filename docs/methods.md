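# Methods

This note documents the models, conventions, numerical choices, and known
limitations of `shoulderkin`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate frames and landmarks

All frames are right-handed orthonormal bases stored column-wise with +X
anterior, +Y superior, +Z lateral (toward the affected shoulder), origins
in mm. Landmarks come from a fixed vocabulary: sternal notch, distal
sternum, xiphoid, C7 spinous process (torso); glenosphere center, inferior
angle, trigonum spinae (scapula); lesser tuberosity plus a shaft
point cloud (humerus). The glenosphere center — a postoperative implant
landmark — is the shared origin of the scapula and humerus frames, which
sidesteps fitting a sphere to the pathologic humeral head.

**Torso.** +Y = unit(xiphoid → sternal notch); ±Z is the normal of the
{sternal notch, xiphoid, C7} plane; the sign is fixed by requiring
+X = Y × Z to have positive dot product with the C7 → sternal-notch
direction, which always points anteriorly for midline landmarks. This
sternum-based frame replaces the ISB T8/PX torso frame, whose landmarks
clinical shoulder CT does not cover.

**Synthetic-xiphoid correction.** Supine CT often truncates the sternum,
so the supine set carries a `distal_sternum` point instead of the xiphoid.
Given the upright opening angle θ_u (angle between xiphoid→SN and SN→C7,
computed with atan2 for stability near 0°/180°), the corrected supine axis
is built by placing a synthetic xiphoid in the plane of {SN, distal
sternum, C7} such that the supine opening angle equals θ_u. Two in-plane
directions satisfy the angle constraint; the one angularly closer to the
original truncated-sternum direction is chosen (the correction is a small
adjustment of an existing axis, so the near solution is the intended one).
The synthetic point is placed at the distal sternum's distance from the
sternal notch — distance does not enter any angle; reusing the measured
distance just keeps the point anatomically plausible. By construction
θ_cs = θ_u to floating-point precision; the pipeline verifies this on
every run. The correction is idempotent: feeding its own output back
reproduces the same axis.

**Scapula.** +Z = unit(trigonum → glenosphere center); +X is the
scapular-plane normal made exactly orthogonal to +Z, with sign resolved
against the torso's anterior axis when available (the pipeline passes it
automatically) or a user-supplied anterior hint; +Y = Z × X. The
superior axis is defined via Y = Z × X so the triad is right-handed.

**Humerus.** +Y is the cylinder-fit shaft axis oriented superiorly; +X is
the Gram–Schmidt component of glenosphere-center → lesser-tuberosity
orthogonal to +Y; +Z = X × Y (right-handed, lateral on the right side). A
lesser tuberosity within 1° of the shaft axis is rejected as degenerate.

**Sides.** Left-shoulder landmark sets are mirrored across a configurable
coordinate plane (default the x–z plane of the input system) before
construction, so one right-side sign convention serves both sides.

## Cylinder fit

The shaft axis minimizes Σᵢ (dist(pᵢ, axis) − r)² over the axis line and
radius. Parameterization: direction by spherical angles, axis point by two
offsets in the plane through the cloud centroid normal to the initial
direction (removing the gauge freedom along the axis), radius free — five
parameters, analytic Jacobian, damped Gauss–Newton (Levenberg–Marquardt)
with multiplicative damping (decrease ×0.3 on accepted steps, ×10 on
rejections). Initialization: dominant principal direction of the centered
cloud, centroid, mean orthogonal distance. Convergence: relative cost
change below 1e-12, iteration cap 200; non-convergence returns the best
iterate flagged `converged=False` with a warning rather than raising. The
accepted-cost trace is stored and is non-increasing by construction. The
reported RMS residual is recomputed independently from the returned
parameters. Superior orientation is fixed by a hint vector (default +Y of
the input system; the pipeline uses cloud-centroid → glenosphere-center,
which is robust in any pose because the cloud is distal to the joint).
Clouds need ≥ 50 points and ≥ 10 mm extent (20–120 mm typical; outside
that a warning); region selection is deliberately manual — deciding where
the shaft stops tapering is a view-dependent judgement, and automating it
would add an unvalidated step.

## Euler sequences and signs

Both sequences are intrinsic (body-fixed): scapulothoracic Y-X′-Z″,
glenohumeral X-Z′-Y″. The closed-form decompositions keep the middle angle
on [−90°, 90°]; within 0.057° (1e-3 rad) of ±90° the first and third
rotations are indistinguishable, so a3 is pinned to 0, a1 absorbs the
combined rotation, and a gimbal flag is raised. That tolerance is far
tighter than any anatomical configuration in scope. Flagged patients are
excluded from cohort statistics with a warning (angles are non-unique at
gimbal lock; silently averaging them would corrupt the summary). All
clinical sign reversals — upward rotation = −a2, elevation = −a1 — live in
one module; the rotation core is strictly right-hand-rule. The mapping of
the glenohumeral axes to angle names (elevation on X, plane of elevation
on Z′, axial rotation on Y″) follows the order in which the angles are
conventionally listed against that sequence. X-Z′-Y″ is used instead of
Y-X′-Y″ because the latter's plane-of-elevation is ill-conditioned at low
elevation; a test demonstrates the variance gap under sub-degree jitter.
Angles are degrees at every interface (radians internally) and differences
are wrapped to (−180°, 180°].

## Statistics

Paired t-test: t = d̄/(s_d/√n), d = upright − supine, df = n − 1, two-sided
p from the Student-t survival function. All-zero differences give t = 0,
p = 1 (identical samples are evidence of no difference); zero-variance
nonzero differences are flagged degenerate with p = NaN instead of
aborting batch runs. Significance p ≤ .05, marginal p ≤ .10, and no
multiple-testing correction across the six DOFs — correcting would change
which effects are declared significant and is deliberately not applied.

ICC: single-measure absolute agreement from the two-way ANOVA mean squares,
ICC(A,1) = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)). The same point
estimate serves the two-way random model (interobserver: observers a
random sample) and two-way mixed model (intraobserver: sessions fixed);
only the label and interpretation differ. Interpretation bands: < 0.5
poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.9 excellent; 0.75 is used as
the moderate/good boundary (conventions in the literature overlap between
0.7 and 0.75). Constant ratings matrices are flagged undefined (0/0).
F-based confidence intervals for ICC are out of scope.

## Synthetic cohorts

The generator inverts the pipeline: canonical bone templates (torso
landmarks in a midline plane with the xiphoid 120 mm inferior / 15 mm
anterior of the sternal notch; scapular landmarks expressed in the scapula
frame with the trigonum 110 mm medial; lesser tuberosity 25 mm anterior of
the shaft axis; glenosphere center 170 mm lateral of the sternal notch) are
posed by the exact intrinsic rotations that encode the prescribed clinical
angles, after un-mapping the two sign reversals. The supine set replaces
the xiphoid by a truncated distal-sternum landmark rotated 8° in the
midline plane (configurable), so the synthetic-xiphoid correction is
exercised non-trivially on every patient. Whole-body placement adds a
random rigid transform per pose (supine additionally lying, −90° about the
anterior axis). With zero noise the pipeline reproduces the generating
angles to < 1e-6° — the generator's central guarantee and the pipeline's
headline correctness test.

Cohort defaults are the study conditions this package targets: 7 patients;
upright-minus-supine offsets drawn per patient as Normal(mean, SD) with
means/SDs −9.3 ± 12.9° (upward rotation), +13.2 ± 17.6° (elevation),
−15.4 ± 26.6° (internal rotation); the remaining three DOFs have no
published cohort means, so defaults were fixed once inside the reported
per-patient ranges: protraction −2.0 ± 11.0°, posterior tilt +4.0 ± 9.0°,
plane of elevation +5.0 ± 8.0°. Supine baseline angles (10/30/−10/35/20/25°,
SD 6°) are plausible resting values for an rTSA cohort; they cancel out of
deltas. Landmark noise is isotropic Gaussian per landmark, independent
across landmarks and poses, matching the few-mm optical-marker accuracy
scale (≤ 3 mm); shaft clouds are 12 mm radius × 50 mm length with
configurable circumferential arc (360° default; 180° emulates single-sided
cortical sampling). Draws near gimbal lock (|middle angle| > 85°) are
refused or clipped. One seeded generator per cohort is consumed in a
documented fixed order, so cohorts are bit-reproducible.

What the generator does *not* emulate: real bone-surface geometry and
segmentation error, correlated/anisotropic marker noise, posture-type
structure, fluoroscopic tracking error, or soft-tissue artefact. Passing
tests therefore demonstrate the correctness of the measurement chain given
landmarks, not the accuracy of landmarking itself.

## Problem sizes

The test suite uses 10⁴ Euler round-trip triples per sequence, 100-instance
oracle comparisons, 50 zero-noise patients for the forward-inverse
identity, 20-replicate cylinder Monte-Carlo runs, and 200 seeded cohorts
for the sampling-distribution check. `scripts/acceptance.py` pools 30
seven-patient cohorts (210 patients) at 1 mm landmark noise for the delta
means. These sizes give stable statistics at interactive runtimes.

## Known limitations

* The acceptance surface is the synthetic forward model; reproducing a
  specific clinical cohort's numbers requires that cohort's landmark data.
* The cylinder fit assumes a circular cross-section; tapered or elliptical
  shafts bias the axis slightly (bounded by the noise Monte-Carlo tests).
* Humerothoracic angles, time-series kinematics, and scapulohumeral rhythm
  are out of scope, as are CT segmentation, landmark digitization, and
  fluoroscopy tracking.
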