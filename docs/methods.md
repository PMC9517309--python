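# Methods

## Coordinate conventions and angle definitions

Frames live in a camera-fixed right-handed system: origin at the depth
sensor, `x` lateral (subject's left), `y` up, `z` along the view direction;
coordinates in meters. Anthropometry is kept in millimeters — the unit
furniture dimensions are quoted in — and the two conventions meet only at
explicit type boundaries (e.g. thigh length entering the seat geometry).

The sagittal plane is taken as the camera's y–z plane (drop the `x`
component), which is valid for a subject facing the sensor; this is an
assumption of the default definitions, not of the geometry engine, and every
definition can be overridden per angle via a YAML/JSON config block.

Default definitions for the 12 angles (all unsigned, in [0°, 180°]):

| angle | construction | upright value |
| --- | --- | --- |
| θ1 | neck→head vs anti-gravity | 0° |
| θ2-1/2 | shoulder→elbow (sagittal) vs gravity | 0° |
| θ3-1/2 | three-point at the elbow (shoulder, elbow, wrist) | 180° |
| θ4 | neck→spine-base vs gravity | 0° |
| θ5-1/2 | knee→hip (sagittal) vs gravity | 180° |
| θ6-1/2 | three-point at the knee (hip, knee, ankle) | 180° |
| θ7-1/2 | ankle→knee (sagittal) vs forward-horizontal | 90° |

The elbow and knee use three-point flexion (rather than segment-vs-gravity)
because the young-control ranges reach full extension (≈180°), which only a
flexion angle can express. Angles are stored at full precision and rounded
only at presentation (3 decimals). Signed/anatomical conventions (ISB joint
coordinate systems, flexion-negative angles) are deliberately out of scope.

A body mirror is defined as x-negation *plus* swapping left/right joint
labels; under it the left/right angle values swap exactly (all default
definitions are invariant to reflection across the sagittal plane), which is
used as a structural test of the definition set.

## Seat-surface geometry

During the transition the knee is the pivot and the thigh the radius, giving
`θ5 = 90° − arctan(y/x)` for seat height `y` and thigh length `x`; the
inverse `y = x·tan(90° − θ5)` turns a thigh-angle comfort band into a
seat-height interval. This seated convention spans (0°, 90°], while the
kinematic θ5 measured against gravity spans ≈90–180° over a sit-to-stand.
The two conventions are kept separate; where a kinematic threshold range
must feed the seated geometry (seat-height recommendation, G3/G4/H1
ratings) it is converted by `θ_seated = θ_kinematic − 90°` (clipped to
(0°, 90°]), i.e. the thigh's elevation above the seated horizontal. Under
this conversion the published elderly right-thigh range implies a strictly
higher minimum seat height than the control range, consistent with the
finding that elderly users need higher initial seat surfaces.

Thigh length defaults to Z9 − Z7 (sitting lower-limb length minus
calf-plus-foot height); it is a parameter everywhere it is used, since no
single catalogued measure is literally "thigh length".

## Synthetic motion generator

The generator emulates the study conditions, not any particular subject:

* **Chain.** Planar (sagittal) kinematic chain — ankle→knee→hip/spine-base→
  spine→neck→head plus symmetric arms — embedded in the y–z plane with fixed
  lateral offsets for paired joints, so per-side bone vectors stay sagittal
  and the default angle definitions are exactly recoverable (forward/inverse
  consistency ≈1e-13° in tests). Segment lengths come from the subject's
  anthropometry (shank L5, thigh Z9−Z7, trunk Z2, arms L2/L3).
* **Stages.** Four keyframes (pre-rise, hip-raise, mid-rise, upright) hold
  per-angle targets and dwell durations; angles ease between keyframes with
  a monotone cosine ramp. On a planar chain the knee flexion is implied by
  the thigh and shin angles (`cos θ6 = sin(θ5 + θ7)`), so θ6 targets are
  validated against that identity (0.5° tolerance) and realized implicitly.
* **Defaults.** 1 s sampling (configurable — analyses typically use 0.25 s
  for enough frames per stage), 5 mm isotropic Gaussian coordinate noise,
  stage durations summing to 12 s (elderly) / 8 s (control), anthropometry
  drawn per subject from per-measure normal distributions (sd = 3 % of the
  mean; the control cohort 5 % taller). Keyframe targets are fixture
  parameters chosen so extracted ranges differ between cohorts in the
  published *direction* (elderly torso-bend excursion strictly inside the
  control excursion; larger elderly initial thigh angle; slower elderly
  script). The published threshold values themselves are not reproduced:
  several printed ranges sit in a different sign convention than the default
  definitions (e.g. a torso-bend of 131–179° where an upright trunk reads
  0° here), so matching their numbers is not meaningful.
* **Not emulated.** Dynamics (forces, torques, balance), occlusion and
  sensor dropout, left/right asymmetry by default (available via per-side
  keyframe offsets), EMG. Passing tests therefore validate the *pipeline*
  (geometry, clustering, thresholds, ranking, determinism) — not claims
  about real elderly kinematics.

Randomness is routed through `numpy` seed sequences: one root seed per
cohort/run, children per subject and per stage, so any subject or stage is
reproducible independently of the rest.

## Behavior analysis

* **Clustering.** k-means (k-means++ init, 10 restarts, tol 1e-6, fixed
  seed) over the 12-dimensional angle vectors; centroids are recomputed as
  exact member means. Default granularity: fine k = 9 behaviors,
  agglomerated (Ward linkage on centroids) to 4 coarse stages; 3-stage
  grouping is a parameter. Stage ids are renumbered by mean member
  timestamp so stage 1 is earliest. Result order-invariance holds on
  separable data (seeded restarts index into the data, so unstructured data
  can reach a different local optimum under row permutation).
* **Thresholds.** Per cohort and angle, the min/max over all frames of all
  subjects; bounds are tight (attained by an observed frame). Degenerate
  frames are skipped with a logged count; an all-degenerate cohort raises.
* **Importance.** Stage labels (coarse cluster membership) are the
  dependent variable. The classifier is a one-hidden-layer tanh perceptron
  (4 units), softmax output, trained by full-batch gradient descent with an
  adaptive learning rate (max 1000 epochs, tol 1e-6, fixed seed); covariates
  are z-scored with training-split statistics; the default split is 75/25.
  Importance is the mean decrease in held-out accuracy over 20 permutations
  of each angle column, clipped at 0 and normalized to sum to 1; normalized
  importance divides by the maximum (top angle = 100 %). If no column moves
  the accuracy, a flat profile is reported. Non-convergence produces a
  warning and a flagged best-effort result, not an error. Raw (pre-
  normalization) drops and their permutation standard errors are exposed for
  diagnostics; note the permutation SE measures the Monte-Carlo error of the
  estimate, so a genuinely null column shows a *small* drop rather than one
  statistically at zero.

## AHP

Weights are the principal eigenvector of the positive reciprocal judgment
matrix, by power iteration (tol 1e-12, L1 normalization); λmax is the mean
of the component-wise ratios `(Mw)_i / w_i`. CI = (λmax − n)/(n − 1),
CR = CI/RI(n) with the standard RI table for orders 3–30 (orders 1–2 are
consistent by construction: RI = CR = 0); the matrix passes when CR < 0.1.
Reciprocity is validated to 1e-9. Because the study's raw 30-expert matrix
is not published, a feature-vector path reproduces the printed percentage
weights directly (entry / sum × 100, 3 decimals); of the printed weights
only the leading one reproduces exactly from the printed vector, so tests
anchor on it. The printed maximum eigenvalue 4.067 is used (a second printed
value, 4.076, is inconsistent with the printed CI).

## Comfort model

The default element mapping carries the ten published rows. Elements with a
geometric pathway to an angle are rated against the user's threshold range:
E1 (induced neck angle = backrest inclination), E2 (trunk angle
`arccos(min(h, Z2)/Z2)` for backrest height h), G3 (seat height through the
knee-pivot relation vs the θ5-1 band), G4 (as G3 plus the seat inclination,
vs θ5-2), H1 (shin analogue, `90° − arctan(leg height/Z7)`, vs θ6-1).
Armrest spacing (F2) and seat width (G1) carry their published elbow-angle
links verbatim but are rated dimensionally — a spacing or width induces no
elbow angle geometrically — as are E3 (backrest width vs L14 as the
shoulder-width proxy), F1 (armrest height vs Z11) and G2 (seat depth vs Z3).

Rating rules (the published scale is 1–5; the scoring function is this
package's choice): an angle inside the user range scores 5, minus one point
per started 25 % of the range width outside it (floor 1; a 1° width floor
guards degenerate ranges) — moving an induced angle toward the band midpoint
never lowers the score. A dimension within ±10 % of its body reference
scores 5, minus one point per further started 10 % deviation.

## Problem sizes

Defaults throughout are desk-scale: quickstart runs use 6 subjects per
cohort at 0.25 s sampling (≈500 frames), clustering k ≤ 9, and importance
replicate studies use 240-frame tables; these sizes make every documented
property (keyframe recovery, threshold tightness, planted-angle recovery in
≥95 of 100 replicates) observable while keeping a full run in seconds.

## Known limitations

* The sagittal-projection defaults mis-handle subjects not facing the
  sensor; there is no pose normalization step.
* Unsigned angles cannot distinguish flexion from extension past vertical.
* The kinematic↔seated θ5 conversion is a modelling bridge between two
  printed conventions that are not mutually consistent; absolute recommended
  heights inherit that approximation even though the direction-of-effect is
  stable under it.
* The comfort scoring function and the dimensional tolerances are design
  choices, not fitted to preference data.
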