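# Methods

`airwaymorph` quantifies how the pharyngeal airway responds to surgical
repositioning of the jaws. It works on paired pre-/post-operative surface
models (STL, millimetres) and named anatomical landmark sets, and answers
two questions: *how far did each bony segment move* (signed six-degree-of-
freedom displacement, with the antero-posterior component as the analysed
predictor) and *how did the airway change* (per-slab cross-sectional area
and total volume), culminating in an ROC/Youden analysis that locates the
displacement threshold above which airway cross-sections expand.

## Coordinate and sign conventions

All geometry lives in a patient-aligned frame: +x patient-right (lateral),
+y anterior, +z cranial. Euler angles use the intrinsic z–y–x order
(yaw about z, then roll, then pitch), composed as
`R = Rz(yaw) · Ry(roll) · Rx(pitch)`. At gimbal lock (|roll| = 90°) yaw is
conventionally zero and the result is flagged. Antero-posterior (AP)
displacement is the y translation: advancement positive, setback negative.
STL carries no units; millimetres are assumed and stated in outputs.

## Registration

1. **Cranial base.** The four landmarks untouched by surgery
   (frontozygomatic sutures, inner posterior zygomatic arches) are fitted
   by least-squares rigid Kabsch alignment (no scaling, no reflection);
   correspondence is by label, never order.
2. **Bone segments.** Post-operative molar/canine cusp landmarks are
   re-expressed in the pre-operative frame via the cranial-base transform,
   then fitted rigidly. The reported translation is the motion of the
   landmark centroid; rotation is taken about it, so AP is insensitive to
   the rotation estimate. Because the four cusps are nearly coplanar
   (occlusal plane), pitch is poorly conditioned from landmarks alone;
   optional ICP against segment meshes refines it.
3. **Airway models.** The three posterior-wall landmarks (pharyngeal
   recesses, interarytenoid notch) seed the alignment, refined by ICP.
   When a posterior-wall face mask is supplied, ICP samples only that
   region — the posterior wall is the structure least affected by jaw
   repositioning, so anterior-wall remodelling cannot drag the alignment.

ICP is point-to-surface: surface samples of the moving mesh are matched to
exact closest points on the fixed surface (see *Numerics*), pairs beyond a
rejection distance (default 10 mm) are dropped, and the pose update
minimises the linearised distance to the local tangent planes
(point-to-plane). A point-to-point (Kabsch) update is available. RMS over
accepted pairs is non-increasing across accepted iterations by
construction: a step that would raise it is reverted and iteration stops.
Defaults: 50 iterations, 1e-6 mm RMS-change tolerance, 5000 samples, fixed
sampling seed. The cohort pipeline uses a throughput profile
(30 iterations, 1e-3 mm, 2000 samples): registration is needed to roughly
0.1 mm and the point-to-plane update reaches that in well under ten
iterations, so the high-precision tail buys nothing for cohort statistics.

## Airway morphometry

The cropped airway (superior plane pair, inferior horizontal cut; cut
faces capped so models stay watertight) is divided along its **own**
cranio-caudal extent into 25 equal-height slabs, ordered superior to
inferior and mapped to the pharyngeal subregions as 5 nasopharyngeal,
9 oropharyngeal and 11 hypopharyngeal slabs. Dividing each model's own
extent into equal fractions is the vertical normalisation: slab *i* of the
pre- and post-operative models spans the same fractional interval, so
their areas are comparable even when airway height changes after surgery.
Slab z-intervals are half-open `[z_lo, z_hi)` with the topmost slab
closed; each slab's bounding box is the minimal axis-aligned box of the
mesh portion inside its band.

**Projected area.** Per slab the measure is the orthographic silhouette
along z of the solid portion inside the band: the band is cut out of the
watertight model and capped, and the union of the xy-projections of the
resulting boundary triangles (walls + caps) is rasterised on a grid over
the slab's xy box — default pixel 0.1 mm, a pixel counting when its centre
falls inside any projected triangle. The projection axis is fixed to the
cranio-caudal axis, the standard cross-sectional airway direction.
Outcomes per case: ΔArea% = 100·(A_post − A_pre)/A_pre per slab (slabs
with zero pre-operative area are flagged invalid, never silently dropped)
and ΔVolume% from the signed divergence-theorem volumes.

## Threshold statistics

The unit of analysis is the *slice* (one slab of one patient). Its score
is the patient's segment AP displacement — a deliberate pseudo-replication
(25 slices share one score) matching how such cohorts are analysed
clinically; a patient-averaged mode exists as a sensitivity analysis.

* **Subgroup comparisons.** Slices split into MAMS vs MMA-below vs
  MMA-at-or-above a 5 mm AP cut (boundary inclusive upward). ΔArea%
  contrasts use one-way ANOVA plus a first-class Games–Howell post hoc
  test: Welch t per pair, Welch–Satterthwaite degrees of freedom, p-values
  from the studentized-range distribution with q = |t|·√2 and k groups.
  ΔVolume% uses a two-tailed Mann–Whitney test (exact when min(n) ≤ 8
  without ties, tie-corrected normal approximation otherwise). α = 0.05,
  two-tailed; no further multiplicity correction beyond Games–Howell's
  family-wise control.
* **ROC / Youden.** A slice is positive when ΔArea% reaches the cutoff
  (+30, +50, +100 %). Candidate thresholds are midpoints of consecutive
  sorted unique scores; AUC is the trapezoid over the full staircase (and
  equals the Mann–Whitney U identity U/(n₊·n₋), which is tested). The
  primary threshold maximises J = sens + spec − 1, ties resolved toward
  the smaller displacement (clinically conservative); secondary thresholds
  are other local maxima of J within a 0.05 window of the maximum,
  reported in the "(secondary) primary" convention — a dual peak signals a
  possible double threshold.
* **Combined logistic ROC.** For the +30 % cutoff (positive-to-negative
  slice ratio nearest 1) a binomial logit on both jaws' AP yields the
  multivariate score; complete separation is flagged and a lightly
  ridge-penalised fit supplies the separating score.

The packaged reference table (`data/table3_thresholds.csv`) stores the
reference threshold points per segment × cutoff × region. Its tabulated
values are authoritative where narrative summaries of the same analysis
quote slightly different mandibular +100 % cut-offs.

## Synthetic cohorts

No imaging data can ship with the package, so a generator produces
cohorts with full ground truth. What it emulates:

* **Anatomy.** A watertight elliptical tube (default length 70 mm, 96
  angular × 71 axial vertices) with a narrower oropharyngeal waist, a
  gentle anterior bow, and ~5 % per-case size jitter. Landmark bundles sit
  at plausible skull offsets, left/right symmetric up to picking jitter.
* **Surgery.** MMA (n = 29) advances both jaws; MAMS (n = 16) advances
  the maxilla and sets the mandible back. AP displacements are truncated
  normals calibrated to typical practice: medians +3.8/+4.6 mm (MMA
  maxilla/mandible), +3.9/−2.5 mm (MAMS), mandibular setback bounded at
  −5.8 mm. True segment transforms are pure AP translations plus optional
  ≤ 1° rotations about the landmark centroid, so the true AP is exact.
* **Response.** Per-slab ΔArea% is pure noise (SD σ = 15 %) below the
  displacement threshold θ = 5.5 mm and linear with slope β = 25 %/mm
  above it, applied to the effective displacement
  d_eff = w·AP_maxilla + (1−w)·AP_mandible with maxilla weights
  0.8/0.5/0.2 for naso/oro/hypopharynx (the maxilla drives the
  nasopharynx, the mandible the hypopharynx). Draws at or below −100 %
  are truncated to −95 % with a warning.
* **Post model.** The pre-operative rings are scaled radially by
  √(1 + ΔArea%/100), PCHIP-interpolated through slab-centre heights, then
  moved by a random scan pose (≤ 2 mm / 2°) that registration must undo.
  Landmarks get Gaussian picking noise (default σ = 0.3 mm). All
  randomness flows from one seed through `SeedSequence` spawning.

What the generator does **not** emulate — hence what passing tests do not
show about real data: segmentation artefacts and holes, non-rigid
posterior-wall deformation (the synthetic deformation scales the whole
cross-section, so even the posterior wall moves slightly), soft-tissue
biomechanics, breathing/tongue-posture variation, and CT intensity. Slab
silhouettes are unions over the band, so smooth within-slab variation of
the radial scale biases measured ΔArea% slightly upward relative to the
slab-centre truth; with the default response the pooled 50 %-cutoff
Youden threshold recovers θ to within a few tenths of a millimetre, and
an upward offset of up to ~θ + 50/β is inherent to thresholding at a
positive ΔArea cutoff.

## Numerics

* **Closest points.** Nearest-point-on-surface queries use vectorised
  exact point-triangle distances with a k-d tree candidate prune over
  triangle centroids (oversized triangles are subdivided in the index
  only); a candidate ball bounded by the best upper estimate plus the
  maximal triangle radius guarantees the result equals exhaustive search,
  which is tested on meshes up to 500 faces.
* **Capping.** Plane cuts are closed by centroid fans after welding
  coincident vertices; cap triangles traverse each boundary edge opposite
  to the adjacent face, preserving outward orientation. Cut loops are
  assumed star-shaped about their centroid — true for the near-convex
  pharyngeal cross-sections this package produces.
* **Rasterisation.** Triangle-by-triangle barycentric tests on the pixel
  grid with a 1e-12 edge tolerance; boundary pixels count as inside.
  Halving the pixel changes slab areas by < 0.5 % on the test fixtures.
* **Degenerate inputs.** Collinear or < 3 landmark pairs, empty crops,
  zero-extent partitions, single-class ROC labels and too-small test
  groups raise typed errors naming the offending quantity; empty slabs
  and empty subgroups are flagged and carried, not dropped.

## Problem sizes

Default analyses run on one CPU: a 45-patient cohort (90 meshes of ~14 k
faces, 0.1 mm raster) completes in a few minutes; the test suite uses
coarser rasters (0.2–0.3 mm) and smaller cohorts where the property under
test permits, and the statistical null calibrations use 2000 replicates.

## Known limitations

* Rotational and vertical displacement are recorded but not analysed; the
  threshold analysis is AP-only.
* Slice-level ROC ignores within-patient correlation (by design, to match
  the clinical analysis); no mixed-effects alternative is provided.
* The crop planes are consumed as point+normal inputs; deriving them from
  skull anatomy (basion, sphenoid sinus) is upstream of this package.
* Minimal cross-sectional area (mCSA) and centerline-based metrics are out
  of scope.
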