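# Methods

`airwaymorph` measures the pediatric upper airway — choanae to first
tracheal ring — from head/neck CT, and models its growth. This note
documents the algorithms, the tunable parameters and their defaults, what
the synthetic phantoms do and do not emulate, and the numerical choices
made where the procedure left room for interpretation.

## Coordinate convention

Every volume is reoriented on load to RAS millimeters: array axis 0 points
patient-Right, axis 1 patient-Anterior, axis 2 patient-Superior. DICOM
series (LPS) are converted during loading; NIfTI files pass through
`nibabel`'s closest-canonical reorientation. All "anterior-posterior
distance" and "width" logic assumes this convention. Oblique acquisitions
are rejected rather than silently resampled.

## Segmentation (`ct_io`)

**Kernel harmonization.** Scans reconstructed with a soft kernel are
sharpened with a per-axial-slice 5×5 unsharp enhancement
(`out = in + (in − boxmean₅(in))`); bone-kernel scans are smoothed with a
3×3 uniform low-pass. Boundaries are reflective. Standard-kernel scans pass
through unchanged.

**Threshold rule.** The segmentation threshold is image-specific: the HU
histogram (10-HU bins with centers on multiples of 10, smoothed by a 3-bin
moving average) is searched for its modal bin in an air window
([−1100, −900] HU) and a soft-tissue window ([+50, +350] HU); the threshold
is the exact arithmetic midpoint of the two peak positions. Bin centers are
aligned to multiples of 10 so that idealized populations at −1000/+100 HU
report peaks exactly there (midpoint −450 HU). Ties after smoothing resolve
to the bin with the largest raw count. The tissue window is wider than the
textbook +100…+300 HU band so low-density or noisy tissue still produces a
peak.

**Region growing.** Voxels with HU ≤ threshold (inclusive) are labeled with
26-connectivity inside an axial band [roi_inferior, roi_superior] (mm); the
component containing a user-supplied seed is the lumen. Air outside the
body is excluded by connectivity, not by masking heuristics. The axial band
is how the protocol bounds the airway: the superior plane at the choanae,
the inferior plane at the first tracheal ring (a proxy for the cricoid's
inferior border, which is unossified in young children).

## Surface extraction and fairing (`meshing`)

Marching cubes runs in two modes. On a bare binary mask the isosurface is
taken at level 0.5, which places the wall midway between lumen and tissue
voxel centers (half-voxel accuracy). When the source HU volume and
threshold are available — the pipeline's default — the isosurface is taken
at the threshold intensity on the HU field restricted to the segmented
component (plus a one-voxel halo; other air is clamped away). Because CT
partial-volume averaging makes intensity ramp approximately linearly across
the wall, linear interpolation of that ramp recovers the wall at sub-voxel
accuracy; this is precisely why a midpoint threshold is the right contour
level. Voxel layers outside the axial ROI are clamped with an intensity as
far above threshold as lumen air is below it, so the interpolated end caps
land on the clip planes without bias. The clip levels are recorded in the
mesh provenance for the centerline stage.

Fairing is implicit Laplacian diffusion with uniform (umbrella) weights:
each iteration solves `(I − λ·dt·L) x′ = x` per coordinate with a sparse LU
factorization reused across iterations. Implicit integration is
unconditionally stable, damps staircase noise strongly and low frequencies
weakly. Defaults: `lambda_dt = 0.5`, `iterations = 2`, calibrated on the
tubular phantoms below: two iterations remove marching-cubes staircase
artifacts while the fairing-induced cross-sectional area bias on a 5 mm
tube stays under 1%; ten iterations measurably erode the clipped tube ends
(the tracheal boundary section loses >10% of its area). Topology is never
changed; watertightness is required on input.

## Centerline and cross-sections (`centerline`)

The centerline is recovered in stages:

1. **Level contours.** The faired surface is sliced every `contour_spacing`
   (default 2 mm) along the superior axis; the area centroid of the
   largest contour per level is recorded. Levels within ~1.25 lumen radii
   (estimated from the median contour area) of the axial extremes are
   dropped: there the parallel planes cut end caps or clipped rims
   obliquely and their centroids are biased off-axis.
2. **Spline.** A smoothing cubic B-spline is fitted through the centroid
   sequence (chord-length parameterization; residual budget such that the
   RMS deviation is about a quarter of the slice spacing, absorbing the
   obliquity bias of parallel slicing on tilted segments).
3. **Orthogonal refinement (one pass).** The surface is re-sliced
   orthogonally to the current tangents at arc-spaced points and the
   centroids recomputed. Orthogonal recentering removes the tilt bias; the
   refined centroids carry little residual noise.
4. **End marching.** From both ends of the refined polyline the algorithm
   marches in half-spacing steps, cutting an orthogonal section at each
   step and snapping to its area centroid, so the path follows the lumen
   center around bends right to the ends. The step direction is estimated
   over a three-step baseline: on tapering tubes a tilted cutting plane
   biases the centroid toward the wider side, and a single-step direction
   update would amplify that tilt into a runaway drift. Marching terminates
   exactly at a recorded ROI clip plane, otherwise at the surface via ray
   casting (Möller–Trumbore, brute force over triangles).
5. **Final smoothing.** One light smoothing spline through all measured
   centroids (refined + marched) stabilizes tangents everywhere — boundary
   sections taken near an end cap need the plane normal within a few
   degrees of the cap normal, or the plane clips the cap — and the result
   is resampled at `resample_step` (default 1 mm).

Cross-sections are mesh∩plane contours orthogonal to each centerline
segment (the last point reuses the preceding tangent). When a plane cuts
several closed contours — e.g. piriform sinuses flanking the laryngeal
vestibule — only the contour whose area centroid is nearest the centerline
point is kept, so sinus lumina do not inflate laryngopharyngeal widths.
Area is the planar polygon area; AP distance and width are the extents of
the boundary vertices projected on the patient anterior and right axes
projected into the plane (the lateral axis is additionally orthogonalized
against the AP axis within the plane). A plane perpendicular to the
anterior axis leaves the extents undefined and flags them rather than
fabricating values. Planes that miss the surface yield empty sections,
never interpolated ones.

## Regions and variables (`anatomy`)

The 26-landmark registry (20 pharyngeal, 2 reference, 4 maxillary) is
validated by name; three landmarks are derived midpoints (MidVe, NpxMid,
MMax) recomputed from their parents on load, and the piriform-floor pair
may be unilateral. The airway is partitioned by five boundaries on the
centerline:

- **a — palatal plane:** true crossing of the centerline with the plane
  through the ANS→PNS line spanned laterally (zero lateral tilt, the
  cephalometric convention); the most superior crossing wins.
- **b — velum tip,** **c — aryepiglottic-fold midpoint** (midpoint of
  PSSuL/PSSuR), **d — glottis** (midpoint of ga/gp): arc length of the
  closest point on the centerline polyline (continuous projection onto
  segments, not nearest vertex, which would quantize region lengths to the
  resample step).
- **e — tracheal end:** the centerline end; valid because segmentation was
  clipped at the first tracheal ring.

Per region (nasopharynx a–b, oropharynx b–c, laryngopharynx c–d, subglottal
d–e): volume is the trapezoidal integral of orthogonal section areas over
arc length, length is the boundary arc difference, and one bounding section
contributes CSA/APDist/Width (the superior border for the three pharyngeal
regions; the glottis and the tracheal end for the subglottal region).
Boundary sections falling between centerline samples are recomputed at the
interpolated plane. A boundary that coincides with an end cap is evaluated
0.5 mm inside (a plane through the cap itself has no interior contour).
Pharynx totals are sums of the three supraglottal regions, so the
additivity identities hold to machine precision by construction, and the
record validator enforces them.

Additional lengths: VTLength_i is the oral polyline ABI→MMax→PNS→(palatal
centerline point) plus the centerline arc to the glottis — the oral segment
is a polyline approximation, since no lumen path is available above the
palatal plane. Velum length is the arc length of a quadratic Bézier with
control polygon PNS→VeBa→VeEnd: VeBa (the velum's supero-posterior bend)
controls the curvature, the arc length always lies between the straight
chord and the two-segment polyline, and the arc degenerates to the chord
when VeBa is the midpoint. (An interpolating quadratic through the three
points was rejected: it overshoots sharply bent configurations and can
exceed the polyline length.) Piriform sinus lengths are 3D landmark
distances, averaged with a single-side fallback.

The inter-rater reliability statistic, the average relative error
`ARE = mean(|a−b| / mean(a,b))`, is implemented symmetrically and doubles
as the phantom accuracy bar (≤5%).

## Phantoms (`phantom`)

Phantoms are tubes with elliptical, linearly tapering cross-sections
(lateral semi-axis `a`, AP semi-axis `b`) following a parametric centerline
(straight line, planar circular arc, or cubic-polynomial deflection), with
air at −1000 HU inside and soft tissue at +100 HU outside. Voxelization
assigns each voxel to its nearest point on a densely sampled centerline
(step ≤ min(voxel/4, 0.2 mm)) and applies the local elliptical profile;
boundary voxels get a partial-volume air fraction from a 4×4×4 midpoint
subgrid, after which the volume is blurred (σ = 0.3 mm) and Gaussian noise
added (20 HU, seeded). Partial-volume antialiasing matters: blurring a
center-sampled binary volume would center the half-intensity crossing on
the quantized binary edge (±¼ voxel) instead of the true wall, which alone
exceeds the error budget for 6–8 mm lumina at 0.5 mm voxels.

The default phantom is an arc of radius 30 mm spanning 60°, tapering from
5 mm to 3 mm semi-axes, oriented anatomically: tangent tilted 60°
anteriorly at the choanae end and vertical at the tracheal end. The tube
overruns both clip planes by 5 mm and the segmentation ROI truncates it
with axial planes, exactly as the protocol bounds the real airway — this
matters because a physical end cap (blur-rounded, obliquely cut by axial
slicing) corrupts the boundary sections measured there. Region boundaries
default to fractions (0.20, 0.45, 0.65, 0.85) of the arc length so the
palatal boundary sits below the wedge that the superior clip leaves on a
tilted tube, as it does anatomically. Landmarks are planted consistently
with their roles (glottis pair at ±b on the AP axis, fold midpoints at ±a
laterally with piriform floors 8 mm inferior, the palatal pair positioned
so the palatal plane passes exactly through the curve point at the planned
arc length, VeBa at the PNS–VeEnd midpoint so the velum truth is the
chord). Ground truth comes from quadrature of the analytic integrals
(∫ π a b ds for volumes, π a b and 2a/2b at boundaries).

What the phantoms do **not** emulate: mucosal surface texture, adenoid and
lymphoid tissue encroachment, bone and its reconstruction-kernel halos,
beam hardening, gantry tilt, swallowing/motion artifacts, and branching
topology (the piriform sinuses are represented only as landmarks, not as
lumina). Passing the phantom suite therefore demonstrates geometric
fidelity of the measurement chain, not robustness to every clinical
artifact.

The growth simulator draws log-scale responses from the mixed model below
with known coefficients, a shared per-subject random intercept across
repeat scans, and stores raw-scale values (`exp` of the draw). Defaults:
25% adults (the study cohort is roughly 61 pediatric to 17 adult subjects),
pediatric ages uniform on [0, 5) years (the oldest pediatric age group ends
at 4;11), equal sex ratio.

## Growth model (`growth`)

Each variable is fitted on the log scale with

    log y = β₀ + β₁·Sex + β₂·Adult + β₃·Sex·Adult
            + β₄·PediatricAge + β₅·Sex·PediatricAge + αᵢ + ε

Sex is coded male = 1 (contrasts report male−female); Adult is an indicator
with PediatricAge fixed at 0 for adults; αᵢ ~ N(0, σ²ᵤ) is a per-subject
random intercept absorbing repeat scans. Fitting uses `statsmodels`
`MixedLM` by maximum likelihood (not REML) so likelihood-ratio tests
between nested fixed-effect structures are valid; the fit is verified
against an independent `lme4` fit in the test suite (coefficients,
log-likelihood and variance components agree to numerical precision).

- **Outlier screen:** one pass; rows with |standardized conditional
  residual| > 2.576 (the 0.995 normal quantile, i.e. the two-sided 1%
  tail) are removed and the model refitted once. Conditional residuals
  (observed − fixed effects − predicted subject intercept) are used so a
  single aberrant scan of a multi-scan subject is flagged, not the whole
  subject.
- **Age effect:** LRT dropping both pediatric-age terms (β₄ = β₅ = 0),
  χ² with 2 df.
- **Sex differences:** Wald contrasts c′β with the normal reference —
  β₁ at age <1, β₁ + 5β₅ at age 5, β₁ + β₃ for adults. The normal
  reference is anti-conservative in small samples (the alternative
  Satterthwaite-df correction is what dedicated mixed-model testing
  packages default to); the calibration suite therefore checks type-I
  error and null p-value uniformity at 100-subject cohorts, where the
  asymptotic reference is accurate.
- **Percent growth at age 5:** 100·exp(η̂_ped(5) − η̂_adult) per sex, from
  fixed-effect point estimates only (no retransformation bias correction).
  The ratio is invariant under multiplicative rescaling of the raw
  variable.
- **Reporting:** significance tiers *, **, *** at 0.05/0.01/0.001 and ****
  below the Bonferroni level 0.0004; age-group summaries use whole-year
  pediatric bins <1, 1, 2, 3, 4 plus an adult group.

## Problem sizes used in validation

The phantom oracle suites run at 0.5 mm voxels on tubes of 30–50 mm length
(volumes near 10⁶ voxels); the statistical calibration uses 500 null
replicates of 100-subject, two-scan cohorts and a single 200-subject
recovery fit; resolution convergence is checked at 1.0/0.5/0.25 mm. These
sizes keep the full validation suite in the minutes range on one CPU while
leaving every acceptance margin comfortably resolved.

## Known limitations

- The airway is treated as a single tube; branching structures (nasal
  cavity, piriform lumina) are out of scope, and a plane cutting multiple
  lumina keeps only the contour nearest the centerline.
- The oral segment of VTLength_i is a three-segment polyline, not a lumen
  path; it inherits landmark placement error directly.
- Region boundary localization assumes the anchor landmarks lie close to
  the lumen; a landmark far off-axis projects onto the nearest centerline
  point without warning.
- Wald tests use the normal reference; for cohorts much smaller than ~100
  subjects the printed p-values are anti-conservative (see above).
- Oblique CT acquisitions and gantry-tilted series are rejected, not
  resampled.
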