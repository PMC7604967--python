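# Methods

This note documents the models, geometric procedures, numerical choices and
known limitations behind `sphenoscore`.

## Scope and data model

The package operates on two kinds of input:

1. **Segmentation sets** — co-registered axis-aligned boolean label volumes
   (tumor; up to six named arterial segments C4, C5, M1, M2, A1, A2;
   cavernous sinus; bone) with per-axis voxel spacing in mm. Physical
   coordinates are `index × spacing` with 0-based indices; no affine
   orientation handling beyond axis-aligned spacing is attempted, and
   inputs are expected to be resampled into one common grid beforehand.
2. **Cohort tables** — one row per patient with the four component grades,
   the total score (always cross-checked against the component sum), and
   optional Simpson resection grade (I–IV coded 1–4) and 4-level
   postoperative outcome (0 worse … 3 complete regression).

## Feature extraction

**Tumor volume** is the true-voxel count times the voxel volume, in cm³.
Grading uses `v < 20` → 1, the closed interval `20 ≤ v ≤ 50` → 2, `v > 50`
→ 3. The closed middle interval is a documented convention; the clinical
definition ("between 20 and 50") does not fix the boundaries, and both
boundary values grade 2 consistently with the strict outer inequalities.

**Vessel geometry.** Each artery mask must be a single 26-connected
component; anything else raises a "not a tube" error naming the artery.
The mask is skeletonized (`skimage.morphology.skeletonize`), the skeleton's
longest geodesic path (two-pass BFS over the 26-neighborhood graph) becomes
the centerline — short side spurs are thereby dropped — and the path is
smoothed with a 5-point moving average. Because skeletonization erodes a
tube by roughly one radius at each end, the path is extended along its end
tangents in quarter-voxel steps until it exits the mask, so the arc length
covers the whole vessel (the quarter-torus test requires 5% arc-length
accuracy). Local radius is the Euclidean distance transform of the mask
(anisotropic sampling) interpolated along the path; within 1.5 median radii
of either tip the transform measures distance to the end cap rather than
lumen caliber, so those radii are clamped to the nearest interior value.

**Angular coverage.** At every centerline point an orthonormal frame
perpendicular to the local tangent is built and 360 one-degree bins are
probed over a radial band from the local vessel surface to surface + 2 mm
(default `probe_band_mm`; the band detects abutting tumor without counting
distant tissue). Probes sample a Gaussian-smoothed (σ = 0.5 voxel) copy of
the tumor mask by trilinear interpolation at the 0.5 level, which tracks
the underlying tumor surface rather than the jagged voxel boundary. Three
numerical details matter and were chosen after explicit error analysis on
phantoms with analytically known coverage:

- *Per-ring median.* Each radial ring crossing the tumor yields an
  estimate of the angular extent. The union over rings accumulates the
  outward half-voxel jitter of every ring at each wrap edge (positive
  bias ≈ +10–20° at a 3 mm vessel), while the innermost ring sits on the
  material corner and under-reads. The per-point coverage is therefore the
  **median** over tumor-seeing rings.
- *Union for encirclement.* "Completely encircled" asks whether every bin
  is covered somewhere in the band; inner rings alone show spurious
  lattice gaps on a fully wrapped vessel, so the encirclement flag uses
  the union over rings against the `full_encirclement_deg` threshold.
- *Profile smoothing.* The per-point coverage profile is smoothed with a
  5-point moving average along the centerline before taking the maximum,
  since encasement is a cm-scale feature and the raw maximum over points
  keeps only discretization maxima. A contact so short that smoothing
  would erase it still sets a positive coverage.

The full-encirclement threshold defaults to **355°**, not a literal 360°:
the clinical judgment "completely (360°) encircling" tolerates voxelization,
and a strict 360° would flip on single-bin lattice artifacts. An artery is
*involved* iff its maximal coverage is positive — contact is required;
displacement without contact scores 0 (no displacement measure is
computed, because no pre-tumor vessel course is available).

**Narrowing** is declared when the minimum local radius falls below
`(1 − δ)` times the vessel's own **median** radius, δ = 0.20 by default.
The self-referenced median replaces a contralateral comparison, which a
single segmentation set cannot provide; δ = 0.20 is large enough to be
robust to centerline jitter and small enough to catch clinically apparent
caliber loss. At least 5 centerline points are required.

**CS involvement and bone invasion** are overlap tests: the tumor∩structure
volume must strictly exceed τ = 0.1 cm³ (both configurable). The strict
inequality makes the boundary case reproducible; voxel-adjacency without
shared voxels never counts. The thresholds encode that these are binary
radiologist reads of infiltration, not volumetrics.

**Arterial grade** = 1 point for any involvement + 1 if any artery is
fully encircled + 1 if more than one artery is involved + 1 if any
involved artery is narrowed; each feature counts once regardless of how
many arteries exhibit it. Absent artery masks are treated as "not
involved" and logged.

## Scoring and bands

Total = volume grade + arterial grade + 2·[CS] + 1·[bone] ∈ [1, 10]
(volume grade ≥ 1 puts the floor at 1). Bands: total < 4 → Simpson I,
4–7 inclusive → Simpson II, > 7 → Simpson III/IV. The closed interval
[4, 7] follows from the outer strict inequalities; III and IV are not
separated because the underlying tendency data do not separate them. Band
cutoffs are configurable for sensitivity analysis. Bands are tendencies,
not guarantees.

## Phantoms

Phantoms provide ground truth for every measured feature. Arteries are
tubes swept along polyline centerlines (dense resampling at half-voxel
steps, nearest-sample distance query via a k-d tree); narrowing is a
raised-cosine radial taper reaching the full fractional reduction at the
span centre, by default over the middle third of the arc length. Ground
truth calls a vessel narrowed iff its narrowing fraction is at least the
same δ = 0.20 the detector uses, keeping truth and detector consistent by
construction.

The `annular_wrap` tumor is an annulus in the plane perpendicular to the
local tangent, from the local vessel surface to nominal radius + 3 mm,
spanning exactly `wrap_angle_deg` — so the coverage the extractor should
report is known analytically. The sector is rotated by a fixed generic
offset (13.7°) about the centerline: axis-aligned sector edges would lie
exactly on lattice planes, where rasterization by voxel-center inclusion
is one-sidedly biased and no estimator of the intended angle is unbiased.
CS overlap is realised as an exact shared voxel count in a corner block;
bone contact shares a fixed 0.3 cm³ block with a bone slab. Tumor voxels
never overlap arterial lumina; a tumor or artery reaching the outermost
voxel layer raises a "phantom overflow" error, and overlapping artery
labels raise a "label collision" error.

The default grid is 160³ at 1 mm; the randomized phantoms used in tests
request 96³ (and 64³ for I/O round-trips) to keep suite runtime modest
while leaving ≥ 8 voxels of margin around every structure. Accuracy at
these sizes is verified directly: a 10 mm sphere voxelized at 0.5 mm
recovers its analytic volume within 2%, and wrap angles over
{45, 90, 180, 270, 360}° are recovered within ±10° (observed worst error
6° over 22 seeded phantoms).

What the phantoms do **not** emulate: MR/CT intensities, segmentation or
registration error, vessel branching, tapering anatomical calibers,
contacting-but-distinct structures with partial-volume mixing. Passing the
recovery tests therefore demonstrates the geometry pipeline is correct on
clean labels, not that it is robust to segmentation noise.

## Cohort models

`reconstruct_printed_cohort()` returns the deterministic 46-row table whose
total-score distribution {1:5, 2:6, 3:3, 4:6, 5:3, 6:3, 7:7, 8:6, 9:5,
10:2} and component marginals (volume 23/14/9; arterial 7/6/8/11/14; CS
23 yes; bone 10 yes) all equal the published counts exactly, with each
row's total equal to its component sum. The joint assignment is one
integer solution of the corresponding transportation problem, computed
once and frozen for determinism; the published marginals do not determine
the joint uniquely, so row-level component combinations are a consistent
reconstruction, not recovered data. Simpson grades and outcomes are absent
(NaN): that joint was never published.

`simulate_cohort(CohortModel)` draws full joint tables. Scores come from a
configurable distribution (default: the printed one); the component
combination is uniform over the combinations summing to the drawn score;
the Simpson grade follows a proportional-odds cumulative-logit model
`P(Y ≤ k | s) = σ(θ_k − β s)` with common slope `beta_score` (default 1.0)
and three ordered cutpoints; the 0–3 outcome follows the analogous model
with `outcome_beta` (default −0.5, negative because higher scores worsen
outcomes) and its own three cutpoints — the outcome needs its own cutpoint
set, which is why `CohortModel` carries both `thresholds` and
`outcome_thresholds`. Unset cutpoints are calibrated by solving, per
cumulative split, the monotone scalar equation matching the expected
marginal (averaged over the score distribution) to the published Simpson
(10/17/15/4) and outcome (7/27/10/2) marginals, so default simulations
reproduce the study's marginal composition at the stated effect sizes.
The proportional-odds form is a testing device: the original study never
states a joint model, and no claim about the real data's structure is
implied. All randomness flows from the single integer seed
(`numpy.random.default_rng`), making draws bit-reproducible.

## Statistical battery

- **Descriptives**: mean ± sample SD (n−1) of the score; counts and
  one-decimal percentages per category.
- **Univariate tests**: tie-corrected Kruskal–Wallis across the four
  Simpson-grade groups for ordinal variables; Pearson chi-square without
  Yates continuity correction for the binary flags. Empty grade groups are
  dropped with a warning. A variable constant across the cohort returns
  p = 1 (statistic 0) rather than erroring.
- **Adjusted odds ratios**: proportional-odds ordinal logistic regression
  (statsmodels `OrderedModel`, logit link, BFGS) of grade on all four
  components jointly; OR = exp(coefficient) with Wald 95% CIs. This family
  is the one most consistent with reporting a single OR per predictor for
  a 4-level outcome; a dichotomized fallback (grade I–II vs III–IV,
  ordinary logistic regression) is available via
  `regression_family="binary"` for sensitivity analysis. Non-convergence
  or quasi-separation (SE > 10 or non-finite) is flagged per variable,
  never silent.
- **Spearman correlations** use mid-rank tie handling with the standard
  large-sample t approximation for p (scipy); the implementation is
  checked in the tests against a brute-force mid-rank Pearson oracle to
  1e-10 on 1000 random tied vectors.
- **Discriminant accuracy**: linear discriminant analysis with empirical
  class priors on the total score, resubstitution accuracy in percent to
  two decimals (leave-one-out available). Resubstitution is the default
  because the original single reported accuracy carries no cross-validation
  qualifier. Perfectly separated classes (zero within-class scatter) break
  the SVD solver; that limit is handled by nearest-centroid classification
  with a warning.
- Two-sided p-values throughout; no multiple-testing correction is applied,
  matching the original analysis.

Simulation calibration verified in the tests: at zero generating effect
the adjusted ORs stay in [0.8, 1.25] and discriminant accuracy on balanced
independent classes is 25 ± 5%; at `beta_score = 1`, refitting the
proportional-odds model on its own simulations (n = 2000, 50 replicates)
recovers the slope with well under 15% mean bias.

## Reproducibility boundaries

The published score–grade correlation (R_s = 0.772), the adjusted ORs
(2.474 arterial; 13.095 CS) and the 69.60% discriminant accuracy are
functions of the patient-level (score, grade, outcome) joint, which exists
only in the external data deposit and not in print. They are therefore
**not** recomputed from printed data anywhere in this package; the
property-based substitutes above validate that the machinery would recover
such quantities from data of known provenance. Everything that *is*
printed — the score range 1–10 over the 60-cell component space, the
cohort descriptives (5.3 ± 2.8; 84.8% / 50.0% / 21.7%), the Simpson
distribution percentages, and the worked arterial scenarios scoring
1/2/3/4 — is recomputed end-to-end.

## Known limitations

- Coverage assumes an approximately tubular, non-branching artery segment;
  bifurcations must be split into separate segment masks upstream.
- The ±10° coverage accuracy holds for vessel radii ≈ 3 mm at 1 mm
  spacing; much thinner vessels on coarse grids will degrade first in the
  narrowing detector, then in coverage.
- Venous/MRV analysis, DICOM ingestion, automatic segmentation and any
  intensity modeling are out of scope by design.
- The reconstructed printed cohort fixes one of many joint component
  assignments consistent with the marginals; statistics that depend on the
  component joint beyond its marginals should not be read off it.
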