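# Methods

## Problem and scope

The vertical occipital fasciculus (VOF) is identified in tractography not
by a signature of individual streamlines but by a conjunction of
anatomical relations: it links dorsal parieto-occipital cortex with
ventral and lateral occipito-temporal cortex, courses craniocaudally, and
lies posterior to the arcuate fasciculus (AF) and lateral to the inferior
longitudinal fasciculus (ILF).  `vofdissect` operationalizes that
conjunction as a deterministic filter pipeline over a tractogram, then
quantifies the dissected bundle's cortical endpoints and hemispheric
asymmetry.  Fiber tracking itself is out of scope: the package consumes
streamlines, it does not produce them, and the reference bundles (ILF,
AF) are inputs, exactly as an anatomist supplies them.

## Spatial convention

All computation happens in world RAS millimetres with 0-based voxel
indices.  On-disk dialects are converted at the I/O boundary by nibabel:
TCK stores world mm; TRK stores voxel-mm in the header's voxel order and
is mapped through the header's `voxel_to_rasmm` affine — files without a
usable affine are refused rather than dialect-guessed, which is the
classic source of silent tractogram corruption.  World→voxel uses the
inverse affine with rounding to the nearest integer, halves away from
zero.  The left hemisphere is x < 0; "more lateral" means smaller x on
the left and larger x on the right, and that sign rule lives in exactly
one function.

## Selection model

Filters run in a fixed order — two-ROI → orientation → ROA → posterior →
lateral — and each rejection is charged to the first failing filter, so
the report's counts sum to the input count.  The first three are
per-streamline predicates and therefore commute; the relative-position
filters depend only on the candidate and the fixed reference bundle, so
the composition is idempotent on its own output.

**Endpoint assignment** uses the terminal points only (not a terminal
segment).  A terminal point in background takes the nearest labeled voxel
center within `endpoint_radius_mm` (default 2 mm, compensating for
termination just outside the labeled ribbon); distance ties within 1 nm
resolve to the smaller label id, making assignment deterministic.

**Orientation** follows the RGB direction-map convention: the share of
each axis in the summed absolute per-segment displacement.  "Blue"
(superior-inferior) candidacy requires both dominance and a share ≥ 0.5.
The 0.5 default makes "vertical" mean "more vertical than everything else
combined"; visual RGB dominance has no published cutoff, so the threshold
is exposed as `min_axis_fraction`.  Exact ties break SI > AP > LR.

**Relative position** partitions z into `slab_mm` slabs (default 5 mm,
anchored at z = 0).  In each slab occupied by both sides, the candidate's
coordinate *median* (robust to endpoint splay) is compared against the
reference bundle's per-slab *envelope* — its extreme point toward the
relation, e.g. the most lateral ILF point in that slab.  The candidate
must win strictly in all shared slabs (`slab_majority = 1.0`); with no
shared slab the filter is inapplicable and the candidate passes, with the
count logged.  The envelope (quantile 1.0) rather than the bundle median
is the default reference statistic because the anatomical statement
"lateral to the ILF" refers to the bundle, not to its midline: against a
per-slab median, roughly half of the ILF itself would count as "lateral
to the ILF", whereas against the envelope a bundle is never lateral or
posterior to itself.  `reference_quantile = 0.5` recovers the midline
variant for sensitivity analyses.

The gyrus-based ROI variant of the dissection (fusiform / inferior
occipital gyri as the ventral mask) is expressed by passing explicit
parcel names instead of group names in `SelectionCriteria`.

## Endpoint connectomics

The connectivity matrix counts accepted streamlines per unordered parcel
pair; it is stored symmetric, and its upper triangle including the
diagonal equals the accepted count.  Percentages are computed under the
*endpoints-within-group* convention: each streamline contributes one
endpoint to the group of each of its two parcels, and a parcel's ratio is
its share of its group's endpoints (a within-parcel streamline
contributes two endpoints to that parcel).  Connection ratios are
per-pair shares of all accepted streamlines.  Both conventions are
distinguished because published endpoint tables rarely state which one
they use.

Tract volume is the number of unique voxels intersected by any
streamline point after 1 mm arc-length resampling, times the voxel
volume; overlapping streamlines are not double counted.  Mean FA is the
unweighted mean over the same voxel set, keeping volume and FA on one
support.  The phantom paints its FA field on exactly this voxel support,
so on a noiseless phantom the dissected bundle's mean FA equals the
configured bundle FA identically.

## Laterality

LI = (L − R)/(L + R) for non-negative L, R; L + R = 0 yields NaN
(undefined), which is excluded from group means with a reported count
rather than treated as 0.  Group summaries report mean ± SEM (sd/√n) per
side and for LI.  Left and right values come from the same subjects, so
the default test is the two-sided *paired* Student t-test (unpaired
available by flag).  Zero-variance paired differences with nonzero mean
are flagged `degenerate` (infinite statistic) instead of being reported
as a number.  No multiple-testing correction is applied across
connections by default.

## The synthetic phantom

The phantom emulates the *statistical* structure the analysis assumes,
not brain anatomy.  On a 64×96×80 grid of 2 mm voxels (world origin at
the grid center):

* three box-shaped "shell" regions per hemisphere hold the parcel groups
  — dorsal (|x| 34–50, y −80…−60, z 46–70 mm), ventral (|x| 34–52, same
  y, z −70…−52), lateral occipital (|x| 50–62, same y, z −48…−30) — each
  tiled by nearest-centroid (Voronoi) assignment over its parcels
  (25 parcels per hemisphere);
* VOF-like streamlines are cubic Bézier arcs from a random voxel center
  of a dorsal parcel to one of a ventral or lateral-occipital parcel
  (split `ventral_fraction`, default 0.7), bowed laterally by 2–6 mm,
  resampled at 1 mm;
* the endpoint parcels are drawn from per-group multinomials.  The
  defaults are the hemisphere-specific VOF endpoint profiles with the
  dominant parcels at their reported shares (left ventral: V4 62.0%,
  PIT 16.2%; left dorsal: V3CD 35.2%, V6A 24.8%, V3A 14.8%, IP0 9.5%,
  V7 8.5%; right dorsal: V3A 29.4%, V7 26.5%, V3CD 16.7%; lateral
  occipital left: LO1 35.7%, LO2 27.4%, LO3 21.5%; and the corresponding
  right-hemisphere values); the unnamed remainder of each group splits
  the residual mass uniformly;
* the ILF-like bundle runs along y at |x| 8–18 mm (strictly medial to the
  VOF corridor, whose medial wall is |x| = 34, by at least the
  configurable 6 mm margin); the AF-like bundle is a C-shaped arc whose
  convex-hull bound keeps every point at least 10 mm anterior to the VOF
  corridor's front; clutter streamlines are random short arcs at least
  one of whose endpoints keeps 5 mm clearance from all labeled voxels,
  so they can never satisfy the two-ROI criterion;
* the FA field is `background_fa` (0.15) with traversed voxels at
  `bundle_fa` (0.55) plus Gaussian-smoothed noise of s.d. `fa_noise_sd`
  (0.02), clipped to [0, 1].

Region gaps are sized so that every generated streamline satisfies its
separation invariant *by construction* (worst-case displacement sums keep
the SI fraction above 0.5 for every dorsal→ventral and dorsal→lateral
pairing), and the invariants are additionally asserted per streamline at
generation time.

Two generator choices deserve emphasis.  First, point jitter is a
*smooth correlated* Gaussian perturbation: offsets of s.d. `jitter_mm`
(default 0.5) drawn at ~20 mm knots and interpolated along the arc.
Independent per-point noise at 1 mm spacing would add ≈1.13·n·σ to every
axis's total absolute displacement, drowning the orientation signal for
any realistic bundle — it roughens the polyline rather than bending the
trajectory.  Second, terminal points are pinned (the jitter tapers to
zero at both ends): the endpoint parcels are a generator *contract*, so
selection recall below 1.0 on a well-separated phantom is always a
selector defect, never generator leakage.

All draws flow from one `numpy.random.Generator` in a fixed order
(parcel draws, target-group flips, endpoint voxels, bow, jitter knots —
per hemisphere: VOF, ILF, AF, clutter, then FA noise), so a config + seed
pair is bitwise reproducible.  Lateral quantities are drawn
hemisphere-sign-aware, so left/right twins from one seed are exact mirror
images — the basis of the symmetry tests.

**What the phantom does not emulate:** cortical folding and a realistic
gray-matter ribbon, crossing/kissing-fiber ambiguity, curvature and
dispersion of real bundles, partial-volume FA, scanner noise.  Passing
tests therefore demonstrate the correctness of the *analysis* under its
stated geometric assumptions, not robustness to real tractography
artifacts.

## Problem sizes and tolerances

Unit and property tests run phantoms of 40–500 streamlines; multinomial
recovery uses 10⁴ draws against exact binomial intervals; the
endpoint-profile recovery experiments use 20,000 VOF streamlines per
hemisphere (binomial s.d. ≈ 0.34 pp for a 62% share), checked to ±1.0
percentage point; the paired-t null calibration uses 10⁴ replicates at
tolerance ±0.01.  Format round-trips are checked to 10⁻⁴ mm (streamline
files store float32; the worst-case representation error at these
coordinates is below 10⁻⁵ mm).

## Known limitations

* The relative-position filters compare against pooled reference
  *points*; a reference bundle with wild outlier streamlines tightens the
  envelope criterion accordingly.  Trimming outliers is the caller's
  responsibility (or use `reference_quantile < 1`).
* Endpoint assignment ignores gray-matter geometry beyond the label grid;
  with very coarse parcellations the 2 mm radius can bridge sulci.
* Tract volume depends on the resampling step and voxel size; values are
  comparable only within one grid.
* The phantom's parcels are boxes tiled by Voronoi cells; endpoint-ratio
  recovery is insensitive to this, but any analysis depending on parcel
  shape or adjacency would be.
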