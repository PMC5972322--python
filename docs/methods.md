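# Methods

This note records the models, conventions and parameter choices behind
`cordfit`, and what its synthetic components do and do not emulate.

## Morphometry and the correlation schedule

The packaged table (`cordfit/data/morphometry_table.csv`) holds, for each
of the 30 neuronal segments C1–S5, the population mean and SD of the
transverse and anteroposterior (AP) cord diameter in mm and the number of
subjects behind the estimate, taken from the segmental morphometry
meta-analysis of Frostell et al. 2016. The table is consumed as published;
re-deriving it is out of scope. Loading validates structural invariants
(one row per segment, positive means and SDs, AP ≤ transverse, plausible
subject counts) and fails loudly naming the offending row.

Two derived scalars:

* **Correlation schedule.** Observed cords keep a roughly constant aspect
  ratio, so the simulation ties the two diameters together more strongly
  where cords are small. The only stated anchors are ρ = 0.9 for the
  smallest segments and ρ = 0.4 for the largest, varying continuously with
  transverse diameter; we use the simplest map consistent with both
  anchors, linear interpolation in the segment's mean transverse diameter
  between the table's extremes (S5 at 4.7 mm → 0.9, C5 at 13.3 mm → 0.4).
  Interpolating on segment rank instead would change thoracic values by
  < 0.1 and none of the qualitative behavior.
* **Mean thoracic RAPT**, the AP/transverse ratio defining the "normal"
  interface shape class: the arithmetic mean of the 11 per-segment ratios
  of means over T2–T12 (≈ 0.7361). The alternative — ratio of pooled
  means — differs by < 1%; the choice is exposed through the segment
  subset argument.

## Population simulation

Each requested segment contributes `n_per_segment` draws (default 200,
the study condition) from a bivariate Gaussian with the table's means and
SDs and the scheduled correlation. Draws use a Cholesky transform of
independent standard normals from NumPy's default PCG64 generator, one
generator for the whole run seeded from the config, segments processed in
craniocaudal order — so a (config, seed) pair pins the entire sample
stream. Bit-equality is promised across runs of the same package version,
not across NumPy generations.

Diameters are physical lengths: by default any draw with a non-positive
coordinate is redrawn and counted (`resample_count`), which is negligible
for thoracic segments (means 3–4 SDs above zero) but material for sacral
ones; `truncation="none"` disables this for distributional purity, leaving
the moments exactly Gaussian.

## Interface catalog

The catalog always carries 7 analysis interfaces (3 normal, 2 round, 2
flat) plus 3 oversized safety interfaces, one per class, scaled 1.15× on
both diameters from the largest member of the class. Oversized interfaces
exist as intraoperative head-room (cord swelling) and are excluded from
fit statistics by default.

**Configured placement.** Normal-class transverse diameters default to the
15th/50th/85th percentiles of the pooled simulated thoracic transverse
distribution; round and flat ellipses sit at the two outer normal sizes
with class RAPTs of 1.12× and 0.88× the mean thoracic RAPT. The percentile
spread is deliberately wide: with a tighter spread (e.g. quartiles) the
low-AP corner ellipse captures the largest share of the population and the
catalog no longer *looks* centered; at 15/50/85 the middle normal size
holds the dominant assignment basin across seeds, which is the design
intent of a centered catalog. All of this is configurable
(`CatalogConfig`).

**Direct optimization.** Because a hand placement is not reproducible, the
seven analysis ellipses can instead be chosen by minimizing one of the four
error-of-fit statistics (mean/median/p95 Euclidean, mean area mismatch) on
a simulated sample. The search is derivative-free and multi-restart:
k-means++ seedings refined by k-median alternation (per-cluster Weiszfeld
geometric medians, a descent method for the mean-distance objective),
for the 95th-percentile objective an additional tail-weighted refinement
(samples beyond the 90th distance percentile get 4× weight), then two
Nelder–Mead passes over the 14 free diameters; the configured catalog is
always included as a warm start, so the optimized objective never exceeds
the configured one. A structured mode ties each ellipse's RAPT to one of
three ordered class values (10 parameters). Assignment inside the
objective is always nearest-Euclidean; the area objective only changes the
scoring of assigned pairs.

Shape classes for freely optimized ellipses are assigned afterwards by
RAPT ranking (2 lowest → flat, 3 middle → normal, 2 highest → round),
which preserves the catalog's 3/2/2 class structure by construction.

## Error-of-fit

Per sample: `e_T = |T_s − T_d|`, `e_AP = |AP_s − AP_d|`,
`e_euclid = √(e_T² + e_AP²)`, `e_area = |π T_s AP_s/4 − π T_d AP_d/4|`
(absolute value — the summary is a single non-negative column set).
Summaries are median, mean, and the 95th percentile computed by linear
interpolation of order statistics (the "type 7" convention, the default of
both NumPy and R); at two printed decimals the interpolated and empirical
quantiles are indistinguishable on n = 2,200. Ties in assignment (a
measure-zero event) resolve to the larger-area interface, consistent with
the safety-margin philosophy of the oversized sizes.

## Synthetic cross-section tracings

The two published histology series behind the vector model are not
available as data, so a generator emulates them. The outer boundary is an
ellipse; gray matter is the union of a central band (commissural gray) and
four capsule-shaped lobes (ventral and dorsal horn per side). Two features
seen in traced series are built in: the dorsal-horn angle grows linearly
in the cranial direction (default 18° at T12, +1.2°/segment, so ≈ 30° at
T2), and the two parameter presets ("sources" A and B) differ in their
anterior gray span and horn proportions. Left and right halves are
stretched independently by ~0.6% (asymmetry noise 0.05 mm on a 4.5 mm
semi-axis) to emulate tracing asymmetry.

What the generator does **not** emulate: real micrograph texture and
tracing jitter along the contour, segment-to-segment autocorrelation of
shape within a subject, gray-matter area scaling with cord size, and any
pathology. Tests passing on this family therefore validate the geometric
operations and the pipeline's statistical logic, not anatomical fidelity
of the resulting mean shape.

Contours are stored counter-clockwise with vertex 0 exactly on the dorsal
midline crossing, resampled to equal arc-length spacing (256 points by
default). That convention makes vertex `n − i` the arc-length mirror
partner of vertex `i`, which the symmetrization exploits.

## Symmetrize, scale, average

* **Midline**: the vertical axis through the outer contour's area
  centroid — parameter-free and deterministic; rigid rotation correction
  is deliberately out of scope (the subsequent mirror-averaging removes
  residual tilt sensitivity for near-upright tracings).
* **Symmetrization** recenters on the midline and averages each contour
  with its mirror image under the index correspondence `i ↔ n − i`. The
  output is mirror-symmetric to the last bit and the operation is exactly
  idempotent; both properties are asserted rather than approximated. An
  angular (polar) correspondence was considered and rejected: it is
  undefined for non-star-shaped gray contours.
* **Scaling** is anisotropic about the origin so that the outer contour's
  axis-aligned bounding box exactly equals the target transverse and AP
  diameters — matching how caliper diameters are reported in the source
  morphometry — and is exactly invertible.
* **Averaging** is pointwise over vertices of index-aligned contours, in
  two stages (segments within source, then sources with equal weight).
  Equal source weighting is an assumption; it is configurable by passing a
  different source list.

The dorsal-horn angle of a finished section is measured as the polar angle
(from the dorsal vertical) of the most dorsolateral gray vertex relative
to the gray centroid. It is a vertex-based estimate, accurate to a couple
of degrees on averaged shapes — sufficient for trend assertions, not a
goniometric measurement.

## Channel planning

Coordinates: x transverse (+right), y AP (+dorsal), z from the cranial
face (0) to the caudal face (device length), all mm. Tract anchors are
specified anatomically rather than absolutely: a polar angle from the
dorsal midline plus a radial fraction between the gray boundary and the
outer contour along that ray, evaluated on the mean cross-section scaled
to the device's diameters. Defaults (illustrative, not clinically
prescriptive): lateral corticospinal tract at 55°, fraction 0.5,
descending; dorsal column at 20°, fraction 0.45, ascending; one channel
per side each, radius 0.4 mm. Descending channels exit at the ventral-horn
centroid of the same side; ascending channels exit at the dorsal gray
centroid clipped to the medial 55% of the gray half-width (the
dorsal-intermediate gray), which keeps ascending paths medial to the
descending ones — with unclipped dorsal-horn centroids the four channels
cannot simultaneously respect the 0.4 mm wall on mid-sized interfaces.
The right side is computed and mirrored, so anchor pairs are exactly
symmetric.

Clearance: the wall between two straight channels is the minimum distance
between their 3D axis segments (closed-form clamped quadratic
minimization) minus both radii; the wall to the outer boundary is the
point-to-ellipse distance (one-dimensional root-finding formulation,
solved with Brent's method to 1e−13) at both end faces minus the radius —
exact for a straight channel in a convex elliptical cylinder, since the
cross-section of the channel at any z is a disk whose center interpolates
the two face positions. Feasibility requires every wall ≥ 0.4 mm. An
infeasible layout raises an error carrying the full report (planning) or
is recorded with `passed: false` in the pipeline manifest (orchestration).

Channel-to-anatomy deviation: overlaying anatomy scaled to a cord of size
(T_s, AP_s) on a device of size (T_d, AP_d) moves an anchor at (x, y) to
(x·T_s/T_d, y·AP_s/AP_d); the deviation is the Euclidean distance between
the two. It vanishes at the device midpoint and, for any anchor inside
the ellipse (|x| ≤ T_d/2, |y| ≤ AP_d/2), is bounded by half the sample's
Euclidean error-of-fit — the size mismatch is split symmetrically between
the two halves.

## Pipeline and reproducibility

One config object drives all stages; per-stage seeds are
`seed XOR crc32(stage_name) mod (2³¹ − 1)`, so any stage can be reproduced
in isolation. Artifacts are CSV/JSON/GeoJSON/SVG plus a manifest with the
config echo and SHA-256 of every artifact; reruns with the same config and
seed are hash-identical (the SVG renderer is pinned to a fixed hash salt
and dateless metadata for this reason).

## Problem sizes and numerical choices

* Simulation and error-of-fit statistics use the study size, 200 draws per
  level (2,200 thoracic samples); parameter-recovery tests use 10,000–
  20,000 draws for one segment, asserted at 3× the standard error of the
  respective moment.
* Catalog optimization defaults: 4–6 restarts, 8,000 Nelder–Mead
  evaluations per pass, two passes; on 2,200 samples each objective
  optimizes in a few seconds. Thirty independent restarts move the
  optimized mean Euclidean error by < 0.1%, so the defaults sit at the
  practical floor.
* Contours use 256 points (128 in fast tests); symmetrization and scaling
  assertions are exact (≤ 1e−9 mm tolerances cover only floating-point
  rounding).
* Degenerate inputs: zero SDs produce exact segment means; a single-sample
  catalog optimization places an ellipse exactly on the sample; one draw
  per level still yields a complete pipeline run with 11 fit records.

## Known limitations

* The simulation extrapolates healthy-population sizes; post-injury
  atrophy (11–30% cross-sectional area loss reported at C2 in chronic
  cervical injury) is deliberately not modeled, matching the design
  decision the device set compensates for by covering a size range.
* With seven interfaces on the full stated population (SDs of ~2–3 mm per
  segment), the quantization floor of the mean Euclidean error is ≈ 1.0 mm
  (independent k-means cross-check agrees); the reported optimized
  statistics sit at that floor, and no seven-ellipse catalog can do
  better under these simulation conditions.
* Channels are straight; curved channels, axon-level modeling, surgical
  fixation mechanics and CAD surface export are out of scope.
* The default channel layout is an illustration of the planning machinery;
  clinical channel counts, radii and tract coordinates would come from the
  device design itself.
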