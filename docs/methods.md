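# Methods

This note documents the measurement definitions, the synthetic-data model,
the numerical choices, and what the tests do and do not establish.

## Apical-domain detection

A cell's cortical signal at one (t, z) is sampled as a **contact-free
profile**: one sample per boundary pixel of the cell's label mask,
excluding pixels within a configurable band (default 2 px, Chebyshev) of
any neighboring cell; samples are ordered by angular position about the
cell centroid, measured from the embryo-center → cell-centroid axis so the
outward-facing cortex is centered at 0°. Arc position is cumulative
Euclidean step length in µm.

The candidate domain is the contiguous arc, with length between 33% and
80% of the contact-free total, that maximizes the **intensity ratio** —
window mean divided by the mean of the remaining contact-free samples.
The ratio (not the raw window mean) is the search objective because the
criterion itself thresholds the ratio, and because the mean objective is
degenerate: every sub-window of a uniform bright domain ties on mean, so
pixel noise collapses the choice onto arbitrary small sub-windows, which
leaves domain samples in the "rest" and deflates the measured ratio. The
ratio objective is maximized exactly by the full domain arc. Ties are
broken toward longer arcs, then smaller start angle. Closed profiles
(cells without contacts) are searched with wrap-around windows; profiles
fragmented by contacts are searched per contiguous segment.

A frame is called polarized when (a) the candidate's length fraction is in
[0.33, 0.80] (bounds inclusive, matching "between"), (b) its ratio is
strictly greater than 1.5 (matching "more than"), and (c) slices passing
(a) and (b), with ≥ 50% mutual angular overlap between consecutive slices,
form a contiguous z-run spanning ≥ 3 µm. The z-extent of a k-slice run is
counted as the slab thickness k·Δz, so a single slice with Δz ≥ 3 µm can
satisfy depth on coarsely sampled stacks — a deliberate, documented
convention. The reported arc comes from the run's highest-ratio slice.
A temporal onset requires the call to persist for a configurable number of
consecutive frames (default 2) to reject single-frame noise.

Domain size in degrees is the angle the reported arc subtends at the cell
centroid. The apical-nucleus distance is measured from the cortex point at
the domain's angular midpoint to the nearest nucleus boundary point, on
the plane where the nucleus is largest.

## Polarity timing

Onset is the time of the first frame of the first persistent positive run
at or after cleavage. A cell is **EP** iff onset − reference ≤ 60 min
(boundary inclusive: at 20-min frames, onsets at frames 0–3 post-cleavage
qualify) *and* the minimum IEA over the cell's adjacent neighbors at the
onset frame is < 120°; polarized cells failing either condition are LP;
cells with no accepted onset are unpolarized and flagged censored (the
movie cannot exclude a later onset). The reference event is the cell's own
cleavage in `live` mode and the embryo's last cleavage in `fixed` mode.
The minimum over neighbors is used because the source definition ("the
angle between the cell and its neighbors") states no aggregation rule;
the minimum is the most conservative choice (a cell is pre-compaction
only while at least one of its contacts still is).

## Inter-blastomere angle

The IEA is computed by fitting a least-squares (Kasa) circle to each
cell's contact-free sub-pixel outline (`skimage.find_contours`, excluding
points within 1.5 px of any other cell) and taking the angle between the
two fitted arcs analytically:

IEA = 180° − arccos((r₁² + r₂² − d²) / (2 r₁ r₂)),

where d is the fitted center distance. This gives 0 at a point contact
(d = 2r) and 180° for fully flattened cells. The construction rests on the
same physical assumption as the classical circle-circle geometry: uniform
cortical tension keeps the contact-free surface of a blastomere at
constant curvature. It was chosen over tangent-line fits at the junction
because secant fits on pixelated masks carry a curvature bias of order
(arc length)/(2r) plus extrapolation noise — empirically 10–30° of error
at realistic cell radii, versus ≤ 2.5° for the circle fit at r = 15 px and
≤ 1° at r ≥ 40 px across 30–170°. An optional `local_arc_um` restricts the
fit to outline points near the contact for strongly non-circular cells.
An embryo is compacted when every measured IEA is ≥ 120°.

## 2-D apex geometry and 3-D aspect ratio

For a mid-plane outline with a known apical arc: the **apex** is the
boundary point at the arc's angular midpoint; the **basal edge** is the
boundary band at minimal projection onto the apical axis (bottom 15% of
the projection range), and its endpoints are that band's lateral extremes.
The converging lines join the basal endpoints to the apex; the apex angle
is measured between them; side lengths join each basal endpoint to the
domain endpoint on its side; the length ratio is mean side / mean
converging length. Wider cells yield larger apex angles and larger ratios.

3-D aspect ratios come from second-order spatial moments of the
calibration-scaled voxel coordinates: axis half-lengths are √(5λ) for the
covariance eigenvalues λ (exact for a solid ellipsoid), the aspect ratio
is longest/shortest, and embryo-normalized values divide by the mean over
the embryo's cells so they average exactly 1.

## Statistics

* **Fisher exact test** (two-tailed, probability-mass convention: sum of
  fixed-margin tables no more probable than the observed) via
  `scipy.stats.fisher_exact`; verified against an explicit hypergeometric
  enumeration, exhaustively for small grand totals.
* **Two-proportion z-test** with pooled variance,
  z = (p̂₁ − p̂₂)/√(p̂(1−p̂)(1/n₁+1/n₂)), two-tailed normal p; pooled
  proportions of 0 or 1 are rejected as degenerate.
* **Binomial independence**: per-embryo EP counts are compared with
  Binomial(n_cells, p̂), p̂ pooled over cells, via a chi-square statistic
  whose null distribution is obtained by parametric bootstrap (p̂
  re-estimated per replicate, default 10,000 replicates) because expected
  counts in the upper tail are far below the asymptotic regime.
* **Test selection** follows the standard decision tree: D'Agostino
  K-squared normality per group at α = 0.05 → t-test (Welch-corrected when
  a two-sided F-test finds unequal variances) or one-way ANOVA; otherwise
  Mann-Whitney U or Kruskal-Wallis with Dunn post-hoc; groups with n < 8
  default to the rank-based branch.
* Profile smoothing is a local polynomial (Savitzky-Golay-style) fit of
  order 2 over a 20-sample window shrinking at the ends, applied over arc
  position; it reproduces constants and quadratics exactly. This is one
  reading of a graphing-package smoother ("smooth, factor 20, second-order
  polynomial") and is used for display profiles, not for detection.

## Synthetic embryos

The generator emulates the study conditions rather than embryo physics:

* **Acquisition**: 21 frames at 20 min (frames every 20 min is the source
  acquisition rate), 5 z-slices at 2 µm, 0.75 µm pixels.
* **Geometry**: 8 cells of radius 15 µm as spheres centered on a mid-plane
  ring, deformed at contacts by a nearest-center label partition. The
  compaction ramp drives the adjacent-pair IEA from 60° at 0.3°/min
  starting at t = 120 min (120° at t = 320 min); the ring spacing is set
  from the target angle via d = 2r·cos(θ/2). The default movie ends at
  θ ≈ 144°, while every cell retains an outer surface — a 2-D ring at
  θ = 180° would have none, which real (3-D) embryos avoid.
* **Polarization**: each cell is EP independently with probability 0.2
  (the live-imaging division dataset has 46 EP of 245 counted cells).
  EP onsets are uniform within 60 min of the cell's cleavage (cleavage
  jitter uniform over one frame); LP onsets are normal (mean 340 min,
  sd 40) truncated to [t(120°), movie end − 2 frames] so every onset is
  observable — the source reports only "a broader peak", so these
  parameters are illustrative. From onset, a cortical arc covering 50% of
  the current contact-free arc, centered on the outward axis, carries 2×
  the cortical baseline across a 6 µm z-extent.
* **Intensities**: background 40, cytoplasm 200, nucleus 300, cortex 600
  (arbitrary units, uint16); additive Gaussian noise clipped at zero.
  Nuclei sit on the outward axis with apical gaps of 1 µm (EP) vs 5 µm
  (LP), emulating the apical nuclear bias of EP cells.
* **Lineage**: division symmetry is Bernoulli conditional on EP status
  (0.717 / 0.387, the published symmetric-division frequencies);
  symmetric → both daughters polar, asymmetric → exactly one. TE fate is
  Bernoulli conditional on daughter polarity (0.95 / 0.08, solved from
  the published polar-daughter and TE frequencies of the two mother
  classes). All randomness flows from one explicit seeded generator.

What the generator does **not** emulate: membrane mechanics, fluorophore
photophysics, uneven illumination, segmentation errors (label masks are
exact), cell movement or mitosis between frames, and 16-cell-stage images
(lineage outcomes are tabular). Passing tests therefore demonstrate the
correctness and calibration of the measurement code under the stated
model, not robustness to real segmentation noise.

## Problem sizes and numerical choices

The validation studies use 50 rendered embryos per noise level for onset
recovery, 5,000 simulated embryos for the EP-frequency calibration, 10,000
replicates for the z-test type-I study, and exhaustive Fisher enumeration
to grand total 25 plus random tables to total 60 — sizes chosen so the
whole suite runs in minutes on one CPU while leaving the statistical
assertions with comfortable margins. Boundary conventions: length-fraction
bounds inclusive, intensity threshold strict, EP window inclusive,
compaction threshold inclusive (≥ 120°). Degenerate inputs (empty
profiles, enclosed cells, empty groups, all-zero EP counts) raise typed
errors rather than returning defaults.

## Known limitations

* The detector assumes one domain per cell; multiple disjoint bright arcs
  return only the best window.
* The IEA circle fit needs a few dozen contact-free outline points per
  cell; tiny cross-sections (cell caps at extreme z) are skipped.
* Onset resolution is one frame; sub-frame onset interpolation is out of
  scope.
* The apex-geometry construction anchors on the domain arc midpoint; for
  unpolarized cells the caller must supply the contact-free arc instead.
* In deeply compacted ring geometries next-nearest cells begin to touch;
  the minimum-IEA aggregation then reflects those shallow contacts, which
  is geometrically real but differs from the adjacent-pair ramp value.
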