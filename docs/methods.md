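# Methods

## Scope and data model

The unit of analysis is a cuboid sub-volume ("cube") of segmented
cortical bone with isotropic voxels. Arrays are indexed `(Z, Y, X)`
(slice-major, the order a TIFF stack pages in); every physical-space
3-vector — origin, centroids, direction vectors — is written `(X, Y, Z)`
in µm. The physical coordinate of the corner of voxel `(i, j, k)` is
`origin + s·(k, j, i)` with `s` the voxel size; voxel centers sit at a
further `+s/2` per axis. Only isotropic voxels are supported: all
distance-based morphometrics (Feret lengths, solidity) assume a single
spacing, and anisotropy would silently bias them. Cube extraction uses
0-based half-open `[lo, hi)` index ranges, so cube voxel counts are
exact products of the extents, and cubes within one comparison set are
required to have identical extents.

The default voxel size is 0.678 µm, the resolution of the sub-micron
synchrotron scans this style of lacunar analysis is designed for.

## Extraction chain

`binarize → label_components → remove_noise → remove_edge_cut`

* Thresholding is fixed-value or Otsu; a polarity flag states whether
  lacunae are the bright or the dark phase (`dark` for rendered µCT,
  where lacunae are voids). Foreground is `> t` for bright, `<= t` for
  dark.
* Labeling uses 26-connectivity by default: stellate lacunae have thin,
  obliquely running processes that 6-connectivity would shatter into
  separate components. Connectivity is configurable (6/18/26) for
  sensitivity analysis.
* The noise filter removes components below `min_volume_um3` (default
  5 µm³ ≈ 16 voxels at 0.678 µm). Any real osteocyte lacuna is two
  orders of magnitude larger; segmentation speckle is a few voxels. The
  threshold is a config knob because it is a property of the
  segmentation, not of the biology.
* The edge-cut filter removes every component with a voxel on any of
  the cube's own six faces: a truncated lacuna has biased volume, shape
  and orientation. No stereological edge correction (e.g.
  Miles–Lantuéjoul) is applied to the retained counts: the analysis
  compares identically sized cubes, so the edge bias largely cancels in
  ratios. This is a known limitation for absolute density estimates.

Labels are renumbered consecutively after every filter and each step is
appended to a provenance list.

## Per-lacuna morphometry

* **Volume** is voxel count × `s³` exactly.
* **Maximum length** is the 3D Feret diameter: the maximum pairwise
  distance between voxel centers. The implementation reduces the voxel
  set to its convex-hull vertices first — the maximum pairwise distance
  of a point set is attained at hull vertices, so the reduction is
  exact, not approximate — and evaluates squared distances on integer
  index differences, so the maximum is found in exact integer
  arithmetic. The Feret definition (rather than the principal axis of
  the voxel covariance) is chosen deliberately: for a stellate cell the
  longest spike pair *is* the maximum length, whereas the inertia
  ellipsoid mixes all processes. Among equidistant extremal pairs the
  lexicographically earliest is used, making the direction
  deterministic.
* **Axis binning** assigns the direction to the referential axis with
  the largest absolute component; exact ties break X > Y > Z. An
  angular-tolerance mode (within θ of an axis, else "oblique") is easy
  to add on top of the stored directions but is off by default, since a
  forced trichotomy keeps the orientation histogram three-valued.
  Single-voxel (or otherwise degenerate) components have an undefined
  direction; they stay in the counts but are excluded from the
  orientation histogram.
* **Solidity** is voxel count divided by the number of integer grid
  points inside-or-on the convex hull of the voxel centers. The count
  is computed column-wise: for every (y, x) column of the bounding box
  the hull cross-section is a z-interval bounded by the facet planes.
  Tolerances exploit integrality: a grid point strictly off a facet
  plane through integer points is ≥ ~1e-4 away in the facet metric,
  float errors are < 1e-7, so a 1e-6 slack classifies every point
  correctly and keeps on-facet points inside. Components with fewer
  than 4 non-coplanar voxels default to solidity 1 (compact).
* **Shape class**: stellate iff solidity < 0.60. The generator's
  ellipsoids score ≈ 1.0 and its spiked particles median ≈ 0.39 (99 %
  below 0.55), so the cut sits in a wide gap; it is configurable for
  real data, where segmentation quality may shift the distribution.

## Region statistics

* **Density** is retained count over cube volume in mm³; the comparison
  reports the attachment/reference ratio.
* **Volume comparison**: two-sided Mann-Whitney (Wilcoxon rank-sum).
  With both groups ≤ 10 observations and no ties, the exact null
  distribution is evaluated by the standard counting recurrence and the
  two-sided p is `2·P(U ≤ min(U₁, U₂))` capped at 1. Otherwise the
  normal approximation is used with midranks, tie-corrected variance
  and a 0.5 continuity correction. The lacuna volume distribution is
  right-skewed (the package ships a normal qq diagnostic that shows
  exactly this on generated data), which is why a rank test rather than
  a t-test is the primary tool.
* **Orientation comparison**: Pearson χ² homogeneity on the 2×k table
  of axis counts (k = axes with a nonzero column total; df = k−1), with
  a note emitted when any expected count falls below 5.
* Verdicts are "different" when p < α (default α = 0.05, two-sided,
  i.e. 95 % confidence) and "similar" otherwise. No multiple-testing
  correction is applied across the three criteria; with only three
  tests per comparison and α = 0.05 this inflates the family-wise error
  modestly, and is noted here as a caveat.

## Classification rules

UMFE ⇔ orientation different ∧ volume different ∧ stellate;
PMFE ⇔ orientation different ∧ volume similar ∧ compact;
otherwise indeterminate, with flags naming the mismatch (e.g. "volume
different but shape compact" for the anomalous fibre-free region seen
in practice). Density is demoted to a supporting flag because observed
UMFE density ratios (×1.04–×2.5) overlap the PMFE range (×1.5–×1.8): no
threshold separates them consistently. The classifier's domain is
fibrous entheses only; fibrocartilaginous entheses (with a calcified
cartilage layer) are out of scope.

## Synthetic phantoms

The generator emulates what the analysis assumes about segmented bone
cubes, with ground truth for validation:

* **Lacunae** are non-overlapping particles placed by rejection
  sampling with a 26-neighbourhood separation (so each particle is
  exactly one labeled component). Compact lacunae are triaxial
  ellipsoids (long/short axis ratio 1.3–2.4); stellate lacunae are an
  ellipsoid body plus 8–12 radiating capsule spikes (radius 0.9 µm,
  length 10 µm or 1.6× the body long semi-axis, whichever is larger —
  spikes must protrude for the shape to read as a star). One antipodal
  spike pair lies along the particle's orientation axis, slightly
  longer than the rest, so the true maximum-length direction is the
  orientation axis by construction.
* **Volumes** follow a lognormal law parameterized by its mean (µm³)
  and log-sd; body volumes of 250–350 µm³ with σ ≈ 0.4–0.45 give the
  right-skewed distributions seen in large urodele-like lacunae.
* **Orientation** is isotropic or axis-aligned with a tangent-plane
  Gaussian scatter (default 25°).
* **Clustering** optionally arranges lacunae in "stacks" along an axis
  (the fibre-parallel columns characteristic of attachment bone);
  stack proposals fall back to uniform placement when a neighbourhood
  is too crowded, so the requested count is always honoured.
* **Speckle** adds 1–4-voxel specks (≤ 1.3 µm³, far below the noise
  threshold); **fibres** optionally add cube-spanning cylinders, which
  the edge-cut filter removes — as it should.
* **Rendering** produces grayscale from the mask with a Gaussian
  point-spread and additive noise, to exercise thresholding.

Placement rasterizes each particle once (per-primitive bounding boxes)
and translates it by integer offsets across attempts against a
pre-dilated occupancy grid; the sub-voxel phase is refreshed
periodically. A scene that cannot be packed raises an explicit error
rather than silently under-filling.

The **presets** encode published attachment/reference comparison rows:
the attachment cube's parameters express the row's density multiplier
(×2.5 and ×1.8 for the salamander UMFE/PMFE; ×1.5/×1.5/×1.7 for the
three Eusthenopteron areas; ×1.04/×1.3/×1.2 for Compagopiscis),
orientation similar/different (isotropic vs aligned), volume
similar/different (equal vs shifted lognormal), and stellate vs compact
shape. The Eusthenopteron fibre-bearing cube holds 490 lacunae, within
the published 450–500 range; reference-cube counts for the other taxa
(140–315 per 200³ cube, i.e. ~56 000–126 000 mm⁻³) are this package's
own choices at realistic packing densities, since absolute counts were
not published for them. Presets place lacunae interior-only: the preset
counts are therefore *post-filter* retained counts, matching how the
published ratios were measured (after noise and edge-cut removal);
edge-cut behaviour itself is validated separately on `allow_cut`
scenes against ground truth. Counts scale with cube volume when presets
are built at non-default extents, preserving densities and ratios.

What the phantoms do **not** emulate: reconstruction artefacts (ring
artefacts, phase fringes), spatially varying contrast, canalicular
networks connecting lacunae, curved fibres, and real biological
covariation between lacuna size and shape. Passing tests therefore
demonstrate that the pipeline measures what it claims on data matching
its assumptions — not that any particular scan is segmented correctly.

## Validation strategy

Every non-trivial numeric path is checked against an independent
oracle: labeling against a BFS flood fill; the Feret reduction against
exhaustive all-pairs distances (exact, via integer squared distances);
the solidity count against exact rational halfspace arithmetic built
from integer hull vertices; the exact rank-sum against full enumeration
of group assignments (and scipy as a second cross-check); the χ²
statistic against the direct Σ(O−E)²/E formula. Statistical calibration
is simulated: type-I error of both tests at n = 50 over 1000 null
replicates, and power against a 50 % volume shift. End-to-end, the
pipeline re-recovers each preset's encoded density multiplier over 20
seeds, and the eight published signature rows classify to their
published interpretation.

Problem sizes used in the shipped tests and acceptance script — 200³
voxel cubes, 20 seeds per comparison, 1000-replicate calibrations —
were chosen to exercise the full pipeline at the published cube scale
while keeping a complete run in the minutes range on a single CPU.

## Known limitations

* Counts are not edge-corrected (see above); ratios are the intended
  endpoint.
* The stellate threshold and noise threshold are calibrated on the
  generator's geometry; real segmentations should re-examine both.
* The χ² orientation test treats axis bins as unordered categories;
  finer orientation statistics (spherical, e.g. Bingham-type) are out
  of scope.
* The "similar" verdicts inherit the usual null-test caveat: failure to
  reject is not evidence of equality, especially in small cubes.
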