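# Methods

This note documents the models, parameters and numerical choices behind
`leafdissect`, and what its synthetic benchmark does and does not show.

## Input model and assumptions

The pipeline assumes one dissected leaf per image, petiole pointing
toward the image bottom (an `orientation` flag pre-rotates scans taken
otherwise), on a light, weakly saturated background. Leaflets must be
"fatter" than the stalks that carry them — the maximal inscribed circle
inside a blade is larger than inside a petiolule or the rachis. That
single geometric property drives the whole segmentation; leaves whose
blades are as thin as their stalks have no blade/stem contrast and are
rejected (`DegenerateClusterError`).

## Binarization

- RGB → HSV; clustering happens in (saturation, value) space, which
  separates a colored leaf from a near-white scanner background far
  more reliably than gray levels.
- 2-means (fixed seed, 4 restarts) initializes a 2-component
  full-covariance Gaussian mixture; covariances start as identity
  scaled by the standard deviation of the whole SV sample. EM runs at
  most 200 iterations at tolerance 1e-4 (mean log-likelihood); if EM
  fails to converge the 2-means labels are used with a logged warning.
- The foreground is the component with the larger mean saturation; the
  `foreground="dark"` option instead takes the lower mean value, for
  unusual backgrounds. If the two components' mean saturation differs
  by less than 0.01 the image is treated as having no foreground.
- Only the largest 8-connected component survives; interior holes
  under 25 px (scan speckle) are filled so they cannot distort the
  distance transform. Both thresholds are configurable.

## Skeleton graph

- Exact Euclidean distance transform (`scipy.ndimage`); the image frame
  counts as background so masks touching the border stay finite.
- Skeletonization uses a standard thinning routine; the pipeline's
  contracts are on its outcome (one-pixel-wide, connectivity- and
  topology-preserving, medial), not the algorithm identity.
- 8-connectivity throughout, the usual choice for thin structures.
- **Pruning.** Terminal branches shorter than 25 px are removed,
  iteratively, until stable. Two refinements make this robust on
  discrete skeletons:
  1. *Fork detection is cluster-wise.* Raw degree ≥ 3 both
     over-triggers (staircase corners form pixel triangles) and
     under-describes real joints (which appear as clusters of adjacent
     degree-3 pixels). A cluster of adjacent degree-≥3 pixels is a
     genuine fork iff ≥ 3 skeleton branches leave it.
  2. *Medial salience guard.* A short branch is only a spur if its
     distance values never rise above the fork's (+1 px). Noise spurs
     point toward the boundary, so their d stays at stem level; the
     short internal skeleton of a small terminal blade climbs to ~b and
     must survive even below the length threshold. Without this guard,
     leaflets whose internal skeleton is shorter than the pruning
     threshold are destroyed whenever a twig artifact sits at their
     attachment.
- The base node is the extremal (degree-1) node with the maximal row
  index, ties to the smaller column — the lowest skeleton tip, i.e.
  the petiole end under the scanning convention.

## Cut nodes

- Node distance values are clustered by a 1-D 2-Gaussian mixture
  (fixed seed, 2 restarts); the larger-mean component is the leaflet
  class L. The mixture is preferred over a hard threshold because the
  two distance populations have very different variances.
- On each base→tip path the cut index minimizes
  M(k) = |{1..k} ∩ L| + |{k+1..N} ∩ R|, k ∈ 0..N; k = 0 and k = N are
  legitimate outcomes ("all blade" / "no blade on this path"), so the
  function is total. The first minimum is taken.
- Paths ending in the same connected L-region describe the same
  leaflet; on disagreement the candidate with the smallest M wins,
  ties to the smallest index. (On clean inputs the candidates agree.)
- The branching node is the last genuine fork strictly before the cut
  node, or the base when none exists (first leaflet pair / simple
  leaf).

## Boundary cut and dissection

The continuous definition — b1 the nearest outline point to c, b2 the
nearest outline point with d(b1,b2) > d(c,b2) — needs three discrete
repairs, all of which preserve its intent (a short chord across the
stalk, just below the blade):

1. **4-connected, extended chords.** An 8-connected Bresenham line can
   never disconnect an 8-connected region (diagonal leaks), so chords
   are rasterized 4-connected and extended 2 px past both endpoints
   (the endpoints themselves lie on the jagged outline, where diagonal
   neighbors would otherwise bridge the cut).
2. **Severing validation.** The chosen chord must actually separate
   the leaflet: the leaflet-side skeleton seed must land in a component
   that contains neither the base nor any other leaflet's seed.
   Candidates are tried in order of distance, restricted to a local
   radius (a severing chord crosses one stalk, not the leaf).
3. **Anchor retreat.** The optimal cut node sits exactly at the
   stalk/blade transition, where the local cross-section is wide and no
   short chord exists. If needed, the chord anchor walks back along
   the path toward the branching node (≤ 8 px) until a severing chord
   appears. The reported cut node is unchanged; only the chord moves.
   The retreat adds at most a few stalk pixels to the leaflet mask.
4. If c itself lies on the outline (very thin stalks), b1 = c and the
   opposite-side constraint — vacuous in that case — reduces to "the
   nearest other outline point".

Leaflets for which no severing chord exists are flagged and excluded
from per-leaflet outputs, never silently dropped. After removing all
chords, each leaflet is the component holding its seed (chord pixels
are returned to it); remaining stem pixels are attributed to the
nearest labeled skeleton node (petiole = base→first branching node,
rachis = rest of the main axis, petiolule_i = branching→cut path).
The terminal leaflet's stalk is part of the rachis in the pixel
partition, while its branching→cut length is still reported as that
leaflet's petiolule feature.

## Ordering and features

- The terminal leaflet is the one whose cut node is graph-farthest
  from the base. Laterals are ranked per side by graph distance from
  their branching node to the terminal branching node (rank 1 nearest
  the apex, matching the numbering convention "by distance to the
  terminal leaflet"). Side is the sign of the cross product between
  the local rachis direction (toward the apex) and the branching→cut
  direction, in an upright frame; mirroring the image swaps all sides.
- Shape features come from the moment-equivalent ellipse (normalized
  second central moments); e = √(1 − b²/a²). The perimeter is the
  standard weighted outline-chain estimate (within 5% on rasterized
  disks of radius 10–50).
- **Axis lengths are weighted chain lengths** along skeleton paths:
  1 per axial step, √2 per diagonal step. Raw node counts are also
  reported (`*_node_count`). The package reports the weighted value as
  the primary feature because chain-code pixel counting systematically
  understates oblique segments — a 45° petiolule by ~29% — while the
  weighted length tracks true geometric length within a few percent at
  any orientation; on near-vertical paths (the rachis) the two
  conventions coincide.
- Undefined values (inter-rachis on a single-pair leaf, base-to-
  branching for a leaflet attached at the base) are explicit NaN /
  empty CSV cells, never 0.
- mm conversions use the effective dpi = scanner dpi × load-time scale
  factor; lengths are reported in post-rescale pixels plus mm.

## Landmarks

Eight landmarks on the terminal leaflet: apex (axis∩outline farthest
from the base, where the axis is the base→terminal-cut line), basal
point (axis∩outline nearest the base), the two endpoints of the longest
chord perpendicular to the axis, and the four intersections of the
±45° lines through the width-chord midpoint. The ±45° anchor at the
chord midpoint is a design choice (it reproduces a symmetric spread;
on a circle the construction degenerates to eight points 45° apart).
The width-chord search samples 600 axis positions and takes the center
of the near-maximal band (discrete outlines have a flat chord-length
profile near the maximum, so a plain argmax is unstable by several
pixels). Landmarks are emitted clockwise from the apex; TPS export
flips rows into Cartesian y so shapes are upright.

## Population summaries

- normalize: the unique 4-dof similarity transform base→(0,0),
  top→(0,1) (implemented with complex arithmetic; exact to machine
  precision). Two points cannot determine a general affine map, so the
  similarity transform is the only well-posed choice.
- metaleaf pools five marker classes: leaflet centers, cut nodes,
  branching nodes, base and top points; class centroids are arithmetic
  means of the pooled points.
- merged-feature PCA: whole-leaf features plus leaflet ranks 1..3,
  both sides; leaves lacking any of those ranks are excluded (logged).
  Columns are z-scored (sample sd) because the features mix px, px²
  and dimensionless units; constant columns are dropped. Loadings
  follow the sign convention that each component's largest-magnitude
  entry is positive.

## Synthetic benchmark

The generator emulates the architecture of a scanned dissected leaf:
a stroked vertical petiole and rachis (optionally curved), lateral
leaflet pairs attached through petiolules at a branch angle, elliptical
leaflets, a terminal leaflet at the apex; additive Gaussian intensity
noise; optional background fissure wedges cut into a leaflet. Defaults
describe realistic geometry at the working scale of a 600 dpi scan
rescaled to 25%: petiolules of 26 px, branch angle 50°, leaflet aspect
b = 0.6a. Anti-aliasing is off, so the ground-truth mask is exact;
rachis segments are auto-spaced (validated with shapely) so leaflets
never touch. The evaluation grid draws 50 leaves with 1–7 lateral
pairs, semi-major axes 8–40 px and stem widths 2–6 px — sizes chosen so
the full 50-leaf pipeline pass stays under a minute.

What passing these tests shows: the skeleton-graph cut algorithm, the
dissection, and the feature definitions are correct and robust over a
wide geometric range, including non-convex (fissured) leaflets, at
realistic noise. What it does not show: robustness to venation texture,
specular artifacts, overlapping or lobed (not fully dissected)
leaflets, color-calibration drift, or multi-leaf scans — real-scan
performance must be validated on real material.

## Numerical details

- All clustering (2-means, both Gaussian mixtures, PCA) runs with
  fixed seeds; batch outputs are byte-reproducible for a fixed
  config + seed.
- Ties: base node (max row, then min col); b1/b2 candidates (distance,
  then row, then column); cut index (first minimum).
- EM: 200 iterations, tol 1e-4, reg_covar 1e-8.
- Degenerate inputs: empty masks, all-equal distance values, coincident
  base/top, single-pixel leaflets and cycles without tips each raise a
  dedicated exception (see `leafdissect.errors`); the batch driver
  converts them to QC rows.

## Known limitations

- Bipinnate (second-order) dissection is out of scope; each path is
  assumed to cross the stem/blade boundary once.
- Leaflets that physically overlap in the scan merge into one
  component and cannot be separated by outline chords.
- The terminal-leaflet identification (graph-farthest cut node) can
  mislabel exotic architectures where a lateral extends beyond the
  apex.
- Landmark identities are construction-based, not anatomically
  homologous beyond the apex/basal pair; downstream Procrustes
  analysis treats them as fixed landmarks.
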