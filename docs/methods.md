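# Methods

This note records the models, rules and numerical choices behind
`rootanat`, and what the synthetic test bed does and does not establish.

## Image model and segmentation

The pipeline treats a micrograph as a single-channel intensity raster
`I` normalised to [0, 1] (RGB input is collapsed by ITU-R 601 luminance;
min–max normalisation maps a constant image to zeros so a blank input
produces an empty segmentation rather than an error). Stained sections
show dark cell-wall lines on a brighter background whose level drifts
across the slide with staining and illumination.

Segmentation is local: the difference image `Î = I − (I ⋆ M)` subtracts
from each pixel the mean of the `(2w+1)×(2w+1)` window centred on it,
and a pixel is foreground when `Î` exceeds a threshold `T` (strict
inequality). Defaults `T = 0.05`, `w = 12` suit micrographs of roughly
1000 px across a root; both are resolution-dependent tunables. Because
walls are dark, the default polarity applies the rule to the negated
image (equivalently `Î < −T`); a `polarity = bright_walls` setting
covers inverted stains. Window means are computed with running sums
(`scipy.ndimage.uniform_filter`); near the border the window is
truncated and normalised by its true pixel count, which avoids a
spurious foreground band there. The implementation agrees with a literal
double-loop evaluation to better than 1e−9 per pixel, and that agreement
is asserted in the test suite.

## Cell detection and recovery

The wall mask is dilated once with a 2×2 all-ones kernel anchored at its
top-left element (a single pixel grows toward larger row/column
indices); this closes 1-px wall leaks at the cost of shaving roughly one
pixel from two sides of every cell interior. Cells are maximal
4-connected background components that do not touch the image border
(partial border cells are unmeasurable); walls are implicitly
8-connected, the standard duality. Each cell's boundary is traced with
marching squares (`skimage.measure.find_contours`), its area is the
interior pixel count, and its eccentricity comes from the ellipse fit
described below.

Detected regions darker than one third of the mean region intensity are
discarded as lateral-root formations — their enclosed interiors are far
darker than cell lumina. The initial root boundary Γ_ini is the outer
contour of the filled union of the wall mask and all cell interiors
(largest connected component); the filled region mask itself is kept for
point-in-region tests, which are exact where polygon tests would wobble
on one-pixel inlets.

Faintly stained boundary cells fail the strict threshold, leak into the
outer background and are lost from the first pass. The recovery pass
re-segments at `T/2` — far too noisy for general detection but enough to
complete faint boundaries — and computes the Euclidean distance
transform `D` of the first-pass mask. Regional maxima of `D` (after
h-maxima suppression with h = 1 px, keeping peaks with
`D ≥ √(A_s/π)/2` to ignore sub-cell-scale structure) mark prospective
cell centres. A relaxed-pass cell is admitted only when such a peak lies
outside the Γ_ini region and inside that cell, the cell does not overlap
an existing one, and its interior passes the same darkness rule as
first-pass cells (otherwise the relaxed pass re-admits removed
lateral-root interiors). All other relaxed-pass regions are discarded,
first-pass cells are never removed, and Γ_final is recomputed over the
enlarged set. On intact synthetic roots the pass is a no-op and
Γ_final = Γ_ini exactly.

## Tissue classification

The cascade uses prior knowledge of root anatomy, not staining contrast:

1. **Epidermis.** Cells whose pixels come within ~4.5 px of the outside
   of Γ_final (2 px of wall plus the dilation bias, with slack) are
   perimeter cells. Sorted by increasing area (ties by id), the first
   80% are epidermis; the rest are taken to be cortex cells exposed by
   damaged epidermis. On pristine sections this deliberately sacrifices
   the largest fifth of true epidermal cells — the price of robustness
   to damage, and the dominant residual error on clean synthetic roots.
2. **Area gates.** Non-epidermal cells with area below `A_s` are
   segmentation noise and leave the analysis; between `A_s` and `A_l`
   they are "small", above `A_l` "large". Defaults 50 and 1000 px²; a
   parameter file may give only `A_s`, in which case `A_l = 33·A_s`, a
   ratio that holds across image resolutions. `suggest_A_l(d)` offers
   the empirical quadratic `0.0004d² + 0.668d − 112` of the root
   diameter, floored at `A_s` where the polynomial goes negative.
3. **Small-cell cluster.** Distances from small-cell centroids to their
   centre of mass are fitted with a Gaussian; cells within mean + 3σ
   form the stele/endodermis cluster. When small cells are also
   scattered through the cortex the distance distribution is bimodal;
   the fit is then restricted to the lower mode, split off at the
   dominant gap in the sorted distances. The gap must exceed the overall
   standard deviation and leave the majority below it — tight unimodal
   distance sets must not be split (Otsu thresholding was tried for this
   cut and misplaced it on small samples).
4. **Metaxylem.** A candidate vessel lies within the cluster's spatial
   extent, has area above the cluster mean + 2σ, and is completely
   surrounded by cluster cells: every cell sharing a wall with it
   (EDT adjacency within 4.5 px) is a cluster member or a fellow
   candidate, with members at least half. Adjacency, not centroid k-NN,
   because mutual candidacy otherwise lets a ring of large cortex cells
   certify each other. When candidates remain, the markedly larger mode
   is peeled off at the largest area gap (repeatedly, while the mode
   separation exceeds max(pooled σ, 20% of the mean)): maize protoxylem
   elements satisfy every other test but are several-fold smaller than
   true vessels. The stele centre is the area-weighted centroid of the
   metaxylem, falling back to the cluster centroid.
5. **Stele/endodermis candidates and refinement.** A cluster cell stays
   a candidate when the largest of its distances to its 5 nearest small
   cells is at most 50 px (all available neighbours are used when fewer
   exist); failures revert to cortex. The approximate endodermis
   boundary is the outer contour of the candidate union after a
   morphological closing with a disk of radius `neighbor_dist_max/2`
   (closing is computed via two Euclidean distance thresholds, which is
   fast and exact for disks). Large non-metaxylem cells wholly inside
   that region join the candidates (protoxylem and similar); cells with
   eccentricity above 0.9 whose centroid is within 10 px of the boundary
   join as well (flattened endodermal cells just outside the cluster;
   the distance is measured from the centroid). Finally a candidate
   reverts to cortex when more than half of its wall-adjacent cells are
   cortex — adjacency again, since centroid k-NN let distant-but-few
   neighbours outvote the true ring.
6. **Endodermis vs stele.** The candidate union is closed with the same
   disk and filled; members whose pixels come within 4.5 px of its
   outer contour are endodermis, the rest stele, a single member is
   endodermis by convention, and every remaining non-noise cell is
   cortex. The closing radius spans single missing members, so one lost
   endodermal cell does not pull interior stele cells onto the contour.

The cascade is deterministic: ties break by ascending cell id and no
stage draws random numbers.

## Maize extension

Protoxylem: large stele cells (non-metaxylem) whose centroid lies more
than half way along the ray from the stele centre to the stele boundary
— the outer contour of the stele∪endodermis region — are protoxylem.
The fraction is a ratio of collinear distances and therefore invariant
to uniform rescaling. Aerenchyma: the areas of large cortex cells are
fitted with a two-component Gaussian mixture (EM, k-means
initialisation, fixed seed so batch runs reproduce); the threshold is
`μ_larger − σ_larger`. The fit is declared degenerate — and no
aerenchyma reported — when a one-component fit has the better BIC or
the component means are separated by less than one pooled σ. Both
detectors are no-ops for wheat, where protoxylem is not distinguishable
and aerenchyma are absent.

## Morphometrics

Eccentricity uses an algebraic least-squares ellipse fit
(`skimage.measure.EllipseModel`), with a second-moment fallback for
degenerate inputs; `E = √(1 − b²/a²)` with `a ≥ b` enforced by swap.
Fewer than 5 points or collinear points are an error.

The summary table covers whole root, cortex, stele, endodermis and
metaxylem (maize adds protoxylem and aerenchyma): total area, cell
count, mean cell area and mean cell eccentricity, with whole-root and
stele eccentricities from Γ_final and the endodermis contour. All
internal geometry is in pixels; the µm scale enters only at reporting
time (areas × scale²). The stele's total area is the area enclosed by
the endodermis outer contour — walls included, matching how the region
reads visually — while cell-level areas always exclude walls; with one
metaxylem the "mean" fields are that cell's values.

Cheesewheel statistics: the stele zone spans from the stele centre to
the endodermis contour, the cortex zone from that contour to Γ_final.
Along each ray the span is divided into 6 annuli of equal radial
fraction (linear interpolation between the two bounding contours, which
need not be concentric); wedges are six 60° sectors anchored at
image-east, counter-clockwise — equal angle, one of the two readings of
"equal wedges", fixed and documented. Cells are assigned by centroid,
epidermal cells belong to neither zone, and each zone cell lands in
exactly one of its 36 regions.

## Synthetic roots and what the tests show

The generator builds concentric anatomy in polar coordinates: a central
metaxylem disc (wheat, radius 28 px) or a polyarch ring of vessel discs
plus peripheral protoxylem discs (maize), stele rings of small cells,
one endodermal ring of flattened cells, cortex rings of large cells and
an outer epidermal ring, out to a root radius of 222 px (wheat defaults;
images ~512 px). Ring cells are angular sectors with edges jittered by
up to 12% of the sector width so areas vary; the outermost stele ring is
20% thinner and denser, like the small cells bordering the pericycle.
Walls are the 2-px lines where cell identity changes, rendered at a
contrast of 0.20 below the local background; the background is 0.65 plus
a linear horizontal gradient (default amplitude 0.15) plus clipped
Gaussian noise (default σ 0.01). That wall contrast overlaps the
background range once the gradient reaches ~0.3, so a single global
threshold provably loses the bright-side walls while the local rule
keeps them — the regression the generator exists to exercise.

Degradations: `break_probability` renders, for selected epidermal cells
(at least one when the probability is positive), an 8–14 px arc of the
outer wall at a depression of 0.05 — calibrated so the local difference
at those pixels falls between `T/2` and `T`, i.e. invisible to the first
pass and recoverable by the relaxed one; a fully erased wall would be
unrecoverable and does not represent weak staining. `lateral_root`
attaches a dark elliptical blob to the perimeter. Vessel discs that
would overlap raise a validation error.

Ground truth records the per-pixel cell identity, wall mask, tissue
labels, boundaries and per-tissue statistics. Scoring matches each
planted cell to the detected cell that best overlaps it; unmatched
planted cells count as errors. On default wheat roots the pipeline
detects 100% of planted cells with a mean area error of ~9.6% —
dominated by the deterministic one-pixel shave of the 2×2 dilation plus
wall staircase effects on curved boundaries, not by noise — and labels
~95% of cells correctly, the remainder being the deliberate 20%
epidermis sacrifice. The generator's cells are convex angular sectors
with clean walls and planted size ratios that satisfy the cascade's
assumptions by construction; real sections add irregular cell shapes,
partial tears, debris, and size distributions that can violate those
assumptions, so synthetic accuracy is an upper bound and a correctness
check of the rules, not a field-performance estimate.

Problem sizes in the tests and the acceptance script — 64×64 filter
oracles, 3 segmentation roots, 10 detection and 10 recovery roots, 20
classification roots, one maize ray fixture — are chosen so the full
cycle completes in a few minutes while every rule is still exercised at
realistic cell counts (~160–200 cells per root).

## Known limitations

- Root fragments fully separated from the main body are not reconnected;
  only the largest connected component is analysed.
- The epidermis percentile rule mislabels ~20% of true epidermal cells
  on undamaged sections by construction.
- The 10-px endodermis-proximity rule measures from the cell centroid,
  not the nearest boundary point; very large flattened cells could slip
  through.
- Parameters are resolution-dependent; `A_s`, `A_l` (and the 33× ratio
  or the quadratic diameter rule) must be rescaled for image sizes far
  from ~1000 px per root.
- Aerenchyma detection needs at least two large cortex cells and a
  genuinely bimodal area distribution; gradual lacuna formation below
  the mixture's resolution is reported as ordinary cortex.
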