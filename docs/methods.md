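# Methods

## Image model and assumptions

The pipeline assumes a 2-D view of a tissue surface (a single plane or a
maximum projection) in two registered channels with isotropic pixel size:
a wall channel in which cell walls are bright, connected ridges enclosing
every measurable cell, and a puncta channel in which PD-associated callose
appears as diffraction-limited spots located on or near walls. Intensities
are arbitrary units, finite and non-negative. There is no 3-D (z-resolved)
analysis and no montage stitching.

## Wall network

**Mask.** The wall channel is Gaussian-smoothed (`wall_smoothing_sigma`,
default 1 px) and thresholded. The default threshold is Otsu's global
threshold on the smoothed channel; a fixed value can be configured, and a
polarity flag handles walls dark on bright. A constant image is rejected
("no wall signal") rather than silently producing an empty mask.

**Skeleton.** The mask is thinned with a topology-preserving skeletonization
and then post-processed in two deterministic passes that are iterated to a
fixed point (at most 3 rounds):

* *simple-point cleanup* — parallel thinning leaves staircase/triangle
  corner pixels that carry no connectivity but read as branch points. A
  pixel is removed when its skeleton neighbours remain one 8-connected
  group without it **and** exactly one local background 4-component touches
  one of its edge neighbours (the classical simple-point criterion; the
  second clause keeps the degree-4 crossing pixel, whose removal would open
  a one-pixel hole). The pass runs in row-major order and only visits pixels
  inside 2×2 blocks with ≥ 3 skeleton pixels, so straight runs are skipped.
* *spur pruning* — dead-end chains strictly shorter than `prune_length_px`
  are removed. The default is 5 px: frame corners and shallow junctions
  leave 3–4 px thinning tails, while real wall segments produced by the
  generator are ≥ 8 px, so 5 px cannot remove a genuine wall. Dead-end
  chains at least as long as the prune length are kept as genuine dead-end
  walls.

**Junctions.** Branch pixels (≥ 3 skeleton neighbours in 8-connectivity)
are clustered by 8-connectivity; clusters joined by skeleton chains of at
most `junction_merge_gap_px` (default 3 px) are merged, the connecting
pixels absorbed into the junction. This absorbs the 2–3 px split that
thinning produces at fat junctions (degree-4 crossings, shallow angles)
while staying below the shortest legitimate wall chain. Degree-4 crossings
are admitted as single junctions and recorded identically to tri-junctions.

**Walls and cells.** Removing junction pixels disconnects the skeleton;
each remaining 8-connected chain is ordered end-to-end (preferring
4-connected continuations so corner pixels are not skipped) and becomes one
wall segment carrying its terminal junction ids; a junction-free loop is a
single closed-loop wall. Lengths are step sums (1·px orthogonal, √2·px
diagonal; closed loops include the closing step; a single-pixel wall has
length 0 and a flag). Cells are 4-connected components of the skeleton
complement, excluding every component touching the image border (clipped
cells are not measurable); 8-connectivity for the skeleton with
4-connectivity for regions prevents diagonal leakage through 1-px walls.

## Puncta

The puncta channel is smoothed (default 1 px) and background-subtracted by
grey-scale morphological opening with a disk (default radius 15 px) — the
flat-structuring-element equivalent of a rolling-ball background — then
clipped at 0. Strict local maxima above a threshold are detected; plateaus
collapse to their centroid; greedy non-maximum suppression in order of
decreasing intensity (ties: smaller (row, col) first) enforces
`min_separation_px` (default 3). The detection threshold defaults to an
automatic robust estimate, median + 5·σ with σ from the median absolute
deviation of the preprocessed channel, and can be fixed via
`min_peak_intensity`. Positions are refined by a 3×3 intensity-weighted
centroid (≈ 0.3 px RMS at zero noise on rendered spots). Peak and
integrated intensity (disk of `integration_radius_px`, default 3) are
measured on the **raw** channel so totals stay comparable across images
whatever the background settings; a disk clipped by the image border sets a
`clipped` flag.

## Relational graph

Punctum → wall: nearest wall-path pixel by Euclidean distance (k-d tree over
all wall pixels, exhaustive tie resolution to the lowest wall id); puncta
farther than `parent_search_tolerance_um` (default 0.5 µm, about one
diffraction-limited punctum radius) from every wall are orphans, retained
and reported. Wall → cells: per wall pixel, the distinct cell labels among
its 8-neighbours vote; the two strongest labels are the adjacent cells,
`BORDER` standing in when only one interior cell is adjacent; a third label
supported by more than 25 % of the wall's pixels indicates a segmentation
failure and raises an integrity error. Junction → walls is the inverse of
the wall endpoint map; junctions left with fewer than three walls are kept
but flagged. After assembly the graph is validated: punctum conservation
(assigned + orphans = detected), mutual consistency of the wall↔cell and
wall↔junction maps, and distinctness of the two cells across a wall.

## Quantification conventions

* Wall mean callose intensity = mean of the puncta channel over the wall
  path dilated by 1 px (a 3-px-wide periphery band), measured on the raw
  channel.
* Per-cell periphery callose = sum of the cell's walls' means; PD counts and
  periphery lengths sum the same way. A shared wall contributes fully to
  both cells — a plasmodesma is a channel of both — so summing per-cell PD
  over all cells counts interior-wall puncta twice by convention (stated in
  the output headers and asserted in the tests).
* PD density per wall = n/L; zero-length walls report density 0 with a flag.
* Immunogold density = particle count / window area, window defaulting to
  the standard 0.025 µm² delineated around a plasmodesma.
* Coordinates in outputs are 0-based (row, col) pixel centers; lengths and
  areas are µm and µm² via the pixel size; channel order (wall first) is
  fixed.

## Cohort statistics

Per group: percent bud break = 100·n_broken/n_total; mean day; sample
variance with n−1 denominator (cohorts are 10–15 plants); CV = sd/mean as a
dimensionless ratio. Variance and CV are emitted side by side under
explicit column names because prose accounts frequently interchange them.
Histograms use left-closed, right-open bins from ⌊min⌋ with a configurable
width; counts always sum to the number of events. Plants that never broke
bud enter n_total only.

## Synthetic tissue (what it emulates, what it does not)

`make_tessellation(nx, ny, jitter, cell_pitch, pixel_size, seed)` builds a
Voronoi tessellation of a jittered rectangular lattice (uniform jitter of
±`jitter`·pitch per coordinate; jitter 0 is the exact square lattice, whose
degree-4 crossings serve as a stress case). The frame is the outer boundary
of the union of the nx·ny core cells. Voronoi vertices closer than 8 px are
snapped to their centroid: a jittered lattice is near the degenerate square
configuration, so quads of almost-cocircular seeds otherwise produce pairs
of tri-junctions separated by sub-resolution edges; snapping collapses them
into single degree-4 junctions, which the graph admits. Default geometry:
8 µm cell pitch at 0.25 µm/px (32 px across a cell, typical of a confocal
meristem-surface image), 2 µm margins.

A tessellation is rejected as **unresolvable** — and the jitter redrawn, up
to 40 deterministic attempts from the seeded generator — when its rendering
could not be segmented by *any* faithful method at the requested resolution:
a wall segment shorter than 8 px, walls meeting a junction or an interior
polyline vertex at under 45° (the rendered ridges would stay merged past
the junction, i.e. run closer than ~3 px), or a cell with a wedge/neck
thinner than the rendered wall width (tested by morphological opening of
the cell polygon at the wall half-width: it must stay one piece with only
corner-sized area loss). All checks are purely geometric.

`place_puncta(gt, rate, min_gap, seed)` places puncta along each wall as a
stationary hard-core renewal process: gaps are `min_gap + Exp` with the
exponential mean chosen so the mean gap is exactly 1/rate, and the first
punctum is drawn from the equilibrium forward-recurrence distribution, so
the expected count per wall equals rate·length exactly while no two puncta
on a wall are closer than `min_gap` (default 1 µm, resolvable at the
default detection separation). A thinned homogeneous Poisson process would
systematically under-shoot the nominal rate, which is the quantity the
density-recovery checks compare against. A final global greedy pass
enforces the gap across walls; it removes a small fraction of puncta near
junctions (≈ 5–8 % at 0.5/µm), which is why pooled density is checked
through the pipeline's own length measurement rather than against raw
placement counts.

`render(gt)` draws wall polylines at the configured width (default 3 px),
blurs with a Gaussian PSF (default σ 1 px), adds puncta as Gaussian spots
(default σ 1.2 px, amplitude 200) whose stated amplitude is the rendered
peak, then background (default 10) and additive Gaussian read noise, clipped
at 0. Identical seeds give identical ground truth and renders.

**Limitations.** The generator emulates flat tessellations with straight
walls, uniform wall brightness, spatially uniform Gaussian noise and
in-focus puncta. It does not model curved meristem surfaces, uneven
staining, wall-channel bleed-through into the puncta channel, Poisson shot
noise (a documented extension) or out-of-focus light. Passing recovery
tests therefore demonstrate correctness of the graph/quantification
machinery under controlled degradation, not segmentation performance on
arbitrary microscope data; on real images the preprocessing parameters are
the knobs that matter.

## Numerical and design choices

* Equidistant punctum between two walls → lower wall id (deterministic,
  measure-zero). Equal-intensity competing maxima → smaller (row, col).
* Puncta within 2 px of a junction are legitimately ambiguous between the
  junction's walls; ground-truth parentage checks exclude that zone.
* Automatic detection threshold (median + 5·MAD-σ) holds the false-positive
  rate of pure-noise maxima near zero per image at the default sizes while
  detecting SNR-5 spots after smoothing; at very low SNR a fixed threshold
  is preferable.
* Recovery test problem sizes: tessellations of 2×2 … 10×10 cells (images
  up to ≈ 360 px) with 3 seeds per size/jitter; spot-calling pools ≥ 500
  puncta over 4 seeds of a 6×6 fixture; density recovery uses two 8×8
  fixtures (≈ 1000 puncta). These sizes give the counts the binomial/Poisson
  tolerances in the tests need.
* Input is multi-page TIFF (wall page first) with the pixel size from the
  resolution tags (µm assumed; a 1 px/unit tag is treated as unset) or an
  explicit override — never a silent default. Proprietary microscope
  containers should be converted to TIFF upstream; a conversion hook is out
  of scope.
* The batch pooled summary weights per-image means by cell counts (it is
  the plain mean over all cells of a condition), so pooling order cannot
  change the result.
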