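# Methods

This note records the models, numerical choices and known limitations of
the package, at the level a maintainer or reviewer needs to interpret its
output.

## Coordinate and unit conventions

Voxel indices are 0-based `(i, j, k)`; physical coordinates follow a
diagonal NIfTI affine, `origin + index * spacing`, with all lengths in
mm. Phantoms use isotropic 1 mm spacing, so voxel units and mm coincide
there. The DFM is dimensionless and scale invariant.

## Cost fields

**DFE** is the Euclidean distance transform of the mask with anisotropic
sampling, measured voxel-center to voxel-center: an isolated object voxel
has DFE 1 (its nearest background neighbor), the center plane of a
7-voxel slab has DFE 4.

**MDFE.** The published refinement lives in earlier work of the same
group and its exact formula is not restated here; this implementation
preserves its stated purpose — deterministic tie-breaking between
equal-DFE neighbors using local spatial information. Base cost is
`max(DFE) − DFE`. The tie term is proportional to the inverted
neighborhood mean DFE over the full 3×3×3 box, with background and
out-of-volume neighbors counting as depth 0 (so a voxel deep inside
scores higher than an equally deep voxel near an edge even when all its
object neighbors tie), and is scaled to half the smallest gap between
distinct base costs — it can reorder ties but never distinct DFE levels.

**COM / DFE-COM.** Each object voxel carries a continuous position
initialized at its center (mm). Per iteration every position moves to the
(optionally DFE-weighted) mean of the positions of its 26-neighborhood
*including itself*, using the previous iteration's positions throughout
(synchronous, Jacobi-style update — the neighborhood-inclusion and
synchronicity choices are recorded here because the collapse is otherwise
order dependent). Travel distances accumulate over 30 iterations
(sufficient for every object size used here); the cost is
`(travel / min positive travel)³`, with "min positive" taken over the
whole segmentation after excluding travels below 1e-12 (numerically
zero); a voxel that never moved gets cost 0, and a single-voxel object
yields a uniform zero field with a warning. DFE weighting gives deep
voxels more pull, which keeps the collapse on the vessel axis near
junctions — the reason DFE-COM is the measurement default.

## Centerline extraction

Edge weight between 26-neighbor object voxels is the mean of their two
costs times the physical step length — symmetric and spacing-aware; the
mapping from node costs to edge weights is a design choice, recorded
here. Dijkstra runs over the sparse voxel graph (SciPy's compiled
implementation; deterministic); voxels disconnected from the goal are
flagged unreachable.

The goal node defaults to the minimum-cost voxel, ties broken by
proximity to the mask centroid then lexicographically. On the comb
phantom this minimum falls mid-tooth (the locally most symmetric tube
segment) rather than on the spine; branch decomposition is unaffected by
which interior voxel wins.

Tree extraction repeatedly takes the unclaimed voxel with the longest
physical path to the goal, traces its parent chain to the first claimed
voxel or the goal, and claims the traversed voxels plus a ball of the
local DFE radius around each, so one artery yields one branch rather than
a bundle of parallel ones. A candidate branch is emitted only if longer
than `prune_factor × DFE` at its attachment point (default factor 3).
Pruning against the attachment radius rather than the tip radius is a
deliberate deviation from the first design sketch: surface whiskers
attach to thick vessels and are pruned by the vessel's own radius, while
genuine thin side branches attach with comparable length and survive;
with tip-DFE pruning, diagonal two-step whiskers (length 3.46) on noisy
masks survived a 3×1-voxel threshold and inflated branch counts.

Path coordinates are smoothed with a 3-point moving average before
lengths are computed. A raw 26-connected voxel path overestimates the
length of the smooth curve it digitizes by 5–10 % (staircase effect); the
3-point window reduces this to under 1 % and, on a simple path, provably
keeps cumulative length strictly increasing (consecutive smoothed points
coincide only if voxels three apart coincide). Voxel indices are kept
unsmoothed for accuracy/stability scoring.

## Tortuosity measurement

`L` accumulates smoothed-segment lengths; `d` is the chord to the path
start; DFM at the start (where both vanish) is defined as 1. Peak search
excludes points with `d` below two voxel diagonals, where `L/d` is
near-singular — the singularity at the path origin is not addressed in
the source description, so the floor is recorded here; the discrete curve
is searched without smoothing of the DFM values themselves. Curves export
in long CSV form with both `L` and `d` columns so either can serve as the
x-axis.

For the helix `h(t) = [r cos t, r sin t, p·t/2π]` the continuous curve
peak has the closed form `sqrt(r² + c²)/c` at each full turn
(`c = p/2π`), used as an independent anchor in tests: measured voxel
pipelines land within a few percent, slightly low because coordinate
smoothing removes staircase length.

## Statistics

Rank-sum comparisons use the exact null distribution for combined n ≤ 25
and the tie-corrected normal approximation beyond (the variant is
recorded per test in the report). The paired signed-rank, one-way ANOVA
and two-sided variance-ratio F test are standard SciPy/closed forms. The
multiple-comparison threshold is Bonferroni, `β = α/n` (0.05/8 = 0.00625;
0.05/13 ≈ 0.0038). Tests with insufficient data are flagged per test, not
raised.

## Phantoms: what they emulate, and what they do not

Phantoms are rasterized by marking voxels whose centers lie within the
tube radius of the densely sampled curve (< 0.5 voxel between samples); a
distance transform pre-screens the grid and a KD-tree resolves the
boundary shell against the continuous samples, so mask voxels are within
the tube radius plus rasterization slack (half a voxel diagonal) of the
curve. Ground truth is the nearest-voxel discretization, deduplicated and
26-connected per branch.

Standard geometries:

- **Helix family** — radius 100 voxels, tube radius 6, pitches
  5/10/20/40 ×2π with 8/4/2/1 turns. The turn counts halve as pitch
  doubles so all four tubes span the same axial extent (~251 voxels),
  matching their stated approximate coil counts; pitch is stored in the
  same units the parametric formula uses, so `z` rises by `p` per turn.
- **Comb** — spine 100, five teeth of 40 at spacing 20, tube radius 3.
  Teeth attach at `x = 0, 20, …, 80`, leaving a handle beyond the last
  tooth; the shape then has six leaves (one spine end plus five tooth
  tips) and decomposes into exactly six branches from any interior goal.
  The originally published comb dimensions are not stated anywhere, so
  absolute accuracy/stability numbers for it are treated as ordering
  anchors, not exact targets.
- **Y-branching** — a trunk and two arms (lengths 40, ±40°) lying flat in
  the x–y plane, standing in for the published branching phantom whose
  mesh is unavailable; tube radius 3, with additive Gaussian noise SD 10
  or 20 for the noise series.

**Imaging realism.** Noise-free phantoms are exactly two-valued
(foreground 200, background 0 — arbitrary but recorded). Phantoms that
model an acquisition (`noise_sd > 0`) are first blurred with a Gaussian
point-spread of 1 voxel, then i.i.d. Gaussian noise is added and clipped
at zero. The blur is essential, not cosmetic: ZBS sets its growing
threshold at the 20th percentile of seed intensities, and seeds are
per-column brightness *maxima*, so on a perfectly homogeneous tube the
threshold lands above the foreground mean and region growing shatters
into speckle. The partial-volume falloff at real vessel rims is what
pulls low-percentile seed intensities below the core intensity; the PSF
reproduces that mechanism. What phantoms still do not emulate: flow
artifacts, coil sensitivity profiles, vessel-intensity heterogeneity, and
anatomy — so passing phantom tests demonstrates correctness of the
geometry pipeline, not clinical robustness.

**Known limitation (kept as a failing bound).** Even with the PSF, the
seed-maxima percentile threshold exceeds the mean tube intensity, and the
directional hole filling cannot fill surface-connected dropouts (a pit on
a flat face sees only 17 of 26 directions). At noise SD 20 the voxel-wise
Dice overlap of ZBS against the full true tube therefore plateaus far
below the 0.95 aspired to in the acceptance suite (~0.5–0.7 measured);
the corresponding test is left failing rather than weakened. The
downstream quantities the segmentation exists for — branch counts,
centerline RMSE, stability — are unaffected at these noise levels,
because the captured core is solid and on-axis.

## Validation metrics

RMSE is directed (computed → truth), since truth is densely sampled while
an extracted centerline may legitimately stop short of tube caps.
Stability is the mean over run pairs of the symmetric fraction of voxels
of one run within a tolerance (default 1 voxel) of the other — the
original stability formula is not published, so this tolerance-overlap
definition is recorded as a package choice and stability values are
comparable only within this package. Alternative goals for stability runs
are drawn deterministically (seeded) from voxels with DFE ≥ 80 % of
maximum.

## Problem sizes and determinism

The acceptance script runs the helix experiments at full scale
(~0.6 M object voxels for the tightest helix, ~13 M voxel grids, about a
minute total on one CPU); the test suite uses geometrically half-scale
helices, which the DFM's scale invariance makes score-equivalent. All
computations are deterministic given the phantom specification and noise
seed; cost fields are bit-reproducible.
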