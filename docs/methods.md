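# Methods

This note records the models implemented in `espsim`, the defaults and
the reasoning behind the genuinely open design choices. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Grids and conventions

All rasters share one projected frame: square cells, row 0 at the top,
`origin` at the upper-left corner. Areas are cell counts ×
cell_size²/10⁶ km² (1 hm² = 0.01 km²); nodata cells are excluded from
every area and zonal statistic. No reprojection is implemented — the
method operates on a single co-registered stack, and resampling beyond
nearest-neighbor block replication is out of scope. GeoTIFF files carry
the geotransform in the ModelPixelScale/ModelTiepoint tags; the ESRI
ASCII grid is supported as a plain-text interchange format. Categorical
rasters round-trip bit-faithfully as integers.

## MSPA

The ecological foreground is woodland + grassland (the 6-class legend
cannot isolate "high-coverage" grassland, so the class list is a config
knob). Edge width is measured in erosion iterations with the 3×3
structuring element, i.e. Chebyshev distance; the default width 1 equals
30 m at the working resolution. Cells outside the grid count as
background.

Pixel classes: *core* = foreground farther than the edge width from
background; *islet* = an entire 8-connected component with no core;
*edge*/*perforation* = non-core cells within the edge width of a core,
split by whether the nearby background is outer (reachable from the grid
border, 4-connected) or an enclosed hole — outer wins when both are in
reach; the remaining residue components are *bridge* (contacting ≥ 2
distinct core regions, directly or through their edge zones), *loop*
(one core contacted at ≥ 2 separate stretches) or *branch*. A literal
"everything within edge width of background" reading of edge would leave
no connector pixels at all (non-core cells are by definition that close
to background), so the boundary zone is anchored on cores, which is the
published MSPA geometry. Tests pin the 7-way partition, the
erosion-oracle equivalence and monotonicity in the edge width, not
subclass identity on pathological shapes.

## Connectivity (PC / dPC)

Patch-to-patch distance is the minimum Euclidean distance between
boundary-cell centers (0 for touching patches). The distance
threshold/probability pair (1500 m, 0.5) parameterizes a
negative-exponential kernel p(d) = exp(−kd), k = −ln 0.5/1500; a
hard-threshold mode (p = 0.5 within range, else 0) is available because
the original tooling's kernel choice is not documented. Best-path
probabilities are shortest paths on −ln p edge weights; direct
probabilities below 1e-9 are pruned.

AL defaults to the sum of habitat-patch areas (the verbatim "total area
of all patches"); the total-landscape-area convention of the reference
software is a constructor argument. Under patch removal AL is held
fixed — only paths through the removed patch are lost — which keeps
dPC within [0, 100] and makes the dPC > 1 source rule scale-meaningful.

Sources = cores ≥ 100 hm² with dPC > 1, plus water bodies > 100 hm² that
are not rivers. A water patch counts as a river when its elongation
(principal-axis length² / area, in cell units) exceeds 10, or when it
intersects a designated river mask.

## Resistance, corridors, gravity

Resistance = 0.7 × land-use score + 0.3 × relief score. Land-use scores:
woodland 1, water 1, grassland 30, arable 50, unused 90, construction
100. Relief scores by focal range bins (left-closed): [0, 8) → 90,
[8, 17) → 70, [17, 27) → 50, [27, 37) → 30, [37, 50) → 10, ≥ 50 → 1 —
flat open terrain resists forest-species dispersal most. Cost distance
uses the common discretization of the minimum-cumulative-resistance
path sum: step cost = mean of the two endpoint resistances × step length
(cell_size orthogonally, ×√2 diagonally), solved by Dijkstra on the
8-connected lattice with a virtual zero-cost super-source.

Corridors are least-cost boundary-to-boundary paths for every source
pair. Gravity importance G = [ln Sᵢ/Pᵢ][ln Sⱼ/Pⱼ](L_max/Lᵢⱼ)² with Sᵢ
the patch area in hm² (so ln S > 0 for ≥ 100 hm² sources), Pᵢ the mean
resistance over the patch's cells, and L the cumulative path cost;
touching patches (L = 0) get G = +∞ and are always kept. The printed
algebra of the gravity formula in the source literature is internally
inconsistent; the definitional form above matches its verbal meaning
(stronger interaction ⇔ lower normalized resistance). Selection keeps
the top-k corridors by G (k = 14 by default, matching the study's final
corridor count on real data) and always adds a maximum-G spanning forest
so no source is isolated. Selected paths are buffered 100 m (the width
of urban protective forests); water components longer than 5000 m with
mean width (area/length) over 30 m join as river corridors.

Node selection in the original workflow was expert judgment; the
rule-based surrogate takes the top-n (default 7) non-source core patches
by area, optionally within a distance of the selected corridors, with a
lower candidate area floor (default 10 hm²) so genuinely small stepping
stones qualify. Sources ∪ buffered corridors ∪ rivers ∪ nodes form the
restricted mask.

## Demand

The transition matrix is the observed cell cross-tabulation between two
epochs (identity rows for absent classes). Projection raises it to
horizon/interval: integer powers exactly; fractional powers via the real
matrix root, falling back to integer-step powers with linear count
interpolation when the root leaves the stochastic simplex (fractional
roots of stochastic matrices need not be stochastic). Demands are cells,
rounded by largest-remainder apportionment so they sum exactly to the
valid-cell total.

## Suitability and allocation

Suitability: an MLP with one hidden layer (12 units by default) fitted
on a uniform seeded sample (5 % by default) of cells — factor vector in,
observed class out — with softmax probabilities renormalized over the
six classes. The sampling rate, hidden size and iteration budget are not
documented in the source workflow; the defaults here are deliberately
modest and are config fields.

Allocation iterates synchronous sweeps. Per cell and class the joint
score is suitability × neighborhood effect × inertia × transfer
permission, zero for restricted cells and banned conversions. The
neighborhood effect is the class share in a 3×3 Moore window (center
excluded) scaled by the class weight (arable 0.1, woodland 0.23,
grassland 0.35, water 0.5, construction 1, unused 0.4) and floored at a
small epsilon (10⁻³ of the weight) so spontaneous emergence is possible.
Each convertible cell of an over-supplied class draws one class by
roulette; proposals are visited in seeded random order and committed
only while the target class is under- and the source class over-supplied,
so counts approach the demand monotonically and never overshoot. The
adaptive inertia of a class follows the standard rule (unchanged while
its residual does not worsen; boosted/damped by the residual ratio when
it does). Because the commit rule prevents the oscillation that drives
that rule, a separate competition-escalation factor doubles the roulette
weight of a still-unmet class after every sweep that brought it nothing,
and resets on success — this is a numerical convergence device, not a
model change: it only reweights the draw among already-legal moves.
Classes whose demand is met are excluded from the draw. A run stops at
tolerance (0 cells by default), at the iteration cap (500), or after 60
consecutive empty sweeps, which past the escalation ramp indicates the
demand is infeasible under the constraints; residuals are then reported
as diagnostics. Infeasible demand is expected, not exceptional, under
the ecological scenario: demand extrapolated from an unconstrained past
cannot always be met once woodland/grassland conversions are banned and
the ESP is frozen — the reported shortfall *is* the restriction effect.

Scenario definitions: *natural* = the permissive transfer table, no
restricted area; *ecological* = the stricter table (woodland may only
stay or become grassland; grassland may not become arable) plus the ESP
restricted mask. Determinism: one seeded generator drives each run; the
pipeline fans a single global seed out to per-stage seeds by fixed
offsets so stages can be re-run in isolation.

## Metrics and validation

AI carries units km²/yr ((A_end − A_start)/d on km² areas); AGR is the
compound rate in %/yr. Quadrants split at the N–S/E–W axes through the
construction center of gravity (2018-epoch convention); axis ties join
the counter-clockwise-first quadrant. Rings are 5-km bands (12 by
default); cells beyond the last ring are labeled "outside" and excluded.
Validation samples 10 % of valid cells (seeded), builds the 6×6
confusion matrix and reports overall accuracy, per-class recall and
Cohen's kappa.

## Synthetic data: what it does and does not emulate

`generate_landscape` thresholds per-class Gaussian-filtered noise fields
(argmax after an iterative bias calibration) to hit target class shares
within ±2 % of cells. The default correlation range (18 cells ≈ 540 m)
is chosen so that, at the default 200×200 extent, woodland forms the
contiguous multi-hundred-hectare massifs on which source selection
operates in real landscapes; the default shares describe a peri-urban
mosaic (30 % arable, 30 % woodland, 10 % grassland, 10 % water, 15 %
construction, 5 % unused). `evolve_landscape` applies a known
row-stochastic matrix per epoch; with the spatial kernel on (default),
each row's conversion mass is redistributed toward classes present in
the 5×5 window — stay probabilities are preserved exactly, so the
kernel-off (i.i.d.) mode is the verifiable limit used by the
parameter-recovery tests. The default evolution matrix encodes gentle
urbanization with construction nearly absorbing. `generate_factors`
builds the nine driving layers with planted, recoverable signal (night
light and density smoothed from construction; elevation raised under
woodland; distance fields from the actual water/construction masks).
The relief operator is a focal range; the default 3×3 window is the
smallest Moore window, consistent with the 8-neighbor convention used
throughout (the source workflow does not state its focal window).

What passing tests therefore show: the algorithms are correct against
independent oracles and the pipeline's constraints are enforced
exactly. What they do not show: realism of any particular map. The
synthetic landscapes lack anisotropy, road-network geometry, planning
shocks and class-boundary mixing of real imagery, and at 36 km² the
absolute patch statistics (source areas, corridor counts) are
necessarily far below the published study's 3349 km² values — the
structural comparisons (scenario ordering, constraint audits, hindcast
skill above a constant-map baseline) are the meaningful checks at this
scale. Problem sizes used: 200×200 cells for the end-to-end runs and
acceptance script, 245×245 for Markov parameter recovery (≈ 10⁴ cells
per class), ≤ 400-cell grids for exact shortest-path oracles, ≤ 6
patches for exhaustive path enumeration.

## Known limitations

* Connector subclassing (bridge/loop/branch) uses contact-region
  counting rather than full skeleton analysis; degenerate shapes may be
  labeled branch where a topological loop exists.
* dPC is recomputed by patch deletion (O(n) shortest-path solves); fine
  for the tens of patches the source rule produces, not tuned for
  thousands.
* The allocator's demand satisfaction is exact only when the demand is
  feasible under the transfer/restriction constraints; otherwise it is
  best-effort with reported residuals (by design).
* Night-light inter-calibration across sensor generations is not
  modeled; synthetic factors stand in for all drivers.
* The calendar (epoch years, 2030 horizon) is a config concern; epochs
  are abstract t0, t1, t2 internally.
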