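# Methods

This note documents the models and procedures implemented in
`patchconnect`, the assumptions behind them, the defaults and why they were
chosen, and the known limits of what the synthetic tests demonstrate.

## Scoring and weighting

Landscape perception is encoded as two independent expert score systems on
the same 1–10 integer scale: habitat quality (suitability model, eight
variables) and movement resistance (cost model, seven variables).  The two
variable sets deliberately differ: NDVI and distance to river enter only the
suitability model (their effect on movement is ambiguous — attractive
forage can either hold animals in place or be irrelevant to transit), while
distances to settlements and individual houses replace coarse human-density
grids in the cost model, where fine-scale human presence matters most.
An N/A entry in a rule table is a **barrier**: absolute behavioral
avoidance.  Barriers are distinct from nodata (no information): barrier
cells are excluded from habitat and removed from the movement graph, nodata
merely propagates through every operation.

**Rule-table bins.**  Published class boundaries are printed as touching
ranges ("250–500", "500–1000") without inclusion rules.  The package
declares one convention — closed lower bound, open upper bound `[a, b)`,
with `< x` = (−∞, x) and `> x` = [x, ∞) — so the bins of every table tile
the variable's domain exactly; tiling is validated at load and a sweep test
confirms every bin is reachable.  Which side a boundary value such as
3200 m fell on in the original ArcGIS runs is unknowable; the convention is
declared, not inferred.

**AHP weights.**  `compute_weights` implements Saaty's eigenvector method:
power iteration on the positive reciprocal comparison matrix (convergence
when successive L1-normalized iterates differ by < 1e-10 in max norm, cap
10,000 iterations — the Perron eigenpair of a positive matrix makes this
safe), λ_max from the iterate's Rayleigh sum, CI = (λ_max − n)/(n − 1), and
CR = CI/RI(n) with Saaty's published random indices for n ≤ 10.  CR is 0
by definition for n ≤ 2 (2×2 reciprocal matrices are always consistent).
The expert matrices behind the shipped gazelle weights were never published,
so the defaults are the published weight vectors themselves; AHP is exposed
for user-supplied matrices.  The published cost-weight row sums to 1.0001
(printing residue); `WeightSet` renormalizes every weight vector to sum to
exactly 1, so overlay outputs stay within [1, 10].

## Surfaces and patches

The overlay is a pointwise convex combination of the score grids, with
barrier dominance: a barrier in any input is a barrier in the output,
regardless of that variable's weight — N/A means "never", not "weighted
penalty".  The original workflow modeled suitability at 250 m and cost at
30 m; here resolution is a per-surface config parameter, and inputs are
resampled by nearest neighbor (which preserves integer scores; the original
resampling rule was not documented).

Patches are 8-connected components of cells strictly above the suitability
threshold (default 9.50) that cover strictly more than the minimum area
(default 60 km²).  Thresholding is applied per cell before component
labeling; a moving-window mean is available as an option (default off)
because some corridor-design tools smooth before thresholding.
8-connectivity matches the movement graph used downstream.  Inter-patch
Euclidean distance is edge-to-edge (minimum over boundary-cell centers),
not centroid-to-centroid — adjacent patches can be 0.2 km apart only under
this convention.

## Cost distance, paths, corridors

The movement model is Dijkstra's algorithm on the 8-connected grid graph,
with the ArcGIS Cost Distance step convention: moving between adjacent
cells i and j costs (c_i + c_j)/2 · d_ij, where d_ij is the metric step
(cell size orthogonally, ×√2 diagonally).  Accumulated cost therefore has
units of resistance-score × meters; on the published gazelle table the
0.2 km GZ–HG path with cost 291 implies a mean per-meter resistance of
about 1.5, inside the 1–10 score range, which is what fixes this unit
interpretation.  Implementation choices for reproducibility: the priority
queue breaks cost ties by flat cell index, and path backtracking descends
the source cost field by the steepest admissible neighbor with ties broken
in fixed row-major neighbor order — fields and paths are bit-reproducible,
which the test suite exploits by demanding bit-for-bit equality with a
naive O(V²) Dijkstra oracle on over a hundred random instances.
Unreachable cells carry an infinity sentinel, distinct from nodata;
mutually unreachable pairs yield an explicit no-path record, never a silent
omission.

The corridor surface C = cd_A + cd_B gives, per cell, the cost of the best
A–B route forced through that cell; min C equals the pair's LCP cost (an
exact identity at grid nodes, asserted in tests).  Backtracked path cells
satisfy C ≤ min C + one maximal step cost; the slack is pure grid
discretization.

**Width-constrained corridor cost.**  The 1-km-corridor cost is the
smallest threshold t such that the slice {C ≤ t} (together with the two
patch footprints) contains a connected region linking the patches that is
at least 1 km wide at its narrowest point.  Width is tested with the
Euclidean distance transform: a cell belongs to the corridor core iff its
distance to the slice complement is ≥ width/2, and the link succeeds when
one 8-connected core component comes within width/2 of both patches.  The
link test is monotone in t, so t* is found by bisection over the sorted
distinct values of C — equivalent to an exhaustive sweep (asserted against
one in tests) at logarithmic cost.  Distances are measured between cell
centers, so a strip of k cells registers as (k+1)·cellsize wide; at 250 m
resolution a 4-cell strip is exactly 1 km.  When no threshold achieves the
requested width the function returns a bounded-failure result carrying the
landscape's maximum achievable width rather than raising.  Whether the
original tool's "1-km corridor" was the minimal width-achieving threshold
or a percentile slice is not documented; the minimal-threshold reading
follows directly from "minimum width of one km at the narrowest point".

## Network assembly

`build_network` computes records for every unordered patch pair within the
25 km Euclidean gate (beyond which essentially no gene flow is observed in
the study system), reusing one cost-distance field per patch across pairs.
`classify_traversable` flags pairs whose movement cost does not exceed the
reference pair's and sorts by ascending cost (descending permeability).
Pairs without a reference remain undetermined (serialized empty, not
false).  Reported precision follows the published table: lengths 0.1 km,
costs to the nearest integer, means as printed (Euclidean mean at 2 d.p.);
all internal computation is full precision.

## Synthetic landscapes and what the tests show

The generator emulates the ten raw layers on a 200×200-cell window at
250 m (50 × 50 km): terrain is Gaussian-smoothed white noise scaled to
2500–5200 m (the study region's relief), slope its gradient magnitude in
degrees, NDVI and human density independent smoothed fields on [0, 1] and
[0, 60] /km².  Sparse vector features (defaults: 2 rivers, 1 highway,
1 railway, 4 farmland polygons, 5 settlements, 40 houses — the sparse
human footprint of a high-plateau pastoral basin) become distance layers
via exact Euclidean distance from cell centers to the geometry.  With a
terrain autocorrelation length of 5 cells the resulting background slope
distribution (median near 10–15°) keeps matrix resistance well above the
planted corridors' score-1 cells, and the suitability deficit of typical
background cells keeps spurious > 9.5 components far below the 60 km²
area criterion.  All randomness flows from one integer seed through a
single generator.

Planting works by local override of *derived* layers: inside a planted
patch disc the eight suitability variables are set to raw values whose
weighted reclassified score meets the target (all variables at score 10,
one variable lowered to land nearest the target, e.g. 9.8), and
settlement/house distances are set safely non-barrier; inside a corridor
buffer (half-width 2 cells) the seven cost variables are set to values
scoring nearest the target resistance.  Because distance rasters are
overridden after the distance transform, the planted layers are no longer
exact distance fields of any geometry — the triangle-inequality property
of `distance_raster` holds for its own output, and is tested there.  Slope
is re-derived from the final elevation and then re-flattened inside
planted footprints, since disc rims would otherwise leak gradient spikes
into edge cells.

Passing recovery tests (patch count exact, footprint Jaccard ≥ 0.9,
corridor route tracked within 2 cells over ≥ 90 % of the path, planted
pair attaining the network's minimum cost, across 10 seeds) show the
pipeline is internally consistent and recovers known structure under
realistic spatial autocorrelation.  They do **not** validate the expert
scores or weights themselves, nor reproduce the real study-region maps:
the underlying Qinghai rasters and field-delineated patch boundaries are
unpublished, so study-scale absolute results (per-patch suitability means,
specific corridor costs) are reproducible only as the shipped transcription
of the published 15-pair summary, from which all derivable statistics are
recomputed exactly.

## Numerical and degenerate-input choices

- Power iteration tolerance 1e-10 (max-norm), cap 10,000 iterations;
  reciprocity validated at 1e-6 relative (expert matrices are entered to
  few significant digits).
- Backtracking admissibility tolerance 1e-6 relative to the path cost,
  guarding against accumulation noise; on exact Dijkstra fields the
  descent condition holds exactly.
- Empty patch lists are a valid result (empty landscape ≠ error); empty
  feature sets give all-infinite distance rasters with a warning; an empty
  connectivity table cannot be summarized (error).
- ESRI ASCII grid is the mandatory raster dialect (single square cell
  size; `NODATA_value` honored, default −9999); non-square pixels are
  unsupported by the format and rejected.  Projection strings are carried
  opaquely and never re-projected — all internal math is planar.
- The study-scale preset (970×970 cells ≈ 58,800 km²) exists for realism
  checks but is not used in tests; the default window keeps a full
  pipeline run in the low seconds.

## Known limitations

- Expert-derived scores and weights are taken as given; no sensitivity
  analysis is performed (none was performed in the source workflow either).
- Movement costs are isotropic; slope-direction-dependent or
  circuit-theory (current-flow) connectivity is out of scope.
- Grassland fencing, a known dispersal obstacle in the study system, has
  no layer: its spatial configuration cannot be mapped at regional scale.
- The landscape-genetics columns of the shipped table (F′_ST,
  first-generation migrants) are inert validation annotations from an
  external study, never computed here.
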