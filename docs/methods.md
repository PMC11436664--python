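# Methods

This note documents the models, conventions and numerical choices behind
`reefmetrics`, in the spirit of the methods documentation of statistical
packages: enough detail to know exactly what is computed, which knobs
matter, and what the tests do and do not demonstrate.

## Surface model and sampling

Input models are triangulated surfaces (STL, both dialects auto-detected).
STL carries no units; coordinates are interpreted as centimetres, because
the default sampling density of 1 point/cm² is only meaningful under a
declared unit.  `unit_scale` converts models authored in other units at
read time.

Cleaning on read: vertices are merged within 1e-8, faces with area below
1e-12 of the total are dropped (and counted), stored facet normals are
discarded, and normals are recomputed from the winding order; inconsistent
winding is repaired by propagation from adjacent faces.  Watertight meshes
get the exact divergence-theorem volume.  Open meshes are a reported state,
not an error: they receive a voxel-fill volume (below), flagged as a
fallback in every downstream record.

Surface sampling is stratified per face with largest-remainder allocation:
the total count is `round(area × resolution)`, each face receives its
expectation rounded so that no face is off by more than one point, and
point positions inside each triangle use the standard reflected
`(u, v)` construction.  Each point carries its face's unit normal.  The
sample is deterministic for a given seed, which makes whole-pipeline runs
byte-reproducible.

### Voxel-fill volume (fallback for open meshes)

The surface is sampled at ~16 points per voxel cross-section, occupied
cells are marked, and empty cells connected to the grid border are flood-
filled as exterior; the remaining empty cells are interior.  Two details
matter for accuracy:

- the grid origin is offset by an irrational (golden-ratio) fraction of the
  cell size, so flat CAD faces — which usually sit at rational coordinates —
  do not coincide with grid planes;
- each surface cell contributes its estimated solid fraction rather than a
  blanket 1/2: every sample point defines a tangent plane through the
  point, whose solid-side volume fraction of the cell is, to first order,
  `0.5 + n·(p − c) / (h‖n‖₁)`; fractions are averaged per cell.

On watertight test solids (cube, sponge, icosphere) this estimator is
within ~1% of the exact volume at a voxel of 1/20 of the smallest bounding-
box edge and converges roughly linearly as the voxel shrinks.

## Geometric metrics

`C = (V_hull − V) / V_hull` uses the *accessible* volume of the convex hull
(hull from the vertex set via Qhull).  For open meshes the voxel-fallback
volume is used and flagged; note that with the flood-fill definition a
sealed internal void counts as solid, while any cavity connected to the
outside counts as accessible — the ecologically intended reading.

`P = A_hull / A` is ≤ 1 for watertight meshes (the hull is the area-
minimizing enclosure).  Open shells can exceed 1 (both sides of a wall
count toward `A` is not the issue — the missing cap is); such values are
passed through with a warning flag, and their transform `P_t = 1 − P` goes
slightly negative, matching near-convex open moulds in the reference table.

### Box-counting dimension

`D` is the OLS slope of `log N(s)` versus `log(1/s)` over a descending
geometric series of box sizes (ratio 2) on a single grid anchored at the
bounding-box minimum corner, from the largest bbox edge down to twice the
mean point spacing; the fit's R² is always reported alongside.  At least 5
scales are required.  Optional averaging over offset grids is deliberately
omitted in favour of a simple, fully reproducible convention.

Two tie-break conventions keep counts faithful for flat-faced CAD models
whose surfaces lie exactly on grid planes:

- each sample point is attributed to the cell on its *solid* side (a 1e-9
  relative nudge along the inward normal);
- cell indices are clipped to the bounding-box grid, so points on the far
  bounding faces do not open a spurious extra cell layer.

Finite-range caveats, verified numerically in the test suite:

- A *closed* surface measured from the coarsest scales has an inflated
  slope (the coarse regime counts the enclosing shell, slope → 3 at the
  first halving).  The unit cube reaches `D = 2.00 ± 0.05` only in the
  fine-scale window where the shell count behaves as `6/s²`; the test uses
  an explicit `size_range` of `2⁻⁴ … 2⁻⁸` with sampling dense enough to
  resolve the finest scale.  Flat *point sets* (planar grid, line) have no
  shell regime and give exactly 2 and 1 on the default scales.
- A level-2 Menger sponge surface gives `D ≈ 2.75` on the default ratio-2
  scales (box dimension `log 20 / log 3 ≈ 2.727`); the estimate for
  grid-*aligned* prefractals depends on the grid anchoring, so rotation
  stability of `D` (< 0.05) is asserted on surfaces in generic position
  (noised spheres), while `C` and `P` are rigid-motion invariant to 1e-6
  always.

## Informational metrics

Normals are categorized in two modes:

- **unique-vector** (used for `R`): normals rounded componentwise to 2
  decimals (−0.0 folded into 0.0) and counted as distinct categories.
  `R = S/n` then spans the published range — ~1e-6 for flat-faced moulds
  sampled with millions of points, → 1 for organic surfaces where nearly
  every normal is distinct.
- **sphere-binned** (used for `H` and `J`): normals assigned to the nearest
  of 320 subdivided-icosahedron face centers (an approximately equal-area
  partition; subdivision 2 gives exactly 320 cells).  Binning gives the
  entropy a sample-size-independent ceiling of `ln 320 ≈ 5.77`, consistent
  with published diversities ≤ 2.6; entropy over raw unique vectors would
  grow with the sample size.

`H` uses the natural logarithm throughout.  `J = H / ln S`, with `J := 1`
when `S = 1`: a single orientation is trivially even, matching the
published convention for the simplest designs.  Both modes, the rounding
precision and the cell count are recorded in each record's diagnostics.

## Transforms and the Complexity Index

`P_t = 1 − P`, `D_t = D − 2`, `H_t = H`.  These place all six variables on
comparable order-1 scales: the transformed packing of a convex solid is 0,
the transformed dimension of a flat surface is 0.  The transform scheme is
named, pluggable and provenance-stamped; the default scheme is exactly
invertible.  `CI` is the plain sum of the six metrics — an overview
quantity, deliberately unweighted.

The packaged reference table keeps published values verbatim, including
its CI column; `MetricTable.validate_ci` reports any row whose stored CI
deviates from the six-metric sum by more than 0.002 (the budget left by
3-decimal rounding) instead of silently reconciling.  Likewise the
bio-mimicry purpose group recomputes to CI 5.439 from the table while the
published narrative summary says 5.335; the table is treated as
authoritative and the discrepancy is surfaced, not patched.

## Ordination, clustering, target points

**MFA.**  Active variables are the six metrics in two groups (geometric
`{C, P_t, D_t}`, informational `{R, H_t, J}`).  Each variable is centered
and scaled by its population (1/n) standard deviation — the convention of
the reference implementation this pipeline mirrors; the choice is
configurable because inertia percentages are mildly sensitive to it.  Each
group's block is divided by the square root of the group's first PCA
eigenvalue, then the weighted matrix is decomposed by SVD with uniform row
weights 1/n.  Variable contributions per dimension are the squared right-
singular-vector entries (×100).  The Complexity Index is *supplementary*:
projected by correlation with the dimension scores, provably without any
influence on eigenvalues, scores or loadings (asserted bitwise in tests).

Signs of an SVD are arbitrary, so they are fixed deterministically: Dim.1
so the supplementary CI correlates non-negatively with it (positive sum of
loadings when there is no supplementary variable), higher dimensions so
their largest-|loading| variable loads positively.  On the reference table
this orients bio-mimicry designs positive on Dim.1 and makes J load
positive on Dim.2, reproducing the published orientation.

**Retention.**  The Karlis–Saporta–Spinaki threshold
`1 + 2√((p−1)/(n−1))` (2.03 for n=20, p=6).  All reference-table
eigenvalues sit below it — the MFA eigenvalue scale is bounded by the
number of groups — so the rule alone retains nothing; a minimum of two
dimensions is always kept for the planar ordination and the shortfall is
recorded (`retained_by_rule`).

**Clustering.**  Ward linkage (Ward.D2 merge cost) on Euclidean distances
between component scores, cut at k.  Clustering uses the first five
dimensions by default — the conventional default of factor-analysis
clustering tools, and the configuration that reproduces the published
3-cluster solution (all bio-mimicry prints together; the anomalous
protection design PROT4 with the production group).  Clustering on only
the two retained dimensions instead moves PROT4 into the protection
cluster; `n_dims` is exposed for exactly this kind of sensitivity check.
Rows are processed in lexicographic model-id order so merge tie-breaks are
row-order-free; cluster ids 1..k are assigned by ascending mean Dim.1.
Cluster description uses the classical v-test with population variance;
|v| ≥ 1.96 marks characterizing variables.

**CTPs.**  `distance = √(Dim.1² + Dim.2²)` from the origin (scores are
centered, so origin and centroid coincide); the threshold is the mean
distance over models with Dim.1 > 0; selection keeps ties (≥).  Target
points are the per-metric mean and sample (n−1) standard deviation over
the selected models — the n−1 convention is confirmed by recomputing the
published CTP-C spread (0.232) from the five selected convexity values.
`select_ctp` can run purely from the table's stored score/distance
columns, making the published selection reproducible independently of any
ordination implementation.

## Synthetic shapes and what passing tests show

The generator provides cubes, icospheres, open boxes, Menger sponges
(levels 1–3, built from an occupancy grid with combinatorial face/volume
enumeration oracles written independently of the metric code), perforated
shells and seeded rough spheres.  These span the behaviours the metrics
must get right — exact convexity and packing values, known box dimensions,
degenerate and open geometry, noise-driven dimension increase — and they
are what the metric core is certified against.

They do **not** emulate real reef CAD models: no organic free-form
surfaces, no multi-scale biological texture, no CAD export artifacts
beyond simple degeneracies.  The original reef models are proprietary, so
per-model raw metric values cannot be recomputed from meshes; the
statistical pipeline is instead verified end-to-end against the packaged
published table.  Passing tests therefore demonstrate (a) correctness of
the metric definitions on analytic geometry and (b) exact reproduction of
the published downstream statistics from the published metric table — not
re-derivation of that table from the original CAD files.

### Precision of the packaged table

The packaged table stores the metrics at their published 3-decimal
precision, and the published ordination was computed on full-precision
metrics that are not public.  The evidence that these differ by more than
rounding: first-dimension scores recomputed from the table deviate from
the stored scores by up to 0.39, and the packing–dimension correlation is
0.95 from the table versus the published 0.93.  Consequently the MFA on
the packaged table reproduces the first-dimension inertia (43.33% vs
43.21%) and every variable-contribution figure to a few hundredths, but
the second dimension carries 25.64% vs the published 24.28%, putting the
two-dimension total at 68.97% vs 67.48%.  This residual is a property of
the available data, not of the decomposition, and is left visible in the
acceptance suite rather than absorbed into tolerances.

## Default problem sizes

Defaults used by the test and acceptance suites, chosen to resolve the
relevant scale ranges: 600–18 000 points for cube orientation checks,
1.3×10⁵ points for the level-2 sponge dimension (six ratio-2 scales),
1.8×10⁶ points for the cube's fine-scale dimension window, 100 replicates
of n=50 for planted-factor recovery, and voxel grids of ~1/20 to 1/40 of
the bounding box for volume fallback checks.

## Known limitations

- Box-counting `D` is a finite-range estimate; the reported `fit_r2` and
  the scale list are the user's tools for judging the linear regime.  No
  automatic regime selection is attempted.
- The unique-vector richness depends on the rounding precision (2 decimals
  by default) and, unlike the binned entropy, retains mild sample-size
  dependence by construction (`R = S/n`).
- The voxel fallback treats sealed internal voids as solid; accessible-
  volume semantics for such cavities would require a different definition.
- Only STL input is supported; no remeshing or repair beyond degenerate-
  face removal and winding reorientation.
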