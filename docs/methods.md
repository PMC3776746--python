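# Methods

## The problem

Anatomically defined brain-network nodes are assumed functionally
homogeneous, but often are not. When a region contains subregions with
different latent time courses, the region's mean signal is a lossy
summary: anti-phase subregional signals partially cancel, so region-level
functional connectivity can understate (or, through shared components,
overstate) the connectivity actually present at the subregional level, and
every downstream graph measure inherits the distortion. The package
quantifies this by comparing three parcellations of the same data: the
anatomical atlas, a functional subdivision of it (AHMO), and a node-count
matched random parcellation that controls for graph size.

## AHMO

For each anatomical ROI independently:

1. **Voxel graph.** Per subject, Pearson correlations between all voxel
   time series in the ROI; Fisher r-to-z; multiplied by √(Ns−3) so that a
   null edge is N(0, 1) (Ns = number of time points). Subject matrices are
   averaged element-wise; negative averages are clamped to zero (Newman
   modularity assumes nonnegative weights) and the diagonal is zero.
2. **Modularity optimization.** Q is the total within-cluster weight minus
   its expectation under the strength-preserving null, normalized by the
   total weight V (sum over ordered pairs, i = j included — immaterial
   here since diagonals are zero). The optimizer is a Louvain-style greedy
   search: repeated node-level moves, graph aggregation, then node-level
   refinement on the original graph plus greedy pairwise cluster merges.
   It runs `restarts` times (default 20) — the first pass from the
   singleton partition, later passes from random coarse initializations —
   and keeps the best Q. If no subdivision beats Q = 0, the ROI stays one
   cluster, so the returned Q is never negative. The search is
   deterministic given the seed; on graphs with ≤ 8 nodes it attains the
   exhaustive (Bell-number enumeration) optimum in 100/100 random trials,
   which the test suite re-verifies.
3. **Spatial cleanup.** Clusters are split into spatial connected
   components (6-connectivity by default — the conservative reading of
   spatial contiguity; 18 and 26 available), then clusters smaller than
   `min_size` voxels are merged, smallest first, into the cluster with the
   nearest centroid (millimetres, unweighted voxel centroid) within the
   same parent ROI; spatially adjacent candidates are preferred so merged
   clusters stay contiguous, centroid ties go to the larger cluster, and
   sizes/centroids are refreshed after every merge. A cluster alone in its
   ROI is kept even if undersized (and logged) rather than crossing an
   anatomical boundary. `min_size` defaults to 50 voxels, meant for
   acquisition-resolution data; toy grids scale it down (tests use 10 on
   the 12×12×6 grid, whose smallest planted subregion has 24 voxels).

The result is nested in the anatomical atlas by construction: no cluster
ever crosses an ROI boundary, which is what makes region-level comparison
between the two parcellations well defined.

## Graph construction and measures

Connectivity graphs at any level (voxel, subregion, region) are Pearson
correlation matrices, Fisher-z standardized, optionally group averaged,
then thresholded at a network-forming cutoff Z: edges with weight ≤ Z are
removed, surviving weights are kept (weighted, not binarized). Strict
inequality at the cutoff is a fixed convention (ties are measure-zero);
any Z ≥ 0 removes all negative edges.

Shortest-path measures map weight w to length 1/w. Betweenness uses
fractional counting of equally short paths and the 1/((n−1)(n−2))
normalization over ordered pairs. Global efficiency is the mean inverse
shortest-path length over ordered pairs, with disconnected pairs
contributing zero. Local efficiency follows the weighted form
(w_ij · w_ih · d_jh(N_i)⁻¹)^⅓ summed over ordered neighbor pairs of each
node, with d computed on the neighborhood subgraph, averaged over all n
nodes (degree < 2 contributes 0); mean clustering is the Onnela
geometric-mean form. Both cube-root formulas operate on weights rescaled
by the graph maximum. Betweenness and clustering are computed through
networkx, shortest paths through scipy's Dijkstra; the test suite checks
every measure against naive brute-force re-implementations (Floyd–Warshall
with tight-edge path counting, explicit subgraph extraction, triple
enumeration) on random graphs.

The homogeneity index H averages, over clusters with ≥ 2 voxels, the mean
off-diagonal within-cluster standardized z; singleton clusters are
excluded (and logged) rather than failing the report. Sub-regional mean
functional connectivity averages all pairwise subregion correlations
between two ROIs' subregion sets, reducing to the plain correlation for
single-subregion ROIs. Nodal measures are made comparable across
parcellations of different size by averaging within parent ROIs and
z-scoring across the K parent values (population SD).

## Random-seeding control parcellation

Seeds are placed uniformly at random in the mask; the currently smallest
cluster (ties by ID) grows by one uniformly random frontier voxel (face
adjacency) until the mask is covered; unreachable voxels join the nearest
centroid. "Uniform speed" via smallest-first expansion keeps sizes nearly
equal — exactly equal when no cluster is walled in. A cluster that hits
the mask boundary and its neighbors before others is permanently blocked
and ends smaller; contiguous growth cannot rebalance afterwards. On a 20³
mask with 8 seeds the max/min size ratio stays below 1.5 across 50 random
trials; packing more seeds makes walling-in, and therefore imbalance, more
frequent. The control is used for size-matched global comparisons only —
it ignores both anatomy and function by design.

## Statistics

Paired comparisons are classic paired t-tests per measure, two-sided,
with Bonferroni correction over an explicit family size (`m_tests`;
defaults to the number of columns — family sizes are inputs, not
hard-coded, since the appropriate family depends on the analysis).
Inter-parcellation "linearity" is the Pearson correlation across subjects,
declared significant when |r| exceeds the exact inversion of the
two-sided t test at α/m with n−2 degrees of freedom. The atlas × group
interaction of the mixed 2 (within) × 2 (between) design is computed via
the difference-score equivalence — a pooled two-sample t on per-subject
atlas differences, F = t² — which is exact for a two-level within factor
and trivially verifiable. Zero-variance difference columns yield t = 0,
p = 1 with a warning.

## Preprocessing

The post-alignment chain is: drop initial scans (default 5) → zero-phase
forward-backward Butterworth band-pass, order 2, 0.009–0.08 Hz (zero-phase
filtering preserves correlation structure; the effective magnitude
response is the squared order-2 response) → confound regression with an
intercept, confounds band-passed identically first so regression cannot
reintroduce removed frequencies; rank-deficient designs fall back to the
pseudo-inverse with a warning. Regional representatives are the voxel mean
or the first eigenvariate (leading principal component of the centered
voxel × time matrix, sign aligned with the mean, rescaled to the mean's
SD). Exact SPM eigenvariate scaling is not reproduced; only
correlation-level agreement matters downstream. On coherent regions the
two representatives correlate near 1; on deliberately inhomogeneous
regions the correlation is attenuated — that attenuation is the
phenomenon under study, not an artifact.

## Synthetic cohorts

The generator plants S contiguous subregions inside N contiguous ROIs on
a small grid and drives each subregion with a latent signal; every voxel
is its subregion's latent plus independent white noise of SD `noise_sd`
(planted within-subregion voxel correlation 1/(1+noise_sd²)). Latents are
white Gaussian series band-passed to 0.009–0.08 Hz (so their spectra
resemble band-passed resting BOLD and preprocessing does not destroy the
planted structure), standardized, and mixed by the Cholesky factor of the
target correlation matrix, which must be positive semi-definite (checked;
a factor-loading parameterization guarantees it).

Defaults (12×12×6 grid at 3 mm, 6 ROIs of 144 voxels, subregion counts
(2, 3, 4, 2, 3, 4), 20 subjects, 160 time points at TR 2 s, noise SD 1):
three latent "network" factors; ROI r loads on factor r mod 3 with a
dominant, double-sized +0.8 subregion and one anti-phase −0.8 subregion;
extra subregions load +0.8 on the other factors in turn. This encodes, at
desk scale, the three features the real-data analyses rest on: strong
within-subregion coherence, regions whose means partially cancel genuine
subregional connectivity (the dominant subregion keeps the cancellation
partial — region means still carry attenuated network signal, as real
regional means do), and multi-network membership of larger regions. The
anti-phase subregion is second and smaller than the dominant one; with
equal sizes the cancellation is exact and anatomical-level graphs go
empty at moderate thresholds, which matches no real data.
`connectivity_bias_spec` provides the sharpened two-ROI scenario with
exact cancellation for studying the bias effect itself.

Per-subject variation: each network factor's loadings are rescaled by
1 + 0.15·N(0,1) per subject (clipped to keep communalities below 1).
Real cohorts genuinely differ in network expression; without true
between-subject variance, across-subject correlation analyses would
measure nothing but shared sampling noise.

What the generator does **not** emulate: hemodynamics, spatial smoothness
and partial-volume mixing at boundaries, motion and physiological
artifacts, anatomical geometry, and the ~90/372-node scale of real
whole-brain parcellations. Consequences for interpretation: passing tests
show algorithmic correctness and qualitative reproduction of the
inhomogeneity phenomena, not quantitative agreement with real-data
effect sizes. One documented scale limitation: across the network-forming
threshold sweep, inter-atlas linearity of global efficiency at desk scale
is as high (or higher) unthresholded as at Z=3, because the nested
parcellations are smooth functions of the same few subregion correlations
and share their dominant variance mode at every threshold; a collapse of
unthresholded linearity of the kind real whole-brain data (hundreds of
nodes, globally centred edge distributions) can exhibit is not reproduced
by this generator at 6–48 ROIs (verified over sign schemes, ROI counts,
noise levels, subject-variation modes, and global-signal regression).

## Numerical conventions and degenerate inputs

- Coordinates are 0-based voxel indices; millimetres appear only in
  centroid distances (via the affine's voxel dimensions).
- Label 0 is background everywhere; finalized parcellations are relabeled
  1..K in ROI order.
- Zero-variance series are an error naming the offending node;
  |r| = 1 cannot be z-standardized and is an error (the synthetic cohorts
  avoid it for any noise_sd > 0).
- ROIs with < 2 voxels become trivial single clusters (logged).
  Empty thresholded graphs are allowed and logged.
- Determinism: every entry point takes a seed; internal stage seeds are
  spawned from it (`numpy` SeedSequence), so repeated runs are
  bit-identical.
- Test problem sizes (20-subject cohorts on the 12×12×6 grid, 100 random
  graphs with ≤ 12 nodes for oracle comparisons, 10-seed noise sweeps)
  were chosen so the whole suite and the acceptance script each run in a
  few minutes on one CPU while still exercising every code path at
  non-trivial size.

## Known limitations

- One hierarchy level only: ROI → subregions. No deeper recursion, no
  consensus clustering across seeds, no subject-specific parcellation.
- Modularity's resolution limit applies: planted structure that is not
  the Q-optimum of its ROI graph (e.g., two strongly positively
  correlated same-network subregions inside one ROI) will be merged by
  any correct optimizer.
- The random-growth rule guarantees near-uniform sizes only until
  clusters are walled in (see above).
- Bonferroni family sizes must be supplied by the analyst; the package
  does not guess the intended family.
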