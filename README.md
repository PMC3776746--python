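# ahmo — anatomy-constrained hierarchical modularity optimization

Graph-theoretical studies of the functional brain connectome usually define
network nodes from an anatomical atlas (AAL, Harvard–Oxford, …). Anatomical
regions, however, are not functionally homogeneous: a single gyrus can
contain subregions with distinct — even anti-correlated — resting-state
time courses, so averaging a region's BOLD signal can hide real
connectivity or manufacture spurious connectivity, biasing both
functional-connectivity estimates and weighted network measures.

`ahmo` implements a pipeline for quantifying that node-inhomogeneity bias:

- **AHMO parcellation** — subdivide each anatomical region of interest
  (ROI) into functionally homogeneous subregions by maximizing Newman
  modularity of the group-averaged voxel-wise correlation graph, under the
  constraint that subregions never cross ROI boundaries. For ROI *k* with
  voxel weights *w*ᵢⱼ⁽ᵏ⁾ (group-mean standardized Fisher-z correlations,
  negatives clamped to 0):

      Q_k = (1/V_k) Σ_ij (w_ij − s_i s_j / V_k) δ(C_i, C_j),
      s_i = Σ_j w_ij,   V_k = Σ_ij w_ij

  optimized by a seeded Louvain-style search with restarts, followed by
  contiguity repair (connected-component relabeling) and merging of
  undersized clusters (< 50 voxels at acquisition resolution) into the
  nearest-centroid neighbor within the same ROI.
- **Connectivity and graphs** — Pearson correlation graphs, Fisher r-to-z
  standardized by √(Ns−3) so null edges are N(0, 1), group averaging, and
  network-forming thresholds (weights kept, edges ≤ Z removed).
- **Weighted network measures** — nodal strength, betweenness centrality
  (lengths = 1/w), global and local efficiency, Onnela mean clustering,
  the within-cluster homogeneity index
  H = (1/K) Σ_k mean_{i≠j∈k} z_ij⁽ᵏ⁾, sub-regional mean functional
  connectivity r_kl = (1/n_k n_l) Σ_i Σ_j r(x_i⁽ᵏ⁾, x_j⁽ˡ⁾), and
  across-ROI normalization of nodal measures.
- **Controls and statistics** — random-seeding parcellations grown to
  near-uniform size (node-count-matched, function-blind), paired t-tests
  with Bonferroni correction, inter-atlas Pearson linearity with an exact
  critical value, and the atlas × group interaction of a mixed 2×2 design.
- **Synthetic cohorts** — multi-subject 4D BOLD volumes with planted,
  contiguous subregions driven by band-limited latent network signals
  (including anti-phase subregion pairs), voxel noise, and per-subject
  network-strength variation, so the whole pipeline is testable without
  any data download.

## Worked example

```python
import numpy as np
from ahmo import (SyntheticSpec, make_toy_atlas, simulate_cohort, run_ahmo,
                  random_parcellation, correlation_graph, fisher_z_standardize,
                  homogeneity_index, threshold_graph, global_efficiency,
                  extract_regional_ts, group_average)

spec = SyntheticSpec(seed=1)              # 12x12x6 grid, 6 ROIs, 20 subjects
atlas, truth = make_toy_atlas(spec)
cohort = simulate_cohort(spec, truth)

result = run_ahmo(cohort, atlas, min_size=10, seed=7)
print(f"clusters: {result.cluster_count} "
      f"(planted subregions: {truth.partition.n_clusters})")
print("per-ROI best Q:",
      {r: round(q, 3) for r, q in result.per_roi_Q.items()})

def H(vol, labels):
    mats = [fisher_z_standardize(correlation_graph(vol.data[labels == c]),
                                 ns=160).weights
            for c in np.unique(labels[labels > 0])]
    return homogeneity_index(mats).H

rand = random_parcellation(atlas, result.cluster_count, seed=7)
h = {name: float(np.mean([H(v, lab) for v in cohort]))
     for name, lab in [("AHMO", result.partition.labels),
                       ("random", rand.labels),
                       ("anatomical", atlas.labels)]}
print("mean homogeneity H:", {k: round(v, 2) for k, v in h.items()})

graphs = [fisher_z_standardize(
              correlation_graph(extract_regional_ts(v, atlas, "mean")), ns=160)
          for v in cohort]
g = threshold_graph(group_average(graphs), 3.0)
print(f"anatomical graph at Z=3: {g.n_edges} edges, "
      f"E_glob = {global_efficiency(g):.3f}")
```

prints

```
clusters: 18 (planted subregions: 18)
per-ROI best Q: {1: 0.319, 2: 0.477, 3: 0.478, 4: 0.319, 5: 0.491, 6: 0.506}
mean homogeneity H: {'AHMO': 6.94, 'random': 2.03, 'anatomical': 1.53}
anatomical graph at Z=3: 9 edges, E_glob = 3.547
```

AHMO recovers exactly the 18 planted subregions. The homogeneity ordering
is the pipeline's central result: the functional parcellation is far more
homogeneous than a node-count-matched random parcellation, which in turn
beats the anatomical atlas whose ROIs deliberately mix anti-phase
subregions. `E_glob` here is in standardized-z units (edge length 1/z).

A command-line interface mirrors the library:

```sh
ahmo simulate --spec spec.json --out sim/
ahmo parcellate --atlas sim/atlas.nii.gz --subjects subjects.txt \
     --min-size 10 --seed 7 --out parc.nii.gz
ahmo parcellate-random --mask sim/atlas.nii.gz --n 18 --seed 7 --out rand.nii.gz
ahmo preprocess sim/sub-001_bold.nii.gz --drop 5 --band 0.009:0.08 --out pp.nii.gz
ahmo metrics --graph g.tsv --threshold 3 --out met.tsv
ahmo compare --metrics-a a.tsv --metrics-b b.tsv --out cmp.tsv
```

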