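# incaclust

Distance-based cluster analysis for biomedical data: estimate the number of
clusters from **any** distance matrix (continuous, binary, qualitative or
mixed variables), detect the *absence* of cluster structure, and test
whether a new unit (a gene, a tumor sample, ...) is typical of the existing
clusters or belongs to a novel group.

Most cluster-validity indices require continuous data and cannot signal
"there are no clusters here"; and classical allocation rules force every new
unit into one of the known groups. This package implements the INCA
methodology, which addresses both problems for arbitrary dissimilarities,
and ships the distance constructors (Gower for mixed variables with missing
values, Bhattacharyya for frequency profiles, pairwise Mahalanobis,
correlation) that make it usable on typical clinical and expression data.

## The statistics

Let δ(g, g′) be a distance between units and C₁, …, C_k a partition with
sizes n₁, …, n_k.

- **Geometric variability** (a distance-based within-group variance):
  V̂δ(C_j) = (1 / 2n_j²) Σ_{l,m} δ²(g_l, g_m)
- **Between-group squared distance**:
  Δ̂²_ij = (1 / n_i n_j) Σ_{l,m} δ²(g^i_l, g^j_m) − V̂δ(C_i) − V̂δ(C_j)
- **Proximity** of a unit g₀ to a group:
  φ̂²(g₀, C_j) = (1 / n_j) Σ_l δ²(g₀, g_l) − V̂δ(C_j)
- **INCA statistic**: W(g₀) = min_α L(g₀) subject to Σ α_i = 1, with
  L(g₀) = Σ_i α_i φ̂²_i − Σ_{i<j} α_i α_j Δ̂²_ij.
  Geometrically, W is the squared orthogonal *height* of g₀ above the
  hyperplane through the cluster centers; the projections
  U_j(g₀) = φ̂²_j − W measure the in-plane component toward each center,
  and a typical unit is allocated to the cluster with the smallest U_j.
- **INCA index**: INCA_k = (1/k) Σ_j N_j / n_j, where N_j counts the
  members of C_j whose height above the other clusters' hyperplane strictly
  exceeds the largest height attained by any non-member. Scanning
  k = 2 … K, the number of clusters is read off just before the largest
  decrease of the curve; a low flat curve means no cluster structure.
- **Typicality test**: W(g₀) is compared with the bootstrap distribution of
  W over units resampled from the pooled clusters; units whose height is
  significantly large belong to an unknown group.

Units that repeatedly land in tiny clusters (size ≤ L) across the scanned
partitions can be flagged as noise and removed, which can unmask a cluster
structure hidden by scattered units.

## Worked example

Simulate module-structured expression data (three modules of 480/360/360
genes, each gene correlated with its module's latent profile across 100
samples), score the true partition, and test one gene:

```python
import numpy as np
from incaclust import simulate_modules, inca_index, inca_test

sim = simulate_modules(n_samples=100, module_sizes=(480, 360, 360), seed=3)
D = sim.gene_distance("euclidean")     # 1200 x 1200 distances between genes

print(inca_index(D, sim.labels))
probe = np.where(sim.labels == 3)[0][5]          # a member of module 3
print(inca_test(D, sim.labels, D.values[probe],
                n_boot=1000, alpha=0.05, P=1, seed=3))
```

```
INCA index
  cluster 1: 466/480 well classified
  cluster 2: 348/360 well classified
  cluster 3: 348/360 well classified
  total: 96.81% well classified

INCA test
  INCA statistic value = 67.8737
  U projections values:
    U1 = 62.0822
    U2 = 77.6884
    U3 = 4.16777
  significative tests for alpha=0.05: 0
  verdict: typical, allocated to cluster 3
```

96.81% of genes stand strictly higher above the other modules' hyperplane
than any outsider does — a strong three-cluster structure. The probe gene
is never flagged in the 10 bootstrap repetitions, and the smallest
projection (U₃) allocates it back to module 3.

The scikit-learn-style estimators wrap the same machinery:
`IncaClusterNumber(k_max=10, method="average").fit(D.values)` exposes
`n_clusters_` and the index curve, and `IncaTypicality().fit(D.values,
labels)` gives `predict` / `score_samples` with `-1` marking novel units.
The `incaclust` command line mirrors the library (`dist`, `index`,
`numclu`, `test`, `simulate`) on CSV/TSV files.

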