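# miwas

Indicator-weighted K-means clustering for water-quality monitoring data.

Surface-water assessment is at heart a classification problem: given routine
measurements of a handful of indicators — pH, dissolved oxygen (DO), chemical
oxygen demand (COD), ammonia nitrogen (NH3-N) — assign each sample a quality
class. Plain K-means treats every indicator as equally important, but in real
river basins one or two indicators (typically COD) carry most of the signal.
`miwas` implements a weighted K-means whose per-indicator weights adjust
themselves each iteration from how well each indicator separates the clusters,
plus everything around it: grade-standard filtering, cleaning and
standardization, standards-based centroid seeding, SSE evaluation, LOOCV
verification, and synthetic benchmark generation. It is aimed at environmental
informatics practitioners working with GB3838-2002-style grade standards, but
the clustering core is generic.

## The algorithm

Let X be an M × N data matrix, U ∈ {0,1}^{M×K} a hard cluster membership,
c_k the cluster centroids and w ∈ Δ^{N-1} a weight vector on the probability
simplex. Indicator quality is scored by two per-indicator separations:

- within-cluster:  a_n = Σ_m Σ_k u_mk (x_mn − c_kn)²
- between-cluster: b_n = Σ_k Σ_{j≠k} |C_k| (c_kn − c_jn)²
  (a global-center variant b_n = Σ_k |C_k| (c_kn − g_n)² is also provided)

Maximising (Σ_n w_n b_n)/(Σ_n w_n a_n) over the simplex is a linear-fractional
program whose optimum is a corner: all weight on argmax_n b_n/a_n
(winner-take-all). To keep every indicator in play, the weights are instead
nudged toward an adjustment margin each iteration:

- **difference margin** (default): with a0 = a/Σa, b0 = b/Σb and
  δ = b0 − a0, set Δw_n = (δ_n − min δ)/Σ(δ − min δ) — a rank-preserving
  simplex projection of δ (δ itself sums to zero, so it cannot be normalised
  directly);
- **ratio margin**: Δw_n ∝ b_n/(a_n + σ), σ the average dispersion of the
  data, guarding against a_n = 0.

The update is w ← ½(w + Δw), which stays on the simplex exactly. The outer
loop is Lloyd's: assign each sample to the cluster minimising
Σ_n w_n (x_mn − c_kn)², recompute centroids, adjust weights, and stop when the
membership matrix no longer changes. Cluster validity is the weighted
within-cluster sum of squared errors SSE = Σ_n w_n a_n (lower is better).

Centroids are seeded from the grade standard: the grade-k boundary value of
each indicator, pushed through the same log10 + z-score transform as the data,
so K equals the number of grades (5 for GB3838-2002) and cluster k starts on
the grade-k boundary surface.

## Worked example

```python
import numpy as np
from miwas import (HaiheLikeSpec, generate_haihe_like, gb3838_standards,
                   grade_filter, preprocess, init_centroids_from_standards,
                   ClusteringConfig, miwas_kmeans, kmeans, sse, cluster_summary)

standards = gb3838_standards()
raw = generate_haihe_like(HaiheLikeSpec(n_samples=2000, seed=1))
raw, _ = grade_filter(raw, standards, "V")          # drop beyond-scale rows
clean, params, report = preprocess(raw)             # clean, log10, z-scale

init = init_centroids_from_standards(standards, params, clean)
cfg = ClusteringConfig(n_clusters=5)
res = miwas_kmeans(clean.values, init, cfg)         # adaptive weights
base = kmeans(clean.values, init, cfg)              # equal-weight baseline

print("weights:", np.round(res.weights, 4), "iters:", res.n_iter)
print("SSE  miwas:", round(sse(clean.values, res.labels, res.centroids.c, res.weights), 2),
      " kmeans:", round(sse(clean.values, base.labels, base.centroids.c, base.weights), 2))
```

Output:

```
weights: [2.000e-04 3.429e-01 3.292e-01 3.276e-01] iters: 11
SSE  miwas: 195.82  kmeans: 479.42
```

The adaptive run drives the pH weight to ~0 — pH is drawn independently of
the latent quality grade in this benchmark, so it carries no cluster signal —
and splits the rest between DO, COD and NH3-N, more than halving the weighted
SSE relative to the equal-weight baseline from the same standards-based init.
The per-cluster summary (original units, via `cluster_summary`) shows the
expected gradient from clean to polluted water:

```
 cluster  count  DO_mean  COD_mean  NH3-N_mean
       1    723    10.57      1.42        0.09
       2    529     6.84      2.89        0.28
       3    350     5.57      4.80        0.68
       4    231     4.25      7.47        1.20
       5    123     2.64     10.93        1.67
```

## Command line

```bash
miwas simulate --preset haihe --n-samples 2000 --seed 1 --out river.csv
miwas cluster --input river.csv --algorithm miwas --outdir run/
miwas loocv --config run/config.json --mode centroid --outdir cv/
miwas benchmark --n-seeds 50 --outdir bench/
```

Every run writes its fully resolved config next to its artifacts; identical
config + seed reproduces byte-identical JSON outputs.

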