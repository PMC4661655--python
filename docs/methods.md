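# Methods

This note records the model implemented by `miwas`, the assumptions baked into
it, every tunable parameter with its default and the reason for that default,
what the synthetic generators do and do not emulate, the numerical conventions,
and known limitations. Nothing here claims an empirical result beyond what the
test suite and `scripts/acceptance.py` actually compute.

## 1. Model and procedure

### 1.1 Data model

A sample table is an M × N matrix of indicator measurements (rows = samples,
columns = indicators), with optional per-row site and date metadata. Missing
values are NaN. The default indicator set is pH, dissolved oxygen (DO),
chemical oxygen demand as permanganate index (COD, mg/L) and ammonia nitrogen
(NH3-N, mg/L) — the routinely monitored quartet for surface water. A table
carries a *space* tag (`raw` → `log10` → `standardized`); transforms only move
it forward, which prevents accidentally clustering unstandardized data or
double-transforming.

### 1.2 Grade standards

A standards table holds, per indicator, the boundary value of each quality
grade (I–V by default, matching GB3838-2002) and a direction:

- `higher_is_worse` (COD, NH3-N): a value belongs to the first grade whose
  boundary it does **not exceed**; boundary-equal values belong to that grade
  (inclusive comparison).
- `lower_is_worse` (DO): symmetric, with "below the boundary" as worse.
- `none` (pH): the indicator has no grade boundaries and never influences a
  sample's grade.

A sample's grade is the **worst** of its per-indicator grades. Samples worse
than the worst retained grade (default V) on any indicator are removed by
`grade_filter` before analysis — they fall outside the classification scale
the method targets. Rows with NaN are not judged by the filter (comparisons
with NaN are false); they are removed later by `drop_missing`.

### 1.3 Preprocessing

Order: grade filter → drop rows with any missing value → outlier screen →
log10 transform → z-score standardization.

- **Outlier screen**: one pass; a row is removed if any column's z-score
  exceeds `outlier_threshold` in absolute value (default 3.0, the conventional
  three-sigma rule). Z-scores use the sample SD (ddof=1). The screen runs in
  raw space by default (`screen_space="raw"`); `"log"` screens after the log
  transform instead, for users who consider the log scale the natural one.
  A single pass is deliberate: iterating the three-sigma rule to a fixed point
  removes an unpredictable fraction of heavy-tailed data and makes the kept-row
  set depend on iteration order.
- **log10**: applied to all indicators by default. Concentration-like water
  quality indicators are right-skewed and roughly lognormal; `exempt_log`
  (default empty) lets callers keep near-symmetric indicators such as pH on
  the raw scale. Non-positive values under the log are an error, not a silent
  drop.
- **Standardization**: column-wise z-score with ddof=1. The ddof=1 convention
  is used everywhere a sample SD is reported (preprocessing, cluster
  summaries); population variance (ddof=0) is used only inside the ratio
  margin's dispersion guard, where it measures spread of the data actually
  being clustered rather than estimating a population parameter.

The fitted parameters (per-column mean and SD on the log scale, plus the log
mask) are returned as a `PreprocessParams` object so that the identical
transform can be replayed on the standards boundaries (for centroid seeding)
and inverted (for reporting cluster summaries in original units). The
preprocessing report includes the indices of surviving rows so callers can
align cleaned rows with the raw table.

### 1.4 Clustering

Lloyd iterations with a per-indicator weight vector w on the probability
simplex:

1. **Assign** each sample to the cluster minimising the weighted squared
   distance Σ_n w_n (x_mn − c_kn)². Ties go to the lowest cluster index
   (deterministic).
2. **Converged?** If the membership is identical to the previous assignment,
   stop. A `max_iter` guard (default 100) bounds runtime; in practice runs on
   the synthetic benchmarks converge in well under 30 iterations.
3. **Update centroids** to member means. Empty clusters follow
   `empty_cluster`: `"keep"` (default) retains the previous centroid —
   simplest, fully deterministic, and lets a cluster be reclaimed later —
   while `"reseed"` moves each empty centroid to the sample currently farthest
   (weighted distance) from its own centroid.
4. **Adjust weights** (unless `adapt_weights=False`, in which case the loop is
   exactly equal-weight K-means). Per-indicator separations:

   - within:  a_n = Σ_m (x_mn − c_{k(m),n})²
   - between, `"modified"` (default): b_n = Σ_k Σ_{j≠k} |C_k| (c_kn − c_jn)²,
     summing size-weighted squared gaps over all ordered centroid pairs;
   - between, `"original"`: b_n = Σ_k |C_k| (c_kn − g_n)², against the global
     center g.

   The adjustment margin Δw:

   - `"difference"` (default): normalise a and b to a0 = a/Σa, b0 = b/Σb and
     take δ = b0 − a0. δ sums to zero by construction, so it cannot itself be
     normalised into a weight vector; the implementation uses the min-shifted
     simplex projection Δw_n = (δ_n − min δ) / Σ_j (δ_j − min δ), which
     preserves the ranking of δ and lands exactly on the simplex. If the
     spread of δ is below 1e-12, or Σa = 0, or Σb = 0, the margin degenerates
     and Δw falls back to uniform 1/N (recorded per iteration in the trace).
   - `"ratio"`: Δw_n ∝ b_n / (a_n + σ), where σ is the mean per-indicator
     population variance of the data. σ keeps the ratio finite when an
     indicator is perfectly tight within clusters (a_n = 0) and scales with
     the data, so the guard is unit-free.
   - `"none"`: weights stay fixed (equal-weight K-means when initialized
     uniform).

   Update: w ← ½(w + Δw). The averaging damps oscillation; since w and Δw are
   both on the simplex, so is the update, exactly — verified to 1e-10 at every
   iteration in the tests.

The exact linear-fractional optimum of (w·b)/(w·a) over the simplex is a
corner (all weight on argmax b_n/a_n); `corner_solution` computes it for
reference and testing, but the iterative margins are what the method uses,
precisely to avoid collapsing onto a single indicator.

Entry points: `miwas_kmeans` (difference margin, modified between — the
package default), `iwas_kmeans` (ratio margin, original between) and `kmeans`
(no adaptation). Each run records a trace (weights, weighted SSE, membership
changes, fallbacks, empty clusters per iteration).

### 1.5 Centroid initialization

`init_centroids_from_standards` maps the grade-k boundary of each indicator
through the fitted preprocessing transform, so cluster k starts on the
grade-k boundary surface in clustering space and K must equal the number of
grades (5 by default). Indicators without standards (pH) are seeded at the
standardized column mean (0 for the training data), expressing "no prior
separation along this axis". `init_centroids_random` picks K distinct rows
with a seeded generator for standards-free use.

### 1.6 Evaluation

- **Weighted SSE**: Σ_n w_n a_n, the clustering objective itself; reported
  alongside the equal-weight SSE of the same partition so algorithms with
  different final weights can be compared on common ground.
- **`compare_algorithms`** runs several configurations from copies of the same
  initial centroids and tabulates SSEs, iteration counts and final weights;
  per-run failures become error rows rather than aborting the comparison.
- **LOOCV** (leave-one-out): the reference partition is the full-data run.
  For each fold, `"refit"` mode reclusters the remaining M−1 samples from the
  same initial centroids, matches fold clusters to reference clusters by
  minimum-cost assignment on squared centroid distances (Hungarian algorithm),
  and assigns the held-out sample with the fold's weights. `"centroid"` mode
  removes the sample's contribution from its own centroid in closed form,
  (n·c − x)/(n − 1), and re-assigns — far cheaper, and a lower bound on how
  much one sample can move the solution. The confusion matrix is reported in
  row percentages; folds where the held-out point is a singleton cluster are
  skipped in centroid mode (the deflated centroid is undefined) and counted.
- **Cluster summaries** report per-cluster means and SDs (ddof=1, SD of a
  singleton cluster reported as 0 and flagged) in original units via the
  inverse transform, plus a cluster-by-site crosstab.

## 2. Synthetic generators

### 2.1 Planted-feature Gaussian mixture (`generate_mixture`)

K clusters of given sizes in N features; on the *informative* features,
cluster k has mean k × `separation`; all other coordinates are
N(0, `noise_sd`²) noise, identical across clusters. Defaults: 3 clusters of
100, 4 features, one informative feature, separation 6, noise SD 1. This is
the controlled test bed for weight recovery: the informative feature is the
only one carrying cluster signal, so an adaptive run should concentrate weight
there. Data are generated directly in clustering (standardized-like) space.

### 2.2 River-monitoring emulation (`generate_haihe_like`)

Emulates a multi-site river monitoring campaign:

1. Each sample gets a latent quality grade drawn from its site's grade mix.
   Site mixes are a Dirichlet tilt of the global `grade_mix` with
   concentration `site_concentration` — sites share the basin-wide profile
   but differ realistically in their local mix.
2. Each indicator is drawn from a base marginal distribution **truncated to
   that grade's band** (between consecutive grade boundaries, intersected with
   a physical range), by inverse-CDF sampling. COD and NH3-N use lognormal
   bases (concentrations; parameters from target mean and coefficient of
   variation); pH and DO use normal bases. pH, having no grade boundaries, is
   drawn from its full physical range regardless of grade — it is
   grade-independent by construction.

Defaults — M = 2000 samples, 7 sites, grade mix
(0.35, 0.30, 0.20, 0.09, 0.06), site concentration 8.0 — were chosen so the
generated column means land near published basin-level summary statistics for
this indicator set (targets pH 8.07, DO 9.02, COD 3.51, NH3-N 0.40; the test
suite checks means within ±30%), with a grade profile dominated by classes
I–III and a thin polluted tail, at a campaign size typical of several years of
monthly multi-site monitoring. Physical ranges: pH [6, 10], DO [0.5, 25.5]
mg/L, COD [0.2, 15] mg/L, NH3-N [0.01, 2] mg/L. Every generated sample is
within grade V by construction.

**What the generator does not emulate:** temporal autocorrelation or
seasonality (dates are metadata only, drawn uniformly), spatial covariance
beyond the per-site grade mix, measurement error or censoring at detection
limits, and cross-indicator correlation beyond the shared latent grade — all
graded indicators of a sample sit in the *same* grade band, i.e. indicators
are perfectly grade-coupled, which makes clusters cleaner than field data.
Benchmark results on it demonstrate algorithmic behaviour, not field
performance.

## 3. Numerical conventions

- All randomness flows through `numpy.random.default_rng` with explicit seeds;
  identical config + seed reproduces byte-identical artifacts.
- Assignment and grade ties break to the lowest index/grade, deterministically.
- Simplex membership is enforced to 1e-10; the difference margin's degeneracy
  tolerance is 1e-12 on the spread of δ. The ½(w + Δw) update introduces no
  drift (checked over 10⁴ iterations).
- Non-finite values reaching the clustering core raise immediately rather than
  propagating.
- Distance computations are vectorised (einsum) but defined by, and tested
  against, plain-loop oracles.

## 4. Open design decisions

- The difference margin's min-shifted projection is one of several valid ways
  to map a zero-sum score onto the simplex (softmax is another); it was chosen
  for being parameter-free and exactly rank-preserving. The uniform fallback
  on degenerate margins is likewise a choice — holding the previous weights
  would also be defensible.
- `empty_cluster="keep"` is the default because it is deterministic and
  side-effect-free; `"reseed"` recovers lost clusters faster on pathological
  inits but makes the trajectory depend on the reseeding heuristic.
- The assignment-stability stopping rule can in principle cycle under weight
  adaptation (the weighted objective changes between iterations); the
  `max_iter` guard bounds this, and no cycle has been observed in the test
  workloads.
- K is tied to the number of grades when seeding from standards; choosing K
  independently (elbow/gap heuristics) is out of scope.

## 5. Limitations

- Hard assignments only; no fuzzy or probabilistic membership.
- Weights are global, not per-cluster; an indicator that separates only one
  pair of clusters is under-credited.
- The SSE comparison across algorithms uses each algorithm's own final
  weights for its weighted SSE; the equal-weight SSE column is the
  like-for-like number.
- LOOCV refit mode costs M full clusterings and is intended for moderate M;
  centroid mode is the cheap screen.
- The grade filter trusts the standards table; indicators absent from it are
  never filtered and never graded.
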