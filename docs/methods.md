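# Methods

`connectopharm` implements a task-free (resting-state) fMRI brain-network
analysis for a placebo-controlled pharmacological crossover study, together
with a synthetic cohort generator that makes every stage testable without
access to patient data. This note describes the models, the parameters that
matter, the numerical choices, and what the synthetic experiments do and do
not establish.

## Pipeline overview

Per subject-session, a node × time BOLD matrix passes through:

1. **Volume trimming** — the first 5 volumes are discarded
   (magnetization equilibration).
2. **High-pass filtering** — zero-phase Butterworth (order 2, applied
   forward-backward) with a 0.01 Hz cutoff; the mean is removed.
3. **Nuisance regression** — OLS projection onto an intercept plus supplied
   regressors (e.g. motion-parameter derivatives, CSF signal); residuals
   are exactly orthogonal to the design. Rank-deficient designs fall back
   to the pseudo-inverse with a warning.
4. **Wavelet correlation** — MODWT detail coefficients at scale 3
   (Daubechies-4 by default), Pearson-correlated across node pairs after
   discarding the `L_j − 1 = 49` leading coefficients affected by circular
   filtering. At TR = 2 s, scale 3 covers ≈ 0.031–0.0625 Hz, inside the
   conventional resting-state band and above the high-pass cutoff. Both
   wavelet and scale are configuration options.
5. **Fisher z** — `z = atanh(r)` off-diagonal (variance stabilization);
   values at |r| = 1 are clipped to 1 − 1e−7 with a warning.
6. **Local thresholding** — a binary graph at an exact edge density
   (schedule 1–10 %, primary analysis at 6 %).
7. **Graph metrics** — path length, clustering, modularity, and per-node
   degree / betweenness / closeness / eigenvector centrality.
8. **Hub definition** — split-half degree rule on the control group.
9. **Statistics** — control-vs-patient t-tests and drug-effect
   difference-score regressions on clinical covariates.

### Wavelet correlation and its effective sample size

MODWT (maximal-overlap discrete wavelet transform) coefficients are
computed by circular filtering with the rescaled filters `h/√2`, `g/√2`
(FFT-based convolution with up-sampled filters). Because the MODWT is
non-decimated, scale-`j` coefficients are strongly autocorrelated within a
series: the empirical null SD of the scale-3 correlation at T = 140 is
≈ 0.23 ≈ `1/√(T/2³)`, not `1/√91`. All calibration therefore uses the
effective sample size `N_j = (boundary-free count)/2^j` (the count of
non-redundant coefficients the band supports), exposed as
`connectivity.effective_df`. The 1 % two-sided null bound used in the
calibration experiment is `2.58/√N_j`.

### Local thresholding

Global cutoffs fragment sparse brain graphs; local thresholding preserves
every node's strongest links:

* **Stage 1** — maximum spanning tree over edge strengths (absolute
  Fisher-z values), guaranteeing connectedness at every density.
* **Stage 2** — for k = 1, 2, …, add each node's k-th strongest neighbour
  edge if absent (union of k-nearest-neighbour graphs). After the round
  that overshoots the target `m* = round(density · n(n−1)/2)`, the weakest
  edges added in that round are removed (never tree edges) until exactly
  `m*` remain.

Ties are broken by weight descending, then smaller node-index pair, so the
construction is fully deterministic. Edge strength is sign-agnostic (|z|):
the analysis does not distinguish strong negative from strong positive
coupling, a deliberate policy choice surfaced in the configuration. Since
`atanh` is strictly increasing, thresholding the r-matrix and the z-matrix
yields the identical graph (tested as an invariant); the Fisher transform
matters only for downstream statistics on weights. Densities below the
spanning-tree minimum `(n−1)/(n(n−1)/2)` are rejected with an error — at
n = 100 a 1 % density (50 edges) cannot support a connected graph.

### Graph metrics

* Path length: mean geodesic over unordered pairs (all-pairs BFS; the
  distance matrix is computed by `scipy.sparse.csgraph`).
* Clustering: mean of `C_i = 2t_i/(k_i(k_i−1))`, `C_i = 0` for degree < 2;
  triangle counts from the diagonal of A³.
* Modularity: Newman–Girvan Q of the best Louvain partition over
  `n_restarts` (default 20) seeded restarts; Q is reported as the maximum.
* Betweenness: Brandes accumulation over unordered pairs, endpoints
  excluded; stored unnormalized, written to tables divided by
  `(n−1)(n−2)/2` (no normalization convention is canonical; this one is
  fixed and documented).
* Closeness: `(n−1)/Σd`.
* Eigenvector centrality: power iteration on `A + I` (the shift makes the
  iteration matrix primitive for every connected graph — plain power
  iteration oscillates on bipartite graphs such as low-density trees —
  without changing the eigenvector), normalized to maximum 1. Tolerance
  1e−12 on the max-norm change, up to 10⁴ iterations.

All five are validated against independent brute-force enumeration (BFS,
path enumeration, exhaustive partition search) on hundreds of random small
graphs.

### Hub definition

Hubs are nodes, not subjects: degree at the primary density is averaged
across the *definition* half of the controls, and nodes exceeding the
across-node mean by more than 1.5 SD (SD over nodes of the cohort-mean
degree vector) are hubs. The other half of the controls is reserved for
evaluation, so disease comparisons of hub metrics never reuse the subjects
that chose the hubs. An odd control count puts the extra subject in the
evaluation half (75 → 37/38). "Connection strength" is read as binary
degree at the primary density; a weighted variant would be a
straightforward extension but is not what the split-half rule needs.

### Statistics

* Outlier screening: values beyond 2 SD from the mean removed, single pass,
  mean/SD including the candidates.
* Disease effect: Welch two-sample t-tests (pooled available), patients on
  placebo versus controls — hub metrics against the evaluation half only,
  global metrics against the full control group. No multiple-comparison
  correction is applied (network measures are not independent); every
  report says so explicitly.
* Drug effects: the repeated-measures drug × covariate interaction for a
  two-level within-subject factor is algebraically a regression of the
  within-subject difference (drug − placebo) on the covariate, which is how
  it is implemented. Covariates (age, disease severity, levodopa
  equivalent dose, plasma concentration, cognitive change) are analysed
  one at a time; slope, r² (squared Pearson correlation), two-tailed p and
  CI are reported.

## The synthetic cohort

The generator emulates the target study design: 75 controls scanned once and 30
patients scanned on placebo, a noradrenergic drug (atomoxetine-like) and a
serotonergic drug (citalopram-like), drug order counter-balanced as the six
session permutations within blocks of six patients. Covariate
distributions follow the emulated design's baseline table (UPDRS-III 22.6 (6.8);
LED 870 (469) mg/day; plasma 372.1 (167.4) and 35.6 (14.7) ng/ml; age,
fluency and stop-signal distributions per group).

Node signals follow a modular factor model:

```
x_i(t) = λ_i g_m(i)(t) + [i is hub] Σ_{k≠m(i)} η g_k(t) + ε_i(t)
```

with one latent AR(1) time course `g_m` per module (coefficient 0.6 at
TR 2 s, unit stationary variance, so spectral power concentrates in the
0.01–0.1 Hz band), within-module loading λ (default 1.0), hub cross-module
loading η (default 0.35), and white noise ε (SD 1.0). Expected raw
within-module correlation is `λ²/(λ² + σ²)` = 0.5 at the defaults — mid-range
for band-limited BOLD connectivity.

Geometry: 473 usable nodes (a 500-node parcellation after coverage
exclusion), 20 modules, 5 % hub nodes spread round-robin across modules.
Twenty modules keeps the module size (≈ 5 % of nodes) just below the mean
degree at the 6 % primary density, so each node's strongest-neighbour
budget is exhausted within its module and the remaining edges go to the
cross-module hubs — the geometry that makes hubs hubs. Effects are
multiplicative on loadings (never additive on correlations), so induced
correlations stay in [−1, 1] by construction:

* **Disease**: hub loadings (λ and η of hub nodes) × (1 − 0.2) in patients.
* **Noradrenergic drug**: η × (1 + 0.5 · z), z the standardized plasma
  concentration — hub coupling rises with drug level.
* **Serotonergic drug**: λ × (1 − 0.02 · (UPDRS − 30)) — segregation
  increases below the severity pivot of 30 and decreases above it.

Cognitive outcomes (category fluency, stop-signal RT) are linear in the
injected hub-coupling excess plus noise (gains 8 words and −60 ms per unit
of η-excess, session noise SD 2 words / 20 ms), so brain–behaviour
regressions have recoverable ground truth. Every factor actually applied
is recorded in `GroundTruth.injected`.

Motion traces are zero-translation except for single-volume spikes
(probability 0.02/volume, SD 0.3 mm per axis); a designated outlier gets
6× spikes plus a translational random walk (step SD 0.24 mm). Rotations
follow a small random walk and do not enter the RMS displacement statistic,
which is the mean over successive volume pairs of the Euclidean norm of the
translation difference (frame-to-frame differences, not displacement from a
reference volume — the convention is stated because both exist in the
field).

### What the generator does not emulate

Real BOLD data have spatially structured noise, physiological rhythms
(cardiac/respiratory aliasing), scanner drift beyond a random walk,
hemodynamic response variability, spatial autocorrelation between
neighbouring parcels, and registration/atrophy artefacts. Passing the
synthetic experiments shows the *pipeline* is correct and calibrated (exact
densities, valid type-I error, recoverable planted effects); it does not
show that real drug effects of comparable size would be detected at these
sample sizes, nor validate the preprocessing against real confounds.

## Validation experiments and problem sizes

The `experiments` module defines the package's Monte-Carlo validation
studies; the same functions back the test suite and
`scripts/acceptance.py`:

* **Null calibration** — 1000 independent white-noise pairs at T = 140;
  fraction of |r| inside `2.58/√N_j`.
* **Hub recovery** — 20 seeds at the full design (473 nodes, 37 definition
  controls); sensitivity and false-discovery rate against the planted hub
  set. At desk scale (~150 nodes, 8 definition subjects) the FDR is
  naturally higher (~1 false hub among 8 planted), which is why the strict
  bounds are enforced at full size.
* **Type-I error** — 63 null cohorts (no injected effects) at 60 nodes,
  12 controls, 30 patients, 145 volumes; > 1000 difference-score
  regressions (clustering, path length, hub degree, hub eigenvector
  centrality × two covariates × two drugs per cohort). Modularity and
  betweenness are omitted here purely for runtime; they add no power to a
  null-calibration check.
* **Drug-effect sign recovery** — 50 seeds at 150 nodes with the design's
  full control group (75 → 37 definition subjects) and 30 patients. The
  atomoxetine check (positive slope of Δ hub eigenvector centrality on
  plasma) is the most delicate: eigenvector centrality is max-normalized,
  so the hub mean saturates near the ceiling and the signal comes mostly
  from low-plasma sessions; a clean hub set (hence the full control group)
  is what makes the sign reliable. The citalopram check (negative slope of
  Δ clustering on UPDRS about the pivot) is robust at any of the sizes
  tried.
* **Motion QC** — 100 seeds, one planted outlier among 10 subjects;
  detection by the one-sided mean + 2 SD rule.
* **Determinism** — the demo configuration (20 controls, 10 patients,
  90 nodes) run twice; metric tables must be byte-identical below the
  configuration-hash line.

These sizes were chosen so the full suite runs in well under half an hour
on one core while preserving each experiment's geometry; they are stated
here because the numbers in `results/acceptance.json` are functions of
them.

## Design choices where the design was open

* **Outlier and exclusion rules are single-pass** (mean/SD include the
  candidates, no iterative re-screening) and the absolute motion rule is
  one-sided — unusually *low* motion is never an artefact.
* **RMS displacement** uses frame-to-frame differences (above).
* **Hub SD over nodes, not subjects**: the rule selects nodes, so the
  relevant spread is across nodes of the cohort-mean degree vector.
* **Fisher-z before thresholding**; order is immaterial for the graph
  (rank preservation) and is tested as such.
* **Welch is the default t-test** (unequal group sizes and variances);
  pooled is available for probing summary-statistics comparisons.
* **Counter-balancing** enumerates all six session orders per block of six
  patients, shuffled within block.
* **Session seeds** derive from `(cohort seed, subject index, session)` via
  `numpy.random.SeedSequence`, so any record can be re-simulated in
  isolation, bit-identically.

## Known limitations

* Weighted-graph metrics, rich-club coefficients and the small-world index
  are out of scope.
* The modularity optimizer is a restarted Louvain heuristic; Q is a lower
  bound on the optimum (exact only where tested exhaustively).
* `coverage_exclude` screens zero-variance/missing nodes; in the synthetic
  cohort nodes are always covered, so the rule is exercised by unit tests
  rather than by the default pipeline run.
* The stats stage analyses covariates one at a time by design; joint
  models (mixed effects, multiple regression) are deliberately not
  provided.
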