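# Methods

`dmnet` re-implements, as a reusable and tested pipeline, a
graph-theoretic analysis of the default mode network (DMN) in
resting-state fMRI: regional time series are denoised, correlated,
thresholded into binary graphs across a sparsity range, summarized by
small-world and efficiency metrics against a degree-preserving random
null, reduced to area-under-curve (AUC) scalars, and compared between
two groups (severe obstructive sleep apnea patients, OSA, vs good
sleepers, GS) with covariate adjustment and clinical correlations.
Because no subject-level data from the original cohort are available,
the package ships a synthetic cohort generator whose ground truth is
known by construction; every claim the test suite makes about recovery
and error rates is a claim about that generator, not about real scans.

## Network model

Nodes are 20 canonical DMN subregions (packaged table
`data/dmn_rois.csv`: name, anatomical region, Brodmann areas, MNI
coordinate, and an anterior/posterior subsystem label used only by the
generator). Functional connectivity is the 20 x 20 Pearson correlation
matrix of the (denoised) regional signals; the diagonal is fixed to
zero and excluded everywhere.

A correlation matrix is reduced to binary graphs at each sparsity
`Sp` in the default grid 0.05–0.50, step 0.01 (46 levels):
`K = round(Sp * N(N-1)/2)` edges with the largest correlations are
kept. Conventions that change results and are therefore fixed and
documented:

* **Rounding**: half away from zero (at N = 20, Sp = 0.05 keeps
  round(9.5) = 10 edges; round-half-even would keep 9).
* **Ranking**: signed correlations by default (the dominant convention
  in this literature — strong negative correlations are *not* treated
  as strong edges); `rank="abs"` is available.
* **Ties**: broken by lexicographic node-pair order, so thresholding
  is deterministic even on degenerate inputs.

## Graph metrics

On each binary graph the package computes:

* nodal clustering `Ci` (fraction of realized links among neighbors;
  `Ci = 0` for degree < 2) and its mean `Cp`;
* characteristic path length as the **harmonic mean** distance,
  `Lp = n(n-1) / Σ_{i≠j} 1/d_ij` with `1/∞ = 0`, which stays finite on
  disconnected graphs and satisfies `Lp · Eglob = 1` exactly;
* global efficiency `Eglob` (mean inverse distance) and local
  efficiency `Eloc` (mean, over nodes, of the efficiency of the
  neighbor-induced subgraph; neighborhoods of < 2 nodes contribute 0);
* nodal degree, unnormalized betweenness (sum over unordered pairs of
  the fraction of shortest paths through the node; the group t-test is
  invariant to the normalization constant), and nodal efficiency
  `e_i = mean_j 1/d_ij`;
* largest-component size (isolated nodes are size-1 components; an
  empty graph reports 1).

Small-worldness is normalized against degree-preserving random
networks generated by Maslov–Sneppen double-edge swaps:
`gamma = Cp/⟨Cp_rand⟩`, `lambda = Lp/⟨Lp_rand⟩`, `sigma = gamma/lambda`.
Defaults are 1,000 random networks and 100 swap attempts per edge
(both configurable; the per-subject curves in the shipped replicate
studies use far smaller ensembles, see below). Proposals creating
self-loops or multi-edges are rejected; if no valid swap exists within
the attempt budget (e.g. a star graph) the graph is returned unchanged
with a warning. An ensemble with zero mean clustering makes `gamma`
undefined; it is reported as missing, never as infinity. The null
preserves the degree sequence but not connectedness (whether the
original analysis preserved connectedness is unstated; this choice is
logged here).

Each metric's curve over the sparsity grid is reduced to a trapezoidal
AUC. Missing curve points (e.g. undefined `gamma` at a level) are
dropped pairwise with a warning; a curve with fewer than two finite
points has no AUC.

### Implementation notes

All metrics are computed by a vectorized numpy engine: all-pairs BFS
via level-synchronous boolean matrix products, betweenness via a
level-synchronous (all-sources-at-once) form of Brandes' dependency
accumulation, local efficiency via zero-padded batched neighbor
subgraphs, and thresholding of all 46 levels from a single edge
ranking. This keeps a full 92-subject cohort (46 levels x 92 graphs,
all metrics) near one second, which is what makes the replicate
studies in the test suite affordable. The engine is verified to
1e-12 against a deliberately naive brute-force implementation
(Floyd–Warshall plus explicit shortest-path enumeration) exhaustively
on all connected graphs with n ≤ 5 and on random graphs with n = 6, 7,
and cross-checked against networkx. The ensemble rewirer applies
blocks of non-conflicting swap proposals per vectorized step; each
accepted double swap preserves the degree sequence exactly, so the
blocked chain is still a valid Maslov–Sneppen randomization
(validity checks against a block-stale adjacency only make the chain
slightly more conservative).

## Preprocessing

Operating on extracted regional signals only (image-space steps —
realignment, normalization, smoothing — are out of scope), in the
listed order: linear detrend; band-pass 0.01–0.08 Hz; regression of
nuisance signals (white matter, CSF, global signal) plus the
24-parameter motion expansion `[R(t), R(t-1), R(t)², R(t-1)²]`.
The band-pass is an ideal discrete-frequency mask (band-inclusive,
DC removed when low > 0) rather than an IIR/FIR design: the band is the
only published specification, and the mask is exactly idempotent and
bit-reproducible. Nuisance regression always includes an intercept and
drops rank-deficient regressor columns with a warning. Whether
filtering preceded regression in the original execution is unstated;
the listed order is the default and the alternative order is available
via `denoise(..., order=...)`.

Motion QC excludes a subject when max |translation| > 2.0 mm, max
|rotation| > 2.0° (thresholds interpreted in the printed units), or
mean relative RMS displacement > 0.2 mm. "Relative RMS" is not defined
in the source; here it is the volume-to-volume Euclidean step of the
three translation parameters, averaged over volumes.

## Group statistics

* **Summary t-tests**: pooled-variance two-sample t from printed
  mean/SD/n, df = n1+n2-2 (identical to Welch at equal n and the same
  formula the published demographic table used, which is why ten of
  its t values are reproduced to ±0.03 from two-decimal summaries; the
  oxygen-desaturation row is not reproducible from its printed
  summaries and is flagged in the packaged table).
* **Covariate adjustment**: OLS residualization of the outcome on
  [intercept, age, BMI, education], fitted on the pooled sample so
  group-specific covariate slopes cannot enter the contrast.
* **Edgewise tests**: Fisher z-transform (variance-stabilizing, |r|=1
  clipped at 1-1e-7 with a warning), residualize, pooled t per edge;
  flagged at p < 0.05 uncorrected, matching the exploratory design.
* **Nodal tests**: per node x {degree, betweenness, efficiency} on
  AUCs, Bonferroni multiplier = number of nodes per metric family,
  capped at 1; uncorrected and corrected flags both emitted.
* **Composite score**: mean *raw* correlation over the edges showing a
  significant group difference (the tests run on Fisher z, the
  composite on raw r — the source's composite wording names
  correlation coefficients; both choices are configurable). The edge
  set is determined within the analyzed cohort unless supplied.
* **Clinical correlations**: Pearson r with two-sided t-based p,
  pairwise-complete, computed within the patient group.

Sign convention throughout: positive t means group 1 (patients) above
group 2, with `group1` selectable so that relabeling flips t exactly.

## Synthetic cohort generator

The generator defines the study conditions the tests run under:
46 subjects per group, 230 volumes at TR = 2 s, 20 nodes.

* **Connectivity truth**: a two-module block correlation matrix
  (anterior 8 / posterior 12), within-module r = 0.45, between-module
  r = 0.15. The patient group's matrix subtracts 0.25 from 8
  posterior-module edges (PCC–HF, PCC–Rsp, HF–Rsp pairs), emulating
  decreased posterior DMN coupling. Both matrices are repaired to
  positive definiteness by eigenvalue clipping at 1e-6 and diagonal
  re-normalization (naive delta injection can break PD), with an error
  listing offending eigenvalues if repair fails.
* **Signals**: Gaussian lag-1 autoregressive processes (AR coefficient
  0.3, a typical resting-state autocorrelation at this TR) whose
  innovation correlation equals the target matrix — the simplest model
  carrying the correlation structure the analysis assumes; spectral or
  hemodynamic realism is explicitly not attempted. Per-node linear
  drift (slope SD 1.0) and three shared smooth nuisance processes
  (loading SD 0.5) are injected for preprocessing to remove.
* **Motion**: bounded (reflecting at ±1.8) random walks on the 6
  rigid-body parameters; the step SD (default 0.05 mm/deg, passing QC)
  controls how often the exclusion rule fires.
* **Clinical variables**: drawn per group from the packaged published
  summaries (AHI clamped to its diagnostic ranges, ≥30 / <5). The MoCA
  score is coupled, within the patient group, to each subject's
  realized mean correlation over the affected edges at target r =
  -0.37, so the clinical-correlation stage has a recoverable signal.
* **Adjustment covariates** (age, BMI, education) are drawn
  group-matched by default. This is deliberate: an independently
  sampled group-*separated* covariate is a pure confound that absorbs
  a large fraction of the true group contrast under pooled
  residualization (with the published BMI separation, about 40%),
  which would defeat the generator's purpose of providing recoverable
  truth — and it is not what adjustment encounters in real cohorts,
  where BMI tracks disease severity rather than being an independent
  coin-flip. `match_covariates=False` restores the group-separated
  BMI for confound studies. The published group separations remain
  available to the summary-statistics machinery via the packaged
  table.

All generators are pure functions of their seed; cohorts round-trip
through a plain-text on-disk format (one TSV per subject, subjects.csv
manifest with per-subject seeds, ground_truth.json).

What the generator does *not* emulate — voxel-level structure, slow
physiological rhythms, scanner drift nonlinearity, heavy-tailed motion,
site effects — bounds what passing tests mean: they demonstrate that
the pipeline recovers known correlation-structure differences under
Gaussian AR noise at the study's dimensions, not that it would detect
the same effects in arbitrary real data.

## Replicate-study problem sizes

The recovery and error-rate tests run the full pipeline on replicate
cohorts at the complete study design. Sizes were chosen so the whole
suite stays in the tens of minutes on one core:

* effect direction (Cp AUC t < 0 under the posterior attenuation):
  100 cohorts, raw metrics only;
* null rejection rates for Cp/Lp/Eglob and edgewise/nodal type-I:
  200 delta-free cohorts;
* null rejection for sigma: 50 delta-free cohorts with a deliberately
  tiny null ensemble (2 rewired graphs, 1 swap per edge). Under the
  null both groups share the same ensemble-noise distribution, so the
  test's size is unaffected by ensemble quality — only the *precision*
  of sigma estimates is, which is not what that test measures.

Observed rates are checked against two-sided binomial bands at the
respective replicate counts.

## Known limitations

* Betweenness at 1,000-network ensembles is not precomputed anywhere;
  sigma normalization at the published ensemble size is minutes per
  subject and intended for single-cohort runs, not replicate studies.
* The ideal band-pass assumes stationarity and wraps edges (circular
  convolution); with 230 volumes the leakage is negligible relative to
  between-subject variance but it is not a causal filter.
* `Eloc` of the patient group decreases only weakly under the default
  attenuation (the affected edges sit in a 12-node module whose local
  neighborhoods stay well connected), so its group test is
  underpowered at this effect size — consistent with the borderline
  trend the original analysis reported for it.
* Sphere extraction uses voxel-center membership (boundary inclusive);
  voxel counts differ between membership conventions, so the
  convention is part of the contract.
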