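# Methods

## The statistic

For one subject, the T-volume, M-node ROI time-series matrix is divided
into N = floor(T / l) contiguous non-overlapping windows of l volumes,
anchored at the first volume (the trailing T − N·l volumes are discarded).
Within each window the M×M functional-connectivity (FC) matrix is the
Pearson correlation of the windowed signals — raw signed r, no Fisher
transform, no thresholding (an optional Fisher-z flag exists but is off by
default).

For a *unit* — a node's connectivity profile (its FC row with the
self-entry removed, length M−1), a module's within-block upper triangle,
or a between-module block (every cross pair once, row-major over sorted
node indices, the lexicographically smaller module label first) — the
per-window FC values are unfolded into a vector f_i, and the temporal
variability is

    V = 1 − (2 / (N(N−1))) · Σ_{i<j} corr(f_i, f_j),

one minus the mean Pearson correlation over all N(N−1)/2 window pairs.
V ∈ [0, 2]: 0 when the pattern is perfectly stable, above 1 when profiles
anti-correlate.  The fixed canonical unfolding order makes results
bit-reproducible and makes the inter-network value exactly symmetric in
its two module arguments.

Degenerate inputs: a node constant within a window is a hard error by
default (silent NaN propagation would corrupt the group statistics
downstream); with `skip_degenerate_windows` the window is dropped for all
units, keeping windows aligned.  A unit whose unfolded vector has zero
variance in some window yields a missing value plus a diagnostic, and
missing values are excluded pairwise downstream with counts logged.

Defaults follow the study regime: l = 20 volumes (40 s at TR = 2 s),
robustness sweep over l = 10..20, T = 200 volumes, 264 nodes in 13
modules with the "Uncertain" module computed everywhere but excluded from
default reports.

## Inference

Group differences (patients minus controls, difference of unit means) are
tested by label permutation preserving group sizes, 10000 permutations by
default, with the add-one tail estimator p = (k + 1)/(n_perm + 1) so a
Monte-Carlo p is never zero; both one-sided tails and the two-sided
p = min(1, 2·min(tails)) are reported.  Reporting thresholds mirror the
study design: nodal p < 0.005 uncorrected, network-level p < 0.05 and
p < 0.005 tiers; Benjamini–Hochberg correction is available behind a flag
but off by default.  Within-group intra-vs-inter comparisons use a paired
sign-flip permutation on the per-subject difference between a module's
intra-network variability and its mean inter-network variability with the
other modules.

Clinical association is Spearman rank correlation between per-patient
variability and the motor-severity score, after a single-pass outlier
screen that drops values more than 3 SD (n−1 denominator) from the mean —
applied to the variability values by default, optionally also to the
scores (the screened and unscreened results are both retained).  The p is
exact (full permutation enumeration) for n ≤ 9 and the t approximation
otherwise.  Demographics: sex ratios by chi-square without continuity
correction (for the published table sizes this is numerically equivalent
to a pooled t on binary coding); continuous demographics by Welch t, with
a summary-statistic entry point so printed tables can be checked.

## The synthetic cohort

No scan data ship with the package; the generator produces cohorts with
the statistical structure the analysis assumes, so every pipeline stage
runs and can be validated end to end.

Generative model, per cohort (all randomness seeded):

1. **Stationary structure.** A modular block correlation matrix
   (r_within = 0.4 inside modules, r_between = 0.05 across) is blended,
   node by node, with a random factor correlation matrix R of rank
   `hetero_rank` = 3: B = (u uᵀ)∘R + (v vᵀ)∘block with u_k = √w_k,
   v_k = √(1−w_k) and stable-structure fractions w_k ~ U(0.05, 0.95)
   drawn once per cohort.  Both Schur terms are positive semidefinite and
   the diagonal is exactly 1.  The w_k gradient is what gives the cohort a
   realistic node-level variability map: nodes with high w carry a strong
   persistent connectivity pattern (low V), nodes with low w are
   noise-dominated (high V).  Without this heterogeneity every within-module
   entry would be identical, unfolded module vectors would carry no
   persistent pattern, and — counterintuitively — *increasing* the dynamic
   perturbation would *lower* the variability statistic, because the mean
   pairwise profile correlation is (b² + ρ̄a²)/(b² + a² + σ²): the injected
   amplitude a² raises V only where the persistent profile variance b²
   exceeds ρ̄(b² + σ²), with ρ̄ the same-state window-pair fraction and σ²
   the window-sampling noise.

2. **States.** Each subject has `n_states` = 8 connectivity states:
   C_s = B + D S_s D, where D = diag(per-node amplitude) — amp_target =
   0.25 on nodes of the target modules (subcortical, sensorimotor, visual,
   cerebellum), amp_base = 0.08 elsewhere — and S_s is a zero-mean random
   symmetric matrix of rank `perturb_rank` = 3 with O(1) entries
   (unit-norm directions rescaled to ‖v‖² = M, random ±1 signs).
   Indefinite results are repaired by eigenvalue clipping at 1e−6 and
   re-normalization to unit diagonal.  Eight states keep state recurrence
   between windows low (ρ̄ ≈ 0.2); with very few recurring states the
   same-state term ρ̄a² would re-correlate window pairs and suppress the
   group effect below detectability at the cohort sizes used.

3. **Dynamics.** The state sequence switches with probability
   1/mean_dwell per volume (geometric dwells, mean 25 volumes ≈ 50 s, so
   20-TR windows straddle state changes as real dFC windows do).  Within a
   dwell the signal is multivariate normal with the state's correlation,
   then smoothed by a unit-variance AR(1) filter,
   x_t = φ x_{t−1} + √(1−φ²) e_t with φ = 0.3 standing in for hemodynamic
   and band-pass smoothness.  The normalization makes the single-state
   stationary correlation equal B exactly.

4. **Group and severity.** Patients carry a gain on the target-module
   amplitude: gain = 1 + (group_gain − 1)(c·severity + 1 − c) with
   group_gain = 1.8, coupling c = 0.7, severity ~ U(0, 1).  The observed
   score is score_scale·severity + N(0, 0.1·score_scale), truncated at 0,
   with score_scale = 40 emulating a motor-scale range; controls receive
   no score.  Cohort sizes default to 40 controls + 42 patients.

What the generator does *not* emulate: hemodynamic response convolution,
spatial smoothing and spatial autocorrelation between neighbouring ROIs,
head motion and its artefacts, scanner drift, non-Gaussian BOLD noise, and
anatomically realistic module topography.  Passing tests therefore show
that the statistics and inference machinery behave correctly on data with
the assumed covariance structure — not that the pipeline is robust to
acquisition artefacts.

## Calibration choices and what the validation shows

The study's generative parameters were fixed once, from pilot effect-size
arithmetic, to land in the regime the method is meant for: nodal V
centred near 0.6 with a node-level spread of ~0.1, patient-minus-control
intra-network differences of ~0.02–0.05, and group effects detectable but
not trivial at n = 40 + 42.

- **Window-length robustness.** Variability maps computed at l = 10..20
  correlate across lengths.  With per-subject correlation (computed over
  nodes, then averaged over subjects) the minimum pairwise value on the
  default cohort is ≈ 0.96.  Per-node estimation noise (SD ≈ 0.02–0.03 at
  N = 10 windows) bounds this number: even implausibly wide node-level
  spreads cannot push the per-subject correlation much past ≈ 0.97.
  Correlating cohort-averaged maps instead would give ≈ 0.99+; the
  per-subject convention is the stricter reading and is the one
  implemented.
- **Null calibration.** On single-state null cohorts (no group effect)
  the permutation test's one-sided rejection rate at α = 0.05 over 2000
  unit tests is within [0.04, 0.06].  Single-state cohorts are used
  because a realized state sequence shifts variability at every unit of a
  subject jointly; with state switching the 2000 tests would be strongly
  dependent and the binomial band uninformative.  Many small independent
  cohorts (1000 cohorts × 2 units) keep the tests effectively independent.
- **Effect recovery.** Over 25 replicate default cohorts, the two-sided
  permutation test at α = 0.05 flags elevated intra-network variability in
  ≈ 88% of target-module tests, and the median Spearman rho between
  target-module intra variability and the severity score is positive in
  ≈ 96% of replicates.  The median across the four target modules is the
  summary used because the cerebellum module has only 4 nodes (6
  within-module pairs), making its variability estimate noise-dominated —
  an estimator property, not a generator artefact.

## Numerical choices

- Pearson profile correlations use population normalization internally
  (the denominator convention cancels in correlations).
- Permutation tie handling: permuted differences within 1e−12 (scaled) of
  the observed difference count as extreme, so identity relabelings are
  never lost to floating-point jitter.
- Cross-length averaging propagates a unit missing at more than one
  length as missing; with a single missing length the mean of the present
  values is used and the count recorded.
- Eigenvalue clipping threshold 1e−6; a clipped matrix whose diagonal
  vanishes raises a parameter-range error instead of silently distorting.
- All stochastic procedures take explicit integer seeds; a pipeline run
  writes its full resolved configuration to `run_summary.json`, which
  suffices to reproduce every number byte-for-byte (timings go to the log
  only).

## Problem sizes used in validation

The test suite exercises the full default cohort (82 subjects × 264
nodes) for the window sweep and effect-recovery checks, 1000 small
cohorts for null calibration, and reduced geometries (tens of nodes,
8–24 subjects) for property and direction-only checks, with permutation
counts of 199–4999 in tests against the 10000 default.

## Known limitations

- The variability statistic for very small modules (< ~6 nodes) is
  intrinsically noisy; interpret its group tests and correlations with
  care.
- The generator's states are drawn independently per subject; there is no
  cohort-level state library, so state-level group analyses (e.g. dwell
  time comparisons) are out of scope.
- Non-overlapping windows follow the source method; overlapping or
  tapered windows, DCC/GARCH models, k-means state clustering and
  graph-theoretic summaries are deliberately not implemented.
- The exact Spearman p is enumerated only for n ≤ 9 pairs; above that the
  t approximation is used (adequate for the cohort sizes here).
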