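# dfcvar — temporal variability of dynamic functional connectivity

`dfcvar` quantifies how a brain network's functional connectivity (FC)
reconfigures over time in resting-state fMRI, and tests whether that
reconfiguration differs between patient and control groups and tracks
clinical severity.  It was built around the kind of study that asks
whether a disease such as Parkinson's destabilizes specific brain
systems — subcortical, sensorimotor, visual, cerebellar — rather than
changing average connectivity.

It is aimed at researchers who already have preprocessed ROI time series
(one T×M matrix per subject) and a node-to-module partition, and want a
tested, reproducible pipeline from those inputs to group-level inference.
Because such cohorts are rarely shareable, the package includes a
first-class synthetic-cohort generator with known ground truth, so the
entire pipeline can be exercised and validated without any scan data.

## The statistic

Each subject's series is cut into N = ⌊T/l⌋ non-overlapping windows of
l volumes, and the M×M Pearson FC matrix is computed per window.  For a
unit of interest — node k's connectivity profile F_{i,k} (its FC row in
window i, self-entry removed), a module's within-block upper triangle, or
a between-module block — the windowed values are unfolded into vectors
and the temporal variability is

    V_k = 1 − (2 / (N(N−1))) Σ_{i<j} corr(F_{i,k}, F_{j,k}),

one minus the mean pairwise Pearson correlation of the unit's
connectivity vectors across windows (V ∈ [0, 2]; 0 = perfectly stable).
Group differences are tested with label-permutation tests (difference of
group means, 10000 permutations, add-one tail p), within-group
intra-vs-inter contrasts with paired sign-flip permutation, and clinical
association with Spearman correlation after a 3 SD outlier screen.
See `docs/methods.md` for the full model and all conventions.

## Worked example

Simulate a small cohort and run every stage:

```bash
dfcvar simulate --out demo_cohort --seed 7
dfcvar run-all --manifest demo_cohort/manifest.tsv \
               --partition demo_cohort/partition.tsv \
               --out demo_run --n-perm 2000 --seed 7
```

or, in Python, at full study scale (40 controls + 42 patients, 264 nodes,
200 volumes at TR = 2 s):

```python
import numpy as np
from dfcvar import CohortSpec, WindowSpec, simulate_cohort, variability_set
from dfcvar.stats import permutation_group_test

spec = CohortSpec(seed=1)
cohort = simulate_cohort(spec)
is_pat = np.array([s.group == "patient" for s in cohort.subjects])
intra = np.array([
    variability_set(s.series, spec.partition, WindowSpec(20))
    .module_matrix.loc["Subcortical", "Subcortical"]
    for s in cohort.subjects
])
res = permutation_group_test(intra[~is_pat], intra[is_pat], n_perm=2000, seed=1)
print(f"intra-subcortical variability: control {intra[~is_pat].mean():.3f}, "
      f"patient {intra[is_pat].mean():.3f}, "
      f"diff {res.observed_diff:+.3f}, two-sided p = {res.p_two_sided:.4f}")
```

```
intra-subcortical variability: control 0.354, patient 0.397, diff +0.043, two-sided p = 0.0010
```

Patients show higher intra-subcortical variability (their within-module
connectivity pattern is less stable across 40 s windows), and the
permutation test resolves the injected group effect at this cohort size.
The numbered scripts under `analysis/` run the same machinery end to end
(01 simulates the default cohort to `scratch/`, 02 runs the full pipeline
and copies summary tables to `results/`, 03 checks that flagged units
concentrate in the modules where the effect was injected).

## Layout

- `src/dfcvar/` — the library: `partition` and `io` (data model and TSV
  formats), `cohort` (synthetic generator), `variability` (windowing, FC,
  variability statistics, window-length sweep), `stats` (permutation and
  sign-flip tests, outlier rule, Spearman, demographics), `pipeline` +
  `cli` (orchestration, reporting, `dfcvar` command).
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — pytest suite with independent reference implementations.
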