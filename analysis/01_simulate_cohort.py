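#!/usr/bin/env python
"""Generate the default synthetic cohort and write it to scratch/cohort/.

The cohort emulates the study regime: 40 controls and 42 patients, 264
nodes in 13 functional modules, 200 volumes at TR = 2 s, state-switching
connectivity with elevated reconfiguration amplitude in the subcortical,
sensorimotor, visual and cerebellar modules for patients, and a severity
score coupled to that amplitude.  Series files are large, so they go under
scratch/ (not versioned); the manifest/partition/ground-truth tables are
what downstream steps consume.
"""

from pathlib import Path

from dfcvar.cohort import CohortSpec, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"


def main() -> None:
    spec = CohortSpec(seed=1)
    cohort = simulate_cohort(spec, out_dir=OUT)
    n_pat = sum(s.group == "patient" for s in cohort.subjects)
    print(f"wrote {len(cohort.subjects)} subjects ({n_pat} patients) to {OUT}")
    print(f"modules: {spec.partition.module_sizes()}")
    print(f"target modules (amplified in patients): {spec.target_modules}")


if __name__ == "__main__":
    main()
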