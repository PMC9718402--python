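"""Age/sex-matched case-control design on the simulated cohort.

Builds the 10 strata from case age quintiles x sex, draws 5 matched
controls per incident case (prevalent cases never enter), splits matched
sets 70/30 by stratum, and fills the unmatched 5:1 testing set. Writes
results/design.tsv and the per-stratum summary.

Run after 01_simulate.py:  python analysis/03_design.py [seed]
"""

import sys
from pathlib import Path

import pandas as pd

from prstack import design as dm

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
out = Path("results")

cohort = pd.read_csv("results/data/phenotypes.tsv", sep="\t",
                     dtype={"id": str, "incident": "Int64"})
cases, controls = dm._eligible(cohort)
print(f"{len(cases)} incident cases, {len(controls)} potential controls")

strata = dm.age_strata(cases["age"].to_numpy())
d = dm.sample_matched_training(cohort, strata, seed=seed)
d = dm.build_test_set(cohort, d, seed=seed)

d.to_frame().to_csv(out / "design.tsv", sep="\t", index=False)
d.summary().to_csv(out / "design_summary.tsv", sep="\t", index=False)

print(f"k = {d.k} matched controls per case across "
      f"{strata.n_strata} strata")
print(f"training: {len(d.train_sets)} matched sets "
      f"({len(d.train_ids)} individuals)")
print(f"testing: {len(d.test_cases)} cases + {len(d.test_controls)} "
      f"unmatched controls")
print(d.summary().to_string(index=False))
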