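"""Clumping/thresholding grid, maxCT selection and SCT stacking.

Runs the full pipeline (QC, harmonization, matched design, the
1,400-column-per-chromosome grid, both models, testing-set evaluation) on
the files from 01_simulate.py and writes every artifact — design TSV,
weight files, evaluation JSON, run log — under results/run/.

Run from the repository root:  python analysis/04_fit_models.py [seed]
"""

import sys
import warnings
from pathlib import Path

from prstack import RunConfig, pipeline

warnings.filterwarnings("ignore")
seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
data = Path("results/data")

result = pipeline.run_files(
    data / "cohort", data / "phenotypes.tsv", data / "sumstats.tsv",
    Path("results/run"), RunConfig(seed=seed),
)

print("stage log:", result.log)
mc = result.maxct
print(f"maxCT: r2={mc.r2}, window={mc.base_kb}/{mc.r2}="
      f"{mc.base_kb / mc.r2:.0f} kb, p<={mc.p_threshold:.3g}, "
      f"{mc.n_snps} SNPs (training AUC {mc.training_auc:.3f})")
sc = result.sct
print(f"SCT: lambda={sc.lambda_:.4g}, {sc.n_nonzero_columns} grid columns, "
      f"{sc.n_nonzero_snps} SNPs")
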