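"""Testing-set performance table for the fitted PRSs.

Reads results/run/evaluation.json (from 04_fit_models.py) and prints the
AUC with 95% CI, OR per control-SD, calibration intercept/slope and SNP
counts for maxCT and SCT side by side; writes the same table to
results/performance.tsv.
"""

import json
from pathlib import Path

import pandas as pd

report = json.loads(Path("results/run/evaluation.json").read_text())

rows = []
for method in ("maxct", "sct"):
    r = report[method]
    rows.append({
        "method": method,
        "AUC (95% CI)": "{:.3f} ({:.3f}, {:.3f})".format(
            r["auc"], *r["auc_ci95"]
        ),
        "OR per SD": "{:.2f} ({:.2f}, {:.2f})".format(
            r["or_per_sd"], *r["or_ci95"]
        ),
        "calib. intercept": "{:+.2f}".format(r["calib_intercept"]),
        "calib. slope": "{:.2f}".format(r["calib_slope"]),
        "n SNPs": r["n_snps"],
        "test cases/controls": f"{r['n_cases']}/{r['n_controls']}",
    })
table = pd.DataFrame(rows)
table.to_csv("results/performance.tsv", sep="\t", index=False)
print(table.to_string(index=False))
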