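"""Variant QC and GWAS harmonization for the simulated cohort.

Reads results/data/ (from 01_simulate.py), applies the MAF / HWE /
call-rate filters, intersects the panel with the summary statistics
(dropping strand-ambiguous and duplicated variants, flipping betas onto
the counted allele), and writes the QC report and per-variant disposition
log under results/.
"""

from pathlib import Path

import pandas as pd

from prstack import io_formats, qc

data = Path("results/data")
out = Path("results")

geno = io_formats.read_plink(data / "cohort")
sumstats, skipped = io_formats.read_sumstats(data / "sumstats.tsv")
print(f"read {geno.n_variants} variants, {len(sumstats)} GWAS records "
      f"(skipped {sum(skipped.values())})")

kept, report = qc.variant_qc(geno)
pd.Series(report).rename("count").to_csv(out / "qc_report.tsv", sep="\t")
print("QC:", report)

panel = qc.harmonize(geno.variants.iloc[kept].reset_index(drop=True),
                     sumstats)
panel.to_frame(geno.variants.iloc[kept].reset_index(drop=True)).to_csv(
    out / "dispositions.tsv", sep="\t", index=False
)
print("harmonization:", panel.counts())
print(f"{panel.n_matched} variants enter the scoring grid")
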