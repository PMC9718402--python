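"""Simulate the study cohort and its external GWAS.

Writes the PLINK-1 fileset, the phenotype table and the summary-statistic
file for the default synthetic study (8,000 individuals, 22 x 500 SNPs in
LD blocks, 10% disease prevalence with 10% prevalent cases, h2 = 0.3 over
50 causal SNPs, GWAS of 20,000 independent individuals) under
results/data/.

Run from the repository root:  python analysis/01_simulate.py [seed]
"""

import sys
from pathlib import Path

from prstack import SimConfig, io_formats, synthetic

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
out = Path("results/data")
out.mkdir(parents=True, exist_ok=True)

cfg = SimConfig(seed=seed)
model = synthetic.variant_model(cfg)
geno = synthetic.simulate_genotypes(cfg, model=model)
cohort, effects = synthetic.simulate_phenotypes(geno, cfg)
sumstats = synthetic.simulate_sumstats(cfg, effects, model=model)

io_formats.write_plink(geno, out / "cohort", phenotypes=cohort)
cohort.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
io_formats.write_sumstats(sumstats, out / "sumstats.tsv")

n_cases = (cohort["status"] == "case").sum()
n_prev = (cohort["incident"].astype("Int64") == 0).sum()
print(f"cohort: {cfg.n_ind} individuals x {cfg.n_variants} variants")
print(f"cases: {n_cases} ({n_prev} prevalent, excluded downstream)")
print(f"GWAS: {cfg.gwas_n} independent individuals -> "
      f"{len(sumstats)} summary-statistic records")
print(f"wrote {out}/cohort.{{bed,bim,fam}}, phenotypes.tsv, sumstats.tsv")
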