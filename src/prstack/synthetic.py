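"""Synthetic genotypes, phenotypes and external GWAS summary statistics.

Genotypes are diploid dosages with block LD: within each block of
``block_size`` adjacent variants, each haplotype is a thresholded latent
Gaussian vector with AR(1) correlation ``rho``, so nearby variants are
correlated while variants in different blocks are independent. Disease
status follows a liability-threshold model with additive genetic effects on
standardized dosages, age and sex effects on the liability, and Gaussian
noise; a configurable fraction of cases is flagged prevalent. Summary
statistics come from a marginal per-variant association scan on an
independent cohort drawn from the same genotype model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ConfigurationError, GenotypeMatrix
from .rng import substream

_BASES = np.array(["A", "C", "G", "T"])
# non-ambiguous allele pairs (never {A,T} or {C,G})
_PLAIN_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_AMBIG_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe a cohort of 8,000 individuals genotyped at 500 SNPs on
    each of 22 autosomes (blocks of 20 variants, latent AR(1) rho = 0.6,
    10 kb spacing), a disease with 10% cumulative prevalence of which 10% of
    cases are prevalent at baseline, liability heritability 0.3 spread over
    50 causal SNPs, modest age and sex effects (small enough that every age
    quintile stratum retains at least 5 eligible controls per incident
    case, giving a full 5:1 matched training design of roughly 3,000
    individuals), and an external GWAS of 20,000 independent individuals.
    """

    n_ind: int = 8_000
    n_chrom: int = 22
    snps_per_chrom: int = 500
    block_size: int = 20
    rho: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    spacing_bp: int = 10_000
    n_causal: int = 50
    h2: float = 0.3
    gamma_age: float = 0.15
    gamma_sex: float = 0.1
    prevalence_target: float = 0.1
    prevalent_fraction: float = 0.1
    gwas_n: int = 20_000
    seed: int = 0
    ambiguous_fraction: float = 0.02
    duplicate_fraction: float = 0.005

    @property
    def n_variants(self) -> int:
        return self.n_chrom * self.snps_per_chrom

    def validate(self) -> None:
        if self.n_ind < 1 or self.gwas_n < 1:
            raise ConfigurationError("cohort sizes must be positive")
        if self.snps_per_chrom % self.block_size != 0:
            raise ConfigurationError("block_size must divide snps_per_chrom")
        if not 0 <= self.rho < 1:
            raise ConfigurationError("rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not 0 < self.prevalence_target < 1:
            raise ConfigurationError("prevalence_target must be in (0, 1)")
        if not 0 <= self.prevalent_fraction < 1:
            raise ConfigurationError("prevalent_fraction must be in [0, 1)")
        if not 0 <= self.h2 < 1:
            raise ConfigurationError("h2 must be in [0, 1)")
        cov_var = self.gamma_age ** 2 + 0.25 * self.gamma_sex ** 2
        if self.h2 + cov_var >= 1:
            raise ConfigurationError(
                "h2 plus covariate liability variance must stay below 1"
            )
        if self.n_causal > self.n_variants:
            raise ConfigurationError("n_causal exceeds number of variants")


@dataclass
class TrueEffects:
    """Causal SNP indices and their liability betas (standardized scale)."""

    causal_idx: np.ndarray
    beta: np.ndarray

    def weight_vector(self, n_variants: int) -> np.ndarray:
        w = np.zeros(n_variants)
        w[self.causal_idx] = self.beta
        return w


def variant_model(config: SimConfig) -> pd.DataFrame:
    """Draw the shared variant scheme: positions, alleles, MAFs.

    The same table underlies the target cohort and the GWAS cohort, so the
    two share allele frequencies and identifiers. A configurable fraction of
    variants gets strand-ambiguous (A/T or C/G) alleles and a configurable
    fraction duplicates its neighbour's position, to exercise harmonization.
    """
    config.validate()
    rng = substream(config.seed, "model")
    m = config.n_variants
    chrom = np.repeat(np.arange(1, config.n_chrom + 1), config.snps_per_chrom)
    pos = np.tile(
        np.arange(1, config.snps_per_chrom + 1) * config.spacing_bp,
        config.n_chrom,
    )
    rsid = np.array([f"rs{i + 1}" for i in range(m)])
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)

    pair_idx = rng.integers(0, len(_PLAIN_PAIRS), size=m)
    a1 = np.array([_PLAIN_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_PLAIN_PAIRS[i][1] for i in pair_idx])
    n_ambig = int(round(config.ambiguous_fraction * m))
    if n_ambig:
        idx = rng.choice(m, size=n_ambig, replace=False)
        ambig_idx = rng.integers(0, len(_AMBIG_PAIRS), size=n_ambig)
        a1[idx] = [_AMBIG_PAIRS[i][0] for i in ambig_idx]
        a2[idx] = [_AMBIG_PAIRS[i][1] for i in ambig_idx]
    n_dup = int(round(config.duplicate_fraction * m))
    if n_dup:
        # duplicate the previous variant's position (never across block 0)
        cand = np.where(pos > config.spacing_bp)[0]
        idx = rng.choice(cand, size=min(n_dup, cand.size), replace=False)
        pos[idx] = pos[idx - 1]

    return pd.DataFrame(
        {"chrom": chrom, "rsid": rsid, "pos": pos, "a1": a1, "a2": a2,
         "maf": maf}
    )


def _draw_dosages(config: SimConfig, maf: np.ndarray,
                  n_ind: int, rng: np.random.Generator) -> np.ndarray:
    """Dosages (n_ind x n_variants, int8) under the block-AR(1) model.

    Haplotype allele j is 1 iff its latent Gaussian falls below the
    MAF-matching quantile, so each variant's allele-1 frequency is maf[j]
    and within-block latent correlation is rho^|i-j|.
    """
    m = maf.size
    b = config.block_size
    thr = stats.norm.ppf(maf)
    dosages = np.empty((n_ind, m), dtype=np.int8)
    scale = np.sqrt(1.0 - config.rho ** 2)
    chunk = max(1, int(2e7) // (2 * m) or 1)
    for start in range(0, n_ind, chunk):
        n = min(chunk, n_ind - start)
        z = rng.standard_normal((2 * n, m))
        zb = z.reshape(2 * n, m // b, b)
        for j in range(1, b):
            zb[:, :, j] = config.rho * zb[:, :, j - 1] + scale * zb[:, :, j]
        alleles = (z < thr).view(np.int8)
        dosages[start:start + n] = alleles[0::2] + alleles[1::2]
    return dosages


def simulate_genotypes(config: SimConfig,
                       cohort: str = "genotypes",
                       n_ind: int | None = None,
                       model: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Simulate the target cohort's genotypes (or, with cohort="gwas", an
    independent cohort from the same variant model)."""
    config.validate()
    if model is None:
        model = variant_model(config)
    if n_ind is None:
        n_ind = config.n_ind if cohort == "genotypes" else config.gwas_n
    rng = substream(config.seed, cohort)
    dosages = _draw_dosages(config, model["maf"].to_numpy(), n_ind, rng)
    prefix = "ind" if cohort == "genotypes" else "gw"
    samples = [f"{prefix}{i + 1}" for i in range(n_ind)]
    return GenotypeMatrix(
        samples=samples,
        variants=model[["chrom", "rsid", "pos", "a1", "a2"]].copy(),
        dosages=dosages,
    )


def draw_effects(config: SimConfig) -> TrueEffects:
    """Draw causal SNP indices and betas; N(0, h2/n_causal) per causal SNP
    on the standardized-dosage scale, so genetic liability variance is h2."""
    config.validate()
    rng = substream(config.seed, "effects")
    if config.h2 == 0 or config.n_causal == 0:
        return TrueEffects(np.array([], dtype=np.int64), np.array([]))
    causal = np.sort(rng.choice(config.n_variants, size=config.n_causal,
                                replace=False))
    beta = rng.normal(0.0, np.sqrt(config.h2 / config.n_causal),
                      size=config.n_causal)
    return TrueEffects(causal, beta)


def _standardized(dosage_cols: np.ndarray) -> np.ndarray:
    g = dosage_cols.astype(np.float64)
    mu = g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0  # monomorphic column contributes nothing
    return (g - mu) / sd


def genetic_liability(genotypes: GenotypeMatrix,
                      effects: TrueEffects) -> np.ndarray:
    """Sum of true betas times standardized causal dosages (the oracle
    score on the liability scale)."""
    if effects.causal_idx.size == 0:
        return np.zeros(genotypes.n_samples)
    gs = _standardized(genotypes.dosages[:, effects.causal_idx])
    return gs @ effects.beta


def simulate_phenotypes(genotypes: GenotypeMatrix, config: SimConfig,
                        effects: TrueEffects | None = None,
                        stream: str = "phenotypes"
                        ) -> tuple[pd.DataFrame, TrueEffects]:
    """Liability-threshold phenotypes with age and sex liability effects.

    Liability = genetic + gamma_age * standardized age + gamma_sex * male
    + noise scaled so genetic + noise variance is 1; the case threshold is
    the Gaussian quantile hitting prevalence_target. A prevalent_fraction of
    cases is flagged prevalent (incident = 0); controls carry a missing
    incident flag.
    """
    config.validate()
    if effects is None:
        effects = draw_effects(config)
    rng = substream(config.seed, stream)
    n = genotypes.n_samples

    age = rng.integers(40, 70, size=n)
    male = rng.random(n) < 0.5
    age_std = (age - age.mean()) / (age.std() or 1.0)

    g_lia = genetic_liability(genotypes, effects)
    eps = rng.normal(0.0, np.sqrt(1.0 - config.h2), size=n)
    liability = (g_lia + config.gamma_age * age_std
                 + config.gamma_sex * male + eps)

    mean_l = 0.5 * config.gamma_sex
    sd_l = np.sqrt(1.0 + config.gamma_age ** 2 + 0.25 * config.gamma_sex ** 2)
    threshold = mean_l + sd_l * stats.norm.ppf(1.0 - config.prevalence_target)
    case = liability > threshold

    incident = np.full(n, pd.NA, dtype=object)
    case_idx = np.where(case)[0]
    prevalent = rng.random(case_idx.size) < config.prevalent_fraction
    incident[case_idx] = (~prevalent).astype(int)

    cohort = pd.DataFrame(
        {
            "id": genotypes.samples,
            "age": age,
            "sex": np.where(male, "male", "female"),
            "status": np.where(case, "case", "control"),
            "incident": incident,
        }
    )
    return cohort, effects


def simulate_sumstats(config: SimConfig,
                      effects: TrueEffects | None = None,
                      model: pd.DataFrame | None = None) -> pd.DataFrame:
    """Marginal GWAS summary statistics from an independent cohort.

    A fresh cohort of gwas_n individuals is drawn from the same variant
    model; case status follows the same liability model (fresh noise); each
    variant gets a score test of dosage against status: beta = U/V,
    se = 1/sqrt(V), p from chi2(1), where U is the score and V its variance
    under the null. Monomorphic variants are emitted with beta 0 and p 1.
    About half of the records report the a2 allele as the effect allele
    (with the sign flipped accordingly), to exercise harmonization.
    """
    config.validate()
    if model is None:
        model = variant_model(config)
    if effects is None:
        effects = draw_effects(config)
    geno = simulate_genotypes(config, cohort="gwas", model=model)
    pheno, _ = simulate_phenotypes(geno, config, effects=effects,
                                   stream="gwas")
    y = (pheno["status"] == "case").to_numpy(np.float64)
    ybar = y.mean()
    yc = y - ybar

    m = geno.n_variants
    beta = np.zeros(m)
    se = np.full(m, np.inf)
    pval = np.ones(m)
    chunk = 2_000
    for start in range(0, m, chunk):
        g = geno.dosages[:, start:start + chunk].astype(np.float64)
        gc = g - g.mean(axis=0)
        u = gc.T @ yc
        v = ybar * (1 - ybar) * (gc ** 2).sum(axis=0)
        ok = v > 0
        sl = slice(start, start + g.shape[1])
        beta[sl] = np.where(ok, u / np.where(ok, v, 1.0), 0.0)
        se[sl] = np.where(ok, 1.0 / np.sqrt(np.where(ok, v, 1.0)), np.inf)
        pval[sl] = np.where(ok, stats.chi2.sf(u ** 2 / np.where(ok, v, 1.0), 1), 1.0)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    rng = substream(config.seed, "model")
    rng = np.random.default_rng(rng.integers(2 ** 31))  # allele-report stream
    flip = rng.random(m) < 0.5
    out = pd.DataFrame(
        {
            "rsid": model["rsid"],
            "chrom": model["chrom"],
            "pos": model["pos"],
            "effect_allele": np.where(flip, model["a2"], model["a1"]),
            "other_allele": np.where(flip, model["a1"], model["a2"]),
            "beta": np.where(flip, -beta, beta),
            "se": se,
            "pvalue": pval,
        }
    )
    return out
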