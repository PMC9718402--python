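"""Variant quality control and genotype/summary-statistic harmonization.

QC removes variants by minor allele frequency, Hardy-Weinberg
disequilibrium and call rate. Harmonization intersects the genotype panel
with external GWAS records on rsid, drops strand-ambiguous (A/T, C/G) and
duplicated variants, resolves strand flips by complementing non-ambiguous
allele pairs, and re-signs betas so every aligned effect refers to the
genotype's counted (a1) allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenotypeMatrix

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})

DISPOSITIONS = (
    "kept", "kept_flipped", "dropped_ambiguous", "dropped_unmatched",
    "dropped_duplicate", "dropped_allele_mismatch",
)


@dataclass
class QCThresholds:
    maf_min: float = 0.001
    hwe_p_min: float = 1e-5
    call_rate_min: float = 0.95

    def validate(self) -> None:
        for name in ("maf_min", "hwe_p_min", "call_rate_min"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def hwe_test(n_AA, n_Aa, n_aa):
    """Chi-square (1 df, no continuity correction) Hardy-Weinberg test.

    Expected genotype frequencies are p^2, 2pq, q^2 at the sample allele
    frequency p. Monomorphic input returns p-value 1 by convention.
    Accepts scalars or aligned arrays.
    """
    n_AA = np.asarray(n_AA, dtype=np.float64)
    n_Aa = np.asarray(n_Aa, dtype=np.float64)
    n_aa = np.asarray(n_aa, dtype=np.float64)
    if (n_AA < 0).any() or (n_Aa < 0).any() or (n_aa < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if (n == 0).any():
        raise ValueError("total genotype count must be positive")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    poly = (p > 0) & (p < 1)
    exp_AA = n * p ** 2
    exp_Aa = 2 * n * p * q
    exp_aa = n * q ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = ((n_AA - exp_AA) ** 2 / exp_AA
                + (n_Aa - exp_Aa) ** 2 / exp_Aa
                + (n_aa - exp_aa) ** 2 / exp_aa)
    pval = np.where(poly, stats.chi2.sf(np.where(poly, chi2, 0.0), 1), 1.0)
    if pval.ndim == 0:
        return float(pval)
    return pval


def variant_qc(genotypes: GenotypeMatrix,
               thresholds: QCThresholds | None = None
               ) -> tuple[np.ndarray, dict[str, int]]:
    """Indices of variants passing MAF, HWE and call-rate filters.

    MAF and HWE are computed on non-missing dosages. The report counts
    removals per criterion; a variant failing several criteria counts once
    under each.
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    if genotypes.n_samples < 2:
        raise ValueError("variant QC requires at least 2 samples")
    d = genotypes.dosages
    n_missing = (d == MISSING).sum(axis=0)
    n2 = (d == 2).sum(axis=0)
    n1 = (d == 1).sum(axis=0)
    n0 = (d == 0).sum(axis=0)
    n_obs = n0 + n1 + n2
    call_rate = n_obs / d.shape[0]

    with np.errstate(invalid="ignore", divide="ignore"):
        p_a1 = np.where(n_obs > 0, (2 * n2 + n1) / (2 * np.maximum(n_obs, 1)), 0.0)
    maf = np.minimum(p_a1, 1 - p_a1)
    hwe_p = np.ones(d.shape[1])
    nz = n_obs > 0
    hwe_p[nz] = np.atleast_1d(hwe_test(n2[nz], n1[nz], n0[nz]))

    fail_maf = maf < thresholds.maf_min
    fail_hwe = hwe_p < thresholds.hwe_p_min
    fail_call = call_rate < thresholds.call_rate_min
    keep = ~(fail_maf | fail_hwe | fail_call)
    report = {
        "n_input": int(d.shape[1]),
        "removed_maf": int(fail_maf.sum()),
        "removed_hwe": int(fail_hwe.sum()),
        "removed_call_rate": int(fail_call.sum()),
        "n_retained": int(keep.sum()),
    }
    return np.where(keep)[0], report


@dataclass
class HarmonizedPanel:
    """Genotype variants aligned with summary statistics.

    kept_idx indexes the input variant table; beta/pvalue/se are aligned to
    kept_idx with every beta counting the genotype a1 allele. disposition
    labels every input variant with exactly one of DISPOSITIONS.
    """

    kept_idx: np.ndarray
    beta: np.ndarray
    pvalue: np.ndarray
    se: np.ndarray
    disposition: pd.Series

    @property
    def n_matched(self) -> int:
        return int(self.kept_idx.size)

    def counts(self) -> dict[str, int]:
        c = self.disposition.value_counts().to_dict()
        return {d: int(c.get(d, 0)) for d in DISPOSITIONS}

    def to_frame(self, variants: pd.DataFrame) -> pd.DataFrame:
        out = variants.copy()
        out["disposition"] = self.disposition.to_numpy()
        return out


def _is_ambiguous(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    return np.array([{x, y} in _AMBIGUOUS for x, y in zip(a1, a2)])


def harmonize(variants: pd.DataFrame, sumstats: pd.DataFrame) -> HarmonizedPanel:
    """Match QC-passed genotype variants against GWAS summary statistics.

    Precedence per variant: strand-ambiguous alleles, then duplicated rsid
    (either side) or duplicated position (either side), then absence from
    the sumstats, then allele comparison (direct or after complementing the
    non-ambiguous pair) deciding kept / kept_flipped / mismatch.
    """
    m = len(variants)
    disposition = np.full(m, "", dtype=object)

    g_a1 = variants["a1"].to_numpy(dtype=object)
    g_a2 = variants["a2"].to_numpy(dtype=object)
    ambiguous = _is_ambiguous(g_a1, g_a2)
    disposition[ambiguous] = "dropped_ambiguous"

    g_rsid = variants["rsid"]
    g_pos = list(zip(variants["chrom"], variants["pos"]))
    s_rsid_counts = sumstats["rsid"].value_counts()
    s_pos_counts = pd.Series(
        list(zip(sumstats["chrom"], sumstats["pos"]))
    ).value_counts()
    dup = (
        g_rsid.duplicated(keep=False).to_numpy()
        | pd.Series(g_pos).duplicated(keep=False).to_numpy()
        | (g_rsid.map(s_rsid_counts).fillna(0) > 1).to_numpy()
        | (pd.Series(g_pos).map(s_pos_counts).fillna(0) > 1).to_numpy()
    )
    dup &= disposition == ""
    disposition[dup] = "dropped_duplicate"

    ss = sumstats.drop_duplicates(subset="rsid", keep=False).set_index("rsid")
    open_mask = disposition == ""
    matched = g_rsid.isin(ss.index).to_numpy()
    disposition[open_mask & ~matched] = "dropped_unmatched"

    kept_idx, aligned_beta, aligned_p, aligned_se = [], [], [], []
    for i in np.where(open_mask & matched)[0]:
        rec = ss.loc[g_rsid.iloc[i]]
        ea, oa = rec["effect_allele"], rec["other_allele"]
        pair = {g_a1[i], g_a2[i]}
        if {ea, oa} == pair:
            eff = ea
        elif {_COMPLEMENT.get(ea), _COMPLEMENT.get(oa)} == pair:
            eff = _COMPLEMENT[ea]
        else:
            disposition[i] = "dropped_allele_mismatch"
            continue
        if eff == g_a1[i]:
            disposition[i] = "kept"
            aligned_beta.append(float(rec["beta"]))
        else:
            disposition[i] = "kept_flipped"
            aligned_beta.append(-float(rec["beta"]))
        kept_idx.append(i)
        aligned_p.append(float(rec["pvalue"]))
        aligned_se.append(float(rec["se"]))

    return HarmonizedPanel(
        kept_idx=np.array(kept_idx, dtype=np.int64),
        beta=np.array(aligned_beta),
        pvalue=np.array(aligned_p),
        se=np.array(aligned_se),
        disposition=pd.Series(disposition, index=variants.index),
    )
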