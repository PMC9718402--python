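"""Greedy LD clumping, log-spaced p-value thresholds, and PRS scoring.

For every (r², base window) cell the variants of a chromosome are clumped
greedily in ascending p-value order: each surviving variant becomes an
index SNP and removes every not-yet-processed variant within the effective
window (base_kb / r², center-to-center) whose squared Pearson correlation
with it exceeds r². Crossing 7 r² values, 4 base windows and 50 p-value
thresholds yields 1,400 score columns per chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix


@dataclass(frozen=True)
class GridSpec:
    r2_values: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2, 0.5, 0.8, 0.95)
    base_kb_values: tuple[int, ...] = (50, 100, 200, 500)
    n_thresholds: int = 50

    @property
    def cells(self) -> list[tuple[float, int]]:
        return [(r2, kb) for r2 in self.r2_values for kb in self.base_kb_values]

    @property
    def n_columns_per_chrom(self) -> int:
        return len(self.r2_values) * len(self.base_kb_values) * self.n_thresholds


def mean_impute(dosages_float: np.ndarray,
                means: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Replace NaN dosages by the per-variant mean (training mean when
    given). Columns that are entirely missing impute to 0."""
    x = np.array(dosages_float, dtype=np.float64, copy=True)
    if means is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(x, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
    nan_r, nan_c = np.where(np.isnan(x))
    x[nan_r, nan_c] = means[nan_c]
    return x, means


def squared_correlation(x: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of columns; zero-variance
    columns correlate 0 with everything (so LD never removes them)."""
    xc = x - x.mean(axis=0)
    norms = np.sqrt((xc ** 2).sum(axis=0))
    safe = np.where(norms == 0, 1.0, norms)
    xs = xc / safe
    c2 = (xs.T @ xs) ** 2
    zero = norms == 0
    c2[zero, :] = 0.0
    c2[:, zero] = 0.0
    np.clip(c2, 0.0, 1.0, out=c2)
    return c2


def clump(dosages: np.ndarray, pvalues: np.ndarray, positions: np.ndarray,
          r2_thr: float, base_kb: float, rsids=None,
          corr2: np.ndarray | None = None) -> list[int]:
    """Greedy clumping of one chromosome; returns index SNPs in selection
    (ascending p) order.

    dosages may contain NaN (mean-imputed before correlating); the
    effective window is base_kb / r2_thr kilobases on each side of the
    index SNP, inclusive. Ties in p break by position then rsid.
    """
    pvalues = np.asarray(pvalues, dtype=np.float64)
    positions = np.asarray(positions, dtype=np.int64)
    m = pvalues.size
    if m == 0:
        return []
    if corr2 is None:
        x, _ = mean_impute(np.asarray(dosages, dtype=np.float64))
        corr2 = squared_correlation(x)
    if rsids is None:
        rsids = np.array([""] * m)
    order = np.lexsort((np.asarray(rsids), positions, pvalues))
    window_bp = base_kb / r2_thr * 1000.0
    removed = np.zeros(m, dtype=bool)
    retained: list[int] = []
    for i in order:
        if removed[i]:
            continue
        retained.append(int(i))
        near = np.abs(positions - positions[i]) <= window_bp
        removed |= near & (corr2[i] > r2_thr)
        removed[i] = True  # processed; cannot be removed later
    return retained


def make_thresholds(pvalues, n: int = 50) -> np.ndarray:
    """n p-value thresholds evenly spaced on the -log10 scale between
    0.999 x max(-log10 p) and 0.1, returned ascending in p."""
    pvalues = np.asarray(pvalues, dtype=np.float64)
    pvalues = pvalues[np.isfinite(pvalues)]
    lp_max = -np.log10(pvalues.min()) if pvalues.size else 0.0
    if lp_max <= 0:
        warnings.warn("all p-values equal 1; single threshold used")
        return np.array([1.0])
    grid = np.linspace(0.999 * lp_max, 0.1, n)  # descending -log10 => p asc
    return 10.0 ** (-grid)


def prs_score(dosages: np.ndarray, aligned_betas: np.ndarray,
              snp_subset, impute_means: np.ndarray | None = None
              ) -> np.ndarray:
    """score_i = sum over the subset of beta_j * dosage_ij, missing dosages
    mean-imputed (training means when supplied)."""
    subset = np.asarray(snp_subset, dtype=np.int64)
    n = dosages.shape[0]
    if subset.size == 0:
        return np.zeros(n)
    x = np.asarray(dosages[:, subset], dtype=np.float64)
    if np.isnan(x).any():
        x, _ = mean_impute(
            x, None if impute_means is None else impute_means[subset]
        )
    return x @ np.asarray(aligned_betas)[subset]


@dataclass
class PRSGrid:
    """Per-individual scores for every (chromosome, r², window, threshold)
    cell, with enough metadata to rebuild each column's SNP set.

    Column order is chromosome-major, then r², then base window, then
    threshold (ascending p). cells[(chrom, r2, kb)] lists that clump's
    retained variant indices in ascending-p order; a column's SNP set is
    the prefix of length meta.n_snps.
    """

    scores: np.ndarray                 # n_individuals x n_columns
    meta: pd.DataFrame                 # chrom, r2, base_kb, p_threshold, n_snps
    cells: dict[tuple[int, float, int], np.ndarray]
    thresholds: np.ndarray
    impute_means: np.ndarray           # training mean dosage per variant

    @property
    def n_columns(self) -> int:
        return self.scores.shape[1]

    def column_snps(self, col: int) -> np.ndarray:
        row = self.meta.iloc[col]
        cell = self.cells[(int(row.chrom), float(row.r2), int(row.base_kb))]
        return cell[: int(row.n_snps)]


def build_grid(genotypes: GenotypeMatrix, betas: np.ndarray,
               pvalues: np.ndarray, spec: GridSpec | None = None,
               dtype=np.float64) -> PRSGrid:
    """Clump and score every grid cell on (harmonized) training genotypes.

    genotypes columns, betas and pvalues must be aligned (one entry per
    harmonized variant, betas counting a1). Thresholds are computed once
    from the genome-wide p-values. Chromosomes with an empty clump yield
    all-zero columns (n_snps = 0).
    """
    spec = spec or GridSpec()
    thresholds = make_thresholds(pvalues, spec.n_thresholds)
    n = genotypes.n_samples
    chroms = list(dict.fromkeys(genotypes.variants["chrom"].tolist()))
    n_cols = len(chroms) * len(spec.cells) * len(thresholds)
    scores = np.zeros((n, n_cols), dtype=dtype)

    all_means = np.zeros(genotypes.n_variants)
    cells: dict[tuple[int, float, int], np.ndarray] = {}
    meta_rows = []
    col = 0
    chrom_arr = genotypes.variants["chrom"].to_numpy()
    for chrom in chroms:
        vidx = np.where(chrom_arr == chrom)[0]
        x, means = mean_impute(genotypes.dosages_float(vidx))
        all_means[vidx] = means
        corr2 = squared_correlation(x)
        pos = genotypes.variants["pos"].to_numpy()[vidx]
        rs = genotypes.variants["rsid"].to_numpy()[vidx]
        pv = pvalues[vidx]
        for r2, kb in spec.cells:
            kept_local = clump(None, pv, pos, r2, kb, rsids=rs, corr2=corr2)
            kept = vidx[kept_local]
            cells[(int(chrom), float(r2), int(kb))] = kept
            if kept.size:
                contrib = x[:, kept_local] * betas[kept]
                cums = np.cumsum(contrib, axis=1)
                prefix = np.searchsorted(np.sort(pv[kept_local]), thresholds,
                                         side="right")
            else:
                cums = np.zeros((n, 0))
                prefix = np.zeros(len(thresholds), dtype=np.int64)
            for t_i, thr in enumerate(thresholds):
                k = int(prefix[t_i])
                if k > 0:
                    scores[:, col] = cums[:, k - 1]
                meta_rows.append(
                    {"chrom": int(chrom), "r2": float(r2),
                     "base_kb": int(kb), "p_threshold": float(thr),
                     "n_snps": k}
                )
                col += 1
    meta = pd.DataFrame(meta_rows)
    return PRSGrid(scores=scores, meta=meta, cells=cells,
                   thresholds=thresholds, impute_means=all_means)
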