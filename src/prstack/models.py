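"""maxCT selection and SCT stacking over the clumping/thresholding grid.

maxCT evaluates each of the 1,400 hyperparameter cells as a genome-wide
score (the sum of its per-chromosome columns) and keeps the one with the
highest training AUC. SCT regresses case status on all grid columns with
L1-penalized logistic regression (penalty chosen by stratified K-fold
cross-validated deviance) and collapses the stacking weights to a single
per-SNP weight vector: w_j = sum_g alpha_g * beta_j * [j in SNPset(g)].
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .lasso import lambda_path, lasso_logistic_path
from .rng import substream

logger = logging.getLogger(__name__)


def training_auc(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUC of each column of scores against binary y, ties
    counted one half (constant columns score exactly 0.5)."""
    scores = np.atleast_2d(scores.T).T
    y = np.asarray(y, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    ranks = rankdata(scores, axis=0)
    r1 = ranks[y].sum(axis=0)
    return (r1 - n1 * (n1 + 1) / 2) / (n1 * n0)


@dataclass
class MaxCTModel:
    r2: float
    base_kb: int
    p_threshold: float
    training_auc: float
    snp_idx: np.ndarray        # genome-wide SNP indices of the chosen cell
    weights: np.ndarray        # per-SNP weight vector (aligned betas on set)

    @property
    def n_snps(self) -> int:
        return int(self.snp_idx.size)


def max_ct(grid, y_train: np.ndarray, betas: np.ndarray) -> MaxCTModel:
    """Choose the genome-wide (r², window, threshold) cell with the best
    training AUC; ties break to fewer SNPs, then lower r², smaller window,
    lower threshold."""
    y = np.asarray(y_train, dtype=bool)
    chroms = list(dict.fromkeys(grid.meta["chrom"].tolist()))
    n_chrom = len(chroms)
    n_per_chrom = grid.n_columns // n_chrom
    gw = (
        grid.scores.reshape(grid.scores.shape[0], n_chrom, n_per_chrom)
        .sum(axis=1, dtype=np.float64)
    )
    aucs = training_auc(gw, y)
    sub = grid.meta.iloc[:n_per_chrom]
    n_snps_gw = (
        grid.meta["n_snps"].to_numpy().reshape(n_chrom, n_per_chrom).sum(axis=0)
    )
    # last lexsort key is primary
    order = np.lexsort((
        sub["p_threshold"].to_numpy(), sub["base_kb"].to_numpy(),
        sub["r2"].to_numpy(), n_snps_gw, -aucs,
    ))
    best = int(order[0])
    row = sub.iloc[best]
    snp_idx = np.concatenate([
        grid.cells[(int(c), float(row.r2), int(row.base_kb))][
            : int(grid.meta["n_snps"].iloc[i * n_per_chrom + best])
        ]
        for i, c in enumerate(chroms)
    ]) if n_snps_gw[best] else np.array([], dtype=np.int64)
    weights = np.zeros(betas.size)
    weights[snp_idx] = betas[snp_idx]
    return MaxCTModel(
        r2=float(row.r2), base_kb=int(row.base_kb),
        p_threshold=float(row.p_threshold),
        training_auc=float(aucs[best]), snp_idx=snp_idx, weights=weights,
    )


@dataclass
class StackedModel:
    alpha: np.ndarray          # per grid column, original column scale
    intercept: float
    weights: np.ndarray        # collapsed per-SNP weight vector
    n_nonzero_snps: int
    lambda_: float
    cv_trace: pd.DataFrame     # lambda, mean CV deviance

    @property
    def n_nonzero_columns(self) -> int:
        return int(np.count_nonzero(self.alpha))


def collapse_weights(alpha: np.ndarray, grid, betas: np.ndarray
                     ) -> tuple[np.ndarray, int]:
    """Fold stacking weights back onto SNPs: w_j = sum_g alpha_g * beta_j
    over columns g whose SNP set contains j."""
    w = np.zeros(betas.size)
    for g in np.nonzero(alpha)[0]:
        snps = grid.column_snps(int(g))
        w[snps] += alpha[g] * betas[snps]
    return w, int(np.count_nonzero(w))


def _dedup_columns(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Representative index per unique column (byte-identical), and the
    map from every column to its representative."""
    seen: dict[bytes, int] = {}
    rep_of = np.empty(scores.shape[1], dtype=np.int64)
    reps: list[int] = []
    for g in range(scores.shape[1]):
        h = hashlib.blake2b(np.ascontiguousarray(scores[:, g]).tobytes(),
                            digest_size=16).digest()
        if h not in seen:
            seen[h] = g
            reps.append(g)
        rep_of[g] = seen[h]
    return np.array(reps, dtype=np.int64), rep_of


def sct_stack(grid, y_train: np.ndarray, betas: np.ndarray,
              folds: int = 10, seed: int = 0, n_lambda: int = 30,
              lambda_min_ratio: float = 1e-2, tol: float = 1e-5,
              dfmax: int | None = 1000, rule: str = "min") -> StackedModel:
    """L1-penalized logistic stacking of all grid columns.

    Columns are standardized internally (training mean/SD); the
    regularization path descends log-uniformly from the smallest penalty
    that zeroes every coefficient, and the penalty minimizing K-fold
    cross-validated deviance (minimum rule, folds stratified by case
    status) is kept; rule="1se" instead takes the strongest penalty within
    one standard error of the minimum (more conservative under pure
    noise). Returned alphas are on the original column scale.
    Byte-identical duplicate columns (the same SNP prefix reached in
    several cells) are fitted once and reported on their first occurrence;
    a path tail whose active set exceeds dfmax is truncated.
    """
    if rule not in ("min", "1se"):
        raise ValueError(f"unknown selection rule {rule!r}")
    y = np.asarray(y_train, dtype=np.float64)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    n = y.size
    if min(y.sum(), n - y.sum()) < folds:
        raise ValueError("fewer than one case or control per fold")

    reps, _ = _dedup_columns(grid.scores)
    x = grid.scores[:, reps].astype(np.float64)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    informative = sd > 0
    x = (x[:, informative] - mu[informative]) / sd[informative]
    col_ids = reps[informative]

    lambdas = lambda_path(x, y, n_lambda, lambda_min_ratio)

    fold_seed = int(substream(seed, "stacking").integers(2 ** 31))
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=fold_seed)
    deviance = np.full((folds, n_lambda), np.inf)
    eps = 1e-12
    for f, (tr, va) in enumerate(skf.split(x, y)):
        bpath, b0path = lasso_logistic_path(x[tr], y[tr], lambdas,
                                            tol=tol, dfmax=dfmax)
        eta = x[va] @ np.nan_to_num(bpath) + np.nan_to_num(b0path)
        p = np.clip(1.0 / (1.0 + np.exp(-eta)), eps, 1 - eps)
        dev = -2.0 * np.mean(
            y[va, None] * np.log(p) + (1 - y[va, None]) * np.log(1 - p),
            axis=0,
        )
        computed = ~np.isnan(b0path)
        deviance[f, computed] = dev[computed]
    mean_dev = deviance.mean(axis=0)  # inf where any fold truncated
    best = int(np.argmin(mean_dev))
    if rule == "1se":
        with np.errstate(invalid="ignore"):
            se_dev = deviance.std(axis=0, ddof=1) / np.sqrt(folds)
        within = np.where(mean_dev <= mean_dev[best] + se_dev[best])[0]
        best = int(within[0])  # strongest penalty inside the band
    lam = float(lambdas[best])

    bpath, b0path = lasso_logistic_path(x, y, lambdas[: best + 1],
                                        tol=tol, dfmax=None)
    coef_std = bpath[:, best]
    b0 = float(b0path[best])

    alpha = np.zeros(grid.n_columns)
    alpha[col_ids] = coef_std / sd[informative]
    intercept = float(
        b0 - np.sum(coef_std * mu[informative] / sd[informative])
    )
    weights, n_nonzero = collapse_weights(alpha, grid, betas)
    trace = pd.DataFrame({"lambda": lambdas, "cv_deviance": mean_dev})
    return StackedModel(
        alpha=alpha, intercept=intercept, weights=weights,
        n_nonzero_snps=n_nonzero, lambda_=lam, cv_trace=trace,
    )
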