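import numpy as np
import pandas as pd
import pytest

from prstack import GridSpec, build_grid, max_ct, sct_stack, collapse_weights
from prstack.grid import PRSGrid
from prstack.models import training_auc, _dedup_columns

from conftest import random_genotypes


def manual_grid(scores, cell_keys, cell_snps, n_snps_per_col, thresholds,
                n_variants):
    """Assemble a PRSGrid by hand for model-selection unit tests."""
    meta_rows = []
    cells = {}
    for col, key in enumerate(cell_keys):
        chrom, r2, kb = key
        cells[key] = np.asarray(cell_snps[key], dtype=np.int64)
        meta_rows.append({"chrom": chrom, "r2": r2, "base_kb": kb,
                          "p_threshold": thresholds[col % len(thresholds)],
                          "n_snps": n_snps_per_col[col]})
    return PRSGrid(
        scores=np.asarray(scores, dtype=np.float64),
        meta=pd.DataFrame(meta_rows),
        cells=cells,
        thresholds=np.asarray(thresholds),
        impute_means=np.zeros(n_variants),
    )


def brute_force_auc(scores, y):
    """Average over all case-control pairs of 1[case > control] with ties
    counted one half."""
    cases = scores[y.astype(bool)]
    controls = scores[~y.astype(bool)]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


def _informative_grid(seed, n=200, m=40, n_thresholds=5):
    rng = np.random.default_rng(seed)
    gm = random_genotypes(rng, n, m, n_chrom=2)
    betas = rng.normal(size=m) * 0.2
    pvalues = 10 ** (-rng.uniform(0, 6, size=m))
    spec = GridSpec(r2_values=(0.2, 0.8), base_kb_values=(50, 500),
                    n_thresholds=n_thresholds)
    grid = build_grid(gm, betas, pvalues, spec)
    liab = gm.dosages_float() @ (betas * (pvalues < 1e-2))
    liab = (liab - liab.mean()) / (liab.std() or 1)
    y = (rng.random(n) < 1 / (1 + np.exp(-liab - 1.2))).astype(float)
    if y.sum() < 20 or y.sum() > n - 20:  # keep both classes populated
        y[:20] = 1
        y[-20:] = 0
    return gm, betas, grid, y


class TestMaxCT:
    def test_perfect_separator_chosen(self):
        y = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        scores = np.column_stack([
            np.array([5, 6, 7, 1, 2, 3], float),   # separates perfectly
            np.array([1, 0, 1, 0, 1, 0], float),
        ])
        grid = manual_grid(
            scores,
            [(1, 0.2, 50), (1, 0.8, 50)],
            {(1, 0.2, 50): [0, 1], (1, 0.8, 50): [2]},
            [2, 1], [0.5, 0.5], n_variants=3,
        )
        model = max_ct(grid, y, betas=np.array([0.1, 0.2, 0.3]))
        assert model.training_auc == 1.0
        assert model.r2 == 0.2

    def test_matches_exhaustive_argmax_oracle(self):
        """The chosen cell maximizes brute-force pairwise AUC among all
        genome-wide candidates."""
        for seed in range(5):
            gm, betas, grid, y = _informative_grid(seed, n=60, m=20)
            model = max_ct(grid, y, betas)
            n_per_chrom = grid.n_columns // 2
            gw = (grid.scores[:, :n_per_chrom]
                  + grid.scores[:, n_per_chrom:])
            best_auc = max(brute_force_auc(gw[:, c], y)
                           for c in range(n_per_chrom))
            assert model.training_auc == pytest.approx(best_auc)

    def test_tie_breaks_to_fewer_snps(self):
        y = np.array([1, 1, 0, 0], dtype=float)
        col = np.array([4, 3, 2, 1], float)
        scores = np.column_stack([col, col])
        grid = manual_grid(
            scores,
            [(1, 0.2, 50), (1, 0.8, 50)],
            {(1, 0.2, 50): [0, 1, 2], (1, 0.8, 50): [0, 1]},
            [3, 2], [0.5, 0.5], n_variants=3,
        )
        model = max_ct(grid, y, betas=np.ones(3))
        assert model.n_snps == 2

    def test_scale_invariance(self):
        gm, betas, grid, y = _informative_grid(11)
        m1 = max_ct(grid, y, betas)
        grid.scores = grid.scores * 7.5
        m2 = max_ct(grid, y, betas)
        assert (m1.r2, m1.base_kb, m1.p_threshold) == \
            (m2.r2, m2.base_kb, m2.p_threshold)

    def test_constant_columns_score_half(self):
        y = np.array([1.0, 0, 1, 0])
        aucs = training_auc(np.ones((4, 2)), y)
        np.testing.assert_allclose(aucs, 0.5)


def _noise_grid(rng, n, k, n_variants=30):
    scores = rng.normal(size=(n, k))
    keys = [(1, 0.2, 50 + i) for i in range(k)]
    cells = {key: rng.choice(n_variants, size=3, replace=False)
             for key in keys}
    return manual_grid(scores, keys, cells, [3] * k, [0.5] * k, n_variants)


class TestSCT:
    def test_null_data_shrinks_everything(self):
        """Independent y: under the conservative 1se rule the selected
        penalty keeps no columns in nearly all replicates; under the
        minimum rule a handful of noise columns may survive, but never a
        substantial fraction, and the empty model is always on the path."""
        wins_1se = 0
        min_sizes = []
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)
            grid = _noise_grid(rng, n=500, k=40)
            y = (rng.random(500) < 0.3).astype(float)
            m1 = sct_stack(grid, y, betas=np.zeros(30), folds=5,
                           seed=rep, rule="1se")
            wins_1se += (m1.n_nonzero_columns == 0)
            m2 = sct_stack(grid, y, betas=np.zeros(30), folds=5, seed=rep)
            min_sizes.append(m2.n_nonzero_columns)
            assert np.count_nonzero(m2.weights) == m2.n_nonzero_snps
        assert wins_1se >= 40
        assert np.median(min_sizes) <= 5

    def test_single_informative_column_recovered(self):
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(200 + rep)
            grid = _noise_grid(rng, n=400, k=40)
            y = (rng.random(400)
                 < 1 / (1 + np.exp(-1.5 * grid.scores[:, 7]))).astype(float)
            model = sct_stack(grid, y, betas=np.zeros(30), folds=5,
                              seed=rep)
            alpha = np.abs(model.alpha)
            if alpha.max() > 0 and np.argmax(alpha) == 7:
                hits += 1
        assert hits >= int(0.95 * 50)

    def test_collapsed_weights_reproduce_column_scores(self):
        """Per-SNP collapsed weights give the same per-individual score as
        the alpha-weighted grid columns (algebraic identity)."""
        for seed in (0, 1, 2):
            gm, betas, grid, y = _informative_grid(seed, n=240, m=30)
            model = sct_stack(grid, y, betas, folds=5, seed=seed)
            via_columns = grid.scores @ model.alpha
            d, _ = np.broadcast_arrays(gm.dosages_float(), None)
            via_snps = np.nan_to_num(gm.dosages_float()) @ model.weights
            scale = max(np.abs(via_columns).max(), 1e-12)
            np.testing.assert_allclose(via_snps, via_columns,
                                       atol=1e-8 * scale)

    def test_reproducible_with_seed(self):
        gm, betas, grid, y = _informative_grid(5)
        m1 = sct_stack(grid, y, betas, folds=5, seed=42)
        m2 = sct_stack(grid, y, betas, folds=5, seed=42)
        np.testing.assert_array_equal(m1.alpha, m2.alpha)
        assert m1.lambda_ == m2.lambda_

    def test_too_few_cases_per_fold_rejected(self):
        rng = np.random.default_rng(0)
        grid = _noise_grid(rng, n=30, k=5)
        y = np.zeros(30)
        y[:3] = 1
        with pytest.raises(ValueError):
            sct_stack(grid, y, betas=np.zeros(30), folds=10)

    def test_maxct_model_is_sparser_than_sct(self):
        """Where SCT keeps more than one cell it rests on more SNPs than
        maxCT (soft property over seeded replicates)."""
        ok = total = 0
        for seed in range(12):
            gm, betas, grid, y = _informative_grid(seed, n=300, m=40)
            mc = max_ct(grid, y, betas)
            sc = sct_stack(grid, y, betas, folds=5, seed=seed)
            if sc.n_nonzero_columns > 1:
                total += 1
                ok += (mc.n_snps <= sc.n_nonzero_snps)
        assert total >= 5
        assert ok >= 0.8 * total


class TestCollapse:
    def _grid(self):
        keys = [(1, 0.2, 50), (1, 0.8, 50)]
        cells = {keys[0]: np.array([2]), keys[1]: np.array([2])}
        scores = np.zeros((4, 2))
        return manual_grid(scores, keys, cells, [1, 1], [0.5, 0.5],
                           n_variants=5)

    def test_single_cell(self):
        grid = self._grid()
        betas = np.array([0, 0, 0.3, 0, 0])
        w, nnz = collapse_weights(np.array([2.0, 0.0]), grid, betas)
        assert w[2] == pytest.approx(0.6)
        assert nnz == 1

    def test_cancellation_excluded(self):
        grid = self._grid()
        betas = np.array([0, 0, 0.3, 0, 0])
        w, nnz = collapse_weights(np.array([1.0, -1.0]), grid, betas)
        assert w[2] == 0.0
        assert nnz == 0


def test_dedup_columns_finds_identical():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(20, 3))
    scores = np.column_stack([a[:, 0], a[:, 1], a[:, 0], a[:, 2], a[:, 1]])
    reps, rep_of = _dedup_columns(scores)
    assert list(reps) == [0, 1, 3]
    assert list(rep_of) == [0, 1, 0, 3, 1]
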