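import numpy as np
import pandas as pd
import pytest

from prstack import GridSpec, build_grid, clump, make_thresholds, prs_score
from prstack.grid import mean_impute, squared_correlation

from conftest import random_genotypes


def brute_force_clump(dosages, pvalues, positions, r2_thr, base_kb,
                      rsids=None):
    """Reference clumping that re-derives eligibility from the full
    pairwise r-squared matrix at every step."""
    m = len(pvalues)
    if rsids is None:
        rsids = [""] * m
    x, _ = mean_impute(np.asarray(dosages, dtype=float))
    c2 = squared_correlation(x)
    window = base_kb / r2_thr * 1000.0
    alive = set(range(m))
    retained = []
    while alive:
        best = min(alive, key=lambda j: (pvalues[j], positions[j], rsids[j]))
        retained.append(best)
        alive.remove(best)
        for j in list(alive):
            if abs(positions[j] - positions[best]) <= window \
                    and c2[best, j] > r2_thr:
                alive.remove(j)
    return retained


class TestClump:
    def test_perfect_ld_keeps_lowest_p(self):
        d = np.random.default_rng(0).integers(0, 3, size=(50, 1))
        dosages = np.hstack([d, d]).astype(float)
        kept = clump(dosages, [1e-8, 1e-4], [1000, 11000], 0.5, 100)
        assert kept == [0]

    def test_effective_window_base_over_r2(self):
        """base 500 kb at r2 = 0.5 reaches 1,000 kb but not beyond."""
        d = np.random.default_rng(1).integers(0, 3, size=(100, 1))
        dosages = np.hstack([d, d]).astype(float)
        inside = clump(dosages, [1e-8, 1e-4], [1, 1 + 1_000_000], 0.5, 500)
        assert inside == [0]
        outside = clump(dosages, [1e-8, 1e-4], [1, 2 + 1_000_000], 0.5, 500)
        assert outside == [0, 1]

    def test_zero_variance_column_never_removed(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(50, 3)).astype(float)
        d[:, 1] = 1.0
        kept = clump(d, [1e-6, 1e-5, 1e-4], [1000, 2000, 3000], 0.1, 500)
        assert 1 in kept

    def test_p_tie_breaks_by_position(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(50, 2)).astype(float)
        kept = clump(d, [1e-4, 1e-4], [5000, 1000], 0.99, 1)
        assert kept[0] == 1  # lower position wins the tie

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_reference(self, seed):
        """Greedy clumping equals the re-evaluating reference on random
        instances (random sizes, r2 and windows)."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(5, 51))
        n = int(rng.integers(20, 301))
        gm = random_genotypes(rng, n, m, missing_rate=0.05)
        dosages = gm.dosages_float()
        pvalues = 10 ** (-rng.uniform(0, 8, size=m))
        positions = np.sort(rng.choice(10_000_000, size=m, replace=False))
        for _ in range(4):
            r2 = float(rng.choice([0.01, 0.1, 0.2, 0.5, 0.8, 0.95]))
            kb = float(rng.choice([5, 50, 200, 500]))
            got = clump(dosages, pvalues, positions, r2, kb,
                        rsids=gm.variants["rsid"].to_numpy())
            want = brute_force_clump(dosages, pvalues, positions, r2, kb,
                                     rsids=list(gm.variants["rsid"]))
            assert got == want


class TestThresholds:
    def test_always_n_values(self):
        rng = np.random.default_rng(0)
        p = 10 ** (-rng.uniform(0, 10, size=200))
        t = make_thresholds(p, 50)
        assert len(t) == 50
        assert (np.diff(t) > 0).all()

    def test_even_log_spacing_and_endpoints(self):
        p = np.array([1e-8, 1e-4, 1e-2])
        t = make_thresholds(p, 50)
        lg = -np.log10(t)
        gaps = np.diff(lg)
        assert np.ptp(gaps) < 1e-9
        assert lg.max() == pytest.approx(0.999 * 8)
        assert lg.min() == pytest.approx(0.1)
        # interior values follow the linear formula on the -log10 scale
        # (descending, since thresholds are returned ascending in p)
        expect = np.linspace(0.999 * 8, 0.1, 50)
        np.testing.assert_allclose(lg, expect)

    def test_all_p_one_degenerates_with_warning(self):
        with pytest.warns(UserWarning):
            t = make_thresholds(np.ones(5))
        assert list(t) == [1.0]


class TestScore:
    def test_zero_betas_zero_scores(self):
        d = np.random.default_rng(0).integers(0, 3, (10, 4)).astype(float)
        s = prs_score(d, np.zeros(4), [0, 1, 2, 3])
        np.testing.assert_array_equal(s, 0)

    def test_single_snp(self):
        d = np.array([[2.0], [0.0]])
        s = prs_score(d, np.array([0.5]), [0])
        np.testing.assert_allclose(s, [1.0, 0.0])

    def test_additive_over_disjoint_subsets(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, (20, 10)).astype(float)
        b = rng.normal(size=10)
        a, bset = [0, 2, 4], [1, 3, 5, 7]
        total = prs_score(d, b, a + bset)
        np.testing.assert_allclose(
            total, prs_score(d, b, a) + prs_score(d, b, bset)
        )

    def test_empty_subset_zero(self):
        d = np.ones((5, 3))
        np.testing.assert_array_equal(prs_score(d, np.ones(3), []), 0)

    def test_missing_uses_training_mean(self):
        d = np.array([[np.nan], [2.0]])
        s = prs_score(d, np.array([1.0]), [0], impute_means=np.array([0.5]))
        np.testing.assert_allclose(s, [0.5, 2.0])


class TestBuildGrid:
    @pytest.fixture(scope="class")
    def small_grid(self):
        rng = np.random.default_rng(5)
        gm = random_genotypes(rng, 120, 60, n_chrom=2)
        betas = rng.normal(size=60) * 0.1
        pvalues = 10 ** (-rng.uniform(0, 6, size=60))
        grid = build_grid(gm, betas, pvalues, GridSpec())
        return gm, betas, pvalues, grid

    def test_column_count_per_chromosome(self, small_grid):
        _, _, _, grid = small_grid
        counts = grid.meta.groupby("chrom").size()
        assert (counts == 1400).all()
        assert grid.n_columns == 2800

    def test_snp_counts_nested_in_threshold(self, small_grid):
        _, _, _, grid = small_grid
        for _, cell in grid.meta.groupby(["chrom", "r2", "base_kb"]):
            ordered = cell.sort_values("p_threshold")["n_snps"].to_numpy()
            assert (np.diff(ordered) >= 0).all()

    def test_single_threshold_override(self):
        rng = np.random.default_rng(6)
        gm = random_genotypes(rng, 50, 20)
        spec = GridSpec(n_thresholds=1)
        grid = build_grid(gm, rng.normal(size=20), rng.uniform(1e-6, 0.5, 20),
                          spec)
        assert grid.n_columns == 28

    def test_scores_match_direct_scoring(self, small_grid):
        gm, betas, _, grid = small_grid
        d = gm.dosages_float()
        rng = np.random.default_rng(7)
        for col in rng.choice(grid.n_columns, 25, replace=False):
            snps = grid.column_snps(int(col))
            direct = prs_score(d, betas, snps, grid.impute_means)
            np.testing.assert_allclose(grid.scores[:, col], direct,
                                       rtol=1e-10, atol=1e-12)

    def test_scores_invariant_to_variant_permutation(self):
        rng = np.random.default_rng(8)
        gm = random_genotypes(rng, 80, 30)
        betas = rng.normal(size=30)
        pvals = 10 ** (-rng.uniform(0, 5, size=30))
        grid1 = build_grid(gm, betas, pvals)
        perm = rng.permutation(30)
        gm2 = gm.subset_variants(perm)
        grid2 = build_grid(gm2, betas[perm], pvals[perm])
        np.testing.assert_allclose(grid1.scores, grid2.scores, atol=1e-9)

    def test_retained_count_shrinks_with_window_on_full_ld_blocks(self):
        """With fully-correlated blocks, growing the effective window can
        only merge clumps."""
        rng = np.random.default_rng(9)
        base = rng.integers(0, 3, size=(200, 10)).astype(np.int8)
        dosages = np.repeat(base, 3, axis=1)  # 10 blocks of 3 identical
        gm = random_genotypes(rng, 200, 30)
        gm.dosages = dosages
        pv = 10 ** (-rng.uniform(0, 6, size=30))
        pos = np.arange(30) * 10_000 + 1
        r2 = 0.5
        counts = [
            len(clump(dosages.astype(float), pv, pos, r2, kb))
            for kb in (5, 10, 50, 200, 1000)
        ]
        assert (np.diff(counts) <= 0).all()
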