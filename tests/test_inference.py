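"""Permutation tests against enumeration oracles; BH-FDR; rank sums."""

from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from earqc.inference import (
    bh_fdr,
    permutation_corr_test,
    permutation_mean_diff_test,
    rank_sum_right,
)


def naive_block_perm_null(a, b, n_per):
    """Oracle: recompute Pearson r on every explicitly permuted series."""
    nb = a.size // n_per
    bb = b[: nb * n_per].reshape(nb, n_per)
    return np.array(
        [
            np.corrcoef(a[: nb * n_per], bb[list(p)].ravel())[0, 1]
            for p in permutations(range(nb))
        ]
    )


def bh_oracle(pvals, q):
    """Brute-force step-up: largest k with p(k) <= k q / m; reject all below."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_max = rank
    reject = np.zeros(m, bool)
    reject[order[:k_max]] = True
    return reject


class TestCorrPermutation:
    def test_identical_signals_hit_the_add_one_floor(self, rng):
        x = rng.standard_normal(30 * 25)  # 30 blocks at fs 2.5
        res = permutation_corr_test(x, x, fs=2.5, n_perm=400)
        assert res.method == "monte_carlo"
        assert res.p_two_sided == pytest.approx(1 / 401)

    def test_three_blocks_match_exhaustive_enumeration(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(30)
        res = permutation_corr_test(a, b, fs=1.0, block_len_s=10.0, n_perm=400)
        null = naive_block_perm_null(a, b, 10)
        r_obs = np.corrcoef(a, b)[0, 1]
        assert res.method == "exact"
        assert res.observed_stat == pytest.approx(r_obs)
        assert res.p_two_sided == pytest.approx(
            np.mean(np.abs(null) >= abs(r_obs) - 1e-12)
        )

    def test_fast_path_equals_naive_recomputation(self, rng):
        """The block cross-dot shortcut must reproduce the naive null set."""
        a = rng.standard_normal(48)
        b = rng.standard_normal(48)
        res = permutation_corr_test(a, b, fs=1.0, block_len_s=12.0, n_perm=30)
        null = naive_block_perm_null(a, b, 12)
        assert res.method == "exact"
        assert np.allclose(np.sort(res.null_stats), np.sort(null))

    def test_mask_restricts_to_clean_blocks(self, rng):
        a = rng.standard_normal(60)
        b = rng.standard_normal(60)
        mask = np.array([True, False, True, True, False, True])
        res = permutation_corr_test(
            a, b, fs=1.0, block_len_s=10.0, n_perm=100, mask=mask
        )
        clean = mask.repeat(10)
        assert res.observed_stat == pytest.approx(
            np.corrcoef(a[clean], b[clean])[0, 1]
        )

    def test_fewer_than_two_blocks_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_corr_test(
                rng.standard_normal(12), rng.standard_normal(12),
                fs=1.0, block_len_s=10.0,
            )

    def test_affine_invariance_of_p(self, rng):
        a = rng.standard_normal(80)
        b = rng.standard_normal(80) + 0.5 * a
        res1 = permutation_corr_test(a, b, fs=1.0, block_len_s=10.0,
                                     n_perm=200, seed=7)
        res2 = permutation_corr_test(a, 3.0 * b - 11.0, fs=1.0,
                                     block_len_s=10.0, n_perm=200, seed=7)
        assert res1.p_two_sided == res2.p_two_sided
        assert res1.observed_stat == pytest.approx(res2.observed_stat)

    def test_type_one_error_calibrated(self):
        """500 independent white-noise pairs, 30 blocks x 10 s: rejection
        rate at alpha = 0.01 lies in the binomial 99% interval."""
        rng = np.random.default_rng(606)
        # 30 blocks of 10 s at 25 Hz -> 7500 samples per series
        rejections = 0
        n_rep = 500
        for i in range(n_rep):
            a = rng.standard_normal(7500)
            b = rng.standard_normal(7500)
            res = permutation_corr_test(a, b, fs=25.0, block_len_s=10.0,
                                        n_perm=400, seed=i)
            rejections += res.p_two_sided < 0.01
        rate = rejections / n_rep
        half = 2.576 * np.sqrt(0.01 * 0.99 / n_rep)
        assert abs(rate - 0.01) <= half

    def test_power_grows_with_shared_source_strength(self):
        """Rejection is much more frequent under dependence (rho = 0.4) than
        under the null, and grows with rho."""
        rng = np.random.default_rng(99)
        rates = []
        for rho in (0.0, 0.2, 0.4, 0.6):
            rej = 0
            for i in range(40):
                n = 3000
                g = np.sqrt(1 / rho - 1) if rho > 0 else np.inf
                s = rng.standard_normal(n)
                if rho > 0:
                    a = s + g * rng.standard_normal(n)
                    b = s + g * rng.standard_normal(n)
                else:
                    a, b = rng.standard_normal(n), rng.standard_normal(n)
                res = permutation_corr_test(a, b, fs=10.0, block_len_s=10.0,
                                            n_perm=200, seed=i)
                rej += res.p_two_sided < 0.01
            rates.append(rej / 40)
        assert rates[2] > rates[0] + 0.5
        assert rates[3] >= rates[2]


class TestMeanDiffPermutation:
    def test_identical_groups_give_p_one(self):
        res = permutation_mean_diff_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.observed_stat == 0.0
        assert res.p_two_sided == 1.0

    def test_toy_case_matches_exhaustive_enumeration(self):
        x = np.array([0.0, 0.0, 0.0, 0.0])
        y = np.array([10.0, 10.0, 10.0, 10.0])
        res = permutation_mean_diff_test(x, y, n_perm=400)
        # oracle: all C(8,4) = 70 label assignments
        pooled = np.concatenate([x, y])
        null = [
            abs(pooled[list(ix)].mean()
                - pooled[[i for i in range(8) if i not in ix]].mean())
            for ix in combinations(range(8), 4)
        ]
        p_exact = np.mean(np.array(null) >= abs(res.observed_stat) - 1e-12)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(p_exact)
        assert p_exact == pytest.approx(2 / 70)

    def test_constant_pool_gives_p_one(self):
        res = permutation_mean_diff_test([5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.p_two_sided == 1.0

    def test_type_one_error_calibrated(self):
        """Two N(0,1) samples of size 20, 500 replicates: rejection rate at
        alpha = 0.01 within the binomial 99% interval."""
        rng = np.random.default_rng(17)
        n_rep = 500
        rej = 0
        for i in range(n_rep):
            res = permutation_mean_diff_test(
                rng.standard_normal(20), rng.standard_normal(20),
                n_perm=400, seed=i,
            )
            rej += res.p_two_sided < 0.01
        half = 2.576 * np.sqrt(0.01 * 0.99 / n_rep)
        assert abs(rej / n_rep - 0.01) <= half


class TestBhFdr:
    def test_step_up_rejects_all_four(self):
        reject, _ = bh_fdr([0.002, 0.01, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_all_ones_reject_nothing(self):
        reject, _ = bh_fdr([1.0, 1.0, 1.0], q=0.05)
        assert not reject.any()

    def test_single_p_reduces_to_plain_threshold(self):
        assert bh_fdr([0.04], q=0.05)[0][0]
        assert not bh_fdr([0.06], q=0.05)[0][0]

    def test_empty_input(self):
        reject, p_adj = bh_fdr([], q=0.05)
        assert reject.size == 0 and p_adj.size == 0

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            m = rng.integers(1, 21)
            p = np.round(rng.uniform(0, 1, m), 4)
            q = rng.choice([0.01, 0.05, 0.1])
            reject, _ = bh_fdr(p, q=q)
            assert np.array_equal(reject, bh_oracle(p, q))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=15),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_decisions_are_monotone_in_p(self, pvals, q):
        reject, _ = bh_fdr(pvals, q=q)
        p = np.asarray(pvals)
        if reject.any():
            threshold = p[reject].max()
            assert np.all(reject[p <= threshold])


class TestRankSum:
    def test_separated_groups_match_enumeration(self):
        # oracle: C(6,3) = 20 equally likely rank assignments, one maximal
        assert rank_sum_right([4, 5, 6], [1, 2, 3]) == pytest.approx(1 / 20)

    def test_identical_groups_show_no_shift(self):
        assert rank_sum_right([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) >= 0.5

    def test_agrees_with_enumeration_on_random_samples(self):
        """50 random tie-free small samples vs explicit enumeration of all
        rank assignments, agreement to 1e-6."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            nx, ny = rng.integers(3, 7), rng.integers(3, 7)
            vals = rng.permutation(np.arange(1.0, nx + ny + 1.0))
            x, y = vals[:nx], vals[nx:]
            null = [
                sum(c) for c in combinations(range(1, nx + ny + 1), nx)
            ]
            ranks = np.argsort(np.argsort(np.concatenate([x, y]))) + 1
            obs_rank = ranks[:nx].sum()
            p_exact = np.mean(np.array(null) >= obs_rank)
            assert rank_sum_right(x, y) == pytest.approx(p_exact, abs=1e-6)
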