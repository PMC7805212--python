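"""Matched nonparametric tests against enumeration and permutation oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from ftdindex import (
    DominantSets,
    bonferroni_correct,
    friedman_test,
    identify_dominant_sets,
    wilcoxon_posthoc,
)
from ftdindex.exceptions import MatchingError, NoSignalError, SchemaError
from ftdindex.group_stats import _signed_rank_exact_p, compare_all, triplet_blocks
from ftdindex.volumetry import MeasureMatrix


def matrix_from_blocks(blocks, measure="m"):
    """One-measure matrix whose rows are NC/AD/FTD triplet values."""
    blocks = np.asarray(blocks, dtype=float)
    n = blocks.shape[0]
    values, groups, sids, tids = [], [], [], []
    for t in range(n):
        for gi, g in enumerate(("NC", "AD", "FTD")):
            values.append([blocks[t, gi]])
            groups.append(g)
            sids.append(f"{g}{t}")
            tids.append(f"T{t:02d}")
    return MeasureMatrix(
        measure_names=[measure],
        values=np.array(values),
        subject_ids=sids,
        groups=np.array(groups, dtype=object),
        triplet_ids=tids,
    )


def brute_force_friedman_p(blocks):
    """Enumerate every within-block ordering (6^n) of the observed values."""
    blocks = np.asarray(blocks, dtype=float)

    def statistic(b):
        ranks = np.vstack([stats.rankdata(row) for row in b])
        colsums = ranks.sum(axis=0)
        return ((colsums - colsums.mean()) ** 2).sum()

    s_obs = statistic(blocks)
    perms = list(itertools.permutations(range(3)))
    count = total = 0
    for assignment in itertools.product(perms, repeat=len(blocks)):
        permuted = np.vstack([blocks[i][list(p)] for i, p in enumerate(assignment)])
        total += 1
        if statistic(permuted) >= s_obs - 1e-9:
            count += 1
    return count / total


def brute_force_signed_rank_p(diffs):
    """Enumerate all 2^n sign assignments of the observed magnitudes."""
    diffs = np.asarray(diffs, dtype=float)
    ranks = stats.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(diffs)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestFriedman:
    def test_identical_groups_give_p_one(self):
        m = matrix_from_blocks(np.tile([[3.0, 3.0, 3.0]], (6, 1)))
        assert friedman_test(m, "m") == 1.0

    def test_consistent_ordering_matches_full_enumeration(self):
        # FTD always largest, NC always smallest, 5 triplets: 6^5 orderings
        rng = np.random.default_rng(0)
        blocks = np.sort(rng.uniform(0, 1, size=(5, 3)), axis=1)  # NC<AD<FTD
        m = matrix_from_blocks(blocks)
        assert friedman_test(m, "m") == pytest.approx(
            brute_force_friedman_p(blocks), abs=1e-12
        )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_small_matrices_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        blocks = rng.normal(size=(4, 3))
        if seed == 3:  # inject within-block ties
            blocks[0, 1] = blocks[0, 0]
            blocks[2] = blocks[2, 0]
        m = matrix_from_blocks(blocks)
        assert friedman_test(m, "m") == pytest.approx(
            brute_force_friedman_p(blocks), abs=1e-12
        )

    def test_block_order_exchangeability(self):
        rng = np.random.default_rng(4)
        blocks = rng.normal(size=(7, 3))
        p1 = friedman_test(matrix_from_blocks(blocks), "m")
        p2 = friedman_test(matrix_from_blocks(blocks[::-1]), "m")
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_asymptotic_option_matches_scipy(self):
        rng = np.random.default_rng(6)
        blocks = rng.normal(size=(12, 3))
        m = matrix_from_blocks(blocks)
        expected = stats.friedmanchisquare(*blocks.T).pvalue
        assert friedman_test(m, "m", method="asymptotic") == pytest.approx(expected)

    def test_exact_close_to_asymptotic_at_moderate_n(self):
        rng = np.random.default_rng(8)
        blocks = rng.normal(size=(40, 3)) + [0.0, 0.2, 0.5]
        m = matrix_from_blocks(blocks)
        p_exact = friedman_test(m, "m")
        p_asym = friedman_test(m, "m", method="asymptotic")
        assert abs(p_exact - p_asym) < 0.05

    def test_incomplete_triplets_named(self):
        m = matrix_from_blocks(np.random.default_rng(9).normal(size=(4, 3)))
        m.groups[0] = "AD"  # triplet T00 now has two AD, no NC
        with pytest.raises(MatchingError) as exc:
            friedman_test(m, "m")
        assert "T00" in str(exc.value)

    def test_requires_triplet_ids(self):
        m = matrix_from_blocks(np.random.default_rng(10).normal(size=(4, 3)))
        m.triplet_ids = None
        with pytest.raises(MatchingError):
            friedman_test(m, "m")


class TestWilcoxon:
    def test_all_zero_differences(self):
        m = matrix_from_blocks(np.tile([[1.0, 2.0, 2.0]], (8, 1)))
        with pytest.warns(UserWarning):
            assert wilcoxon_posthoc(m, "m", ("AD", "FTD")) == 1.0

    def test_eight_consistent_pairs(self):
        # all 8 paired differences positive -> two-sided exact p = 2/2^8
        blocks = np.array([[0.0, 1.0 + 0.1 * i, 0.5] for i in range(8)])
        m = matrix_from_blocks(blocks)
        assert wilcoxon_posthoc(m, "m", ("AD", "FTD")) == pytest.approx(2 / 256, abs=1e-12)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(12)
        blocks = rng.normal(size=(10, 3))
        m1 = matrix_from_blocks(blocks)
        flipped = blocks.copy()
        flipped[:, [1, 2]] = flipped[:, [2, 1]]  # swap AD and FTD columns
        m2 = matrix_from_blocks(flipped)
        assert wilcoxon_posthoc(m1, "m", ("AD", "FTD")) == pytest.approx(
            wilcoxon_posthoc(m2, "m", ("AD", "FTD")), abs=1e-12
        )

    @pytest.mark.parametrize("n,seed", [(5, 0), (8, 1), (11, 2), (12, 3)])
    def test_exact_matches_sign_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        diffs = np.round(rng.normal(size=n), 1)
        diffs = diffs[diffs != 0]
        assert _signed_rank_exact_p(diffs) == pytest.approx(
            brute_force_signed_rank_p(diffs), abs=1e-12
        )

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(14)
        blocks = rng.normal(size=(47, 3)) + [0.0, 0.0, 0.6]
        m = matrix_from_blocks(blocks)
        p = wilcoxon_posthoc(m, "m", ("AD", "FTD"))
        expected = stats.wilcoxon(
            blocks[:, 1] - blocks[:, 2], correction=True, method="approx"
        ).pvalue
        assert p == pytest.approx(expected, rel=1e-9)

    def test_unpaired_fallback(self):
        rng = np.random.default_rng(15)
        blocks = rng.normal(size=(20, 3))
        m = matrix_from_blocks(blocks)
        m.triplet_ids = None
        p = wilcoxon_posthoc(m, "m", ("AD", "FTD"), paired=False)
        expected = stats.mannwhitneyu(
            blocks[:, 1], blocks[:, 2], alternative="two-sided"
        ).pvalue
        assert p == pytest.approx(expected)


@pytest.mark.parametrize(
    "p,k,expected", [(0.02, 3, 0.06), (0.5, 3, 1.0), (0.123, 1, 0.123)]
)
def test_bonferroni(p, k, expected):
    assert bonferroni_correct(p, k) == pytest.approx(expected, abs=1e-12)


class TestDominantSets:
    def test_null_data_raises_no_signal(self):
        rng = np.random.default_rng(16)
        blocks = rng.normal(size=(20, 3))
        blocks[:, 2] = blocks[:, 1]  # FTD identical to AD
        m = matrix_from_blocks(blocks)
        with pytest.raises(NoSignalError):
            identify_dominant_sets(m)

    def test_partition_property(self, nacc_cohort):
        _, matrix = nacc_cohort
        alpha = 0.05
        dom = identify_dominant_sets(matrix, alpha=alpha)
        results = compare_all(matrix, alpha=alpha)
        n_sig = sum(
            1
            for r in results
            if r.pairwise_p.get("AD-FTD") is not None and r.pairwise_p["AD-FTD"] < alpha
        )
        assert len(dom.ftd_dominant) + len(dom.ad_dominant) == n_sig
        assert not set(dom.ftd_dominant) & set(dom.ad_dominant)

    def test_monotone_transform_invariance(self, nacc_cohort):
        """Rank tests: any strictly increasing per-measure transform leaves
        the identified sets unchanged."""
        _, matrix = nacc_cohort
        transformed = MeasureMatrix(
            measure_names=list(matrix.measure_names),
            values=np.exp(matrix.values / matrix.values.max(axis=0)),
            subject_ids=list(matrix.subject_ids),
            groups=matrix.groups,
            triplet_ids=list(matrix.triplet_ids),
        )
        d1 = identify_dominant_sets(matrix)
        d2 = identify_dominant_sets(transformed)
        assert d1.ftd_dominant == d2.ftd_dominant
        assert d1.ad_dominant == d2.ad_dominant

    def test_column_order_invariance(self, nacc_cohort):
        _, matrix = nacc_cohort
        order = list(range(len(matrix.measure_names)))[::-1]
        reordered = MeasureMatrix(
            measure_names=[matrix.measure_names[i] for i in order],
            values=matrix.values[:, order],
            subject_ids=list(matrix.subject_ids),
            groups=matrix.groups,
            triplet_ids=list(matrix.triplet_ids),
        )
        d1 = identify_dominant_sets(matrix)
        d2 = identify_dominant_sets(reordered)
        assert set(d1.ftd_dominant) == set(d2.ftd_dominant)
        assert set(d1.ad_dominant) == set(d2.ad_dominant)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(SchemaError):
            DominantSets(ftd_dominant=["a", "b"], ad_dominant=["b"])


def test_friedman_matches_mc_permutation_oracle():
    """Exact p agrees with a 10,000-draw within-block permutation oracle."""
    rng = np.random.default_rng(2718)
    for shift in (0.0, 0.4, 1.0):
        blocks = rng.normal(size=(8, 3)) + [0.0, shift / 2, shift]
        m = matrix_from_blocks(blocks)
        p_exact = friedman_test(m, "m")
        ranks = np.vstack([stats.rankdata(row) for row in blocks])
        s_obs = ((ranks.sum(axis=0) - ranks.sum() / 3) ** 2).sum()
        n_perm, hits = 10_000, 0
        for _ in range(n_perm):
            permuted = np.vstack([rng.permutation(row) for row in ranks])
            s = ((permuted.sum(axis=0) - permuted.sum() / 3) ** 2).sum()
            hits += s >= s_obs - 1e-9
        p_mc = hits / n_perm
        se = max(np.sqrt(p_mc * (1 - p_mc) / n_perm), 1e-4)
        assert abs(p_exact - p_mc) < 5 * se


def test_triplet_blocks_orders_columns_nc_ad_ftd():
    blocks = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    m = matrix_from_blocks(blocks)
    np.testing.assert_array_equal(triplet_blocks(m, "m"), blocks)
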