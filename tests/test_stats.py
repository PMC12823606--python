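"""Staging clusters, rank statistics, normality and power."""

import itertools

import numpy as np
import pytest

from lymphspec.stats import (
    hsi_stage,
    mann_whitney_u,
    min_detectable_r,
    normality_omnibus,
    spearman,
)


def optimal_contiguous_partition(values, k):
    """DP oracle: contiguous partition of sorted 1-D data minimizing
    total within-cluster sum of squares; returns labels aligned to the
    input order (0 = lowest cluster)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    prefix = np.concatenate([[0.0], np.cumsum(v)])
    prefix2 = np.concatenate([[0.0], np.cumsum(v**2)])

    def ssq(i, j):  # within-SS of v[i:j]
        s, s2, m = prefix[j] - prefix[i], prefix2[j] - prefix2[i], j - i
        return s2 - s * s / m

    cost = {(0, 0): 0.0}
    choice = {}
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            best, arg = np.inf, None
            for i in range(kk - 1, j):
                if (kk - 1, i) not in cost:
                    continue
                c = cost[(kk - 1, i)] + ssq(i, j)
                if c < best:
                    best, arg = c, i
            cost[(kk, j)] = best
            choice[(kk, j)] = arg
    # recover boundaries
    bounds, j = [], n
    for kk in range(k, 0, -1):
        i = choice[(kk, j)]
        bounds.append((i, j))
        j = i
    bounds.reverse()
    sorted_labels = np.empty(n, dtype=int)
    for lab, (i, j) in enumerate(bounds):
        sorted_labels[i:j] = lab
    order = np.argsort(np.asarray(values, dtype=float), kind="stable")
    labels = np.empty(n, dtype=int)
    labels[order] = sorted_labels
    return labels


class TestHsiStage:
    def test_three_clump_example(self):
        values = [0.00, 0.01, 0.02, 0.50, 0.52, 1.00, 1.05]
        staging = hsi_stage(values, k=3)
        assert staging.labels == ["low"] * 3 + ["mid"] * 2 + ["high"] * 2

    def test_k_one_labels_everything_identically(self):
        staging = hsi_stage([0.1, 0.5, 0.9], k=1)
        assert len(set(staging.labels)) == 1

    def test_input_order_invariance(self, rng):
        values = np.concatenate(
            [rng.normal(0, 0.02, 10), rng.normal(0.5, 0.02, 10), rng.normal(1, 0.02, 10)]
        )
        perm = rng.permutation(values.size)
        base = dict(zip(values, hsi_stage(values).labels))
        shuffled = dict(zip(values[perm], hsi_stage(values[perm]).labels))
        assert base == shuffled

    def test_labels_monotone_in_value(self, rng):
        values = rng.normal(0, 1, 40)
        staging = hsi_stage(values, k=3)
        codes = staging.label_codes()
        order = np.argsort(values)
        assert np.all(np.diff(codes[order]) >= 0)

    def test_matches_dp_oracle_on_separated_clumps(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            centers = np.sort(rng.uniform(0, 10, 3))
            while np.min(np.diff(centers)) < 2.0:  # well-separated
                centers = np.sort(rng.uniform(0, 10, 3))
            sizes = rng.integers(3, 8, 3)
            values = np.concatenate(
                [rng.normal(c, 0.1, n) for c, n in zip(centers, sizes)]
            )
            rng.shuffle(values)
            got = hsi_stage(values, k=3).label_codes()
            oracle = optimal_contiguous_partition(values, 3)
            np.testing.assert_array_equal(got, oracle)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            hsi_stage([1.0, 1.0, 1.0], k=3)


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [-v**3 for v in x]) == pytest.approx(-1.0)

    def test_tied_example_matches_manual_midranks(self):
        # x = [1, 2, 2, 3] -> ranks [1, 2.5, 2.5, 4]
        # y = [10, 20, 20, 15] -> ranks [1, 3.5, 3.5, 2]
        x, y = [1, 2, 2, 3], [10, 20, 20, 15]
        rx = np.array([1, 2.5, 2.5, 4.0])
        ry = np.array([1, 3.5, 3.5, 2.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(expected)

    def test_equals_spearman_of_ranks(self, rng):
        from scipy.stats import rankdata

        x, y = rng.random(30), rng.random(30)
        assert spearman(x, y) == pytest.approx(spearman(rankdata(x), rankdata(y)))

    def test_invariant_under_monotone_transform(self, rng):
        x, y = rng.random(25), rng.random(25)
        assert spearman(np.exp(3 * x), y) == pytest.approx(spearman(x, y))

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


def enumerate_mwu_p(a, b):
    """Exact two-sided p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    n = len(pooled)
    mean_u = n1 * (n - n1) / 2
    count = total = 0
    for comb in itertools.combinations(range(n), n1):
        u = np.sum(ranks[list(comb)]) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        # U for the first group is 0; 2 of the 20 assignments are as extreme
        assert min(res.statistic, 9 - res.statistic) == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.method.endswith("exact")

    def test_identical_samples_not_significant(self):
        res = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value > 0.9

    def test_exact_path_matches_enumeration(self, rng):
        for _ in range(10):
            a, b = rng.random(5), rng.random(5)
            res = mann_whitney_u(a, b)
            assert res.method.endswith("exact")
            assert res.p_value == pytest.approx(enumerate_mwu_p(a, b))

    def test_enumeration_across_all_small_sizes(self, rng):
        for n1 in range(1, 6):
            for n2 in range(n1, 11 - n1):
                a, b = rng.random(n1), rng.random(n2)
                res = mann_whitney_u(a, b)
                assert res.p_value == pytest.approx(enumerate_mwu_p(a, b)), (n1, n2)

    def test_ties_switch_to_asymptotic(self):
        res = mann_whitney_u([1, 2, 2, 3], [2, 3, 4, 4])
        assert res.method.endswith("asymptotic")

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])


class TestNormalityOmnibus:
    def test_rejection_rate_calibrated_under_null(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            normality_omnibus(rng.normal(size=5000)).p_value < 0.05 for _ in range(500)
        )
        assert 0.03 <= rejections / 500 <= 0.07

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(1)
        assert normality_omnibus(rng.exponential(size=500)).p_value < 0.01

    def test_affine_invariance(self, rng):
        v = rng.normal(size=200)
        a = normality_omnibus(v)
        b = normality_omnibus(5.0 * v - 3.0)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-9)

    def test_small_sample_flagged(self, rng):
        res = normality_omnibus(rng.normal(size=12))
        assert "unreliable" in res.note


class TestMinDetectableR:
    def test_published_study_size(self):
        # n = 58, alpha = 0.05, power = 0.80 -> r = 0.36
        assert round(min_detectable_r(58, 0.05, 0.80), 2) == 0.36

    def test_decreasing_in_n_with_zero_limit(self):
        ns = [10, 30, 100, 1000, 100000]
        bounds = [min_detectable_r(n) for n in ns]
        assert all(a > b for a, b in zip(bounds, bounds[1:]))
        assert bounds[-1] < 0.01

    def test_half_power_drops_power_term(self):
        from scipy.stats import norm

        n = 40
        expected = np.tanh(norm.ppf(0.975) / np.sqrt(n - 3))
        assert min_detectable_r(n, 0.05, 0.5) == pytest.approx(expected)

    def test_invalid_domain_rejected(self):
        with pytest.raises(ValueError):
            min_detectable_r(3)
        with pytest.raises(ValueError):
            min_detectable_r(58, alpha=1.2)
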