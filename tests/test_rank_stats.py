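"""Tie-corrected Kruskal-Wallis, Dunn post hoc, and the NPP correlation.

The Kruskal-Wallis path is cross-checked against scipy's independent
implementation; Dunn z-values are checked against hand-computed frozen
values (no-tie case) and against a literal re-evaluation of the rank-sum
formula written independently inside the test (tied case).
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from aviprey import (
    GroupedSamples,
    consumption_npp_correlation,
    dunn_test,
    kruskal_wallis,
    midranks,
)
from aviprey.rank_stats import tie_term


class TestMidranks:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([10, 20, 30], [1, 2, 3]),
            ([5, 5, 9], [1.5, 1.5, 3]),
            ([7, 7, 7, 7], [2.5, 2.5, 2.5, 2.5]),
        ],
    )
    def test_known_rankings(self, values, expected):
        assert midranks(values).tolist() == expected

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=50))
    def test_ranks_sum_to_triangular_number(self, values):
        n = len(values)
        assert midranks(values).sum() == pytest.approx(n * (n + 1) / 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            midranks([])


def _h_direct(groups):
    """Independent direct-formula evaluation of tie-corrected H."""
    pooled = np.concatenate(list(groups.values()))
    n = pooled.size
    ranks = sps.rankdata(pooled)
    idx = 0
    s = 0.0
    for v in groups.values():
        r = ranks[idx : idx + len(v)].sum()
        s += r**2 / len(v)
        idx += len(v)
    h = 12.0 / (n * (n + 1)) * s - 3 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    c = 1 - np.sum(t.astype(float) ** 3 - t) / (n**3 - n)
    return h / c


class TestKruskalWallis:
    def test_three_even_groups(self):
        res = kruskal_wallis(
            GroupedSamples.from_mapping({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        )
        assert res.statistic == pytest.approx(32.0 / 7.0, rel=1e-12)  # 4.5714...
        assert res.df == 2
        assert res.tie_correction == 1.0

    def test_all_tied_degenerate_input(self):
        res = kruskal_wallis(
            GroupedSamples.from_mapping({"a": [3, 3], "b": [3, 3, 3], "c": [3]})
        )
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_matches_direct_formula_oracle(self):
        groups = {"a": [1.0, 2.0, 2.0, 5.0], "b": [2.0, 3.0, 7.0], "c": [4.0, 4.0, 9.0]}
        res = kruskal_wallis(GroupedSamples.from_mapping(groups))
        expected = _h_direct({k: np.asarray(v) for k, v in groups.items()})
        assert res.statistic == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_with_and_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = {
            "a": rng.integers(0, 8, size=12).astype(float),  # forces ties
            "b": rng.integers(0, 8, size=9).astype(float),
            "c": rng.normal(size=15),
        }
        res = kruskal_wallis(GroupedSamples.from_mapping(groups))
        ref = sps.kruskal(*groups.values())
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(
        data=st.lists(
            # coarse grid keeps the transform injective in floating point
            # while still generating genuine ties
            st.lists(st.integers(1, 50).map(lambda k: k / 2.0), min_size=2, max_size=5),
            min_size=2,
            max_size=3,
        ),
        seed=st.integers(0, 10),
    )
    def test_invariant_under_monotone_transform(self, data, seed):
        groups = {f"g{i}": v for i, v in enumerate(data)}
        base = kruskal_wallis(GroupedSamples.from_mapping(groups))
        transformed = {k: [math.log(x) + 2 * x for x in v] for k, v in groups.items()}
        res = kruskal_wallis(GroupedSamples.from_mapping(transformed))
        assert res.statistic == pytest.approx(base.statistic, abs=1e-9)

    def test_tie_correction_in_unit_interval(self):
        res = kruskal_wallis(GroupedSamples.from_mapping({"a": [1, 1, 2], "b": [2, 3]}))
        assert 0.0 < res.tie_correction <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            GroupedSamples.from_mapping({"a": [1.0], "b": []})

    def test_permutation_p_ordering_small_n(self):
        """Chi-square p-values order datasets the same way exhaustive
        label-permutation p-values do (N <= 8)."""

        def perm_p(groups):
            pooled = np.concatenate(list(groups.values()))
            sizes = [len(v) for v in groups.values()]
            observed = _h_direct(groups)
            count = total = 0
            for perm in itertools.permutations(range(pooled.size)):
                arranged = pooled[list(perm)]
                idx = 0
                g = {}
                for i, sz in enumerate(sizes):
                    g[i] = arranged[idx : idx + sz]
                    idx += sz
                if _h_direct(g) >= observed - 1e-12:
                    count += 1
                total += 1
            return count / total

        weak = {"a": [1.0, 4.0], "b": [2.0, 5.0], "c": [3.0, 6.0]}
        strong = {"a": [1.0, 2.0], "b": [3.0, 4.0], "c": [5.0, 6.0]}
        chi_weak = kruskal_wallis(GroupedSamples.from_mapping(weak)).p_value
        chi_strong = kruskal_wallis(GroupedSamples.from_mapping(strong)).p_value
        assert (chi_strong < chi_weak) == (perm_p(strong) < perm_p(weak))


def _dunn_z_direct(groups):
    """Independent re-evaluation of the Dunn z formula."""
    pooled = np.concatenate(list(groups.values()))
    n = pooled.size
    ranks = sps.rankdata(pooled)
    means, sizes = {}, {}
    idx = 0
    for k, v in groups.items():
        means[k] = ranks[idx : idx + len(v)].mean()
        sizes[k] = len(v)
        idx += len(v)
    var = n * (n + 1) / 12.0 - tie_term(pooled) / (12.0 * (n - 1))
    out = {}
    for a, b in itertools.combinations(groups, 2):
        out[(a, b)] = (means[a] - means[b]) / math.sqrt(var * (1 / sizes[a] + 1 / sizes[b]))
    return out


class TestDunn:
    def test_identical_groups_give_zero_z(self):
        res = dunn_test(GroupedSamples.from_mapping({"a": [1, 2, 3], "b": [1, 2, 3]}))
        (pair,) = res.pairwise
        assert pair.z == pytest.approx(0.0)
        assert pair.p_value == pytest.approx(1.0)

    def test_frozen_no_tie_example(self):
        # groups [1,2,3], [4,5,6], [7,8,9]: mean ranks 2, 5, 8;
        # denominator sqrt((9·10/12)(2/3)) = sqrt(5)
        res = dunn_test(
            GroupedSamples.from_mapping({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        )
        z = {(c.group_a, c.group_b): c.z for c in res.pairwise}
        assert z[("a", "b")] == pytest.approx(-3 / math.sqrt(5), abs=1e-6)
        assert z[("a", "c")] == pytest.approx(-6 / math.sqrt(5), abs=1e-6)
        assert z[("b", "c")] == pytest.approx(-3 / math.sqrt(5), abs=1e-6)

    def test_matches_direct_formula_with_ties(self):
        groups = {"a": [1.0, 2.0, 2.0], "b": [2.0, 3.0, 5.0], "c": [5.0, 5.0, 8.0, 9.0]}
        res = dunn_test(GroupedSamples.from_mapping(groups))
        expected = _dunn_z_direct(groups)
        for c in res.pairwise:
            assert c.z == pytest.approx(expected[(c.group_a, c.group_b)], abs=1e-9)

    def test_shifted_group_has_smallest_pairwise_p(self):
        rng = np.random.default_rng(11)
        groups = {
            "low1": rng.lognormal(1.0, 0.4, 10),
            "low2": rng.lognormal(1.1, 0.4, 10),
            "high": rng.lognormal(4.0, 0.4, 10),
        }
        res = dunn_test(GroupedSamples.from_mapping(groups))
        with_high = [c.p_value for c in res.pairwise if "high" in (c.group_a, c.group_b)]
        without = [c.p_value for c in res.pairwise if "high" not in (c.group_a, c.group_b)]
        assert max(with_high) < min(without)

    def test_bonferroni_and_holm_dominate_raw(self):
        groups = {"a": [1.0, 2.0, 9.0], "b": [3.0, 4.0, 8.0], "c": [5.0, 6.0, 7.0]}
        raw = dunn_test(GroupedSamples.from_mapping(groups), p_adjust="none")
        for method in ("holm", "bonferroni"):
            adj = dunn_test(GroupedSamples.from_mapping(groups), p_adjust=method)
            for r, a in zip(raw.pairwise, adj.pairwise):
                assert a.p_value >= r.p_value - 1e-15
                assert a.p_value <= 1.0

    def test_unknown_adjustment_rejected(self):
        with pytest.raises(ValueError):
            dunn_test(GroupedSamples.from_mapping({"a": [1.0], "b": [2.0]}), p_adjust="fdr")


class TestNppCorrelation:
    def test_perfectly_monotone(self):
        assert consumption_npp_correlation([1, 2, 3, 4], [10, 20, 40, 80]) == pytest.approx(1.0)

    def test_reversed(self):
        assert consumption_npp_correlation([1, 2, 3], [9, 6, 3]) == pytest.approx(-1.0)

    def test_pearson_flag(self):
        r = consumption_npp_correlation([1, 2, 3], [2, 4, 6], method="pearson")
        assert r == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            consumption_npp_correlation([1, 2, 3], [1, 2])

    def test_packaged_tables_correlate_positively(self, summaries):
        from aviprey import read_npp_reference

        npp = read_npp_reference()
        rho = consumption_npp_correlation(
            [s.mean for s in summaries], [npp[s.biome] for s in summaries]
        )
        assert rho > 0
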