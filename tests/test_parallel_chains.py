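"""Two-chain comparison tests and burn-in-aware concatenation."""

import itertools
import math

import numpy as np
import pytest

from phylotrace.parallel_chains import (
    SplitTable,
    build_split_table,
    combine_chains,
    mann_whitney,
    split_chisq,
)
from phylotrace.simulate import Ar1Spec, TreeTraceSpec, gen_ar1, gen_tree_trace, make_trace_table
from phylotrace.summary_stats import summarize
from phylotrace.tree_posterior import topology_frequencies, topology_key

T_A = "(((a,b),c),d,e);"
T_B = "(((a,c),b),d,e);"
T_C = "((a,b),(c,d),e);"


def exact_mw_p(x, y):
    """Enumeration oracle: two-sided p over all labelings of the pooled sample."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_min(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u_x = sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )
        return min(u_x, n1 * len(ys) - u_x)

    observed = u_min(set(range(n1)))
    labelings = list(itertools.combinations(range(len(pooled)), n1))
    count = sum(1 for idx in labelings if u_min(set(idx)) <= observed)
    return count / len(labelings)


class TestMannWhitney:
    def test_fully_separated_small_samples_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert exact_mw_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_against_enumeration_oracle(self, rng):
        for _ in range(5):
            x = rng.integers(0, 100, size=3).astype(float)
            y = rng.integers(0, 100, size=3).astype(float)
            if len(np.unique(np.concatenate([x, y]))) < 6:
                continue  # oracle enumeration assumes no ties here
            res = mann_whitney(x, y)
            assert res.p_value == pytest.approx(exact_mw_p(list(x), list(y)))

    def test_identical_samples_midranks(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == 4.5
        assert res.p_value == pytest.approx(1.0)

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.standard_normal(50), rng.standard_normal(60) + 0.5
        a, b = mann_whitney(x, y), mann_whitney(y, x)
        assert a.statistic == b.statistic and a.p_value == b.p_value

    def test_large_shift_detected(self, rng):
        x = rng.standard_normal(500)
        y = rng.standard_normal(500) + 10.0
        assert mann_whitney(x, y).p_value < 1e-6

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSplitChisq:
    def test_identical_counts_give_zero_statistic(self):
        tbl = SplitTable(
            ["s1", "s2"], np.array([60.0, 40.0]), np.array([60.0, 40.0]), 100, 100
        )
        res = split_chisq(tbl)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_disjoint_split_usage_rejected_strongly(self):
        tbl = SplitTable(
            ["A", "B"], np.array([100.0, 0.0]), np.array([0.0, 100.0]), 100, 100
        )
        res = split_chisq(tbl)
        assert res.statistic > 50 and res.p_value < 1e-10

    def test_invariant_to_split_order(self):
        c1, c2 = np.array([50.0, 30.0, 70.0]), np.array([45.0, 40.0, 60.0])
        a = split_chisq(SplitTable(["x", "y", "z"], c1, c2, 100, 100))
        perm = [2, 0, 1]
        b = split_chisq(
            SplitTable(
                [["x", "y", "z"][i] for i in perm], c1[perm], c2[perm], 100, 100
            )
        )
        assert a.statistic == pytest.approx(b.statistic)

    def test_rare_splits_pooled_into_other(self):
        # second split expected count 1 < 5 -> pooled; still >= 2 categories
        tbl = SplitTable(
            ["s1", "s2", "s3"],
            np.array([90.0, 1.0, 50.0]),
            np.array([88.0, 1.0, 55.0]),
            100,
            100,
        )
        res = split_chisq(tbl)
        assert math.isfinite(res.statistic) and 0 <= res.p_value <= 1

    def test_single_category_not_applicable(self):
        tbl = SplitTable(["s1"], np.array([90.0]), np.array([88.0]), 100, 100)
        with pytest.raises(ValueError, match="not applicable"):
            split_chisq(tbl)

    def test_identical_tree_traces_give_zero(self):
        trace = gen_tree_trace(TreeTraceSpec([T_A, T_B], [0.7, 0.3], 100, seed=5))
        res = split_chisq(build_split_table(trace, trace))
        assert res.statistic == 0.0

    def test_build_split_table_counts(self):
        tbl = build_split_table([T_A, T_A, T_B], [T_B])
        idx = {frozenset(s): i for i, s in enumerate(tbl.splits)}
        assert tbl.n1 == 3 and tbl.n2 == 1
        # shared split de|abc present in every tree of both chains
        assert tbl.counts1[idx[frozenset({"d", "e"})]] == 3
        assert tbl.counts2[idx[frozenset({"d", "e"})]] == 1
        assert tbl.counts1[idx[frozenset({"c", "d", "e"})]] == 2  # ab cherry in T_A


class TestCombineChains:
    def _tables(self):
        t1 = make_trace_table(
            [gen_ar1(Ar1Spec(n=10, rho=0.0, seed=1, name="x"))],
            {"tree": gen_tree_trace(TreeTraceSpec([T_A, T_B], [0.5, 0.5], 10, seed=2))},
        )
        t2 = make_trace_table(
            [gen_ar1(Ar1Spec(n=8, rho=0.0, mu=5.0, seed=3, name="x"))],
            {"tree": gen_tree_trace(TreeTraceSpec([T_A, T_C], [0.5, 0.5], 8, seed=4))},
        )
        return t1, t2

    def test_joint_length(self):
        t1, t2 = self._tables()
        joint = combine_chains(t1, t2, 2, 3)
        assert joint.n_samples == 13
        assert len(joint.tree_data["tree"]) == 13

    def test_zero_burnins_concatenate(self):
        t1, t2 = self._tables()
        assert combine_chains(t1, t2).n_samples == 18

    def test_joint_mean_is_weighted_mean(self):
        t1, t2 = self._tables()
        joint = combine_chains(t1, t2, 2, 3)
        m = summarize(joint.numeric_data["x"]).mean
        x1 = t1.numeric_data["x"].values[2:]
        x2 = t2.numeric_data["x"].values[3:]
        expected = (x1.sum() + x2.sum()) / (len(x1) + len(x2))
        assert m == pytest.approx(expected)

    def test_combined_posterior_is_countwise_sum(self):
        t1, t2 = self._tables()
        joint = combine_chains(t1, t2, 2, 3)
        post = topology_frequencies(joint.tree_data["tree"])
        c1 = topology_frequencies(t1.tree_data["tree"], 2)
        c2 = topology_frequencies(t2.tree_data["tree"], 3)
        counts = {}
        for p in (c1, c2):
            for e in p.entries:
                counts[e.key] = counts.get(e.key, 0) + e.count
        assert {e.key: e.count for e in post.entries} == counts

    def test_column_mismatch_rejected(self):
        t1, _ = self._tables()
        t3 = make_trace_table([gen_ar1(Ar1Spec(n=10, seed=1, name="y"))])
        with pytest.raises(ValueError):
            combine_chains(t1, t3)
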