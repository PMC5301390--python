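"""Two-chain comparison: Mann-Whitney U, split chi-square, concatenation.

Two independent chains run on the same data should sample the same
posterior.  Numeric parameters are compared with a two-sided
Mann-Whitney U test; tree samples are compared through their split
(bipartition) frequencies with a two-sample chi-square homogeneity test.

The split test treats per-split presence counts as categorical counts.
Splits within one tree are correlated, so the test is approximate — its
type-I error is calibrated, not exact (see the test suite); the same
caveat applies to any split-frequency comparison between chains.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .summary_stats import NumericSeries, _as_array
from .trace_io import TraceTable
from .tree_posterior import TopologyKey, _keys_for

__all__ = [
    "TwoSampleResult",
    "SplitTable",
    "Method",
    "mann_whitney",
    "split_chisq",
    "build_split_table",
    "combine_chains",
]


class Method(str, Enum):
    MANN_WHITNEY_U = "mann_whitney_u"
    CHISQ_SPLITS = "chisq_splits"


@dataclass
class TwoSampleResult:
    statistic: float
    p_value: float
    method: Method
    n1: int
    n2: int


def mann_whitney(
    x: "NumericSeries | Sequence[float]", y: "NumericSeries | Sequence[float]"
) -> TwoSampleResult:
    """Two-sided Mann-Whitney U test with midranks and tie correction.

    The reported statistic is min(U_x, U_y).  Small samples
    (n1*n2 < 20, no ties) use the exact rank-permutation distribution;
    otherwise the normal approximation with continuity correction.
    """
    a, b = _as_array(x), _as_array(y)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < n1 + n2
    method = "exact" if (n1 * n2 < 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    u_x = float(res.statistic)
    u = min(u_x, n1 * n2 - u_x)
    return TwoSampleResult(
        statistic=u,
        p_value=float(min(res.pvalue, 1.0)),
        method=Method.MANN_WHITNEY_U,
        n1=n1,
        n2=n2,
    )


@dataclass
class SplitTable:
    """Per-split presence counts among the post-burn-in trees of each chain."""

    splits: list  # canonical split sides (frozensets) or the string "other"
    counts1: np.ndarray
    counts2: np.ndarray
    n1: int
    n2: int


def build_split_table(
    trees1: Sequence[str], trees2: Sequence[str], burnin1: int = 0, burnin2: int = 0
) -> SplitTable:
    """Tabulate split presence counts from two ordered Newick sample lists."""

    def count(trees: Sequence[str]) -> dict:
        out: dict = {}
        for key in _keys_for(list(trees)):
            for s in key.splits:
                out[s] = out.get(s, 0) + 1
        return out

    t1, t2 = list(trees1[burnin1:]), list(trees2[burnin2:])
    if not t1 or not t2:
        raise ValueError("empty post-burn-in tree sample")
    c1, c2 = count(t1), count(t2)
    splits = sorted(set(c1) | set(c2), key=lambda s: (len(s), sorted(s)))
    return SplitTable(
        splits=list(splits),
        counts1=np.array([c1.get(s, 0) for s in splits], dtype=float),
        counts2=np.array([c2.get(s, 0) for s in splits], dtype=float),
        n1=len(t1),
        n2=len(t2),
    )


def split_chisq(table: SplitTable, min_expected: float = 5.0) -> TwoSampleResult:
    """Two-sample chi-square homogeneity test on split presence counts.

    Expected counts come from the pooled split proportions; splits whose
    smaller expected count falls below ``min_expected`` are pooled into a
    single "other" category (standard validity rule).  Degrees of
    freedom = number of categories - 1.
    """
    n1, n2 = table.n1, table.n2
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both chains must contain trees")
    c1 = np.asarray(table.counts1, dtype=float)
    c2 = np.asarray(table.counts2, dtype=float)
    if len(c1) != len(c2) or len(c1) != len(table.splits):
        raise ValueError("ragged split table")
    p_pool = (c1 + c2) / (n1 + n2)
    e_min = np.minimum(n1 * p_pool, n2 * p_pool)
    keep = e_min >= min_expected
    splits: list = [s for s, k in zip(table.splits, keep) if k]
    o1 = list(c1[keep])
    o2 = list(c2[keep])
    if not np.all(keep):
        splits.append("other")
        o1.append(float(c1[~keep].sum()))
        o2.append(float(c2[~keep].sum()))
    o1a, o2a = np.array(o1), np.array(o2)
    pos = (o1a + o2a) > 0
    o1a, o2a = o1a[pos], o2a[pos]
    k = len(o1a)
    if k < 2:
        raise ValueError("test not applicable: fewer than 2 split categories")
    p_pool = (o1a + o2a) / (n1 + n2)
    e1, e2 = n1 * p_pool, n2 * p_pool
    stat = float(np.sum((o1a - e1) ** 2 / e1) + np.sum((o2a - e2) ** 2 / e2))
    df = k - 1
    p = float(stats.chi2.sf(stat, df))
    return TwoSampleResult(
        statistic=stat, p_value=p, method=Method.CHISQ_SPLITS, n1=n1, n2=n2
    )


def combine_chains(
    t1: TraceTable, t2: TraceTable, burnin1: int = 0, burnin2: int = 0
) -> TraceTable:
    """Append two chains after removing per-chain burn-ins.

    Requires identical column names and kinds.  The generation column is
    dropped (a concatenated iteration counter would not be increasing).
    """
    if t1.columns != t2.columns:
        raise ValueError("chains have mismatched columns")
    if not (0 <= burnin1 < t1.n_samples and 0 <= burnin2 < t2.n_samples):
        raise ValueError("burn-in out of range")
    numeric = {
        name: NumericSeries(
            np.concatenate(
                [t1.numeric_data[name].values[burnin1:], t2.numeric_data[name].values[burnin2:]]
            ),
            name,
        )
        for name in t1.numeric_data
    }
    trees = {
        name: t1.tree_data[name][burnin1:] + t2.tree_data[name][burnin2:]
        for name in t1.tree_data
    }
    return replace(
        t1,
        source_path=f"{t1.source_path}+{t2.source_path}",
        n_samples=(t1.n_samples - burnin1) + (t2.n_samples - burnin2),
        numeric_data=numeric,
        tree_data=trees,
        generation=None,
    )
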