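"""Synthetic MCMC traces with known statistical structure.

Numeric parameters are simulated as stationary AR(1) processes — the
simplest model with the tunable autocorrelation that drives ESS and
burn-in behaviour — optionally with a mean-shifted prefix to emulate a
chain that starts far from the stationary distribution.  Tree parameters
are iid draws from a specified topology distribution, which is
sufficient for frequency, consensus and distance-matrix analysis but
does not emulate the serial correlation of a real tree chain.

Writers cover every supported trace dialect and are exact inverses of
:func:`phylotrace.trace_io.parse_trace` on supported content.  All
generators are pure functions of their spec (seed included); there is no
global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from scipy.signal import lfilter

from .summary_stats import NumericSeries
from .trace_io import TraceTable
from .tree_posterior import topology_key

__all__ = [
    "Ar1Spec",
    "TreeTraceSpec",
    "gen_ar1",
    "gen_tree_trace",
    "make_trace_table",
    "write_trace",
]


@dataclass
class Ar1Spec:
    """Stationary AR(1): x_t = mu + rho*(x_{t-1} - mu) + sigma*eps_t.

    ``shift`` = (prefix_fraction, offset) adds ``offset`` to the first
    ``prefix_fraction * n`` samples, emulating an unconverged prefix.
    """

    n: int
    rho: float = 0.0
    mu: float = 0.0
    sigma: float = 1.0
    shift: tuple[float, float] | None = None
    seed: int = 0
    name: str = "x"

    def validate(self) -> None:
        if not (-1.0 < self.rho < 1.0):
            raise ValueError(f"AR(1) requires |rho| < 1, got {self.rho}")
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.shift is not None and not (0.0 <= self.shift[0] < 1.0):
            raise ValueError("prefix_fraction must be in [0, 1)")


@dataclass
class TreeTraceSpec:
    """iid topology draws with fixed probabilities."""

    topologies: list[str]
    probabilities: list[float]
    n: int
    seed: int = 0
    name: str = "tree"

    def validate(self) -> None:
        if len(self.topologies) != len(self.probabilities):
            raise ValueError("topologies and probabilities differ in length")
        if abs(sum(self.probabilities) - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")
        keys = [topology_key(t) for t in self.topologies]
        if len(set(keys)) != len(keys):
            raise ValueError("topologies must have pairwise distinct keys")


def gen_ar1(spec: Ar1Spec) -> NumericSeries:
    """Simulate a stationary AR(1) series, reproducible from the seed.

    The first sample is drawn from the stationary distribution
    N(mu, sigma^2 / (1 - rho^2)).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    e = rng.standard_normal(spec.n) * spec.sigma
    e[0] = rng.standard_normal() * spec.sigma / math.sqrt(1.0 - spec.rho**2)
    x = lfilter([1.0], [1.0, -spec.rho], e) + spec.mu
    if spec.shift is not None:
        frac, offset = spec.shift
        x[: int(frac * spec.n)] += offset
    return NumericSeries(x, spec.name)


def gen_tree_trace(spec: TreeTraceSpec) -> list[str]:
    """Draw an ordered Newick sample list, reproducible from the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(len(spec.topologies), size=spec.n, p=spec.probabilities)
    return [spec.topologies[i] for i in idx]


def make_trace_table(
    numeric: Sequence[NumericSeries] = (),
    trees: "dict[str, list[str]] | None" = None,
    generation_step: int = 1,
    source: str = "<synthetic>",
) -> TraceTable:
    """Assemble generated columns into a TraceTable (with a Gen column)."""
    trees = trees or {}
    lengths = [len(s) for s in numeric] + [len(v) for v in trees.values()]
    if not lengths or len(set(lengths)) != 1:
        raise ValueError("columns must be non-empty and length-matched")
    n = lengths[0]
    columns: list[tuple[str, str]] = [(s.name, "numeric") for s in numeric]
    columns += [(name, "tree") for name in trees]
    return TraceTable(
        source_path=source,
        n_samples=n,
        columns=columns,  # type: ignore[arg-type]
        numeric_data={s.name: s for s in numeric},
        tree_data=dict(trees),
        generation=np.arange(n) * generation_step,
    )


def _format_value(v: float) -> str:
    if math.isnan(v):
        return "NA"
    return repr(float(v))  # shortest round-trip representation


def write_trace(table: TraceTable, path: str, dialect: str = "tabular") -> None:
    """Write a trace file that ``parse_trace`` reads back value-identically.

    ``tabular`` writes a Gen column plus every column tab-separated at
    full float precision; ``nexus_trees`` requires exactly one tree
    column (and no numeric columns) and writes a trees block with a
    Translate table.
    """
    if dialect == "tabular":
        gen = (
            table.generation
            if table.generation is not None
            else np.arange(table.n_samples)
        )
        names = [n for n, _ in table.columns]
        lines = ["\t".join(["Gen"] + names)]
        for i in range(table.n_samples):
            row = [str(int(gen[i]))]
            for name, kind in table.columns:
                if kind == "numeric":
                    row.append(_format_value(table.numeric_data[name].values[i]))
                elif kind == "tree":
                    row.append(table.tree_data[name][i].strip())
                else:
                    raise ValueError(f"cannot write column of kind {kind!r}")
            lines.append("\t".join(row))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
    elif dialect == "nexus_trees":
        if len(table.tree_names()) != 1 or table.numeric_names():
            raise ValueError("nexus_trees dialect requires exactly one tree column")
        newicks = table.tree_data[table.tree_names()[0]]
        taxa = sorted(topology_key(newicks[0]).leaves)
        index = {lb: str(i + 1) for i, lb in enumerate(taxa)}
        lines = ["#NEXUS", "", "Begin trees;", "\tTranslate"]
        for i, lb in enumerate(taxa):
            sep = "," if i < len(taxa) - 1 else ";"
            lines.append(f"\t\t{i + 1} {lb}{sep}")
        for i, nw in enumerate(newicks):
            t = dendropy.Tree.get(data=nw, schema="newick")
            for leaf in t.leaf_node_iter():
                leaf.taxon.label = index[leaf.taxon.label]
            s = t.as_string(
                schema="newick", suppress_rooting=True, unquoted_underscores=True
            ).strip()
            gen = (
                int(table.generation[i]) if table.generation is not None else i
            )
            lines.append(f"tree STATE_{gen} = {s}")
        lines += ["End;", ""]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
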