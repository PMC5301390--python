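"""Tree-posterior summarisation: topology identity, frequencies, consensus.

Topology identity is **unrooted** and branch-length-free: a topology is
identified by its set of non-trivial leaf bipartitions (splits).  Each
split is canonicalised as the side *not* containing the lexicographically
smallest leaf label, so rooted inputs, node rotations and alternative
root placements all map to the same key.  Rooted data whose clade
structure matters would need a rooted (clade-based) mode, which this
module deliberately does not provide: unrooted identity matches the
unweighted Robinson-Foulds metric used for tree-space analysis.

The weighted majority-rule consensus retains exactly the splits whose
weighted frequency is strictly greater than 0.5; such splits are always
pairwise compatible, so the consensus assembles without greedy
tie-breaking, and regions without majority support appear as polytomies.
Supports are the weighted split frequencies, computed only from the
selected trees and their weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "TopologyKey",
    "TreePosterior",
    "PosteriorEntry",
    "ConsensusTree",
    "parse_newick",
    "strip_branch_lengths",
    "topology_key",
    "topology_frequencies",
    "majority_consensus",
    "mark_occurrences",
]


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string (must end in ``;``; quoted labels supported)."""
    t = text.strip()
    if not t.endswith(";"):
        raise ValueError(f"Newick string must end with ';' (got {t[-20:]!r})")
    try:
        return dendropy.Tree.get(data=t, schema="newick")
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc


def strip_branch_lengths(newick: str) -> str:
    """Serialise a Newick string without branch lengths or internal labels."""
    tree = parse_newick(newick)
    return tree.as_string(
        schema="newick",
        suppress_edge_lengths=True,
        suppress_rooting=True,
        suppress_internal_node_labels=True,
        unquoted_underscores=True,
    ).strip()


@dataclass(frozen=True)
class TopologyKey:
    """Canonical identity of an unrooted topology.

    ``splits`` holds every non-trivial bipartition, each represented by
    the side excluding the lexicographically smallest leaf label.  Equal
    keys are equivalent to Robinson-Foulds distance zero.
    """

    leaves: frozenset
    splits: frozenset

    def serialize(self) -> str:
        parts = sorted(
            ("|".join(sorted(s)) for s in self.splits), key=lambda p: (p.count("|"), p)
        )
        return "{" + ",".join(sorted(self.leaves)) + "}" + ";".join(parts)

    def __repr__(self) -> str:  # compact, deterministic
        return f"TopologyKey({self.serialize()})"


def _leaf_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label is not None:
        return node.taxon.label
    if node.label is not None:
        return node.label
    raise ValueError("leaf without a label")


def topology_key(tree: "dendropy.Tree | str") -> TopologyKey:
    """Canonical unrooted topology key of a tree (Newick string or tree).

    Branch lengths are ignored; a degree-2 root is implicitly suppressed
    because its two child bipartitions canonicalise identically.
    """
    if isinstance(tree, str):
        tree = parse_newick(tree)
    leafsets: dict[dendropy.Node, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = frozenset([_leaf_label(node)])
        else:
            s: set = set()
            for ch in node.child_nodes():
                s |= leafsets[ch]
            leafsets[node] = frozenset(s)
    all_leaves = leafsets[tree.seed_node]
    n = len(all_leaves)
    if n < 3:
        raise ValueError(f"topology_key requires >= 3 leaves, got {n}")
    if len({lb for lb in all_leaves}) != n:
        raise ValueError("duplicate leaf labels")
    ref = min(all_leaves)
    splits = set()
    for node, side in leafsets.items():
        if node is tree.seed_node or node.is_leaf():
            continue
        if ref in side:
            side = all_leaves - side
        if 1 < len(side) < n - 1:
            splits.add(side)
    return TopologyKey(leaves=all_leaves, splits=frozenset(splits))


@dataclass
class PosteriorEntry:
    key: TopologyKey
    exemplar_newick: str
    count: int
    probability: float


@dataclass
class TreePosterior:
    """Unique topologies with counts and probabilities, sorted descending
    by probability (ties by first occurrence in the trace)."""

    entries: list[PosteriorEntry]
    n_total: int

    def __len__(self) -> int:
        return len(self.entries)


def _keys_for(trees: Sequence[str]) -> list[TopologyKey]:
    """Topology key per sample, caching by raw Newick string."""
    cache: dict[str, TopologyKey] = {}
    out = []
    for nw in trees:
        k = cache.get(nw)
        if k is None:
            k = topology_key(nw)
            cache[nw] = k
        out.append(k)
    return out


def topology_frequencies(trees: Sequence[str], burnin: int = 0) -> TreePosterior:
    """Tabulate the tree posterior from an ordered Newick sample list.

    Counts are over samples ``[burnin:]``; the exemplar Newick of each
    topology is its first post-burn-in occurrence with branch lengths
    stripped.
    """
    if burnin < 0 or burnin >= len(trees):
        raise ValueError(f"burnin {burnin} out of range for {len(trees)} samples")
    post = trees[burnin:]
    keys = _keys_for(post)
    counts: dict[TopologyKey, int] = {}
    first: dict[TopologyKey, int] = {}
    for i, k in enumerate(keys):
        if k not in counts:
            counts[k] = 0
            first[k] = i
        counts[k] += 1
    n_total = len(post)
    order = sorted(counts, key=lambda k: (-counts[k], first[k]))
    entries = [
        PosteriorEntry(
            key=k,
            exemplar_newick=strip_branch_lengths(post[first[k]]),
            count=counts[k],
            probability=counts[k] / n_total,
        )
        for k in order
    ]
    return TreePosterior(entries=entries, n_total=n_total)


@dataclass
class ConsensusTree:
    """Majority-rule consensus: Newick with supports as internal labels,
    plus the support of every retained split."""

    newick: str
    supports: dict  # frozenset (canonical split side) -> weighted frequency
    leaves: frozenset


def _compatible(a: frozenset, b: frozenset) -> bool:
    # both sides exclude the reference leaf, so compatibility on the
    # unrooted tree reduces to nested-or-disjoint
    return a.isdisjoint(b) or a <= b or b <= a


def majority_consensus(
    selection: Iterable[tuple[TopologyKey, float]],
) -> ConsensusTree:
    """Weighted majority-rule consensus of selected topologies.

    Weights must be positive and are renormalised to sum to 1.  A split
    is retained iff its weighted frequency exceeds 0.5 strictly; splits
    at exactly 0.5 are dropped (guaranteeing pairwise compatibility).
    """
    selection = list(selection)
    if not selection:
        raise ValueError("empty selection")
    total = sum(w for _, w in selection)
    if total <= 0 or any(w <= 0 for _, w in selection):
        raise ValueError("weights must be positive")
    leaves = selection[0][0].leaves
    if any(k.leaves != leaves for k, _ in selection):
        raise ValueError("selected topologies have differing leaf sets")

    freq: dict[frozenset, float] = {}
    for key, w in selection:
        for s in key.splits:
            freq[s] = freq.get(s, 0.0) + w / total
    retained = {s: f for s, f in freq.items() if f > 0.5}

    # splits already exclude the smallest leaf, so they nest as clades of
    # the tree rooted on that leaf's pendant edge
    clades = sorted(retained, key=lambda s: (-len(s), sorted(s)))
    children: dict[object, list] = {None: []}
    parent_of_leaf: dict[str, object] = {}
    for i, c in enumerate(clades):
        par = None
        for j in range(i - 1, -1, -1):
            if c <= clades[j]:
                par = clades[j]
                break
            if not c.isdisjoint(clades[j]):
                raise ValueError("retained splits are not pairwise compatible")
        children.setdefault(c, [])
        children[par].append(c)
    for lf in sorted(leaves):
        host = None
        for c in sorted(clades, key=len):
            if lf in c:
                host = c
                break
        parent_of_leaf[lf] = host
        children.setdefault(host, []).append(lf)

    def render_children(node) -> list[str]:
        out = []
        for k in children.get(node, []):
            if isinstance(k, str):
                out.append(k)
            else:
                out.append(f"({','.join(render_children(k))}){retained[k]:g}")
        return out

    newick = f"({','.join(render_children(None))});"
    return ConsensusTree(newick=newick, supports=retained, leaves=leaves)


def mark_occurrences(
    trees: Sequence[str], selected: Iterable[TopologyKey]
) -> Mapping[TopologyKey, list[int]]:
    """0-based sample indices at which each selected topology occurs.

    Topologies absent from the trace map to empty lists.
    """
    selected = list(selected)
    keys = _keys_for(trees)
    out: dict[TopologyKey, list[int]] = {k: [] for k in selected}
    sel = set(selected)
    for i, k in enumerate(keys):
        if k in sel:
            out[k].append(i)
    return out
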