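"""Tree-space analysis: Robinson-Foulds distances and 2-D MDS embedding.

The unweighted Robinson-Foulds (RF) distance between two unrooted trees
on the same leaf set is the size of the symmetric difference of their
non-trivial bipartition sets.  For fully resolved (binary) trees it is
always even and bounded by 2*(L-3).

Because the pairwise matrix is quadratic in the number of unique
topologies, the matrix is restricted to topologies whose posterior
probability is at least 0.2% by default; when more than 45 topologies
pass the filter a warning is emitted (computation still proceeds — the
warning only flags an expected delay).

The embedding is classical (Torgerson) multidimensional scaling: double
centring B = -1/2 * J D^2 J, top-2 eigenpairs, negative eigenvalues
clamped to zero.  Eigenvector sign indeterminacy is resolved by making
the first nonzero coordinate of each axis positive, so embeddings are
reproducible; distances are only meaningful up to rotation/reflection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .tree_posterior import TopologyKey, TreePosterior, topology_key

__all__ = [
    "DistanceMatrix",
    "Embedding2D",
    "TreeSpaceSizeWarning",
    "rf_distance",
    "rf_matrix",
    "mds_2d",
    "FILTER_THRESHOLD_DEFAULT",
    "WARN_LIMIT_DEFAULT",
]

#: topologies below this posterior probability are excluded from the matrix
FILTER_THRESHOLD_DEFAULT = 0.002
#: emit a warning when more unique topologies than this pass the filter
WARN_LIMIT_DEFAULT = 45


class TreeSpaceSizeWarning(UserWarning):
    """More unique frequent topologies than expected; computation may be slow."""


def _as_key(t: "dendropy.Tree | TopologyKey | str") -> TopologyKey:
    if isinstance(t, TopologyKey):
        return t
    return topology_key(t)


def rf_distance(
    t1: "dendropy.Tree | TopologyKey | str",
    t2: "dendropy.Tree | TopologyKey | str",
) -> int:
    """Unweighted Robinson-Foulds distance between two trees.

    Accepts Newick strings, dendropy trees, or precomputed topology keys.
    The leaf sets must be identical.
    """
    k1, k2 = _as_key(t1), _as_key(t2)
    if k1.leaves != k2.leaves:
        raise ValueError("trees have different leaf sets")
    return len(k1.splits ^ k2.splits)


@dataclass
class DistanceMatrix:
    """Pairwise RF distances among the frequent unique topologies."""

    keys: list[TopologyKey]
    d: np.ndarray  # symmetric, zero diagonal, integer-valued
    probabilities: list[float]
    filter_threshold: float = FILTER_THRESHOLD_DEFAULT
    warn_limit: int = WARN_LIMIT_DEFAULT

    def to_tsv(self) -> str:
        lines = ["\t".join(str(int(v)) for v in row) for row in self.d]
        return "\n".join(lines) + "\n"


def rf_matrix(
    posterior: TreePosterior,
    threshold: float = FILTER_THRESHOLD_DEFAULT,
    warn_limit: int = WARN_LIMIT_DEFAULT,
) -> DistanceMatrix:
    """RF distance matrix over topologies with probability >= ``threshold``.

    Raises if the filter removes every topology; warns (but computes)
    when more than ``warn_limit`` topologies qualify.
    """
    entries = [e for e in posterior.entries if e.probability >= threshold]
    if not entries:
        raise ValueError(
            f"no topologies with posterior probability >= {threshold}"
        )
    if len(entries) > warn_limit:
        warnings.warn(
            f"{len(entries)} unique topologies above probability {threshold}; "
            "expect a delay computing the distance matrix",
            TreeSpaceSizeWarning,
            stacklevel=2,
        )
    k = len(entries)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = len(entries[i].key.splits ^ entries[j].key.splits)
    return DistanceMatrix(
        keys=[e.key for e in entries],
        d=d,
        probabilities=[e.probability for e in entries],
        filter_threshold=threshold,
        warn_limit=warn_limit,
    )


@dataclass
class Embedding2D:
    """2-D coordinates per topology; probability sets the plot point size.

    Classical-MDS centring places the centroid at the origin.
    """

    coords: np.ndarray  # shape (k, 2)
    probabilities: list[float] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [
            {
                "topology_index": i,
                "x": float(x),
                "y": float(y),
                "probability": float(p) if self.probabilities else None,
            }
            for i, ((x, y), p) in enumerate(
                zip(self.coords, self.probabilities or [0.0] * len(self.coords))
            )
        ]


def mds_2d(dm: "DistanceMatrix | np.ndarray") -> Embedding2D:
    """Classical (Torgerson) MDS embedding of a distance matrix into 2-D.

    Exact for distances that are 2-D Euclidean; negative eigenvalues are
    clamped to zero.  A single point maps to the origin.
    """
    if isinstance(dm, DistanceMatrix):
        d = np.asarray(dm.d, dtype=float)
        probs = dm.probabilities
    else:
        d = np.asarray(dm, dtype=float)
        probs = []
    k = d.shape[0]
    if k == 1:
        return Embedding2D(coords=np.zeros((1, 2)), probabilities=probs)
    j = np.eye(k) - np.ones((k, k)) / k
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1][:2]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    # deterministic sign: first nonzero coordinate of each axis positive
    for axis in range(2):
        col = coords[:, axis]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return Embedding2D(coords=coords, probabilities=probs)


def scatter_plot(embedding: Embedding2D, path: str, scale: float = 2000.0) -> None:
    """Write a static scatter plot, point sizes proportional to probability."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sizes = (
        np.asarray(embedding.probabilities) * scale
        if embedding.probabilities
        else 40.0
    )
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(embedding.coords[:, 0], embedding.coords[:, 1], s=sizes, alpha=0.6)
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
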