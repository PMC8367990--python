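"""Network construction: global and local (k-NNG) thresholding of connectomes.

Both constructions are parameterised by *edge density* (network cost),
``2T/(N^2 - N) x 100%`` where ``T`` is the number of undirected edges kept and
``N`` the node count.  The global threshold keeps the ``T`` strongest edges of
the whole matrix; the local threshold guarantees every node keeps its ``k``
strongest neighbours (the union k-nearest-neighbour graph) and augments with
the next ring of neighbour candidates until the same ``T`` is reached, which
favours modular segregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "WeightedConnectome",
    "BinaryNetwork",
    "WeightedThresholdedNetwork",
    "DensityTooLowError",
    "edge_density",
    "global_threshold",
    "local_threshold",
    "weighted_mask",
    "added_edge_classes",
]

_SYM_TOL = 1e-9


class DensityTooLowError(ValueError):
    """Requested density sits below the 1-NNG floor of the local threshold."""

    def __init__(self, requested: float, minimum: float):
        self.requested = float(requested)
        self.minimum = float(minimum)
        super().__init__(
            f"requested density {requested:.4g}% is below the 1-NNG floor "
            f"({minimum:.4g}%); the local threshold cannot go sparser"
        )


@dataclass
class WeightedConnectome:
    """One participant's symmetric |r| connectivity matrix.

    Parameters
    ----------
    weights
        Square symmetric matrix of absolute correlation weights in [0, 1]
        with zero diagonal.
    node_labels
        Node names; defaults to stringified indices.
    coordinates
        Optional (N, 3) node positions in mm, used for distance analyses.
    """

    weights: np.ndarray
    node_labels: Optional[Sequence[str]] = None
    coordinates: Optional[np.ndarray] = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=_SYM_TOL):
            raise ValueError("weights must be symmetric")
        if np.abs(np.diag(w)).max(initial=0.0) > _SYM_TOL:
            raise ValueError("weights must have a zero diagonal")
        if w.min(initial=0.0) < -_SYM_TOL or w.max(initial=0.0) > 1 + 1e-6:
            raise ValueError("weights must lie in [0, 1] (absolute correlations)")
        w = np.clip((w + w.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.node_labels is None:
            self.node_labels = [str(i) for i in range(w.shape[0])]
        elif len(self.node_labels) != w.shape[0]:
            raise ValueError("node_labels length must match matrix size")
        if self.coordinates is not None:
            c = np.asarray(self.coordinates, dtype=float)
            if c.shape != (w.shape[0], 3):
                raise ValueError("coordinates must be (n_nodes, 3)")
            self.coordinates = c

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class BinaryNetwork:
    """Thresholded 0/1 adjacency with its construction provenance."""

    adjacency: np.ndarray
    method: str  # "global" | "local"
    requested_density: float  # percent
    realized_density: float = field(init=False)
    threshold_tau: Optional[float] = None  # global cutoff weight
    k_base: Optional[int] = None  # base k-NNG order for the local method

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        _check_binary_adjacency(a)
        self.adjacency = a.astype(np.uint8)
        self.realized_density = edge_density(self.adjacency)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_set(self) -> set:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return set(zip(i.tolist(), j.tolist()))


@dataclass
class WeightedThresholdedNetwork:
    """Hadamard product of a binary adjacency and its source weighted matrix."""

    weights: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def _check_binary_adjacency(a: np.ndarray) -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("adjacency must be 0/1")


def edge_density(adjacency: np.ndarray) -> float:
    """Edge density (network cost) in percent: ``2T/(N^2 - N) x 100``."""
    a = np.asarray(adjacency)
    _check_binary_adjacency(a)
    n = a.shape[0]
    t = int(a.sum()) // 2
    return 2.0 * t / (n * n - n) * 100.0


def _target_edge_count(n: int, density: float) -> int:
    if not (0.0 < density <= 100.0):
        raise ValueError(f"density must be in (0, 100], got {density}")
    return math.floor(density * (n * n - n) / 200.0)


def _sorted_edges(weights: np.ndarray):
    """Positive off-diagonal pairs (i<j) ordered by weight desc, then (i, j) asc."""
    iu, ju = np.triu_indices(weights.shape[0], k=1)
    w = weights[iu, ju]
    keep = w > 0.0
    iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order], w[order]


def global_threshold(connectome: WeightedConnectome, density: float) -> BinaryNetwork:
    """Keep the strongest edges of the whole matrix at the requested cost.

    Retains the ``floor(density * (N^2 - N) / 200)`` strongest undirected
    edges; ties are broken deterministically by ascending node-index pair.
    Exact-zero weights never become edges, even at 100% density.
    """
    n = connectome.n_nodes
    t = _target_edge_count(n, density)
    iu, ju, w = _sorted_edges(connectome.weights)
    t = min(t, len(w))
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[:t], ju[:t]] = 1
    adj |= adj.T
    tau = float(w[t - 1]) if t > 0 else None
    return BinaryNetwork(adj, "global", float(density), threshold_tau=tau)


def _knng_edges(weights: np.ndarray, k: int) -> set:
    """Union k-NNG: edge (i, j) kept if either endpoint ranks the other top-k.

    Neighbour rank is by descending weight, ties by ascending neighbour index;
    zero-weight pairs are never neighbours.
    """
    n = weights.shape[0]
    edges: set = set()
    for i in range(n):
        w = weights[i]
        nbr = np.nonzero(w > 0.0)[0]
        if nbr.size == 0:
            continue
        order = np.lexsort((nbr, -w[nbr]))
        for j in nbr[order][:k]:
            edges.add((min(i, int(j)), max(i, int(j))))
    return edges


def local_threshold(connectome: WeightedConnectome, density: float) -> BinaryNetwork:
    """k-nearest-neighbour-graph construction at the requested edge density.

    Finds the largest ``k`` whose union k-NNG does not exceed the target edge
    count (``k_base``), then augments with candidate edges from the
    (k_base+1)-NNG in descending weight order until the target is met.  The
    result therefore always contains the 1-NNG, so every node with at least
    one positive weight keeps its strongest neighbour.

    Raises
    ------
    DensityTooLowError
        If the requested density is below the density of the 1-NNG, which is
        the sparsest network this construction can produce.
    """
    n = connectome.n_nodes
    t = _target_edge_count(n, density)
    w = connectome.weights

    base = _knng_edges(w, 1)
    if len(base) > t:
        raise DensityTooLowError(density, 2.0 * len(base) / (n * n - n) * 100.0)

    n_positive = int(np.count_nonzero(np.triu(w, 1) > 0.0))
    k_base = 1
    edges = base
    while k_base < n:
        nxt = _knng_edges(w, k_base + 1)
        if len(nxt) > t:
            break
        k_base += 1
        edges = nxt
        if len(edges) == n_positive:  # k-NNG saturated: no more positive edges
            break

    if len(edges) < t:
        candidates = sorted(
            _knng_edges(w, k_base + 1) - edges,
            key=lambda e: (-w[e[0], e[1]], e[0], e[1]),
        )
        edges = set(edges)
        for e in candidates:
            if len(edges) >= t:
                break
            edges.add(e)

    adj = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryNetwork(adj, "local", float(density), k_base=k_base)


def weighted_mask(
    connectome: WeightedConnectome, binary: BinaryNetwork
) -> WeightedThresholdedNetwork:
    """Hadamard product of the binary adjacency and the weighted matrix."""
    if binary.adjacency.shape != connectome.weights.shape:
        raise ValueError("connectome and binary network shapes differ")
    masked = connectome.weights * binary.adjacency
    return WeightedThresholdedNetwork(
        masked,
        provenance={
            "method": binary.method,
            "requested_density": binary.requested_density,
            "realized_density": binary.realized_density,
        },
    )


def added_edge_classes(local_net: BinaryNetwork, global_net: BinaryNetwork, partition) -> dict:
    """Classify the symmetric-difference edges of the two constructions.

    Edges present only in the local network were *added by local thresholding*
    (typically weaker, intra-modular, nearest-neighbour links); edges present
    only in the global network were kept for raw strength.  Each is counted as
    intra- or inter-modular under ``partition``.
    """
    n = local_net.adjacency.shape[0]
    one_edge_pct = 2.0 / (n * n - n) * 100.0
    if abs(local_net.realized_density - global_net.realized_density) > one_edge_pct:
        raise ValueError(
            "networks must have matching densities (within one-edge resolution)"
        )
    labels = np.asarray(partition.labels)
    loc, glo = local_net.edge_set(), global_net.edge_set()
    counts = {
        "intra_added_by_local": 0,
        "inter_added_by_local": 0,
        "intra_only_global": 0,
        "inter_only_global": 0,
    }
    for i, j in loc - glo:
        key = "intra_added_by_local" if labels[i] == labels[j] else "inter_added_by_local"
        counts[key] += 1
    for i, j in glo - loc:
        key = "intra_only_global" if labels[i] == labels[j] else "inter_only_global"
        counts[key] += 1
    return counts
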