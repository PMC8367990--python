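"""Community detection: Louvain, rewired nulls, optimal density, consensus.

Community structure is always estimated on the *weighted thresholded* matrix
(the Hadamard product of the binary adjacency and the original weights).
Louvain maximisation is stochastic, so every partition reported by this
module is the best of N independent runs; the optimal cohort edge density is
the grid point maximising the mean of Q - Q_rand across participants, where
Q_rand is the mean modularity of degree-preserving (and, where feasible,
connectedness-preserving) rewired copies of the same thresholded network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import igraph
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ._seeds import child_seeds, seed_igraph
from .networks import (
    DensityTooLowError,
    WeightedConnectome,
    WeightedThresholdedNetwork,
    global_threshold,
    local_threshold,
    weighted_mask,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "DensityCurve",
    "ConsensusError",
    "modularity_q",
    "louvain_best_of",
    "null_modularity",
    "optimal_density_search",
    "consensus_partition",
    "meta_consensus",
    "default_density_grid",
]


class ConsensusError(RuntimeError):
    """Consensus clustering failed to converge within the iteration cap."""


@dataclass
class Partition:
    """Node -> module assignment with its modularity score."""

    labels: np.ndarray
    Q: Optional[float] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D node->module map")

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    @property
    def n_modules(self) -> int:
        return np.unique(self.labels).size

    def canonical(self) -> np.ndarray:
        """Labels relabelled by first occurrence, for label-free comparison."""
        _, canon = np.unique(self.labels, return_inverse=True)
        first = {}
        out = np.empty_like(canon)
        nxt = 0
        for idx, lab in enumerate(canon):
            if lab not in first:
                first[lab] = nxt
                nxt += 1
            out[idx] = first[lab]
        return out

    def community_of(self, node: int) -> np.ndarray:
        """Indices of all nodes sharing ``node``'s module (the node-set X_s)."""
        return np.nonzero(self.labels == self.labels[node])[0]


@dataclass
class DensityCurve:
    """Q and Q_rand means over a density grid, and the selected optimum."""

    densities: np.ndarray
    Q_mean: np.ndarray
    Q_rand_mean: np.ndarray
    optimal_density: float = field(init=False)

    def __post_init__(self):
        self.densities = np.asarray(self.densities, dtype=float)
        self.Q_mean = np.asarray(self.Q_mean, dtype=float)
        self.Q_rand_mean = np.asarray(self.Q_rand_mean, dtype=float)
        obj = self.Q_minus_Qrand
        finite = np.isfinite(obj)
        if not finite.any():
            raise ValueError("no density had a computable Q - Q_rand")
        best = np.nanmax(obj[finite])
        # ties broken toward the sparsest density
        self.optimal_density = float(self.densities[np.nonzero(obj == best)[0][0]])

    @property
    def Q_minus_Qrand(self) -> np.ndarray:
        return self.Q_mean - self.Q_rand_mean


def _weights_of(network) -> np.ndarray:
    if isinstance(network, WeightedThresholdedNetwork):
        return network.weights
    if isinstance(network, WeightedConnectome):
        return network.weights
    return np.asarray(network, dtype=float)


def modularity_q(network, partition: Partition) -> float:
    """Newman-Girvan weighted modularity of a partition.

    Q = sum_c [ W_cc / (2m) - (S_c / (2m))^2 ] where W_cc is twice the total
    intra-module weight of module c, S_c the total strength of its nodes and
    m the total edge weight.
    """
    w = _weights_of(network)
    labels = np.asarray(partition.labels)
    if labels.size != w.shape[0]:
        raise ValueError("partition does not cover all nodes")
    strength = w.sum(axis=1)
    two_m = strength.sum()
    if two_m == 0:
        raise ValueError("network has no edges; modularity undefined")
    q = 0.0
    for lab in np.unique(labels):
        idx = labels == lab
        w_cc = w[np.ix_(idx, idx)].sum()
        s_c = strength[idx].sum()
        q += w_cc / two_m - (s_c / two_m) ** 2
    return float(q)


def _to_igraph(w: np.ndarray) -> igraph.Graph:
    src, dst = np.nonzero(np.triu(w, 1) > 0)
    g = igraph.Graph(n=w.shape[0], edges=list(zip(src.tolist(), dst.tolist())))
    g.es["weight"] = w[src, dst].tolist()
    return g


def louvain_best_of(network, n_runs: int = 1000, seed: int = 0) -> Partition:
    """Best-of-N Louvain maximisation on a weighted (thresholded) network.

    Runs igraph's multilevel (Louvain) algorithm ``n_runs`` times with
    independent seeds derived from ``seed`` and returns the partition with
    the highest modularity Q (first encountered on ties).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    w = _weights_of(network)
    g = _to_igraph(w)
    if g.ecount() == 0:
        raise ValueError("network has no edges")
    best_q, best_membership = -np.inf, None
    for s in child_seeds(seed, n_runs):
        seed_igraph(s)
        clust = g.community_multilevel(weights="weight")
        q = g.modularity(clust.membership, weights="weight")
        if q > best_q:
            best_q, best_membership = q, clust.membership
    part = Partition(np.asarray(best_membership, dtype=int))
    part.Q = modularity_q(w, part)
    return part


def _reachable(adj: np.ndarray, start: int, target: int) -> bool:
    """Vectorised BFS reachability on a boolean adjacency matrix."""
    visited = np.zeros(adj.shape[0], dtype=bool)
    visited[start] = True
    frontier = adj[start] & ~visited
    while frontier.any():
        if frontier[target]:
            return True
        visited |= frontier
        frontier = adj[frontier].any(axis=0) & ~visited
    return bool(visited[target])


def _rewire_weighted(w: np.ndarray, seed: int, iter_per_edge: int = 10) -> np.ndarray:
    """Degree-preserving edge swap of a weighted adjacency matrix.

    Weights travel with their edges (swap (a,b),(c,d) -> (a,d),(c,b)).  If the
    source network is connected, swaps that would disconnect it are reverted,
    so the null preserves connectedness as well; on a disconnected source only
    the degree sequence is preserved.  Because the swap inserts edges a-d and
    c-b, the rewired graph stays connected iff b remains reachable from a, so
    a single BFS per accepted swap suffices.  If no swap succeeds on a network
    with more than two edges, a warning is logged (rewiring-infeasible
    topologies such as stars fall back to the identity).
    """
    rng = np.random.default_rng(seed)
    w = w.copy()
    adj = w > 0
    src, dst = np.nonzero(np.triu(adj, 1))
    edges = list(zip(src.tolist(), dst.tolist()))
    n_edges = len(edges)
    if n_edges < 2:
        return w
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    was_connected = n_comp == 1
    n_success = 0
    pair_draws = rng.integers(0, n_edges, size=(iter_per_edge * n_edges, 2))
    flip_draws = rng.random(iter_per_edge * n_edges)
    for (e1, e2), flip in zip(pair_draws, flip_draws):
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        w_ab, w_cd = w[a, b], w[c, d]
        w[a, b] = w[b, a] = 0.0
        w[c, d] = w[d, c] = 0.0
        w[a, d] = w[d, a] = w_ab
        w[c, b] = w[b, c] = w_cd
        adj[a, b] = adj[b, a] = adj[c, d] = adj[d, c] = False
        adj[a, d] = adj[d, a] = adj[c, b] = adj[b, c] = True
        if was_connected and not _reachable(adj, a, b):
            adj[a, d] = adj[d, a] = adj[c, b] = adj[b, c] = False
            adj[a, b] = adj[b, a] = adj[c, d] = adj[d, c] = True
            w[a, d] = w[d, a] = 0.0
            w[c, b] = w[b, c] = 0.0
            w[a, b] = w[b, a] = w_ab
            w[c, d] = w[d, c] = w_cd
            continue
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
        n_success += 1
    if n_success == 0 and n_edges > 2:
        logger.warning(
            "rewiring infeasible for this topology; null equals the input network"
        )
    return w


def null_modularity(
    network, n_null: int = 40, seed: int = 0, n_runs: int = 10
) -> float:
    """Mean modularity Q_rand of degree-preserving rewired null networks."""
    w = _weights_of(network)
    if not (np.triu(w, 1) > 0).any():
        raise ValueError("network has no edges")
    seeds = child_seeds(seed, 2 * n_null)
    qs = []
    for i in range(n_null):
        null_w = _rewire_weighted(w, seeds[2 * i])
        qs.append(louvain_best_of(null_w, n_runs=n_runs, seed=seeds[2 * i + 1]).Q)
    return float(np.mean(qs))


def default_density_grid(n_nodes: int) -> np.ndarray:
    """Density grid convention by parcellation size (percent).

    451-node-scale parcellations scan 0.08-5% in 51 equally spaced steps;
    ~200-250 node parcellations 0.2-10% in 73 steps; ~100 nodes 0.3-25% in
    100 steps.
    """
    if n_nodes >= 300:
        return np.linspace(0.08, 5.0, 51)
    if n_nodes >= 150:
        return np.linspace(0.2, 10.0, 73)
    return np.linspace(0.3, 25.0, 100)


def optimal_density_search(
    connectomes: Sequence[WeightedConnectome],
    density_grid: Optional[Iterable[float]] = None,
    method: str = "local",
    seed: int = 0,
    n_runs: int = 10,
    n_null: int = 40,
) -> DensityCurve:
    """Scan a density grid for the argmax of mean Q - Q_rand across participants.

    For each (participant, density) cell the connectome is thresholded by
    ``method``, masked, and its best-of-``n_runs`` Louvain Q and the mean Q of
    ``n_null`` rewired nulls computed.  Cells whose density is infeasible for
    the local threshold (below the participant's 1-NNG floor) are excluded
    from the means.  Ties in the argmax go to the sparsest density.
    """
    if len(connectomes) == 0:
        raise ValueError("at least one participant required")
    if method not in ("local", "global"):
        raise ValueError("method must be 'local' or 'global'")
    grid = (
        np.asarray(list(density_grid), dtype=float)
        if density_grid is not None
        else default_density_grid(connectomes[0].n_nodes)
    )
    threshold = local_threshold if method == "local" else global_threshold
    q = np.full((len(connectomes), grid.size), np.nan)
    q_rand = np.full_like(q, np.nan)
    seeds = child_seeds(seed, 2 * q.size)
    idx = 0
    for p, conn in enumerate(connectomes):
        for d, dens in enumerate(grid):
            s_q, s_null = seeds[2 * idx], seeds[2 * idx + 1]
            idx += 1
            try:
                net = threshold(conn, float(dens))
            except DensityTooLowError:
                logger.info(
                    "participant %d: density %.4g%% below local floor; cell skipped",
                    p,
                    dens,
                )
                continue
            if net.n_edges == 0:
                continue
            masked = weighted_mask(conn, net)
            q[p, d] = louvain_best_of(masked, n_runs=n_runs, seed=s_q).Q
            q_rand[p, d] = null_modularity(masked, n_null=n_null, seed=s_null, n_runs=n_runs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return DensityCurve(grid, np.nanmean(q, axis=0), np.nanmean(q_rand, axis=0))


def _coassignment(memberships: np.ndarray) -> np.ndarray:
    """Fraction of partitions assigning each node pair to the same module."""
    n_part, _ = memberships.shape
    acc = np.zeros((memberships.shape[1], memberships.shape[1]))
    for row in memberships:
        acc += np.equal.outer(row, row)
    return acc / n_part


def _null_coassignment_level(memberships: np.ndarray) -> float:
    """Expected co-assignment under label-permuted (size-preserving) nulls."""
    n = memberships.shape[1]
    levels = []
    for row in memberships:
        _, counts = np.unique(row, return_counts=True)
        levels.append((counts * (counts - 1)).sum() / (n * (n - 1)))
    return float(np.mean(levels))


def consensus_partition(
    partitions: Sequence[Partition],
    seed: int = 0,
    n_rep: int = 10,
    max_iter: int = 50,
) -> Partition:
    """Association-matrix consensus of a set of partitions.

    The node-pair co-assignment fraction is thresholded at the expected
    co-assignment of label-permuted null partitions, the thresholded matrix
    is re-clustered (Louvain, ``n_rep`` replicate runs), and the procedure
    iterates until all replicate runs return the same partition.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    n = partitions[0].n_nodes
    if any(p.n_nodes != n for p in partitions):
        raise ValueError("all partitions must cover the same node set")
    memberships = np.vstack([p.labels for p in partitions])
    seeds = iter(child_seeds(seed, n_rep * max_iter))
    for _ in range(max_iter):
        canon = np.vstack([Partition(row).canonical() for row in memberships])
        if (canon == canon[0]).all():
            return Partition(canon[0])
        assoc = _coassignment(memberships)
        tau = _null_coassignment_level(memberships)
        assoc[assoc <= tau] = 0.0
        np.fill_diagonal(assoc, 0.0)
        if not assoc.any():
            # threshold wiped the association structure: all-singleton consensus
            return Partition(np.arange(n))
        g = _to_igraph(assoc)
        reps = []
        for _ in range(n_rep):
            seed_igraph(next(seeds))
            clust = g.community_multilevel(weights="weight")
            full = np.asarray(clust.membership, dtype=int)
            reps.append(full)
        memberships = np.vstack(reps)
    raise ConsensusError(f"consensus did not converge in {max_iter} iterations")


def meta_consensus(consensus_list: Sequence[Partition], seed: int = 0) -> Partition:
    """Consensus of consensus partitions (one per bootstrap iteration)."""
    return consensus_partition(consensus_list, seed=seed)
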