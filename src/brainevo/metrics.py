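"""Graph-topology parameters of binary networks, computed from scratch.

Everything here is written directly against the adjacency matrix, with
tests backing each metric by brute-force oracles. The per-network feature
vector (global efficiency, average clustering coefficient, edge count,
transitivity, long-distance edge count) is what the downstream SVM
classifies, and node betweenness drives the evolution rules.

Conventions, frozen for reproducibility:

* Global efficiency averages 1/d(i, j) over all ordered pairs i != j, with
  disconnected pairs contributing 0.
* Average clustering counts degree-<2 nodes as 0 in the denominator of N
  nodes (they are not excluded), keeping group curves comparable across
  thresholds.
* Transitivity is 3 * triangles / connected triples, 0 when no triples.
* Betweenness uses the unnormalized Brandes convention: fractional
  shortest-path credit, each unordered pair counted once, endpoints
  excluded. The evolution rules renormalize the scale away.
* Long-distance edges are strictly farther than 75 mm apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import LONG_DISTANCE_MM, RegionAtlas
from .construction import BinaryNetwork
from .errors import InvalidArgumentError


@dataclass(frozen=True)
class TopologyProfile:
    """Feature vector of one network at one threshold."""

    global_efficiency: float
    clustering_coefficient: float
    edge_count: int
    transitivity: float
    long_distance_edge_count: int
    threshold: float | None = None
    subject_id: str = ""
    group: str = ""

    FEATURES = (
        "global_efficiency",
        "clustering_coefficient",
        "edge_count",
        "transitivity",
    )


@dataclass(frozen=True)
class BetweennessVector:
    """Unnormalized node betweenness (pair-count scale)."""

    values: np.ndarray


def _as_adjacency(net) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.adjacency
    return np.asarray(net, dtype=float)


def _bfs_counts(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs hop distances and shortest-path counts, level-synchronous.

    Runs BFS from every source simultaneously with matrix products: at
    level d, path counts into newly reached nodes are the counts at the
    frontier pushed across edges.
    """
    n = len(A)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    sigma = np.eye(n)
    d = 0
    while True:
        frontier = sigma * (dist == d)
        cand = frontier @ A
        new = (dist == np.inf) & (cand > 0)
        if not new.any():
            break
        d += 1
        sigma[new] = cand[new]
        dist[new] = d
    return dist, sigma


def shortest_path_lengths(net) -> np.ndarray:
    """Hop-count distance matrix; ``inf`` marks disconnected pairs."""
    A = _as_adjacency(net)
    return _bfs_counts(A)[0]


def global_efficiency(net) -> float:
    """Mean of 1/d(i, j) over ordered pairs i != j, with 1/inf = 0."""
    A = _as_adjacency(net)
    n = len(A)
    if n < 2:
        raise InvalidArgumentError("global efficiency needs at least 2 nodes")
    dist = shortest_path_lengths(A)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def clustering_coefficient(net) -> float:
    """Average local clustering; nodes with degree < 2 contribute 0."""
    A = _as_adjacency(net)
    n = len(A)
    if n == 0:
        raise InvalidArgumentError("clustering needs at least 1 node")
    deg = A.sum(axis=1)
    triangles = np.diag(A @ A @ A) / 2.0
    pairs = deg * (deg - 1) / 2.0
    local = np.where(pairs > 0, triangles / np.where(pairs > 0, pairs, 1.0), 0.0)
    return float(local.mean())


def transitivity(net) -> float:
    """3 x triangles / connected triples; 0 when the network has no triples."""
    A = _as_adjacency(net)
    if len(A) < 3:
        raise InvalidArgumentError("transitivity needs at least 3 nodes")
    deg = A.sum(axis=1)
    triples = float((deg * (deg - 1) / 2.0).sum())
    if triples == 0:
        return 0.0
    n_triangles = float(np.trace(A @ A @ A)) / 6.0
    return 3.0 * n_triangles / triples


def edge_count(net) -> int:
    """Unordered edges, counted once."""
    A = _as_adjacency(net)
    return int(A.sum()) // 2


def long_distance_edge_count(net, atlas: RegionAtlas, cutoff_mm: float = LONG_DISTANCE_MM) -> int:
    """Edges whose endpoints are strictly farther than ``cutoff_mm`` apart."""
    A = _as_adjacency(net)
    if A.shape[0] != atlas.n_regions:
        raise InvalidArgumentError("network and atlas disagree on the number of nodes")
    iu = np.triu_indices(len(A), 1)
    return int(((A[iu] > 0) & (atlas.distance[iu] > cutoff_mm)).sum())


def node_betweenness(net) -> BetweennessVector:
    """Brandes betweenness, vectorized over sources.

    The dependency accumulation runs level-by-level on the whole
    source x node matrix: a node at distance L from a source passes
    ``sigma_sv / sigma_sw * (1 + delta_sw)`` credit to each predecessor at
    distance L-1. Undirected pairs are then counted once.
    """
    A = _as_adjacency(net)
    n = len(A)
    dist, sigma = _bfs_counts(A)
    finite = np.isfinite(dist)
    if n == 0 or not finite.any():
        return BetweennessVector(values=np.zeros(n))
    max_d = int(dist[finite].max())
    delta = np.zeros((n, n))
    sigma_safe = np.where(sigma > 0, sigma, 1.0)
    for level in range(max_d, 1, -1):
        coef = np.where(dist == level, (1.0 + delta) / sigma_safe, 0.0)
        delta = delta + np.where(dist == level - 1, sigma * (coef @ A), 0.0)
    return BetweennessVector(values=delta.sum(axis=0) / 2.0)


def topology_profile(net: BinaryNetwork, atlas: RegionAtlas) -> TopologyProfile:
    """The full feature vector of one network."""
    return TopologyProfile(
        global_efficiency=global_efficiency(net),
        clustering_coefficient=clustering_coefficient(net),
        edge_count=edge_count(net),
        transitivity=transitivity(net),
        long_distance_edge_count=long_distance_edge_count(net, atlas),
        threshold=net.threshold,
        subject_id=net.subject_id,
        group=net.group,
    )


def group_mean_profiles(
    profiles: list[TopologyProfile], group: str, threshold: float | None
) -> TopologyProfile:
    """Arithmetic mean of each feature over one group at one threshold."""
    cell = [p for p in profiles if p.group == group and p.threshold == threshold]
    if not cell:
        raise InvalidArgumentError(f"no profiles for group={group!r} at threshold={threshold!r}")
    return TopologyProfile(
        global_efficiency=float(np.mean([p.global_efficiency for p in cell])),
        clustering_coefficient=float(np.mean([p.clustering_coefficient for p in cell])),
        edge_count=float(np.mean([p.edge_count for p in cell])),
        transitivity=float(np.mean([p.transitivity for p in cell])),
        long_distance_edge_count=float(np.mean([p.long_distance_edge_count for p in cell])),
        threshold=threshold,
        subject_id=f"mean_{group}",
        group=group,
    )
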