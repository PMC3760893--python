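"""Stochastic rewiring of healthy networks toward an AD-like state.

Each evolution step draws a fresh symmetric uniform random matrix R and,
synchronously over all unordered node pairs, adds the edge (i, j) when the
pair is unconnected, its connection weight CP(i, j) is at least 0.5 and
R(i, j) <= 0.03; removes it when the pair is connected, its disconnection
weight DP(i, j) is at least 0.5 and R(i, j) <= 0.03; and otherwise leaves
the pair alone. Betweenness and both weight matrices are recomputed from
the current network every step. Evolution runs for 100 steps.

Weights follow the two stated proportionalities, with K_i the betweenness
of node i and D(i, j) the anatomical distance in mm:

* connection:     w_cp(i, j) = (K_i + K_j) / D(i, j)^2
* disconnection:  w_dp(i, j) = (K_i + K_j) * D(i, j)^2

Both weights must land on [0, 1] for the 0.5 threshold to be meaningful,
and the normalization scales are where the dynamics live; both are exposed
on :class:`EvolutionParams`.

* DP is normalized by a constant frozen at step 0 — twice the
  ``dp_scale_quantile`` (default 0.70) quantile of the initial over-edge
  weights — and clipped to 1. A frozen scale lets the disconnection
  pressure *rise* as betweenness concentrates on the surviving long-range
  bridges, and die away once the network has decomposed into modules whose
  internal betweenness is negligible, which is what stabilizes the
  trajectory. Normalizing DP by its own per-step maximum would instead pin
  the top weight at 1 forever and leave the 0.5 threshold selecting only a
  measure-zero sliver of the heavy-tailed weight distribution, freezing
  the dynamics.
* CP is normalized per step on the connection candidates (the non-edges):
  by twice their ``cp_scale_quantile`` (default 0.9925) weight quantile,
  clipped to 1, or by their maximum when the quantile is ``None``. The
  per-step scale keeps additions sparse and self-limiting — they track the
  current betweenness concentration instead of compounding it — and
  concentrates them on short-range pairs around high-betweenness hubs,
  which dilutes transitivity the way a degenerating network loses
  triangle closure faster than it loses triples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .atlas import RegionAtlas
from .construction import BinaryNetwork
from .errors import InvalidArgumentError
from .metrics import BetweennessVector, TopologyProfile, node_betweenness, topology_profile
from .synthetic import EVOLVED


@dataclass(frozen=True)
class EvolutionParams:
    """Rule parameters.

    The thresholds, acceptance cut-off and step count are the published
    operating point; the two scale quantiles fix the free normalization
    constants of the weight formulas (see the module docstring).
    """

    cp_threshold: float = 0.5
    dp_threshold: float = 0.5
    random_threshold: float = 0.03
    n_steps: int = 100
    dp_scale_quantile: float = 0.70
    cp_scale_quantile: float | None = 0.9925  # None: per-step candidate max normalization
    seed: int = 0

    def validate(self) -> None:
        for name in ("cp_threshold", "dp_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InvalidArgumentError(f"{name} must lie in (0, 1]")
        if not 0 <= self.random_threshold <= 1:
            raise InvalidArgumentError("random_threshold must lie in [0, 1]")
        if self.n_steps < 0:
            raise InvalidArgumentError("n_steps must be non-negative")
        if not 0 < self.dp_scale_quantile < 1:
            raise InvalidArgumentError("dp_scale_quantile must lie in (0, 1)")
        if self.cp_scale_quantile is not None and not 0 < self.cp_scale_quantile < 1:
            raise InvalidArgumentError("cp_scale_quantile must lie in (0, 1) or be None")


@dataclass(frozen=True)
class EvolutionState:
    """One step of the evolution: network plus the quantities that gate it."""

    step: int
    adjacency: np.ndarray
    betweenness: BetweennessVector
    cp: np.ndarray
    dp: np.ndarray
    r: np.ndarray  # the uniform draw that produced this state (ones at step 0)
    dp_scale: float  # frozen step-0 normalization constant for dp
    cp_quantile: float | None = None  # per-step candidate quantile for cp (None: candidate max)


@dataclass(frozen=True)
class EvolutionTrace:
    """Initial and final networks plus one topology profile per step."""

    initial: BinaryNetwork
    final: BinaryNetwork
    per_step_profiles: tuple[TopologyProfile, ...]
    params: EvolutionParams


def _pair_weights(adjacency, betweenness, atlas):
    K = betweenness.values
    D2 = atlas.distance**2
    off = ~np.eye(len(adjacency), dtype=bool)
    if np.any(D2[off] == 0):
        raise InvalidArgumentError("atlas has coincident regions (zero inter-node distance)")
    K_sum = K[:, None] + K[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        w_cp = np.where(off, K_sum / np.where(D2 > 0, D2, np.inf), 0.0)
    w_dp = np.where(off, K_sum * D2, 0.0)
    return w_cp, w_dp


def connection_weights(adjacency, betweenness: BetweennessVector, atlas: RegionAtlas) -> np.ndarray:
    """CP matrix: (K_i + K_j) / D^2, max-normalized; all-zero when flat."""
    w_cp, _ = _pair_weights(adjacency, betweenness, atlas)
    m = w_cp.max()
    return w_cp / m if m > 0 else w_cp


def disconnection_weights(
    adjacency,
    betweenness: BetweennessVector,
    atlas: RegionAtlas,
    scale: float | None = None,
) -> np.ndarray:
    """DP matrix: (K_i + K_j) * D^2 on [0, 1].

    With ``scale=None`` the matrix is max-normalized. The evolution passes
    the frozen step-0 scale instead, under which values clip at 1.
    """
    _, w_dp = _pair_weights(adjacency, betweenness, atlas)
    if scale is None:
        m = w_dp.max()
        return w_dp / m if m > 0 else w_dp
    if scale <= 0:
        return np.zeros_like(w_dp)
    return np.minimum(w_dp / scale, 1.0)


def dp_scale_from_network(adjacency, betweenness, atlas, quantile: float) -> float:
    """Frozen DP normalization: 2 x the over-edge weight quantile at step 0."""
    _, w_dp = _pair_weights(adjacency, betweenness, atlas)
    iu = np.triu_indices(len(adjacency), 1)
    on_edges = w_dp[iu][np.asarray(adjacency)[iu] > 0]
    if on_edges.size == 0:
        return 0.0
    return 2.0 * float(np.quantile(on_edges, quantile))


def _cp_matrix(adjacency, betweenness, atlas, quantile):
    """CP over [0, 1], scaled per step on the connection candidates (non-edges):
    by their maximum weight, or by twice their ``quantile`` weight (clipped)."""
    w_cp, _ = _pair_weights(adjacency, betweenness, atlas)
    iu = np.triu_indices(len(adjacency), 1)
    off = w_cp[iu][np.asarray(adjacency)[iu] == 0]
    if off.size == 0 or off.max() <= 0:
        return np.zeros_like(w_cp)
    scale = off.max() if quantile is None else 2.0 * float(np.quantile(off, quantile))
    if scale <= 0:
        return np.zeros_like(w_cp)
    return np.minimum(w_cp / scale, 1.0)


def initial_state(net: BinaryNetwork, params: EvolutionParams, atlas: RegionAtlas) -> EvolutionState:
    A = net.adjacency.copy()
    K = node_betweenness(A)
    scale = dp_scale_from_network(A, K, atlas, params.dp_scale_quantile)
    return EvolutionState(
        step=0,
        adjacency=A,
        betweenness=K,
        cp=_cp_matrix(A, K, atlas, params.cp_scale_quantile),
        dp=disconnection_weights(A, K, atlas, scale=scale),
        r=np.ones_like(A),
        dp_scale=scale,
        cp_quantile=params.cp_scale_quantile,
    )


def evolution_step(
    state: EvolutionState,
    params: EvolutionParams,
    atlas: RegionAtlas,
    rng: np.random.Generator,
) -> EvolutionState:
    """One synchronous rewiring pass; all decisions use the entry state."""
    A = state.adjacency
    n = len(A)
    iu = np.triu_indices(n, 1)
    R = np.zeros((n, n))
    R[iu] = rng.uniform(size=iu[0].size)
    R = R + R.T

    non_edge = (A == 0) & ~np.eye(n, dtype=bool)
    lucky = R <= params.random_threshold
    add = non_edge & (state.cp >= params.cp_threshold) & lucky
    remove = (A == 1) & (state.dp >= params.dp_threshold) & lucky

    A_new = A.copy()
    A_new[add] = 1.0
    A_new[remove] = 0.0
    np.fill_diagonal(A_new, 0.0)

    K = node_betweenness(A_new)
    return EvolutionState(
        step=state.step + 1,
        adjacency=A_new,
        betweenness=K,
        cp=_cp_matrix(A_new, K, atlas, state.cp_quantile),
        dp=disconnection_weights(A_new, K, atlas, scale=state.dp_scale),
        r=R,
        dp_scale=state.dp_scale,
        cp_quantile=state.cp_quantile,
    )


def evolve(net: BinaryNetwork, atlas: RegionAtlas, params: EvolutionParams) -> EvolutionTrace:
    """Run ``params.n_steps`` steps from a seeded generator.

    Records a topology profile after every step; bit-identical traces for
    identical ``(net, params)``.
    """
    params.validate()
    if net.n_nodes != atlas.n_regions:
        raise InvalidArgumentError("network and atlas disagree on the number of nodes")
    rng = np.random.default_rng(params.seed)
    state = initial_state(net, params, atlas)
    profiles = []
    for _ in range(params.n_steps):
        state = evolution_step(state, params, atlas, rng)
        prof = topology_profile(
            BinaryNetwork(
                adjacency=state.adjacency,
                threshold=net.threshold,
                subject_id=net.subject_id,
                group=EVOLVED,
            ),
            atlas,
        )
        profiles.append(replace(prof, threshold=net.threshold))
    final = BinaryNetwork(
        adjacency=state.adjacency,
        threshold=net.threshold,
        subject_id=net.subject_id,
        group=EVOLVED,
    )
    return EvolutionTrace(
        initial=net, final=final, per_step_profiles=tuple(profiles), params=params
    )


def evolve_group(
    networks: list[BinaryNetwork], atlas: RegionAtlas, params: EvolutionParams
) -> list[EvolutionTrace]:
    """One trace per input network, with per-network substream seeds.

    Substream seeds derive deterministically from ``params.seed`` and the
    subject order, so the group run is reproducible as a whole and each
    subject's trace is reproducible in isolation.
    """
    traces = []
    for idx, net in enumerate(networks):
        sub_seed = int(np.random.SeedSequence([params.seed, idx]).generate_state(1)[0] % 2**31)
        traces.append(evolve(net, atlas, replace(params, seed=sub_seed)))
    return traces
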