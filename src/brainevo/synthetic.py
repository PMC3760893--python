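"""Synthetic cohort generator with planted group-level network structure.

Two groups of subjects are generated: a denser "healthy-like" group and a
sparser "AD-like" group with fewer long-distance (> 75 mm) edges. Each
group has a planted binary network; each subject gets a jittered copy of
it, a correlation matrix carrying the planted edges at a target Pearson r,
and a Gaussian time-series matrix drawn from that correlation.

Planted graphs are spatially modular: regions are partitioned into
spatially compact communities that are fully connected internally, plus a
small set of distance-penalized cross-community edges. Modularity is what
makes a planted edge correlation of 0.6 representable at realistic edge
densities — a correlation matrix that is 0.6 on the edges of a graph whose
neighbours are mutually uncorrelated cannot support degree above 2, whereas
compound-symmetric blocks support it at any size. It also gives the planted
graphs genuine triangle content, so clustering and transitivity contrasts
between the groups are structural rather than sampling noise.

The subject covariance is the nearest correlation matrix (Higham
alternating projections with an eigenvalue floor) to ``I + r * A``, with a
few rounds of per-edge recalibration so the realized on-edge values hit the
target. Signals are i.i.d.-in-time zero-mean Gaussian draws from that
correlation; no autocorrelation or band-limiting is modelled, since sample
Pearson r is unaffected by either.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import LONG_DISTANCE_MM, RegionAtlas
from .errors import CovarianceError, InvalidArgumentError

__all__ = [
    "SyntheticCohortConfig",
    "GroundTruthNetwork",
    "SubjectTimeSeries",
    "generate_atlas",
    "plant_group_adjacency",
    "sample_cohort",
    "nearest_correlation",
    "planted_covariance",
]

# re-export so the module covers atlas generation too
from .atlas import generate_atlas  # noqa: E402  (public surface)

HEALTHY = "healthy"
AD = "ad"
EVOLVED = "evolved"


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study-condition defaults for the synthetic cohort.

    Densities may be fractions in (0, 1) or absolute edge counts (>= 1).
    ``ad_block_size`` sets the AD-like community size explicitly (smaller,
    less clustered modules); the healthy group derives the largest feasible
    block size from its edge budget.
    """

    n_healthy: int = 11
    n_ad: int = 10
    n_regions: int = 90
    n_timepoints: int = 240  # 8 min at TR = 2 s
    healthy_density: float = 480.0  # edges (of 4005 pairs at n=90)
    ad_density: float = 330.0
    long_range_retention_ad: float = 0.3
    edge_correlation: float = 0.6
    subject_jitter: float = 0.02
    ad_block_size: int | None = 9
    ad_within_completeness: float = 0.90
    healthy_block_size: int | None = None
    min_cross_fraction: float = 0.02
    cross_degree_cap: int = 2
    cross_scale_mm: float = 75.0
    eig_floor: float = 0.01
    seed: int = 0

    def edge_target(self, density: float) -> int:
        n_pairs = self.n_regions * (self.n_regions - 1) // 2
        m = int(round(density * n_pairs)) if 0 < density < 1 else int(round(density))
        if not 0 <= m <= n_pairs:
            raise InvalidArgumentError(f"edge target {m} infeasible for {n_pairs} pairs")
        return m

    def validate(self) -> None:
        if self.n_healthy < 1 or self.n_ad < 1:
            raise InvalidArgumentError("both groups need at least one subject")
        mh, ma = self.edge_target(self.healthy_density), self.edge_target(self.ad_density)
        if ma >= mh:
            raise InvalidArgumentError("ad_density must be below healthy_density")
        if not 0 <= self.long_range_retention_ad <= 1:
            raise InvalidArgumentError("long_range_retention_ad must lie in [0, 1]")
        if not 0 < self.edge_correlation < 1:
            raise InvalidArgumentError("edge_correlation must lie in (0, 1)")
        if not 0 <= self.subject_jitter < 1:
            raise InvalidArgumentError("subject_jitter must lie in [0, 1)")


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Planted 0/1 adjacency for one group (or one subject)."""

    adjacency: np.ndarray
    group: str

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise InvalidArgumentError("adjacency must be symmetric with a zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise InvalidArgumentError("adjacency entries must be 0/1")

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class SubjectTimeSeries:
    """One subject's regions x timepoints signal matrix."""

    subject_id: str
    group: str
    signal: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.signal, dtype=float)
        if s.ndim != 2:
            raise InvalidArgumentError("signal must be a 2-D (regions x timepoints) matrix")
        if not np.isfinite(s).all():
            raise InvalidArgumentError("signal contains non-finite values")
        object.__setattr__(self, "signal", s)

    @property
    def n_regions(self) -> int:
        return self.signal.shape[0]


# ---------------------------------------------------------------------------
# planted adjacency


def _block_sizes(n: int, k: int) -> list[int]:
    nb, rem = divmod(n, k)
    return [k] * nb + ([rem] if rem else [])


def _within_count(n: int, k: int) -> int:
    return sum(s * (s - 1) // 2 for s in _block_sizes(n, k))


def _fit_partition(n: int, max_within: int) -> list[int]:
    """Most-concentrated near-balanced partition with at most ``max_within``
    internal pairs: fewest parts, sizes differing by at most one."""
    for t in range(1, n + 1):
        k, u = divmod(n, t)
        sizes = [k + 1] * u + [k] * (t - u)
        if sum(s * (s - 1) // 2 for s in sizes) <= max_within:
            return sizes
    return [1] * n


def _balanced_spatial_partition(coords: np.ndarray, sizes: list[int], rng) -> np.ndarray:
    """Capacity-constrained k-means-style partition of regions into communities."""
    n = len(coords)
    cent = coords[rng.choice(n, len(sizes), replace=False)].copy()
    caps = np.asarray(sorted(sizes, reverse=True))
    labels = np.full(n, -1)
    for _ in range(30):
        d = np.linalg.norm(coords[:, None, :] - cent[None, :, :], axis=-1)
        cap = caps.copy()
        labels = np.full(n, -1)
        for i in np.argsort(d.min(axis=1)):
            for c in np.argsort(d[i]):
                if cap[c] > 0:
                    labels[i] = c
                    cap[c] -= 1
                    break
        new_cent = np.array([coords[labels == c].mean(axis=0) for c in range(len(sizes))])
        if np.allclose(new_cent, cent):
            break
        cent = new_cent
    return labels


def plant_group_adjacency(
    atlas: RegionAtlas,
    density: float,
    long_range_retention: float,
    seed: int,
    *,
    block_size: int | None = None,
    within_completeness: float = 1.0,
    min_cross_fraction: float = 0.02,
    cross_degree_cap: int = 2,
    cross_scale_mm: float = 75.0,
    group: str = HEALTHY,
) -> GroundTruthNetwork:
    """Plant a group adjacency with exactly ``m`` edges.

    Spatially compact communities are densely connected internally — a
    fraction ``within_completeness`` of each block's pairs, dropped
    uniformly at random below 1.0, which lowers clustering and transitivity
    without touching the edge budget's correlation feasibility. The
    remaining budget goes to cross-community edges sampled without
    replacement with weight ``exp(-D/cross_scale_mm)``, multiplied by
    ``long_range_retention`` for pairs beyond 75 mm, under a per-node
    cross-degree cap. Deterministic for fixed arguments.
    """
    if not 0 < within_completeness <= 1:
        raise InvalidArgumentError("within_completeness must lie in (0, 1]")
    n = atlas.n_regions
    n_pairs = n * (n - 1) // 2
    m = int(round(density * n_pairs)) if 0 < density < 1 else int(round(density))
    if m < 0 or m > n_pairs:
        raise InvalidArgumentError(f"edge target {m} infeasible for {n_pairs} pairs")
    rng = np.random.default_rng(seed)
    A = np.zeros((n, n))
    if m == 0:
        return GroundTruthNetwork(adjacency=A, group=group)

    if block_size is None:
        m_cross_min = max(2, int(round(min_cross_fraction * m)))
        budget = int((m - m_cross_min) / within_completeness)
        sizes = _fit_partition(n, budget)
    else:
        sizes = _block_sizes(n, block_size)
    total_within = sum(s * (s - 1) // 2 for s in sizes)
    m_within = int(round(within_completeness * total_within))
    if m_within > m:
        raise InvalidArgumentError(
            f"blocks of sizes {sizes} need {m_within} within-block edges, target is {m}"
        )
    labels = _balanced_spatial_partition(atlas.coords, sizes, rng)
    same = labels[:, None] == labels[None, :]
    A[same] = 1.0
    np.fill_diagonal(A, 0.0)
    if within_completeness < 1.0:
        iu = np.triu_indices(n, 1)
        within_idx = np.flatnonzero(A[iu] > 0)
        drop = rng.choice(within_idx, size=within_idx.size - m_within, replace=False)
        A[iu[0][drop], iu[1][drop]] = 0.0
        A[iu[1][drop], iu[0][drop]] = 0.0

    m_cross = m - int(A.sum()) // 2
    if m_cross > 0:
        iu = np.triu_indices(n, 1)
        D = atlas.distance[iu]
        cand = np.where(~same[iu])[0]
        w = np.exp(-D[cand] / cross_scale_mm)
        w[D[cand] > LONG_DISTANCE_MM] *= long_range_retention
        # Gumbel top-k = weighted sampling without replacement; greedy under the degree cap
        keys = np.where(w > 0, np.log(np.maximum(w, 1e-300)), -np.inf) + rng.gumbel(size=w.size)
        deg = np.zeros(n, dtype=int)
        added = 0
        order = np.argsort(keys)[::-1]
        order = order[np.isfinite(keys[order])]  # zero-weight pairs are never selected
        for idx in cand[order]:
            i, j = iu[0][idx], iu[1][idx]
            if deg[i] >= cross_degree_cap or deg[j] >= cross_degree_cap:
                continue
            A[i, j] = A[j, i] = 1.0
            deg[i] += 1
            deg[j] += 1
            added += 1
            if added == m_cross:
                break
        if added < m_cross:
            raise InvalidArgumentError(
                "could not place all cross edges under the degree cap; "
                "raise cross_degree_cap or lower the edge target"
            )
    return GroundTruthNetwork(adjacency=A, group=group)


# ---------------------------------------------------------------------------
# covariance


def nearest_correlation(M: np.ndarray, eig_floor: float = 0.01, max_iter: int = 80) -> np.ndarray:
    """Nearest correlation matrix by Higham alternating projections.

    Projects alternately onto {symmetric PSD with eigenvalues >= eig_floor}
    and {unit diagonal}, with Dykstra's correction.
    """
    Y = np.asarray(M, dtype=float).copy()
    dS = np.zeros_like(Y)
    for _ in range(max_iter):
        R = Y - dS
        lam, V = np.linalg.eigh(R)
        X = (V * np.maximum(lam, eig_floor)) @ V.T
        dS = X - R
        Y = X.copy()
        np.fill_diagonal(Y, 1.0)
        if np.abs(X - Y).max() < 1e-7 and lam.min() >= eig_floor - 1e-9:
            break
    d = np.sqrt(np.clip(np.diag(Y), 1e-12, None))
    Y = Y / np.outer(d, d)
    np.fill_diagonal(Y, 1.0)
    return (Y + Y.T) / 2


def planted_covariance(
    adjacency: np.ndarray,
    edge_correlation: float = 0.6,
    eig_floor: float = 0.01,
    rounds: int = 10,
) -> np.ndarray:
    """Correlation matrix carrying ``edge_correlation`` on planted edges.

    Starts from ``I + r A`` and alternates nearest-correlation projection
    with per-edge recalibration, so realized on-edge values converge to the
    target as closely as positive-definiteness allows. Raises
    :class:`CovarianceError` if the result is not positive definite.
    """
    A = np.asarray(adjacency, dtype=float)
    E = A > 0
    if not E.any():
        return np.eye(len(A))
    M = np.eye(len(A)) + edge_correlation * A
    S = M
    for _ in range(rounds):
        S = nearest_correlation(M, eig_floor=eig_floor)
        err = edge_correlation - S[E]
        if np.abs(err).max() < 0.005:
            break
        M = M.copy()
        M[E] = np.clip(M[E] + err, 0.0, 0.985)
    lam_min = np.linalg.eigvalsh(S).min()
    if lam_min <= 0:
        raise CovarianceError(f"planted covariance not positive definite (lambda_min={lam_min:.3g})")
    return S


# ---------------------------------------------------------------------------
# cohort


def _jitter_adjacency(adjacency, atlas, fraction, long_range_retention, cross_scale_mm, rng):
    """Resample a fraction of edges: drop k random edges, add k fresh pairs."""
    A = adjacency.copy()
    n = len(A)
    iu = np.triu_indices(n, 1)
    edges = np.flatnonzero(A[iu] > 0)
    k = int(round(fraction * edges.size))
    if k == 0:
        return A
    drop = rng.choice(edges, size=k, replace=False)
    non_edges = np.flatnonzero(A[iu] == 0)
    D = atlas.distance[iu][non_edges]
    w = np.exp(-D / cross_scale_mm)
    w[D > LONG_DISTANCE_MM] *= long_range_retention
    keys = np.log(np.maximum(w, 1e-300)) + rng.gumbel(size=w.size)
    add = non_edges[np.argsort(keys)[-k:]]
    for idx, val in ((drop, 0.0), (add, 1.0)):
        A[iu[0][idx], iu[1][idx]] = val
        A[iu[1][idx], iu[0][idx]] = val
    return A


def sample_cohort(
    config: SyntheticCohortConfig, atlas: RegionAtlas
) -> tuple[list[SubjectTimeSeries], list[GroundTruthNetwork]]:
    """Draw the full cohort: time series plus per-subject planted networks.

    Per subject: jitter the group adjacency, build the planted correlation,
    and draw ``n_timepoints`` i.i.d. Gaussian samples via its Cholesky
    factor. Bit-identical for identical ``(config, atlas)``.
    """
    config.validate()
    if atlas.n_regions != config.n_regions:
        raise InvalidArgumentError("atlas size disagrees with config.n_regions")
    root = np.random.SeedSequence(config.seed)
    group_specs = [
        (HEALTHY, config.n_healthy, config.edge_target(config.healthy_density), 1.0,
         config.healthy_block_size, 1.0),
        (AD, config.n_ad, config.edge_target(config.ad_density), config.long_range_retention_ad,
         config.ad_block_size, config.ad_within_completeness),
    ]
    subjects: list[SubjectTimeSeries] = []
    truths: list[GroundTruthNetwork] = []
    for g_idx, (group, n_subj, m, retention, block_size, completeness) in enumerate(group_specs):
        plant_seed = np.random.SeedSequence([config.seed, g_idx]).generate_state(1)[0] % 2**31
        planted = plant_group_adjacency(
            atlas, m, retention, int(plant_seed),
            block_size=block_size,
            within_completeness=completeness,
            min_cross_fraction=config.min_cross_fraction,
            cross_degree_cap=config.cross_degree_cap,
            cross_scale_mm=config.cross_scale_mm,
            group=group,
        )
        for s in range(n_subj):
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, g_idx, s, 7]))
            A_s = _jitter_adjacency(
                planted.adjacency, atlas, config.subject_jitter, retention,
                config.cross_scale_mm, rng,
            )
            S = planted_covariance(A_s, config.edge_correlation, config.eig_floor)
            try:
                L = np.linalg.cholesky(S)
            except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
                raise CovarianceError("subject covariance is not positive definite") from exc
            Z = rng.standard_normal((config.n_regions, config.n_timepoints))
            subjects.append(
                SubjectTimeSeries(subject_id=f"{group}_{s:02d}", group=group, signal=L @ Z)
            )
            truths.append(GroundTruthNetwork(adjacency=A_s, group=group))
    return subjects, truths
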