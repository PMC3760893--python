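import numpy as np
import pytest

from brainevo import (
    BetweennessVector,
    BinaryNetwork,
    EvolutionParams,
    RegionAtlas,
    connection_weights,
    disconnection_weights,
    evolution_step,
    evolve,
    evolve_group,
    initial_state,
    plant_group_adjacency,
)


class _FixedRng:
    """Duck-typed generator returning a constant uniform draw."""

    def __init__(self, value):
        self.value = value

    def uniform(self, size=None):
        return np.full(size, self.value) if size is not None else self.value


@pytest.fixture()
def tri_atlas():
    """Three nodes: pair (0,1) at 10 mm, pair (0,2) at 20 mm."""
    coords = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 20.0, 0.0]])
    return RegionAtlas(labels=("a", "b", "c"), coords=coords)


class TestWeights:
    def test_zero_betweenness_gives_zero_weights(self, tri_atlas):
        A = np.zeros((3, 3))
        K = BetweennessVector(values=np.zeros(3))
        assert np.all(connection_weights(A, K, tri_atlas) == 0)
        assert np.all(disconnection_weights(A, K, tri_atlas) == 0)

    def test_inverse_square_distance_ratio(self, tri_atlas):
        # equal K-sums at 10 mm and 20 mm: cp ratio 4:1 after max-normalization
        A = np.zeros((3, 3))
        K = BetweennessVector(values=np.array([1.0, 0.0, 0.0]))
        cp = connection_weights(A, K, tri_atlas)
        assert cp[0, 1] == pytest.approx(1.0)
        assert cp[0, 2] == pytest.approx(0.25)
        assert cp[1, 2] == 0.0  # zero K-sum

    def test_square_distance_ratio_for_disconnection(self, tri_atlas):
        A = np.zeros((3, 3))
        K = BetweennessVector(values=np.array([1.0, 0.0, 0.0]))
        dp = disconnection_weights(A, K, tri_atlas)
        assert dp[0, 2] == pytest.approx(1.0)
        assert dp[0, 1] == pytest.approx(0.25)

    def test_weights_symmetric_and_bounded(self, atlas12):
        rng = np.random.default_rng(0)
        A = (rng.uniform(size=(12, 12)) < 0.3).astype(float)
        A = np.triu(A, 1) + np.triu(A, 1).T
        K = BetweennessVector(values=rng.uniform(0, 10, 12))
        for w in (connection_weights(A, K, atlas12), disconnection_weights(A, K, atlas12)):
            assert np.allclose(w, w.T)
            assert w.min() >= 0 and w.max() <= 1
            assert np.all(np.diag(w) == 0)

    def test_single_nonzero_weight_self_normalizes(self, tri_atlas):
        A = np.zeros((3, 3))
        K = BetweennessVector(values=np.array([0.0, 0.0, 5.0]))
        dp = disconnection_weights(A, K, tri_atlas)
        assert dp.max() == pytest.approx(1.0)

    def test_coincident_nodes_rejected(self):
        atlas = RegionAtlas(labels=("a", "b"), coords=np.zeros((2, 3)))
        K = BetweennessVector(values=np.ones(2))
        with pytest.raises(Exception):
            connection_weights(np.zeros((2, 2)), K, atlas)


def _healthy_net(atlas, m=120, seed=3, threshold=0.55):
    truth = plant_group_adjacency(atlas, m, 1.0, seed=seed)
    return BinaryNetwork(
        adjacency=truth.adjacency, threshold=threshold, subject_id="h0", group="healthy"
    )


class TestStep:
    def test_unlucky_draw_changes_nothing(self, atlas90):
        net = _healthy_net(atlas90)
        params = EvolutionParams(seed=0)
        state = initial_state(net, params, atlas90)
        out = evolution_step(state, params, atlas90, _FixedRng(1.0))
        assert np.array_equal(out.adjacency, state.adjacency)
        assert out.step == 1

    def test_eligible_pairs_flip_exactly_when_lucky(self, atlas90):
        rng = np.random.default_rng(12)
        a = (rng.uniform(size=(90, 90)) < 0.08).astype(float)
        a = np.triu(a, 1) + np.triu(a, 1).T
        net = BinaryNetwork(adjacency=a, threshold=0.55, subject_id="r", group="healthy")
        params = EvolutionParams(seed=0)
        state = initial_state(net, params, atlas90)
        add_mask = (state.adjacency == 0) & (state.cp >= 0.5) & ~np.eye(90, dtype=bool)
        rem_mask = (state.adjacency == 1) & (state.dp >= 0.5)
        assert rem_mask.sum() > 0  # the planted network exposes removable edges
        out = evolution_step(state, params, atlas90, _FixedRng(0.01))
        expected = state.adjacency.copy()
        expected[add_mask] = 1
        expected[rem_mask] = 0
        assert np.array_equal(out.adjacency, expected)

    def test_weights_recomputed_for_new_state(self, atlas90):
        net = _healthy_net(atlas90)
        params = EvolutionParams(seed=0)
        state = initial_state(net, params, atlas90)
        out = evolution_step(state, params, atlas90, _FixedRng(0.01))
        assert not np.array_equal(out.betweenness.values, state.betweenness.values)
        assert out.dp_scale == state.dp_scale  # frozen normalization constant


class TestEvolve:
    def test_zero_steps_is_identity(self, atlas90):
        net = _healthy_net(atlas90)
        trace = evolve(net, atlas90, EvolutionParams(n_steps=0, seed=1))
        assert np.array_equal(trace.final.adjacency, net.adjacency)
        assert trace.per_step_profiles == ()

    def test_zero_random_threshold_is_identity_for_any_step_count(self, atlas90):
        net = _healthy_net(atlas90)
        trace = evolve(net, atlas90, EvolutionParams(n_steps=25, random_threshold=0.0, seed=1))
        assert np.array_equal(trace.final.adjacency, net.adjacency)

    def test_empty_network_stays_empty(self, atlas90):
        net = BinaryNetwork(
            adjacency=np.zeros((90, 90)), threshold=0.55, subject_id="e", group="healthy"
        )
        trace = evolve(net, atlas90, EvolutionParams(n_steps=20, seed=1))
        assert trace.final.edge_count == 0

    def test_same_seed_gives_identical_traces(self, atlas90):
        net = _healthy_net(atlas90)
        params = EvolutionParams(n_steps=15, seed=42)
        a, b = evolve(net, atlas90, params), evolve(net, atlas90, params)
        assert np.array_equal(a.final.adjacency, b.final.adjacency)
        assert a.per_step_profiles == b.per_step_profiles

    def test_final_network_is_labelled_evolved(self, atlas90):
        net = _healthy_net(atlas90)
        trace = evolve(net, atlas90, EvolutionParams(n_steps=5, seed=1))
        assert trace.final.group == "evolved"
        assert trace.final.threshold == net.threshold
        assert len(trace.per_step_profiles) == 5

    def test_group_evolution_is_per_subject_reproducible(self, atlas90):
        nets = [_healthy_net(atlas90, seed=s) for s in (1, 2, 3)]
        params = EvolutionParams(n_steps=8, seed=7)
        first = evolve_group(nets, atlas90, params)
        second = evolve_group(nets, atlas90, params)
        assert len(first) == 3
        for a, b in zip(first, second):
            assert np.array_equal(a.final.adjacency, b.final.adjacency)
        # distinct substreams: subjects do not share the random sequence
        assert not np.array_equal(first[0].final.adjacency, first[1].final.adjacency)

    def test_empty_group_gives_empty_output(self, atlas90):
        assert evolve_group([], atlas90, EvolutionParams(seed=0)) == []

    def test_invalid_params_rejected(self, atlas90):
        net = _healthy_net(atlas90)
        with pytest.raises(Exception):
            evolve(net, atlas90, EvolutionParams(cp_threshold=0.0))
        with pytest.raises(Exception):
            evolve(net, atlas90, EvolutionParams(n_steps=-1))
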