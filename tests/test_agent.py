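"""Channel graphs, GCN actor/critic behavior, and the TD3 update rules."""

import numpy as np
import pytest
from scipy.stats import kstest

from herdnet.agent import (
    Actor,
    AgentNets,
    BufferEntry,
    ChannelGraph,
    Critic,
    GCNLayer,
    ReplayBuffer,
    TD3Config,
    actor_forward,
    build_channel_graph,
    critic_forward,
    explore_action,
    normalize_adjacency,
    search,
    td3_targets,
    td3_update,
)
from herdnet.nn import Adam, Tensor
from herdnet.prune import CouplingGroup, LayerState

from toyenv import ToyPruningEnv


def make_state(slices: np.ndarray, seed=0) -> LayerState:
    M = slices.shape[0]
    rng = np.random.default_rng(seed)
    rows = rng.uniform(size=(M, 11))
    group = CouplingGroup(1, ("c",), ("p",), M)
    return LayerState(group, rows, rows.copy(), slices)


def random_graph(M=7, seed=0) -> ChannelGraph:
    rng = np.random.default_rng(seed)
    return build_channel_graph(make_state(rng.normal(size=(M, 6)), seed), 3)


class TestGraphConstruction:
    def test_single_channel_is_one_self_looped_node(self):
        g = build_channel_graph(make_state(np.ones((1, 4))), 5)
        np.testing.assert_array_equal(g.adjacency, [[1.0]])
        np.testing.assert_allclose(g.normalized, [[1.0]])

    def test_identical_channels_connect_fully(self):
        g = build_channel_graph(make_state(np.ones((2, 4))), 1)
        np.testing.assert_array_equal(g.adjacency, np.ones((2, 2)))

    def test_adjacency_symmetric_with_unit_diagonal(self):
        for seed in range(5):
            g = random_graph(M=10, seed=seed)
            assert (g.adjacency == g.adjacency.T).all()
            assert (np.diag(g.adjacency) == 1.0).all()

    def test_every_node_has_degree_at_least_knn_plus_one(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            M = int(rng.integers(7, 20))
            state = make_state(rng.normal(size=(M, 5)))
            g = build_channel_graph(state, 5)
            assert (g.adjacency.sum(axis=1) >= 6).all()

    def test_normalization_is_symmetric_scaling(self):
        g = random_graph(M=6, seed=3)
        deg = g.adjacency.sum(axis=1)
        expected = g.adjacency / np.sqrt(np.outer(deg, deg))
        np.testing.assert_allclose(g.normalized, expected, atol=1e-6)


class TestGCNLayer:
    def test_isolated_self_loops_with_identity_weight_pass_through(self):
        layer = GCNLayer(3, 3, np.random.default_rng(0))
        layer.weight.data = np.eye(3, dtype=np.float32)
        H = np.random.default_rng(1).normal(size=(1, 4, 3))
        out = layer(Tensor(np.eye(4)[None]), Tensor(H))
        np.testing.assert_allclose(out.data, H, atol=1e-6)

    def test_complete_graph_with_constant_features_gives_equal_rows(self):
        layer = GCNLayer(2, 3, np.random.default_rng(0))
        adj = normalize_adjacency(np.ones((3, 3)))
        H = np.tile([1.5, -0.5], (3, 1))[None]
        out = layer(Tensor(adj[None]), Tensor(H)).data[0]
        np.testing.assert_allclose(out, np.tile(out[0], (3, 1)), atol=1e-7)

    def test_matches_naive_neighbor_aggregation(self):
        rng = np.random.default_rng(2)
        g = random_graph(M=6, seed=2)
        layer = GCNLayer(11, 4, rng)
        H = g.features
        out = layer(Tensor(g.normalized[None]), Tensor(H[None])).data[0]
        HW = H @ layer.weight.data
        naive = np.zeros_like(out)
        for i in range(6):
            for j in range(6):
                naive[i] += g.normalized[i, j] * HW[j]
        np.testing.assert_allclose(out, naive, atol=1e-5)


class TestActorCritic:
    def test_zero_weight_actor_outputs_one_half(self):
        actor = Actor(11, np.random.default_rng(0))
        for p in actor.parameters():
            p.data = np.zeros_like(p.data)
        out = actor_forward(actor, [random_graph()])
        assert out[0] == pytest.approx(0.5)

    def test_actor_output_strictly_inside_unit_interval(self):
        actor = Actor(11, np.random.default_rng(1))
        graphs = [random_graph(M=int(m), seed=int(m)) for m in
                  np.random.default_rng(2).integers(2, 30, size=200)]
        out = actor_forward(actor, graphs)
        assert np.all((out > 0.0) & (out < 1.0))

    def test_actor_invariant_to_node_relabeling(self):
        actor = Actor(11, np.random.default_rng(3))
        g = random_graph(M=12, seed=5)
        base = actor_forward(actor, [g])[0]
        rng = np.random.default_rng(6)
        for _ in range(20):
            perm = rng.permutation(12)
            gp = ChannelGraph(
                g.features[perm],
                g.adjacency[np.ix_(perm, perm)],
                g.normalized[np.ix_(perm, perm)],
            )
            assert actor_forward(actor, [gp])[0] == pytest.approx(base, abs=1e-6)

    def test_zero_weight_critic_returns_bias_only_constant(self):
        critic = Critic(11, np.random.default_rng(0))
        for name, p in critic.named_parameters():
            if name.endswith("weight"):
                p.data = np.zeros_like(p.data)
        qs = critic_forward(critic, [random_graph(seed=1), random_graph(seed=2)],
                            np.array([0.3, 0.9]))
        # with all weights zero only the chain of biases survives
        assert qs[0] == pytest.approx(qs[1])

    def test_critic_is_affine_in_action_while_relu_stays_active(self):
        critic = Critic(11, np.random.default_rng(4))
        critic.fc1.bias.data += 5.0  # keep the post-sum relu active
        g = random_graph(seed=7)
        actions = np.array([0.2, 0.4, 0.6, 0.8])
        qs = critic_forward(critic, [g] * 4, actions)
        slopes = np.diff(qs) / np.diff(actions)
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-4)
        expected_slope = (
            critic.fc2.weight.data @ critic.fc1.weight.data
            @ critic.action_fc.weight.data[:, 0]
        ).item()
        assert slopes[0] == pytest.approx(expected_slope, rel=1e-4)

    def test_critic_invariant_to_node_relabeling(self):
        critic = Critic(11, np.random.default_rng(5))
        g = random_graph(M=9, seed=8)
        base = critic_forward(critic, [g], np.array([0.5]))[0]
        perm = np.random.default_rng(9).permutation(9)
        gp = ChannelGraph(g.features[perm], g.adjacency[np.ix_(perm, perm)],
                          g.normalized[np.ix_(perm, perm)])
        assert critic_forward(critic, [gp], np.array([0.5]))[0] == pytest.approx(
            base, abs=1e-6
        )


class TestExploration:
    def test_exploration_phase_is_uniform(self):
        cfg = TD3Config(episodes=10, exploration_episodes=5, seed=0)
        actor = Actor(11, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        g = random_graph()
        draws = np.array([
            explore_action(actor, g, 3, cfg, rng) for _ in range(5000)
        ])
        stat = kstest(draws, "uniform", args=(0.2, 0.8)).pvalue
        assert stat > 0.01

    def test_zero_noise_returns_actor_output_exactly(self):
        cfg = TD3Config(episodes=10, exploration_episodes=2, delta1=0.0, seed=0)
        actor = Actor(11, np.random.default_rng(2))
        g = random_graph(seed=3)
        mu = actor_forward(actor, [g])[0]
        got = explore_action(actor, g, 8, cfg, np.random.default_rng(0))
        assert got == pytest.approx(max(0.2, min(1.0, mu)))

    def test_all_samples_respect_action_bounds(self):
        cfg = TD3Config(episodes=10, exploration_episodes=2, delta1=0.5,
                        noise_decay=1.0, seed=0)
        actor = Actor(11, np.random.default_rng(4))
        g = random_graph(seed=5)
        rng = np.random.default_rng(6)
        draws = np.array([
            explore_action(actor, g, 5, cfg, rng) for _ in range(2000)
        ])
        assert draws.min() >= 0.2 and draws.max() <= 1.0

    def test_noise_scale_decays_with_episodes(self):
        cfg = TD3Config(episodes=500, exploration_episodes=10, delta1=0.3,
                        noise_decay=0.9, seed=0)
        actor = Actor(11, np.random.default_rng(7))
        g = random_graph(seed=8)
        early = [explore_action(actor, g, 12, cfg, np.random.default_rng(s))
                 for s in range(300)]
        late = [explore_action(actor, g, 80, cfg, np.random.default_rng(s))
                for s in range(300)]
        assert np.std(late) < np.std(early) * 0.5


def _batch_from_toy(n, seed=0, reward=1.0):
    env = ToyPruningEnv(seed)
    rng = np.random.default_rng(seed)
    entries = []
    while len(entries) < n:
        _, trans = env.episode(lambda s, gi: rng.uniform(0.2, 1.0))
        for tr in trans:
            g = build_channel_graph(tr.state, 5)
            ng = build_channel_graph(tr.next_state, 5) if tr.next_state else None
            entries.append(BufferEntry(g, tr.action,
                                       reward if tr.terminal else 0.0,
                                       ng, tr.terminal))
    return entries[:n]


class TestTD3Update:
    def test_zero_discount_targets_equal_rewards(self):
        nets = AgentNets(11, np.random.default_rng(0))
        cfg = TD3Config(gamma=0.0, seed=0)
        batch = _batch_from_toy(16, reward=0.73)
        y = td3_targets(nets, batch, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(y, [e.reward for e in batch])

    def test_target_uses_smaller_of_the_twin_critics(self):
        nets = AgentNets(11, np.random.default_rng(0))

        class StubCritic:
            def __init__(self, value):
                self.value = value

            def __call__(self, ahat, h, a):
                return Tensor(np.full(h.shape[0], self.value))

        nets.critic1_target = StubCritic(2.0)
        nets.critic2_target = StubCritic(3.0)
        cfg = TD3Config(gamma=1.0, delta2=0.0, seed=0)
        batch = _batch_from_toy(8, reward=0.5)
        y = td3_targets(nets, batch, cfg, np.random.default_rng(0))
        for e, yi in zip(batch, y):
            assert yi == pytest.approx(e.reward + (0.0 if e.terminal else 2.0))

    def test_tau_one_soft_update_copies_online_weights(self):
        nets = AgentNets(11, np.random.default_rng(1))
        for p in nets.actor.parameters():
            p.data += 0.5
        nets.soft_update(tau=1.0)
        on = dict(nets.actor.named_parameters())
        for name, p in nets.actor_target.named_parameters():
            np.testing.assert_array_equal(p.data, on[name].data)

    def test_soft_update_is_elementwise_contraction(self):
        nets = AgentNets(11, np.random.default_rng(2))
        for p in nets.actor.parameters():
            p.data += 1.0
        on = dict(nets.actor.named_parameters())
        before = {k: np.abs(p.data - on[k].data)
                  for k, p in nets.actor_target.named_parameters()}
        nets.soft_update(tau=0.25)
        for k, p in nets.actor_target.named_parameters():
            after = np.abs(p.data - on[k].data)
            np.testing.assert_allclose(after, 0.75 * before[k], atol=1e-6)

    def test_undersized_batch_rejected(self):
        nets = AgentNets(11, np.random.default_rng(3))
        cfg = TD3Config(batch_size=64)
        with pytest.raises(ValueError, match="batch"):
            td3_update(nets, _batch_from_toy(8), cfg, 1, {},
                       np.random.default_rng(0))

    def test_update_moves_critics_toward_targets(self):
        nets = AgentNets(11, np.random.default_rng(4))
        cfg = TD3Config(batch_size=16, gamma=0.0, seed=0)
        opts = {
            "actor": Adam(nets.actor.parameters(), lr=1e-3),
            "critic1": Adam(nets.critic1.parameters(), lr=1e-3),
            "critic2": Adam(nets.critic2.parameters(), lr=1e-3),
        }
        batch = _batch_from_toy(16, reward=0.9)
        rng = np.random.default_rng(0)
        first = td3_update(nets, batch, cfg, 1, opts, rng)["critic1"]
        for step in range(2, 60):
            last = td3_update(nets, batch, cfg, step, opts, rng)["critic1"]
        assert last < first


class TestReplayBuffer:
    def test_fifo_eviction_at_capacity(self):
        buf = ReplayBuffer(3)
        for i in range(5):
            buf.push(BufferEntry(None, float(i), 0.0, None, True))
        actions = sorted(e.action for e in buf._items)
        assert actions == [2.0, 3.0, 4.0]

    def test_sampling_without_replacement(self):
        buf = ReplayBuffer(10)
        for i in range(10):
            buf.push(BufferEntry(None, float(i), 0.0, None, True))
        batch = buf.sample(10, np.random.default_rng(0))
        assert sorted(e.action for e in batch) == [float(i) for i in range(10)]

    def test_oversized_sample_rejected(self):
        buf = ReplayBuffer(10)
        buf.push(BufferEntry(None, 0.0, 0.0, None, True))
        with pytest.raises(ValueError, match="buffer"):
            buf.sample(2, np.random.default_rng(0))


class TestSearch:
    def test_pure_exploration_performs_no_gradient_updates(self):
        env = ToyPruningEnv(0)
        cfg = TD3Config(episodes=10, exploration_episodes=10, batch_size=4,
                        seed=0)
        before = Actor(11, np.random.default_rng(0))
        res = search(env, cfg)
        # fresh nets with the same seed should still match: no updates ran
        after = dict(res.nets.actor.named_parameters())
        for name, p in before.named_parameters():
            np.testing.assert_array_equal(p.data, after[name].data)
        assert len(res.history) == 10

    def test_running_best_reward_is_monotone(self):
        env = ToyPruningEnv(1)
        cfg = TD3Config(episodes=30, exploration_episodes=10, batch_size=8,
                        seed=1)
        res = search(env, cfg)
        best = [h["best_reward"] for h in res.history]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))
        assert res.best.reward == best[-1]

    def test_search_is_reproducible_given_seed(self):
        env = ToyPruningEnv(2)
        cfg = TD3Config(episodes=25, exploration_episodes=10, batch_size=8,
                        seed=5)
        a = search(ToyPruningEnv(2), cfg)
        b = search(ToyPruningEnv(2), cfg)
        assert a.best.retentions == b.best.retentions
        assert [h["reward"] for h in a.history] == [h["reward"] for h in b.history]

    def test_checkpoint_resume_matches_uninterrupted_run(self, tmp_path):
        cfg = TD3Config(episodes=20, exploration_episodes=8, batch_size=8,
                        checkpoint_every=10, seed=3)
        full = search(ToyPruningEnv(3), cfg)
        # run to the first checkpoint only, then resume
        cfg_half = TD3Config(episodes=10, exploration_episodes=8, batch_size=8,
                             checkpoint_every=10, seed=3)
        search(ToyPruningEnv(3), cfg_half, checkpoint_dir=tmp_path)
        resumed = search(ToyPruningEnv(3), cfg, checkpoint_dir=tmp_path,
                         resume=True)
        assert resumed.best.reward == pytest.approx(full.best.reward)
        assert [h["reward"] for h in resumed.history] == pytest.approx(
            [h["reward"] for h in full.history]
        )
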