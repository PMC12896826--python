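"""Graph-convolutional TD3 agent for the channel-pruning search.

Each pruning decision is observed as a channel graph: one node per input
channel of the coupling group, node features the 11 state-row entries,
edges connecting each channel to its most cosine-similar peers (by
flattened weight slice), symmetrized and self-looped.  A shared three-layer
GCN actor maps the graph to a retention rate through mean pooling and a
sigmoid; two independent GCN critics score (state, action) pairs.

Policy search follows TD3: an exploration phase of uniform random actions
fills the replay buffer, after which actions come from the actor with
truncated-Gaussian noise whose scale decays exponentially.  Updates use
clipped double-Q targets with target-policy smoothing, delayed actor
updates, and soft target tracking.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm
from sklearn.base import BaseEstimator

from .classifier import SResNetClassifier
from .nn import Linear, Module, Tensor
from .nn.layers import _fan_in_uniform
from .prune import Budget, LayerState, PruneResult, PruningEnv

_DT = np.float32  # agent-side precision


@dataclass
class ChannelGraph:
    """Node features plus (normalized) self-looped adjacency."""

    features: np.ndarray    # (M, F)
    adjacency: np.ndarray   # (M, M), symmetric 0/1, diag 1
    normalized: np.ndarray  # D^-1/2 A D^-1/2

    @property
    def n_nodes(self) -> int:
        return self.features.shape[0]


def normalize_adjacency(adj: np.ndarray) -> np.ndarray:
    deg = adj.sum(axis=1)
    dinv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    return (adj * dinv[:, None]) * dinv[None, :]


def build_channel_graph(state: LayerState, k_nn: int = 5) -> ChannelGraph:
    """k-nearest-neighbor cosine-similarity graph over channel weight
    slices, symmetrized, with self-loops."""
    slices = state.slices
    M = slices.shape[0]
    k = max(0, min(k_nn, M - 1))
    adj = np.eye(M, dtype=_DT)
    if k > 0:
        norms = np.linalg.norm(slices, axis=1)
        unit = slices / np.maximum(norms, 1e-12)[:, None]
        sim = unit @ unit.T
        np.fill_diagonal(sim, -np.inf)  # exclude self from neighbor pick
        nbrs = np.argpartition(-sim, kth=k - 1, axis=1)[:, :k]
        rows = np.repeat(np.arange(M), k)
        adj[rows, nbrs.reshape(-1)] = 1.0
        adj = np.maximum(adj, adj.T)
    return ChannelGraph(
        features=state.scaled_rows.astype(_DT),
        adjacency=adj,
        normalized=normalize_adjacency(adj).astype(_DT),
    )


class GCNLayer(Module):
    """H' = activation(Ahat @ H @ W)."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        super().__init__()
        self.weight = _fan_in_uniform(rng, (in_features, out_features),
                                      in_features, dtype=_DT)

    def __call__(self, ahat: Tensor, h: Tensor) -> Tensor:
        return ahat @ (h @ self.weight)


class Actor(Module):
    """GCN(11->400) -> GCN(400->300) -> GCN(300->1) -> mean-pool -> sigmoid."""

    def __init__(self, in_features: int, rng: np.random.Generator,
                 hidden: tuple[int, int] = (400, 300)):
        super().__init__()
        self.g1 = GCNLayer(in_features, hidden[0], rng)
        self.g2 = GCNLayer(hidden[0], hidden[1], rng)
        self.g3 = GCNLayer(hidden[1], 1, rng)

    def __call__(self, ahat: Tensor, h: Tensor) -> Tensor:
        """Batched forward: ahat (n, M, M), h (n, M, F) -> actions (n,)."""
        z = self.g1(ahat, h).relu()
        z = self.g2(ahat, z).relu()
        z = self.g3(ahat, z)              # (n, M, 1)
        pooled = z.mean(axis=1)           # (n, 1)
        return pooled.sigmoid().reshape(-1)


class Critic(Module):
    """GCN state branch and affine action branch fused by elementwise sum."""

    def __init__(self, in_features: int, rng: np.random.Generator,
                 hidden: tuple[int, int] = (400, 300)):
        super().__init__()
        self.g1 = GCNLayer(in_features, hidden[0], rng)
        self.action_fc = Linear(1, hidden[0], rng, dtype=_DT)
        self.fc1 = Linear(hidden[0], hidden[1], rng, dtype=_DT)
        self.fc2 = Linear(hidden[1], 1, rng, dtype=_DT)

    def __call__(self, ahat: Tensor, h: Tensor, action: Tensor) -> Tensor:
        """ahat (n, M, M), h (n, M, F), action (n,) -> Q (n,)."""
        s = self.g1(ahat, h).relu().mean(axis=1)       # (n, hidden0)
        a = self.action_fc(action.reshape(-1, 1))      # (n, hidden0)
        q = self.fc1(s + a).relu()
        return self.fc2(q).reshape(-1)


@dataclass(frozen=True)
class TD3Config:
    """TD3 search hyperparameters.

    episodes/exploration_episodes, the retention bounds (a, b) = (r_min, 1),
    the soft-update coefficient tau = 0.01, mini-batch 64 and both learning
    rates 0.001 follow the reference compression setup; the discount, noise
    scales, buffer capacity and decay rate are documented package defaults.
    """

    episodes: int = 600
    exploration_episodes: int = 100
    gamma: float = 0.99
    delta1: float = 0.25
    delta2: float = 0.1
    action_low: float = 0.2
    action_high: float = 1.0
    tau: float = 0.01
    batch_size: int = 64
    policy_delay: int = 2
    buffer_capacity: int = 10_000
    noise_decay: float = 0.99
    actor_lr: float = 0.001
    critic_lr: float = 0.001
    k_nn: int = 5
    checkpoint_every: int = 50
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.exploration_episodes <= self.episodes:
            raise ValueError("need 0 <= exploration_episodes <= episodes")
        if not self.action_low < self.action_high:
            raise ValueError("action bounds must satisfy a < b")


@dataclass
class BufferEntry:
    graph: ChannelGraph
    action: float
    reward: float
    next_graph: ChannelGraph | None
    terminal: bool


class ReplayBuffer:
    """FIFO experience buffer with without-replacement batch sampling."""

    def __init__(self, capacity: int):
        self.capacity = capacity
        self._items: list[BufferEntry] = []
        self._next = 0

    def push(self, entry: BufferEntry) -> None:
        if len(self._items) < self.capacity:
            self._items.append(entry)
        else:  # overwrite oldest
            self._items[self._next] = entry
            self._next = (self._next + 1) % self.capacity

    def sample(self, n: int, rng: np.random.Generator) -> list[BufferEntry]:
        if n > len(self._items):
            raise ValueError(f"buffer holds {len(self._items)} < batch {n}")
        idx = rng.choice(len(self._items), size=n, replace=False)
        return [self._items[i] for i in idx]

    def __len__(self) -> int:
        return len(self._items)


class AgentNets:
    """Actor, twin critics, and their target copies."""

    def __init__(self, in_features: int, rng: np.random.Generator):
        self.actor = Actor(in_features, rng)
        self.critic1 = Critic(in_features, rng)
        self.critic2 = Critic(in_features, rng)
        self.actor_target = Actor(in_features, rng)
        self.critic1_target = Critic(in_features, rng)
        self.critic2_target = Critic(in_features, rng)
        for online, target in self.target_pairs():
            target.load_state_dict(online.state_dict())

    def target_pairs(self):
        return [
            (self.actor, self.actor_target),
            (self.critic1, self.critic1_target),
            (self.critic2, self.critic2_target),
        ]

    def soft_update(self, tau: float) -> None:
        for online, target in self.target_pairs():
            op = dict(online.named_parameters())
            for name, p in target.named_parameters():
                p.data = tau * op[name].data + (1 - tau) * p.data

    def state_dict(self):
        return {
            "actor": self.actor.state_dict(),
            "critic1": self.critic1.state_dict(),
            "critic2": self.critic2.state_dict(),
            "actor_target": self.actor_target.state_dict(),
            "critic1_target": self.critic1_target.state_dict(),
            "critic2_target": self.critic2_target.state_dict(),
        }

    def load_state_dict(self, state) -> None:
        self.actor.load_state_dict(state["actor"])
        self.critic1.load_state_dict(state["critic1"])
        self.critic2.load_state_dict(state["critic2"])
        self.actor_target.load_state_dict(state["actor_target"])
        self.critic1_target.load_state_dict(state["critic1_target"])
        self.critic2_target.load_state_dict(state["critic2_target"])


def _stack(graphs: list[ChannelGraph]) -> list[tuple[np.ndarray, Tensor, Tensor]]:
    """Group graphs by node count and stack into batched tensors.

    Returns (original indices, Ahat (n, M, M), H (n, M, F)) per group.
    """
    by_m: dict[int, list[int]] = {}
    for i, g in enumerate(graphs):
        by_m.setdefault(g.n_nodes, []).append(i)
    out = []
    for m, idx in by_m.items():
        ahat = Tensor(np.stack([graphs[i].normalized for i in idx]))
        h = Tensor(np.stack([graphs[i].features for i in idx]))
        out.append((np.array(idx), ahat, h))
    return out


def actor_forward(actor: Actor, graphs: list[ChannelGraph]) -> np.ndarray:
    """Deterministic actor outputs for a list of graphs (no gradients kept)."""
    out = np.empty(len(graphs), dtype=np.float64)
    for idx, ahat, h in _stack(graphs):
        out[idx] = actor(ahat, h).data
    return out


def critic_forward(critic: Critic, graphs: list[ChannelGraph],
                   actions: np.ndarray) -> np.ndarray:
    out = np.empty(len(graphs), dtype=np.float64)
    for idx, ahat, h in _stack(graphs):
        a = Tensor(np.asarray(actions, dtype=_DT)[idx])
        out[idx] = critic(ahat, h, a).data
    return out


def explore_action(
    actor: Actor,
    graph: ChannelGraph,
    episode: int,
    cfg: TD3Config,
    rng: np.random.Generator,
) -> float:
    """Uniform during exploration; afterwards truncated-Gaussian around the
    actor output with exponentially decaying scale."""
    a, b = cfg.action_low, cfg.action_high
    if episode <= cfg.exploration_episodes:
        return float(rng.uniform(a, b))
    mu = float(actor_forward(actor, [graph])[0])
    mu = min(max(mu, a), b)
    std = cfg.delta1 * cfg.noise_decay ** (episode - cfg.exploration_episodes)
    if std <= 0:
        return mu
    lo, hi = (a - mu) / std, (b - mu) / std
    return float(truncnorm.rvs(lo, hi, loc=mu, scale=std, random_state=rng))


def td3_targets(
    nets: AgentNets,
    batch: list[BufferEntry],
    cfg: TD3Config,
    rng: np.random.Generator,
) -> np.ndarray:
    """Clipped double-Q regression targets for a batch.

    y = r + gamma * min(Q1', Q2') evaluated at the smoothed target action
    clip(actor'(S') + eps, a, b); the bootstrap term is dropped at terminal
    transitions (finite-horizon episodes).
    """
    y = np.array([e.reward for e in batch], dtype=np.float64)
    nonterm = [i for i, e in enumerate(batch) if not e.terminal]
    if nonterm and cfg.gamma != 0.0:
        next_graphs = [batch[i].next_graph for i in nonterm]
        a_next = actor_forward(nets.actor_target, next_graphs)
        noise = rng.normal(0.0, cfg.delta2, size=len(nonterm))
        a_next = np.clip(a_next + noise, cfg.action_low, cfg.action_high)
        q1 = critic_forward(nets.critic1_target, next_graphs, a_next)
        q2 = critic_forward(nets.critic2_target, next_graphs, a_next)
        y[nonterm] += cfg.gamma * np.minimum(q1, q2)
    return y


def td3_update(
    nets: AgentNets,
    batch: list[BufferEntry],
    cfg: TD3Config,
    step: int,
    optimizers: dict,
    rng: np.random.Generator,
) -> dict:
    """One TD3 gradient step on a sampled batch.

    Clipped double-Q targets with smoothed target actions; both critics
    regressed to the shared target; actor and target networks updated every
    ``policy_delay`` steps.  Returns the losses.
    """
    if len(batch) < cfg.batch_size:
        raise ValueError(f"batch of {len(batch)} < configured {cfg.batch_size}")

    y = td3_targets(nets, batch, cfg, rng)
    graphs = [e.graph for e in batch]
    actions = np.array([e.action for e in batch], dtype=_DT)
    losses = {}
    for name, critic in (("critic1", nets.critic1), ("critic2", nets.critic2)):
        critic.zero_grad()
        total = None
        for idx, ahat, h in _stack(graphs):
            q = critic(ahat, h, Tensor(actions[idx]))
            err = (q - Tensor(y[idx].astype(_DT))) ** 2.0
            part = err.sum() * (1.0 / len(batch))
            total = part if total is None else total + part
        total.backward()
        optimizers[name].step()
        losses[name] = float(total.data)

    if step % cfg.policy_delay == 0:
        nets.actor.zero_grad()
        nets.critic1.zero_grad()
        total = None
        for idx, ahat, h in _stack(graphs):
            act = nets.actor(ahat, h)
            q = nets.critic1(ahat, h, act)
            part = q.sum() * (-1.0 / len(batch))
            total = part if total is None else total + part
        total.backward()
        optimizers["actor"].step()
        nets.critic1.zero_grad()  # drop critic grads from the policy pass
        losses["actor"] = float(total.data)
        nets.soft_update(cfg.tau)
    return losses


@dataclass
class SearchResult:
    best: PruneResult
    best_episode: int
    history: list[dict]
    nets: AgentNets


def search(
    env: PruningEnv,
    cfg: TD3Config = TD3Config(),
    checkpoint_dir: str | Path | None = None,
    resume: bool = False,
) -> SearchResult:
    """Run the full exploration/exploitation pruning-strategy search.

    Returns the best-reward episode's PruneResult plus a per-episode
    history; fully deterministic given ``cfg.seed``.
    """
    from .nn import Adam

    rng = np.random.default_rng(cfg.seed)
    n_features = 11
    nets = AgentNets(n_features, rng)
    buffer = ReplayBuffer(cfg.buffer_capacity)
    optimizers = {
        "actor": Adam(nets.actor.parameters(), lr=cfg.actor_lr),
        "critic1": Adam(nets.critic1.parameters(), lr=cfg.critic_lr),
        "critic2": Adam(nets.critic2.parameters(), lr=cfg.critic_lr),
    }
    start_episode, best, best_episode, history = 1, None, -1, []
    update_step = 0

    ckpt = Path(checkpoint_dir) / "search_ckpt.pkl" if checkpoint_dir else None
    if resume and ckpt and ckpt.exists():
        state = pickle.loads(ckpt.read_bytes())
        nets.load_state_dict(state["nets"])
        rng.bit_generator.state = state["rng_state"]
        start_episode = state["episode"] + 1
        best, best_episode = state["best"], state["best_episode"]
        history = state["history"]
        update_step = state["update_step"]
        buffer = state["buffer"]

    for t in range(start_episode, cfg.episodes + 1):
        graphs: dict[int, ChannelGraph] = {}

        def policy(state: LayerState, gi: int) -> float:
            g = build_channel_graph(state, cfg.k_nn)
            graphs[id(state)] = g
            return explore_action(nets.actor, g, t, cfg, rng)

        result, transitions = env.episode(policy)
        for tr in transitions:
            buffer.push(BufferEntry(
                graph=graphs[id(tr.state)],
                action=tr.action,
                reward=tr.reward,
                next_graph=graphs.get(id(tr.next_state)),
                terminal=tr.terminal,
            ))
        if best is None or result.reward > best.reward:
            best, best_episode = result, t
        history.append({
            "episode": t,
            "retentions": [round(r, 4) for r in result.retentions],
            "reward": result.reward,
            "mac_ratio": result.mac_ratio,
            "best_reward": best.reward,
        })
        if t > cfg.exploration_episodes and len(buffer) >= cfg.batch_size:
            update_step += 1
            td3_update(nets, buffer.sample(cfg.batch_size, rng), cfg,
                       update_step, optimizers, rng)
        if ckpt and t % cfg.checkpoint_every == 0:
            ckpt.parent.mkdir(parents=True, exist_ok=True)
            ckpt.write_bytes(pickle.dumps({
                "nets": nets.state_dict(),
                "rng_state": rng.bit_generator.state,
                "episode": t,
                "best": best,
                "best_episode": best_episode,
                "history": history,
                "update_step": update_step,
                "buffer": buffer,
            }))
    return SearchResult(best=best, best_episode=best_episode,
                        history=history, nets=nets)


class TD3ChannelPruner(BaseEstimator):
    """scikit-learn-style wrapper: fit(X, y) runs the pruning search.

    X, y are the held-out frames used for the terminal accuracy reward
    (never the training partition).  After fitting, ``result_`` holds the
    best strategy, ``pruned_classifier_`` a classifier shell around the
    pruned network (fine-tune it with its ``finetune`` method).
    """

    def __init__(
        self,
        classifier: SResNetClassifier | None = None,
        r_target: float = 0.5,
        r_min: float = 0.2,
        episodes: int = 600,
        exploration_episodes: int = 100,
        reward_scale: float = 0.01,
        eval_subsample: int | None = None,
        k_nn: int = 5,
        random_state: int | None = None,
    ):
        self.classifier = classifier
        self.r_target = r_target
        self.r_min = r_min
        self.episodes = episodes
        self.exploration_episodes = exploration_episodes
        self.reward_scale = reward_scale
        self.eval_subsample = eval_subsample
        self.k_nn = k_nn
        self.random_state = random_state

    def fit(self, X, y):
        if self.classifier is None or not hasattr(self.classifier, "network_"):
            raise ValueError("TD3ChannelPruner needs a fitted SResNetClassifier")
        env = PruningEnv(
            self.classifier,
            Budget(self.r_target, self.r_min),
            eval_X=X, eval_y=y,
            reward_scale=self.reward_scale,
            eval_subsample=self.eval_subsample,
            seed=self.random_state,
        )
        cfg = TD3Config(
            episodes=self.episodes,
            exploration_episodes=self.exploration_episodes,
            action_low=self.r_min,
            k_nn=self.k_nn,
            seed=self.random_state,
        )
        search_result = search(env, cfg)
        self.search_result_ = search_result
        self.result_ = search_result.best
        self.best_retentions_ = search_result.best.retentions
        self.history_ = search_result.history
        pruned_net = env.rebuild(search_result.best)
        self.pruned_classifier_ = self.classifier.copy_with_network(pruned_net)
        return self
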