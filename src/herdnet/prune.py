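"""Structured channel pruning of S-ResNet as a Markov decision process.

Pruning proceeds over five *coupling groups* — sets of layers whose channel
dimensions must change together because of the residual wiring.  Each group
is one decision: the agent picks a retention rate R_l in [r_min, 1], the
ceil(R_l * c_in) input channels with the largest L2 weight norm are kept,
and the matching producer filters (plus biases and batch-norm rows) are
removed.  conv1's input is the raw frame and is excluded from pruning; the
two residual adds tie the main-path and shortcut producers, which are
pruned jointly.

A MAC budget (pruned/original <= R_target) is enforced by clamping each
action to the largest retention that still leaves the budget reachable when
every remaining group is pruned to the floor, so a finished episode can
never exceed the target.

The per-group observation follows the per-channel state-row layout
[l, t, c_in, c_out, stride, k, Wprod_m, Wnorm_m, reduced, rest, R_prev]:
one row per input channel, static architecture fields plus the channel's
parameter count and L2 norm, the MACs removed so far, the MACs of layers
still awaiting a decision, and the previous action.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .classifier import SResNetClassifier
from .model import MacReport, ModelSpec, SResNet, count_macs, layer_macs

#: Decision-group wiring for the S-ResNet family.  ``consumers`` lose input
#: channels; ``producers`` lose the matching output filters.  The residual
#: adds force joint producers in groups 3 and 5.
GROUP_WIRING = [
    (["b1_conv_a", "b1_shortcut"], ["conv1"]),
    (["b1_conv_b"], ["b1_conv_a"]),
    (["b2_conv_a", "b2_shortcut"], ["b1_conv_b", "b1_shortcut"]),
    (["b2_conv_b"], ["b2_conv_a"]),
    (["fc1"], ["b2_conv_b", "b2_shortcut"]),
]

#: with_widths() keyword controlled by each group's kept count.
GROUP_WIDTH_KEY = ["conv1", "block1_mid", "block1_out", "block2_mid", "block2_out"]


@dataclass(frozen=True)
class CouplingGroup:
    index: int  # 1-based decision index
    consumers: tuple[str, ...]
    producers: tuple[str, ...]
    c_in: int  # input-channel count of the consumers at decision time


@dataclass(frozen=True)
class Budget:
    """MAC budget: pruned/original <= r_target, per-group retention >= r_min."""

    r_target: float
    r_min: float = 0.2

    def __post_init__(self):
        if not 0.0 < self.r_target <= 1.0:
            raise ValueError("r_target must lie in (0, 1]")
        if not 0.0 < self.r_min <= 1.0:
            raise ValueError("r_min must lie in (0, 1]")


@dataclass
class LayerState:
    """Observation for one pruning decision."""

    group: CouplingGroup
    rows: np.ndarray          # (M, 11) raw state rows
    scaled_rows: np.ndarray   # (M, 11) min-max scaled per column
    slices: np.ndarray        # (M, D) flattened per-channel weight slices

    @property
    def n_channels(self) -> int:
        return self.rows.shape[0]


@dataclass
class Transition:
    state: LayerState
    action: float
    reward: float
    next_state: LayerState | None
    terminal: bool


@dataclass
class PruneResult:
    retentions: list[float]
    kept_indices: list[np.ndarray]
    spec: ModelSpec
    macs_before: MacReport
    macs_after: MacReport
    reward: float
    accuracy: float | None
    finetuned_accuracy: float | None = None

    @property
    def mac_ratio(self) -> float:
        return self.macs_after.total / self.macs_before.total

    def to_json(self) -> str:
        return json.dumps(
            {
                "retentions": self.retentions,
                "kept_indices": [k.tolist() for k in self.kept_indices],
                "spec": json.loads(self.spec.to_json()),
                "macs_before": self.macs_before.total,
                "macs_after": self.macs_after.total,
                "mac_ratio": self.mac_ratio,
                "reward": self.reward,
                "accuracy": self.accuracy,
                "finetuned_accuracy": self.finetuned_accuracy,
            },
            indent=2,
        )


def coupling_groups(spec: ModelSpec) -> list[CouplingGroup]:
    """The five pruning decisions of an S-ResNet spec, in network order."""
    groups = []
    for i, (consumers, producers) in enumerate(GROUP_WIRING, start=1):
        try:
            widths = {spec.layer(c).in_channels for c in consumers}
        except KeyError as e:  # pragma: no cover - guarded by ModelSpec
            raise ValueError(f"spec lacks residual structure: missing {e}")
        if len(widths) != 1:
            raise ValueError(
                f"group {i}: consumers {consumers} disagree on in_channels"
            )
        groups.append(
            CouplingGroup(i, tuple(consumers), tuple(producers), widths.pop())
        )
    return groups


def _channel_slices(net: SResNet, group: CouplingGroup) -> np.ndarray:
    """Flattened per-input-channel weight slices, concatenated over the
    group's consumers: shape (c_in, total_slice_size)."""
    parts = []
    for name in group.consumers:
        w = getattr(net, name).weight.data
        if w.ndim == 3:  # conv: (out, in, k) -> (in, out*k)
            parts.append(w.transpose(1, 0, 2).reshape(w.shape[1], -1))
        else:  # fc: (out, in) -> (in, out)
            parts.append(w.T)
    return np.concatenate(parts, axis=1)


def channel_importance(group: CouplingGroup, net: SResNet) -> np.ndarray:
    """L2 norm of each input channel's weight slices across all consumers."""
    return np.linalg.norm(_channel_slices(net, group), axis=1)


def kept_count(r: float, c_in: int, r_min: float) -> int:
    """ceil(R * c_in), floored at ceil(r_min * c_in) and capped at c_in."""
    return min(c_in, max(math.ceil(r * c_in), math.ceil(r_min * c_in)))


def top_channels(scores: np.ndarray, n_keep: int) -> np.ndarray:
    """Indices (sorted ascending) of the n_keep highest scores; ties go to
    the lower channel index for reproducibility."""
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:n_keep])


def clone_network(net: SResNet) -> SResNet:
    fresh = SResNet(net.spec, np.random.default_rng(0),
                    head_relu=net.head_relu, dtype=net.dtype)
    fresh.load_state_dict(net.state_dict())
    fresh.train(net.training)
    return fresh


def _apply_prune(net: SResNet, group: CouplingGroup, keep: np.ndarray) -> None:
    """In-place surgery: slice consumer inputs and producer outputs."""
    for name in group.consumers:
        layer = getattr(net, name)
        w = layer.weight
        w.data = w.data[:, keep, :] if w.data.ndim == 3 else w.data[:, keep]
        if hasattr(layer, "in_channels"):
            layer.in_channels = len(keep)
        if hasattr(layer, "in_features"):
            layer.in_features = len(keep)
    for name in group.producers:
        layer = getattr(net, name)
        layer.weight.data = layer.weight.data[keep]
        if layer.bias is not None:
            layer.bias.data = layer.bias.data[keep]
        layer.out_channels = len(keep)
        bn = getattr(net, name + "_bn", None)
        if bn is not None:
            bn.gamma.data = bn.gamma.data[keep]
            bn.beta.data = bn.beta.data[keep]
            bn.running_mean = bn.running_mean[keep]
            bn.running_var = bn.running_var[keep]
            bn.channels = len(keep)
    net.spec = net.spec.with_widths(
        **{GROUP_WIDTH_KEY[group.index - 1]: len(keep)}
    )


def prune_group(
    net: SResNet, group: CouplingGroup, r: float, r_min: float = 0.2
) -> tuple[SResNet, np.ndarray]:
    """Prune one coupling group at retention ``r`` on a copy of ``net``.

    Returns the pruned network and the kept channel indices.  With r = 1
    every array is left bit-identical (kept indices are sorted), so the
    network function is unchanged.
    """
    if not r_min <= r <= 1.0 + 1e-12:
        raise ValueError(f"retention {r} outside [{r_min}, 1]")
    n_keep = kept_count(r, group.c_in, r_min)
    if n_keep < 1:
        raise ValueError("pruning would leave zero channels")
    keep = top_channels(channel_importance(group, net), n_keep)
    out = clone_network(net)
    _apply_prune(out, group, keep)
    return out, keep


class PruningEnv:
    """Episode engine: state construction, budget clamping, reward.

    Parameters
    ----------
    classifier : fitted SResNetClassifier to prune.
    budget : MAC budget (r_target, r_min).
    eval_X, eval_y : held-out frames for the terminal accuracy reward;
        may be None, in which case rewards are 0 (useful for pure budget
        exercises).
    reward_scale : terminal reward = accuracy * reward_scale (0.01 default;
        0.1 is the alternative convention).
    eval_subsample : cap on reward-evaluation frames (deterministically
        subsampled once) to keep episode cost bounded.
    """

    def __init__(
        self,
        classifier: SResNetClassifier,
        budget: Budget,
        eval_X: np.ndarray | None = None,
        eval_y: np.ndarray | None = None,
        reward_scale: float = 0.01,
        eval_subsample: int | None = None,
        seed: int | None = None,
    ):
        self.clf = classifier
        self.budget = budget
        self.reward_scale = reward_scale
        self.spec0 = classifier.spec_
        self.groups = coupling_groups(self.spec0)
        self.original_macs = count_macs(self.spec0).total
        if eval_X is not None:
            eval_X = np.asarray(eval_X, dtype=float)
            eval_y = np.asarray(eval_y)
            if eval_subsample is not None and len(eval_X) > eval_subsample:
                idx = np.random.default_rng(seed).choice(
                    len(eval_X), size=eval_subsample, replace=False
                )
                eval_X, eval_y = eval_X[idx], eval_y[idx]
        self.eval_X, self.eval_y = eval_X, eval_y
        self._check_feasible()
        self._static_scale = self._static_column_ranges()

    # -- MAC bookkeeping -------------------------------------------------
    def _min_keep(self, gi: int) -> int:
        c = self.groups[gi].c_in
        return kept_count(self.budget.r_min, c, self.budget.r_min)

    def _total_macs(self, kept: dict[int, int]) -> int:
        """Total MACs with decided groups at their kept counts and the rest
        at full width (kept maps 0-based group index -> kept count)."""
        widths = {
            GROUP_WIDTH_KEY[i]: kept.get(i, self.groups[i].c_in)
            for i in range(len(self.groups))
        }
        return count_macs(self.spec0.with_widths(
            conv1=widths["conv1"], block1_mid=widths["block1_mid"],
            block1_out=widths["block1_out"], block2_mid=widths["block2_mid"],
            block2_out=widths["block2_out"],
        )).total

    def _check_feasible(self) -> None:
        all_min = {i: self._min_keep(i) for i in range(len(self.groups))}
        floor = self._total_macs(all_min)
        limit = self.budget.r_target * self.original_macs
        if floor > limit:
            raise ValueError(
                f"budget infeasible: even at minimum retention "
                f"{self.budget.r_min} the model needs {floor} MACs "
                f"> target {limit:.0f}"
            )

    def feasible_action(self, kept: dict[int, int], gi: int, proposed: float) -> float:
        """Clamp the proposed retention for group ``gi`` so the budget stays
        reachable with all later groups at the floor."""
        group = self.groups[gi]
        limit = self.budget.r_target * self.original_macs
        later_min = {j: self._min_keep(j) for j in range(gi + 1, len(self.groups))}
        lo, hi = self._min_keep(gi), group.c_in
        # largest kept count still within reach (total is monotone in k)
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if self._total_macs({**kept, gi: mid, **later_min}) <= limit:
                lo = mid
            else:
                hi = mid - 1
        r_max = lo / group.c_in
        r = min(max(proposed, self.budget.r_min), r_max)
        # keep the executed action consistent with the kept count it induces
        return min(r, 1.0)

    # -- state construction ----------------------------------------------
    def _static_column_ranges(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-episode min/max of the six static columns over all groups."""
        rows = []
        for g in self.groups:
            first = self.spec0.layer(g.consumers[0])
            rows.append([
                g.index,
                0.0 if first.kind == "conv1d" else 1.0,
                g.c_in,
                first.out_channels,
                first.stride,
                first.kernel if first.kind == "conv1d" else 1,
            ])
        rows = np.asarray(rows, dtype=float)
        return rows.min(axis=0), rows.max(axis=0)

    def layer_state(
        self,
        net: SResNet,
        gi: int,
        reduced: float,
        rest: float,
        r_prev: float,
    ) -> LayerState:
        group = self.groups[gi]
        slices = _channel_slices(net, group)
        wprod = np.full(len(slices), float(slices.shape[1]))
        wnorm = np.linalg.norm(slices, axis=1)
        first = net.spec.layer(group.consumers[0])
        static = np.array([
            group.index,
            0.0 if first.kind == "conv1d" else 1.0,
            group.c_in,
            first.out_channels,
            first.stride,
            first.kernel if first.kind == "conv1d" else 1,
        ], dtype=float)
        M = len(slices)
        rows = np.column_stack([
            np.tile(static, (M, 1)),
            wprod,
            wnorm,
            np.full(M, reduced),
            np.full(M, rest),
            np.full(M, r_prev),
        ])
        scaled = rows.copy()
        lo, hi = self._static_scale
        span = np.where(hi > lo, hi - lo, 1.0)
        scaled[:, :6] = (rows[:, :6] - lo) / span
        for j in (6, 7):  # per-layer min-max of the channel columns
            cmin, cmax = rows[:, j].min(), rows[:, j].max()
            scaled[:, j] = 0.0 if cmax == cmin else (rows[:, j] - cmin) / (cmax - cmin)
        scaled[:, 8] = reduced / self.original_macs
        scaled[:, 9] = rest / self.original_macs
        return LayerState(group, rows, scaled, slices)

    def _rest_macs(self, kept: dict[int, int], gi: int) -> float:
        """MACs of consumers of groups after ``gi`` at current widths."""
        widths = {
            GROUP_WIDTH_KEY[i]: kept.get(i, self.groups[i].c_in)
            for i in range(len(self.groups))
        }
        spec = self.spec0.with_widths(
            conv1=widths["conv1"], block1_mid=widths["block1_mid"],
            block1_out=widths["block1_out"], block2_mid=widths["block2_mid"],
            block2_out=widths["block2_out"],
        )
        total = 0
        for g in self.groups[gi + 1:]:
            total += sum(layer_macs(spec.layer(c), spec.input_length)
                         for c in g.consumers)
        return float(total)

    # -- episode -----------------------------------------------------------
    def evaluate_accuracy(self, net: SResNet) -> float:
        logits = net.predict_logits(self.eval_X)
        pred = self.clf.classes_[logits.argmax(axis=1)]
        return float(np.mean(pred == self.eval_y))

    def episode(self, policy) -> tuple[PruneResult, list[Transition]]:
        """Run one pruning episode under ``policy``.

        ``policy(state: LayerState, group_index: int) -> float`` proposes a
        retention; the environment clamps it to the feasible range before
        executing.  Returns the finished PruneResult and one Transition per
        group (reward 0 except at the terminal step).
        """
        net = clone_network(self.clf.network_)
        net.eval()
        kept: dict[int, int] = {}
        retentions: list[float] = []
        kept_idx: list[np.ndarray] = []
        states: list[LayerState] = []
        actions: list[float] = []
        r_prev = 1.0
        for gi, group in enumerate(self.groups):
            reduced = float(self.original_macs - self._total_macs(kept))
            rest = self._rest_macs(kept, gi)
            state = self.layer_state(net, gi, reduced, rest, r_prev)
            proposed = float(policy(state, gi))
            r = self.feasible_action(kept, gi, proposed)
            n_keep = kept_count(r, group.c_in, self.budget.r_min)
            keep = top_channels(channel_importance(group, net), n_keep)
            _apply_prune(net, group, keep)
            kept[gi] = n_keep
            retentions.append(n_keep / group.c_in)
            kept_idx.append(keep)
            states.append(state)
            actions.append(n_keep / group.c_in)
            r_prev = n_keep / group.c_in
        if self.eval_X is not None:
            accuracy = self.evaluate_accuracy(net)
            reward = accuracy * self.reward_scale
        else:
            accuracy, reward = None, 0.0
        transitions = [
            Transition(
                state=states[i],
                action=actions[i],
                reward=reward if i == len(states) - 1 else 0.0,
                next_state=states[i + 1] if i + 1 < len(states) else None,
                terminal=i == len(states) - 1,
            )
            for i in range(len(states))
        ]
        result = PruneResult(
            retentions=retentions,
            kept_indices=kept_idx,
            spec=net.spec,
            macs_before=count_macs(self.spec0),
            macs_after=count_macs(net.spec),
            reward=reward,
            accuracy=accuracy,
        )
        return result, transitions

    def rebuild(self, result: PruneResult) -> SResNet:
        """Re-apply a recorded pruning strategy to the original network."""
        net = clone_network(self.clf.network_)
        net.eval()
        for group, keep in zip(self.groups, result.kept_indices):
            _apply_prune(net, group, keep)
        return net
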