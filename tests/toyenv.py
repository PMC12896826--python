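"""A two-decision pruning environment with a known-optimal strategy.

The reward is a smooth concave function of the two retention rates, peaked
at (0.55, 0.35).  With 20 input channels per group, executed retentions are
multiples of 0.05, so exhaustive enumeration of the 17 x 17 action grid
yields the exact optimum that the TD3 search should recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from herdnet.prune import CouplingGroup, LayerState, Transition

C_IN = 20
OPTIMUM = (0.55, 0.35)
R_MIN = 0.2


def toy_reward(r1: float, r2: float) -> float:
    o1, o2 = OPTIMUM
    return 1.0 - ((r1 - o1) ** 2 + (r2 - o2) ** 2)


def executed_retention(action: float) -> float:
    a = min(max(action, R_MIN), 1.0)
    return math.ceil(a * C_IN) / C_IN


def grid_optimum() -> tuple[float, tuple[float, float]]:
    """Best reward over the 0.05-step retention grid (exhaustive oracle)."""
    grid = np.round(np.arange(R_MIN, 1.0 + 1e-9, 0.05), 2)
    best, arg = -np.inf, None
    for r1 in grid:
        for r2 in grid:
            v = toy_reward(r1, r2)
            if v > best:
                best, arg = v, (r1, r2)
    return best, arg


@dataclass
class ToyResult:
    retentions: list[float]
    reward: float
    mac_ratio: float


class ToyPruningEnv:
    """Duck-typed stand-in for PruningEnv with two decisions."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.slices = [rng.normal(size=(C_IN, 16)) for _ in range(2)]
        self.groups = [
            CouplingGroup(i + 1, (f"toy_consumer_{i}",), (f"toy_producer_{i}",), C_IN)
            for i in range(2)
        ]

    def _state(self, gi: int, r_prev: float) -> LayerState:
        slices = self.slices[gi]
        wnorm = np.linalg.norm(slices, axis=1)
        rows = np.column_stack([
            np.full(C_IN, gi + 1.0),
            np.zeros(C_IN),
            np.full(C_IN, float(C_IN)),
            np.full(C_IN, float(C_IN)),
            np.ones(C_IN),
            np.full(C_IN, 3.0),
            np.full(C_IN, float(slices.shape[1])),
            wnorm,
            np.full(C_IN, 0.0),
            np.full(C_IN, 1.0 - gi),
            np.full(C_IN, r_prev),
        ])
        scaled = rows.copy()
        scaled[:, 0] = gi
        span = wnorm.max() - wnorm.min()
        scaled[:, 7] = (wnorm - wnorm.min()) / (span if span else 1.0)
        return LayerState(self.groups[gi], rows, scaled, slices)

    def episode(self, policy):
        states, retentions = [], []
        r_prev = 1.0
        for gi in range(2):
            state = self._state(gi, r_prev)
            states.append(state)
            r = executed_retention(float(policy(state, gi)))
            retentions.append(r)
            r_prev = r
        reward = toy_reward(*retentions)
        transitions = [
            Transition(states[0], retentions[0], 0.0, states[1], False),
            Transition(states[1], retentions[1], reward, None, True),
        ]
        return ToyResult(retentions, reward, 1.0), transitions
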