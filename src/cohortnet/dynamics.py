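"""Synchronous Boolean dynamics on the signed network under periodic forcing.

Every node is active (1) or inactive (0). At each step, all nodes update
simultaneously: a node's input is the sum of its neighbours' edge weights
restricted to *active* neighbours (inactive neighbours contribute nothing);
the node becomes active iff that sum is strictly positive, so isolated nodes
and exact ties (sum = 0) go inactive. One designated input node is clamped to
a square wave (``half_period`` steps active, then ``half_period`` inactive)
and is exempt from both the update and the noise; every other node flips its
freshly updated state with probability ``noise_prob`` each step. The order
within one step is: synchronous update -> noise -> clamp.

Without noise a strongly coupled network tends to lock: mutually positive
neighbours sustain each other once activated, so traces saturate and pairwise
cross-correlations pile up; a small flip probability keeps states moving so
connection strength is visible in the cross-correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "StateTrace",
    "square_wave",
    "weighted_input",
    "update_step",
    "apply_noise",
    "run_forced_simulation",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one forced Boolean simulation."""

    input_node: Hashable
    steps: int = 100
    half_period: int = 10
    noise_prob: float = 0.05
    init_active_prob: float = 0.5
    input_initial_phase: str = "active"
    seed: int = 0
    # recorded so alternates are switchable / auditable
    step_order: str = "update-noise-clamp"

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.half_period < 1:
            raise ValueError("half_period must be >= 1")
        if not (0.0 <= self.noise_prob <= 1.0):
            raise ValueError("noise_prob must lie in [0, 1]")
        if not (0.0 <= self.init_active_prob <= 1.0):
            raise ValueError("init_active_prob must lie in [0, 1]")
        if self.input_initial_phase not in ("active", "inactive"):
            raise ValueError("input_initial_phase must be 'active' or 'inactive'")

    def with_input(self, node: Hashable, seed: int | None = None) -> "SimulationConfig":
        return replace(self, input_node=node, seed=self.seed if seed is None else seed)


def square_wave(t: int, half_period: int, initial_phase: str = "active") -> int:
    """Clamp value of the input node at step ``t`` (0-based)."""
    phase_active = (t // half_period) % 2 == 0
    if initial_phase == "inactive":
        phase_active = not phase_active
    return int(phase_active)


def weighted_input(states: Mapping[Hashable, int], net: nx.Graph) -> dict[Hashable, float]:
    """Signed weighted sum of active-neighbour contributions, per node."""
    return {
        v: float(sum(net[v][u].get("weight", 1.0) * states[u] for u in net[v]))
        for v in net.nodes
    }


def update_step(states: Mapping[Hashable, int], net: nx.Graph) -> dict[Hashable, int]:
    """One synchronous threshold update: active iff weighted input > 0."""
    s = weighted_input(states, net)
    return {v: int(s[v] > 0.0) for v in net.nodes}


def apply_noise(
    states: Mapping[Hashable, int],
    noise_prob: float,
    rng: np.random.Generator,
    exempt: Hashable | None = None,
) -> dict[Hashable, int]:
    """Flip each state with probability ``noise_prob``; ``exempt`` is untouched."""
    out = dict(states)
    for v in out:
        if v == exempt:
            continue
        if rng.random() < noise_prob:
            out[v] = 1 - out[v]
    return out


@dataclass
class StateTrace:
    """Nodes x time binary activity matrix from one forced simulation."""

    nodes: tuple
    states: np.ndarray  # (n_nodes, steps), values in {0, 1}
    config: SimulationConfig

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.nodes)}

    def series(self, node: Hashable) -> np.ndarray:
        return self.states[self._index[node]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.states,
            index=pd.Index(list(self.nodes), name="node"),
            columns=pd.RangeIndex(self.states.shape[1], name="step"),
        )


def run_forced_simulation(net: nx.Graph, cfg: SimulationConfig) -> StateTrace:
    """Run one forced Boolean simulation; deterministic given ``cfg.seed``.

    States are initialised independently active with probability
    ``init_active_prob`` (the input node is clamped from step 0); the recorded
    trace has exactly ``cfg.steps`` columns and its input row equals the
    square wave regardless of noise.
    """
    nodes = tuple(net.nodes)
    if cfg.input_node not in net:
        raise KeyError(f"input node {cfg.input_node!r} not in network")
    i_in = nodes.index(cfg.input_node)
    n = len(nodes)
    w = nx.to_numpy_array(net, nodelist=nodes, weight="weight")

    rng = np.random.default_rng(cfg.seed)
    s = (rng.random(n) < cfg.init_active_prob).astype(np.int8)
    s[i_in] = square_wave(0, cfg.half_period, cfg.input_initial_phase)

    trace = np.empty((n, cfg.steps), dtype=np.int8)
    trace[:, 0] = s
    for t in range(1, cfg.steps):
        nxt = (w @ s > 0.0).astype(np.int8)
        flips = rng.random(n) < cfg.noise_prob
        nxt = np.where(flips, 1 - nxt, nxt).astype(np.int8)
        nxt[i_in] = square_wave(t, cfg.half_period, cfg.input_initial_phase)
        s = nxt
        trace[:, t] = s
    return StateTrace(nodes=nodes, states=trace, config=cfg)
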