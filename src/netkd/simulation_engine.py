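"""Deterministic synchronous discrete-state network dynamics.

Every node holds an integer expression level (normally 0-9; scenario
overrides may start higher). At each global step all nodes update in
parallel:

    delta(n) = sum over incoming edges (s -> n) of weight(e) * active(s)
    next(n)  = clamp(level(n) + delta(n), 0, max(9, level(n)))

where active(s) is 1 if level(s) exceeds the activity threshold (default 0)
in indicator mode, or level(s)/9 in level-scaled mode. The degradation
self-loop contributes exactly -1 whenever the node's own level is positive,
so an unsupported signal fades by one level per step. The upper clamp
max(9, current) lets override values above 9 decay naturally instead of
snapping to 9; levels never grow beyond 9.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, TYPE_CHECKING

import numpy as np
import pandas as pd

from .network_model import EdgeKind, PathwayNetwork

if TYPE_CHECKING:
    from .scenarios import ScenarioConfig

__all__ = [
    "LEVEL_MAX",
    "UpdateKernel",
    "Trajectory",
    "step",
    "run_simulation",
    "detect_steady_state",
]

LEVEL_MAX = 9


@dataclass(frozen=True)
class UpdateKernel:
    """Update-rule variant: how a source's level turns into influence.

    mode='indicator' (default): a source is fully active iff its level is
    above ``activity_threshold``. mode='level_scaled': influence scales
    linearly with level/9 (fractional deltas rounded half away from zero);
    provided for sensitivity analysis.
    """

    mode: str = "indicator"
    activity_threshold: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("indicator", "level_scaled"):
            raise ValueError(f"unknown kernel mode {self.mode!r}")

    def activity(self, level: int) -> float:
        if self.mode == "indicator":
            return 1.0 if level > self.activity_threshold else 0.0
        return level / LEVEL_MAX


class Trajectory:
    """Node x step matrix of simulated levels; column t = state after t
    synchronous updates (column 0 = initial state)."""

    def __init__(self, frame: pd.DataFrame, name: str = "trajectory") -> None:
        self.frame = frame
        self.name = name

    @classmethod
    def from_states(cls, states: list[Mapping[str, int]],
                    name: str = "trajectory") -> "Trajectory":
        nodes = sorted(states[0])
        data = {f"step_{t}": [s[n] for n in nodes]
                for t, s in enumerate(states)}
        return cls(pd.DataFrame(data, index=nodes, dtype=int), name)

    @property
    def node_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def step_count(self) -> int:
        return self.frame.shape[1] - 1

    def state(self, t: int) -> dict[str, int]:
        return self.frame[f"step_{t}"].to_dict()

    def series(self, node_id: str) -> np.ndarray:
        if node_id not in self.frame.index:
            raise KeyError(f"node {node_id!r} not in trajectory")
        return self.frame.loc[node_id].to_numpy()

    def level(self, node_id: str, t: int) -> int:
        return int(self.frame.at[node_id, f"step_{t}"])

    def to_csv(self, path: str) -> None:
        self.frame.to_csv(path, index_label="node", lineterminator="\n")

    @classmethod
    def read_csv(cls, path: str, name: str | None = None) -> "Trajectory":
        frame = pd.read_csv(path, index_col="node").astype(int)
        return cls(frame, name or str(path))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trajectory):
            return NotImplemented
        return self.frame.equals(other.frame)

    def __repr__(self) -> str:
        return (f"Trajectory({self.name!r}, {len(self.frame)} nodes, "
                f"{self.step_count} steps)")


def _incoming_influences(net: PathwayNetwork
                         ) -> dict[str, tuple[list[tuple[str, int]], int]]:
    """Per node: ([(source, weight) for non-degradation edges], self-degradation
    weight total). Precomputed once per run."""
    table: dict[str, tuple[list[tuple[str, int]], int]] = {}
    for node_id in net.node_ids:
        influences: list[tuple[str, int]] = []
        self_weight = 0
        for e in net.in_edges(node_id):
            if e.kind is EdgeKind.SELF_INHIBITION:
                self_weight += e.weight
            else:
                influences.append((e.source, e.weight))
        table[node_id] = (influences, self_weight)
    return table


def step(net: PathwayNetwork, state: Mapping[str, int],
         kernel: UpdateKernel = UpdateKernel()) -> dict[str, int]:
    """One synchronous update of every node (see module docstring)."""
    unknown = set(state) - set(net.graph.nodes)
    if unknown:
        raise KeyError(f"state keys not in network: {sorted(unknown)[:5]}")
    return _step_fast(_incoming_influences(net), state, kernel)


def _step_fast(influences: Mapping[str, tuple[list[tuple[str, int]], int]],
               state: Mapping[str, int],
               kernel: UpdateKernel) -> dict[str, int]:
    nxt: dict[str, int] = {}
    for node, level in state.items():
        incoming, self_weight = influences[node]
        delta = 0.0
        for source, weight in incoming:
            delta += weight * kernel.activity(state[source])
        if level > 0:
            delta += self_weight  # degradation: -1 per self-loop while expressed
        raw = level + delta
        if kernel.mode == "level_scaled":
            raw = np.floor(raw + 0.5) if raw >= 0 else -np.floor(-raw + 0.5)
        nxt[node] = int(min(max(raw, 0), max(LEVEL_MAX, level)))
    return nxt


def run_simulation(net: PathwayNetwork, baseline, scenario: "ScenarioConfig"
                   ) -> Trajectory:
    """Run a scenario: initial states from the baseline with the scenario's
    overrides applied verbatim (values above 9 allowed), then
    ``scenario.steps`` synchronous updates. The full trajectory of steps+1
    states is returned; a fixed point does not stop the run early."""
    from .expression_baseline import initialize_states
    from .scenarios import apply_overrides

    initial = initialize_states(net, baseline)
    initial = apply_overrides(initial, scenario, known_nodes=set(net.graph.nodes))
    influences = _incoming_influences(net)
    states = [initial]
    current = initial
    for _ in range(scenario.steps):
        current = _step_fast(influences, current, scenario.kernel)
        states.append(current)
    return Trajectory.from_states(states, name=scenario.name)


def detect_steady_state(traj: Trajectory) -> int | None:
    """Smallest step t from which the state never changes again; None if the
    final two states differ (no fixed point reached)."""
    frame = traj.frame
    n_states = frame.shape[1]
    if n_states >= 2 and not frame.iloc[:, -1].equals(frame.iloc[:, -2]):
        return None
    t = n_states - 1
    while t > 0 and frame.iloc[:, t - 1].equals(frame.iloc[:, t]):
        t -= 1
    return t
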