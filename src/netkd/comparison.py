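"""Trajectory comparison between scenarios.

A gene is *changed* when its simulated trajectory under a perturbation
differs from the reference (control) trajectory at any step, including step
0 — so overridden nodes themselves count, and a gene that deviates
transiently but returns to the reference level is still changed. Changed
sets from two perturbations are combined into a Venn partition
(perturbation-specific vs shared responders). Levels are integers; equality
is exact, with no numeric tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .simulation_engine import Trajectory

__all__ = [
    "ComparisonResult",
    "VennPartition",
    "DIVERGED_AT_START",
    "changed_genes",
    "venn_partition",
    "last_agreement_step",
    "first_return_to_level",
    "comparison_to_json",
    "plot_node_trajectories",
]


class _DivergedAtStart:
    """Sentinel for nodes whose trajectories never agree (differ at step 0),
    kept distinct from integer step values."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "DIVERGED_AT_START"


DIVERGED_AT_START = _DivergedAtStart()


@dataclass(frozen=True)
class ComparisonResult:
    reference_name: str
    test_name: str
    changed: frozenset[str]
    first_divergence: Mapping[str, int]
    step_count: int

    def __post_init__(self) -> None:
        if set(self.first_divergence) != set(self.changed):
            raise ValueError(
                "first_divergence must be defined exactly for changed nodes")


@dataclass(frozen=True)
class VennPartition:
    only_a: frozenset[str]
    only_b: frozenset[str]
    both: frozenset[str]

    @property
    def union_size(self) -> int:
        return len(self.only_a) + len(self.only_b) + len(self.both)


def _check_comparable(ref: Trajectory, test: Trajectory) -> None:
    if set(ref.node_ids) != set(test.node_ids):
        extra = set(ref.node_ids) ^ set(test.node_ids)
        raise ValueError(f"trajectories cover different node sets "
                         f"(symmetric difference {sorted(extra)[:5]})")
    if ref.step_count != test.step_count:
        raise ValueError(f"trajectories have different lengths "
                         f"({ref.step_count} vs {test.step_count} steps)")


def changed_genes(ref: Trajectory, test: Trajectory) -> ComparisonResult:
    """Nodes whose test trajectory differs from the reference at any step,
    with the first step of divergence for each."""
    _check_comparable(ref, test)
    test_aligned = test.frame.loc[ref.frame.index]
    differs = ref.frame.to_numpy() != test_aligned.to_numpy()
    changed: set[str] = set()
    first_div: dict[str, int] = {}
    for i, node in enumerate(ref.frame.index):
        hits = np.nonzero(differs[i])[0]
        if hits.size:
            changed.add(node)
            first_div[node] = int(hits[0])
    return ComparisonResult(ref.name, test.name, frozenset(changed),
                            first_div, ref.step_count)


def venn_partition(a: ComparisonResult, b: ComparisonResult) -> VennPartition:
    """Three-way split of two changed-gene sets sharing a reference run."""
    if a.reference_name != b.reference_name:
        raise ValueError(
            f"comparisons use different references "
            f"({a.reference_name!r} vs {b.reference_name!r})")
    return VennPartition(
        only_a=frozenset(a.changed - b.changed),
        only_b=frozenset(b.changed - a.changed),
        both=frozenset(a.changed & b.changed))


def last_agreement_step(ref: Trajectory, test: Trajectory, node: str
                        ) -> int | _DivergedAtStart:
    """Largest step t such that the node's levels agree at every step <= t;
    the full step count if the trajectories never diverge, and the
    DIVERGED_AT_START sentinel if they already differ at step 0."""
    _check_comparable(ref, test)
    a, b = ref.series(node), test.series(node)
    disagree = np.nonzero(a != b)[0]
    if disagree.size == 0:
        return ref.step_count
    first = int(disagree[0])
    if first == 0:
        return DIVERGED_AT_START
    return first - 1


def first_return_to_level(traj: Trajectory, node: str, level: int
                          ) -> int | None:
    """First step at which the node regains ``level`` after having left it.

    None when the node never sits at that level, never leaves it, or never
    comes back.
    """
    if not 0 <= level <= 9:
        raise ValueError(f"level must be in [0, 9], got {level}")
    series = traj.series(node)
    at = np.nonzero(series == level)[0]
    if at.size == 0:
        return None
    t_at = int(at[0])
    left = np.nonzero(series[t_at:] != level)[0]
    if left.size == 0:
        return None
    t_left = t_at + int(left[0])
    back = np.nonzero(series[t_left:] == level)[0]
    if back.size == 0:
        return None
    return t_left + int(back[0])


def comparison_to_json(results: list[ComparisonResult],
                       venn: VennPartition | None = None) -> str:
    payload: dict = {
        "comparisons": [
            {
                "reference": r.reference_name,
                "test": r.test_name,
                "n_changed": len(r.changed),
                "changed": sorted(r.changed),
                "first_divergence": {n: r.first_divergence[n]
                                     for n in sorted(r.changed)},
            }
            for r in results
        ]
    }
    if venn is not None:
        payload["venn"] = {
            "only_a": sorted(venn.only_a),
            "only_b": sorted(venn.only_b),
            "both": sorted(venn.both),
            "counts": {"only_a": len(venn.only_a),
                       "only_b": len(venn.only_b),
                       "both": len(venn.both),
                       "union": venn.union_size},
        }
    return json.dumps(payload, indent=2)


def plot_node_trajectories(trajectories: list[Trajectory], node: str,
                           path: str) -> None:
    """Line plot of one node's level across scenarios (level vs step)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    for traj in trajectories:
        ax.plot(range(traj.step_count + 1), traj.series(node),
                label=traj.name, drawstyle="steps-post")
    ax.set_xlabel("simulation step")
    ax.set_ylabel("expression level")
    ax.set_title(node)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
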