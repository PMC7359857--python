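"""Perturbation scenarios: named simulations with initial-value overrides.

The receptor-knockdown experimental design compares three runs on one
network: a ligand-boosted control (both ligands INS and IGF1 forced to the
very-high level 20 so the signal survives deep into the network), and two
knockdowns in which one receptor and its ligand are forced to 0 (not
detectable) while the surviving ligand keeps its control boost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from .simulation_engine import UpdateKernel

__all__ = [
    "ScenarioConfig",
    "receptor_kd_scenarios",
    "apply_overrides",
    "load_scenarios",
    "dump_scenarios",
]

CONTROL_BOOST = 20  # "very high" ligand override used in the control run
KNOCKDOWN_LEVEL = 0


@dataclass(frozen=True)
class ScenarioConfig:
    """A named simulation: per-node initial-value overrides + step count."""

    name: str
    overrides: Mapping[str, int] = field(default_factory=dict)
    steps: int = 100
    kernel: UpdateKernel = field(default_factory=UpdateKernel)

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError(f"steps must be >= 1, got {self.steps}")
        negative = {n: v for n, v in self.overrides.items() if v < 0}
        if negative:
            raise ValueError(f"negative override values: {negative}")


def receptor_kd_scenarios(steps: int = 100,
                          kernel: UpdateKernel | None = None
                          ) -> list[ScenarioConfig]:
    """The three-simulation design: control, IGF1R-KD, INSR-KD.

    Control boosts both ligands to 20. Each knockdown zeroes one receptor
    and its ligand; the surviving ligand keeps the control-level boost so
    the comparison isolates the silenced branch.
    """
    kernel = kernel or UpdateKernel()
    common = dict(steps=steps, kernel=kernel)
    return [
        ScenarioConfig("control",
                       {"IGF1": CONTROL_BOOST, "INS": CONTROL_BOOST},
                       **common),
        ScenarioConfig("IGF1R-KD",
                       {"IGF1R": KNOCKDOWN_LEVEL, "IGF1": KNOCKDOWN_LEVEL,
                        "INS": CONTROL_BOOST},
                       **common),
        ScenarioConfig("INSR-KD",
                       {"INSR": KNOCKDOWN_LEVEL, "INS": KNOCKDOWN_LEVEL,
                        "IGF1": CONTROL_BOOST},
                       **common),
    ]


def apply_overrides(initial: Mapping[str, int], scenario: ScenarioConfig,
                    known_nodes: Iterable[str] | None = None
                    ) -> dict[str, int]:
    """Replace the listed nodes' initial values verbatim; all other nodes
    untouched. Overriding a node absent from the network is an error."""
    universe = set(known_nodes) if known_nodes is not None else set(initial)
    unknown = sorted(set(scenario.overrides) - universe)
    if unknown:
        raise KeyError(
            f"scenario {scenario.name!r} overrides unknown node(s): {unknown}")
    out = dict(initial)
    out.update(scenario.overrides)
    return out


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def _scenario_to_dict(s: ScenarioConfig) -> dict:
    return {
        "name": s.name,
        "steps": s.steps,
        "overrides": dict(s.overrides),
        "kernel": {"mode": s.kernel.mode,
                   "activity_threshold": s.kernel.activity_threshold},
    }


def _scenario_from_dict(d: Mapping) -> ScenarioConfig:
    kernel_spec = d.get("kernel", {})
    kernel = UpdateKernel(
        mode=kernel_spec.get("mode", "indicator"),
        activity_threshold=int(kernel_spec.get("activity_threshold", 0)))
    return ScenarioConfig(
        name=d["name"],
        overrides={str(k): int(v) for k, v in d.get("overrides", {}).items()},
        steps=int(d.get("steps", 100)),
        kernel=kernel)


def dump_scenarios(scenarios: list[ScenarioConfig], path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump([_scenario_to_dict(s) for s in scenarios], fh, indent=2)
        fh.write("\n")


def load_scenarios(path: str) -> list[ScenarioConfig]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if isinstance(payload, Mapping):
        payload = [payload]
    return [_scenario_from_dict(d) for d in payload]


def packaged_receptor_kd_path() -> str:
    """Path of the packaged receptor-KD scenario file (JSON)."""
    return str(resources.files("netkd.data") / "receptor_kd_scenarios.json")
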