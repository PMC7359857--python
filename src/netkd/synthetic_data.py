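"""Synthetic networks and expression tables for testing the pipeline.

Two generators: seeded random signed digraphs with replicate baseline
tables (the statistical shape the analysis assumes — directed edges with
typed signs, nonnegative continuous expression with replicates), and a
fixed ~20-node miniature of the insulin/IGF1 receptor system: two ligands
(INS, IGF1) feeding their receptors, a shared RAS/AKT/MTOR core reachable
from both, one receptor-specific branch each, and a downstream checkpoint
chain several edges away from the ligands. The miniature exists so every
pipeline stage — knockdown scenarios, changed-gene sets, Venn partition,
signal distances — can be exercised and hand-checked without any external
pathway or expression download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .network_model import (
    DEFAULT_WEIGHT_SCHEME,
    EdgeKind,
    PathwayNetwork,
    add_self_inhibition,
)

__all__ = [
    "SynthesisSpec",
    "random_network",
    "random_baseline",
    "ins_igf1_miniature",
    "MINIATURE_KEY_GENES",
]

_DEFAULT_KIND_PROBS: dict[EdgeKind, float] = {
    EdgeKind.ACTIVATION: 0.55,
    EdgeKind.INHIBITION: 0.25,
    EdgeKind.PHOSPHORYLATION: 0.1,
    EdgeKind.DEPHOSPHORYLATION: 0.05,
    EdgeKind.UBIQUITINATION: 0.05,
}


@dataclass(frozen=True)
class SynthesisSpec:
    """Parameters of the random generator (one global seed, one stream)."""

    n_nodes: int = 20
    edge_density: float = 0.15
    kind_probabilities: Mapping[EdgeKind, float] = field(
        default_factory=lambda: dict(_DEFAULT_KIND_PROBS))
    n_replicates: int = 3
    baseline_distribution: tuple = ("lognormal", 6.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must be in (0, 1]")
        total = sum(self.kind_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"kind probabilities must sum to 1, got {total!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        dist = self.baseline_distribution[0]
        if dist not in ("uniform", "lognormal"):
            raise ValueError(f"unknown baseline distribution {dist!r}")


def _node_names(n: int) -> list[str]:
    return [f"G{i:03d}" for i in range(n)]


def random_network(spec: SynthesisSpec,
                   with_self_inhibition: bool = True) -> PathwayNetwork:
    """Erdos-Renyi-style signed digraph: each ordered pair (u, v), u != v,
    gets an edge with probability ``edge_density``; the kind is drawn from
    ``kind_probabilities``. Deterministic given the spec seed."""
    rng = np.random.default_rng(spec.seed)
    kinds = list(spec.kind_probabilities)
    probs = np.array([spec.kind_probabilities[k] for k in kinds], dtype=float)
    probs = probs / probs.sum()

    net = PathwayNetwork(f"random-{spec.seed}")
    names = _node_names(spec.n_nodes)
    for name in names:
        net.add_node(name, kind="gene")
    for u in names:
        for v in names:
            if u == v:
                continue
            if rng.random() < spec.edge_density:
                kind = kinds[rng.choice(len(kinds), p=probs)]
                net.add_edge(u, v, kind,
                             DEFAULT_WEIGHT_SCHEME.weight_for(kind),
                             provenance=["synthetic"])
    if with_self_inhibition:
        net = add_self_inhibition(net)
    return net


def random_baseline(genes: list[str], spec: SynthesisSpec) -> pd.DataFrame:
    """Replicate expression table (genes x replicates), drawn i.i.d. from the
    spec's baseline distribution. Deterministic given the spec seed."""
    rng = np.random.default_rng(spec.seed + 1)  # distinct stream from edges
    dist = spec.baseline_distribution
    shape = (len(genes), spec.n_replicates)
    if dist[0] == "uniform":
        lo, hi = float(dist[1]), float(dist[2])
        values = rng.uniform(lo, hi, size=shape)
    else:
        mu, sigma = float(dist[1]), float(dist[2])
        values = rng.lognormal(mu, sigma, size=shape)
    columns = [f"rep{i + 1}" for i in range(spec.n_replicates)]
    return pd.DataFrame(values, index=genes, columns=columns)


# ---------------------------------------------------------------------------
# Miniature INS/IGF1 receptor-network fixture
# ---------------------------------------------------------------------------

#: Focal genes of the miniature (used as seeds for the reduced network).
MINIATURE_KEY_GENES = (
    "INSR", "IGF1R", "HRAS", "AKT3", "MTOR", "TP53", "ATM", "CHEK2",
    "JAK1", "STAT3", "CCND1", "SOD2", "CDKN1A", "CASP3", "CDKN2A", "PRKAA1",
)

#: (source, target, kind) triples of the miniature network.
_MINIATURE_EDGES: tuple[tuple[str, str, EdgeKind], ...] = (
    # ligand -> receptor
    ("INS", "INSR", EdgeKind.ACTIVATION),
    ("IGF1", "IGF1R", EdgeKind.ACTIVATION),
    # both receptors feed the shared RAS/AKT/MTOR core
    ("INSR", "HRAS", EdgeKind.ACTIVATION),
    ("IGF1R", "HRAS", EdgeKind.ACTIVATION),
    ("HRAS", "AKT3", EdgeKind.ACTIVATION),
    ("AKT3", "MTOR", EdgeKind.ACTIVATION),
    # constitutive RAS GAP brake: a mutual-activation pair sustains NF1, so
    # HRAS saturates only when BOTH receptors drive it — this is what lets a
    # single-receptor knockdown leave a trace on the shared core
    ("NF1", "HRAS", EdgeKind.INHIBITION),
    ("NF1", "NF1B", EdgeKind.ACTIVATION),
    ("NF1B", "NF1", EdgeKind.ACTIVATION),
    # downstream checkpoint chain (>= 6 edges from the ligands)
    ("MTOR", "TP53", EdgeKind.ACTIVATION),
    ("TP53", "ATM", EdgeKind.ACTIVATION),
    ("ATM", "CHEK2", EdgeKind.ACTIVATION),
    ("TP53", "CDKN1A", EdgeKind.EXPRESSION),
    ("TP53", "CASP3", EdgeKind.ACTIVATION),
    # IGF1R-specific branch
    ("IGF1R", "JAK1", EdgeKind.ACTIVATION),
    ("JAK1", "STAT3", EdgeKind.PHOSPHORYLATION),
    ("STAT3", "CCND1", EdgeKind.EXPRESSION),
    ("STAT3", "SOD2", EdgeKind.EXPRESSION),
    # INSR-specific branch (adaptor and its ubiquitin ligase)
    ("INSR", "SH2B2", EdgeKind.ACTIVATION),
    ("SH2B2", "CBLC", EdgeKind.ACTIVATION),
    # energy/senescence periphery, independent of the ligand signal
    ("PRKAA1", "MTOR", EdgeKind.INHIBITION),
    ("CDKN2A", "CCND1", EdgeKind.INHIBITION),
)

#: Mean-intensity scale of each gene's baseline (arbitrary array units).
_MINIATURE_BASELINE: dict[str, float] = {
    "INS": 50.0, "IGF1": 180.0,
    "INSR": 420.0, "IGF1R": 530.0,
    "HRAS": 610.0, "AKT3": 700.0, "MTOR": 480.0,
    "TP53": 820.0, "ATM": 360.0, "CHEK2": 940.0,
    "CDKN1A": 280.0, "CASP3": 330.0,
    "JAK1": 390.0, "STAT3": 760.0, "CCND1": 880.0, "SOD2": 560.0,
    "SH2B2": 240.0, "CBLC": 150.0,
    "PRKAA1": 450.0, "CDKN2A": 310.0,
    "NF1": 650.0, "NF1B": 590.0,
}


def ins_igf1_miniature() -> tuple[PathwayNetwork, pd.DataFrame]:
    """Fixed 20-node miniature of the INS/IGF1 receptor system.

    Returns the network (degradation self-loops included, default weights)
    and a 3-replicate baseline expression table with small deterministic
    replicate jitter around each gene's mean intensity. All quantities are
    small enough that a full 100-step run is instantaneous and every
    assertion about it can be checked by hand.
    """
    net = PathwayNetwork("ins-igf1-miniature")
    for gene in _MINIATURE_BASELINE:
        net.add_node(gene, kind="gene")
    for source, target, kind in _MINIATURE_EDGES:
        net.add_edge(source, target, kind,
                     DEFAULT_WEIGHT_SCHEME.weight_for(kind),
                     provenance=["miniature"])
    net = add_self_inhibition(net)

    rng = np.random.default_rng(20200421)
    genes = list(_MINIATURE_BASELINE)
    means = np.array([_MINIATURE_BASELINE[g] for g in genes])
    jitter = rng.normal(1.0, 0.03, size=(len(genes), 3))
    table = pd.DataFrame(np.abs(means[:, None] * jitter), index=genes,
                         columns=["rep1", "rep2", "rep3"])
    return net, table
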