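import pytest

from netkd import (
    BaselineLevels,
    EdgeKind,
    PathwayNetwork,
    UpdateKernel,
    add_self_inhibition,
    average_replicates,
    ins_igf1_miniature,
    normalize_to_levels,
    receptor_kd_scenarios,
    run_simulation,
)


def brute_force_step(net, state, kernel=UpdateKernel()):
    """Independent per-node recomputation of one synchronous update,
    straight from the edge list (oracle for the engine)."""
    nxt = {}
    for node in net.node_ids:
        delta = 0.0
        for e in net.edges:
            if e.target != node:
                continue
            if e.kind is EdgeKind.SELF_INHIBITION:
                if state[node] > 0:
                    delta += e.weight
            elif kernel.mode == "indicator":
                if state[e.source] > kernel.activity_threshold:
                    delta += e.weight
            else:
                delta += e.weight * state[e.source] / 9
        raw = state[node] + delta
        if kernel.mode == "level_scaled":
            raw = int(raw + 0.5) if raw >= 0 else -int(-raw + 0.5)
        nxt[node] = int(min(max(raw, 0), max(9, state[node])))
    return nxt


@pytest.fixture
def toy_pair():
    """S(level 3) -activation-> G(level 0), both with degradation loops."""
    net = PathwayNetwork("toy")
    net.add_edge("S", "G", EdgeKind.ACTIVATION, weight=2)
    net = add_self_inhibition(net)
    baseline = BaselineLevels({"S": 3, "G": 0})
    return net, baseline


@pytest.fixture(scope="session")
def miniature():
    return ins_igf1_miniature()


@pytest.fixture(scope="session")
def miniature_runs(miniature):
    """Control / IGF1R-KD / INSR-KD trajectories on the miniature fixture."""
    net, table = miniature
    baseline = normalize_to_levels(average_replicates(table))
    return {s.name: run_simulation(net, baseline, s)
            for s in receptor_kd_scenarios()}
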