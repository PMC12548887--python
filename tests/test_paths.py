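"""Cross-correlation weights and k-lowest-score path extraction."""

import itertools

import networkx as nx
import numpy as np
import pytest

from cohortnet.dynamics import SimulationConfig, run_forced_simulation
from cohortnet.paths import (
    all_pairs_top_paths,
    cross_correlation_map,
    k_lowest_score_paths,
    max_cross_correlation,
    node_path_frequency,
    phenotype_cooccurrence,
    reweight_network,
)

from conftest import random_weighted_graph


def test_identical_traces_give_cc_one_at_lag_zero():
    u = np.tile([1, 1, 0, 0], 20)
    cc, lag = max_cross_correlation(u, u.copy(), max_lag=5)
    assert cc == pytest.approx(1.0)
    assert lag == 0


def test_exact_shift_recovered():
    rng = np.random.default_rng(8)
    u = (rng.random(60) < 0.5).astype(float)
    v = np.concatenate([np.zeros(3), u[:-3]])  # v lags u by exactly 3 steps
    cc, lag = max_cross_correlation(u, v, max_lag=5)
    assert cc == pytest.approx(1.0)
    assert lag == 3
    cc_b, lag_b = max_cross_correlation(v, u, max_lag=5)
    assert cc_b == pytest.approx(1.0)
    assert lag_b == -3


def test_matches_bruteforce_lag_grid_on_noise():
    rng = np.random.default_rng(3)
    u = (rng.random(100) < 0.5).astype(float)
    v = (rng.random(100) < 0.5).astype(float)
    got_cc, got_lag = max_cross_correlation(u, v, max_lag=10)

    def corr(a, b):
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    brute = {}
    n = len(u)
    for lag in range(-10, 11):
        if lag >= 0:
            brute[lag] = corr(u[: n - lag] if lag else u, v[lag:])
        else:
            brute[lag] = corr(u[-lag:], v[: n + lag])
    assert got_cc == pytest.approx(max(brute.values()), abs=1e-9)
    assert brute[got_lag] == pytest.approx(got_cc, abs=1e-9)
    assert got_cc < 0.5  # independent noise: no strong alignment


def test_constant_trace_yields_zero_correlation():
    u = np.ones(50)
    v = np.tile([0, 1], 25).astype(float)
    cc, _ = max_cross_correlation(u, v, max_lag=4)
    assert cc == 0.0
    with pytest.raises(ValueError):
        max_cross_correlation(np.ones(5), np.ones(5), max_lag=4)


def test_reweight_lengths_and_floor():
    g = nx.Graph()
    g.add_edge("a", "b", weight=0.5)
    g.add_edge("b", "c", weight=0.5)
    g.add_edge("a", "c", weight=0.5)
    ccmap = {("a", "b"): (1.0, 0), ("b", "c"): (0.5, 1), ("a", "c"): (-0.2, 0)}
    d = reweight_network(g, ccmap)
    assert d["a"]["b"]["length"] == pytest.approx(1.0)
    assert d["b"]["c"]["length"] == pytest.approx(2.0)
    assert not d.has_edge("a", "c")  # non-positive cc dropped
    # no edge beyond the original topology
    assert set(d.edges) <= {tuple(e) for e in g.edges} | {
        tuple(reversed(e)) for e in g.edges
    }


def test_two_node_and_diamond_graphs():
    g = nx.Graph()
    g.add_edge("a", "b", length=1.25)
    (only,) = k_lowest_score_paths(g, "a", "b", k=10)
    assert only.nodes == ("a", "b")
    assert only.score == pytest.approx(1.25)

    d = nx.Graph()
    d.add_edge("A", "B", length=1.0)
    d.add_edge("B", "D", length=1.0)
    d.add_edge("A", "C", length=1.0)
    d.add_edge("C", "D", length=2.0)
    got = k_lowest_score_paths(d, "A", "D", k=2)
    assert [p.nodes for p in got] == [("A", "B", "D"), ("A", "C", "D")]
    assert [p.score for p in got] == [pytest.approx(2.0), pytest.approx(3.0)]


def test_no_path_returns_empty_list():
    g = nx.Graph()
    g.add_edge("a", "b", length=1.0)
    g.add_node("z")
    assert k_lowest_score_paths(g, "a", "z") == []
    with pytest.raises(ValueError):
        k_lowest_score_paths(g, "a", "a")


def brute_force_paths(graph, source, target, k):
    scored = []
    for nodes in nx.all_simple_paths(graph, source, target):
        sc = sum(graph[a][b]["length"] for a, b in zip(nodes[:-1], nodes[1:]))
        scored.append((sc, tuple(nodes)))
    scored.sort(key=lambda item: (item[0], [str(x) for x in item[1]]))
    return scored[:k]


def test_matches_exhaustive_enumeration_on_small_graphs():
    rng = np.random.default_rng(17)
    checked = 0
    for _ in range(40):
        g = random_weighted_graph(rng, int(rng.integers(4, 9)), 0.45)
        nodes = sorted(g.nodes)
        src, tgt = nodes[0], nodes[-1]
        expect = brute_force_paths(g, src, tgt, k=10)
        got = k_lowest_score_paths(g, src, tgt, k=10)
        assert [(p.score, p.nodes) for p in got] == [
            (pytest.approx(sc), nodes_) for sc, nodes_ in expect
        ]
        checked += len(expect) > 0
    assert checked >= 20  # enough non-trivial cases exercised


def test_scores_nondecreasing_and_paths_simple():
    rng = np.random.default_rng(23)
    g = random_weighted_graph(rng, 10, 0.4)
    got = k_lowest_score_paths(g, sorted(g.nodes)[0], sorted(g.nodes)[-1], k=15)
    scores = [p.score for p in got]
    assert scores == sorted(scores)
    for p in got:
        assert len(set(p.nodes)) == len(p.nodes)
        for a, b in zip(p.nodes[:-1], p.nodes[1:]):
            assert g.has_edge(a, b)
        assert p.score >= len(p.nodes) - 1  # cc <= 1 so each edge length >= 1


def test_all_pairs_counting_and_unreachable():
    g = nx.Graph()
    g.add_edge("s1", "m", weight=0.9)
    g.add_edge("s2", "m", weight=0.9)
    g.add_edge("m", "t1", weight=0.9)
    g.add_edge("m", "t2", weight=0.9)
    g.add_node("t3")  # unreachable target
    cfg = SimulationConfig(input_node="s1", noise_prob=0.05, steps=100)
    out = all_pairs_top_paths(g, ["s1", "s2"], ["t1", "t2", "t3"],
                              sim_cfg=cfg, k=3, seed=1)
    assert set(out) <= set(itertools.product(["s1", "s2"], ["t1", "t2"]))
    assert all(len(v) <= 3 for v in out.values())
    assert not any(t == "t3" for _, t in out)


def test_driven_pendant_edge_gets_higher_cc_than_locked_side_edge():
    """A pendant leaf copies the input wave, so its edge earns a high cc and
    a short length; leaves that also couple to each other lock active (the
    saturation phenomenon) and their mutual edge scores poorly."""
    g = nx.Graph()
    for leaf in "abc":
        g.add_edge("in", leaf, weight=0.9)
    g.add_edge("a", "b", weight=0.05)  # leaves a, b sustain each other
    cfg = SimulationConfig(input_node="in", noise_prob=0.05, steps=100, seed=2)
    trace = run_forced_simulation(g, cfg)
    ccmap = cross_correlation_map(trace, g, max_lag=10)
    cc = {frozenset(e): v[0] for e, v in ccmap.items()}
    pendant = cc[frozenset(("in", "c"))]
    side = cc[frozenset(("a", "b"))]
    assert pendant > 0.8  # near-exact delayed copy of the wave
    assert pendant > side


def test_node_path_frequency_fractions():
    from cohortnet.paths import PathResult

    paths = [
        PathResult(("s", "a", "t"), 2.0, "s", "t"),
        PathResult(("s", "a", "b", "t"), 3.0, "s", "t"),
        PathResult(("s", "t"), 1.0, "s", "t"),
    ]
    freq = node_path_frequency(paths)
    assert freq["s"] == freq["t"] == 1.0
    assert freq["a"] == pytest.approx(2 / 3)
    assert freq["b"] == pytest.approx(1 / 3)
    assert "z" not in freq
    with pytest.raises(ValueError):
        node_path_frequency([])


def test_phenotype_cooccurrence_hand_counted():
    from cohortnet.paths import PathResult

    pheno = ["p1", "p2", "p3"]
    paths = [
        PathResult(("s", "p1", "p2"), 2.0, "s", "p2"),
        PathResult(("s", "p1", "p2"), 2.0, "s", "p2"),
        PathResult(("s", "a", "p3"), 2.0, "s", "p3"),  # no pheno-pheno step
    ]
    mat = phenotype_cooccurrence(paths, pheno)
    assert mat.loc["p1", "p2"] == 2
    assert mat.loc["p2", "p1"] == 2
    assert mat.to_numpy().sum() == 4  # symmetric, nothing else counted
    assert (mat.to_numpy() == mat.to_numpy().T).all()
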