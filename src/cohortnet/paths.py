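"""From simulation traces to cross-correlation weights and top-k paths.

After a forced simulation, every edge of the signed network gets the maximal
lagged Pearson cross-correlation between its endpoints' activity traces
(maximised over integer lags in [-max_lag, max_lag]); the reciprocal of that
maximum is the edge's *length*, so strong dynamic coupling means a short
edge. No edge is ever added beyond the original topology; edges whose best
cross-correlation is non-positive (or below a small floor) are dropped as
uninformative. The score of a path is the sum of its edge lengths — it
simultaneously favours few hops and high cross-correlations — and the k
loopless paths of smallest score between a source and a phenotype target are
extracted with a k-shortest-paths (Yen) algorithm built on Dijkstra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from ._util import derive_seed
from .dynamics import SimulationConfig, StateTrace, run_forced_simulation

__all__ = [
    "PathResult",
    "max_cross_correlation",
    "cross_correlation_map",
    "reweight_network",
    "k_lowest_score_paths",
    "all_pairs_top_paths",
    "node_path_frequency",
    "phenotype_cooccurrence",
]

_SCORE_EPS = 1e-9


@dataclass(frozen=True)
class PathResult:
    """An ordered source -> ... -> target node sequence with its score."""

    nodes: tuple
    score: float
    source: Hashable
    target: Hashable

    def __len__(self) -> int:
        return len(self.nodes)


def _segment_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.clip(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb), -1, 1))


def max_cross_correlation(
    trace_u: Sequence[int],
    trace_v: Sequence[int],
    max_lag: int,
) -> tuple[float, int]:
    """Maximal lagged Pearson correlation between two binary traces.

    Lag ell > 0 aligns u(t) with v(t + ell) (v lags u). Zero-variance
    segments contribute correlation 0 at that lag. Ties broken toward the
    smallest |lag|, then the smaller lag. Returns (cc, lag).
    """
    u = np.asarray(trace_u, dtype=float)
    v = np.asarray(trace_v, dtype=float)
    n = len(u)
    if len(v) != n:
        raise ValueError("traces must have equal length")
    if n < 2 * max_lag + 2:
        raise ValueError(f"traces too short for max_lag={max_lag}: length {n}")
    best_cc, best_lag = -np.inf, 0
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l)):
        if lag >= 0:
            c = _segment_corr(u[: n - lag] if lag else u, v[lag:])
        else:
            c = _segment_corr(u[-lag:], v[: n + lag])
        if c > best_cc + _SCORE_EPS:
            best_cc, best_lag = c, lag
    return best_cc, best_lag


def cross_correlation_map(
    trace: StateTrace,
    net: nx.Graph,
    max_lag: int,
) -> dict[tuple, tuple[float, int]]:
    """Max lagged cross-correlation for every edge of ``net``.

    Keys are edges as given by ``net.edges``; defined only on the original
    topology.
    """
    out: dict[tuple, tuple[float, int]] = {}
    for u, v in net.edges:
        out[(u, v)] = max_cross_correlation(trace.series(u), trace.series(v), max_lag)
    return out


def reweight_network(
    net: nx.Graph,
    ccmap: Mapping[tuple, tuple[float, int]],
    cc_floor: float = 1e-3,
) -> nx.Graph:
    """Distance graph on the unchanged topology: edge length = 1/cc.

    Edges with cc <= cc_floor (including any non-positive maximum) are
    dropped as dynamically uninformative.
    """
    g = nx.Graph()
    g.add_nodes_from(net.nodes(data=True))
    for u, v in net.edges:
        if (u, v) in ccmap:
            cc, lag = ccmap[(u, v)]
        elif (v, u) in ccmap:
            cc, lag = ccmap[(v, u)]
        else:
            raise KeyError(f"cross-correlation map does not cover edge {u!r}-{v!r}")
        if cc > cc_floor:
            g.add_edge(u, v, length=1.0 / cc, cc=cc, lag=lag)
    return g


def _path_score(graph: nx.Graph, nodes: Sequence) -> float:
    return float(sum(graph[a][b]["length"] for a, b in zip(nodes[:-1], nodes[1:])))


def k_lowest_score_paths(
    graph: nx.Graph,
    source: Hashable,
    target: Hashable,
    k: int = 10,
) -> list[PathResult]:
    """The k loopless paths of smallest score, ascending.

    Fewer than k are returned when fewer simple paths exist; an unreachable
    target yields an empty list. Ties in score are broken by the
    lexicographic node sequence, so the output is deterministic.
    """
    if source == target:
        raise ValueError("source and target must differ")
    if source not in graph or target not in graph:
        return []
    collected: list[tuple[float, tuple]] = []
    try:
        for nodes in nx.shortest_simple_paths(graph, source, target, weight="length"):
            sc = _path_score(graph, nodes)
            if len(collected) >= k and sc > collected[k - 1][0] + _SCORE_EPS:
                break
            collected.append((sc, tuple(nodes)))
            collected.sort(key=lambda item: (item[0], [str(x) for x in item[1]]))
    except nx.NetworkXNoPath:
        return []
    return [
        PathResult(nodes=nodes, score=sc, source=source, target=target)
        for sc, nodes in collected[:k]
    ]


def all_pairs_top_paths(
    net: nx.Graph,
    input_nodes: Sequence[Hashable],
    target_nodes: Sequence[Hashable],
    sim_cfg: SimulationConfig | None = None,
    k: int = 10,
    max_lag: int | None = None,
    cc_floor: float = 1e-3,
    seed: int = 0,
) -> dict[tuple, list[PathResult]]:
    """Top-k paths for every (input, target) combination.

    One forced simulation per input node (its seed derived from ``seed``), one
    shared cross-correlation reweighting per input, then k-lowest-score paths
    to each target. Pairs whose target is unreachable are absent from the
    result.
    """
    if not target_nodes:
        raise ValueError("target node set is empty")
    base = sim_cfg or SimulationConfig(input_node=input_nodes[0])
    if max_lag is None:
        max_lag = base.half_period
    out: dict[tuple, list[PathResult]] = {}
    for src in input_nodes:
        cfg = base.with_input(src, seed=derive_seed(seed, "sim", src))
        trace = run_forced_simulation(net, cfg)
        ccmap = cross_correlation_map(trace, net, max_lag)
        dist = reweight_network(net, ccmap, cc_floor=cc_floor)
        for tgt in target_nodes:
            if tgt == src:
                continue
            paths = k_lowest_score_paths(dist, src, tgt, k=k)
            if paths:
                out[(src, tgt)] = paths
    return out


def _flatten(paths: Iterable[PathResult] | Mapping) -> list[PathResult]:
    if isinstance(paths, Mapping):
        return [p for plist in paths.values() for p in plist]
    return list(paths)


def node_path_frequency(paths: Iterable[PathResult] | Mapping) -> dict:
    """Fraction of paths containing each node, in [0, 1]."""
    flat = _flatten(paths)
    if not flat:
        raise ValueError("path collection is empty")
    counts: dict = {}
    for p in flat:
        for node in set(p.nodes):
            counts[node] = counts.get(node, 0) + 1
    total = len(flat)
    return {node: c / total for node, c in counts.items()}


def phenotype_cooccurrence(
    paths: Iterable[PathResult] | Mapping,
    phenotype_nodes: Sequence[Hashable],
):
    """Symmetric counts of phenotype-node pairs adjacent within paths."""
    import pandas as pd

    pheno = list(phenotype_nodes)
    mat = pd.DataFrame(0, index=pheno, columns=pheno)
    pheno_set = set(pheno)
    for p in _flatten(paths):
        for a, b in zip(p.nodes[:-1], p.nodes[1:]):
            if a in pheno_set and b in pheno_set:
                mat.loc[a, b] += 1
                mat.loc[b, a] += 1
    return mat
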