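"""Degree-preserving network permutation nulls and path-specificity testing.

A permuted network is produced by repeated double edge swaps — (a,b),(c,d)
becomes (a,c),(b,d) or (a,d),(b,c) — rejecting any proposal that would create
a self-edge or duplicate an existing edge, so every node's degree is conserved
exactly. Each edge undergoes ``swaps_per_edge`` *attempted* swaps on average
(attempts are counted, not acceptances; the acceptance rate is recorded on
the result). The signed weights are then permuted uniformly over the new edge
set, conserving the weight multiset.

For each permuted network the forced simulations and top-path extraction are
re-run with identical settings, and every original path is classified into
one of three categories: it reappears as a top path, it exists in the
permuted topology but is not a top path, or it is absent altogether. A path
is called *specific* when it reappears as a top path in less than a small
fraction (default 1%) of the permuted networks; because existence alone is
also informative, the existence fraction and its pass flag are reported too.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from ._util import derive_seed
from .dynamics import SimulationConfig
from .paths import PathResult, all_pairs_top_paths, _flatten

__all__ = ["degree_preserving_permutation", "control_analysis"]


def degree_preserving_permutation(
    net: nx.Graph,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> nx.Graph:
    """Degree-preserving rewiring with weight permutation.

    Attempts ``swaps_per_edge * |E|`` double edge swaps with rejection of
    self-edges and duplicates, then permutes all edge attribute records over
    the new edge set. Graph attribute ``swap_acceptance_rate`` records the
    accepted fraction. A graph with fewer than 2 edges cannot be rewired and
    is returned weight-permuted (trivially) with a warning.
    """
    rng = np.random.default_rng(seed)
    edges = [tuple(e) for e in net.edges]
    n_edges = len(edges)
    out = nx.Graph()
    out.add_nodes_from(net.nodes(data=True))
    if n_edges < 2:
        warnings.warn("graph has fewer than 2 edges; only weights permuted")
        attrs = [dict(net.edges[e]) for e in edges]
        for e, a in zip(edges, attrs):
            out.add_edge(*e, **a)
        out.graph["swap_acceptance_rate"] = 0.0
        return out

    present = {frozenset(e) for e in edges}
    attempts = swaps_per_edge * n_edges
    accepted = 0
    for _ in range(attempts):
        i = int(rng.integers(n_edges))
        j = int(rng.integers(n_edges - 1))
        if j >= i:
            j += 1
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            new1, new2 = (a, c), (b, d)
        else:
            new1, new2 = (a, d), (b, c)
        if new1[0] == new1[1] or new2[0] == new2[1]:
            continue
        f1, f2 = frozenset(new1), frozenset(new2)
        if f1 == f2 or f1 in present or f2 in present:
            continue
        present.discard(frozenset(edges[i]))
        present.discard(frozenset(edges[j]))
        present.add(f1)
        present.add(f2)
        edges[i], edges[j] = new1, new2
        accepted += 1

    attr_records = [dict(net.edges[e]) for e in net.edges]
    order = rng.permutation(len(attr_records))
    for e, oi in zip(edges, order):
        out.add_edge(*e, **attr_records[oi])
    out.graph["swap_acceptance_rate"] = accepted / attempts
    return out


def _exists_in(net: nx.Graph, nodes: tuple) -> bool:
    return all(net.has_edge(u, v) for u, v in zip(nodes[:-1], nodes[1:]))


def control_analysis(
    original_paths: Iterable[PathResult] | Mapping,
    net: nx.Graph,
    sim_cfg: SimulationConfig | None = None,
    n_networks: int = 100,
    threshold: float = 0.01,
    k: int = 10,
    max_lag: int | None = None,
    cc_floor: float = 1e-3,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Classify each original path across ``n_networks`` permuted networks.

    Returns one row per original path with the three category counts (they
    always sum to ``n_networks``), ``fraction_top`` and ``fraction_exists``,
    and the pass flags ``passes`` (fraction_top < threshold; the default
    specificity criterion) and ``passes_exists`` (fraction_exists <
    threshold; the stricter reading that mere topological existence counts).
    """
    originals = _flatten(original_paths)
    if not originals:
        raise ValueError("original path collection is empty")
    sources = sorted({p.source for p in originals}, key=str)
    targets = sorted({p.target for p in originals}, key=str)

    count_top = np.zeros(len(originals), dtype=int)
    count_exists = np.zeros(len(originals), dtype=int)
    for m in range(n_networks):
        pnet = degree_preserving_permutation(
            net, swaps_per_edge=swaps_per_edge, seed=derive_seed(seed, "swap", m)
        )
        tops = all_pairs_top_paths(
            pnet, sources, targets, sim_cfg=sim_cfg, k=k, max_lag=max_lag,
            cc_floor=cc_floor, seed=derive_seed(seed, "net", m),
        )
        top_sequences = {
            (s, t): {p.nodes for p in plist} for (s, t), plist in tops.items()
        }
        for pi, p in enumerate(originals):
            if p.nodes in top_sequences.get((p.source, p.target), set()):
                count_top[pi] += 1
                count_exists[pi] += 1
            elif _exists_in(pnet, p.nodes):
                count_exists[pi] += 1

    rows = []
    for pi, p in enumerate(originals):
        frac_top = count_top[pi] / n_networks
        frac_exists = count_exists[pi] / n_networks
        rows.append({
            "source": p.source,
            "target": p.target,
            "nodes": " -> ".join(str(x) for x in p.nodes),
            "score": p.score,
            "n_networks": n_networks,
            "count_exists_and_top": int(count_top[pi]),
            "count_exists_not_top": int(count_exists[pi] - count_top[pi]),
            "count_absent": int(n_networks - count_exists[pi]),
            "fraction_top": frac_top,
            "fraction_exists": frac_exists,
            "passes": bool(frac_top < threshold),
            "passes_exists": bool(frac_exists < threshold),
        })
    return pd.DataFrame(rows)
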