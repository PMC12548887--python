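"""Multilayer and signed network construction and connectivity summaries.

Within each layer, every variable pair whose binned mutual information is
permutation-significant (p < alpha) becomes an undirected edge weighted by the
normalized mutual information; layers are then joined by bipartite inter-layer
edges built with the same criterion, giving one global multilayer network with
no predefined hierarchy. A secondary *signed* network over all layers jointly
uses the Pearson coefficient (two-tailed permutation test) so edges carry an
activating (+) or inhibitory (-) sign for the Boolean dynamics.

Connectivity is summarised by weighted densities: within a layer
d = 2 * sum(w) / (|V| (|V|-1)); between layers d_bip = sum(w) / (|Vi| |Vj|);
the L x L connectance matrix has the within-layer densities on the diagonal
and the bipartite densities off it.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._util import derive_seed
from .associations import (
    InsufficientDataError,
    UndefinedCorrelationError,
    _contingency,
    _entropy_from_counts,
    _mi_from_counts,
    _mi_null,
    _pearson_null,
    _prepare_codes,
    _TIE_EPS,
    pairwise_complete,
)
from .synthetic import CohortTable

__all__ = [
    "build_layer_network",
    "build_interlayer_edges",
    "assemble_multilayer",
    "build_multilayer_network",
    "build_signed_network",
    "weighted_density",
    "bipartite_density",
    "connectance_matrix",
    "average_shortest_path_length",
]


def _mi_edge_stats(
    table: CohortTable,
    a: str,
    b: str,
    n_bins: int | None,
    n_perm: int,
    seed: int,
) -> tuple[float, float, float, int] | None:
    """(nmi, p_mi, mi, n_complete) for a pair, or None if not estimable."""
    xa = table.data[a].to_numpy(dtype=float)
    xb = table.data[b].to_numpy(dtype=float)
    try:
        ix, iy, kx, ky = _prepare_codes(
            xa, xb, n_bins, (table.is_discrete(a), table.is_discrete(b))
        )
    except InsufficientDataError:
        return None
    counts = _contingency(ix, iy, kx, ky)
    mi = max(0.0, _mi_from_counts(counts))
    hx = _entropy_from_counts(counts.sum(axis=1))
    hy = _entropy_from_counts(counts.sum(axis=0))
    nmi = float(np.clip(mi / math.sqrt(hx * hy), 0.0, 1.0)) if hx > 0 and hy > 0 else 0.0
    rng = np.random.default_rng(derive_seed(seed, "mi", *sorted((a, b))))
    null = _mi_null(ix, iy, kx, ky, n_perm, rng)
    p = float((1 + int((null >= mi - _TIE_EPS).sum())) / (1 + n_perm))
    return nmi, p, mi, len(ix)


def build_layer_network(
    table: CohortTable,
    layer: str,
    alpha: float = 0.05,
    n_perm: int = 1000,
    n_bins: int | None = None,
    seed: int = 0,
) -> nx.Graph:
    """Within-layer MI network: edges for pairs with permutation p < alpha.

    Edge attributes: ``weight`` (nmi), ``mi``, ``p``, ``n_complete``. Every
    layer variable is a node even if isolated.
    """
    variables = table.variables(layer)
    if len(variables) < 2:
        raise ValueError(f"layer {layer!r} has fewer than 2 variables")
    g = nx.Graph(layer=layer)
    g.add_nodes_from(variables, layer=layer)
    for a, b in itertools.combinations(variables, 2):
        stats = _mi_edge_stats(table, a, b, n_bins, n_perm, seed)
        if stats is None:
            continue
        nmi, p, mi, n_complete = stats
        if p < alpha:
            g.add_edge(a, b, weight=nmi, mi=mi, p=p, n_complete=n_complete)
    return g


def build_interlayer_edges(
    table: CohortTable,
    layer_i: str,
    layer_j: str,
    alpha: float = 0.05,
    n_perm: int = 1000,
    n_bins: int | None = None,
    seed: int = 0,
) -> list[tuple[str, str, dict]]:
    """Significant bipartite MI edges between two distinct layers."""
    if layer_i == layer_j:
        raise ValueError("inter-layer edges require two distinct layers")
    edges = []
    for a in table.variables(layer_i):
        for b in table.variables(layer_j):
            stats = _mi_edge_stats(table, a, b, n_bins, n_perm, seed)
            if stats is None:
                continue
            nmi, p, mi, n_complete = stats
            if p < alpha:
                edges.append((a, b, {"weight": nmi, "mi": mi, "p": p,
                                     "n_complete": n_complete}))
    return edges


def assemble_multilayer(
    layer_networks: Sequence[nx.Graph],
    interlayer_edges: Iterable[tuple[str, str, dict]] = (),
) -> nx.Graph:
    """Union of layer networks plus inter-layer edges; no hierarchy filter.

    Node sets must be disjoint across layers (every node lives in exactly one
    layer).
    """
    g = nx.Graph()
    for lay in layer_networks:
        for node in lay.nodes:
            if node in g:
                raise ValueError(f"node {node!r} appears in more than one layer")
        g.add_nodes_from(lay.nodes(data=True))
        g.add_edges_from(lay.edges(data=True))
    for u, v, attrs in interlayer_edges:
        if g.nodes[u]["layer"] == g.nodes[v]["layer"]:
            raise ValueError(f"inter-layer edge {u!r}-{v!r} lies within one layer")
        g.add_edge(u, v, **attrs)
    return g


def build_multilayer_network(
    table: CohortTable,
    alpha: float = 0.05,
    n_perm: int = 1000,
    n_bins: int | None = None,
    seed: int = 0,
) -> nx.Graph:
    """Convenience: all layer networks + all inter-layer edge sets, assembled."""
    layers = table.layer_names
    layer_nets = [
        build_layer_network(table, lay, alpha=alpha, n_perm=n_perm,
                            n_bins=n_bins, seed=seed)
        for lay in layers
    ]
    inter: list[tuple[str, str, dict]] = []
    for li, lj in itertools.combinations(layers, 2):
        inter.extend(
            build_interlayer_edges(table, li, lj, alpha=alpha, n_perm=n_perm,
                                   n_bins=n_bins, seed=seed)
        )
    return assemble_multilayer(layer_nets, inter)


def build_signed_network(
    table: CohortTable,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> nx.Graph:
    """Signed Pearson network over all layers jointly (for the dynamics).

    Edges for pairs significant under the two-tailed Pearson permutation test;
    ``weight`` is the signed coefficient r (0-weight edges are excluded, as
    are pairs constant on their pairwise-complete rows). Disconnected nodes
    are retained.
    """
    variables = table.variables()
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    g = nx.Graph()
    for v in variables:
        g.add_node(v, layer=table.layer_of(v))
    for a, b in itertools.combinations(variables, 2):
        xc, yc = pairwise_complete(
            table.data[a].to_numpy(dtype=float), table.data[b].to_numpy(dtype=float)
        )
        if len(xc) < 3:
            continue
        rng = np.random.default_rng(derive_seed(seed, "r", *sorted((a, b))))
        try:
            r, null = _pearson_null(xc, yc, n_perm, rng)
        except UndefinedCorrelationError:
            continue
        p = float((1 + int((np.abs(null) >= abs(r) - _TIE_EPS).sum())) / (1 + n_perm))
        if p < alpha and r != 0.0:
            g.add_edge(a, b, weight=float(np.clip(r, -1, 1)), p=p, n_complete=len(xc))
    return g


def weighted_density(net: nx.Graph) -> float:
    """Weighted density d = 2 * sum(w) / (|V| (|V|-1))."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    total = sum(abs(d.get("weight", 1.0)) for _, _, d in net.edges(data=True))
    return 2.0 * total / (n * (n - 1))


def bipartite_density(
    edges: Iterable[tuple[str, str, float] | tuple[str, str, dict]],
    n_i: int,
    n_j: int,
) -> float:
    """Bipartite weighted density d_bip = sum(w) / (|Vi| |Vj|)."""
    if n_i < 1 or n_j < 1:
        raise ValueError("both layers must be non-empty")
    total = 0.0
    for e in edges:
        w = e[2]
        if isinstance(w, dict):
            w = w.get("weight", 1.0)
        total += abs(float(w))
    return total / (n_i * n_j)


def connectance_matrix(mln: nx.Graph) -> pd.DataFrame:
    """L x L symmetric connectance matrix of a multilayer network.

    Diagonal: weighted density within each layer (computed on the layer's
    induced subgraph). Off-diagonal: bipartite weighted density between the
    two layers' node sets.
    """
    layer_nodes: dict[str, list] = {}
    for node, lay in mln.nodes(data="layer"):
        layer_nodes.setdefault(lay, []).append(node)
    layers = list(layer_nodes)
    if any(len(v) == 0 for v in layer_nodes.values()):
        raise ValueError("all layers must be non-empty")
    cm = pd.DataFrame(0.0, index=layers, columns=layers)
    for lay in layers:
        sub = mln.subgraph(layer_nodes[lay])
        cm.loc[lay, lay] = weighted_density(sub) if len(layer_nodes[lay]) >= 2 else 0.0
    for li, lj in itertools.combinations(layers, 2):
        si, sj = set(layer_nodes[li]), set(layer_nodes[lj])
        cross = [
            (u, v, d)
            for u, v, d in mln.edges(data=True)
            if (u in si and v in sj) or (u in sj and v in si)
        ]
        d = bipartite_density(cross, len(si), len(sj))
        cm.loc[li, lj] = d
        cm.loc[lj, li] = d
    return cm


def average_shortest_path_length(
    net: nx.Graph,
    weight: str = "weight",
    largest_component: bool = False,
) -> float:
    """Mean shortest-path distance over ordered node pairs, length = 1/weight.

    Stronger edges are shorter. Raises on a disconnected graph unless
    ``largest_component`` restricts the computation (which is then reported on
    that component only).
    """
    if net.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    g = net
    if not nx.is_connected(g):
        if not largest_component:
            raise ValueError(
                "graph is disconnected; pass largest_component=True to restrict"
            )
        g = net.subgraph(max(nx.connected_components(net), key=len))
        if g.number_of_nodes() < 2:
            raise ValueError("largest component has fewer than 2 nodes")
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        w = abs(float(d.get(weight, 1.0)))
        if w <= 0:
            raise ValueError(f"edge {u!r}-{v!r} has non-positive weight")
        h.add_edge(u, v, length=1.0 / w)
    return nx.average_shortest_path_length(h, weight="length")
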