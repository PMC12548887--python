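"""Aggregate summaries: focal connectivity, stratified runs, pooled paths.

These are pure views over the networks and path collections produced by the
other modules: every reported count can be re-derived from the serialized
edge lists and path records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Hashable, Sequence

import networkx as nx
import pandas as pd

from ._util import derive_seed
from .dynamics import SimulationConfig
from .networks import build_multilayer_network, build_signed_network
from .paths import PathResult, all_pairs_top_paths, k_lowest_score_paths
from .synthetic import CohortTable

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "focal_connectivity",
    "run_pipeline",
    "stratified_run",
    "source_restricted_shortest_paths",
]


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings: significance, simulation, path extraction."""

    source_layers: tuple[str, ...]
    target_layer: str = "phenotype"
    alpha: float = 0.05
    n_perm: int = 1000
    n_bins: int | None = None
    k: int = 10
    max_lag: int | None = None
    cc_floor: float = 1e-3
    min_group_n: int = 50
    include_multilayer: bool = False
    sim: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(input_node=None)
    )
    seed: int = 0


@dataclass
class PipelineResult:
    """Networks and path collections from one pipeline run."""

    signed_network: nx.Graph
    paths: dict[tuple, list[PathResult]]
    multilayer_network: nx.Graph | None = None


def focal_connectivity(mln: nx.Graph, focal_nodes: Sequence[Hashable]) -> pd.DataFrame:
    """Per-layer edge counts and mean weight between a focal set and the rest.

    Counts every multilayer-network edge with exactly one endpoint in the
    focal set, grouped by the layer of the non-focal endpoint; ``mean_weight``
    is the mean edge weight (normalized mutual information) over those edges.
    """
    focal = set(focal_nodes)
    missing = focal - set(mln.nodes)
    if missing:
        raise KeyError(f"unknown focal nodes: {sorted(map(str, missing))}")
    tallies: dict[str, list[float]] = {}
    for u, v, d in mln.edges(data=True):
        if (u in focal) == (v in focal):
            continue
        other = v if u in focal else u
        tallies.setdefault(mln.nodes[other]["layer"], []).append(
            float(d.get("weight", 1.0))
        )
    layers = sorted({lay for _, lay in mln.nodes(data="layer")})
    rows = [
        {
            "layer": lay,
            "n_edges": len(tallies.get(lay, [])),
            "mean_weight": (
                sum(tallies[lay]) / len(tallies[lay]) if lay in tallies else float("nan")
            ),
        }
        for lay in layers
    ]
    return pd.DataFrame(rows).set_index("layer")


def run_pipeline(table: CohortTable, cfg: PipelineConfig) -> PipelineResult:
    """Signed network -> forced simulations -> top-k paths, one call.

    Sources are all nodes of ``cfg.source_layers`` present in the signed
    network; targets are all ``cfg.target_layer`` nodes.
    """
    signed = build_signed_network(
        table, alpha=cfg.alpha, n_perm=cfg.n_perm, seed=derive_seed(cfg.seed, "signed")
    )
    sources = [v for lay in cfg.source_layers for v in table.variables(lay)]
    targets = table.variables(cfg.target_layer)
    paths = all_pairs_top_paths(
        signed, sources, targets, sim_cfg=cfg.sim, k=cfg.k, max_lag=cfg.max_lag,
        cc_floor=cfg.cc_floor, seed=derive_seed(cfg.seed, "paths"),
    )
    mln = None
    if cfg.include_multilayer:
        mln = build_multilayer_network(
            table, alpha=cfg.alpha, n_perm=cfg.n_perm, n_bins=cfg.n_bins,
            seed=derive_seed(cfg.seed, "mln"),
        )
    return PipelineResult(signed_network=signed, paths=paths, multilayer_network=mln)


def stratified_run(table: CohortTable, cfg: PipelineConfig) -> dict[str, PipelineResult]:
    """The full pipeline per diagnostic group, tagged by group name.

    Groups with fewer than ``cfg.min_group_n`` subjects are skipped with a
    warning (their statistics would be unreliable).
    """
    results: dict[str, PipelineResult] = {}
    for group in pd.unique(table.groups):
        sub = table.subset(group)
        if sub.n_subjects < cfg.min_group_n:
            warnings.warn(
                f"group {group!r} has {sub.n_subjects} subjects "
                f"(< {cfg.min_group_n}); skipped"
            )
            continue
        results[group] = run_pipeline(
            sub, replace(cfg, seed=derive_seed(cfg.seed, "group", group))
        )
    return results


def source_restricted_shortest_paths(
    graph: nx.Graph,
    sources: Sequence[Hashable],
    targets: Sequence[Hashable],
    n: int = 20,
) -> list[PathResult]:
    """Pooled n lowest-score paths from any source to any target.

    Computes the n best paths per (source, target) pair and returns the n
    globally lowest scores, ascending (ties broken lexicographically).
    """
    pool: list[PathResult] = []
    for s in sources:
        for t in targets:
            if s == t:
                continue
            pool.extend(k_lowest_score_paths(graph, s, t, k=n))
    pool.sort(key=lambda p: (p.score, [str(x) for x in p.nodes]))
    return pool[:n]
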