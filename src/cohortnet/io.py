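"""Plain-text serialization of cohorts, networks, traces and path records.

Cohorts are tab-delimited (empty cell = missing) with a companion metadata
table; networks go to flat edge lists and node-link JSON; connectance
matrices to delimited L x L tables with layer-name headers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .paths import PathResult, _flatten
from .synthetic import CohortTable

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_edge_list",
    "write_node_link",
    "read_node_link",
    "write_connectance",
    "read_connectance",
    "write_paths",
    "read_paths",
    "write_trace",
]


def write_cohort(table: CohortTable, data_path: str | Path, meta_path: str | Path) -> None:
    df = table.data.copy()
    df.insert(0, "group", table.groups.to_numpy())
    df.to_csv(data_path, sep="\t", index=True, na_rep="")
    table.meta.to_csv(meta_path, sep="\t")


def read_cohort(data_path: str | Path, meta_path: str | Path) -> CohortTable:
    df = pd.read_csv(data_path, sep="\t", index_col=0)
    groups = df.pop("group").reset_index(drop=True)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CohortTable(data=df.reset_index(drop=True), meta=meta, groups=groups)


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    rows = [
        {
            "source": u,
            "target": v,
            "layer_source": net.nodes[u].get("layer", ""),
            "layer_target": net.nodes[v].get("layer", ""),
            **{k: d[k] for k in sorted(d)},
        }
        for u, v, d in net.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_node_link(net: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(nx.node_link_data(net, edges="links"), fh, indent=1)


def read_node_link(path: str | Path) -> nx.Graph:
    with open(path) as fh:
        return nx.node_link_graph(json.load(fh), edges="links")


def write_connectance(cm: pd.DataFrame, path: str | Path) -> None:
    cm.to_csv(path, sep="\t")


def read_connectance(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_paths(paths: Iterable[PathResult] | Mapping, path: str | Path) -> None:
    """Structured text path records: source, target, rank, score, sequence."""
    flat = _flatten(paths)
    rows = []
    rank: dict[tuple, int] = {}
    for p in flat:
        key = (p.source, p.target)
        rank[key] = rank.get(key, 0) + 1
        rows.append({
            "source": p.source,
            "target": p.target,
            "rank": rank[key],
            "score": p.score,
            "nodes": " -> ".join(str(x) for x in p.nodes),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_paths(path: str | Path) -> list[PathResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        PathResult(
            nodes=tuple(str(r["nodes"]).split(" -> ")),
            score=float(r["score"]),
            source=r["source"],
            target=r["target"],
        )
        for _, r in df.iterrows()
    ]


def write_trace(trace, path: str | Path) -> None:
    """Nodes x time trace as TSV with a config header comment block."""
    cfg = trace.config
    with open(path, "w") as fh:
        for k in ("input_node", "steps", "half_period", "noise_prob",
                  "init_active_prob", "input_initial_phase", "seed"):
            fh.write(f"# {k}={getattr(cfg, k)}\n")
        trace.to_frame().to_csv(fh, sep="\t")
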