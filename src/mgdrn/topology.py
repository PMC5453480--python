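"""Topological ranking of nodes in the differential network.

Degree, betweenness centrality and closeness centrality are computed on the
undirected bipartite graph, each top-10 list is taken over miRNA nodes, and
the intersection of the three lists yields the key regulators. Path-based
centralities treat the graph as undirected and unweighted.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .diffnet import MGDRN

logger = logging.getLogger(__name__)

_ARM_SUFFIXES = ("-3p", "-5p")


def _as_graph(graph: MGDRN | nx.Graph) -> nx.Graph:
    return graph.to_networkx() if isinstance(graph, MGDRN) else graph


def degree(graph: MGDRN | nx.Graph, v: str) -> int:
    """Number of edges incident to ``v`` (simple graph, no multi-edges)."""
    g = _as_graph(graph)
    if v not in g:
        raise KeyError(f"unknown node {v!r}")
    return g.degree[v]


def betweenness_centrality(
    graph: MGDRN | nx.Graph, normalized: bool = True
) -> dict[str, float]:
    """Fraction of all-pairs shortest paths passing through each node.

    For node v: Σ_{s≠v≠t} σ_st(v)/σ_st over unordered pairs {s, t} with
    σ_st > 0, endpoints excluded, unreachable pairs contributing 0. With
    ``normalized`` the sum is divided by (N−1)(N−2)/2, its maximum on N
    nodes, so a star centre scores exactly 1. Graphs with fewer than three
    nodes have no interior pairs; every node scores 0.
    """
    g = _as_graph(graph)
    if g.number_of_nodes() < 3:
        return {v: 0.0 for v in g}
    return nx.betweenness_centrality(g, normalized=normalized)


def closeness_centrality(
    graph: MGDRN | nx.Graph, mode: str = "normalized"
) -> dict[str, float]:
    """Reciprocal-of-total-distance closeness, raw or component-normalized.

    ``raw`` returns 1/Σ_u d(u, v) over nodes reachable from v — the textbook
    reciprocal form, whose value shrinks with network size (bounded by
    1/(N−1)). ``normalized`` (default) returns the Wasserman–Faust form
    ((r−1)/Σd)·((r−1)/(N−1)) with r the size of v's connected component,
    which is comparable across components and network sizes and lies in
    [0, 1]. Isolated nodes score 0 in both modes.
    """
    g = _as_graph(graph)
    if mode == "normalized":
        return nx.closeness_centrality(g, wf_improved=True)
    if mode != "raw":
        raise ValueError(f"unknown closeness mode {mode!r}")
    out: dict[str, float] = {}
    for v in g:
        dist = nx.single_source_shortest_path_length(g, v)
        total = sum(d for u, d in dist.items() if u != v)
        out[v] = 1.0 / total if total > 0 else 0.0
    return out


def node_types(graph: MGDRN | nx.Graph) -> dict[str, str]:
    g = _as_graph(graph)
    return {v: g.nodes[v].get("node_type", "gene") for v in g}


def top_k(
    values: Mapping[str, float],
    k: int = 10,
    restrict_to: str = "all",
    types: Mapping[str, str] | None = None,
    include_ties: bool = False,
) -> list[str]:
    """Top-``k`` node ids by descending value, ties broken lexicographically.

    ``restrict_to`` limits ranking to ``"mirna"`` or ``"gene"`` nodes (then
    ``types`` is required). With ``include_ties``, every node tied with the
    k-th value is returned as well. Fewer than k nodes returns them all,
    with a warning.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if restrict_to not in ("all", "mirna", "gene"):
        raise ValueError(f"unknown restrict_to {restrict_to!r}")
    if restrict_to != "all":
        if types is None:
            raise ValueError("restrict_to requires a node-type mapping")
        values = {v: x for v, x in values.items() if types.get(v) == restrict_to}
    ranked = sorted(values, key=lambda v: (-values[v], v))
    if len(ranked) < k:
        logger.warning("top_k: only %d nodes available for k=%d", len(ranked), k)
        return ranked
    if include_ties:
        cutoff = values[ranked[k - 1]]
        return [v for v in ranked if values[v] >= cutoff]
    return ranked[:k]


def normalize_arm(mirna_id: str) -> str:
    """Strip a trailing -3p/-5p arm suffix for cross-list comparison."""
    for suffix in _ARM_SUFFIXES:
        if mirna_id.endswith(suffix):
            return mirna_id[: -len(suffix)]
    return mirna_id


def key_regulators(
    top_by_degree: Sequence[str],
    top_by_betweenness: Sequence[str],
    top_by_closeness: Sequence[str],
    normalize_arms: bool = True,
) -> set[str]:
    """Nodes appearing in all three top lists.

    Rankings may mix precursor names with specific mature arms of the same
    miRNA; with ``normalize_arms`` the -3p/-5p suffix is ignored so an arm
    and its precursor name count as the same regulator. The returned set
    holds normalized ids.
    """
    lists = (top_by_degree, top_by_betweenness, top_by_closeness)
    if any(len(lst) == 0 for lst in lists):
        raise ValueError("all three top lists must be non-empty")
    norm = normalize_arm if normalize_arms else (lambda x: x)
    sets = [{norm(v) for v in lst} for lst in lists]
    return sets[0] & sets[1] & sets[2]


def centrality_table(
    graph: MGDRN | nx.Graph, closeness_mode: str = "normalized"
) -> pd.DataFrame:
    """Per-node degree, betweenness and closeness as a DataFrame."""
    g = _as_graph(graph)
    types = node_types(g)
    btw = betweenness_centrality(g)
    cls = closeness_centrality(g, mode=closeness_mode)
    rows = [
        {
            "node": v,
            "type": types[v],
            "degree": g.degree[v],
            "betweenness": btw[v],
            "closeness": cls[v],
        }
        for v in sorted(g)
    ]
    return pd.DataFrame(rows).set_index("node")


def key_regulator_report(
    graph: MGDRN | nx.Graph,
    k: int = 10,
    restrict_to: str = "mirna",
    closeness_mode: str = "normalized",
    normalize_arms: bool = True,
) -> dict:
    """Three top-k centrality lists plus their intersection, JSON-ready."""
    g = _as_graph(graph)
    types = node_types(g)
    deg = {v: float(g.degree[v]) for v in g}
    btw = betweenness_centrality(g)
    cls = closeness_centrality(g, mode=closeness_mode)
    lists = {
        "top_by_degree": top_k(deg, k, restrict_to, types),
        "top_by_betweenness": top_k(btw, k, restrict_to, types),
        "top_by_closeness": top_k(cls, k, restrict_to, types),
    }
    inter = key_regulators(
        lists["top_by_degree"], lists["top_by_betweenness"],
        lists["top_by_closeness"], normalize_arms=normalize_arms,
    )
    return {**lists, "intersection": sorted(inter)}


def write_key_regulator_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")
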