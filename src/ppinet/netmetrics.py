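"""Topological metrics used to rank nodes: degree, betweenness, bridging.

Degree identifies hubs, betweenness centrality identifies bottlenecks, and
bridging centrality — betweenness multiplied by the bridging coefficient
b(v) = (1/deg(v)) / Σ_{u∈N(v)} 1/deg(u) — highlights nodes connecting
communities.  Betweenness is unnormalized (shortest-path pair counts with
even splitting over equal-length paths); Top-N rankings are invariant to
that scale choice.  Ties in :func:`select_top_n` break by node id so
replicate rankings are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

METRICS = ("degree", "betweenness", "bridging")


@dataclass
class CentralityMap:
    """Per-node values of one centrality metric."""

    metric: str
    values: dict[str, float]


def _as_graph(network) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    return network.to_networkx()


def bridging_coefficient(g: nx.Graph, v) -> float:
    """(1/deg(v)) / Σ_{u∈N(v)} 1/deg(u); 0 for isolated nodes or nodes all
    of whose neighbors are isolated apart from v."""
    dv = g.degree(v)
    if dv == 0:
        return 0.0
    denom = sum(1.0 / g.degree(u) for u in g.neighbors(v) if g.degree(u) > 0)
    if denom == 0:
        return 0.0
    return (1.0 / dv) / denom


def compute_centrality(network, metric: str) -> CentralityMap:
    """Compute one of the supported centrality maps over all nodes."""
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if metric == "degree":
        values = {v: float(d) for v, d in g.degree()}
    elif metric == "betweenness":
        values = {v: float(b) for v, b in nx.betweenness_centrality(g, normalized=False).items()}
    elif metric == "bridging":
        bet = nx.betweenness_centrality(g, normalized=False)
        values = {v: float(bet[v]) * bridging_coefficient(g, v) for v in g.nodes}
    else:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    return CentralityMap(metric=metric, values=values)


def select_top_n(cmap: CentralityMap, n: int) -> list[tuple[int, str, float]]:
    """Top-n nodes by value descending, ties by node id ascending.

    Returns (rank, node, value) triples, rank starting at 1; at most
    min(n, |V|) rows.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(cmap.values.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(rank, node, value) for rank, (node, value) in enumerate(ordered[:n], start=1)]
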