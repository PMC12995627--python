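"""Summary metrics of an undirected protein–protein interaction graph."""

from __future__ import annotations

import networkx as nx


def _check_simple(g: nx.Graph, min_nodes: int = 1) -> None:
    if g.number_of_nodes() < min_nodes:
        raise ValueError(f"graph needs at least {min_nodes} node(s)")
    if any(u == v for u, v in g.edges):
        raise ValueError("self-loops are not allowed")


def average_degree(g: nx.Graph) -> float:
    """2·|E| / |N|."""
    _check_simple(g)
    return 2.0 * g.number_of_edges() / g.number_of_nodes()


def avg_local_clustering(g: nx.Graph) -> float:
    """Mean local clustering coefficient, with C_i = 0 for degree-<2 nodes."""
    _check_simple(g)
    return float(nx.average_clustering(g, count_zeros=True))


def density(g: nx.Graph) -> float:
    """|E| / (|N|·(|N|−1)/2)."""
    _check_simple(g, min_nodes=2)
    return float(nx.density(g))


def summarize(g: nx.Graph) -> dict[str, float]:
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "average_degree": average_degree(g),
        "avg_local_clustering": avg_local_clustering(g),
        "density": density(g),
    }
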