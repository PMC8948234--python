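"""Key-driver analysis and signature-subnetwork extraction.

A key driver is a network node whose l-step neighborhood is maximally
enriched for a signature gene set (Fisher's exact test over the network
genes). Drivers are selected greedily: the most significant node is
accepted, every remaining candidate inside its l-step neighborhood is
discarded, and the scan continues down the sorted candidate list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .network import ConsensusNetwork
from .stats import fisher_exact

logger = logging.getLogger(__name__)

__all__ = [
    "Neighborhood",
    "KeyDriver",
    "neighborhood",
    "key_driver_analysis",
    "extract_signature_subnetworks",
]


def _graph_of(net) -> nx.DiGraph:
    return net.graph if isinstance(net, ConsensusNetwork) else net


@dataclass
class Neighborhood:
    """Nodes within ``l`` steps of the seed(s) plus their induced edges."""

    seeds: list[str]
    l: int
    direction: str  # downstream | undirected
    nodes: set[str]
    subgraph: nx.DiGraph


def neighborhood(net, seeds, l: int = 2,
                 direction: str = "downstream") -> Neighborhood:
    """Breadth-first expansion to depth ``l`` from the seed node(s).

    ``downstream`` follows directed edges (descendants); ``undirected``
    ignores edge direction. The returned subgraph is induced on the
    collected nodes.
    """
    g = _graph_of(net)
    if isinstance(seeds, str):
        seeds = [seeds]
    seeds = list(seeds)
    unknown = [s for s in seeds if s not in g]
    if unknown:
        raise ValueError(f"seed(s) not in network: {unknown}")
    if direction == "downstream":
        expand = g
    elif direction == "undirected":
        expand = g.to_undirected(as_view=True)
    else:
        raise ValueError(f"unknown direction: {direction}")
    nodes: set[str] = set(seeds)
    frontier = set(seeds)
    for _ in range(l):
        frontier = {w for u in frontier for w in expand.neighbors(u)} - nodes
        if not frontier:
            break
        nodes |= frontier
    return Neighborhood(seeds=seeds, l=l, direction=direction, nodes=nodes,
                        subgraph=g.subgraph(nodes).copy())


@dataclass
class KeyDriver:
    gene: str
    p: float
    odds_ratio: float
    neighborhood_size: int
    overlap: int
    rank: int


def key_driver_analysis(net, signature, p_thresh: float = 1e-8, l: int = 2,
                        direction: str = "downstream") -> list[KeyDriver]:
    """Greedy neighborhood-enrichment selection of key drivers.

    Every (gene) node's l-step neighborhood is Fisher-tested against the
    signature over the universe of network genes. Nodes with p below
    ``p_thresh`` are sorted by p (ties by gene identifier); the best is
    accepted, candidates within its l-step neighborhood are removed, and the
    scan continues through the sorted list.
    """
    g = _graph_of(net)
    universe = {n for n in g.nodes if ":" not in n}
    if not universe:
        raise ValueError("empty network")
    signature = set(signature) & universe
    if not signature:
        return []

    scored = []
    hoods: dict[str, set[str]] = {}
    for node in sorted(universe):
        nb = neighborhood(g, node, l=l, direction=direction).nodes & universe
        hoods[node] = nb
        a = len(nb & signature)
        b = len(nb - signature)
        c = len(signature - nb)
        d = len(universe) - a - b - c
        res = fisher_exact([[a, b], [c, d]])
        if res.p_two_sided < p_thresh:
            scored.append((res.p_two_sided, node, res.odds_ratio_cmle,
                           len(nb), a))
    scored.sort(key=lambda r: (r[0], r[1]))

    drivers: list[KeyDriver] = []
    excluded: set[str] = set()
    for p, node, oddsr, size, overlap in scored:
        if node in excluded:
            continue
        drivers.append(KeyDriver(gene=node, p=p, odds_ratio=oddsr,
                                 neighborhood_size=size, overlap=overlap,
                                 rank=len(drivers) + 1))
        excluded |= hoods[node]
    return drivers


def drivers_frame(drivers: list[KeyDriver]) -> pd.DataFrame:
    """Tabular rendering of a key-driver list."""
    return pd.DataFrame(
        [(d.gene, d.p, d.odds_ratio, d.neighborhood_size, d.overlap, d.rank)
         for d in drivers],
        columns=["gene", "p", "odds_ratio", "neighborhood_size",
                 "overlap", "rank"])


def extract_signature_subnetworks(net, signature) -> list[nx.DiGraph]:
    """Connected components of the signature-induced subnetwork.

    The network is restricted to signature genes; components are taken under
    undirected connectivity and returned as induced directed subgraphs
    sorted by size (largest first, ties by smallest member name).
    """
    g = _graph_of(net)
    members = [n for n in g.nodes if n in set(signature)]
    sub = g.subgraph(members)
    comps = [set(c) for c in nx.connected_components(sub.to_undirected())]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return [g.subgraph(c).copy() for c in comps]
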