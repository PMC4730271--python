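"""Degree-percentile hub annotation and intra-compartment connectivity.

Hubs are the top-percentile most connected proteins of the full PPI network
(default: top 20% by degree).  The percentile cut is converted to a degree
threshold k* — the degree of the node at rank ceil(p/100 * n) when sorted by
decreasing degree — and every node with degree >= k* is a hub, so ties at
the threshold are all included and the result is order-independent.

An intra-compartment hub is a compartment protein that still clears the same
global threshold k* after discarding its interactions with nuclear proteins
of *other* compartments (edges to partners sharing at least one compartment,
and to non-nuclear partners, are kept).  A per-compartment re-ranked
percentile is available via ``method="rerank"``.
"""

from __future__ import annotations

from math import ceil
from typing import Iterable, Mapping, Sequence

import networkx as nx

HUB_PERCENTILE = 20.0


def build_network(edges: Iterable[tuple[str, str]]) -> nx.Graph:
    """Simple undirected graph from an id-pair edge list (self-loops dropped)."""
    g = nx.Graph()
    g.add_edges_from((a, b) for a, b in edges if a != b)
    return g


def hub_degree_threshold(network: nx.Graph, percentile: float = HUB_PERCENTILE) -> int:
    """Degree threshold k* such that nodes with degree >= k* are hubs."""
    if network.number_of_nodes() == 0:
        raise ValueError("cannot annotate hubs on an empty network")
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    degrees = sorted((d for _, d in network.degree()), reverse=True)
    rank = ceil(percentile / 100.0 * len(degrees))
    return int(degrees[rank - 1])


def annotate_hubs(
    network: nx.Graph, percentile: float = HUB_PERCENTILE
) -> tuple[frozenset[str], int]:
    """Hub set and the degree threshold k* it was cut at."""
    k_star = hub_degree_threshold(network, percentile)
    hubs = frozenset(n for n, d in network.degree() if d >= k_star)
    return hubs, k_star


def intra_compartment_degrees(
    network: nx.Graph, compartments: Mapping[str, frozenset[str]]
) -> dict[str, int]:
    """Degree after removing edges to nuclear proteins of disjoint compartment sets.

    Computed for every compartment-assigned node of the network.  A neighbour
    is kept if it is non-nuclear (no compartments) or shares at least one
    compartment with the protein.
    """
    out: dict[str, int] = {}
    for node in network.nodes:
        mine = compartments.get(node)
        if not mine:
            continue
        kept = 0
        for nbr in network.neighbors(node):
            theirs = compartments.get(nbr)
            if not theirs or (mine & theirs):
                kept += 1
        out[node] = kept
    return out


def annotate_intra_hubs(
    network: nx.Graph,
    compartments: Mapping[str, frozenset[str]],
    k_star: int | None = None,
    percentile: float = HUB_PERCENTILE,
    method: str = "global",
) -> dict[str, frozenset[str]]:
    """Per-compartment intra-hub sets.

    ``method="global"`` (default) reuses the full-network degree threshold
    ``k_star`` so counts are comparable across compartments; pass the value
    returned by :func:`annotate_hubs`, or it is recomputed here.
    ``method="rerank"`` instead re-applies the percentile cut to the
    intra-compartment degrees within each compartment.
    """
    if method not in ("global", "rerank"):
        raise ValueError(f"method must be 'global' or 'rerank', got {method!r}")
    intra = intra_compartment_degrees(network, compartments)
    comp_labels = sorted({c for comps in compartments.values() for c in comps})
    out: dict[str, frozenset[str]] = {}
    if method == "global":
        if k_star is None:
            k_star = hub_degree_threshold(network, percentile)
        for c in comp_labels:
            out[c] = frozenset(
                p for p, d in intra.items() if c in compartments.get(p, ()) and d >= k_star
            )
        return out
    for c in comp_labels:
        members = sorted(p for p in intra if c in compartments.get(p, ()))
        if not members:
            out[c] = frozenset()
            continue
        degs = sorted((intra[p] for p in members), reverse=True)
        rank = ceil(percentile / 100.0 * len(degs))
        cut = degs[rank - 1]
        out[c] = frozenset(p for p in members if intra[p] >= cut)
    return out


def connectivity_summary(
    group: Sequence[str],
    network: nx.Graph,
    hubs: frozenset[str],
    intra_degrees: Mapping[str, int] | None = None,
    intra_hubs: frozenset[str] | None = None,
) -> dict[str, float]:
    """Hub fractions and mean (intra-)degree over a group of PPI-mapped proteins.

    When ``intra_degrees`` is not supplied (e.g. for the non-nuclear control
    group, which has no compartment), intra quantities fall back to the plain
    degree and hub status.
    """
    members = [p for p in group if network.has_node(p)]
    if not members:
        raise ValueError("connectivity summary of an empty (or unmapped) group")
    n = len(members)
    degs = [network.degree(p) for p in members]
    if intra_degrees is None:
        idegs = degs
        ihubs = hubs
    else:
        idegs = [intra_degrees.get(p, network.degree(p)) for p in members]
        ihubs = intra_hubs if intra_hubs is not None else hubs
    return {
        "n": n,
        "pct_hubs": 100.0 * sum(p in hubs for p in members) / n,
        "pct_intra_hubs": 100.0 * sum(p in ihubs for p in members) / n,
        "mean_degree": sum(degs) / n,
        "mean_intra_degree": sum(idegs) / n,
    }
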