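"""Pathway-glycogene bipartite graph and functional hub selection.

Enriched pathways that contain at least one differentially expressed
glycogene form one partition; the DE glycogenes they contain form the
other. A glycogene's degree is the number of pathways it belongs to,
and the glycogene of maximal degree is the functional hub (PLOD3-style
candidate in real data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from glycohub.io import GeneSetCollection

__all__ = ["build_bipartite", "rank_by_degree", "select_hub", "HubSelection"]


def build_bipartite(
    enriched_sets: GeneSetCollection, de_glycogenes: Sequence[str]
) -> nx.Graph:
    """Membership graph between enriched pathways and DE glycogenes.

    Pathway nodes (bipartite=0) are the enriched sets containing at
    least one DE glycogene; gene nodes (bipartite=1) are the DE
    glycogenes present in at least one such set. An empty intersection
    yields an empty graph with a warning, not an error.
    """
    genes = set(de_glycogenes)
    if not genes:
        raise ValueError("de_glycogenes must be non-empty")
    graph = nx.Graph()
    for s in enriched_sets:
        members = [g for g in s.members if g in genes]
        if not members:
            continue
        graph.add_node(s.name, bipartite=0)
        for g in members:
            graph.add_node(g, bipartite=1)
            graph.add_edge(s.name, g)
    if graph.number_of_nodes() == 0:
        warnings.warn("no enriched pathway contains a DE glycogene; empty graph")
    return graph


def gene_nodes(graph: nx.Graph) -> list[str]:
    return [n for n, d in graph.nodes(data=True) if d.get("bipartite") == 1]


def rank_by_degree(graph: nx.Graph) -> list[tuple[str, int, int]]:
    """Glycogenes ordered by pathway degree, competition-ranked.

    Ties share a rank (1,1,3,... style) and are listed alphabetically
    within a tie. Returns (gene, degree, rank) triples; an empty graph
    yields an empty list.
    """
    degrees = sorted(
        ((g, graph.degree[g]) for g in gene_nodes(graph)),
        key=lambda t: (-t[1], t[0]),
    )
    out: list[tuple[str, int, int]] = []
    for i, (g, d) in enumerate(degrees):
        rank = out[i - 1][2] if i > 0 and out[i - 1][1] == d else i + 1
        out.append((g, d, rank))
    return out


@dataclass(frozen=True)
class HubSelection:
    """Rank-1 glycogene(s); ``tied`` flags a multi-way tie at the top."""

    genes: tuple[str, ...]
    degree: int
    tied: bool

    @property
    def gene(self) -> str:
        """The hub gene (alphabetically first on a tie)."""
        return self.genes[0]


def select_hub(graph: nx.Graph) -> HubSelection:
    """The glycogene with the highest pathway degree."""
    ranking = rank_by_degree(graph)
    if not ranking:
        raise ValueError("cannot select a hub from an empty graph")
    top = [g for g, _, r in ranking if r == 1]
    return HubSelection(tuple(top), ranking[0][1], len(top) > 1)
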