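"""Protein-protein interaction networks as undirected gene-symbol graphs."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx


def normalize_symbol(gene: str) -> str:
    """Case-insensitive, whitespace-trimmed gene symbol matching."""
    return gene.strip().upper()


@dataclass
class PPINetwork:
    """Undirected, self-loop-free interaction network over gene symbols."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "PPINetwork":
        g = nx.Graph()
        for a, b in edges:
            a, b = normalize_symbol(a), normalize_symbol(b)
            if a == b:
                continue
            g.add_edge(a, b)
        return cls(g)

    @property
    def genes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self.graph
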