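"""Mutation connection scores: how functionally clustered a sample's
mutated genes are on a protein-protein interaction network.

The score of one sample is the fraction of its mutated genes that interact
with at least one other mutated gene of the same sample:

    score = n_connected / n_mutated

with n_connected counted as degree >= 1 in the subgraph of the PPI network
induced on the sample's mutated gene set.  Randomly scattered mutations
score near 0; mutations concentrated in a functional module score near 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import scipy.stats

from .network import PPINetwork, normalize_symbol


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class ConnectionScore:
    sample_id: str
    n_mutated: int
    n_connected: int

    @property
    def score(self) -> float:
        return self.n_connected / self.n_mutated


def connection_score(
    mutated_genes: Iterable[str],
    network: PPINetwork,
    sample_id: str = "",
    reading: str = "induced",
) -> ConnectionScore:
    """Score one sample's mutated gene set against a PPI network.

    ``reading="induced"`` (default) counts a gene as connected when it has
    an interaction partner *within the mutated set*; ``reading="global"``
    counts any interaction in the full network, which measures little more
    than network coverage and is provided only for comparison.
    Genes absent from the network count as unconnected.
    """
    genes = {normalize_symbol(g) for g in mutated_genes}
    if not genes:
        raise DegenerateInputError("empty mutated gene set")
    if reading == "induced":
        sub = network.graph.subgraph(g for g in genes if g in network.graph)
        n_connected = sum(1 for g in sub.nodes if sub.degree(g) >= 1)
    elif reading == "global":
        n_connected = sum(
            1 for g in genes if g in network.graph and network.graph.degree(g) >= 1
        )
    else:
        raise ValueError(f"unknown reading {reading!r}")
    return ConnectionScore(sample_id, len(genes), n_connected)


def compare_score_groups(
    scores_by_group: Mapping[str, Sequence[float]],
) -> dict[tuple[str, str], tuple[float, float]]:
    """Pairwise two-sided Wilcoxon rank-sum tests between score groups.

    Returns (U statistic, p value) per unordered group pair.  The exact
    null distribution is used for small pooled samples (n <= 20), the
    tie-corrected normal approximation otherwise.
    """
    names = list(scores_by_group)
    for g in names:
        if len(scores_by_group[g]) < 2:
            raise DegenerateInputError(f"group {g!r} has fewer than 2 observations")
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            x, y = scores_by_group[a], scores_by_group[b]
            method = "exact" if len(x) + len(y) <= 20 else "asymptotic"
            res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            out[(a, b)] = (float(res.statistic), float(min(res.pvalue, 1.0)))
    return out
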