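"""Network-derived predictors.

Genes are nodes in a weighted functional-interaction network whose edge
weights are log-likelihood scores. Two measures of proximity to a seed set
(the known haploinsufficient genes) are computed: the unweighted shortest
path to the nearest seed and the summed weight of direct links to seeds.
For a gene that is itself a seed, leave-one-out removes it from the seed
set for its own computation so the feature carries no label leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx


@dataclass(frozen=True)
class ProximityResult:
    gene_id: str
    shortest_path_hops: int | None  # None = unreachable or absent
    direct_weight_sum: float | None  # None = gene absent from network


def node_degree(network: nx.Graph, gene: str) -> int | None:
    """Distinct-neighbor count; None (missing) for a gene not in the network."""
    if gene not in network:
        return None
    return network.degree(gene)


def proximity_to_seeds(
    network: nx.Graph,
    seeds: set[str] | list[str],
    gene: str,
    exclude_self: bool = True,
) -> ProximityResult:
    """Shortest-path hops to the nearest seed and summed direct edge weight.

    ``exclude_self`` applies leave-one-out when the gene is itself a seed.
    A gene absent from the network yields missing values; a present gene
    with no path to any seed has missing hops but a (zero) weight sum.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set must be non-empty")
    if gene not in network:
        return ProximityResult(gene, None, None)
    targets = seeds - {gene} if exclude_self else seeds

    weight_sum = 0.0
    for nbr in network[gene]:
        if nbr in targets:
            weight_sum += network[gene][nbr]["weight"]

    if gene in targets:
        return ProximityResult(gene, 0, weight_sum)
    hops = None
    for depth, layer in enumerate(nx.bfs_layers(network, gene)):
        if targets.intersection(layer):
            hops = depth
            break
    return ProximityResult(gene, hops, weight_sum)


def proximity_table(
    network: nx.Graph,
    seeds: set[str] | list[str],
    genes: list[str],
    exclude_self: bool = True,
):
    """Proximity results for many genes as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for g in genes:
        r = proximity_to_seeds(network, seeds, g, exclude_self=exclude_self)
        rows.append(
            {
                "gene_id": g,
                "shortest_path_hops": r.shortest_path_hops,
                "direct_weight_sum": r.direct_weight_sum,
                "degree": node_degree(network, g),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
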