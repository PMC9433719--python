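"""Within/between-network decomposition and strength-based hub scoring.

Once a suprathreshold component is identified, its edges are classified as
within-network (both regions share a network) or between-network (unordered
network pair), and summed-|t| strengths are computed per region (node
strength) and per network pair.  Regions are ranked by node strength; the
top-ranked regions with high degree are reported descriptively as
provincial hubs.  Strengths sum the *absolute* t values, so an all-negative
component still yields positive strengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import RegionSet, edge_count
from .nbs import ComponentResult, EdgeStatMap


def _net_pair(a: str, b: str) -> tuple:
    return (a, b) if a <= b else (b, a)


def classify_links(component: ComponentResult, regions: RegionSet) -> tuple:
    """Split component edges into within- and between-network groups.

    Returns ``(within, between)``: ``within`` maps network name -> edge
    list, ``between`` maps unordered network pairs ``(netA, netB)`` ->
    edge list.  The labeling is exhaustive and exclusive.
    """
    within: dict = {}
    between: dict = {}
    for i, j in component.edge_list:
        if not (0 <= i < regions.n_regions and 0 <= j < regions.n_regions):
            raise ValueError(f"edge ({i}, {j}) references unknown region")
        ni, nj = regions.networks[i], regions.networks[j]
        if ni == nj:
            within.setdefault(ni, []).append((i, j))
        else:
            between.setdefault(_net_pair(ni, nj), []).append((i, j))
    return within, between


def possible_links(partition_sizes: Sequence[int]) -> tuple:
    """Total possible within- and between-network links for a partition.

    ``within_total = sum_k n_k (n_k - 1) / 2``; ``between_total`` is the
    remainder of all ``R (R - 1) / 2`` links.
    """
    sizes = [int(s) for s in partition_sizes]
    if not sizes or any(s <= 0 for s in sizes):
        raise ValueError("partition sizes must be positive")
    R = sum(sizes)
    within_total = sum(s * (s - 1) // 2 for s in sizes)
    return within_total, edge_count(R) - within_total


@dataclass
class StrengthTable:
    """Node and network-pair strength summaries of a component."""

    nodes: pd.DataFrame = field(repr=False)          # region_id, label, network, strength, degree
    network_pairs: pd.DataFrame = field(repr=False)  # network_a, network_b, strength, n_links, possible_links

    def hubs(self, top_k: int = 3, min_degree: int = 10) -> pd.DataFrame:
        """Top-k regions by node strength with degree above ``min_degree``."""
        eligible = self.nodes[self.nodes["degree"] > min_degree]
        return eligible.head(top_k).reset_index(drop=True)


def strength_table(
    component: ComponentResult, stats: EdgeStatMap, regions: RegionSet
) -> StrengthTable:
    """Summed-|t| strengths per region and per network pair of a component.

    Node strength of a region is the sum of |t| over its incident component
    edges (so total node strength is exactly twice the total edge |t|, the
    handshake identity).  Regions are sorted by strength, ties broken by
    degree then region index.
    """
    R = regions.n_regions
    node_strength = np.zeros(R)
    node_degree = np.zeros(R, dtype=int)
    pair_strength: dict = {}
    pair_count: dict = {}
    for (i, j), flat in zip(component.edge_list, component.edge_indices):
        if flat >= stats.n_edges:
            raise ValueError(f"edge {flat} missing from statistics map")
        w = abs(float(stats.t_values[flat]))
        node_strength[[i, j]] += w
        node_degree[[i, j]] += 1
        key = _net_pair(regions.networks[i], regions.networks[j])
        pair_strength[key] = pair_strength.get(key, 0.0) + w
        pair_count[key] = pair_count.get(key, 0) + 1

    nodes = pd.DataFrame(
        {
            "region_id": np.arange(R),
            "label": regions.labels,
            "network": regions.networks,
            "strength": node_strength,
            "degree": node_degree,
        }
    )
    nodes = nodes.sort_values(
        by=["strength", "degree", "region_id"], ascending=[False, False, True]
    ).reset_index(drop=True)

    sizes = regions.partition_sizes()
    rows = []
    names = regions.network_names
    for a, b in list(combinations(names, 2)) + [(n, n) for n in names]:
        key = _net_pair(a, b)
        possible = (
            sizes[a] * (sizes[a] - 1) // 2 if a == b else sizes[a] * sizes[b]
        )
        rows.append(
            {
                "network_a": key[0],
                "network_b": key[1],
                "strength": pair_strength.get(key, 0.0),
                "n_links": pair_count.get(key, 0),
                "possible_links": possible,
            }
        )
    pairs = (
        pd.DataFrame(rows)
        .sort_values("strength", ascending=False)
        .reset_index(drop=True)
    )
    return StrengthTable(nodes=nodes, network_pairs=pairs)


def connectogram_edges(
    component: ComponentResult, stats: EdgeStatMap, regions: RegionSet
) -> pd.DataFrame:
    """Connectogram-ready edge list: labels, networks and t per edge."""
    rows = []
    for (i, j), flat in zip(component.edge_list, component.edge_indices):
        rows.append(
            {
                "region_a": regions.labels[i],
                "network_a": regions.networks[i],
                "region_b": regions.labels[j],
                "network_b": regions.networks[j],
                "t": float(stats.t_values[flat]),
            }
        )
    return pd.DataFrame(rows)
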