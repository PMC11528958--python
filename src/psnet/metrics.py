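"""Descriptive statistics for patient-sharing networks.

Conventions: density = 2E / (N(N-1)); mean distance averages geodesic
lengths over *reachable* ordered pairs only (the number of unreachable
pairs is reported alongside); transitivity is the global clustering
coefficient; betweenness is unnormalized shortest-path betweenness on the
unweighted graph.  Undefined quantities are NaN, never exceptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from psnet.errors import SpecificationError

#: Scalar statistics, in report order.
SCALAR_STATS = (
    "n_nodes",
    "n_edges",
    "mean_degree",
    "density",
    "mean_distance",
    "transitivity",
    "mean_betweenness",
)


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    mean_degree: float
    density: float
    mean_distance: float
    n_unreachable_pairs: int
    transitivity: float
    mean_betweenness: float
    relative_degree: dict = field(default_factory=dict)
    relative_betweenness: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flatten into a single mapping (one comparison-report row)."""
        row = {s: getattr(self, s) for s in SCALAR_STATS}
        row["n_unreachable_pairs"] = self.n_unreachable_pairs
        for level, v in self.relative_degree.items():
            row[f"relative_degree_{level}"] = v
        for level, v in self.relative_betweenness.items():
            row[f"relative_betweenness_{level}"] = v
        return row


def mean_geodesic_distance(net: nx.Graph) -> tuple[float, int]:
    """Mean shortest-path length over reachable ordered pairs.

    Returns (mean, number of unreachable ordered pairs); mean is NaN when
    no pair is reachable.
    """
    n = net.number_of_nodes()
    total = 0
    reachable = 0
    for _, lengths in nx.all_pairs_shortest_path_length(net):
        total += sum(lengths.values())
        reachable += len(lengths) - 1  # drop the self-pair
    unreachable = n * (n - 1) - reachable
    if reachable == 0:
        return math.nan, unreachable
    return total / reachable, unreachable


def network_summary(
    net: nx.Graph,
    attribute: str = "occupation",
    with_betweenness: bool = True,
) -> NetworkStats:
    """Compute the full statistics bundle for one network.

    Relative per-group ratios are computed for ``attribute`` when it has
    at least two observed levels, otherwise left empty.
    """
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n == 0:
        return NetworkStats(0, 0, math.nan, math.nan, math.nan, 0, math.nan, math.nan)
    mean_degree = 2 * e / n
    density = math.nan if n < 2 else 2 * e / (n * (n - 1))
    mean_dist, unreachable = mean_geodesic_distance(net)
    transitivity = nx.transitivity(net)
    stats = NetworkStats(
        n_nodes=n,
        n_edges=e,
        mean_degree=mean_degree,
        density=density,
        mean_distance=mean_dist,
        n_unreachable_pairs=unreachable,
        transitivity=transitivity,
        mean_betweenness=math.nan,
    )
    if with_betweenness:
        bc = nx.betweenness_centrality(net, normalized=False, weight=None)
        stats.mean_betweenness = sum(bc.values()) / n
    levels = {net.nodes[v].get(attribute) for v in net.nodes}
    levels.discard(None)
    if len(levels) >= 2:
        stats.relative_degree = relative_group_metric(net, attribute, "degree")
        if with_betweenness:
            stats.relative_betweenness = relative_group_metric(
                net, attribute, "betweenness"
            )
    return stats


def relative_group_metric(net: nx.Graph, attribute: str, metric: str) -> dict:
    """In-group mean centrality divided by out-group mean centrality.

    For each level g of ``attribute``: mean(metric | node in g) /
    mean(metric | node not in g).  A zero (or empty) denominator yields
    NaN, matching the dashes of suppressed report cells.
    """
    if metric == "degree":
        values = dict(net.degree())
    elif metric == "betweenness":
        values = nx.betweenness_centrality(net, normalized=False, weight=None)
    else:
        raise SpecificationError(f"unknown metric {metric!r}")
    groups: dict = {}
    for v in net.nodes:
        groups.setdefault(net.nodes[v].get(attribute), []).append(values[v])
    groups.pop(None, None)
    if len(groups) < 2:
        raise SpecificationError(
            f"attribute {attribute!r} has fewer than 2 observed levels"
        )
    out = {}
    for level in sorted(groups):
        inside = groups[level]
        outside = [x for g, vals in groups.items() if g != level for x in vals]
        mean_in = sum(inside) / len(inside)
        mean_out = sum(outside) / len(outside) if outside else math.nan
        out[level] = math.nan if not mean_out else mean_in / mean_out
        if mean_out == 0:
            out[level] = math.nan
    return out


def stats_table(rows: dict[str, NetworkStats]) -> pd.DataFrame:
    """Assemble named NetworkStats into one comparison frame."""
    return pd.DataFrame({name: s.to_row() for name, s in rows.items()}).T
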