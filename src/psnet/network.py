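"""Professional attribute resolution, bipartite construction and projection.

The patient-sharing network is an undirected :class:`networkx.Graph` over
professional ids with node attributes ``occupation`` and ``municipality``
and edge attribute ``shared_patients`` (number of distinct common
patients).  The construction threshold is stored in ``G.graph["min_shared"]``.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from psnet.cohort import DEFAULT_OCCUPATION_MAP

logger = logging.getLogger(__name__)

_PAT = "pat::"
_PRO = "pro::"


def _modal_with_tiebreak(values: pd.Series, rng: np.random.Generator) -> tuple[str, bool]:
    """Most frequent value; exact ties broken by a seeded uniform draw."""
    counts = values.value_counts()
    top = counts[counts == counts.iloc[0]].index.tolist()
    if len(top) == 1:
        return top[0], False
    return rng.choice(sorted(top)), True


def resolve_attributes(
    visits: pd.DataFrame,
    seed: int,
    occupation_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-professional modal occupation class and modal municipality.

    Occupation codes are first mapped to {physician, nurse, other}; codes
    absent from the map fall back to "other".  Exact frequency ties are
    broken uniformly at random among the tied values using ``seed``;
    tie-break outcomes are recorded in ``result.attrs["tie_breaks"]``.
    """
    occupation_map = dict(occupation_map or DEFAULT_OCCUPATION_MAP)
    rng = np.random.default_rng(seed)
    df = visits[["professional_id", "occupation_code", "municipality"]].copy()
    df["occupation"] = df["occupation_code"].map(lambda c: occupation_map.get(c, "other"))

    rows = []
    tie_log = []
    for pid, grp in df.groupby("professional_id", sort=True):
        occ, occ_tied = _modal_with_tiebreak(grp["occupation"], rng)
        muni, muni_tied = _modal_with_tiebreak(grp["municipality"], rng)
        rows.append((pid, occ, muni))
        if occ_tied:
            tie_log.append((pid, "occupation", occ))
        if muni_tied:
            tie_log.append((pid, "municipality", muni))
    if tie_log:
        logger.info("attribute tie-breaks: %d (seed=%d)", len(tie_log), seed)
    out = pd.DataFrame(rows, columns=["professional_id", "occupation", "municipality"])
    out.attrs["tie_breaks"] = tie_log
    return out


def build_bipartite(visits: pd.DataFrame) -> nx.Graph:
    """Two-mode patient-professional graph; tie weight = visit count.

    Patient nodes carry ``bipartite=0``, professional nodes ``bipartite=1``;
    ids are namespaced so the two sets can never collide.
    """
    bg = nx.Graph()
    if len(visits) == 0:
        return bg
    counts = visits.groupby(["patient_id", "professional_id"]).size()
    bg.add_nodes_from(
        (_PAT + str(p) for p in visits["patient_id"].unique()), bipartite=0
    )
    bg.add_nodes_from(
        (_PRO + str(h) for h in visits["professional_id"].unique()), bipartite=1
    )
    bg.add_weighted_edges_from(
        (_PAT + str(p), _PRO + str(h), int(w)) for (p, h), w in counts.items()
    )
    return bg


def project_sharing(
    bg: nx.Graph,
    min_shared: int = 5,
    keep_isolates: bool = True,
) -> nx.Graph:
    """One-mode projection: professionals tied iff they share >= ``min_shared``
    distinct patients; edge weight is the exact shared-patient count.

    Professionals with no qualifying tie are kept as isolated nodes when
    ``keep_isolates`` (the default), so density denominators always refer
    to the full professional set.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    pair_counts: dict[tuple[str, str], int] = {}
    professionals = []
    for node, data in bg.nodes(data=True):
        if data.get("bipartite") == 1:
            professionals.append(node[len(_PRO):])
        else:
            neigh = sorted(n[len(_PRO):] for n in bg.neighbors(node))
            for pair in combinations(neigh, 2):
                pair_counts[pair] = pair_counts.get(pair, 0) + 1
    net = nx.Graph(min_shared=min_shared)
    if keep_isolates:
        net.add_nodes_from(professionals)
    net.add_edges_from(
        (i, j, {"shared_patients": w})
        for (i, j), w in pair_counts.items()
        if w >= min_shared
    )
    return net


def set_node_attributes_from_table(net: nx.Graph, professionals: pd.DataFrame) -> nx.Graph:
    """Attach occupation/municipality attributes from a professional table."""
    table = professionals.set_index("professional_id")
    occ = {str(k): str(v) for k, v in table["occupation"].items()}
    muni = {str(k): str(v) for k, v in table["municipality"].items()}
    nx.set_node_attributes(net, occ, "occupation")
    nx.set_node_attributes(net, muni, "municipality")
    return net


def build_sharing_network(
    visits: pd.DataFrame,
    min_shared: int = 5,
    keep_isolates: bool = True,
    professionals: pd.DataFrame | None = None,
    seed: int = 0,
) -> nx.Graph:
    """Convenience: resolve attributes (unless given), project, attach attrs."""
    if professionals is None:
        professionals = resolve_attributes(visits, seed=seed)
    bg = build_bipartite(visits)
    net = project_sharing(bg, min_shared=min_shared, keep_isolates=keep_isolates)
    return set_node_attributes_from_table(net, professionals)


def prune_small_components(net: nx.Graph, min_size: int = 5) -> nx.Graph:
    """Drop connected components smaller than ``min_size`` nodes.

    Intended for layout export only; statistics are computed on the
    unpruned network.
    """
    keep: set = set()
    for comp in nx.connected_components(net):
        if len(comp) >= min_size:
            keep |= comp
    return net.subgraph(keep).copy()


def export_layout(net: nx.Graph, seed: int) -> pd.DataFrame:
    """Force-directed (Fruchterman-Reingold) coordinates for plotting.

    Returns columns id, x, y, degree, occupation; deterministic for a
    fixed seed.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot lay out an empty network")
    pos = nx.spring_layout(net, seed=seed)
    deg = dict(net.degree())
    rows = [
        (n, float(pos[n][0]), float(pos[n][1]), deg[n], net.nodes[n].get("occupation", ""))
        for n in net.nodes
    ]
    return pd.DataFrame(rows, columns=["id", "x", "y", "degree", "occupation"])


def write_network(net: nx.Graph, graphml_path, edgelist_path=None) -> None:
    """Serialize as GraphML and (optionally) a tab-delimited edge list."""
    nx.write_graphml(net, graphml_path)
    if edgelist_path is not None:
        rows = sorted(
            (str(u), str(v), d["shared_patients"]) if str(u) <= str(v)
            else (str(v), str(u), d["shared_patients"])
            for u, v, d in net.edges(data=True)
        )
        pd.DataFrame(rows, columns=["source", "target", "shared_patients"]).to_csv(
            edgelist_path, sep="\t", index=False
        )
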