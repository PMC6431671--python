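"""Typed interaction networks, centralities and triple-median hub screening.

Networks are simple undirected graphs whose nodes carry a role (herb,
compound, putative_target or disease_target) and whose edges carry a
combined confidence score in [0, 1].  Edges are first thinned by the
median-score rule (keep scores strictly above the median of all scores);
shortest paths are then unweighted — the score never acts as a path weight.

Three centralities drive hub screening:

* degree — number of links to the node;
* betweenness — for node v, the sum over unordered pairs (s, t) of the
  fraction of shortest s-t paths passing through v (pair-fraction
  convention, unnormalized);
* closeness — (n_comp - 1) / sum of distances to the other nodes of v's
  connected component (Wasserman-Faust per-component form; isolated
  nodes score 0).

A *major hub* is a node whose degree, betweenness and closeness all
strictly exceed the respective network-wide cut statistic (median by
default; mean available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NODE_ROLES = ("herb", "compound", "putative_target", "disease_target")
METRICS = ("degree", "betweenness", "closeness")


def build_network(
    edges: pd.DataFrame,
    nodes: pd.DataFrame | None = None,
) -> nx.Graph:
    """Build a simple scored graph from an edge table (node_a, node_b,
    combined_score), optionally adding roles / isolated nodes from a node
    table (node_id, role)."""
    g = nx.Graph()
    if nodes is not None:
        bad_roles = set(nodes["role"]) - set(NODE_ROLES)
        if bad_roles:
            raise ValueError(f"unknown node roles: {sorted(bad_roles)}")
        for _, row in nodes.iterrows():
            g.add_node(row["node_id"], role=row["role"])
    for _, row in edges.iterrows():
        a, b, s = row["node_a"], row["node_b"], float(row["combined_score"])
        if a == b:
            raise ValueError(f"self-loop on node {a!r} not allowed")
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"combined_score {s} outside [0, 1] on edge {a}-{b}")
        if nodes is not None and (a not in g or b not in g):
            missing = [n for n in (a, b) if n not in g]
            raise ValueError(f"edge endpoints missing from node table: {missing}")
        g.add_edge(a, b, combined_score=s)
    return g


def filter_edges_by_median_score(edges: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Keep edges whose combined_score strictly exceeds the median score.

    Returns (filtered edges, retained fraction).  With a strict cut the
    retained fraction never exceeds one half; if every score is equal,
    nothing survives and a warning is emitted.
    """
    if edges.empty:
        raise ValueError("cannot median-filter an empty edge list")
    med = float(np.median(edges["combined_score"].to_numpy(float)))
    keep = edges["combined_score"] > med
    retained = float(keep.mean())
    if retained == 0.0:
        logger.warning("median edge filter retained no edges (all scores <= %g)", med)
    return edges.loc[keep].reset_index(drop=True), retained


def degree(g: nx.Graph) -> dict:
    return dict(g.degree())


def betweenness(g: nx.Graph) -> dict:
    # unnormalized pair-fraction convention: path A-B-C gives B exactly 1.0
    return nx.betweenness_centrality(g, normalized=False)


def closeness(g: nx.Graph) -> dict:
    # Wasserman-Faust per-component closeness without the component scaling
    return nx.closeness_centrality(g, wf_improved=False)


def topology_table(g: nx.Graph) -> pd.DataFrame:
    """One TopologyRecord per node: node_id, degree, betweenness, closeness."""
    deg, btw, clo = degree(g), betweenness(g), closeness(g)
    return pd.DataFrame(
        {
            "node_id": list(g.nodes()),
            "degree": [deg[n] for n in g.nodes()],
            "betweenness": [btw[n] for n in g.nodes()],
            "closeness": [clo[n] for n in g.nodes()],
        }
    ).sort_values("node_id", ignore_index=True)


@dataclass
class HubSelection:
    """Outcome of the triple-cut hub screen: the three cut values, the hub
    list and a per-node audit of each criterion."""

    cuts: dict[str, float]
    hubs: list[str]
    audit: pd.DataFrame = field(repr=False)
    stat: str = "median"


def select_hubs(records: pd.DataFrame, stat: str = "median") -> HubSelection:
    """Screen major hubs: all three centralities strictly above their cut.

    ``records`` is a topology table (node_id, degree, betweenness,
    closeness).  The cut statistic is the median by default (mean
    available).  The audit table reports each node's pass/fail per metric.
    """
    if records.empty:
        raise ValueError("need at least one topology record")
    if stat not in ("median", "mean"):
        raise ValueError(f"unknown cut statistic {stat!r}")
    agg = np.median if stat == "median" else np.mean
    cuts = {m: float(agg(records[m].to_numpy(float))) for m in METRICS}
    audit = records[["node_id"]].copy()
    for m in METRICS:
        audit[f"passes_{m}"] = records[m].to_numpy(float) > cuts[m]
    audit["is_hub"] = audit[[f"passes_{m}" for m in METRICS]].all(axis=1)
    hubs = sorted(audit.loc[audit["is_hub"], "node_id"])
    return HubSelection(cuts=cuts, hubs=hubs, audit=audit, stat=stat)


def write_sif(g: nx.Graph, path, interaction: str = "pp") -> None:
    """Export edges as SIF (node_a TAB interaction TAB node_b)."""
    with open(path, "w") as fh:
        for a, b in sorted(g.edges()):
            fh.write(f"{a}\t{interaction}\t{b}\n")
        for n in sorted(nx.isolates(g)):
            fh.write(f"{n}\n")
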