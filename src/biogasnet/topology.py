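"""Module detection, Guimera-Amaral connectivity roles and network summaries.

Nodes are assigned to modules by greedy modularity maximization on the
unsigned, unweighted skeleton of the network (a deterministic stand-in for
interactive community plugins).  Each node then gets a within-module degree
z-score and a participation coefficient

    z_i = (k_i,own - mean_own) / sd_own,      P_i = 1 - sum_s (k_is / k_i)^2,

and a topological role from the standard (z, P) cut-offs: peripheral
(z <= 2.5, P <= 0.62), connector (z <= 2.5, P > 0.62), module hub (z > 2.5,
P <= 0.62), network hub (z > 2.5, P > 0.62).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities

Z_THRESHOLD = 2.5
P_THRESHOLD = 0.62

ROLE_PERIPHERAL = "peripheral"
ROLE_CONNECTOR = "connector"
ROLE_MODULE_HUB = "module_hub"
ROLE_NETWORK_HUB = "network_hub"
ROLES = (ROLE_PERIPHERAL, ROLE_CONNECTOR, ROLE_MODULE_HUB, ROLE_NETWORK_HUB)


def detect_modules(graph: nx.Graph, seed: int = 0) -> dict:
    """Assign every node to exactly one module.

    Greedy modularity maximization on the unsigned skeleton; isolated nodes
    and singleton components form their own modules.  Module ids are integers
    ordered by (descending size, smallest member) so the assignment is
    deterministic for a given graph; ``seed`` is accepted for interface
    stability but the algorithm itself is deterministic.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot detect modules in an empty graph")
    skeleton = nx.Graph()
    skeleton.add_nodes_from(graph.nodes)
    skeleton.add_edges_from(graph.edges)
    if skeleton.number_of_edges() == 0:
        communities = [{n} for n in skeleton.nodes]
    else:
        communities = [set(c) for c in greedy_modularity_communities(skeleton)]
    communities.sort(key=lambda c: (-len(c), min(map(str, c))))
    return {node: mid for mid, comm in enumerate(communities) for node in comm}


def connectivity_stats(graph: nx.Graph, modules: dict) -> pd.DataFrame:
    """Per-node degree, within-module degree z and participation coefficient.

    ``z`` standardizes the node's own-module link count against its module's
    distribution (population sd; sd = 0 gives z = 0).  ``P`` measures how
    evenly the node's links spread over modules; an isolated node gets
    z = 0, P = 0.
    """
    missing = set(graph.nodes) - set(modules)
    if missing:
        raise ValueError(f"modules do not cover all nodes: {sorted(map(str, missing))[:5]}")
    nodes = list(graph.nodes)
    own_degree = {}
    participation = {}
    for n in nodes:
        counts: dict[int, int] = {}
        for nb in graph.neighbors(n):
            counts[modules[nb]] = counts.get(modules[nb], 0) + 1
        k = sum(counts.values())
        own_degree[n] = counts.get(modules[n], 0)
        participation[n] = 1.0 - sum((c / k) ** 2 for c in counts.values()) if k else 0.0

    z = {}
    for mid in set(modules[n] for n in nodes):
        members = [n for n in nodes if modules[n] == mid]
        ks = np.array([own_degree[n] for n in members], dtype=float)
        sd = ks.std(ddof=0)
        mean = ks.mean()
        for n, kown in zip(members, ks):
            z[n] = (kown - mean) / sd if sd > 0 else 0.0

    return pd.DataFrame(
        {
            "module_id": [modules[n] for n in nodes],
            "degree": [graph.degree(n) for n in nodes],
            "within_module_degree": [own_degree[n] for n in nodes],
            "z": [z[n] for n in nodes],
            "P": [participation[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node_id"),
    )


def assign_role(z: float, P: float,
                z_thresh: float = Z_THRESHOLD, p_thresh: float = P_THRESHOLD) -> str:
    """Topological role from within-module degree z and participation P."""
    if z <= z_thresh:
        return ROLE_PERIPHERAL if P <= p_thresh else ROLE_CONNECTOR
    return ROLE_MODULE_HUB if P <= p_thresh else ROLE_NETWORK_HUB


def role_table(graph: nx.Graph, seed: int = 0,
               z_thresh: float = Z_THRESHOLD, p_thresh: float = P_THRESHOLD) -> pd.DataFrame:
    """Modules + connectivity statistics + role label for every node."""
    modules = detect_modules(graph, seed=seed)
    table = connectivity_stats(graph, modules)
    table["role"] = [assign_role(zi, pi, z_thresh, p_thresh)
                     for zi, pi in zip(table["z"], table["P"])]
    return table


@dataclass
class NetworkSummary:
    """Headline counts of a signed co-occurrence network."""

    nodes: int
    edges_positive: int
    edges_negative: int
    edges_total: int
    edges_in_module: int
    edges_outside_module: int
    n_modules: int
    n_connectors: int
    n_module_hubs: int
    n_network_hubs: int
    n_peripherals: int

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


def summarize_network(graph: nx.Graph, roles: pd.DataFrame) -> NetworkSummary:
    """Count nodes, signed edges, in/out-of-module edges, modules and roles.

    An edge is in-module iff both endpoints share a module.  Edge sign is read
    from the ``sign`` edge attribute (+1 co-presence / -1 exclusion; missing
    sign counts as positive).
    """
    modules = roles["module_id"]
    pos = neg = inside = outside = 0
    for a, b, data in graph.edges(data=True):
        if data.get("sign", 1) >= 0:
            pos += 1
        else:
            neg += 1
        if modules[a] == modules[b]:
            inside += 1
        else:
            outside += 1
    counts = roles["role"].value_counts()
    return NetworkSummary(
        nodes=graph.number_of_nodes(),
        edges_positive=pos,
        edges_negative=neg,
        edges_total=pos + neg,
        edges_in_module=inside,
        edges_outside_module=outside,
        n_modules=int(modules.nunique()),
        n_connectors=int(counts.get(ROLE_CONNECTOR, 0)),
        n_module_hubs=int(counts.get(ROLE_MODULE_HUB, 0)),
        n_network_hubs=int(counts.get(ROLE_NETWORK_HUB, 0)),
        n_peripherals=int(counts.get(ROLE_PERIPHERAL, 0)),
    )
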