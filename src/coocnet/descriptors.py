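"""Global network descriptors and ecological role classification.

The descriptor suite summarises one signed co-occurrence network:

=================  ======================================================
N                  number of nodes (the fixed OTU universe)
L                  number of links (significant strong correlations)
N_C                connected nodes (OTUs with at least one link)
L_max              N(N-1)/2, the maximum undirected link count
D                  density, L / L_max
L_P, L_N           positive / negative link counts
%L_P, %L_N         their proportions of L
m_t, m_p, m_n      mean strength over all / positive / negative links
n_sub              subnetworks: connected components with >= 2 nodes
mean degree        2L / N_C (average over *connected* nodes)
d_max              maximum node degree; ties all reported
=================  ======================================================

Node degree doubles as the centrality measure: a high-degree OTU is a
candidate community "hub".  An OTU whose links are mostly negative is
classified competitive, mostly positive cooperative; an exact tie is
labelled mixed and an unlinked OTU neutral.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import networkx as nx
import pandas as pd

from .network import InteractionNetwork

__all__ = ["NetworkDescriptors", "NodeRole", "compute_descriptors",
           "classify_roles", "descriptor_table", "roles_table", "round3"]


def round3(x: float) -> float:
    """Half-away-from-zero rounding at 3 decimals (presentation only)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class NetworkDescriptors:
    """The descriptor bundle for one network (full precision)."""

    n_nodes: int
    n_links: int
    n_connected: int
    l_max: int
    density: float
    n_pos: int
    n_neg: int
    prop_pos: float | None
    prop_neg: float | None
    mean_total: float | None
    mean_pos: float | None
    mean_neg: float | None
    n_subnetworks: int
    mean_degree: float
    max_degree: int
    max_degree_nodes: list[str]


ROLE_COMPETITIVE = "competitive"
ROLE_COOPERATIVE = "cooperative"
ROLE_MIXED = "mixed"
ROLE_NEUTRAL = "neutral"


@dataclass
class NodeRole:
    otu_id: str
    degree: int
    degree_pos: int
    degree_neg: int
    role: str
    is_hub: bool


def compute_descriptors(network: InteractionNetwork) -> NetworkDescriptors:
    g = network.to_networkx()
    n = len(network.nodes)
    strengths = list(network.links.values())
    l = len(strengths)
    pos = [s for s in strengths if s > 0]
    neg = [s for s in strengths if s < 0]
    degrees = dict(g.degree())
    connected = [v for v, d in degrees.items() if d > 0]
    n_c = len(connected)
    l_max = n * (n - 1) // 2
    n_sub = sum(1 for comp in nx.connected_components(g) if len(comp) >= 2)
    d_max = max(degrees.values(), default=0)
    hubs = ([v for v in network.nodes if degrees[v] == d_max]
            if d_max > 0 else [])
    return NetworkDescriptors(
        n_nodes=n,
        n_links=l,
        n_connected=n_c,
        l_max=l_max,
        density=l / l_max if l_max else 0.0,
        n_pos=len(pos),
        n_neg=len(neg),
        prop_pos=len(pos) / l if l else None,
        prop_neg=len(neg) / l if l else None,
        mean_total=sum(strengths) / l if l else None,
        mean_pos=sum(pos) / len(pos) if pos else None,
        mean_neg=sum(neg) / len(neg) if neg else None,
        n_subnetworks=n_sub,
        mean_degree=2.0 * l / n_c if n_c else 0.0,
        max_degree=d_max,
        max_degree_nodes=hubs,
    )


def classify_roles(network: InteractionNetwork) -> list[NodeRole]:
    """Majority-sign role per node; hubs are all nodes attaining d_max."""
    signed = network.signed_degrees()
    d_max = max((p + m for p, m in signed.values()), default=0)
    roles = []
    for node in network.nodes:
        p, m = signed[node]
        d = p + m
        if d == 0:
            role = ROLE_NEUTRAL
        elif m > p:
            role = ROLE_COMPETITIVE
        elif p > m:
            role = ROLE_COOPERATIVE
        else:
            role = ROLE_MIXED
        roles.append(NodeRole(otu_id=node, degree=d, degree_pos=p,
                              degree_neg=m, role=role,
                              is_hub=d > 0 and d == d_max))
    return roles


_ROW_ORDER = [
    ("Number of links (L)", "n_links"),
    ("Number of connected nodes (N_C)", "n_connected"),
    ("Density of the network (D)", "density"),
    ("Number of positive links (L_P)", "n_pos"),
    ("Number of negative links (L_N)", "n_neg"),
    ("Proportion of positive links (%L_P)", "prop_pos"),
    ("Proportion of negative links (%L_N)", "prop_neg"),
    ("Mean of total correlations (m_t)", "mean_total"),
    ("Mean of positive correlations (m_p)", "mean_pos"),
    ("Mean of negative correlations (m_n)", "mean_neg"),
    ("Number of subnetworks (n_sub)", "n_subnetworks"),
    ("Mean degree", "mean_degree"),
    ("Maximum degree (d_max)", "max_degree"),
    ("OTUs with maximum degree", "max_degree_nodes"),
]


def descriptor_table(networks: dict[str, InteractionNetwork]) -> pd.DataFrame:
    """One column per network, descriptor rows in report order, reals at 3 d.p.

    Prepends the node count and L_max rows so the table is self-contained
    (17 rows in total); empty link classes render as ``-``.
    """
    if not networks:
        raise ValueError("need at least one network")
    cols = {}
    for label, net in networks.items():
        d = compute_descriptors(net)
        col = {"Number of nodes (N)": d.n_nodes,
               "Maximum possible links (L_max)": d.l_max,
               "Number of hubs": len(d.max_degree_nodes)}
        for row, attr in _ROW_ORDER:
            v = getattr(d, attr)
            if v is None:
                v = "-"
            elif attr == "max_degree_nodes":
                v = ", ".join(v) if v else "-"
            elif isinstance(v, float):
                v = f"{round3(v):.3f}"
            col[row] = v
        cols[label] = col
    return pd.DataFrame(cols)


def roles_table(network: InteractionNetwork) -> pd.DataFrame:
    """Per-OTU role report: id, lineage, signed link counts, role, hub flag."""
    ann = network.node_annotations
    rows = []
    for r in classify_roles(network):
        lineage = ""
        if ann is not None and r.otu_id in ann.index and "lineage" in ann:
            lineage = str(ann.loc[r.otu_id, "lineage"])
        rows.append({"otu": r.otu_id, "lineage": lineage,
                     "positive_links": r.degree_pos,
                     "negative_links": r.degree_neg,
                     "degree": r.degree, "role": r.role, "hub": r.is_hub})
    return pd.DataFrame(rows)
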