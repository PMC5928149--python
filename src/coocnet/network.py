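"""Signed co-occurrence networks on a fixed OTU node universe.

A link is a significant strong correlation: pseudo p-value at or below
the significance threshold and absolute correlation strictly exceeding
the strength cut-off (default 0.5).  Positive links are read as proxies
for cooperation, negative links for competition.  Networks built per
developmental stage share one node universe — the union of all OTUs
linked in at least one stage — so that stage networks are directly
comparable and isolated (degree-0) nodes are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .sparcc import CorrelationResult

__all__ = [
    "InteractionNetwork",
    "build_network",
    "union_node_set",
    "restrict_to_universe",
    "shared_links",
    "write_edgelist_tsv",
    "read_edgelist_tsv",
    "write_graphml",
    "write_node_table_tsv",
]


@dataclass
class InteractionNetwork:
    """Undirected signed weighted graph on an ordered node list.

    ``links`` maps ``(a, b)`` OTU-id pairs — ordered by node position,
    ``a`` before ``b`` — to correlation strengths in [-1, 1] with
    absolute value above the construction cut-off.  ``node_annotations``
    optionally carries a taxonomy ``lineage`` string and ``median_reads``
    per node (used for the canonical node ordering).
    """

    nodes: list[str]
    links: dict[tuple[str, str], float] = field(default_factory=dict)
    node_annotations: pd.DataFrame | None = None
    stage_label: str = ""

    def __post_init__(self) -> None:
        order = {n: k for k, n in enumerate(self.nodes)}
        if len(order) != len(self.nodes):
            raise ValueError("duplicate node ids")
        canon = {}
        for (a, b), s in self.links.items():
            if a == b:
                raise ValueError(f"self-link on {a}")
            if a not in order or b not in order:
                raise ValueError(f"link ({a},{b}) outside node universe")
            key = (a, b) if order[a] < order[b] else (b, a)
            if key in canon and canon[key] != s:
                raise ValueError(f"conflicting strengths for link {key}")
            canon[key] = float(s)
        self.links = canon

    # -- derived quantities ----------------------------------------------

    @property
    def n_links(self) -> int:
        return len(self.links)

    def linked_nodes(self) -> set[str]:
        return {n for pair in self.links for n in pair}

    def signed_degrees(self) -> dict[str, tuple[int, int]]:
        """Per node: (number of positive links, number of negative links)."""
        deg = {n: [0, 0] for n in self.nodes}
        for (a, b), s in self.links.items():
            k = 0 if s > 0 else 1
            deg[a][k] += 1
            deg[b][k] += 1
        return {n: (p, m) for n, (p, m) in deg.items()}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), s in self.links.items():
            g.add_edge(a, b, strength=s, sign="+" if s > 0 else "-")
        if self.node_annotations is not None:
            for col in self.node_annotations.columns:
                nx.set_node_attributes(
                    g, self.node_annotations[col].to_dict(), name=col)
        return g


def build_network(result: CorrelationResult, p_threshold: float = 0.05,
                  r_threshold: float = 0.5,
                  nodes: list[str] | None = None,
                  node_annotations: pd.DataFrame | None = None,
                  stage_label: str = "") -> InteractionNetwork:
    """Keep links with ``pval <= p_threshold`` and ``|rho| > r_threshold``.

    The strength cut-off is strict ("exceeding"), the significance
    cut-off inclusive.  ``nodes`` fixes the universe; by default it is
    the correlation matrix's own OTU list.
    """
    if result.pvals is None:
        raise ValueError("CorrelationResult has no pseudo p-values; "
                         "run pseudo_pvalues first")
    nodes = list(result.otu_ids) if nodes is None else list(nodes)
    idx = {o: k for k, o in enumerate(result.otu_ids)}
    missing = [n for n in nodes if n not in idx]
    if missing:
        raise ValueError(f"universe nodes absent from result: {missing}")
    links: dict[tuple[str, str], float] = {}
    for a_pos in range(len(nodes)):
        for b_pos in range(a_pos + 1, len(nodes)):
            a, b = nodes[a_pos], nodes[b_pos]
            i, j = idx[a], idx[b]
            r = result.rho[i, j]
            if abs(r) > r_threshold and result.pvals[i, j] <= p_threshold:
                links[(a, b)] = float(r)
    return InteractionNetwork(nodes=nodes, links=links,
                              node_annotations=node_annotations,
                              stage_label=stage_label)


def _phylum(lineage: str) -> str:
    return str(lineage).split(";")[0].strip()


def union_node_set(networks: list[InteractionNetwork]) -> list[str]:
    """Union of all OTUs incident to at least one link in any network.

    Ordered by (phylum-level lineage, descending median reads, id) when
    annotations are available for every member, else lexicographically —
    a deterministic stand-in for "arranged by taxonomy and relative
    abundance".
    """
    if not networks:
        raise ValueError("need at least one network")
    members: set[str] = set()
    for net in networks:
        members |= net.linked_nodes()
    ann = {}
    for net in networks:
        if net.node_annotations is not None:
            for n, row in net.node_annotations.iterrows():
                ann.setdefault(str(n), row)
    if members and members <= set(ann):
        return sorted(members, key=lambda n: (
            _phylum(ann[n].get("lineage", "")),
            -float(ann[n].get("median_reads", 0.0)),
            n))
    return sorted(members)


def restrict_to_universe(network: InteractionNetwork,
                         universe: list[str]) -> InteractionNetwork:
    """Re-seat a network on a (larger) universe, keeping every link.

    Adds isolated nodes, never drops links; node order follows the
    universe.  A linked node outside the universe is an error.
    """
    outside = network.linked_nodes() - set(universe)
    if outside:
        raise ValueError(f"linked nodes outside universe: {sorted(outside)}")
    ann = network.node_annotations
    if ann is not None:
        ann = ann.reindex(universe)
    return InteractionNetwork(nodes=list(universe),
                              links=dict(network.links),
                              node_annotations=ann,
                              stage_label=network.stage_label)


def shared_links(networks: dict[str, InteractionNetwork]
                 ) -> list[tuple[tuple[str, str], list[str]]]:
    """Links present in two or more networks, with the stages carrying them."""
    universes = {tuple(net.nodes) for net in networks.values()}
    if len(universes) != 1:
        raise ValueError("networks must share one node universe")
    where: dict[tuple[str, str], list[str]] = {}
    for stage, net in networks.items():
        for pair in net.links:
            where.setdefault(pair, []).append(stage)
    return [(pair, stages) for pair, stages in where.items()
            if len(stages) >= 2]


# -- persistence ----------------------------------------------------------

def write_edgelist_tsv(network: InteractionNetwork, path: str | Path) -> None:
    """Edge list as TSV: source, target, strength (full precision), sign."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tstrength\tsign\n")
        for (a, b), s in network.links.items():
            fh.write(f"{a}\t{b}\t{s!r}\t{'+' if s > 0 else '-'}\n")


def read_edgelist_tsv(path: str | Path, nodes: list[str],
                      stage_label: str = "") -> InteractionNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    links = {(r.source, r.target): float(r.strength)
             for r in df.itertuples(index=False)}
    return InteractionNetwork(nodes=list(nodes), links=links,
                              stage_label=stage_label)


def write_graphml(network: InteractionNetwork, path: str | Path) -> None:
    nx.write_graphml(network.to_networkx(), path)


def write_node_table_tsv(network: InteractionNetwork, path: str | Path) -> None:
    rows = []
    for n in network.nodes:
        row = {"id": n, "stage": network.stage_label}
        if network.node_annotations is not None and n in network.node_annotations.index:
            row.update(network.node_annotations.loc[n].to_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
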