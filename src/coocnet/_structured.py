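"""Deterministic construction of networks with prescribed global structure.

Useful for arithmetic checks and worked examples: given node counts, a
target number of connected nodes and signed link counts, build one graph
realising them — a spanning path over the connected nodes plus extra
links in lexicographic order, positive links first.
"""

from __future__ import annotations

from .network import InteractionNetwork

__all__ = ["structured_network"]


def structured_network(n_nodes: int, n_connected: int, n_pos: int,
                       n_neg: int, pos_strength: float = 0.6,
                       neg_strength: float = -0.6,
                       stage_label: str = "") -> InteractionNetwork:
    """A network with exactly the requested N, N_C, L_P and L_N.

    Requires ``n_pos + n_neg >= n_connected - 1`` (a spanning path over
    the connected nodes) and enough room for the extras.
    """
    n_links = n_pos + n_neg
    if n_connected > n_nodes:
        raise ValueError("n_connected cannot exceed n_nodes")
    if n_connected >= 2 and n_links < n_connected - 1:
        raise ValueError("too few links to connect n_connected nodes")
    if n_links > n_connected * (n_connected - 1) // 2:
        raise ValueError("too many links for n_connected nodes")
    if n_links > 0 and n_connected < 2:
        raise ValueError("links need at least 2 connected nodes")
    nodes = [f"u{k:03d}" for k in range(n_nodes)]
    pairs: list[tuple[str, str]] = []
    path = [(nodes[k], nodes[k + 1]) for k in range(n_connected - 1)]
    pairs.extend(path)
    used = set(path)
    for i in range(n_connected):
        for j in range(i + 1, n_connected):
            if len(pairs) == n_links:
                break
            p = (nodes[i], nodes[j])
            if p not in used:
                pairs.append(p)
                used.add(p)
    strengths = [pos_strength] * n_pos + [neg_strength] * n_neg
    return InteractionNetwork(nodes=nodes,
                              links=dict(zip(pairs, strengths)),
                              stage_label=stage_label)
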