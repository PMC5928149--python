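"""Independent brute-force oracles kept deliberately separate from the
package implementation: plain loops over edges and explicit equation
lists, no shared helpers."""

from __future__ import annotations

import numpy as np


def brute_force_descriptors(nodes: list[str],
                            edges: dict[tuple[str, str], float]) -> dict:
    """Descriptor suite by exhaustive edge iteration (no graph library)."""
    n = len(nodes)
    l = len(edges)
    deg = {v: 0 for v in nodes}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    connected = [v for v in nodes if deg[v] > 0]
    # connected components by repeated flood fill over the edge list
    comp_of = {}
    comp_id = 0
    for v in nodes:
        if v in comp_of:
            continue
        stack, members = [v], set()
        while stack:
            u = stack.pop()
            if u in members:
                continue
            members.add(u)
            for a, b in edges:
                if a == u and b not in members:
                    stack.append(b)
                elif b == u and a not in members:
                    stack.append(a)
        for u in members:
            comp_of[u] = comp_id
        comp_id += 1
    comp_sizes = {}
    for v, c in comp_of.items():
        comp_sizes[c] = comp_sizes.get(c, 0) + 1
    pos = [s for s in edges.values() if s > 0]
    neg = [s for s in edges.values() if s < 0]
    l_max = n * (n - 1) // 2
    d_max = max(deg.values(), default=0)
    return {
        "n_nodes": n,
        "n_links": l,
        "n_connected": len(connected),
        "l_max": l_max,
        "density": l / l_max if l_max else 0.0,
        "n_pos": len(pos),
        "n_neg": len(neg),
        "prop_pos": len(pos) / l if l else None,
        "prop_neg": len(neg) / l if l else None,
        "mean_total": sum(edges.values()) / l if l else None,
        "mean_pos": sum(pos) / len(pos) if pos else None,
        "mean_neg": sum(neg) / len(neg) if neg else None,
        "n_subnetworks": sum(1 for c, s in comp_sizes.items() if s >= 2),
        "mean_degree": (2.0 * l / len(connected)) if connected else 0.0,
        "max_degree": d_max,
        "max_degree_nodes": [v for v in nodes if deg[v] == d_max and d_max > 0],
    }


def lstsq_basis_variances(t: np.ndarray, excluded_pairs=frozenset(),
                          floor: float = 1e-6) -> np.ndarray:
    """Least-squares solve of the explicit pair equations w_i + w_j = t_ij."""
    d = t.shape[0]
    excl = {(min(i, j), max(i, j)) for i, j in excluded_pairs}
    rows, rhs = [], []
    for i in range(d):
        for j in range(i + 1, d):
            if (i, j) in excl:
                continue
            row = np.zeros(d)
            row[i] = row[j] = 1.0
            rows.append(row)
            rhs.append(t[i, j])
    sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    return np.where(sol > 0, sol, floor)


def naive_pearson_on_fractions(counts: np.ndarray) -> np.ndarray:
    """The estimator the log-ratio method replaces: Pearson on closed
    relative abundances (negatively biased by the closure)."""
    fr = counts / counts.sum(axis=1, keepdims=True)
    return np.corrcoef(fr, rowvar=False)


def random_signed_graph(rng: np.random.Generator,
                        max_nodes: int = 12
                        ) -> tuple[list[str], dict[tuple[str, str], float]]:
    """A random node list plus signed strengths on a random edge subset."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"OTU{k}" for k in range(n)]
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.3:
                s = rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
                edges[(nodes[i], nodes[j])] = float(s)
    return nodes, edges
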