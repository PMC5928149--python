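#!/usr/bin/env python
"""Build the co-occurrence networks and compute descriptors and roles.

Thresholds the inferred correlations (pseudo p <= 0.05 and |rho| > 0.5),
forms the union node universe across the whole-development and stage
networks, re-seats every network on that universe, and writes the
descriptor table, per-stage role tables, shared links, edge lists and
GraphML files under results/networks/.
"""

from pathlib import Path

import pandas as pd

from coocnet.descriptors import descriptor_table, roles_table
from coocnet.network import (build_network, restrict_to_universe,
                             shared_links, union_node_set,
                             write_edgelist_tsv, write_graphml)
from coocnet.sparcc import CorrelationResult, read_matrix_tsv

IN = Path("results/inference")
OUT = Path("results/networks")
LABELS = ["whole", "larva", "juvenile", "adult"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    nets = {}
    for label in LABELS:
        rho, ids = read_matrix_tsv(IN / f"rho_{label}.tsv")
        pvals, _ = read_matrix_tsv(IN / f"pvals_{label}.tsv")
        res = CorrelationResult(rho=rho, otu_ids=ids, pvals=pvals)
        nets[label] = build_network(res, stage_label=label)

    universe = union_node_set(list(nets.values()))
    nets = {lab: restrict_to_universe(net, universe)
            for lab, net in nets.items()}
    print(f"union universe: {len(universe)} OTUs linked in >= 1 network")

    table = descriptor_table(nets)
    table.to_csv(OUT / "descriptor_table.tsv", sep="\t")
    print(table.loc[["Number of links (L)", "Number of connected nodes (N_C)",
                     "Density of the network (D)", "Mean degree"]])

    for label, net in nets.items():
        write_edgelist_tsv(net, OUT / f"edges_{label}.tsv")
        write_graphml(net, OUT / f"network_{label}.graphml")
        roles_table(net).to_csv(OUT / f"roles_{label}.tsv", sep="\t",
                                index=False)

    stage_nets = {k: v for k, v in nets.items() if k != "whole"}
    shared = shared_links(stage_nets)
    pd.DataFrame([{"source": a, "target": b, "stages": ",".join(st)}
                  for (a, b), st in shared]).to_csv(
        OUT / "shared_links.tsv", sep="\t", index=False)
    for (a, b), st in shared:
        print(f"shared link {a}-{b} present in: {', '.join(st)}")
    print(f"reports written to {OUT}/")


if __name__ == "__main__":
    main()
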