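# coocnet

Inference and analysis of bacteria–bacteria co-occurrence networks from
compositional 16S OTU count tables, with the community-comparison
statistics used to evaluate recolonization experiments, and a synthetic
data generator with known ground truth.

## The problem

Amplicon sequencing of a host-associated bacterial community yields
*relative* abundances: each sample's counts are closed to the sequencing
depth. Naive Pearson correlations between OTU fractions are therefore
negatively biased and cannot be read as interactions. The log-ratio
approach (SparCC) works around the closure: for OTUs *i*, *j* the
variation statistic

    t_ij = Var[ log(f_i / f_j) ] = ω_i + ω_j − 2 ρ_ij √(ω_i ω_j)

depends only on ratios, with ω_i the log-scale variance of the
unobserved *basis* (absolute) abundance and ρ_ij the basis correlation.
Under sparsity (most pairs uncorrelated) the ω solve a linear system in
the row sums of *t*; correlations follow from the identity, the single
strongest pair is iteratively excluded from the system and the solution
refined, and count uncertainty is integrated out by resampling fractions
from a Dirichlet posterior (counts + 1) and taking the elementwise
median. Significance comes from permutation pseudo *p*-values (per-OTU
independent shuffles, two-sided via |ρ|).

A signed network keeps links with pseudo *p* ≤ 0.05 and |ρ| > 0.5
(strict). Positive links proxy cooperation, negative links competition.
Per-node signed degrees classify OTUs as competitive (mostly negative
links), cooperative (mostly positive), neutral (unlinked) or hubs
(maximum degree); a descriptor suite (density, signed link counts and
means, subnetworks, mean/max degree) summarises each network. Community
comparisons use the standard workflow: drop OTUs under 50 total reads,
rarefy to 10,000 reads, Chao1 (bias-corrected, ten rarefaction
replicates), Bray–Curtis distances, PCoA, PERMANOVA (ADONIS-style R²
and permutation *p*), and isolate fold-change over-representation.

Intended users: microbiome researchers who want a tested, seedable
implementation of this exact chain — inference → network → descriptors
→ community statistics — plus a generator to validate it end-to-end.

## Worked example

The numbered scripts under `analysis/` run the whole chain on synthetic
data (450 samples × 40 OTUs, three developmental stages with planted
strong correlations, one edge shared between larva and adult):

```bash
python analysis/01_simulate_communities.py
python analysis/02_infer_networks.py
python analysis/03_describe_networks.py
python analysis/04_recolonization_metrics.py
```

prints, among other things:

```
whole     n=450  strong |rho|>0.5: 30
larva     n=150  strong |rho|>0.5: 3
juvenile  n=150  strong |rho|>0.5: 4
adult     n=150  strong |rho|>0.5: 2
shared link OTU000-OTU001 present in: larva, adult
PERMANOVA source1 vs source2: R2 = 0.355, p = 0.004 (PC1 explains 37.4%)
estimated over-representation of OTU022: 8.9-fold at 3dpr
```

The per-stage networks recover exactly the planted edge counts (3, 4
and 2) and the one deliberately shared larva/adult edge; the whole
series pooled across stages shows additional links driven by
stage-level abundance shifts — the same reason a whole-development
network differs from its stage networks on real data. Two distinct
source communities separate significantly in Bray–Curtis space, and a
10-fold spiked isolate is measured back at ≈9-fold over-representation
after rarefaction (sampling error and closure account for the
shrinkage). Tables land under `results/`.

Library use mirrors the scripts:

```python
from coocnet import (BasisSpec, simulate_counts, infer_correlations,
                     pseudo_pvalues, build_network, compute_descriptors)

spec = BasisSpec(n_otus=50, planted_edges=((0, 1, 0.8),), seed=1)
ds = simulate_counts(spec, n_samples=500, depth=5000)
table = ds.to_otu_table()
res = pseudo_pvalues(table, infer_correlations(table, seed=2),
                     n_perm=1000, seed=3)
net = build_network(res)             # p <= 0.05 and |rho| > 0.5
print(compute_descriptors(net).n_links)
```

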