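# Methods

## Basis-correlation inference

The estimator treats each sample's observed counts as a multinomial
draw from closed fractions of unobserved absolute ("basis") abundances.
For OTUs *i*, *j* the log-ratio variance across samples,
`t_ij = Var[log(f_i/f_j)]`, is closure-invariant and decomposes as
`ω_i + ω_j − 2 ρ_ij √(ω_i ω_j)` with ω the basis log-variances and ρ
the basis correlations. Two approximations make it estimable:

1. **Sparsity.** Assuming most pairs are uncorrelated, dropping the
   cross terms leaves one equation `ω_i + ω_j ≈ t_ij` per pair. The
   implementation solves the least-squares normal equations of that
   system — `(ones(D,D) + (D−2)·I) ω = rowsum(t)` for the full pair
   set — which an independent `lstsq` oracle over the explicit pair
   equations confirms to 1e−8 in the tests. Strong pairs violate the
   assumption, so the single strongest |ρ| above 0.1 is excluded from
   the system and the solution re-computed, up to 10 iterations
   (excluding one pair per iteration); a singular system after
   exclusions keeps the last valid estimate. Below D = 4 the system is
   degenerate and the input is rejected.
2. **Count uncertainty.** Fractions are not plugged in as `counts/total`
   but resampled 20 times from the per-sample Dirichlet posterior with
   a symmetric unit prior (counts + 1), which also guarantees strictly
   positive fractions for the logarithms. Per-resample correlation
   matrices are aggregated by the elementwise median, then symmetrised
   and clipped to [−1, 1]. Non-positive solved variances are floored at
   1e−6 before the square root so ρ stays defined.

Hyperparameters (20 resamples, exclusion threshold 0.1, 10 iterations,
median aggregation, +1 pseudocount) follow the reference tool's
defaults and are recorded in every result's `params`.

**Pseudo p-values.** Each permutation shuffles every OTU's counts
independently across samples — destroying all correlation while
preserving marginals, the reference tool's scheme — and re-runs the full
inference with the same settings. The two-sided p-value of a pair is
the plain proportion of permutations with `|ρ_perm| ≥ |ρ_obs|`, so p = 0
is representable (1,000 permutations is the conventional default; the
desk-scale analyses here use 100–200). Seeding uses `SeedSequence`
spawning: one child stream for the shuffles, one per permutation for the
Dirichlet draws, so results are reproducible for any permutation count.

## Network construction and descriptors

A link requires pseudo p ≤ 0.05 (inclusive) **and** |ρ| > 0.5 (strict —
"exceeding" the cut-off). Networks are kept on a fixed node universe:
the union of all OTUs incident to at least one link in any of the
compared networks, so stage networks are directly comparable and
isolated nodes are retained. Union ordering is (phylum-level lineage,
descending median reads, id) when annotations exist, else
lexicographic — a deterministic stand-in for "arranged by taxonomy and
abundance".

Descriptors follow the definitions tabulated in the README. Two
conventions are deliberate and verified against the published
descriptor table's printed values:

- **Mean degree is `2L / N_C`** (over connected nodes, not all N): the
  only denominator consistent with all four printed values
  (2·22/20 = 2.200, 2·56/29 = 3.862, …).
- **Subnetworks count components with ≥ 2 nodes**; isolated nodes are
  not subnetworks.

Role classification is a strict majority of signed links: competitive
if d⁻ > d⁺, cooperative if d⁺ > d⁻, mixed on an exact nonzero tie,
neutral at degree 0. Hubs are all nodes attaining the
maximum degree (ties allowed). Presentation rounding is half-away-from-
zero at 3 decimals; stored values keep full precision. The reconstructed
whole-development mean correlation from 3-d.p. inputs is 0.0445 against
a printed 0.045, so that one identity is checked at ±0.001.

## Community statistics

Standard estimators are delegated to scikit-bio; this package fixes the
surrounding conventions.

- **Filtering**: OTUs with < 50 reads *totalled over the dataset* are
  dropped (the common reading; per-sample filtering would change OTU
  sets between samples).
- **Rarefaction**: sampling without replacement (multivariate
  hypergeometric) to 10,000 reads by default; samples under depth are
  dropped with a warning.
- **Chao1**: bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))` (defined
  at F2 = 0), averaged over ten independent rarefaction replicates when
  a depth is given.
- **PERMANOVA**: scikit-bio's seeded implementation; R² is derived from
  the pseudo-F as `R² = F(a−1) / (F(a−1) + (N−a))` (algebraically
  SS_among/SS_total) and cross-checked against vegan's `adonis2` in the
  tests. p is `(k+1)/(n_perm+1)`, the ADONIS convention — unlike the
  inference module's verbatim-proportion pseudo p; both are documented
  where defined. Default 999 permutations.
- **PCoA**: classical scaling; only positive-eigenvalue axes are
  returned and explained fractions are taken over the positive sum.
- **Fold change**: mean focal-OTU relative abundance in treatment over
  control, after rarefaction, with one pseudocount read added to the
  focal OTU per sample before closure to keep the ratio finite.

## Synthetic data generator

What it emulates: hundreds-scale OTU richness (default desk scale
D = 50), broad log-normal abundance heterogeneity (per-OTU log-means
uniform on (−2, 2), common log-sd 1.0), compositional closure,
multinomial sequencing at fixed depth, stage-structured sampling with
stage-specific planted strong correlations (|r| ∈ [0.5, 1]), and
isolate spiking (multiply one OTU's basis abundance, re-close, re-draw
reads at the same depth — with fold 1 and the same seed the counts are
bit-identical, because the multinomial stream is decoupled from the
basis stream).

Planted target matrices are completed with an identity and, if
indefinite, repaired by clipping negative eigenvalues at zero and
re-normalising the diagonal; a repair that moves a planted entry by
more than 0.05, or induces a non-planted off-diagonal ≥ 0.2, rejects
the spec as over-constrained.

**Where the planted signal lives.** Endpoints of planted edges draw
their log-means from the upper half of the abundance range. Counting
noise adds roughly `2·trigamma(c+1)` to an OTU's log-scale variance
(multinomial plus Dirichlet-posterior draw at mean count c), which
enters both the variation statistic and the inferred ω and attenuates
ρ by ≈ `1/(1 + v/ω)`; with unit biological variance the planted pair
must average a few tens of reads for a 0.8 correlation to be estimable.
This mirrors real data, where inferred-network membership is itself
conditional on adequate sampling — strong links are found among
well-sampled OTUs.

What it does **not** emulate: read-level artefacts (sequencing error,
chimeras), taxonomic structure, overdispersion beyond the log-normal,
zero-inflation mechanisms other than sampling, or temporal
(Lotka–Volterra) dynamics of recolonization. Passing tests therefore
demonstrate correctness of the estimators under the generative model
the inference itself assumes — not robustness to real-data pathologies.

## Problem sizes and numerical choices

The analysis scripts and tests run at desk scale, chosen so the full
chain exercises every code path with clear statistical margins: D = 40–50
OTUs, 100–500 samples, depth 2,000–10,000, 100–200 permutations, 20-seed
replicate banks for the stochastic properties (recovery of a planted
0.8 edge within 0.15; zero false (p ≤ 0.05, |ρ| > 0.5) links on null
data; KS < 0.1 for null p-value uniformity at 300 pairs; PERMANOVA
type-I error within [0.02, 0.08] over 500 runs). Publication-scale
quantities that depend on the original 508-OTU abundance matrix (the
specific 66-node universe, per-stage link identities, ADONIS R² = 0.95,
the ~70% diversity-restoration figure) are not recomputable from
synthetic data; the descriptor *arithmetic* on those published inputs
is verified exactly instead.

Ties in the exclusion step resolve by `argmax` order (first maximal
pair in row-major order); variance uses the unbiased n−1 denominator
throughout; all randomness flows through explicit seeds or
`SeedSequence` children — no global RNG state anywhere.
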