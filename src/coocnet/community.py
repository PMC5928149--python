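"""Community-level statistics for the recolonization analysis.

Covers the standard amplicon workflow steps: dropping OTUs below a total
read cut-off, normalising samples to a common depth by rarefaction,
Chao1 alpha-diversity averaged over rarefaction replicates, Bray-Curtis
beta-diversity, principal-coordinates ordination, PERMANOVA on the
distance matrix, and the fold-change over-representation of a spiked
isolate relative to a control community.

Standard estimators are delegated to scikit-bio (Chao1, Bray-Curtis,
PCoA, PERMANOVA); this module fixes the conventions around them —
seeding, rarefaction behaviour, positive-eigenvalue axes, and the
derived PERMANOVA R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .otu_table import OtuTable

__all__ = ["filter_low_read_otus", "rarefy", "chao1", "diversity_report",
           "bray_curtis", "pcoa", "permanova", "fold_change", "FoldChange",
           "recolonization_dose"]

DEFAULT_MIN_READS = 50
DEFAULT_DEPTH = 10_000
DEFAULT_RAREFACTION_REPS = 10


def filter_low_read_otus(table: OtuTable,
                         min_reads: int = DEFAULT_MIN_READS) -> OtuTable:
    """Drop OTUs with fewer than ``min_reads`` total reads across the dataset.

    Such low-count OTUs are likely sequencing-error artifacts.  The
    cut-off is strict: an OTU totalling exactly ``min_reads`` is kept.
    """
    keep = table.otu_totals() >= min_reads
    if not keep.any():
        raise ValueError("filter removed every OTU")
    return table.select_otus(keep)


def rarefy(table: OtuTable, depth: int = DEFAULT_DEPTH,
           seed: int | None = None) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads cannot be rarefied and
    are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    keep = totals >= depth
    dropped = [table.sample_ids[i] for i in np.flatnonzero(~keep)]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} sample(s) below depth "
                      f"{depth}: {dropped}", stacklevel=2)
    if not keep.any():
        raise ValueError(f"no sample reaches depth {depth}")
    sub = table.select_samples(keep)
    counts = np.empty_like(sub.counts)
    for k in range(sub.n_samples):
        row = sub.counts[k]
        if row.sum() == depth:
            counts[k] = row
        else:
            counts[k] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(counts, list(sub.otu_ids), list(sub.sample_ids),
                    metadata=None if sub.metadata is None
                    else sub.metadata.copy())


def chao1(sample_counts: np.ndarray,
          n_rarefaction_reps: int = DEFAULT_RAREFACTION_REPS,
          depth: int | None = None, seed: int | None = None) -> float:
    """Bias-corrected Chao1 richness, averaged over rarefaction replicates.

    Chao1 = S_obs + F1(F1-1) / (2(F2+1)) with F1/F2 the singleton and
    doubleton counts.  With ``depth`` set, the estimate is the mean over
    ``n_rarefaction_reps`` independent subsamples at that depth; without
    it the raw counts are scored once.
    """
    counts = np.asarray(sample_counts, dtype=np.int64)
    if counts.ndim != 1 or np.any(counts < 0):
        raise ValueError("sample_counts must be a 1-D non-negative vector")
    total = counts.sum()
    if total == 0:
        raise ValueError("empty sample")
    if depth is None or depth >= total:
        return float(_skbio_chao1(counts, bias_corrected=True))
    rng = np.random.default_rng(seed)
    reps = [float(_skbio_chao1(rng.multivariate_hypergeometric(counts, depth),
                               bias_corrected=True))
            for _ in range(n_rarefaction_reps)]
    return float(np.mean(reps))


def diversity_report(table: OtuTable, depth: int | None = None,
                     n_rarefaction_reps: int = DEFAULT_RAREFACTION_REPS,
                     seed: int | None = None) -> pd.DataFrame:
    """Per-sample Chao1 table (sample_id, chao1, observed richness)."""
    ss = np.random.SeedSequence(seed).spawn(table.n_samples)
    rows = []
    for k, sid in enumerate(table.sample_ids):
        row = table.counts[k]
        rows.append({
            "sample_id": sid,
            "observed_otus": int(np.count_nonzero(row)),
            "chao1": chao1(row, n_rarefaction_reps, depth,
                           seed=np.random.default_rng(ss[k]).integers(2**31)),
        })
    return pd.DataFrame(rows)


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between all sample pairs.

    BC(u, v) = sum|u_i - v_i| / sum(u_i + v_i); run on rarefied counts
    so depths are comparable.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    return beta_diversity("braycurtis", table.counts, ids=table.sample_ids)


def pcoa(distances: DistanceMatrix | np.ndarray
         ) -> tuple[np.ndarray, np.ndarray]:
    """Classical metric scaling of a distance matrix.

    Returns ``(coordinates, explained)`` keeping axes with positive
    eigenvalues only; ``explained`` are eigenvalue fractions of the
    positive-eigenvalue sum, non-increasing.
    """
    if not isinstance(distances, DistanceMatrix):
        distances = np.asarray(distances, dtype=float)
        if distances.ndim != 2 or not np.allclose(distances, distances.T):
            raise ValueError("distance matrix must be square symmetric")
        distances = DistanceMatrix(distances)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # negative-eigenvalue advisory
        ord_res = _skbio_pcoa(distances, method="eigh")
    eig = ord_res.eigvals.to_numpy()
    tol = 1e-10 * max(1.0, float(np.abs(eig).max(initial=0.0)))
    keep = np.flatnonzero(eig > tol)
    coords = ord_res.samples.to_numpy()[:, keep]
    explained = eig[keep] / eig[keep].sum()
    return coords, explained


def permanova(distances: DistanceMatrix | np.ndarray, grouping,
              n_perm: int = 999, seed: int | None = None
              ) -> tuple[float, float]:
    """PERMANOVA (ADONIS-style) on a distance matrix.

    Returns ``(R2, p)``: R² is the among-group share of the total sum of
    squared distances, derived from the pseudo-F as
    ``R² = F(a-1) / (F(a-1) + (N-a))``; p is the permutation p-value
    ``(k+1)/(n_perm+1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    grouping = np.asarray(grouping)
    labels, counts = np.unique(grouping, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if not isinstance(distances, DistanceMatrix):
        distances = DistanceMatrix(np.asarray(distances, dtype=float))
    res = _skbio_permanova(distances, grouping, permutations=n_perm,
                           seed=seed)
    f = float(res["test statistic"])
    a, n = len(labels), len(grouping)
    r2 = f * (a - 1) / (f * (a - 1) + (n - a))
    return r2, float(res["p-value"])


@dataclass
class FoldChange:
    """Over-representation of one OTU in a treatment vs a control."""

    otu_id: str
    fc: float
    timepoint_label: str = ""


def fold_change(treatment: OtuTable, control: OtuTable, otu_id: str,
                depth: int = DEFAULT_DEPTH, seed: int | None = None,
                timepoint_label: str = "",
                rarefy_first: bool = True) -> FoldChange:
    """Mean relative abundance in treatment over control for one OTU.

    Both tables are rarefied to ``depth`` first; one pseudocount read is
    added to the focal OTU in every sample before closure so the ratio
    stays finite when the OTU drops out of the control.
    """
    if otu_id not in treatment.otu_ids and otu_id not in control.otu_ids:
        raise ValueError(f"{otu_id} absent from both tables")
    ss = np.random.SeedSequence(seed).spawn(2)

    def mean_rel(table: OtuTable, child) -> float:
        if rarefy_first:
            table = rarefy(table, depth,
                           seed=np.random.default_rng(child).integers(2**31))
        if otu_id in table.otu_ids:
            col = table.counts[:, table.otu_ids.index(otu_id)].astype(float)
        else:
            col = np.zeros(table.n_samples)
        totals = table.counts.sum(axis=1).astype(float)
        return float(np.mean((col + 1.0) / (totals + 1.0)))

    fc = mean_rel(treatment, ss[0]) / mean_rel(control, ss[1])
    return FoldChange(otu_id=otu_id, fc=fc, timepoint_label=timepoint_label)


def recolonization_dose(native_cfu: float, excess_factor: float = 2.0) -> float:
    """Inoculum size ensuring successful recolonization.

    The inoculum is the animal's native culturable bacterial load
    (colony-forming units per individual) multiplied by a safety excess,
    double by default.
    """
    if native_cfu <= 0 or excess_factor <= 0:
        raise ValueError("native_cfu and excess_factor must be positive")
    return native_cfu * excess_factor
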