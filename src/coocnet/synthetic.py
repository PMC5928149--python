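"""Synthetic OTU tables with planted basis-correlation structure.

The generator produces sequencing-like count data whose ground truth is
known, so that every downstream stage (correlation inference, network
construction, descriptors, community statistics) can be tested without
any external download.  The generative model is the one the log-ratio
correlation estimator assumes: each OTU has an unobserved absolute
("basis") abundance that is log-normal across samples, a chosen set of
OTU pairs is given strong basis correlations, abundances are closed to
fractions (compositionality), and reads are drawn multinomially at a
fixed sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .otu_table import OtuTable, write_otu_table_tsv

__all__ = [
    "BasisSpec",
    "SimulatedDataset",
    "make_basis_correlations",
    "simulate_counts",
    "simulate_staged_dataset",
    "spike_isolate",
    "write_dataset",
]

#: planted entries may move at most this far during the PSD repair
PSD_TOLERANCE = 0.05
#: multinomial draws use an RNG stream decoupled from the basis draw so
#: that an abundance perturbation can be re-drawn reproducibly
_COUNT_STREAM = 0x5EED


@dataclass(frozen=True)
class BasisSpec:
    """Recipe for one community: size, planted correlations, abundance scale.

    ``planted_edges`` are ``(i, j, r)`` triples with ``0.5 <= |r| <= 1`` —
    only "strong" correlations, the regime the downstream network builder
    keeps, are plantable.  Per-OTU log-scale means are drawn uniformly from
    ``log_mean_range`` (natural log), giving the broad abundance spread
    typical of amplicon data; ``log_sd`` is the common log-scale standard
    deviation.

    Endpoints of planted edges draw their log-means from the *upper half*
    of ``log_mean_range``: a strong correlation is only estimable from
    count data when the biological log-variance dominates the counting
    noise (about ``2 * trigamma(count + 1)`` on the log scale), so the
    planted signal is placed on well-sampled OTUs — the same regime the
    OTUs of an inferred co-occurrence network occupy in real data.
    """

    n_otus: int
    planted_edges: tuple[tuple[int, int, float], ...] = ()
    log_mean_range: tuple[float, float] = (-2.0, 2.0)
    log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 1:
            raise ValueError("n_otus must be positive")
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")
        object.__setattr__(self, "planted_edges",
                           tuple((int(i), int(j), float(r))
                                 for i, j, r in self.planted_edges))
        seen = set()
        for i, j, r in self.planted_edges:
            if i == j:
                raise ValueError(f"self-edge ({i},{j}) not allowed")
            if not (0 <= i < self.n_otus and 0 <= j < self.n_otus):
                raise ValueError(f"edge ({i},{j}) outside 0..{self.n_otus - 1}")
            if not (0.5 <= abs(r) <= 1.0):
                raise ValueError(
                    f"planted correlation {r} must satisfy 0.5 <= |r| <= 1")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate planted edge {key}")
            seen.add(key)


@dataclass
class SimulatedDataset:
    """Counts plus the ground truth that generated them.

    ``log_abundances`` are the pre-closure log basis abundances; they are
    kept so tests can check the generator against its own parameters, and
    so an OTU can be over-represented ("spiked") and the reads re-drawn.
    """

    counts: np.ndarray                      # (n_samples, D) ints
    stage_correlations: dict[str, np.ndarray]
    sample_stage: np.ndarray                # per-sample stage label
    depth: int
    otu_ids: list[str]
    sample_ids: list[str]
    log_abundances: np.ndarray              # (n_samples, D) reals
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.all(self.counts.sum(axis=1) == self.depth):
            raise ValueError("every sample must sum exactly to depth")

    @property
    def true_correlations(self) -> np.ndarray:
        if len(self.stage_correlations) != 1:
            raise ValueError(
                "dataset has several stages; use stage_correlations[stage]")
        return next(iter(self.stage_correlations.values()))

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def to_otu_table(self) -> OtuTable:
        meta = pd.DataFrame({"stage": self.sample_stage},
                            index=self.sample_ids)
        return OtuTable(self.counts, list(self.otu_ids),
                        list(self.sample_ids), metadata=meta)


def make_basis_correlations(spec: BasisSpec) -> np.ndarray:
    """Complete the planted edges into a valid correlation matrix.

    The target matrix is the identity with the planted entries filled in.
    If it is not positive semi-definite it is repaired by clipping negative
    eigenvalues at zero and re-normalising to unit diagonal.  A repair that
    moves any planted entry by more than ``PSD_TOLERANCE`` means the spec
    is over-constrained and is rejected.
    """
    d = spec.n_otus
    target = np.eye(d)
    for i, j, r in spec.planted_edges:
        target[i, j] = target[j, i] = r

    eigval_min = np.linalg.eigvalsh(target)[0] if d > 1 else 1.0
    if eigval_min >= 0:
        return target

    w, v = np.linalg.eigh(target)
    w = np.clip(w, 0.0, None)
    repaired = (v * w) @ v.T
    scale = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(scale, scale)
    np.fill_diagonal(repaired, 1.0)

    for i, j, r in spec.planted_edges:
        if abs(repaired[i, j] - r) > PSD_TOLERANCE:
            raise ValueError(
                "planted correlations are jointly infeasible: PSD repair "
                f"moved edge ({i},{j}) from {r:+.3f} to {repaired[i, j]:+.3f}")
    planted = {(min(i, j), max(i, j)) for i, j, _ in spec.planted_edges}
    off = [(a, b) for a in range(d) for b in range(a + 1, d)
           if (a, b) not in planted]
    if off and max(abs(repaired[a, b]) for a, b in off) >= 0.2:
        raise ValueError("PSD repair induced a spurious strong correlation; "
                         "thin out the planted edges")
    return repaired


def _count_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, _COUNT_STREAM])


def _draw_basis(spec: BasisSpec, n_samples: int,
                seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Log basis abundances (n x D) and the correlation matrix used."""
    corr = make_basis_correlations(spec)
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    lo, hi = spec.log_mean_range
    mu = rng.uniform(lo, hi, size=spec.n_otus)
    planted_nodes = sorted({k for i, j, _ in spec.planted_edges
                            for k in (i, j)})
    if planted_nodes:
        mu[planted_nodes] = rng.uniform((lo + hi) / 2.0, hi,
                                        size=len(planted_nodes))
    cov = (spec.log_sd ** 2) * corr
    log_ab = rng.multivariate_normal(mu, cov, size=n_samples,
                                     method="eigh", check_valid="ignore")
    return log_ab, corr


def _multinomial_rows(fracs: np.ndarray, depth: int,
                      rng: np.random.Generator) -> np.ndarray:
    counts = np.empty_like(fracs, dtype=np.int64)
    for k in range(fracs.shape[0]):
        counts[k] = rng.multinomial(depth, fracs[k])
    return counts


def simulate_counts(spec: BasisSpec, n_samples: int, depth: int,
                    stage: str = "all", seed: int | None = None,
                    sample_prefix: str = "S") -> SimulatedDataset:
    """Draw one community: log-normal basis, closure, multinomial reads."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if depth < spec.n_otus:
        raise ValueError("depth must be >= n_otus")
    seed = spec.seed if seed is None else seed

    log_ab, corr = _draw_basis(spec, n_samples, seed)
    basis = np.exp(log_ab)
    fracs = basis / basis.sum(axis=1, keepdims=True)
    counts = _multinomial_rows(fracs, depth, _count_rng(seed))

    ids = [f"OTU{i:03d}" for i in range(spec.n_otus)]
    samples = [f"{sample_prefix}{k:04d}" for k in range(n_samples)]
    return SimulatedDataset(
        counts=counts,
        stage_correlations={stage: corr},
        sample_stage=np.repeat(stage, n_samples),
        depth=int(depth),
        otu_ids=ids,
        sample_ids=samples,
        log_abundances=log_ab,
        seed=int(seed),
    )


def simulate_staged_dataset(specs: dict[str, BasisSpec], n_per_stage: int,
                            depth: int,
                            seed: int | None = None) -> SimulatedDataset:
    """Concatenate per-stage draws sharing one OTU universe.

    Each developmental stage gets its own planted correlation structure
    (its ``BasisSpec``), emulating stage-specific interaction networks;
    the per-stage ground-truth matrices are retained.
    """
    sizes = {s.n_otus for s in specs.values()}
    if len(sizes) != 1:
        raise ValueError(f"all stages must share n_otus, got {sorted(sizes)}")
    parts, truths, stages = [], {}, []
    for k, (stage, spec) in enumerate(specs.items()):
        stage_seed = spec.seed if seed is None else seed + k
        ds = simulate_counts(spec, n_per_stage, depth, stage=stage,
                             seed=stage_seed, sample_prefix=f"{stage}_")
        parts.append(ds)
        truths[stage] = ds.stage_correlations[stage]
        stages.append(np.repeat(stage, n_per_stage))
    first = parts[0]
    return SimulatedDataset(
        counts=np.vstack([p.counts for p in parts]),
        stage_correlations=truths,
        sample_stage=np.concatenate(stages),
        depth=int(depth),
        otu_ids=list(first.otu_ids),
        sample_ids=[s for p in parts for s in p.sample_ids],
        log_abundances=np.vstack([p.log_abundances for p in parts]),
        seed=first.seed,
    )


def spike_isolate(dataset: SimulatedDataset, otu: int,
                  fold: float, seed: int | None = None) -> SimulatedDataset:
    """Over-represent one OTU and re-draw the reads.

    The OTU's basis abundance is multiplied by ``fold`` in every sample
    before closure, emulating an isolate added in excess to an inoculum;
    re-closure keeps every sample at the original depth.  With ``fold=1``
    and the dataset's own seed the counts are reproduced exactly.
    """
    if not 0 <= otu < dataset.n_otus:
        raise ValueError(f"otu index {otu} out of range")
    if fold <= 0:
        raise ValueError("fold must be positive")
    seed = dataset.seed if seed is None else seed
    basis = np.exp(dataset.log_abundances)
    basis[:, otu] *= fold
    fracs = basis / basis.sum(axis=1, keepdims=True)
    counts = _multinomial_rows(fracs, dataset.depth, _count_rng(seed))
    return replace(dataset, counts=counts, log_abundances=np.log(basis))


def write_dataset(dataset: SimulatedDataset, outdir: str | Path,
                  spec: BasisSpec | None = None) -> None:
    """Write counts, metadata, truth matrices and a key=value manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = dataset.to_otu_table()
    write_otu_table_tsv(table, outdir / "otu_table.tsv")
    table.metadata.to_csv(outdir / "sample_metadata.tsv", sep="\t",
                          index_label="sample_id")
    for stage, corr in dataset.stage_correlations.items():
        pd.DataFrame(corr, index=dataset.otu_ids,
                     columns=dataset.otu_ids).to_csv(
            outdir / f"true_correlations_{stage}.tsv", sep="\t")
    lines = [f"seed={dataset.seed}", f"depth={dataset.depth}",
             f"n_samples={len(dataset.sample_ids)}",
             f"n_otus={dataset.n_otus}",
             f"stages={','.join(dict.fromkeys(dataset.sample_stage))}"]
    if spec is not None:
        lines += [f"log_sd={spec.log_sd}",
                  f"log_mean_range={spec.log_mean_range[0]},{spec.log_mean_range[1]}",
                  f"planted_edges={';'.join(f'{i}-{j}:{r}' for i, j, r in spec.planted_edges)}"]
    (outdir / "manifest.txt").write_text("\n".join(lines) + "\n")
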