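"""Basis-correlation inference for compositional count data.

Sequencing yields relative, not absolute, abundances: the counts of a
sample are closed to a constant sum, so naive Pearson correlations on
fractions are biased (spuriously negative).  The estimator implemented
here works on log-ratios, which are invariant to the closure.  For OTUs
``i, j`` with fractions ``f_i, f_j`` define the variation statistic

    t_ij = Var[ log(f_i / f_j) ]  =  w_i + w_j - 2 rho_ij sqrt(w_i w_j)

where ``w_i`` is the variance of the log *basis* (absolute) abundance of
OTU i and ``rho_ij`` the basis correlation.  Under sparsity — most pairs
uncorrelated — the cross terms are negligible and the basis variances
solve a linear system in the row sums of ``t``; correlations then follow
from the displayed identity.  Strongly correlated pairs violate the
sparsity assumption, so the single strongest pair is iteratively excluded
from the system and the variances re-solved.  Count uncertainty is
handled by resampling fractions from a Dirichlet posterior (counts + 1)
and taking the elementwise median across resamples.

Significance is attached by a permutation scheme: each OTU's counts are
shuffled independently across samples (destroying all correlation while
preserving marginals), inference is re-run, and the two-sided pseudo
p-value of a pair is the proportion of permuted datasets whose inferred
correlation is at least as extreme in absolute value as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .otu_table import OtuTable

__all__ = [
    "SparccSettings",
    "CorrelationResult",
    "estimate_fractions",
    "variation_matrix",
    "solve_basis_variances",
    "correlations_from_basis",
    "infer_correlations",
    "pseudo_pvalues",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

#: non-positive solved basis variances are floored here to keep the
#: correlation formula defined
OMEGA_FLOOR = 1e-6

SeedLike = "int | np.random.SeedSequence | None"


@dataclass(frozen=True)
class SparccSettings:
    """Inference hyperparameters (reference-tool defaults).

    n_resamples
        Dirichlet fraction resamples aggregated by the elementwise median.
    exclusion_threshold
        |rho| above which the strongest pair is excluded from the
        sparsity system before re-solving.
    max_exclusions
        Cap on exclusion iterations (one pair per iteration).
    permutation_mode
        Recorded for provenance; per-OTU independent shuffling is the
        only implemented scheme.
    """

    n_resamples: int = 20
    exclusion_threshold: float = 0.1
    max_exclusions: int = 10
    permutation_mode: str = "per-otu-independent"


@dataclass
class CorrelationResult:
    """Inferred basis correlations and (optionally) pseudo p-values."""

    rho: np.ndarray
    otu_ids: list[str]
    pvals: np.ndarray | None = None
    n_permutations: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = self.rho.shape[0]
        if self.rho.shape != (d, d):
            raise ValueError("rho must be square")
        if len(self.otu_ids) != d:
            raise ValueError("otu_ids length must match rho")
        if np.max(np.abs(self.rho)) > 1 + 1e-12:
            raise ValueError("|rho| must not exceed 1")


def _validate_table(table: OtuTable) -> None:
    if table.n_otus < 4:
        raise ValueError(
            "basis-variance system is degenerate below 4 OTUs; "
            f"got {table.n_otus}")


def estimate_fractions(table: OtuTable, n_resamples: int,
                       seed: SeedLike = None) -> np.ndarray:
    """Posterior fraction resamples, shape (n_resamples, n_samples, D).

    Per sample the fraction vector is drawn from a Dirichlet with a
    symmetric unit prior over the counts (counts + 1); this both
    propagates count uncertainty and guarantees strictly positive
    fractions for the logarithms downstream.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    alpha = table.counts.astype(float) + 1.0
    draws = rng.standard_gamma(alpha, size=(n_resamples,) + alpha.shape)
    return draws / draws.sum(axis=2, keepdims=True)


def variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """Log-ratio variance t_ij = Var[log(f_i/f_j)] (unbiased, n-1).

    Computed through the covariance matrix of the log fractions:
    t_ij = C_ii + C_jj - 2 C_ij, which is exact and O(n D^2).
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions <= 0):
        raise ValueError("fractions must be strictly positive (log-ratios)")
    if fractions.shape[0] < 2:
        raise ValueError("need at least 2 samples for a variance")
    logf = np.log(fractions)
    cov = np.cov(logf, rowvar=False)          # D x D, n-1 denominator
    dvar = np.diag(cov)
    t = dvar[:, None] + dvar[None, :] - 2.0 * cov
    t = np.maximum(0.5 * (t + t.T), 0.0)      # symmetrize, clip fp negatives
    np.fill_diagonal(t, 0.0)
    return t


def solve_basis_variances(t: np.ndarray,
                          excluded_pairs: frozenset | set = frozenset()
                          ) -> np.ndarray:
    """Solve for log-basis variances under the sparsity approximation.

    With cross terms dropped, each included pair contributes the equation
    ``w_i + w_j = t_ij``; the normal equations of that least-squares
    problem are ``(deg_i) w_i + sum_{j in pairs(i)} w_j = rowsum_i(t)``,
    which for the full pair set is the matrix ``ones(D,D) + (D-2) I``.
    Excluding a pair removes its equation.  Non-positive solutions are
    floored at ``OMEGA_FLOOR``.

    Raises ``np.linalg.LinAlgError`` if the system is singular after
    exclusions (callers keep their last valid estimate).
    """
    d = t.shape[0]
    m = np.ones((d, d)) + np.diag(np.full(d, d - 2.0))
    t_work = t.copy()
    for i, j in excluded_pairs:
        t_work[i, j] = t_work[j, i] = 0.0
        m[i, j] = m[j, i] = 0.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
    omega = np.linalg.solve(m, t_work.sum(axis=1))
    return np.where(omega > 0, omega, OMEGA_FLOOR)


def correlations_from_basis(t: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)), clipped to [-1, 1]."""
    if np.any(omega <= 0):
        raise ValueError("basis variances must be positive")
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - t) / denom
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _infer_from_fractions(fractions: np.ndarray,
                          settings: SparccSettings) -> np.ndarray:
    """One resample's correlation matrix, with iterative pair exclusion."""
    t = variation_matrix(fractions)
    d = t.shape[0]
    excluded: set[tuple[int, int]] = set()
    omega = solve_basis_variances(t)
    rho = correlations_from_basis(t, omega)
    for _ in range(settings.max_exclusions):
        masked = np.abs(rho.copy())
        np.fill_diagonal(masked, 0.0)
        for i, j in excluded:
            masked[i, j] = masked[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= settings.exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        try:
            omega = solve_basis_variances(t, excluded)
        except np.linalg.LinAlgError:
            break  # too many exclusions: keep last valid estimate
        rho = correlations_from_basis(t, omega)
    return rho


def infer_correlations(table: OtuTable,
                       settings: SparccSettings | None = None,
                       seed: SeedLike = None) -> CorrelationResult:
    """Full estimator: fraction resamples -> per-resample inference -> median."""
    settings = settings or SparccSettings()
    _validate_table(table)
    fracs = estimate_fractions(table, settings.n_resamples, seed)
    rhos = np.stack([_infer_from_fractions(f, settings) for f in fracs])
    rho = np.median(rhos, axis=0)
    rho = np.clip(0.5 * (rho + rho.T), -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationResult(rho=rho, otu_ids=list(table.otu_ids),
                             params=asdict(settings))


def pseudo_pvalues(table: OtuTable, observed: CorrelationResult,
                   n_perm: int = 1000, seed: SeedLike = None,
                   settings: SparccSettings | None = None
                   ) -> CorrelationResult:
    """Two-sided permutation pseudo p-values for every pair.

    ``p_ij`` is the plain proportion of permuted datasets whose inferred
    ``|rho_ij|`` is at least the observed ``|rho_ij|`` (so ``p = 0`` is
    representable).  Each permutation shuffles every OTU's counts
    independently across samples.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    settings = settings or SparccSettings()
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    children = root.spawn(n_perm + 1)
    shuffle_rng = np.random.default_rng(children[0])

    abs_obs = np.abs(observed.rho)
    hits = np.zeros_like(abs_obs)
    for k in range(n_perm):
        perm_counts = shuffle_rng.permuted(table.counts, axis=0)
        perm_table = OtuTable(perm_counts, list(table.otu_ids),
                              list(table.sample_ids))
        perm = infer_correlations(perm_table, settings, seed=children[k + 1])
        hits += np.abs(perm.rho) >= abs_obs
    pvals = hits / n_perm
    pvals = np.clip(0.5 * (pvals + pvals.T), 0.0, 1.0)
    np.fill_diagonal(pvals, 1.0)
    return CorrelationResult(
        rho=observed.rho, otu_ids=list(observed.otu_ids), pvals=pvals,
        n_permutations=n_perm,
        params={**observed.params, **asdict(settings)},
    )


def write_matrix_tsv(matrix: np.ndarray, otu_ids: list[str], path) -> None:
    """Square matrix (correlations or p-values) as TSV with OTU-id headers."""
    import pandas as pd
    pd.DataFrame(matrix, index=otu_ids, columns=otu_ids).to_csv(path, sep="\t")


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    import pandas as pd
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]
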