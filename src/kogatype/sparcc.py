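"""SparCC compositional correlation with permutation significance.

Count data from amplicon sequencing are compositional: naive Pearson
correlations of relative abundances are distorted by the closure to 1.
SparCC instead works from the variances of pairwise log-ratios,
T_ij = Var(log x_i/x_j), which are invariant to per-sample scaling, and
solves for basis variances under a sparsity assumption: if most taxon
pairs are uncorrelated, T_ij ≈ ω_i + ω_j, giving a linear system whose
solution yields correlations ρ_ij = (ω_i + ω_j − T_ij)/(2√(ω_i ω_j)).
Strongly correlated pairs violate the assumption, so the single
strongest pair above an exclusion threshold is iteratively removed from
the system and the basis re-solved.  Sampling noise is integrated out by
drawing posterior fractions from Dirichlet(counts + 1) a number of times
and taking the element-wise median correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import AbundanceTable, ValidationError

__all__ = ["CorrelationEstimate", "sparcc", "permutation_pvalues", "correlation_estimate"]

_OMEGA_FLOOR = 1e-12


@dataclass(frozen=True)
class CorrelationEstimate:
    """SparCC correlation matrix with permutation p-values and provenance."""

    taxon_labels: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame | None
    n_inner: int
    n_perm: int | None
    seed: int | None

    def __post_init__(self) -> None:
        vals = self.r.to_numpy()
        if not np.allclose(vals, vals.T, atol=1e-9):
            raise ValidationError("correlation matrix must be symmetric")
        if np.abs(vals).max() > 1 + 1e-9:
            raise ValidationError("correlations must lie in [-1, 1]")


def _check_counts(t: AbundanceTable) -> np.ndarray:
    if t.mode != "counts":
        raise ValidationError("SparCC operates on count data")
    if t.n_taxa < 4:
        raise ValidationError(
            f"SparCC needs at least 4 taxa (got {t.n_taxa}); the basis system is degenerate"
        )
    counts = t.values
    zero = counts.sum(axis=0) == 0
    if zero.any():
        taxon = t.taxon_labels[int(np.argmax(zero))]
        raise ValidationError(f"taxon {taxon!r} has zero counts in every sample")
    return counts


def _one_sparcc_iteration(
    fractions: np.ndarray, exclusion_threshold: float, max_exclusions: int
) -> np.ndarray:
    """Basis-solve + pair exclusion for one Dirichlet draw of fractions."""
    logf = np.log(fractions)
    var = logf.var(axis=0, ddof=1)
    cov = np.cov(logf, rowvar=False, ddof=1)
    big_t = var[:, None] + var[None, :] - 2.0 * cov  # Var(log f_i/f_j)
    np.fill_diagonal(big_t, 0.0)
    d = big_t.shape[0]

    m = np.ones((d, d)) + np.diag(np.full(d, d - 2.0))
    rhs = big_t.sum(axis=1)
    excluded = np.zeros((d, d), dtype=bool)
    np.fill_diagonal(excluded, True)

    def solve_rho() -> np.ndarray:
        omega = np.linalg.solve(m, rhs)
        omega = np.maximum(omega, _OMEGA_FLOOR)
        rho = (omega[:, None] + omega[None, :] - big_t) / (
            2.0 * np.sqrt(np.outer(omega, omega))
        )
        return np.clip(rho, -1.0, 1.0)

    rho = solve_rho()
    for _ in range(max_exclusions):
        masked = np.where(excluded, 0.0, np.abs(rho))
        np.fill_diagonal(masked, 0.0)
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        rhs[i] -= big_t[i, j]
        rhs[j] -= big_t[i, j]
        if m[i, i] < 1.0 or m[j, j] < 1.0:  # system would go singular
            break
        rho = solve_rho()
    np.fill_diagonal(rho, 1.0)
    return rho


def sparcc(
    t: AbundanceTable,
    n_inner: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Estimate the SparCC correlation matrix of a counts table.

    ``n_inner`` Dirichlet(counts+1) resamplings are aggregated by the
    element-wise median.  Deterministic given ``seed``.
    """
    counts = _check_counts(t)
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_inner):
        gammas = rng.gamma(counts + 1.0)
        fractions = gammas / gammas.sum(axis=1, keepdims=True)
        draws.append(
            _one_sparcc_iteration(fractions, exclusion_threshold, max_exclusions)
        )
    r = np.median(np.stack(draws), axis=0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=t.taxon_labels, columns=t.taxon_labels)


def permutation_pvalues(
    t: AbundanceTable,
    r_obs: pd.DataFrame,
    n_perm: int = 100,
    n_inner: int = 5,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-sided permutation p-values for a SparCC correlation matrix.

    Each permutation shuffles every taxon's counts across samples
    independently, destroying all between-taxon association while
    preserving marginals; SparCC is recomputed (with a reduced inner
    iteration count for tractability) and
    p_ij = (#{|R_perm| ≥ |R_obs|} + 1)/(n_perm + 1).
    """
    counts = _check_counts(t)
    if list(r_obs.index) != t.taxon_labels:
        raise ValidationError("r_obs taxa do not match the table")
    if n_perm < 19:
        warnings.warn(
            f"n_perm={n_perm} cannot resolve p < 0.05 (minimum p is 1/(n_perm+1))",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    obs = np.abs(r_obs.to_numpy())
    exceed = np.zeros_like(obs)
    shuffled = counts.copy()
    n = counts.shape[0]
    for _ in range(n_perm):
        for j in range(counts.shape[1]):
            shuffled[:, j] = counts[rng.permutation(n), j]
        perm_table = AbundanceTable(
            pd.DataFrame(shuffled, index=t.sample_ids, columns=t.taxon_labels),
            "counts",
            t.body_site,
        )
        r_perm = sparcc(
            perm_table,
            n_inner=n_inner,
            exclusion_threshold=exclusion_threshold,
            max_exclusions=max_exclusions,
            seed=int(rng.integers(2**31 - 1)),
        )
        exceed += np.abs(r_perm.to_numpy()) >= obs
    p = (exceed + 1.0) / (n_perm + 1.0)
    p = (p + p.T) / 2.0
    return pd.DataFrame(p, index=t.taxon_labels, columns=t.taxon_labels)


def correlation_estimate(
    t: AbundanceTable,
    n_inner: int = 20,
    n_perm: int = 100,
    perm_n_inner: int = 5,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
    seed: int | None = None,
) -> CorrelationEstimate:
    """Convenience wrapper: SparCC R plus permutation p in one object."""
    r = sparcc(
        t,
        n_inner=n_inner,
        exclusion_threshold=exclusion_threshold,
        max_exclusions=max_exclusions,
        seed=seed,
    )
    p = permutation_pvalues(
        t,
        r,
        n_perm=n_perm,
        n_inner=perm_n_inner,
        exclusion_threshold=exclusion_threshold,
        max_exclusions=max_exclusions,
        seed=None if seed is None else seed + 1,
    )
    return CorrelationEstimate(
        taxon_labels=tuple(t.taxon_labels),
        r=r,
        p=p,
        n_inner=n_inner,
        n_perm=n_perm,
        seed=seed,
    )
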