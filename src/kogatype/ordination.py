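"""Ordination and group-difference statistics on distance matrices.

PCoA (classical metric scaling) embeds the JSD distance matrix for
visualization; PERMANOVA tests whether labeled groups differ in their
community composition; per-taxon Mann-Whitney U tests flag differentially
abundant taxa between two groups (raw p-values with significance stars,
no multiplicity adjustment — matching common practice for star
annotation of supplementary tables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .abundance import AbundanceTable, ValidationError

__all__ = ["pcoa", "permanova", "rank_sum_differential", "PermanovaResult"]


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling of a distance matrix.

    Returns per-sample coordinates on the top ``n_axes`` positive-
    eigenvalue axes and the corresponding shares of explained variation.
    Axis signs are fixed so each axis's largest-magnitude coordinate is
    positive, making the embedding deterministic.  If fewer positive
    eigenvalues exist than requested, the result is truncated with a
    warning.
    """
    if len(d.ids) < 2:
        raise ValidationError("PCoA needs at least 2 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(d, method="eigh")
    eigvals = res.eigvals.to_numpy()
    positive = int((eigvals > 1e-12).sum())
    if n_axes > positive:
        warnings.warn(
            f"only {positive} positive eigenvalues; truncating from {n_axes} axes",
            stacklevel=2,
        )
        n_axes = positive
    coords = res.samples.iloc[:, :n_axes].copy()
    coords.columns = [f"PC{i + 1}" for i in range(n_axes)]
    coords.index = list(d.ids)
    for col in coords.columns:
        v = coords[col].to_numpy()
        if v[np.argmax(np.abs(v))] < 0:
            coords[col] = -v
    shares = res.proportion_explained.to_numpy()[:n_axes]
    return coords, shares


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int


def _within_ss(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    pseudo-F = (SS_between/(a−1)) / (SS_within/(n−a)) with sums of squared
    distances; the p-value is the permutation tail probability
    (#{F_perm ≥ F_obs} + 1)/(n_perm + 1) under label shuffling.
    """
    labels = np.asarray(list(groups))
    n = len(d.ids)
    if labels.shape[0] != n:
        raise ValidationError("group labels must match the distance matrix samples")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    d2 = np.asarray(d.data, dtype=float) ** 2
    a = uniq.size
    ss_total = d2.sum() / (2.0 * n)

    def pseudo_f(lab: np.ndarray) -> float:
        ss_w = _within_ss(d2, lab, uniq)
        ss_b = ss_total - ss_w
        return (ss_b / (a - 1)) / (ss_w / (n - a))

    f_obs = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    count = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        if pseudo_f(lab) >= f_obs:
            count += 1
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=(count + 1) / (n_perm + 1),
        n_permutations=n_perm,
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def rank_sum_differential(t: AbundanceTable, groups) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per taxon between exactly two groups.

    Uses the normal approximation with tie correction and continuity
    correction; an all-tied taxon gets U = n·m/2 and p = 1.  Returns a
    frame indexed by taxon with columns U, p and significance stars.
    """
    labels = np.asarray(list(groups))
    if labels.shape[0] != t.n_samples:
        raise ValidationError("group labels must match the table samples")
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValidationError(f"expected exactly 2 groups, got {uniq.size}")
    mask = labels == uniq[0]
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValidationError("both groups must be non-empty")
    x, y = t.values[mask], t.values[~mask]
    n, m = x.shape[0], y.shape[0]
    rows = []
    for j, taxon in enumerate(t.taxon_labels):
        xv, yv = x[:, j], y[:, j]
        if np.ptp(np.concatenate([xv, yv])) == 0:
            u, p = n * m / 2.0, 1.0
        else:
            u, p = mannwhitneyu(xv, yv, alternative="two-sided", method="asymptotic")
        rows.append((taxon, float(u), float(p), _stars(float(p))))
    return pd.DataFrame(
        rows, columns=["taxon", "U", "p", "significance"]
    ).set_index("taxon")
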