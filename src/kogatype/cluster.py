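"""Distance-based community clustering: JSD metric, PAM, and k selection.

The clustering distance is the square root of the Jensen-Shannon
divergence (natural log), a metric bounded by sqrt(ln 2).  Clustering is
k-medoids via the classical deterministic PAM algorithm (greedy BUILD
initialization followed by best-improvement SWAP), which operates on the
distance matrix only.  The number of clusters is chosen by maximizing a
medoid-based Calinski-Harabasz index, with the mean silhouette width
reported alongside as a robustness check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from sklearn.metrics import silhouette_samples

from .abundance import AbundanceTable, ValidationError

__all__ = [
    "JSD_MAX",
    "ClusterSolution",
    "KSelectionReport",
    "jsd_distance_matrix",
    "pam",
    "ch_index",
    "silhouette_mean",
    "select_k",
]

#: upper bound of the sqrt-JSD metric (disjoint supports)
JSD_MAX = math.sqrt(math.log(2.0))


@dataclass(frozen=True)
class ClusterSolution:
    """A k-medoids partition of the samples of a distance matrix."""

    k: int
    labels: np.ndarray                 # per-sample cluster index in [0, k)
    medoid_indices: np.ndarray         # position of each cluster's medoid
    medoid_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    objective: float                   # sum of distances to assigned medoids
    dominant_taxon: dict[int, str] = field(default_factory=dict)

    def cluster_members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)


@dataclass(frozen=True)
class KSelectionReport:
    """CH / silhouette profile over candidate cluster numbers."""

    candidate_ks: tuple[int, ...]
    ch_values: tuple[float, ...]
    silhouette_values: tuple[float, ...]
    chosen_k: int
    solutions: dict[int, ClusterSolution] = field(default_factory=dict, repr=False)


def jsd_distance_matrix(
    t: AbundanceTable, pseudocount: float = 1e-9
) -> DistanceMatrix:
    """Pairwise sqrt-Jensen-Shannon-divergence distances between samples.

    Zeros are replaced by an additive pseudocount and each profile is
    re-normalized before the divergence is evaluated with natural
    logarithms; the returned value is ``sqrt(JSD)``, a metric in
    ``[0, sqrt(ln 2)]``.
    """
    if t.n_samples == 0 or t.n_taxa == 0:
        raise ValidationError("cannot compute distances on an empty table")
    profiles = t.values + pseudocount
    profiles /= profiles.sum(axis=1, keepdims=True)
    condensed = pdist(profiles, metric="jensenshannon")
    # guard against tiny negative round-off inside scipy's sqrt
    condensed = np.nan_to_num(condensed, nan=0.0)
    return DistanceMatrix(squareform(condensed), ids=t.sample_ids)


def _assign(d: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    sub = d[:, medoids]
    labels = np.argmin(sub, axis=1)        # ties -> lowest medoid position
    cost = float(sub[np.arange(d.shape[0]), labels].sum())
    return labels, cost


def pam(d: DistanceMatrix, k: int, seed: int | None = None) -> ClusterSolution:
    """Partitioning Around Medoids on a precomputed distance matrix.

    Deterministic BUILD+SWAP: BUILD greedily adds the medoid that most
    reduces the total distance to the nearest medoid; SWAP repeatedly
    applies the single best strictly-improving medoid/non-medoid exchange.
    All ties break toward the lowest sample index, so the result is a pure
    function of the distances (``seed`` is accepted for interface
    uniformity but unused).
    """
    del seed
    dist = np.asarray(d.data, dtype=float)
    n = dist.shape[0]
    if not 1 <= k < n:
        raise ValidationError(f"k={k} must satisfy 1 <= k < n={n}")

    # BUILD
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    nearest = dist[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        cand = int(np.argmax(gains))
        medoids.append(cand)
        nearest = np.minimum(nearest, dist[:, cand])

    medoids = sorted(medoids)
    _, cost = _assign(dist, np.asarray(medoids))

    # SWAP: best strictly-improving exchange per sweep
    while True:
        best = (0.0, None)
        med_arr = np.asarray(medoids)
        for mi, m in enumerate(medoids):
            others = np.delete(med_arr, mi)
            if others.size:
                base = dist[:, others].min(axis=1)
            else:
                base = np.full(n, np.inf)
            nonmed = np.setdiff1d(np.arange(n), med_arr, assume_unique=False)
            # cost after swapping m -> h, for every candidate h at once
            costs = np.minimum(base[:, None], dist[:, nonmed]).sum(axis=0)
            j = int(np.argmin(costs))
            delta = float(costs[j]) - cost
            if delta < best[0] - 1e-12:
                best = (delta, (mi, int(nonmed[j])))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
        medoids = sorted(medoids)
        _, cost = _assign(dist, np.asarray(medoids))

    med_arr = np.asarray(medoids)
    labels, cost = _assign(dist, med_arr)
    # relabel so medoid of cluster c carries label c (guaranteed: a medoid's
    # nearest medoid is itself at distance 0; ties at 0 go to the lowest
    # position, which for sorted medoids is the medoid itself only if no
    # earlier medoid is at distance 0 — force it explicitly for safety)
    labels[med_arr] = np.arange(k)
    ids = tuple(str(i) for i in d.ids)
    return ClusterSolution(
        k=k,
        labels=labels,
        medoid_indices=med_arr,
        medoid_ids=tuple(ids[m] for m in medoids),
        sample_ids=ids,
        objective=cost,
    )


def _check_solution(d: DistanceMatrix, s: ClusterSolution) -> np.ndarray:
    dist = np.asarray(d.data, dtype=float)
    if len(s.labels) != dist.shape[0]:
        raise ValidationError("solution and distance matrix disagree on samples")
    sizes = np.bincount(s.labels, minlength=s.k)
    if (sizes == 0).any():
        empty = int(np.argmax(sizes == 0))
        raise ValidationError(f"cluster {empty} is empty")
    return dist


def ch_index(d: DistanceMatrix, s: ClusterSolution) -> float:
    """Medoid-based Calinski-Harabasz index.

    Within dispersion W is the sum of squared distances of samples to
    their cluster medoid; between dispersion B weights the squared
    distance of each cluster medoid to the global medoid (the sample
    minimizing the total squared distance) by cluster size.  Returns
    ``+inf`` when W is exactly 0.
    """
    dist = _check_solution(d, s)
    if s.k < 2:
        raise ValidationError("CH index requires k >= 2")
    n = dist.shape[0]
    w = float((dist[np.arange(n), s.medoid_indices[s.labels]] ** 2).sum())
    global_medoid = int(np.argmin((dist**2).sum(axis=0)))
    sizes = np.bincount(s.labels, minlength=s.k)
    b = float((sizes * dist[s.medoid_indices, global_medoid] ** 2).sum())
    if w == 0.0:
        return math.inf
    return (b / (s.k - 1)) / (w / (n - s.k))


def silhouette_mean(d: DistanceMatrix, s: ClusterSolution) -> float:
    """Mean silhouette width from the distance matrix (singletons score 0)."""
    dist = _check_solution(d, s)
    if s.k < 2:
        raise ValidationError("silhouette requires k >= 2")
    return float(silhouette_samples(dist, s.labels, metric="precomputed").mean())


def select_k(
    d: DistanceMatrix, k_max: int = 10, seed: int | None = None
) -> KSelectionReport:
    """Run PAM for k = 2..k_max and choose the k maximizing the CH index.

    Ties break toward the smallest k.  Mean silhouette widths are recorded
    per k for robustness assessment but do not affect the choice.
    """
    n = len(d.ids)
    if k_max >= n:
        raise ValidationError(f"k_max={k_max} must be < n={n}")
    ks = tuple(range(2, k_max + 1))
    if not ks:
        raise ValidationError("k_max must be >= 2")
    solutions: dict[int, ClusterSolution] = {}
    ch_vals: list[float] = []
    sil_vals: list[float] = []
    for k in ks:
        sol = pam(d, k, seed=seed)
        solutions[k] = sol
        ch_vals.append(ch_index(d, sol))
        sil_vals.append(silhouette_mean(d, sol))
    chosen = ks[int(np.argmax(ch_vals))]
    return KSelectionReport(
        candidate_ks=ks,
        ch_values=tuple(ch_vals),
        silhouette_values=tuple(sil_vals),
        chosen_k=chosen,
        solutions=solutions,
    )
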