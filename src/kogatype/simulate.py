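"""Synthetic paired oral/gut cohorts with planted community types.

The generator emulates the statistical structure the typing pipeline
assumes in real 16S genus profiles: each body site hosts a two-cluster
mixture of Dirichlet-multinomial communities, where one dominant genus
per cluster (Streptococcus/Haemophilus orally, Bacteroides/Prevotella in
the gut) has its Dirichlet concentration multiplied by a dominance
boost.  A subject's gut cluster is drawn conditionally on its oral
cluster through a 2×2 coupling matrix, so composite oral-gut types have
controllable frequencies.  Defaults mirror a 112-subject healthy cohort:
mixture weights 0.554/0.446 and coupling rows 0.694/0.306 and 0.72/0.28,
215 oral genera of which exactly 75 sit above the 0.01% mean-abundance
filter in expectation, and a sequencing depth of 20 000 reads.

A separate log-normal/multinomial generator produces count tables with a
known basis correlation structure for exercising SparCC, and a small
helper materializes species-level tables with prescribed per-type means
for testing the scoring statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceTable, SampleMetadata, ValidationError
from .typology import taxon_initial

__all__ = [
    "CohortSpec",
    "CorrelatedCountSpec",
    "simulate_paired_cohort",
    "simulate_correlated_counts",
    "simulate_typed_species_table",
]

ORAL_DOMINANTS = ("Streptococcus", "Haemophilus")
GUT_DOMINANTS = ("Bacteroides", "Prevotella")


def _site_taxa(site: str, dominants: tuple[str, str], n_common: int, n_rare: int) -> list[str]:
    common = [f"{site.capitalize()}_genus_{i:03d}" for i in range(3, 3 + n_common)]
    rare = [f"{site.capitalize()}_rare_{i:03d}" for i in range(n_rare)]
    return list(dominants) + common + rare


def _site_concentration(n_common: int) -> np.ndarray:
    """Core concentrations: dominants 2.0, common taxa decay 1.5→0.5.

    With a boost of 50 the boosted dominant takes roughly 60% of the
    community and common taxa land between ~3×10^-3 and ~10^-2, all
    comfortably above the 10^-4 prevalence cutoff even at cohort size
    112.  Rare taxa are not part of this vector: they share a fixed
    small fraction of the community (see ``rare_fraction``), which keeps
    their mean abundance bounded well below the cutoff — a tiny-alpha
    Dirichlet component would instead be heavy-tailed enough for single
    samples to push rare taxa across it.
    """
    return np.concatenate([[2.0, 2.0], np.geomspace(1.5, 0.5, n_common)])


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a paired two-site synthetic cohort."""

    n_subjects: int = 112
    oral_taxa: tuple[str, ...] = field(
        default_factory=lambda: tuple(_site_taxa("oral", ORAL_DOMINANTS, 73, 140))
    )
    gut_taxa: tuple[str, ...] = field(
        default_factory=lambda: tuple(_site_taxa("gut", GUT_DOMINANTS, 58, 120))
    )
    oral_dominants: tuple[str, str] = ORAL_DOMINANTS
    gut_dominants: tuple[str, str] = GUT_DOMINANTS
    oral_concentration: tuple[float, ...] = field(
        default_factory=lambda: tuple(_site_concentration(73))
    )
    gut_concentration: tuple[float, ...] = field(
        default_factory=lambda: tuple(_site_concentration(58))
    )
    #: community fraction shared uniformly (Dirichlet(1,...,1)) by the taxa
    #: beyond the core concentration vector; 0.15% over 140 oral rare taxa
    #: puts each rare genus near 1e-5 mean abundance, an order of magnitude
    #: below the prevalence cutoff
    rare_fraction: float = 0.0015
    dominance_boost: float = 50.0
    mixture_weights: tuple[float, float] = (0.554, 0.446)
    coupling: tuple[tuple[float, float], tuple[float, float]] = (
        (0.694, 0.306),
        (0.72, 0.28),
    )
    depth: int = 20000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be positive")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.dominance_boost < 1:
            raise ValidationError("dominance_boost must be >= 1")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValidationError("mixture_weights must sum to 1")
        for row in self.coupling:
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValidationError("each coupling row must sum to 1")
        if not 0 <= self.rare_fraction < 1:
            raise ValidationError("rare_fraction must be in [0, 1)")
        for taxa, dom, conc, site in (
            (self.oral_taxa, self.oral_dominants, self.oral_concentration, "oral"),
            (self.gut_taxa, self.gut_dominants, self.gut_concentration, "gut"),
        ):
            if len(conc) > len(taxa):
                raise ValidationError(f"{site} concentration longer than taxa list")
            if len(conc) < len(taxa) and self.rare_fraction == 0:
                raise ValidationError(
                    f"{site} has rare taxa but rare_fraction is 0"
                )
            if min(conc) <= 0:
                raise ValidationError(f"{site} concentrations must be positive")
            core = taxa[: len(conc)]
            for g in dom:
                if g not in core:
                    raise ValidationError(f"{site} dominant {g!r} not in core taxa")


def _draw_site(
    rng: np.random.Generator,
    clusters: np.ndarray,
    taxa: tuple[str, ...],
    dominants: tuple[str, str],
    concentration: tuple[float, ...],
    rare_fraction: float,
    boost: float,
    depth: int,
    sample_ids: list[str],
    body_site: str,
) -> AbundanceTable:
    base = np.asarray(concentration, dtype=float)
    n_core, n_rare = base.size, len(taxa) - base.size
    dom_idx = [taxa.index(g) for g in dominants]
    eps = rare_fraction if n_rare else 0.0
    counts = np.empty((len(clusters), len(taxa)), dtype=int)
    for i, c in enumerate(clusters):
        alpha = base.copy()
        alpha[dom_idx[c]] *= boost
        comp = np.empty(len(taxa))
        comp[:n_core] = (1.0 - eps) * rng.dirichlet(alpha)
        if n_rare:
            comp[n_core:] = eps * rng.dirichlet(np.ones(n_rare))
        counts[i] = rng.multinomial(depth, comp)
    df = pd.DataFrame(counts, index=sample_ids, columns=list(taxa))
    return AbundanceTable(df, "counts", body_site)


def simulate_paired_cohort(
    spec: CohortSpec,
) -> tuple[AbundanceTable, AbundanceTable, SampleMetadata, pd.DataFrame]:
    """Draw a paired oral/gut cohort with planted type labels.

    Returns (oral counts table, gut counts table, metadata, truth frame
    with per-subject planted oral/gut cluster letters and composite
    label).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    subjects = [f"subj{i:03d}" for i in range(n)]
    oral_ids = [f"{s}_O" for s in subjects]
    gut_ids = [f"{s}_G" for s in subjects]

    oral_clusters = rng.choice(2, size=n, p=np.asarray(spec.mixture_weights))
    coupling = np.asarray(spec.coupling)
    gut_clusters = np.array(
        [rng.choice(2, p=coupling[c]) for c in oral_clusters], dtype=int
    )

    oral = _draw_site(
        rng, oral_clusters, spec.oral_taxa, spec.oral_dominants,
        spec.oral_concentration, spec.rare_fraction, spec.dominance_boost,
        spec.depth, oral_ids, "oral",
    )
    gut = _draw_site(
        rng, gut_clusters, spec.gut_taxa, spec.gut_dominants,
        spec.gut_concentration, spec.rare_fraction, spec.dominance_boost,
        spec.depth, gut_ids, "gut",
    )

    meta = SampleMetadata.from_records(
        [(sid, subj, "oral") for sid, subj in zip(oral_ids, subjects)]
        + [(sid, subj, "gut") for sid, subj in zip(gut_ids, subjects)]
    )
    oral_letter = [taxon_initial(spec.oral_dominants[c]) for c in oral_clusters]
    gut_letter = [taxon_initial(spec.gut_dominants[c]) for c in gut_clusters]
    truth = pd.DataFrame(
        {
            "subject_id": subjects,
            "oral_cluster": oral_clusters,
            "gut_cluster": gut_clusters,
            "ko_label": oral_letter,
            "gut_label": gut_letter,
            "koga_label": [a + b for a, b in zip(oral_letter, gut_letter)],
        }
    )
    return oral, gut, meta, truth


@dataclass(frozen=True)
class CorrelatedCountSpec:
    """Log-normal basis abundances with a target correlation structure."""

    n_samples: int
    basis_log_mean: tuple[float, ...]
    basis_log_covariance: tuple[tuple[float, ...], ...]
    depth: int = 10000
    seed: int | None = None

    def __post_init__(self) -> None:
        d = len(self.basis_log_mean)
        if d < 3:
            raise ValidationError("need at least 3 taxa")
        cov = np.asarray(self.basis_log_covariance, dtype=float)
        if cov.shape != (d, d):
            raise ValidationError("covariance shape must match basis_log_mean")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValidationError("covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-8:
            raise ValidationError("covariance must be positive semidefinite")
        if self.depth < 1 or self.n_samples < 2:
            raise ValidationError("depth >= 1 and n_samples >= 2 required")


def simulate_correlated_counts(
    spec: CorrelatedCountSpec, taxon_labels: list[str] | None = None
) -> AbundanceTable:
    """Counts whose latent (basis) log-abundances have a known covariance.

    Basis abundances are log-normal, closed to fractions, then observed
    through a multinomial of the given depth — the generative model under
    which SparCC consistently recovers the basis correlations.
    """
    rng = np.random.default_rng(spec.seed)
    mean = np.asarray(spec.basis_log_mean, dtype=float)
    cov = np.asarray(spec.basis_log_covariance, dtype=float)
    logs = rng.multivariate_normal(mean, cov, size=spec.n_samples, method="eigh")
    basis = np.exp(logs)
    fractions = basis / basis.sum(axis=1, keepdims=True)
    counts = np.array([rng.multinomial(spec.depth, f) for f in fractions])
    labels = taxon_labels or [f"taxon_{i:03d}" for i in range(mean.size)]
    ids = [f"s{i:03d}" for i in range(spec.n_samples)]
    return AbundanceTable(pd.DataFrame(counts, index=ids, columns=labels), "counts")


def simulate_typed_species_table(
    means: pd.DataFrame,
    samples_per_type: int = 5,
    depth: int | None = None,
    seed: int | None = None,
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Species-level table with prescribed per-type mean abundances.

    ``means`` is species × type (relative abundances; column sums may be
    below 1 — the remainder is unobserved background).  With
    ``depth=None`` every sample of a type equals the type's mean profile
    exactly (a relative table), so downstream type means are recovered
    without sampling noise; with a depth, multinomial counts are drawn
    over the species plus a background bucket and returned as counts.
    Also returns the sample → type assignment frame.
    """
    if (means.to_numpy() < 0).any() or (means.sum(axis=0) > 1 + 1e-9).any():
        raise ValidationError("per-type species means must be >= 0 and sum to <= 1")
    rng = np.random.default_rng(seed)
    rows, assign = [], []
    ids = []
    for ty in means.columns:
        profile = means[ty].to_numpy(dtype=float)
        for i in range(samples_per_type):
            sid = f"{ty}_{i:02d}"
            ids.append(sid)
            assign.append((sid, sid, ty))
            if depth is None:
                rows.append(profile)
            else:
                full = np.append(profile, max(0.0, 1.0 - profile.sum()))
                full /= full.sum()
                rows.append(rng.multinomial(depth, full)[:-1])
    df = pd.DataFrame(rows, index=ids, columns=list(means.index))
    mode = "relative" if depth is None else "counts"
    assignments = pd.DataFrame(
        assign, columns=["sample_id", "subject_id", "koga_label"]
    )
    return AbundanceTable(df, mode), assignments
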