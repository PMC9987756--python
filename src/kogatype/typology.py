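"""KO/KOGA typing: dominant-genus labels and the nested oral→gut pipeline.

A subject's oral community type (KO type) is the label of its PAM cluster
on the oral JSD distance matrix, named after the cluster's dominant
genus (S = Streptococcus-dominant, H = Haemophilus-dominant in the
reference cohort).  The composite oral-gut type (KOGA type) re-runs the
identical clustering pipeline on the gut samples *within each KO
subgroup* and concatenates the two dominant-genus initials (SB, SP, HB,
HP for Bacteroides/Prevotella gut clusters).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .abundance import AbundanceTable, SampleMetadata, ValidationError, prevalence_filter
from .cluster import ClusterSolution, KSelectionReport, jsd_distance_matrix, pam, select_k

__all__ = [
    "TypingParams",
    "dominant_taxon_labels",
    "taxon_initial",
    "assign_ko_types",
    "assign_koga_types",
    "type_frequencies",
]


@dataclass(frozen=True)
class TypingParams:
    """Knobs of the typing pipeline.

    min_mean_frac applies only when a stage is asked to (re-)filter;
    dominant_rule is either "difference" (inside-mean minus outside-mean,
    the default — robust when one genus is globally abundant) or
    "inside" (plain within-cluster mean).
    """

    k_max: int = 10
    pseudocount: float = 1e-9
    min_mean_frac: float = 1e-4
    refilter_subgroups: bool = False
    dominant_rule: str = "difference"
    seed: int | None = None


def taxon_initial(label: str) -> str:
    """Single-letter type code of a taxon label (rank prefixes stripped)."""
    name = label.rsplit(";", 1)[-1]
    name = re.sub(r"^[a-z]__", "", name)
    return name[:1].upper() or "?"


def dominant_taxon_labels(
    t: AbundanceTable, s: ClusterSolution, rule: str = "difference"
) -> ClusterSolution:
    """Label each cluster with its dominant taxon.

    "difference" picks the taxon maximizing (mean inside cluster − mean
    outside cluster); "inside" maximizes the within-cluster mean.  For
    k=1 the two rules coincide (the outside mean is taken as 0).  Ties
    break alphabetically.
    """
    if rule not in ("difference", "inside"):
        raise ValidationError(f"unknown dominant-taxon rule {rule!r}")
    if list(t.sample_ids) != list(s.sample_ids):
        raise ValidationError("table and cluster solution have different samples")
    values = t.values
    order = np.argsort(np.asarray(t.taxon_labels, dtype=object))
    dominant: dict[int, str] = {}
    for c in range(s.k):
        inside = s.labels == c
        score_in = values[inside].mean(axis=0)
        if rule == "difference" and (~inside).any():
            score = score_in - values[~inside].mean(axis=0)
        else:
            score = score_in
        # alphabetical tie-break: scan taxa in alphabetical order, keep max
        best = order[int(np.argmax(score[order]))]
        dominant[c] = t.taxon_labels[best]
    return replace(s, dominant_taxon=dominant)


def assign_ko_types(
    oral: AbundanceTable,
    meta: SampleMetadata,
    params: TypingParams = TypingParams(),
) -> tuple[pd.DataFrame, ClusterSolution, KSelectionReport]:
    """Cluster oral samples and assign each subject its oral (KO) type.

    ``oral`` must be a relative table, typically already prevalence-
    filtered.  Returns the per-subject assignment frame (columns
    subject_id, ko_taxon, ko_label), the labeled cluster solution and the
    k-selection report.
    """
    meta.check_covers(oral)
    d = jsd_distance_matrix(oral, pseudocount=params.pseudocount)
    k_max = min(params.k_max, oral.n_samples - 1)
    report = select_k(d, k_max=k_max, seed=params.seed)
    sol = dominant_taxon_labels(oral, report.solutions[report.chosen_k], params.dominant_rule)
    rows = []
    for sid, lab in zip(sol.sample_ids, sol.labels):
        taxon = sol.dominant_taxon[int(lab)]
        rows.append((meta.subject_of(sid), taxon, taxon_initial(taxon)))
    assignments = pd.DataFrame(rows, columns=["subject_id", "ko_taxon", "ko_label"])
    return assignments, sol, report


def assign_koga_types(
    gut: AbundanceTable,
    meta: SampleMetadata,
    ko_assignments: pd.DataFrame,
    params: TypingParams = TypingParams(),
) -> pd.DataFrame:
    """Extend KO assignments with gut types to form composite KOGA labels.

    For each KO subgroup the gut table is restricted to that subgroup's
    subjects and the same pipeline (optional re-filter → JSD → select_k →
    PAM → dominant-genus labels) is applied.  Subgroups smaller than 4
    samples cannot be clustered and raise an error.
    """
    out = ko_assignments.copy()
    out["gut_taxon"] = pd.NA
    out["gut_label"] = pd.NA
    for ko_label, group in ko_assignments.groupby("ko_label", sort=True):
        sample_ids = [meta.sample_of(s, "gut") for s in group["subject_id"]]
        if len(sample_ids) < 4:
            raise ValidationError(
                f"KO subgroup {ko_label!r} has only {len(sample_ids)} gut samples; "
                "need at least 4 to cluster"
            )
        sub = gut.subset_samples(sample_ids)
        if params.refilter_subgroups:
            sub, _ = prevalence_filter(sub, params.min_mean_frac)
        d = jsd_distance_matrix(sub, pseudocount=params.pseudocount)
        k_max = min(params.k_max, len(sample_ids) - 1)
        report = select_k(d, k_max=k_max, seed=params.seed)
        sol = dominant_taxon_labels(sub, report.solutions[report.chosen_k], params.dominant_rule)
        for sid, lab in zip(sol.sample_ids, sol.labels):
            taxon = sol.dominant_taxon[int(lab)]
            subj = meta.subject_of(sid)
            mask = out["subject_id"] == subj
            out.loc[mask, "gut_taxon"] = taxon
            out.loc[mask, "gut_label"] = taxon_initial(taxon)
    out["koga_label"] = out["ko_label"] + out["gut_label"]
    return out


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def type_frequencies(labels: pd.Series | list[str]) -> pd.DataFrame:
    """Count and percentage (1 decimal, half-up) per type label."""
    s = pd.Series(list(labels), dtype=object)
    if s.empty:
        raise ValidationError("no labels to tally")
    counts = s.value_counts().sort_index()
    total = int(counts.sum())
    pct = [_round_half_up(100.0 * c / total) for c in counts]
    return pd.DataFrame({"count": counts.astype(int), "percent": pct})
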