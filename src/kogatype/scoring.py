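"""Quartile health scoring of community types from indicator species.

The statistic characterizes each community type by a panel of indicator
species with known beneficial or harmful effects.  Per species, the mean
relative abundance across types is standardized to a z-score (sample
standard deviation, n−1); harmful species have their z-scores negated so
that *low* abundance raises the score.  Each z is mapped to a percentile
through the standard normal CDF, rounded to the nearest integer
percentage, and binned into quartile scores 1–4 at 25/50/75 (lower-closed
bins, outer values clamped).  Summing the quartile scores over the panel
gives a per-type site total, and oral + gut totals give the grand score
used to rank types.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .abundance import AbundanceTable, ValidationError

__all__ = [
    "SpeciesPanel",
    "ScoreCard",
    "type_means",
    "z_across_types",
    "reverse_harmful",
    "percentile_from_z",
    "quartile_score",
    "score_panel",
    "grand_totals",
]


@dataclass(frozen=True)
class SpeciesPanel:
    """Indicator species with role (beneficial|harmful) and body site."""

    data: pd.DataFrame  # columns: species, role, body_site

    def __post_init__(self) -> None:
        required = {"species", "role", "body_site"}
        if not required.issubset(self.data.columns):
            raise ValidationError(f"panel needs columns {sorted(required)}")
        if self.data.duplicated(["species", "body_site"]).any():
            raise ValidationError("duplicate (species, body_site) entries in panel")
        bad = ~self.data["role"].isin(["beneficial", "harmful"])
        if bad.any():
            raise ValidationError(
                f"roles must be beneficial|harmful, got {self.data.loc[bad, 'role'].unique().tolist()}"
            )
        if self.data.empty:
            raise ValidationError("species panel is empty")

    @classmethod
    def from_roles(cls, roles: pd.Series, body_site: str) -> "SpeciesPanel":
        return cls(
            pd.DataFrame(
                {
                    "species": roles.index,
                    "role": roles.to_numpy(),
                    "body_site": body_site,
                }
            )
        )

    def for_site(self, body_site: str) -> "SpeciesPanel":
        sub = self.data[self.data["body_site"] == body_site]
        return SpeciesPanel(sub.reset_index(drop=True))

    @property
    def species(self) -> list[str]:
        return list(self.data["species"])

    def role_of(self, species: str) -> str:
        row = self.data[self.data["species"] == species]
        if row.empty:
            raise ValidationError(f"species {species!r} not in panel")
        return str(row["role"].iloc[0])


@dataclass(frozen=True)
class ScoreCard:
    """Per-species and per-type scoring results for one body site."""

    body_site: str
    type_labels: tuple[str, ...]
    z: pd.DataFrame            # species × type, harmful rows already reversed
    percentile: pd.DataFrame   # integer 0-100
    quartile: pd.DataFrame     # integer 1-4
    totals: pd.Series          # per-type sum of quartile scores

    def long_format(self) -> pd.DataFrame:
        """Heatmap-ready long table (species, type, z, percentile, quartile)."""
        rows = []
        for sp in self.z.index:
            for ty in self.type_labels:
                rows.append(
                    (
                        sp,
                        ty,
                        float(self.z.at[sp, ty]),
                        int(self.percentile.at[sp, ty]),
                        int(self.quartile.at[sp, ty]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["species", "type", "z", "percentile", "quartile"]
        )


def type_means(
    t: AbundanceTable, assignments: pd.DataFrame, panel: SpeciesPanel
) -> pd.DataFrame:
    """Mean relative abundance of each panel species within each type.

    ``assignments`` must map every sample's subject to a type via columns
    ``subject_id`` and ``koga_label`` plus a ``sample_id`` column (or the
    table's sample ids must equal subject ids).  Panel species absent
    from the table are recorded as all-zero rows with a warning.
    """
    if t.mode != "relative":
        raise ValidationError("type_means expects a relative table")
    if "sample_id" in assignments.columns:
        mapping = assignments.set_index("sample_id")["koga_label"]
    else:
        mapping = assignments.set_index("subject_id")["koga_label"]
    try:
        sample_types = mapping.loc[t.sample_ids]
    except KeyError as exc:
        raise ValidationError(f"sample without type assignment: {exc}") from exc
    type_labels = sorted(sample_types.unique())
    out = pd.DataFrame(0.0, index=panel.species, columns=type_labels)
    for ty in type_labels:
        samples = sample_types.index[sample_types == ty]
        if len(samples) == 0:
            raise ValidationError(f"type {ty!r} has no samples")
        sub = t.data.loc[samples]
        for sp in panel.species:
            if sp in t.data.columns:
                out.at[sp, ty] = float(sub[sp].mean())
    missing = [sp for sp in panel.species if sp not in t.data.columns]
    if missing:
        warnings.warn(
            f"panel species absent from the table, scored as zero: {missing}",
            stacklevel=2,
        )
    return out


def z_across_types(means: pd.DataFrame) -> pd.DataFrame:
    """Standardize each species row across types (sample sd, n−1).

    A row with identical values in every type degenerates to all zeros
    (scored as the neutral percentile 50 downstream) with a warning.
    """
    if means.shape[1] < 2:
        raise ValidationError("z-scores need at least 2 types")
    values = means.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"species with identical means across types get z=0: "
            f"{list(means.index[flat])}",
            stacklevel=2,
        )
    sd[sd == 0] = 1.0
    z = (values - mu) / sd
    return pd.DataFrame(z, index=means.index, columns=means.columns)


def reverse_harmful(z: pd.DataFrame, panel: SpeciesPanel) -> pd.DataFrame:
    """Negate the z rows of harmful species (beneficial rows untouched)."""
    out = z.copy()
    for sp in z.index:
        if panel.role_of(sp) == "harmful":
            out.loc[sp] = -out.loc[sp]
    return out


def percentile_from_z(z: float) -> int:
    """Standard-normal CDF percentile, rounded half-away-from-zero."""
    if not math.isfinite(z):
        raise ValidationError(f"non-finite z-score {z!r}")
    return int(math.floor(100.0 * norm.cdf(z) + 0.5))


def quartile_score(percentile: int) -> int:
    """Bin an integer percentile into a quartile score 1-4.

    Bins are lower-closed: [0,25)→1, [25,50)→2, [50,75)→3, [75,100]→4.
    """
    if not 0 <= percentile <= 100:
        raise ValidationError(f"percentile {percentile} out of [0, 100]")
    if percentile < 25:
        return 1
    if percentile < 50:
        return 2
    if percentile < 75:
        return 3
    return 4


def score_panel(
    z: pd.DataFrame,
    panel: SpeciesPanel,
    body_site: str = "unspecified",
) -> ScoreCard:
    """Score a role-applied z matrix (harmful rows already reversed).

    Applies percentile_from_z then quartile_score elementwise; per-type
    totals are the column sums of the quartile scores.
    """
    missing = [sp for sp in z.index if sp not in panel.species]
    if missing:
        raise ValidationError(f"z rows not in panel: {missing}")
    pct = z.map(percentile_from_z)
    quart = pct.map(quartile_score)
    totals = quart.sum(axis=0)
    totals.name = "total"
    return ScoreCard(
        body_site=body_site,
        type_labels=tuple(z.columns),
        z=z,
        percentile=pct.astype(int),
        quartile=quart.astype(int),
        totals=totals.astype(int),
    )


def grand_totals(oral: ScoreCard, gut: ScoreCard) -> pd.Series:
    """Per-type oral + gut total scores."""
    if tuple(oral.type_labels) != tuple(gut.type_labels):
        raise ValidationError(
            f"type labels differ: {oral.type_labels} vs {gut.type_labels}"
        )
    out = oral.totals + gut.totals
    out.name = "grand_total"
    return out
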