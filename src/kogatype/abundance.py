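"""Abundance-table I/O, validation, normalization and prevalence filtering.

Tables are held as pandas DataFrames in the canonical orientation
samples-as-rows / taxa-as-columns.  Two modes exist: ``counts`` (raw
non-negative counts) and ``relative`` (per-sample fractions).  A relative
table normally sums to 1 per row; after prevalence filtering the removed
mass is *not* redistributed, so relative row sums may drop below 1 —
downstream clustering consumes the filtered table as-is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "AbundanceTable",
    "SampleMetadata",
    "read_table",
    "write_table",
    "read_biom",
    "to_relative",
    "drop_unnamed_taxa",
    "prevalence_filter",
]

_ROW_SUM_TOL = 1e-9

#: marker SILVA-style lineages use for an unnamed rank, e.g. "f__X;__"
UNNAMED_SUFFIX = ";__"


class ValidationError(ValueError):
    """Raised when an input table or metadata sheet violates an invariant."""


@dataclass(frozen=True)
class AbundanceTable:
    """Samples × taxa abundance matrix with a mode and body-site tag.

    Parameters
    ----------
    data : DataFrame
        Rows are samples (index = sample ids), columns are taxa.
    mode : {"counts", "relative"}
    body_site : {"oral", "gut", "unspecified"}
    """

    data: pd.DataFrame
    mode: str
    body_site: str = "unspecified"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.body_site not in ("oral", "gut", "unspecified"):
            raise ValidationError(f"unknown body_site {self.body_site!r}")
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon labels: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = _first_non_numeric(df)
            raise ValidationError(f"non-numeric cell at {bad}")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"non-numeric cell at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
            )
        if self.mode == "relative":
            sums = values.sum(axis=1)
            if (sums <= 0).any():
                sid = df.index[int(np.argmax(sums <= 0))]
                raise ValidationError(f"all-zero relative row for sample {sid!r}")
            if (sums > 1 + _ROW_SUM_TOL).any():
                sid = df.index[int(np.argmax(sums > 1 + _ROW_SUM_TOL))]
                raise ValidationError(
                    f"relative row for sample {sid!r} sums to more than 1"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def is_normalized(self) -> bool:
        """True when every row sums to 1 within tolerance."""
        return bool(
            self.mode == "relative"
            and np.allclose(self.values.sum(axis=1), 1.0, atol=_ROW_SUM_TOL, rtol=0)
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return AbundanceTable(self.data.loc[list(sample_ids)], self.mode, self.body_site)

    def with_body_site(self, body_site: str) -> "AbundanceTable":
        return AbundanceTable(self.data, self.mode, body_site)


def _first_non_numeric(df: pd.DataFrame) -> str:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            sid = df.index[int(np.argmax(bad.to_numpy()))]
            return f"sample {sid!r}, taxon {col!r} (value {df.at[sid, col]!r})"
    return "unknown cell"


@dataclass(frozen=True)
class SampleMetadata:
    """Sample → subject/body-site map.

    Each subject may contribute at most one oral and one gut sample.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"sample_id", "subject_id", "body_site"}
        if not required.issubset(self.data.columns):
            raise ValidationError(f"metadata needs columns {sorted(required)}")
        if self.data["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        bad_site = ~self.data["body_site"].isin(["oral", "gut"])
        if bad_site.any():
            raise ValidationError(
                f"body_site must be oral|gut, got {self.data.loc[bad_site, 'body_site'].unique().tolist()}"
            )
        counts = self.data.groupby(["subject_id", "body_site"]).size()
        if (counts > 1).any():
            subj = counts[counts > 1].index[0]
            raise ValidationError(f"subject {subj[0]!r} has multiple {subj[1]} samples")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]]
    ) -> "SampleMetadata":
        df = pd.DataFrame(records, columns=["sample_id", "subject_id", "body_site"])
        return cls(df)

    @classmethod
    def read(cls, path: str | Path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", dtype=str, comment="#"))

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def samples_for_site(self, body_site: str) -> pd.DataFrame:
        return self.data[self.data["body_site"] == body_site]

    def subject_of(self, sample_id: str) -> str:
        row = self.data[self.data["sample_id"] == sample_id]
        if row.empty:
            raise ValidationError(f"sample {sample_id!r} not in metadata")
        return str(row["subject_id"].iloc[0])

    def sample_of(self, subject_id: str, body_site: str) -> str:
        row = self.data[
            (self.data["subject_id"] == subject_id)
            & (self.data["body_site"] == body_site)
        ]
        if row.empty:
            raise ValidationError(
                f"subject {subject_id!r} has no {body_site} sample"
            )
        return str(row["sample_id"].iloc[0])

    def check_covers(self, table: AbundanceTable) -> None:
        known = set(self.data["sample_id"])
        missing = [s for s in table.sample_ids if s not in known]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")


def read_table(
    path: str | Path,
    mode: str,
    orientation: str = "samples_as_rows",
    body_site: str = "unspecified",
) -> AbundanceTable:
    """Read a TSV abundance table (header row, one label column).

    ``orientation="taxa_as_rows"`` transposes the file into the canonical
    samples-as-rows layout.  Non-numeric cells (including ``NA``), duplicate
    labels and negative values raise :class:`ValidationError` naming the cell.
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", keep_default_na=True)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "taxa_as_rows":
        df = df.T
    return AbundanceTable(df, mode=mode, body_site=body_site)


def write_table(t: AbundanceTable, path: str | Path) -> None:
    """Write a table as TSV in the canonical samples-as-rows layout."""
    out = t.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_biom(path: str | Path, body_site: str = "unspecified") -> AbundanceTable:
    """Read a BIOM v1 (JSON) table through the same validation.

    BIOM stores observations (taxa) as rows; the result is transposed to
    samples-as-rows.  Mode is taken from the matrix element type: ``int``
    data are treated as counts, ``float`` as relative abundances.
    """
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    dense = np.zeros(shape, dtype=float)
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            dense[int(r), int(c)] = v
    else:
        dense[:] = np.asarray(doc["data"], dtype=float)
    mode = "counts" if doc.get("matrix_element_type", "int") == "int" else "relative"
    df = pd.DataFrame(dense.T, index=samples, columns=taxa)
    return AbundanceTable(df, mode=mode, body_site=body_site)


def to_relative(t: AbundanceTable) -> AbundanceTable:
    """Convert a counts table to per-sample relative abundances.

    Refuses already-relative input (double normalization is almost always a
    pipeline bug) and names any sample whose row is all zeros.
    """
    if t.mode != "counts":
        raise ValidationError("to_relative expects a counts table (already relative)")
    sums = t.values.sum(axis=1)
    if (sums == 0).any():
        sid = t.sample_ids[int(np.argmax(sums == 0))]
        raise ValidationError(f"sample {sid!r} has zero total count")
    return AbundanceTable(t.data.div(sums, axis=0), "relative", t.body_site)


def drop_unnamed_taxa(t: AbundanceTable) -> AbundanceTable:
    """Remove taxa with an unnamed terminal rank (label ends in ";__" or is "__").

    Relative tables are re-normalized afterwards so rows sum to 1 again.
    """
    keep = [
        c
        for c in t.taxon_labels
        if not (c.endswith(UNNAMED_SUFFIX) or c == "__")
    ]
    if not keep:
        raise ValidationError("all taxa are unnamed; nothing left after filtering")
    if len(keep) == len(t.taxon_labels):
        return t
    df = t.data[keep]
    if t.mode == "relative":
        sums = df.to_numpy().sum(axis=1)
        if (sums == 0).any():
            sid = df.index[int(np.argmax(sums == 0))]
            raise ValidationError(
                f"sample {sid!r} has no abundance left after dropping unnamed taxa"
            )
        df = df.div(sums, axis=0)
    return AbundanceTable(df, t.mode, t.body_site)


def prevalence_filter(
    t: AbundanceTable, min_mean_frac: float = 1e-4
) -> tuple[AbundanceTable, list[str]]:
    """Keep taxa whose mean relative abundance exceeds ``min_mean_frac``.

    The mean is the unweighted average of per-sample relative abundances
    over all samples in ``t``; the comparison is strict (``>``).  The
    surviving table is returned *without* re-normalization together with
    the list of removed taxa.
    """
    if t.mode != "relative":
        raise ValidationError("prevalence_filter expects a relative table")
    means = t.values.mean(axis=0)
    keep_mask = means > min_mean_frac
    if not keep_mask.any():
        raise ValidationError(
            f"no taxon has mean relative abundance > {min_mean_frac}"
        )
    keep = [c for c, m in zip(t.taxon_labels, keep_mask) if m]
    removed = [c for c, m in zip(t.taxon_labels, keep_mask) if not m]
    return AbundanceTable(t.data[keep], "relative", t.body_site), removed
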