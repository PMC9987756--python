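"""Seeded two-level co-occurrence networks from a correlation estimate.

Starting from a seed genus (the dominant genus of a community type), the
first network collects every taxon whose correlation with the seed passes
|R| > r_cutoff with p < p_cutoff; the second network repeats the query
from each first-level partner, excluding only the seed itself (other
first-level taxa may legitimately reappear as second-level partners).
Edges carry the correlation, its sign and the p-value, and can be
exported as an edge-list TSV or GraphML for graph tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .abundance import ValidationError
from .sparcc import CorrelationEstimate

__all__ = [
    "Edge",
    "SeedNetwork",
    "seeded_two_level_network",
    "count_network_edges",
    "export_edges",
]


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    r: float
    p: float | None = None

    @property
    def sign(self) -> str:
        return "Positive" if self.r > 0 else "Negative"


@dataclass(frozen=True)
class SeedNetwork:
    seed_taxon: str
    level1_edges: tuple[Edge, ...] = field(default_factory=tuple)
    level2_edges: tuple[Edge, ...] = field(default_factory=tuple)

    @classmethod
    def from_lists(
        cls,
        seed_taxon: str,
        level1: list[tuple[str, float]],
        level2: list[tuple[str, str, float]],
    ) -> "SeedNetwork":
        """Build a network from bare (partner, R) / (parent, partner, R) lists."""
        return cls(
            seed_taxon=seed_taxon,
            level1_edges=tuple(Edge(seed_taxon, g, r) for g, r in level1),
            level2_edges=tuple(Edge(g1, g2, r) for g1, g2, r in level2),
        )


def _significant_partners(
    c: CorrelationEstimate, taxon: str, r_cutoff: float, p_cutoff: float
) -> list[Edge]:
    out = []
    for other in c.taxon_labels:
        if other == taxon:
            continue
        r = float(c.r.at[taxon, other])
        p = float(c.p.at[taxon, other]) if c.p is not None else None
        if abs(r) > r_cutoff and (p is None or p < p_cutoff):
            out.append(Edge(taxon, other, r, p))
    out.sort(key=lambda e: -e.r)
    return out


def seeded_two_level_network(
    c: CorrelationEstimate,
    seed_taxon: str,
    r_cutoff: float = 0.3,
    p_cutoff: float = 0.05,
) -> SeedNetwork:
    """Extract the two-level network around ``seed_taxon``.

    Both cutoffs are strict; partners at each level are sorted by
    descending R.  A pure function of (R, p, cutoffs).
    """
    if seed_taxon not in c.taxon_labels:
        raise ValidationError(f"seed taxon {seed_taxon!r} not in correlation matrix")
    level1 = _significant_partners(c, seed_taxon, r_cutoff, p_cutoff)
    level2: list[Edge] = []
    for e1 in level1:
        for e2 in _significant_partners(c, e1.target, r_cutoff, p_cutoff):
            if e2.target == seed_taxon:
                continue
            level2.append(e2)
    return SeedNetwork(seed_taxon, tuple(level1), tuple(level2))


def count_network_edges(n: SeedNetwork) -> tuple[int, int, int, int]:
    """Sign tallies (level1 pos, level1 neg, level2 pos, level2 neg).

    Second-level edges are counted with multiplicity per first-level
    parent, so a taxon linked to several parents contributes once per
    parent branch.
    """
    l1p = sum(1 for e in n.level1_edges if e.r > 0)
    l1n = len(n.level1_edges) - l1p
    l2p = sum(1 for e in n.level2_edges if e.r > 0)
    l2n = len(n.level2_edges) - l2p
    return l1p, l1n, l2p, l2n


def _edge_frame(n: SeedNetwork) -> pd.DataFrame:
    rows = [
        (e.source, e.target, level, e.r, e.sign, e.p)
        for level, edges in ((1, n.level1_edges), (2, n.level2_edges))
        for e in edges
    ]
    return pd.DataFrame(rows, columns=["source", "target", "level", "R", "sign", "p"])


def export_edges(n: SeedNetwork, path: str | Path, format: str = "edge_tsv") -> Path:
    """Write the network as an edge-list TSV or GraphML file."""
    path = Path(path)
    df = _edge_frame(n)
    if format == "edge_tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        g = nx.MultiDiGraph()
        g.add_node(n.seed_taxon, role="seed")
        for _, row in df.iterrows():
            attrs = {"level": int(row.level), "R": float(row.R), "sign": row.sign}
            if pd.notna(row.p):
                attrs["p"] = float(row.p)
            g.add_edge(row.source, row.target, **attrs)
        nx.write_graphml(g, path)
    else:
        raise ValidationError(f"unknown export format {format!r}")
    return path
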