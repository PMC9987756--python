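"""Bundled reference data from a healthy Korean oral–gut cohort.

Two kinds of reference objects live here:

* the indicator-species z-score panel — 14 oral and 15 gut species with a
  beneficial/harmful role and their z-scores across the four oral–gut
  community types (SB, SP, HB, HP).  Harmful rows are stored *after* sign
  reversal (the convention used for health scoring, where low abundance of
  a harmful species should raise the score);
* the seeded co-occurrence edge lists for the Streptococcus-dominant (S)
  and Haemophilus-dominant (H) oral community types: first-level partners
  of the seed genus and, per partner, its own significant partners
  (second level), with SparCC correlation coefficients.  All listed edges
  passed |R| > 0.3 and p < 0.05 in the reference cohort; the per-edge
  p-values themselves are not available, so they are ``None`` here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

TYPE_LABELS = ("SB", "SP", "HB", "HP")

# (species, role, (z_SB, z_SP, z_HB, z_HP)); harmful rows already reversed.
_ORAL_ROWS = [
    ("Streptococcus sanguinis", "beneficial", (1.109359234, 0.581684099, -0.821522451, -0.869520881)),
    ("Schaalia odontolytica", "beneficial", (0.866037466, 0.849673343, -0.690221094, -1.025489716)),
    ("Streptococcus parasanguinis", "beneficial", (0.337667371, 1.244063456, -0.581878978, -0.999851848)),
    ("Streptococcus gordonii", "beneficial", (-0.358857274, 1.492744777, -0.560460981, -0.573426521)),
    ("Streptococcus salivarius", "beneficial", (0.491720027, 1.165130406, -0.709880128, -0.946970304)),
    ("Haemophilus parainfluenzae", "beneficial", (-0.776220496, -0.94881883, 0.794166776, 0.930872549)),
    ("Prevotella melaninogenica", "beneficial", (0.770450127, 0.826677921, -0.325488334, -1.271639714)),
    ("Prevotella histicola", "beneficial", (0.245255701, 1.30447429, -0.638181156, -0.911548835)),
    ("Porphyromonas pasteri", "beneficial", (-0.78069542, -0.842878657, 1.237271374, 0.386302702)),
    ("Prevotella intermedia", "harmful", (-1.498508, 0.4590254, 0.477864, 0.5616186)),
    ("Veillonella atypica", "harmful", (-0.5790756, -1.109888, 0.7873802, 0.9015834)),
    ("Fusobacterium periodonticum", "harmful", (0.5750737, 0.7623781, -1.4412805, 0.1038287)),
    ("Rothia aeria", "harmful", (-1.3043268, 1.0787586, 0.3468471, -0.121279)),
    ("Rothia mucilaginosa", "harmful", (0.2192554, -1.4718224, 0.6508191, 0.6017479)),
]

_GUT_ROWS = [
    ("Bifidobacterium animalis", "beneficial", (1.494121361, -0.560581746, -0.372957869, -0.560581746)),
    ("Bifidobacterium longum", "beneficial", (1.197021612, -0.703599839, 0.442619949, -0.936041723)),
    ("Roseburia hominis", "beneficial", (0.76553502, 0.087938774, 0.583712049, -1.437185843)),
    ("Akkermansia muciniphila", "beneficial", (0.6107924, -0.848966561, 1.088062043, -0.849887882)),
    ("Bacteroides plebeius", "beneficial", (1.227955621, -0.638367168, 0.380040967, -0.969629421)),
    ("Bacteroides coprocola", "beneficial", (0.887645241, -0.90570478, 0.843182545, -0.825123005)),
    ("Bacteroides vulgatus", "beneficial", (0.427038072, -0.883200836, 1.211329198, -0.755166434)),
    ("Ruminococcus bicirculans", "beneficial", (0.033982266, -1.045271919, 1.340779079, -0.329489427)),
    ("Bifidobacterium bifidum", "beneficial", (1.262130174, -0.747183405, 0.340924182, -0.855870951)),
    ("Bifidobacterium breve", "beneficial", (-0.351455176, -0.570271686, 1.491998548, -0.570271686)),
    ("Fusobacterium nucleatum", "harmful", (0.5, 0.5, -1.5, 0.5)),
    ("Prevotella copri", "harmful", (0.79944717, -0.36895163, 0.8172482, -1.2477437)),
    ("Clostridioides difficile", "harmful", (0.5, 0.5, -1.5, 0.5)),
    ("Ruminococcus torques", "harmful", (-0.72759706, 0.46694355, -0.9229054, 1.183559)),
    ("Desulfovibrio piger", "harmful", (0.25744044, -1.11941193, -0.3780705, 1.240042)),
]


@dataclass(frozen=True)
class ReferencePanel:
    """Indicator-species z-score panel for one body site."""

    body_site: str
    z: pd.DataFrame          # species × type, harmful rows sign-reversed
    roles: pd.Series         # species → {beneficial, harmful}


def _build(rows, site: str) -> ReferencePanel:
    z = pd.DataFrame(
        [r[2] for r in rows],
        index=[r[0] for r in rows],
        columns=list(TYPE_LABELS),
        dtype=float,
    )
    roles = pd.Series([r[1] for r in rows], index=z.index, name="role")
    return ReferencePanel(site, z, roles)


def reference_scoring_panel() -> dict[str, ReferencePanel]:
    """Return the bundled oral (14-species) and gut (15-species) z panels."""
    return {"oral": _build(_ORAL_ROWS, "oral"), "gut": _build(_GUT_ROWS, "gut")}


# ---------------------------------------------------------------------------
# Reference seeded co-occurrence edge lists
# ---------------------------------------------------------------------------

# level 1: (partner, R); level 2: (level-1 parent, partner, R)
S_TYPE_SEED = "Streptococcus"
S_TYPE_LEVEL1 = [
    ("Granulicatella", 0.562),
    ("Gemella", 0.529),
    ("Actinomyces", 0.517),
    ("Neisseria", 0.357),
    ("Corynebacterium", 0.303),
    ("Selenomonas", -0.323),
]
S_TYPE_LEVEL2 = [
    ("Granulicatella", "Rothia", 0.609),
    ("Granulicatella", "Haemophilus", 0.359),
    ("Granulicatella", "Neisseria", 0.350),
    ("Granulicatella", "Selenomonas", -0.395),
    ("Gemella", "Granulicatella", 0.582),
    ("Gemella", "Rothia", 0.536),
    ("Gemella", "Neisseria", 0.372),
    ("Gemella", "Corynebacterium", 0.304),
    ("Gemella", "Selenomonas", -0.509),
    ("Gemella", "Megasphaera", -0.387),
    ("Actinomyces", "Rothia", 0.621),
    ("Actinomyces", "Leptotrichia", 0.399),
    ("Actinomyces", "Neisseria", 0.335),
    ("Actinomyces", "Lachnoanaerobaculum", 0.330),
    ("Actinomyces", "Stomatobaculum", 0.328),
    ("Actinomyces", "Lachnospira", -0.323),
    ("Actinomyces", "UCG-002", -0.303),
    ("Neisseria", "Rothia", 0.538),
    ("Neisseria", "Lachnoanaerobaculum", 0.387),
    ("Neisseria", "Haemophilus", 0.378),
    ("Neisseria", "Gemella", 0.372),
    ("Neisseria", "Granulicatella", 0.350),
    ("Neisseria", "Porphyromonas", 0.338),
    ("Neisseria", "Actinomyces", 0.335),
    ("Neisseria", "Peptostreptococcus", 0.333),
    ("Neisseria", "Leptotrichia", 0.323),
    ("Corynebacterium", "Lautropia", 0.446),
    ("Corynebacterium", "Rothia", 0.390),
    ("Corynebacterium", "Cardiobacterium", 0.374),
    ("Corynebacterium", "F0332", 0.318),
    ("Corynebacterium", "Gemella", 0.304),
    ("Corynebacterium", "Amnipila", -0.302),
    ("Selenomonas", "Alloprevotella", 0.388),
    ("Selenomonas", "Atopobium", 0.373),
    ("Selenomonas", "Megasphaera", 0.336),
    ("Selenomonas", "Prevotella", 0.331),
    ("Selenomonas", "TM7x", 0.306),
    ("Selenomonas", "Capnocytophaga", 0.305),
    ("Selenomonas", "Gemella", -0.509),
    ("Selenomonas", "Granulicatella", -0.395),
    ("Selenomonas", "Rothia", -0.309),
]

H_TYPE_SEED = "Haemophilus"
H_TYPE_LEVEL1 = [
    ("Veillonella", 0.451),
    ("Megasphaera", 0.404),
    ("Streptococcus", 0.377),
    ("Treponema", -0.322),
    ("Bacteroides", -0.321),
]
H_TYPE_LEVEL2 = [
    ("Veillonella", "Fusobacterium", 0.509),
    ("Veillonella", "Leptotrichia", 0.466),
    ("Veillonella", "Prevotella", 0.434),
    ("Veillonella", "Oribacterium", 0.413),
    ("Veillonella", "Lachnoanaerobaculum", 0.393),
    ("Veillonella", "Megasphaera", 0.307),
    ("Veillonella", "Lautropia", -0.369),
    ("Megasphaera", "Veillonella", 0.307),
    ("Streptococcus", "Gemella", 0.810),
    ("Streptococcus", "Rothia", 0.682),
    ("Streptococcus", "Granulicatella", 0.377),
    ("Streptococcus", "Lactococcus", 0.357),
    ("Streptococcus", "Clostridium-sensu-stricto-1", 0.343),
    ("Streptococcus", "Amnipila", 0.343),
    ("Streptococcus", "Lachnospiraceae_uncultured", 0.304),
    ("Streptococcus", "Dialister", -0.421),
    ("Streptococcus", "Selenomonas", -0.419),
    ("Streptococcus", "Alloprevotella", -0.415),
    ("Streptococcus", "Bacteroides", -0.347),
    ("Streptococcus", "Aggregatibacter", -0.347),
    ("Streptococcus", "Prevotella", -0.334),
    ("Streptococcus", "Lachnoanaerobaculum", -0.310),
    ("Streptococcus", "Peptostreptococcus", -0.301),
    ("Treponema", "Lentimicrobium", 0.370),
    ("Bacteroides", "[Ruminococcus]-gnavus-group", 0.441),
    ("Bacteroides", "Megamonas", 0.415),
    ("Bacteroides", "Blautia", 0.355),
    ("Bacteroides", "Escherichia-Shigella", 0.329),
    ("Bacteroides", "Streptococcus", -0.347),
    ("Bacteroides", "TM7x", -0.315),
]
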