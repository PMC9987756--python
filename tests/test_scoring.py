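"""The z-score → percentile → quartile health-scoring statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kogatype as kt
from kogatype.abundance import ValidationError

TYPES = ["SB", "SP", "HB", "HP"]


def beneficial_panel(species, site="oral"):
    return kt.SpeciesPanel.from_roles(pd.Series("beneficial", index=species), site)


class TestZAcrossTypes:
    def test_single_spike_closed_form(self):
        means = pd.DataFrame([[0.0, 0.0, 0.02, 0.0]], index=["sp"], columns=TYPES)
        z = kt.z_across_types(means)
        np.testing.assert_allclose(z.loc["sp"], [-0.5, -0.5, 1.5, -0.5])

    def test_reference_row_is_standardized(self):
        ref = kt.reference_scoring_panel()["oral"]
        row = ref.z.loc["Streptococcus sanguinis"]
        assert row.mean() == pytest.approx(0.0, abs=1e-6)
        assert row.std(ddof=1) == pytest.approx(1.0, abs=1e-6)

    def test_constant_row_degenerates_to_zero(self):
        means = pd.DataFrame([[0.1] * 4], index=["flat"], columns=TYPES)
        with pytest.warns(UserWarning, match="identical means"):
            z = kt.z_across_types(means)
        np.testing.assert_array_equal(z.loc["flat"], [0, 0, 0, 0])

    def test_single_type_rejected(self):
        means = pd.DataFrame([[0.1]], index=["sp"], columns=["SB"])
        with pytest.raises(ValidationError, match="2 types"):
            kt.z_across_types(means)


class TestReverseHarmful:
    def test_harmful_negated_beneficial_untouched(self):
        z = pd.DataFrame(
            [[-0.5, -0.5, 1.5, -0.5], [1.0, -1.0, 0.5, -0.5]],
            index=["bad", "good"],
            columns=TYPES,
        )
        panel = kt.SpeciesPanel(
            pd.DataFrame(
                {
                    "species": ["bad", "good"],
                    "role": ["harmful", "beneficial"],
                    "body_site": "gut",
                }
            )
        )
        out = kt.reverse_harmful(z, panel)
        np.testing.assert_allclose(out.loc["bad"], [0.5, 0.5, -1.5, 0.5])
        np.testing.assert_allclose(out.loc["good"], z.loc["good"])
        back = kt.reverse_harmful(out, panel)
        pd.testing.assert_frame_equal(back, z)


class TestPercentileAndQuartile:
    @pytest.mark.parametrize(
        "z,expected",
        [
            (0.0, 50),
            (-0.690221094, 25),   # 24.506 rounds up across the bin edge
            (1.109359234, 87),
        ],
    )
    def test_percentile_values(self, z, expected):
        assert kt.percentile_from_z(z) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            kt.percentile_from_z(float("nan"))

    @pytest.mark.parametrize(
        "pct,score",
        [(0, 1), (24, 1), (25, 2), (49, 2), (50, 3), (74, 3), (75, 4), (100, 4)],
    )
    def test_quartile_bins(self, pct, score):
        assert kt.quartile_score(pct) == score

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            kt.quartile_score(101)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(-6, 6), st.floats(0, 2))
    def test_monotone_in_z(self, z, delta):
        p1, p2 = kt.percentile_from_z(z), kt.percentile_from_z(z + delta)
        assert p2 >= p1
        assert kt.quartile_score(p2) >= kt.quartile_score(p1)


class TestScorePanel:
    def test_all_zero_z_scores_neutral(self):
        species = [f"sp{i}" for i in range(14)]
        z = pd.DataFrame(0.0, index=species, columns=TYPES)
        card = kt.score_panel(z, beneficial_panel(species), body_site="oral")
        assert (card.totals == 14 * 3).all()

    def test_site_total_bounds(self):
        ref = kt.reference_scoring_panel()["gut"]
        card = kt.score_panel(
            ref.z, kt.SpeciesPanel.from_roles(ref.roles, "gut"), body_site="gut"
        )
        n = len(ref.z)
        assert ((card.totals >= n) & (card.totals <= 4 * n)).all()

    def test_long_format_shape(self):
        ref = kt.reference_scoring_panel()["oral"]
        card = kt.score_panel(
            ref.z, kt.SpeciesPanel.from_roles(ref.roles, "oral"), body_site="oral"
        )
        long = card.long_format()
        assert len(long) == 14 * 4
        assert set(long.columns) == {"species", "type", "z", "percentile", "quartile"}

    def test_beneficial_monotonicity(self):
        """Raising a beneficial z for one type never lowers that type's total."""
        species = ["a", "b", "c"]
        z = pd.DataFrame(
            np.zeros((3, 4)), index=species, columns=TYPES
        )
        base = kt.score_panel(z, beneficial_panel(species)).totals["SB"]
        z2 = z.copy()
        z2.loc["a", "SB"] = 1.2
        bumped = kt.score_panel(z2, beneficial_panel(species)).totals["SB"]
        assert bumped >= base


class TestTypeMeans:
    def test_one_sample_per_type(self):
        means = pd.DataFrame(
            {"SB": [0.1, 0.2], "SP": [0.3, 0.1]}, index=["sp1", "sp2"]
        )
        t, assign = kt.simulate_typed_species_table(means, samples_per_type=1)
        got = kt.type_means(t, assign, beneficial_panel(["sp1", "sp2"]))
        pd.testing.assert_frame_equal(got, means, check_names=False)

    def test_missing_species_zero_filled_with_warning(self):
        means = pd.DataFrame({"SB": [0.4], "SP": [0.2]}, index=["present"])
        t, assign = kt.simulate_typed_species_table(means, samples_per_type=2)
        panel = beneficial_panel(["present", "absent"])
        with pytest.warns(UserWarning, match="absent"):
            got = kt.type_means(t, assign, panel)
        assert (got.loc["absent"] == 0).all()


class TestGrandTotals:
    def test_reference_grand_totals(self):
        panels = kt.reference_scoring_panel()
        cards = {
            site: kt.score_panel(
                ref.z, kt.SpeciesPanel.from_roles(ref.roles, site), body_site=site
            )
            for site, ref in panels.items()
        }
        grand = kt.grand_totals(cards["oral"], cards["gut"])
        assert grand.tolist() == [84, 69, 77, 58]

    def test_commutative_and_zero_identity(self):
        panels = kt.reference_scoring_panel()
        oral = kt.score_panel(
            panels["oral"].z,
            kt.SpeciesPanel.from_roles(panels["oral"].roles, "oral"),
            body_site="oral",
        )
        gut = kt.score_panel(
            panels["gut"].z,
            kt.SpeciesPanel.from_roles(panels["gut"].roles, "gut"),
            body_site="gut",
        )
        pd.testing.assert_series_equal(
            kt.grand_totals(oral, gut), kt.grand_totals(gut, oral),
            check_names=False,
        )

    def test_label_mismatch_rejected(self):
        panels = kt.reference_scoring_panel()
        oral = kt.score_panel(
            panels["oral"].z,
            kt.SpeciesPanel.from_roles(panels["oral"].roles, "oral"),
        )
        other = kt.ScoreCard(
            body_site="gut",
            type_labels=("A", "B", "C", "D"),
            z=oral.z,
            percentile=oral.percentile,
            quartile=oral.quartile,
            totals=oral.totals,
        )
        with pytest.raises(ValidationError, match="labels differ"):
            kt.grand_totals(oral, other)


class TestPipelineComposition:
    def test_planted_means_reproduce_reference_scorecard(self):
        """Back-compute per-type means from the reference z patterns, push a
        synthetic species table through type_means → z → reversal → scoring,
        and recover the reference quartiles exactly."""
        ref = kt.reference_scoring_panel()["oral"]
        panel = kt.SpeciesPanel.from_roles(ref.roles, "oral")
        # un-reverse harmful rows to get raw z, then means = c*(4 + z) > 0
        raw_z = kt.reverse_harmful(ref.z, panel)
        means = 0.001 * (4.0 + raw_z)
        t, assign = kt.simulate_typed_species_table(means, samples_per_type=3)
        got_means = kt.type_means(t, assign, panel)[list(ref.z.columns)]
        z = kt.reverse_harmful(kt.z_across_types(got_means), panel)
        card = kt.score_panel(z, panel, body_site="oral")
        ref_card = kt.score_panel(ref.z, panel, body_site="oral")
        pd.testing.assert_frame_equal(card.quartile, ref_card.quartile)
        assert card.totals.tolist() == [35, 42, 34, 30]
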