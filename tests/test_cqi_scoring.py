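"""Quintile scoring, CQI totals, quantity bands, Mediterranean score."""

import numpy as np
import pandas as pd
import pytest

from carbquality.cqi_scoring import (
    CQIComponents,
    QuintileCutoffs,
    carb_quantity,
    cqi_category,
    derive_cutoffs,
    load_cutoffs,
    med_diet_score,
    quintile_rank,
    save_cutoffs,
    score_cqi,
    score_cqi_frame,
)
from carbquality.ffq_engine import DietProfile


class TestQuintileCutoffs:
    def test_values_1_to_10(self):
        c = derive_cutoffs(range(1, 11), component="x")
        assert c.cuts == pytest.approx((2.8, 4.6, 6.4, 8.2))

    def test_constant_vector_collapses_ranks(self):
        c = derive_cutoffs([3.0] * 8, component="x")
        assert len(set(c.cuts)) == 1
        assert quintile_rank(3.0, c) == 1
        c_inv = derive_cutoffs([3.0] * 8, component="x", invert=True)
        assert quintile_rank(3.0, c_inv) == 5

    def test_strictly_increasing_five_vector_spans_quintiles(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        c = derive_cutoffs(vals, component="x")
        assert [quintile_rank(v, c) for v in vals] == [1, 2, 3, 4, 5]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">=5"):
            derive_cutoffs([1, 2, 3, 4], component="x")

    def test_roundtrip_csv(self, tmp_path):
        cuts = {
            "gi": QuintileCutoffs("gi", (50.1, 55.0, 58.2, 62.7), invert=True),
            "fiber_g_d": QuintileCutoffs("fiber_g_d", (18.0, 22.0, 25.5, 30.0)),
        }
        path = tmp_path / "cutoffs.csv"
        save_cutoffs(cuts, path)
        back = load_cutoffs(path)
        assert back == cuts


class TestQuintileRank:
    CUTS = QuintileCutoffs("x", (10.0, 20.0, 30.0, 40.0))
    CUTS_INV = QuintileCutoffs("x", (10.0, 20.0, 30.0, 40.0), invert=True)

    def test_below_first_cut(self):
        assert quintile_rank(5.0, self.CUTS) == 1
        assert quintile_rank(5.0, self.CUTS_INV) == 5

    def test_boundary_goes_to_lower_bin(self):
        assert quintile_rank(10.0, self.CUTS) == 1
        assert quintile_rank(20.0, self.CUTS) == 2
        assert quintile_rank(40.0, self.CUTS) == 4
        assert quintile_rank(40.0001, self.CUTS) == 5

    def test_missing_value_propagates(self):
        assert quintile_rank(None, self.CUTS) is None
        assert quintile_rank(float("nan"), self.CUTS) is None

    def test_invert_is_reflection(self):
        rng = np.random.default_rng(3)
        for v in rng.uniform(-5, 55, 50):
            assert quintile_rank(v, self.CUTS_INV) == 6 - quintile_rank(v, self.CUTS)

    def test_against_rank_then_bin_oracle(self):
        rng = np.random.default_rng(11)
        vals = rng.random(100)
        cuts = derive_cutoffs(vals, component="x")
        order = np.argsort(vals)
        oracle = np.empty(100, dtype=int)
        oracle[order] = np.arange(100) // 20 + 1  # 5 bins of 20 by rank
        got = np.array([quintile_rank(v, cuts) for v in vals])
        assert (got == oracle).all()

    def test_uniform_over_continuous_distribution(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal(1000)
        cuts = derive_cutoffs(vals, component="x")
        counts = np.bincount([quintile_rank(v, cuts) for v in vals])[1:]
        assert counts.max() - counts.min() <= 1


class TestCQIScore:
    UNIT_CUTS = {
        name: QuintileCutoffs(name, (1.0, 2.0, 3.0, 4.0), invert=(name == "gi"))
        for name in ("gi", "wholegrain_ratio", "fiber_g_d", "solid_ratio")
    }

    def _components(self, gi, wg, fib, sol):
        # wholegrain/solid ratios validated to [0,1]; use raw dataclass
        # bypass by scoring a frame instead for out-of-range test values
        return pd.DataFrame(
            {"gi": [gi], "wholegrain_ratio": [wg], "fiber_g_d": [fib], "solid_ratio": [sol]}
        )

    def test_floor_and_ceiling(self):
        worst = score_cqi_frame(self._components(10, 0, 0, 0), self.UNIT_CUTS)
        assert worst["cqi_total"].iloc[0] == 4
        assert worst["cqi_category"].iloc[0] == "low"
        best = score_cqi_frame(self._components(0, 10, 10, 10), self.UNIT_CUTS)
        assert best["cqi_total"].iloc[0] == 20
        assert best["cqi_category"].iloc[0] == "high"

    def test_component_points_2345_total_14_mid(self):
        # gi 3.5 -> raw rank 4, inverted 2; others land in ranks 3, 4, 5
        frame = score_cqi_frame(self._components(3.5, 2.5, 3.5, 4.5), self.UNIT_CUTS)
        assert frame["cqi_total"].iloc[0] == 14
        assert frame["cqi_category"].iloc[0] == "mid"

    def test_category_bounds(self):
        assert cqi_category(4) == "low" and cqi_category(9) == "low"
        assert cqi_category(10) == "mid" and cqi_category(14) == "mid"
        assert cqi_category(15) == "high" and cqi_category(20) == "high"

    def test_missing_component_rejected(self):
        comp = CQIComponents(gi=None, wholegrain_ratio=0.5, fiber_g_d=20, solid_ratio=0.9)
        with pytest.raises(ValueError, match="gi"):
            score_cqi(comp, self.UNIT_CUTS)

    def test_score_matches_dataclass_path(self):
        cuts = {
            "gi": QuintileCutoffs("gi", (50.0, 55.0, 60.0, 65.0), invert=True),
            "wholegrain_ratio": QuintileCutoffs("wholegrain_ratio", (0.2, 0.4, 0.6, 0.8)),
            "fiber_g_d": QuintileCutoffs("fiber_g_d", (10.0, 20.0, 30.0, 40.0)),
            "solid_ratio": QuintileCutoffs("solid_ratio", (0.2, 0.4, 0.6, 0.8)),
        }
        comp = CQIComponents(gi=57.0, wholegrain_ratio=0.5, fiber_g_d=15.0, solid_ratio=0.9)
        score = score_cqi(comp, cuts)
        assert score.total == sum(score.component_points.values())
        frame = score_cqi_frame(self._components(57.0, 0.5, 15.0, 0.9), cuts)
        assert score.total == frame["cqi_total"].iloc[0]
        assert score.category == frame["cqi_category"].iloc[0]

    def test_monotone_in_each_component(self):
        # moving any single component to a better quintile never lowers the
        # total (better = lower GI, higher anything else)
        rng = np.random.default_rng(17)
        pop = pd.DataFrame(
            {
                "gi": rng.uniform(40, 90, 200),
                "wholegrain_ratio": rng.random(200),
                "fiber_g_d": rng.uniform(5, 45, 200),
                "solid_ratio": rng.random(200),
            }
        )
        from carbquality.cqi_scoring import derive_cqi_cutoffs

        cuts = derive_cqi_cutoffs(pop)
        for _ in range(50):
            base = {
                "gi": rng.uniform(40, 90),
                "wholegrain_ratio": rng.random(),
                "fiber_g_d": rng.uniform(5, 45),
                "solid_ratio": rng.random(),
            }
            t0 = score_cqi_frame(pd.DataFrame([base]), cuts)["cqi_total"].iloc[0]
            for name in base:
                better = dict(base)
                if name == "gi":
                    better[name] = base[name] - rng.uniform(0, 30)
                else:
                    better[name] = base[name] + rng.uniform(0, 20)
                t1 = score_cqi_frame(pd.DataFrame([better]), cuts)["cqi_total"].iloc[0]
                assert t1 >= t0


class TestCarbQuantity:
    def _profile(self, carb, energy):
        return DietProfile(participant_id="p", carb_g_d=carb, energy_kcal_d=energy)

    def test_band_arithmetic(self):
        assert carb_quantity(self._profile(250, 2000)).carb_energy_pct == pytest.approx(50.0)
        assert carb_quantity(self._profile(250, 2000)).category == "ge50"
        assert carb_quantity(self._profile(200, 2000)).category == "le40"  # 40 % inclusive
        assert carb_quantity(self._profile(225, 2000)).category == "mid"

    def test_zero_energy_rejected(self):
        with pytest.raises(ValueError):
            carb_quantity(self._profile(0, 0))


class TestMedDietScore:
    MEDIANS = {
        "vegetables": 2.0, "legumes": 0.5, "fruit_nuts": 2.0, "fish": 0.5,
        "mufa_sfa_ratio": 1.2, "meat": 1.0, "dairy": 2.0,
    }

    def _profile(self, veg, leg, fruit, fish, mufa, sfa, meat, dairy):
        return DietProfile(
            participant_id="p",
            mufa_g_d=mufa,
            sfa_g_d=sfa,
            per_group_servings_d={
                "vegetables": veg, "legumes": leg, "fruit_nuts": fruit,
                "fish": fish, "meat": meat, "dairy": dairy,
            },
        )

    # ten hand-scored participants against the fixed medians
    CASES = [
        ((3, 1, 2, 1, 12, 8, 0.5, 1), 7),    # full adherence
        ((1, 0, 1, 0, 5, 10, 2, 3), 0),      # mirror image
        ((2, 0.5, 1, 0.5, 9, 9, 1, 2), 3),
        ((0, 2, 3, 0, 6, 4, 0, 0), 5),
        ((2, 0, 0, 2, 0, 0, 1, 2), 2),       # undefined MUFA:SFA, no MUFA
        ((5, 1, 5, 1, 10, 2, 3, 5), 5),
        ((1.9, 0.4, 1.9, 0.4, 11.9, 10, 0.9, 1.9), 2),
        ((2, 0.5, 2, 0.5, 12, 10, 1, 2), 5), # everything exactly at median
        ((4, 0, 2, 0, 3, 0, 0, 10), 4),      # undefined ratio, MUFA present
        ((0, 5, 0, 5, 0, 5, 5, 0), 3),
    ]

    @pytest.mark.parametrize("values,expected", CASES)
    def test_hand_scored_population(self, values, expected):
        score = med_diet_score(self._profile(*values), self.MEDIANS)
        assert score.points == expected

    def test_categories(self):
        assert med_diet_score(self._profile(*self.CASES[1][0]), self.MEDIANS).category == "low"
        assert med_diet_score(self._profile(*self.CASES[0][0]), self.MEDIANS).category == "high"

    def test_missing_medians_rejected(self):
        with pytest.raises(ValueError, match="fish"):
            med_diet_score(
                self._profile(*self.CASES[0][0]),
                {k: v for k, v in self.MEDIANS.items() if k != "fish"},
            )
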