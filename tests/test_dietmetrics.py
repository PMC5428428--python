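import numpy as np
import pandas as pd
import pytest

from glyhome import dietmetrics as dm
from glyhome.errors import LookupFoodError, UndefinedGIError
from glyhome.fooddb import FoodEntry, FoodTable


@pytest.fixture(scope="module")
def toy_db():
    return FoodTable(
        [
            FoodEntry("hi", "high-GI food", 50.0, 1.0, True, 200, 5, 1, gi=80),
            FoodEntry("lo", "low-GI food", 50.0, 2.0, True, 200, 5, 1, gi=40),
            FoodEntry("r72", "rice", 25.0, 0.5, True, 115, 2, 0.3, gi=72),
            FoodEntry("meat", "meat", 4.0, 0.0, False, 250, 20, 18),  # zero rule
        ]
    )


def _recalls(rows):
    return pd.DataFrame(rows, columns=["participant_id", "day_index", "food_id", "grams"])


class TestDailyGlGi:
    def test_single_food_gl_is_cho_times_gi(self, toy_db):
        # 200 g of rice -> 50 g CHO at GI 72 -> GL 36
        day = _recalls([("p1", 1, "r72", 200.0)])
        gl, gi, cho = dm.daily_gl_gi(day, toy_db)
        assert (gl, gi, cho) == (pytest.approx(36.0), pytest.approx(72.0), pytest.approx(50.0))

    def test_two_foods_gi_is_cho_weighted(self, toy_db):
        day = _recalls([("p1", 1, "hi", 100.0), ("p1", 1, "lo", 100.0)])
        gl, gi, _ = dm.daily_gl_gi(day, toy_db)
        assert gl == pytest.approx(60.0)
        assert gi == pytest.approx(60.0)

    def test_zero_rule_food_contributes_cho_but_no_load(self, toy_db):
        gl, gi, cho = dm.daily_gl_gi(_recalls([("p1", 1, "meat", 100.0)]), toy_db)
        assert (gl, gi, cho) == (0.0, 0.0, pytest.approx(4.0))

    def test_gl_additive_over_foods(self, toy_db):
        day = _recalls([("p1", 1, "hi", 80.0), ("p1", 1, "lo", 120.0), ("p1", 1, "r72", 60.0)])
        gl, _, _ = dm.daily_gl_gi(day, toy_db)
        parts = [dm.daily_gl_gi(day.iloc[[i]], toy_db)[0] for i in range(3)]
        assert gl == pytest.approx(sum(parts))

    def test_unknown_food_raises_lookup_error(self, toy_db):
        with pytest.raises(LookupFoodError, match="nope"):
            dm.daily_gl_gi(_recalls([("p1", 1, "nope", 10.0)]), toy_db)


class TestSummarize:
    def test_identical_days_equal_single_day(self, toy_db):
        one = _recalls([("p1", 1, "hi", 100.0), ("p1", 1, "meat", 50.0)])
        three = pd.concat(
            [one.assign(day_index=d) for d in (1, 2, 3)], ignore_index=True
        )
        s1 = dm.summarize_participant(one, toy_db)
        s3 = dm.summarize_participant(three, toy_db)
        assert s3["n_recalls"] == 3
        for col in ("energy_kcal_d", "gl_g_d", "gi", "cereal_fiber_g_d"):
            assert s3[col] == pytest.approx(s1[col])

    def test_mean_over_days_is_unweighted(self, toy_db):
        recs = _recalls([("p1", 1, "hi", 60.0), ("p1", 2, "hi", 100.0)])  # GL 24 and 40
        s = dm.summarize_participant(recs, toy_db)
        assert s["gl_g_d"] == pytest.approx(32.0)
        assert s["n_recalls"] == 2

    def test_dietary_gi_within_range_of_consumed_foods(self, small_cohort):
        diet = dm.summarize_cohort(small_cohort.recalls, small_cohort.catalog)
        comp = small_cohort.catalog.composition_frame()
        assert (diet["gi"] >= 0).all()
        assert (diet["gi"] <= comp["gi"].max() + 1e-9).all()

    def test_cereal_fiber_never_exceeds_total_fiber(self, small_cohort):
        diet = dm.summarize_cohort(small_cohort.recalls, small_cohort.catalog)
        assert (diet["cereal_fiber_g_d"] <= diet["fiber_g_d"] + 1e-9).all()

    def test_empty_participant_rejected(self, toy_db):
        with pytest.raises(ValueError, match="no recall"):
            dm.summarize_participant(_recalls([]), toy_db)

    def test_cereal_fiber_zero_without_cereal_foods(self, toy_db):
        s = dm.summarize_participant(_recalls([("p1", 1, "meat", 150.0)]), toy_db)
        assert s["cereal_fiber_g_d"] == 0.0


class TestPlausibilityFilter:
    @pytest.mark.parametrize(
        "sex,energy,kept",
        [
            ("male", 700.0, False),
            ("male", 800.0, True),     # boundary inclusive
            ("male", 4200.0, True),
            ("male", 4201.0, False),
            ("female", 3400.0, True),
            ("female", 3501.0, False),
            ("female", 500.0, True),
        ],
    )
    def test_boundaries(self, sex, energy, kept):
        summaries = pd.DataFrame({"energy_kcal_d": [energy]}, index=["p1"])
        retained, excluded = dm.plausibility_filter(summaries, pd.Series({"p1": sex}))
        assert ("p1" in retained.index) is kept
        if not kept:
            assert "energy" in excluded.loc["p1", "exclusion_reason"]

    def test_unknown_sex_is_an_error(self):
        summaries = pd.DataFrame({"energy_kcal_d": [2000.0]}, index=["p1"])
        with pytest.raises(ValueError, match="p1"):
            dm.plausibility_filter(summaries, pd.Series({"p1": "unknown"}))


class TestEnergyResiduals:
    def test_perfectly_linear_value_gives_zero_residuals(self):
        energy = pd.Series(np.linspace(1000, 3000, 40))
        value = 3.0 + 0.01 * energy
        sex = pd.Series(["male"] * 40)
        res = dm.energy_residuals(value, energy, sex)
        assert np.allclose(res, 0.0, atol=1e-9)

    def test_residuals_orthogonal_to_energy_within_sex(self, small_analysis):
        for s in ("male", "female"):
            sub = small_analysis[small_analysis["sex"] == s]
            assert abs(np.corrcoef(sub["gi_resid"], sub["energy_kcal_d"])[0, 1]) < 1e-8
            assert abs(sub["gi_resid"].mean()) < 1e-8 * sub["gi"].abs().mean()

    def test_constant_energy_falls_back_to_centering(self):
        energy = pd.Series([2000.0] * 10)
        value = pd.Series(np.arange(10, dtype=float))
        with pytest.warns(UserWarning, match="zero energy variance"):
            res = dm.energy_residuals(value, energy, pd.Series(["female"] * 10))
        assert np.allclose(res, value - value.mean())

    def test_noise_scale_recovered(self):
        # value = 2*energy + N(0, 1): residual SD should be ~1
        rng = np.random.default_rng(42)
        energy = pd.Series(rng.uniform(1200, 2800, 1000))
        value = 2.0 * energy + rng.normal(0, 1.0, 1000)
        res = dm.energy_residuals(value, energy, pd.Series(["male"] * 1000))
        assert res.std() == pytest.approx(1.0, rel=0.1)

    def test_ranking_preserved_at_equal_energy(self):
        energy = pd.Series([1500.0, 1500.0, 2500.0, 2500.0, 2000.0, 2000.0])
        value = pd.Series([60.0, 70.0, 55.0, 75.0, 62.0, 68.0])
        res = dm.energy_residuals(value, energy, pd.Series(["male"] * 6))
        assert res[1] > res[0] and res[3] > res[2] and res[5] > res[4]


class TestTertiles:
    def test_one_to_nine_splits_evenly(self):
        t = dm.assign_tertiles(pd.Series(range(1, 10), dtype=float))
        assert t.value_counts().to_dict() == {1: 3, 2: 3, 3: 3}

    def test_all_equal_goes_to_tertile_one_with_warning(self):
        with pytest.warns(UserWarning, match="equal"):
            t = dm.assign_tertiles(pd.Series([5.0] * 9))
        assert (t == 1).all()

    def test_tie_at_cut_goes_to_lower_tertile(self):
        values = pd.Series([1.0, 2.0, 2.0, 2.0, 3.0, 4.0])
        t = dm.assign_tertiles(values)
        assert (t[values == 2.0] <= 2).all()

    def test_default_cohort_tertiles_balanced(self, small_analysis):
        counts = small_analysis["gi_tertile"].value_counts()
        assert counts.max() - counts.min() <= 2


class TestFFQ:
    def test_single_item(self):
        gi, gl = dm.ffq_gi_gl([(2.0, 25.0, 70.0)])
        assert (gi, gl) == (pytest.approx(70.0), pytest.approx(35.0))

    def test_equal_cho_items_average_gi(self):
        gi, _ = dm.ffq_gi_gl([(1.0, 30.0, 40.0), (1.0, 30.0, 80.0)])
        assert gi == pytest.approx(60.0)

    def test_zero_servings_undefined(self):
        with pytest.raises(UndefinedGIError):
            dm.ffq_gi_gl([(0.0, 25.0, 70.0)])
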