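import numpy as np
import pandas as pd
import pytest

from glyhome import assocmodels as am
from glyhome.assocmodels import ModelResult, ModelSpec
from glyhome.dietmetrics import assign_tertiles
from glyhome.errors import ConsistencyError, DegenerateModifierError, GlyhomeError


def toy_frame(n=600, seed=0, beta=0.0, binary=False):
    """Cohort-like table with known outcome structure for model tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "age_y": rng.normal(46, 14, n),
            "female": rng.integers(0, 2, n).astype(float),
            "current_smoker": rng.integers(0, 2, n).astype(float),
            "activity_met_h_wk": rng.gamma(2, 7, n),
            "high_education": rng.integers(0, 2, n).astype(float),
            "cereal_fiber_resid": rng.normal(0, 2, n),
            "protein_resid": rng.normal(0, 5, n),
            "bf_pct": rng.normal(23, 4, n),
            "grs_weighted": rng.normal(0.8, 0.08, n),
            "gi_resid": rng.normal(0, 7, n),
        }
    )
    df["gi_tertile"] = assign_tertiles(df["gi_resid"])
    lp = beta * df["gi_resid"]
    if binary:
        p = 1 / (1 + np.exp(-(-0.3 + lp)))
        df["prediabetes"] = rng.binomial(1, p).astype(float)
    else:
        df["y"] = np.exp(np.log(5.3) + lp + rng.normal(0, 0.1, n))
    return df


class TestAdjustedMeans:
    def test_covariate_free_ls_means_equal_geometric_means(self):
        """Oracle: with no covariates the LS means are stratified geometric means."""
        df = toy_frame(seed=1, beta=0.005)
        spec = ModelSpec(outcome="y", tier=0, adjust_grs=False)
        res = am.fit_adjusted_means(df, spec)
        for t in (1, 2, 3):
            oracle = np.exp(np.log(df.loc[df.gi_tertile == t, "y"]).mean())
            assert abs(res.estimates.loc[t, "mean"] - oracle) < 1e-8

    def test_constant_outcome_gives_equal_means_and_null_trend(self):
        df = toy_frame(seed=2)
        df["y"] = 4.2
        res = am.fit_adjusted_means(df, ModelSpec(outcome="y", tier=0, adjust_grs=False))
        assert np.allclose(res.estimates["mean"], 4.2)
        assert res.p_trend == pytest.approx(1.0)

    def test_back_transformed_means_invariant_to_covariate_shift(self):
        df = toy_frame(seed=3, beta=0.004)
        res1 = am.fit_adjusted_means(df, ModelSpec(outcome="y", tier=3))
        shifted = df.assign(age_y=df.age_y + 25, protein_resid=df.protein_resid + 100)
        res2 = am.fit_adjusted_means(shifted, ModelSpec(outcome="y", tier=3))
        assert np.allclose(res1.estimates["mean"], res2.estimates["mean"], atol=1e-8)

    def test_cis_contain_their_point_estimates(self):
        df = toy_frame(seed=4, beta=0.005)
        res = am.fit_adjusted_means(df, ModelSpec(outcome="y", tier=3))
        est = res.estimates
        assert (est["ci_low"] <= est["mean"]).all() and (est["mean"] <= est["ci_high"]).all()

    def test_rank_deficient_design_names_collinear_column(self):
        df = toy_frame(seed=5)
        df["protein_resid"] = df["cereal_fiber_resid"]  # exact collinearity
        with pytest.raises(GlyhomeError, match="collinear"):
            am.fit_adjusted_means(df, ModelSpec(outcome="y", tier=3))


class TestTrend:
    def test_perfect_linear_outcome_recovers_slope_one(self):
        df = toy_frame(seed=6)
        df["y"] = np.exp(df["gi_resid"])  # log-outcome == exposure
        res = am.trend_test(df, ModelSpec(outcome="y", tier=0, adjust_grs=False))
        assert res.slope == pytest.approx(1.0, abs=1e-10)
        assert res.p_value < 1e-100

    def test_type_i_error_near_nominal(self):
        """Null rejection rate of the adjusted trend test is ~5%."""
        reps, hits = 500, 0
        for i in range(reps):
            df = toy_frame(n=1000, seed=10_000 + i, beta=0.0)
            res = am.trend_test(df, ModelSpec(outcome="y", tier=1, adjust_grs=False))
            hits += res.p_value < 0.05
        rate = hits / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


class TestLogistic:
    def test_saturated_or_equals_cross_product_ratio(self):
        """Tertile ORs from the saturated logistic equal closed-form 2x2 ratios.

        Group sizes and case counts reconstruct a published pre-diabetes
        prevalence gradient (474/1306, 524/1307, 615/1305).
        """
        counts = {1: (474, 1306), 2: (524, 1307), 3: (615, 1305)}
        rows = []
        for t, (cases, n) in counts.items():
            rows += [{"gi_tertile": t, "prediabetes": 1.0}] * cases
            rows += [{"gi_tertile": t, "prediabetes": 0.0}] * (n - cases)
        df = pd.DataFrame(rows)
        df["gi_resid"] = df["gi_tertile"].astype(float)  # only used by trend model
        res = am.fit_prediabetes_or(
            df, ModelSpec(outcome="prediabetes", tier=0, adjust_grs=False, log_transform=False)
        )
        or3 = (615 * (1306 - 474)) / (474 * (1305 - 615))
        assert res.estimates.loc[3, "odds_ratio"] == pytest.approx(or3, abs=1e-3)
        assert res.estimates.loc[1, "odds_ratio"] == 1.0

    def test_null_or_ci_covers_one_at_nominal_rate(self):
        reps, covered = 250, 0
        for i in range(reps):
            df = toy_frame(n=500, seed=20_000 + i, beta=0.0, binary=True)
            res = am.fit_prediabetes_or(
                df, ModelSpec(outcome="prediabetes", tier=1, adjust_grs=False)
            )
            e = res.estimates.loc[3]
            covered += e["ci_low"] <= 1.0 <= e["ci_high"]
        rate = covered / reps
        assert abs(rate - 0.95) < 3 * np.sqrt(0.95 * 0.05 / reps) + 0.01


class TestInteraction:
    def test_type_i_error_near_ten_percent_threshold(self):
        """Null interaction rejection at p<0.1 is ~10%."""
        reps, hits = 500, 0
        for i in range(reps):
            df = toy_frame(n=600, seed=30_000 + i, beta=0.004)
            res = am.interaction_scan(
                df, ModelSpec(outcome="y", tier=1, adjust_grs=False), "grs_weighted"
            )
            hits += res.p_value < 0.1
        rate = hits / reps
        assert abs(rate - 0.10) < 3 * np.sqrt(0.10 * 0.90 / reps)

    def test_constant_modifier_rejected(self):
        df = toy_frame(seed=8)
        df["grs_weighted"] = 0.8
        with pytest.raises(DegenerateModifierError, match="grs_weighted"):
            am.interaction_scan(df, ModelSpec(outcome="y", tier=1, adjust_grs=False), "grs_weighted")

    def test_nonzero_interaction_detected_with_power(self):
        hits = 0
        for i in range(20):
            rng = np.random.default_rng(90_000 + i)  # independent of toy_frame's stream
            df = toy_frame(n=3000, seed=40_000 + i)
            z = rng.standard_normal(len(df))
            df["grs_weighted"] = 0.8 + 0.08 * z
            df["y"] = np.exp(
                np.log(5.3) + 0.004 * df.gi_resid + 0.0015 * df.gi_resid * z
                + rng.normal(0, 0.25, len(df))
            )
            res = am.interaction_scan(
                df, ModelSpec(outcome="y", tier=1, adjust_grs=False), "grs_weighted"
            )
            hits += res.p_value < 0.1
        assert hits >= 14  # >=70% power at this effect size


class TestCrossClassify:
    def test_constant_outcome_gives_flat_adjusted_means(self):
        df = toy_frame(seed=9)
        df["modifier_tertile"] = assign_tertiles(df["grs_weighted"])
        df["y"] = 3.3
        res = am.cross_classify(df, "gi_tertile", "modifier_tertile", "y", tier=1)
        assert np.allclose(res.estimate.to_numpy(), 3.3)
        assert res.n.to_numpy().sum() == len(df)

    def test_reference_cell_or_is_exactly_one(self, medium_analysis):
        res = am.cross_classify(
            medium_analysis, "gi_tertile", "grs_tertile", "prediabetes",
            tier=3, log_transform=False, reference=(1, 1),
        )
        assert res.estimate.loc[1, 1] == 1.0
        assert res.kind == "odds_ratio"
        assert res.n.to_numpy().sum() == len(medium_analysis)

    def test_empty_cell_raises_with_cell_name(self):
        df = toy_frame(seed=10)
        df["modifier_tertile"] = df["gi_tertile"]  # perfectly dependent -> empty off-diagonals
        with pytest.raises(GlyhomeError, match="empty"):
            am.cross_classify(df, "gi_tertile", "modifier_tertile", "y", tier=1)


class TestEnergyPartition:
    @staticmethod
    def _partition_frame(seed=0, effect=0.0004):
        rng = np.random.default_rng(seed)
        df = toy_frame(n=2000, seed=seed)
        df["high_gi_kcal"] = rng.gamma(3, 120, len(df))
        df["low_gi_kcal"] = rng.gamma(3, 100, len(df))
        df["energy_kcal_d"] = df["high_gi_kcal"] + df["low_gi_kcal"] + rng.gamma(5, 150, len(df))
        df["y"] = np.exp(np.log(5.3) + effect * df["high_gi_kcal"] + rng.normal(0, 0.15, len(df)))
        return df

    def test_recovers_source_specific_effect(self):
        df = self._partition_frame(seed=21, effect=0.0004)
        out = am.energy_partition_fit(
            df, ["high_gi_kcal", "low_gi_kcal"], "energy_kcal_d", "y", tier=1
        )
        high = out.loc["high_gi_kcal"]
        assert abs(high["coefficient"] - 0.0004) < 2 * high["se"]
        assert high["p_value"] < 1e-6
        assert abs(out.loc["low_gi_kcal", "coefficient"]) < 3 * out.loc["low_gi_kcal", "se"]

    def test_null_components_give_null_coefficients(self):
        df = self._partition_frame(seed=22, effect=0.0)
        out = am.energy_partition_fit(
            df, ["high_gi_kcal", "low_gi_kcal"], "energy_kcal_d", "y", tier=1
        )
        assert (out["p_value"] > 0.001).all()

    def test_components_exceeding_total_rejected(self):
        df = self._partition_frame(seed=23)
        df["energy_kcal_d"] = df["high_gi_kcal"] * 0.5
        with pytest.raises(ConsistencyError):
            am.energy_partition_fit(
                df, ["high_gi_kcal", "low_gi_kcal"], "energy_kcal_d", "y", tier=1
            )


class TestPercentContrast:
    @staticmethod
    def _result(means):
        est = pd.DataFrame(
            {"tertile": [1, 2, 3], "mean": means,
             "ci_low": means, "ci_high": means, "n": [10, 10, 10]}
        ).set_index("tertile")
        return ModelResult(outcome="y", exposure="gi", tier=3, estimates=est,
                           p_trend=0.5, trend_slope=0.0)

    @pytest.mark.parametrize(
        "means,expected",
        [
            ([5.19, 5.39, 5.67], pytest.approx(9.2485, abs=1e-3)),
            ([4.0, 4.0, 4.0], pytest.approx(0.0)),
            ([1.09, 1.2, 1.40], pytest.approx(28.440, abs=1e-2)),
        ],
    )
    def test_printed_arithmetic(self, means, expected):
        assert am.percent_contrast(self._result(means)) == expected

    def test_nonpositive_baseline_undefined(self):
        with pytest.raises(ValueError):
            am.percent_contrast(self._result([0.0, 1.0, 2.0]))
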