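"""GEE estimation: oracles, invariants, table-shaped analyses."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from carbquality.estimation import (
    ModelSpec,
    component_tertile_analysis,
    cut_tertiles,
    fit_gee,
    joint_quality_quantity,
    per_increment_or,
    sensitivity_runner,
    trend_test,
)
from carbquality.synthetic_data import SimulationConfig, simulate_analysis_dataset

SINGLE_PREG = SimulationConfig(
    n_women=500, pregnancy_count_probs=(1.0, 0.0, 0.0), woman_random_effect_sd=0.0
)


@pytest.fixture(scope="module")
def single_pregnancy_df():
    return simulate_analysis_dataset(SINGLE_PREG, 101)


@pytest.fixture(scope="module")
def clustered_df():
    return simulate_analysis_dataset(SimulationConfig(n_women=3000), 202)


class TestGEEFitOracles:
    def test_independence_equals_logistic_mle(self, single_pregnancy_df):
        """With one observation per cluster the estimating equations reduce
        to the ordinary logistic score equations."""
        spec = ModelSpec(
            exposure="cqi_category",
            adjustment="model1",
            correlation_structure="independence",
        )
        fit = fit_gee(single_pregnancy_df, spec)
        glm = sm.GLM.from_formula(
            "gdm ~ C(cqi_category, levels=['low', 'mid', 'high'])"
            " + age_first_pregnancy + bmi",
            data=single_pregnancy_df.assign(gdm=single_pregnancy_df.gdm.astype(int)),
            family=sm.families.Binomial(),
        ).fit()
        gee_params = fit.result.params
        assert np.max(np.abs(gee_params.to_numpy() - glm.params.to_numpy())) < 1e-6

    def test_crude_or_equals_cross_product_ratio(self, single_pregnancy_df):
        df = single_pregnancy_df.copy()
        df["high_fiber"] = (df["fiber_g_d"] > df["fiber_g_d"].median()).astype(int)
        fit = fit_gee(
            df,
            ModelSpec(
                exposure="C(high_fiber)",
                adjustment="crude",
                correlation_structure="independence",
            ),
        )
        tab = pd.crosstab(df["high_fiber"], df["gdm"])
        a, b = tab.loc[1, 1], tab.loc[1, 0]
        c, d = tab.loc[0, 1], tab.loc[0, 0]
        assert fit.params["or"].iloc[0] == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_separation_warning_on_zero_event_arm(self, single_pregnancy_df):
        df = single_pregnancy_df.copy()
        df["arm"] = (df.index % 2).astype(int)
        df.loc[df["arm"] == 1, "gdm"] = 0
        with pytest.warns(UserWarning, match="separation"):
            fit_gee(
                df,
                ModelSpec(exposure="C(arm)", adjustment="crude",
                          correlation_structure="independence"),
            )

    def test_two_cluster_minimum(self, single_pregnancy_df):
        df = single_pregnancy_df.head(3).copy()
        df["woman_id"] = 0
        with pytest.raises(ValueError, match="two clusters"):
            fit_gee(df, ModelSpec(exposure="cqi_per2", adjustment="crude"))


class TestGEEInvariants:
    def test_exchangeable_matches_independence_without_clustering(self):
        cfg = SimulationConfig(n_women=3000, woman_random_effect_sd=0.0)
        df = simulate_analysis_dataset(cfg, 33)
        fits = {
            cs: fit_gee(
                df,
                ModelSpec(exposure="cqi_category", adjustment="model1",
                          correlation_structure=cs),
            )
            for cs in ("exchangeable", "independence")
        }
        delta = np.abs(
            fits["exchangeable"].result.params.to_numpy()
            - fits["independence"].result.params.to_numpy()
        )
        # the estimated exchangeable correlation is O(1/sqrt(n)) noise, so
        # coefficients agree closely but not to solver tolerance
        assert delta.max() < 0.02
        assert abs(fits["exchangeable"].working_correlation) < 0.02

    def test_null_covariate_leaves_exposure_or_unchanged(self, clustered_df):
        rng = np.random.default_rng(8)
        df = clustered_df.copy()
        df["noise_cov"] = rng.standard_normal(len(df))
        spec = ModelSpec(exposure="cqi_category", adjustment="model1",
                         correlation_structure="independence")
        base = fit_gee(df, spec)
        plus = fit_gee(
            df,
            ModelSpec(exposure="cqi_category", adjustment="model1",
                      correlation_structure="independence",
                      extra_terms=("noise_cov",)),
        )
        assert abs(base.params.loc["high", "coef"] - plus.params.loc["high", "coef"]) < 0.01

    def test_or_and_ci_structure(self, clustered_df):
        fit = fit_gee(
            clustered_df,
            ModelSpec(exposure="cqi_category", adjustment="model1",
                      correlation_structure="exchangeable"),
        )
        p = fit.params
        assert (p["or"] > 0).all()
        assert (p["ci_low"] < p["or"]).all() and (p["or"] < p["ci_high"]).all()
        assert np.allclose(p["or"], np.exp(p["coef"]))
        assert np.allclose(p["ci_high"], np.exp(p["coef"] + 1.96 * p["robust_se"]))
        assert fit.converged
        assert fit.n_clusters == clustered_df["woman_id"].nunique()


class TestTrendAndIncrement:
    def test_trend_sign_matches_seeded_direction(self, clustered_df):
        tt = trend_test(
            clustered_df,
            ModelSpec(adjustment="model1", correlation_structure="independence"),
        )
        assert tt.slope < 0  # protective seeded effect
        assert 0 <= tt.pvalue <= 1

    def test_trend_rejects_degenerate_categories(self, clustered_df):
        df = clustered_df.copy()
        df["cqi_category"] = "mid"
        with pytest.raises(ValueError, match="no members"):
            trend_test(df, ModelSpec(adjustment="crude"))

    def test_per_increment_log_linearity(self, single_pregnancy_df):
        spec = ModelSpec(adjustment="crude", correlation_structure="independence")
        or1 = per_increment_or(single_pregnancy_df, increment=1, spec=spec)
        or2 = per_increment_or(single_pregnancy_df, increment=2, spec=spec)
        assert or2.params["or"].iloc[0] == pytest.approx(
            or1.params["or"].iloc[0] ** 2, rel=1e-6
        )

    def test_zero_variance_rejected(self, single_pregnancy_df):
        df = single_pregnancy_df.copy()
        df["cqi_total"] = 12
        with pytest.raises(ValueError, match="variance"):
            per_increment_or(df, spec=ModelSpec(adjustment="crude"))


class TestComponentTertiles:
    def test_tertile_cutting_exact_thirds(self):
        labels = cut_tertiles(pd.Series(np.arange(1.0, 10.0)))
        assert labels.tolist() == ["T1"] * 3 + ["T2"] * 3 + ["T3"] * 3

    def test_constant_component_rejected(self):
        with pytest.raises(ValueError, match="tertiles"):
            cut_tertiles(pd.Series(np.ones(30)))

    def test_component_models_fit_and_adjust(self, clustered_df):
        fits = component_tertile_analysis(
            clustered_df,
            components=("gi", "fiber_g_d"),
            adjustments=("model1", "model4_components"),
            spec=ModelSpec(correlation_structure="independence"),
        )
        assert set(fits) == {
            ("gi", "model1"), ("gi", "model4_components"),
            ("fiber_g_d", "model1"), ("fiber_g_d", "model4_components"),
        }
        for fit in fits.values():
            assert set(fit.params.index) == {"T2", "T3"}
            assert fit.reference_level == "T1"
        # model 4 includes the other components as covariates
        m4 = fits[("gi", "model4_components")]
        assert "fiber_g_d" in m4.result.params.index


class TestJointAnalysis:
    def test_reference_cell_is_unity(self, clustered_df):
        joint = joint_quality_quantity(
            clustered_df,
            ModelSpec(adjustment="model1", correlation_structure="independence"),
        )
        assert joint.or_table.loc["low", "le40"] == 1.0
        assert "low|le40" not in joint.fit.params.index
        assert 0 <= joint.interaction_pvalue <= 1
        assert joint.interaction_df == 1
        assert joint.cell_counts.to_numpy().sum() == len(
            clustered_df.dropna(subset=["cqi_category", "carb_quantity"])
        )

    def test_empty_cell_warned_and_dropped(self, clustered_df):
        df = clustered_df[
            ~((clustered_df.cqi_category == "high") & (clustered_df.carb_quantity == "le40"))
        ]
        with pytest.warns(UserWarning, match="empty joint cells"):
            joint = joint_quality_quantity(
                df, ModelSpec(adjustment="crude", correlation_structure="independence")
            )
        assert np.isnan(joint.or_table.loc["high", "le40"])

    def test_joint_4df_variant(self, clustered_df):
        joint = joint_quality_quantity(
            clustered_df,
            ModelSpec(adjustment="crude", correlation_structure="independence"),
            interaction="joint",
        )
        assert joint.interaction_df == 4


class TestSensitivityRunner:
    def test_first_pregnancy_only_is_noop_on_single_pregnancy_data(
        self, single_pregnancy_df
    ):
        spec = ModelSpec(exposure="cqi_category", adjustment="model1",
                         correlation_structure="independence")
        table = sensitivity_runner(single_pregnancy_df, ["first-pregnancy-only"], spec)
        main = table[table.scenario == "main"].set_index("exposure_level")
        sub = table[table.scenario == "first-pregnancy-only"].set_index("exposure_level")
        assert np.allclose(main["coef"], sub["coef"])

    def test_unknown_scenario_rejected(self, single_pregnancy_df):
        with pytest.raises(ValueError, match="unknown sensitivity"):
            sensitivity_runner(single_pregnancy_df, ["left-handed-only"])

    def test_empty_scenario_list_gives_main_only(self, single_pregnancy_df):
        spec = ModelSpec(exposure="cqi_category", adjustment="crude",
                         correlation_structure="independence")
        table = sensitivity_runner(single_pregnancy_df, [], spec)
        assert set(table.scenario) == {"main"}

    def test_age_swap_scenarios_run(self, clustered_df):
        spec = ModelSpec(exposure="cqi_category", adjustment="model1",
                         correlation_structure="independence")
        table = sensitivity_runner(
            clustered_df, ["age-at-entry", "both-ages", "nulliparous"], spec
        )
        assert set(table.scenario) == {"main", "age-at-entry", "both-ages", "nulliparous"}
        # restriction reduces the fitted sample
        assert (
            table[table.scenario == "nulliparous"]["n_obs"].iloc[0]
            < table[table.scenario == "main"]["n_obs"].iloc[0]
        )
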