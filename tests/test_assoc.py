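"""Association models: closed-form logistic recovery, exact Mann-Whitney
AUC, likelihood-ratio tests, stratified tables and survival descriptives."""

import numpy as np
import pandas as pd
import pytest

from agestrat_prs.assoc import (
    AssociationResult,
    ModelSpec,
    StratumSpec,
    apoe_survival_tables,
    build_analysis_frame,
    fit_glm,
    likelihood_ratio_test,
    mann_whitney_auc,
    parental_models,
    stratified_table,
)
from agestrat_prs.score import call_apoe_panel
from agestrat_prs.simulate import (
    SimulationConfig,
    attach_apoe,
    simulate_genotypes,
    simulate_parents,
)


def two_by_two_frame():
    """Exposed cases 30, exposed controls 10, unexposed cases 10,
    unexposed controls 30: odds ratio 9."""
    rows = ([(1, 1)] * 30 + [(1, 0)] * 10 + [(0, 1)] * 10 + [(0, 0)] * 30)
    return pd.DataFrame(rows, columns=["exposed", "status"])


def oracle_auc(score, y):
    """O(n²) concordance oracle: P(case outranks control), ties count half."""
    cases = score[y == 1]
    controls = score[y == 0]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
    return wins / (len(cases) * len(controls))


class TestFitGlm:
    def test_two_by_two_recovers_log_odds_ratio(self):
        fit = fit_glm(two_by_two_frame(),
                      ModelSpec(outcome="status", predictors=("exposed",)))
        assert fit.beta("exposed") == pytest.approx(np.log(9), abs=1e-6)

    def test_missing_rows_dropped_and_counted(self):
        frame = two_by_two_frame()
        frame.loc[:4, "exposed"] = np.nan
        fit = fit_glm(frame, ModelSpec(outcome="status", predictors=("exposed",)))
        assert fit.n_dropped == 5
        assert fit.n_obs == 75

    def test_degenerate_outcome_rejected(self):
        frame = two_by_two_frame().assign(status=1)
        with pytest.raises(ValueError, match="degenerate"):
            fit_glm(frame, ModelSpec(outcome="status", predictors=("exposed",)))

    def test_rank_deficient_design_rejected(self):
        frame = two_by_two_frame().assign(exposed_twice=lambda d: 2 * d["exposed"])
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_glm(frame, ModelSpec(outcome="status",
                                     predictors=("exposed", "exposed_twice")))

    def test_separated_predictor_raises(self):
        frame = pd.DataFrame({"status": [0] * 50 + [1] * 50,
                              "x": np.r_[np.zeros(50), np.ones(50)]})
        with pytest.raises((RuntimeError, ValueError)):
            fit_glm(frame, ModelSpec(outcome="status", predictors=("x",)))

    def test_family_outcome_mismatch_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ModelSpec(outcome="parental_count", family="binomial")
        with pytest.raises(ValueError, match="family"):
            ModelSpec(outcome="status", family="poisson")

    def test_zero_parental_events_clean_error(self):
        frame = pd.DataFrame({"parent_count": np.zeros(100),
                              "prs": np.random.default_rng(0).normal(size=100)})
        with pytest.raises(ValueError, match="zero events"):
            fit_glm(frame, ModelSpec(outcome="parental_count", predictors=("prs",),
                                     family="poisson"))


class TestAuc:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_quadratic_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = 300
        y = rng.integers(0, 2, n)
        score = rng.integers(0, 12, n).astype(float)  # many ties
        assert mann_whitney_auc(score, y) == pytest.approx(oracle_auc(score, y),
                                                           abs=1e-12)

    def test_perfect_and_null_separation(self):
        y = np.r_[np.zeros(50), np.ones(50)]
        assert mann_whitney_auc(np.r_[np.zeros(50), np.ones(50)], y) == 1.0
        assert mann_whitney_auc(np.zeros(100), y) == 0.5

    def test_binormal_closed_form(self):
        from scipy.stats import norm

        rng = np.random.default_rng(3)
        d = 1.0
        n = 20_000
        score = np.r_[rng.normal(0, 1, n), rng.normal(d, 1, n)]
        y = np.r_[np.zeros(n), np.ones(n)]
        assert mann_whitney_auc(score, y) == pytest.approx(norm.cdf(d / np.sqrt(2)),
                                                           abs=0.01)


class TestLrt:
    def test_identical_models_give_zero(self):
        fit = fit_glm(two_by_two_frame(),
                      ModelSpec(outcome="status", predictors=("exposed",)))
        stat, df, p = likelihood_ratio_test(fit, fit)
        assert stat == pytest.approx(0, abs=1e-10) and df == 0 and p == 1.0

    def test_strong_predictor_detected(self):
        frame = two_by_two_frame()
        full = fit_glm(frame, ModelSpec(outcome="status", predictors=("exposed",)))
        reduced = fit_glm(frame, ModelSpec(outcome="status", predictors=()))
        stat, df, p = likelihood_ratio_test(full, reduced)
        assert df == 1 and p < 1e-5

    def test_nonnested_predictors_rejected(self):
        frame = two_by_two_frame().assign(z=np.random.default_rng(1).normal(size=80))
        a = fit_glm(frame, ModelSpec(outcome="status", predictors=("exposed",)))
        b = fit_glm(frame, ModelSpec(outcome="status", predictors=("z",)))
        with pytest.raises(ValueError, match="subset"):
            likelihood_ratio_test(a, b)

    def test_fit_failure_detected(self):
        fit = fit_glm(two_by_two_frame(),
                      ModelSpec(outcome="status", predictors=("exposed",)))
        worse = AssociationResult(coefficients=fit.coefficients, llf=fit.llf + 5,
                                  auc=fit.auc, n_params=1, n_obs=fit.n_obs)
        with pytest.raises(ValueError, match="fit failure"):
            likelihood_ratio_test(fit, worse)


@pytest.fixture(scope="module")
def proxy_frame(tiny_config, apoe_panel, cohort):
    _, table, sumstats = cohort
    from agestrat_prs.score import adjust_and_standardize, compute_prs

    ids = [v for v in apoe_panel.variants["id"] if not v.startswith("rs")]
    raw = compute_prs(apoe_panel, sumstats, ids)
    scores = adjust_and_standardize(raw, table, ["pc1", "pc2"])
    return build_analysis_frame(table, scores, call_apoe_panel(apoe_panel))


class TestStratifiedTable:
    def test_emits_three_models_per_stratum(self, proxy_frame):
        table, fits = stratified_table(proxy_frame, ModelSpec())
        assert set(table["stratum"]) == {"all", "<80", ">=80"}
        assert set(table["model"]) == {"apoe", "prs", "joint"}
        assert {"beta", "se", "p", "auc", "lrt_p_joint_vs_apoe"} <= set(table.columns)

    def test_stratum_n_partition(self, proxy_frame):
        table, fits = stratified_table(proxy_frame, ModelSpec())
        n_all = fits[("all", "joint")].n_obs
        assert fits[("<80", "joint")].n_obs + fits[(">=80", "joint")].n_obs == n_all

    def test_cutoff_above_oldest_skips_stratum(self, proxy_frame):
        with pytest.warns(UserWarning, match="skipped"):
            table, fits = stratified_table(
                proxy_frame, ModelSpec(), StratumSpec(cutoff_years=200.0))
        assert ">=80" not in set(table["stratum"])

    def test_age_eighty_goes_to_upper_stratum(self, proxy_frame):
        frame = proxy_frame.copy()
        frame["age"] = 80.0
        with pytest.warns(UserWarning, match="skipped"):
            _, fits = stratified_table(frame, ModelSpec())
        assert ("<80", "joint") not in fits
        assert fits[(">=80", "joint")].n_obs == len(frame)


class TestParentalModels:
    def test_three_fits_with_expected_families(self, proxy_frame):
        fits = parental_models(proxy_frame)
        assert fits["parental_count"].spec.family == "poisson"
        assert fits["maternal"].spec.family == "binomial"
        assert fits["paternal"].spec.family == "binomial"

    def test_symmetric_simulation_gives_agreeing_parent_effects(self, proxy_frame):
        fits = parental_models(proxy_frame)
        bm, bp = fits["maternal"].beta("e4_dose"), fits["paternal"].beta("e4_dose")
        joint_se = np.hypot(fits["maternal"].se("e4_dose"), fits["paternal"].se("e4_dose"))
        assert abs(bm - bp) < 3 * joint_se

    def test_poisson_auc_uses_any_parent_binarization(self, proxy_frame):
        fit = fits = parental_models(proxy_frame)["parental_count"]
        assert 0.4 < fit.auc <= 1.0


class TestSurvivalTables:
    def test_proportions_normalize_within_columns(self, proxy_frame, apoe_panel):
        tables = apoe_survival_tables(proxy_frame, call_apoe_panel(apoe_panel))
        props = tables["proportions"].set_index("apoe_genotype")
        for col in props.columns:
            assert props[col].sum() == pytest.approx(1.0)

    def test_ages_table_has_all_strata(self, proxy_frame, apoe_panel):
        tables = apoe_survival_tables(proxy_frame, call_apoe_panel(apoe_panel))
        assert set(tables["ages"]["apoe_genotype"]) == {"e4/e4", "e3/e3", "e2/e2"}
        assert (tables["ages"]["n"] > 0).all()

    def test_no_homozygotes_rejected(self, proxy_frame, apoe_panel):
        calls = call_apoe_panel(apoe_panel)
        calls["diplotype"] = "e2/e3"
        with pytest.raises(ValueError, match="homozygous"):
            apoe_survival_tables(proxy_frame, calls)

    def test_missing_parent_columns_rejected(self, apoe_panel):
        frame = pd.DataFrame({"sample_id": apoe_panel.sample_ids})
        with pytest.raises(ValueError, match="parental-age"):
            apoe_survival_tables(frame, call_apoe_panel(apoe_panel))
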