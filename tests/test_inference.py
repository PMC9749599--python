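import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from hhnet.errors import ConvergenceError
from hhnet.inference import (
    average_marginal_effect,
    build_design,
    fit_multilevel_logistic,
    fit_weighted_logistic,
    run_model_grid,
)
from hhnet.simulate import GeneratorConfig, generate_cohort


def two_by_two(n11=10, n10=20, n01=5, n00=25, weights=None):
    """Units for a 2x2 table: exposed events/nonevents, unexposed ditto."""
    rows = []
    for exp_, y, n in [(1, 1, n11), (1, 0, n10), (0, 1, n01), (0, 0, n00)]:
        for i in range(n):
            rows.append(
                {
                    "defacto_diversity": exp_,
                    "outcome_introduced": y,
                    "weight": 1.0,
                    "cluster_id": f"c{i % 6}",
                }
            )
    df = pd.DataFrame(rows)
    if weights is not None:
        rng = np.random.default_rng(3)
        df["weight"] = rng.gamma(4, 0.25, len(df))
    return df


class TestWeightedLogistic:
    def test_contingency_table_odds_ratio(self):
        res = fit_weighted_logistic(two_by_two(), "defacto_diversity")
        # OR = (10/20) / (5/25) = 2.5
        assert res.params["defacto_diversity"] == pytest.approx(np.log(2.5), abs=1e-8)
        table = res.odds_ratios(["defacto_diversity"])
        assert table.loc["defacto_diversity", "or"] == pytest.approx(2.5, abs=1e-8)

    def test_equal_weights_match_unweighted(self):
        df = two_by_two()
        w = fit_weighted_logistic(df, "defacto_diversity", weighted=True)
        u = fit_weighted_logistic(df, "defacto_diversity", weighted=False)
        np.testing.assert_allclose(w.params, u.params, atol=1e-10)

    def test_or_ci_is_exp_of_beta_ci(self):
        res = fit_weighted_logistic(two_by_two(weights=True), "defacto_diversity")
        t = res.odds_ratios(["defacto_diversity"]).loc["defacto_diversity"]
        lo = np.exp(t["beta"] - 1.959963984540054 * t["se"])
        assert t["ci_low"] == pytest.approx(lo, rel=1e-12)
        assert t["ci_low"] < t["or"] < t["ci_high"]

    def test_single_class_outcome_errors(self):
        df = two_by_two()
        df["outcome_introduced"] = 1
        with pytest.raises(ConvergenceError):
            fit_weighted_logistic(df, "defacto_diversity")

    def test_zero_variance_exposure_errors(self):
        df = two_by_two()
        df["defacto_diversity"] = 0
        with pytest.raises(ConvergenceError):
            fit_weighted_logistic(df, "defacto_diversity")


class TestMarginalEffects:
    def test_saturated_binary_equals_weighted_risk_difference(self):
        df = two_by_two(weights=True)
        res = fit_weighted_logistic(df, "defacto_diversity")
        me = average_marginal_effect(res, "defacto_diversity")[0]
        w, x, y = df["weight"], df["defacto_diversity"], df["outcome_introduced"]
        rd = (
            np.average(y[x == 1], weights=w[x == 1])
            - np.average(y[x == 0], weights=w[x == 0])
        )
        assert me.me_pp == pytest.approx(100 * rd, abs=1e-10)
        assert me.kind == "discrete_change"

    def test_null_coefficient_gives_zero_me(self):
        df = two_by_two(10, 20, 10, 20)  # identical arms
        res = fit_weighted_logistic(df, "defacto_diversity")
        me = average_marginal_effect(res, "defacto_diversity")[0]
        assert me.me_pp == pytest.approx(0.0, abs=1e-8)

    def test_continuous_me_matches_statsmodels_margeff(self):
        rng = np.random.default_rng(9)
        n = 400
        df = pd.DataFrame(
            {
                "age_sd": rng.normal(10, 3, n),
                "mother_age": rng.normal(28, 6, n),
                "weight": np.ones(n),
                "cluster_id": "c0",
            }
        )
        eta = -1 + 0.08 * (df["age_sd"] - 10) + 0.02 * (df["mother_age"] - 28)
        df["outcome_introduced"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        X, y, _ = build_design(df, ["age_sd", "mother_age"], "outcome_introduced")
        sm_fit = sm.Logit(y, X).fit(disp=0)
        sm_me = sm_fit.get_margeff(at="overall")
        # run this package's delta method on the same fit so both the
        # point estimate and the SE are directly comparable
        from hhnet.inference import ModelResult

        res = ModelResult(
            params=pd.Series(sm_fit.params, index=X.columns),
            cov=pd.DataFrame(sm_fit.cov_params(), index=X.columns, columns=X.columns),
            X=X, y=y.to_numpy(), weights=np.ones(len(y)), n_used=len(y),
            converged=True, kind="glm", exposure="age_sd",
        )
        me = average_marginal_effect(res, "age_sd")[0]
        j = list(X.columns).index("age_sd") - 1  # margeff drops the constant
        assert me.me_pp == pytest.approx(100 * sm_me.margeff[j], abs=1e-6)
        assert me.se_pp == pytest.approx(100 * sm_me.margeff_se[j], rel=1e-4)


class TestMultilevelLogistic:
    def test_pinned_zero_variance_matches_pooled_glm(self, small_cohort):
        data = small_cohort.analysis
        pinned = fit_multilevel_logistic(data, "effective_size_band", fix_sigma=0.0)
        X, y, _ = build_design(data, ["effective_size_band"], "outcome_introduced")
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(pinned.params.to_numpy(), glm.params.to_numpy(), atol=1e-6)
        assert pinned.sigma2_round == 0.0

    def test_single_round_falls_back_with_warning(self, small_cohort):
        one = small_cohort.analysis.query("survey_round == '2011'")
        with pytest.warns(UserWarning, match="single survey round"):
            res = fit_multilevel_logistic(one, "effective_size_band")
        assert res.sigma2_round is None

    def test_matches_lme4_glmer_oracle(self, small_cohort, tmp_path):
        """Independent cross-check of the Gauss-Hermite ML fit against
        lme4::glmer with adaptive quadrature on the same data."""
        data = small_cohort.analysis
        res = fit_multilevel_logistic(data, "effective_size_band", n_quad=15)
        X, y, idx = build_design(data, ["effective_size_band"], "outcome_introduced")
        export = pd.DataFrame(
            {
                "y": y.astype(int),
                "x": X["effective_size_band[high]"].astype(int),
                "g": data.loc[idx, "survey_round"].astype(str),
            }
        )
        csv = tmp_path / "glmm.csv"
        export.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ x + (1 | g), data = d, family = binomial, nAGQ = 15)
            cat(fixef(m)[1], fixef(m)[2], as.numeric(VarCorr(m)$g[1]), sep = "\\n")
        """))
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        b0, b1, s2 = map(float, out.stdout.strip().splitlines())
        assert res.params["const"] == pytest.approx(b0, abs=2e-3)
        assert res.params["effective_size_band[high]"] == pytest.approx(b1, abs=2e-3)
        assert res.sigma2_round == pytest.approx(s2, abs=2e-2)


@pytest.fixture(scope="module")
def grid(small_cohort):
    return run_model_grid(
        small_cohort.analysis,
        exposures=["effective_size_band", "age_sd"],
        covariates=["mother_age", "residence"],
    )


class TestModelGrid:
    def test_shape_contract(self, grid):
        rounds = {"2000", "2005", "2011", "2016"}
        for exposure in ("effective_size_band", "age_sd"):
            sub = grid[grid["exposure"] == exposure]
            assert set(sub.loc[sub["model"] == "crude", "round"]) == rounds
            assert set(sub.loc[sub["model"] == "adjusted", "round"]) == rounds
            pooled = sub[sub["model"] == "pooled"]
            assert set(pooled["estimate_type"]) == {"OR", "ME_pp"}

    def test_deterministic(self, small_cohort, grid):
        again = run_model_grid(
            small_cohort.analysis,
            exposures=["effective_size_band", "age_sd"],
            covariates=["mother_age", "residence"],
        )
        pd.testing.assert_frame_equal(grid, again)

    def test_zero_variance_cell_flagged_but_grid_continues(self, small_cohort):
        data = small_cohort.analysis.copy()
        mask = data["survey_round"] == "2000"
        data.loc[mask, "defacto_diversity"] = 0
        grid = run_model_grid(data, exposures=["defacto_diversity"], covariates=[])
        cell = grid[(grid["round"] == "2000") & (grid["model"] == "crude")]
        assert not cell["converged"].iloc[0]
        others = grid[(grid["round"] == "2011") & (grid["model"] == "crude")]
        assert others["converged"].iloc[0]
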