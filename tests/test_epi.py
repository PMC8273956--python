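"""Survey generator, screening, stepwise logistic regression, comparison."""

import numpy as np
import pytest

from bnhybrid.core import CategoricalVariable, Dataset
from bnhybrid.epi import (
    chi2_screen,
    comparison_report,
    generate_survey,
    or_from_coef,
    proportion_ci,
    stepwise_logistic,
    trend_test,
)
from bnhybrid.errors import DegenerateError, SeparationError
from bnhybrid.inference import fit_mle
from bnhybrid.learn import learn_hybrid


def logistic_dataset(seed, n=2000, n_noise=5, beta=2.0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=(n, 1 + n_noise))
    eta = -1.0 + beta * x[:, 0]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    vs = [CategoricalVariable(f"x{i}", ("0", "1")) for i in range(1 + n_noise)]
    vs.append(CategoricalVariable("y", ("0", "1")))
    return Dataset(vs, np.column_stack([x, y]))


class TestGenerateSurvey:
    def test_shape_and_determinism(self):
        d = generate_survey(4567, seed=1)
        assert d.n == 4567 and len(d.variables) == 10
        again = generate_survey(4567, seed=1)
        assert (d.codes == again.codes).all()

    def test_outcome_rate_matches_published_cpt_at_large_n(self, lipid10):
        # empirical detection rate in the worked-example stratum
        d = generate_survey(500_000, seed=3)
        df = d.to_dataframe()
        sub = df[
            (df.PhysicalActivity == "Insufficient")
            & (df.Gender == "male")
            & (df.BMI == "28.0~")
        ]
        rate = (sub.Hyperlipidemia == "yes").mean()
        assert rate == pytest.approx(0.75273, abs=0.01)

    def test_generator_fidelity_full_outcome_cpt(self, lipid10):
        d = generate_survey(500_000, seed=4)
        refit = fit_mle(lipid10.graph, d)
        truth = lipid10.cpts["Hyperlipidemia"]
        fitted = refit.cpts["Hyperlipidemia"]
        # fitted parent order may differ; compare configuration-wise
        for cfg in truth.configurations():
            by_name = dict(zip(truth.parents, cfg))
            fitted_cfg = tuple(by_name[p] for p in fitted.parents)
            for level, p in truth.prob(cfg).items():
                assert fitted.prob(fitted_cfg)[level] == pytest.approx(p, abs=0.01)


class TestScreening:
    def test_hand_computed_chi_square(self):
        # all expected counts are 20 => chi2 = 4 * (10^2 / 20) = 20
        codes = np.array([[0, 0]] * 30 + [[0, 1]] * 10 + [[1, 0]] * 10 + [[1, 1]] * 30)
        vs = [CategoricalVariable("X", ("a", "b")), CategoricalVariable("Y", ("u", "v"))]
        d = Dataset(vs, codes)
        res = chi2_screen(d, "Y")
        assert res["X"]["chi2"] == pytest.approx(20.0)
        assert res["X"]["df"] == 1

    def test_independent_table_not_significant_but_candidate_rule(self):
        codes = np.array([[0, 0]] * 25 + [[0, 1]] * 25 + [[1, 0]] * 25 + [[1, 1]] * 25)
        vs = [CategoricalVariable("X", ("a", "b")), CategoricalVariable("Y", ("u", "v"))]
        d = Dataset(vs, codes)
        res = chi2_screen(d, "Y")
        assert res["X"]["chi2"] == pytest.approx(0.0)
        assert res["X"]["p"] == pytest.approx(1.0)
        assert not res["X"]["candidate"]  # p = 1 fails the p < 0.5 screen

    def test_constant_covariate_raises(self):
        vs = [CategoricalVariable("X", ("a", "b")), CategoricalVariable("Y", ("u", "v"))]
        d = Dataset(vs, np.column_stack([np.zeros(20, int), np.arange(20) % 2]))
        with pytest.raises(DegenerateError):
            chi2_screen(d, "Y")


class TestTrendTest:
    @staticmethod
    def _ordinal_dataset(props, per_level=100, reverse=False):
        rows = []
        levels = list(range(len(props)))
        if reverse:
            props = props[::-1]
        for lev, p in zip(levels, props):
            k = int(round(p * per_level))
            rows += [[lev, 1]] * k + [[lev, 0]] * (per_level - k)
        vs = [
            CategoricalVariable("G", tuple(f"g{i}" for i in levels)),
            CategoricalVariable("Y", ("0", "1")),
        ]
        return Dataset(vs, np.asarray(rows))

    def test_monotone_proportions_highly_significant(self):
        z, p = trend_test(self._ordinal_dataset([0.1, 0.5, 0.9]), "G", "Y")
        assert p < 1e-6 and z > 0

    def test_flat_proportions_near_zero(self):
        z, _ = trend_test(self._ordinal_dataset([0.5, 0.5, 0.5]), "G", "Y")
        assert z == pytest.approx(0.0, abs=1e-9)

    def test_reversing_level_order_flips_sign(self):
        z1, p1 = trend_test(self._ordinal_dataset([0.2, 0.5, 0.8]), "G", "Y")
        z2, p2 = trend_test(
            self._ordinal_dataset([0.2, 0.5, 0.8], reverse=True), "G", "Y"
        )
        assert z2 == pytest.approx(-z1, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_bmi_trend_on_central_obesity(self):
        d = generate_survey(20_000, seed=9)
        z, p = trend_test(d, "BMI", "CentralObesity")
        assert z > 0 and p < 1e-10


class TestStepwise:
    def test_strong_predictor_survives_noise(self):
        always, exact, extras = 0, 0, []
        for seed in range(10):
            fit = stepwise_logistic(
                logistic_dataset(seed), "y", [f"x{i}" for i in range(6)]
            )
            always += "x0" in fit.retained
            exact += fit.retained == ["x0"]
            extras.append(len(fit.retained) - 1)
        assert always == 10
        assert exact >= 6  # noise terms occasionally enter at the 0.05 level
        assert max(extras) <= 2

    def test_final_model_is_plain_ml_refit(self):
        import statsmodels.api as sm

        d = logistic_dataset(3)
        fit = stepwise_logistic(d, "y", [f"x{i}" for i in range(6)])
        x = np.column_stack([d.column(c).astype(float) for c in fit.retained])
        direct = sm.Logit(
            d.column("y").astype(float), sm.add_constant(x)
        ).fit(disp=0)
        for i, row in enumerate(fit.rows):
            assert row.beta == pytest.approx(direct.params[i + 1], abs=1e-8)
            assert row.se == pytest.approx(direct.bse[i + 1], abs=1e-8)

    def test_constant_outcome_raises(self):
        vs = [CategoricalVariable("x0", ("0", "1")), CategoricalVariable("y", ("0", "1"))]
        d = Dataset(vs, np.column_stack([np.arange(20) % 2, np.zeros(20, int)]))
        with pytest.raises(SeparationError):
            stepwise_logistic(d, "y", ["x0"])

    def test_row_identities(self):
        fit = stepwise_logistic(logistic_dataset(1), "y", [f"x{i}" for i in range(6)])
        for row in fit.rows:
            assert row.odds_ratio == pytest.approx(np.exp(row.beta), rel=1e-12)
            assert row.wald == pytest.approx((row.beta / row.se) ** 2, rel=1e-12)
            lo, hi = row.ci
            assert lo == pytest.approx(np.exp(row.beta - 1.959964 * row.se), rel=1e-9)
            assert hi == pytest.approx(np.exp(row.beta + 1.959964 * row.se), rel=1e-9)


class TestEffectSummaries:
    # printed (beta, SE) -> OR rows from the published regression table
    @pytest.mark.parametrize("beta,se,expected_or", [
        (0.417, 0.048, 1.517),
        (0.501, 0.075, 1.650),
        (0.442, 0.107, 1.556),
        (-0.357, 0.088, 0.700),
        (0.173, 0.064, 1.189),
        (-0.090, 0.045, 0.914),
    ])
    def test_odds_ratio_reproduction(self, beta, se, expected_or):
        orr, lo, hi = or_from_coef(beta, se)
        assert round(orr, 3) == expected_or
        assert lo < orr < hi

    def test_null_coefficient(self):
        orr, lo, hi = or_from_coef(0.0, 0.1)
        assert orr == 1.0
        assert lo == pytest.approx(0.822, abs=5e-4)
        assert hi == pytest.approx(1.217, abs=5e-4)

    def test_proportion_ci_published_rate(self):
        p, lo, hi = proportion_ci(2114, 4567)
        assert 100 * p == pytest.approx(46.3, abs=0.1)
        assert 100 * lo == pytest.approx(44.8, abs=0.1)
        assert 100 * hi == pytest.approx(47.7, abs=0.1)

    def test_proportion_ci_edge_and_hand_values(self):
        p, lo, hi = proportion_ci(10, 10)
        assert p == 1.0 and hi == 1.0
        p, lo, hi = proportion_ci(50, 100)
        assert hi - p == pytest.approx(0.098, abs=5e-4)

    def test_wilson_option_stays_inside_unit_interval(self):
        _, lo, hi = proportion_ci(1, 10, method="wilson")
        assert 0 < lo < hi < 1


class TestComparisonReport:
    def test_lipid10_truth_classification(self, lipid10):
        fit = stepwise_logistic(
            generate_survey(4000, seed=8), "Hyperlipidemia",
            [v.name for v in lipid10.variables if v.name != "Hyperlipidemia"],
        )
        report = comparison_report(lipid10, fit, "Hyperlipidemia")
        roles = {r["variable"]: r["role"] for r in report["covariates"]}
        for direct in ("Gender", "BMI", "PhysicalActivity", "Hypertension", "Diabetes"):
            assert roles[direct] == "direct"
        for indirect in ("Smoking", "SaltIntake", "OilIntake", "CentralObesity"):
            assert roles[indirect] == "indirect"

    def test_outcome_without_edges_all_unconnected(self):
        from bnhybrid.core import DAG
        from bnhybrid.epi import LogisticFit

        g = DAG(["Y", "A", "B"], [("A", "B")])
        report = comparison_report(g, LogisticFit("Y", [], 0.0, 0.0), "Y")
        assert all(r["role"] == "unconnected" for r in report["covariates"])

    def test_report_json_round_trip(self, lipid10):
        import json

        from bnhybrid.epi import LogisticFit

        report = comparison_report(lipid10, LogisticFit("Hyperlipidemia", [], 0, 0),
                                   "Hyperlipidemia")
        assert json.loads(json.dumps(report)) == report


class TestEndToEnd:
    def test_hybrid_learner_finds_outcome_neighbourhood_core(self, lipid10):
        # the outcome's Markov blanket spans all nine other variables, so
        # blanket-conditioned tests lose power for the weakest two parents;
        # the strong adjacencies are recovered and nothing spurious appears
        truth_adj = {"Gender", "BMI", "PhysicalActivity", "Hypertension", "Diabetes"}
        core = {"BMI", "Hypertension", "Diabetes"}
        hits = 0
        for seed in range(10):
            d = generate_survey(20_000, seed=seed)
            res = learn_hybrid(d, "inter.iamb", "tabu")
            adj = set(res.skeleton.neighbors("Hyperlipidemia"))
            hits += core <= adj <= truth_adj
        assert hits >= 8
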