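import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from morphotest.regression import (
    LOGIT_RESIDUAL_VAR,
    fit_model,
    model_formula,
    pooling_test,
    predict_with_ci,
    prepare_model_frame,
    pseudo_r2,
)
from morphotest.synthetic_data import (
    MorphotypeModel,
    QMixtureConfig,
    SimulationConfig,
    generate_study,
)


def design_study(rng, intercept=-2.4, slope=5.4, n_samples=36, per_sample=100, sigma=0.0):
    """Individual table whose T-morphotype law is logistic in the design
    prevalence: logit P(T) = intercept + slope * ptros (+ sample intercept)."""
    grid = np.linspace(0.0, 1.0, n_samples)
    rows = []
    u = rng.normal(0.0, sigma, n_samples) if sigma > 0 else np.zeros(n_samples)
    for i, p in enumerate(grid):
        eta = intercept + slope * p + u[i]
        morph = np.where(rng.random(per_sample) < expit(eta), "T", "E")
        tros = rng.random(per_sample) < p
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": f"S{i:02d}",
                    "set": "SIM",
                    "q": np.where(tros, 0.95, 0.05),
                    "morphotype": morph,
                    "ptros": p,
                    "pt": expit(eta),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestFitModel:
    def test_m1_recovers_generative_coefficients(self, rng):
        data = design_study(rng)
        fit = fit_model("M1", data, covariates="provided")
        est, se = fit.params.to_numpy(), fit.bse.to_numpy()
        assert abs(est[0] - (-2.4)) < 1.96 * se[0]
        assert abs(est[1] - 5.4) < 1.96 * se[1]

    def test_constant_response_rejected(self):
        df = pd.DataFrame(
            {"sample_id": "a", "set": "S", "q": [0.9] * 10, "morphotype": ["T"] * 10}
        )
        with pytest.raises(ValueError, match="degenerate response"):
            fit_model("M1", df)

    def test_fitted_mean_equals_response_mean_without_random_terms(self, rng):
        """The logistic score equation: average fitted probability equals the
        empirical response frequency for GLM fits."""
        data = design_study(rng, n_samples=12, per_sample=80)
        for mid in ("M1", "M4"):
            fit = fit_model(mid, data)
            assert fit.fitted.mean() == pytest.approx(fit.response.mean(), abs=1e-6)

    def test_m1_m4_mutually_consistent(self, rng):
        """Composing the fitted prevalence-from-PT map with the generative
        PT-from-prevalence map approximates the identity mid-range."""
        cfg = SimulationConfig(
            prevalence_grid=tuple(np.linspace(0, 1, 21)),
            sample_size_range=(2000, 2000),
            q_mixture=QMixtureConfig(intermediate_fraction=0.0),
            seed=4,
        )
        individuals, _ = generate_study(cfg)
        m4 = fit_model("M4", individuals)
        p = np.linspace(0.2, 0.8, 7)
        pt = 0.74 * p + 0.04 * (1 - p)  # generative morphotype frequency
        pred = predict_with_ci(m4, pd.DataFrame({"pt": pt}), level=0.0)["fit"].to_numpy()
        assert np.all(np.abs(pred - p) < 0.1)

    def test_unknown_model_rejected(self, small_study):
        with pytest.raises(ValueError):
            fit_model("M9", small_study[0])


class TestPseudoR2:
    def test_nakagawa_schielzeth_arithmetic(self, rng):
        data = design_study(rng, n_samples=10, per_sample=50)
        fit = fit_model("M1", data, covariates="provided")
        # rebuild a fit with controlled variance components
        fit.eta_fixed = np.array([-1.0, 1.0] * 50)  # var exactly 1
        fit.sigma2_alpha = 0.5
        marg, cond = pseudo_r2(fit)
        assert marg == pytest.approx(1.0 / (1.5 + LOGIT_RESIDUAL_VAR), abs=1e-9)
        assert cond == pytest.approx(1.5 / (1.5 + LOGIT_RESIDUAL_VAR), abs=1e-9)
        fit.eta_fixed = np.zeros(100)
        assert pseudo_r2(fit)[0] == 0.0

    def test_zero_sample_variance_makes_marginal_equal_conditional(self, rng):
        data = design_study(rng, n_samples=20, per_sample=60, sigma=0.0)
        fit = fit_model("M6", data, covariates="provided")
        marg, cond = pseudo_r2(fit)
        assert marg <= cond <= 1.0
        assert cond - marg < 0.02

    def test_requires_convergence(self, rng):
        data = design_study(rng, n_samples=8, per_sample=40)
        fit = fit_model("M1", data)
        fit.converged = False
        with pytest.raises(ValueError):
            pseudo_r2(fit)


class TestPredictWithCi:
    def test_prediction_at_design_point_matches_fitted(self, rng):
        data = design_study(rng, n_samples=10, per_sample=60)
        fit = fit_model("M1", data, covariates="provided")
        out = predict_with_ci(fit, pd.DataFrame({"ptros": [0.5]}))
        assert out.loc[0, "lower"] <= out.loc[0, "fit"] <= out.loc[0, "upper"]
        eta = fit.params.iloc[0] + fit.params.iloc[1] * 0.5
        assert out.loc[0, "fit"] == pytest.approx(expit(eta))

    def test_zero_level_degenerates_to_point_estimate(self, rng):
        data = design_study(rng, n_samples=10, per_sample=60)
        fit = fit_model("M1", data, covariates="provided")
        out = predict_with_ci(fit, pd.DataFrame({"ptros": [0.3]}), level=0.0)
        assert out.loc[0, "lower"] == out.loc[0, "fit"] == out.loc[0, "upper"]

    def test_interval_width_shrinks_with_sample_size(self, rng):
        widths = []
        for per in (50, 500, 5000):
            data = design_study(rng, n_samples=10, per_sample=per)
            fit = fit_model("M1", data, covariates="provided")
            out = predict_with_ci(fit, pd.DataFrame({"ptros": [0.5]}))
            widths.append(out.loc[0, "upper"] - out.loc[0, "lower"])
        assert widths[0] > widths[1] > widths[2]


def pooled_sets_study(rng, seed, bh_fpr_logit=-0.2, per_set=10, per_sample=60):
    """Three geographic sets; WS and BL share generative parameters, BH has a
    much higher edulis T-morphotype rate."""
    frames = []
    for set_label, ie in (("WS", -3.2), ("BL", -3.2), ("BH", bh_fpr_logit)):
        cfg = SimulationConfig(
            prevalence_grid=tuple(np.linspace(0.05, 0.95, per_set)),
            sample_size_range=(per_sample, per_sample),
            q_mixture=QMixtureConfig(intermediate_fraction=0.0),
            morph_model=MorphotypeModel(intercept_edu=ie),
            set_label=set_label,
            seed=seed,
        )
        ind, _ = generate_study(cfg)
        ind["sample_id"] = set_label + "_" + ind["sample_id"]
        frames.append(ind)
    return pd.concat(frames, ignore_index=True)


PARTITIONS = [
    [["WS", "BL"], ["BH"]],
    [["WS", "BH"], ["BL"]],
    [["BL", "BH"], ["WS"]],
    [["WS"], ["BL"], ["BH"]],
]


class TestPoolingTest:
    def test_single_partition_returned(self, rng):
        data = pooled_sets_study(rng, seed=1)
        res = pooling_test(data, [PARTITIONS[0]], n_quad=7)
        assert res.best == tuple(tuple(g) for g in PARTITIONS[0])

    def test_partition_must_cover_all_sets(self, rng):
        data = pooled_sets_study(rng, seed=1)
        with pytest.raises(ValueError, match="does not cover"):
            pooling_test(data, [[["WS"], ["BL"]]])

    def test_identical_ws_bl_pooled_with_distinct_bh_selected(self):
        """When WS and BL share a generative law and BH differs, the WSBL+BH
        pooling should usually win the AIC comparison."""
        wins = 0
        for seed in range(5):
            data = pooled_sets_study(np.random.default_rng(seed), seed=seed)
            res = pooling_test(data, PARTITIONS, n_quad=7)
            if {frozenset(g) for g in res.best} == {frozenset({"WS", "BL"}), frozenset({"BH"})}:
                wins += 1
        assert wins >= 3

    def test_identical_sets_full_pooling_not_strongly_beaten(self):
        """With all three sets generated identically, full pooling should sit
        within a small AIC margin of any finer partition."""
        data = pooled_sets_study(np.random.default_rng(3), seed=3, bh_fpr_logit=-3.2)
        parts = [[["WS", "BL", "BH"]]] + PARTITIONS
        res = pooling_test(data, parts, n_quad=7)
        table = res.table.set_index("partition")
        full = table.loc["(BHBLWS)", "aic"]
        assert full <= table["aic"].min() + 4.0
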