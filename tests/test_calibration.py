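import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

from morphotest.calculators import CalculatorParams, get_published, prevalence_from_pt
from morphotest.calibration import (
    delta,
    enumerate_pairs,
    evaluate_pairs,
    goodness_predictive,
    goodness_prevalence,
    loess_summary,
    pairs_frame,
    select_calibrators,
)
from morphotest.loess import loess
from morphotest.metrics import SampleSummary, summarize_study

unit = st.floats(0.0, 1.0, allow_nan=False)


class TestDelta:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [(0.5, 0.5, 0.5), (1.0, 0.0, 1.0), (0.0, 0.0, 0.0), (1.0, 1.0, 0.0), (0.8, 0.3, 0.62)],
    )
    def test_reference_values(self, p1, p2, expected):
        assert delta(p1, p2) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            delta(1.2, 0.5)

    @given(unit, unit)
    def test_symmetric_and_bounded(self, p, q):
        assert delta(p, q) == pytest.approx(delta(q, p))
        assert -1e-12 <= delta(p, q) <= 1.0 + 1e-12

    @given(unit)
    def test_self_delta_is_heterozygosity(self, p):
        assert delta(p, p) == pytest.approx(2 * p * (1 - p))
        assert delta(p, p) <= 0.5 + 1e-12


def summaries_for(ptros_values, n=100):
    """One summary per prevalence; morphotype rates 0.8/0.1 within species."""
    out = []
    for i, p in enumerate(ptros_values):
        n_tros = int(round(n * p))
        n_edu = n - n_tros
        out.append(
            SampleSummary(
                f"S{i:02d}",
                n_T_tros=int(round(0.8 * n_tros)),
                n_E_tros=n_tros - int(round(0.8 * n_tros)),
                n_T_edu=int(round(0.1 * n_edu)),
                n_E_edu=n_edu - int(round(0.1 * n_edu)),
            )
        )
    return out


class TestEnumeratePairs:
    @pytest.mark.parametrize("n,expected", [(36, 630), (2, 1), (10, 45)])
    def test_pair_cardinality(self, n, expected):
        pairs = enumerate_pairs(summaries_for(np.linspace(0.1, 0.9, n)))
        assert len(pairs) == expected

    def test_cardinality_formula_across_sizes(self):
        for n in range(2, 21):
            pairs = enumerate_pairs(summaries_for(np.linspace(0.2, 0.8, n)))
            assert len(pairs) == n * (n - 1) // 2

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            enumerate_pairs(summaries_for([0.5]))

    def test_degenerate_pair_recorded_as_failed(self):
        # two pure-edulis samples: no trossulus to estimate sensitivity from
        pairs = enumerate_pairs(summaries_for([0.0, 0.0]))
        assert pairs[0].failed
        assert "edulis" not in pairs[0].reason or pairs[0].reason  # reason recorded


class TestGoodness:
    def test_perfect_agreement_yields_sentinel(self):
        params = CalculatorParams(0.8, 0.1)
        ref = lambda g: np.asarray(prevalence_from_pt(params, g))
        mss, good = goodness_prevalence(params, ref)
        assert mss == 0.0
        assert np.isinf(good)

    def test_reciprocal_arithmetic(self):
        params = CalculatorParams(0.8, 0.1)
        ref = lambda g: np.asarray(prevalence_from_pt(params, g)) + 0.1
        mss, good = goodness_prevalence(params, ref)
        assert mss == pytest.approx(0.01)
        assert good == pytest.approx(100.0)

    def test_published_reference_accepted(self):
        params = CalculatorParams(0.8, 0.1)
        mss, good = goodness_prevalence(params, get_published("WSBL", "Ptros_from_PT"))
        assert 0 < mss < 1 and good == pytest.approx(1 / mss)

    def test_predictive_target_pools_both_curves(self):
        params = CalculatorParams(0.8, 0.1)
        ppv_ref = lambda g: np.full_like(g, 0.5)
        npv_ref = lambda g: np.full_like(g, 0.5)
        mss, _ = goodness_predictive(params, ppv_ref, npv_ref)
        # hand-computed: mean over the concatenated squared deviations
        g = np.linspace(0, 1, 101)
        from morphotest.calculators import npv, ppv

        expected = np.mean(
            np.r_[np.asarray(ppv(params, g)) - 0.5, np.asarray(npv(params, g)) - 0.5] ** 2
        )
        assert mss == pytest.approx(expected)

    def test_grid_step_halving_preserves_ranking(self):
        summaries = summaries_for(np.linspace(0.05, 0.95, 15), n=200)
        ref = get_published("WSBL", "Ptros_from_PT")
        g1 = [goodness_prevalence(pe.params, ref, 0.01)[1] for pe in enumerate_pairs(summaries) if not pe.failed]
        g2 = [goodness_prevalence(pe.params, ref, 0.005)[1] for pe in enumerate_pairs(summaries) if not pe.failed]
        rho = spearmanr(g1, g2).statistic
        assert rho > 0.999


class TestLoess:
    def test_constant_input_gives_flat_curve(self, rng):
        x = rng.random(40)
        y = np.full(40, 3.5)
        assert np.allclose(loess(x, y, span=0.75, degree=2), 3.5)

    def test_permutation_invariance(self, rng):
        x = rng.random(60)
        y = np.sin(2 * x) + rng.normal(0, 0.05, 60)
        perm = rng.permutation(60)
        grid = np.linspace(0.1, 0.9, 9)
        a = loess(x, y, x_eval=grid)
        b = loess(x[perm], y[perm], x_eval=grid)
        assert np.allclose(a, b)

    def test_monotone_trend_recovered(self, rng):
        x = rng.random(200)
        y = x**2 * 10 + rng.normal(0, 0.2, 200)
        grid = np.linspace(0.5, 1.0, 11)
        curve = loess(x, y, x_eval=grid, span=0.75, degree=2)
        assert np.all(np.diff(curve) > -0.05)

    def test_loess_summary_requires_enough_finite_pairs(self):
        pairs = enumerate_pairs(summaries_for([0.2, 0.8]))
        with pytest.raises(ValueError, match="finite pair"):
            loess_summary(pairs, target="prevalence")

    def test_loess_summary_excludes_sentinels(self):
        summaries = summaries_for(np.linspace(0.1, 0.9, 12), n=300)
        params0 = CalculatorParams(0.8, 0.1)
        ref = lambda g: np.asarray(prevalence_from_pt(params0, g))
        pairs = evaluate_pairs(summaries, reference_prevalence=ref)
        # pairs pooled from identical-rate samples equal the reference exactly
        assert any(np.isinf(pe.goodness_prevalence) for pe in pairs if not pe.failed)
        finite = [pe for pe in pairs if not pe.failed and np.isfinite(pe.goodness_prevalence)]
        if len(finite) >= 10:
            curve = loess_summary(pairs, target="prevalence")
            assert np.isfinite(curve.iloc[:, 1]).all()


class TestSelectCalibrators:
    def test_threshold_application(self):
        summaries = summaries_for([0.05, 0.5, 0.9], n=200)
        params = select_calibrators(summaries, "prevalence")
        # pools samples 1 and 3 (prevalence 0.05 and 0.9)
        assert "S00" not in params.provenance  # provenance is the stratum label
        pooled_ids = {"S00", "S02"}
        from morphotest.metrics import pool_summaries
        from morphotest.calculators import params_from_summary

        expected = params_from_summary(
            pool_summaries([summaries[0], summaries[2]], "x")
        )
        assert params.p_t_tros == pytest.approx(expected.p_t_tros)
        assert params.p_t_edu == pytest.approx(expected.p_t_edu)

    def test_predictive_purpose_uses_mixed_stratum(self):
        summaries = summaries_for([0.05, 0.5, 0.9], n=200)
        params = select_calibrators(summaries, "predictive")
        from morphotest.calculators import params_from_summary

        expected = params_from_summary(summaries[1])
        assert params.p_t_tros == pytest.approx(expected.p_t_tros)

    def test_empty_stratum_rejected_with_name(self):
        mixed_only = summaries_for([0.45, 0.5, 0.55], n=200)
        with pytest.raises(ValueError, match="Ptros"):
            select_calibrators(mixed_only, "prevalence")

    def test_converges_to_generative_rates(self):
        from morphotest.synthetic_data import QMixtureConfig, SimulationConfig, generate_study

        cfg = SimulationConfig(
            prevalence_grid=(0.02, 0.05, 0.5, 0.9, 0.97),
            sample_size_range=(20000, 20000),
            q_mixture=QMixtureConfig(intermediate_fraction=0.0),
            seed=21,
        )
        individuals, _ = generate_study(cfg)
        params = select_calibrators(summarize_study(individuals), "prevalence")
        assert params.p_t_tros == pytest.approx(0.74, abs=0.01)
        assert params.p_t_edu == pytest.approx(0.04, abs=0.005)


def test_prevalence_goodness_rises_with_dissimilarity():
    """Against the published regional curves, dissimilar calibration pairs
    predict prevalence better than similar ones, and the smoothed trend is
    nondecreasing over the upper half of the dissimilarity range."""
    import morphotest as mt

    cfg = mt.wsbl_like_config(seed=2)
    individuals, _ = mt.generate_study(cfg)
    summaries = summarize_study(individuals)
    ref = get_published("WSBL", "Ptros_from_PT")
    pairs = evaluate_pairs(summaries, reference_prevalence=ref)
    df = pairs_frame(pairs)
    ok = df[~df["failed"] & np.isfinite(df["goodness_prevalence"])]
    hi = ok[ok["delta"] > 0.75]["goodness_prevalence"].median()
    lo = ok[ok["delta"] < 0.25]["goodness_prevalence"].median()
    assert hi > lo
    grid = np.linspace(0.5, 0.95, 10)
    curve = loess(
        ok["delta"].to_numpy(), ok["goodness_prevalence"].to_numpy(), x_eval=grid
    )
    assert np.all(np.diff(curve) > -1e-6 * max(1.0, np.max(np.abs(curve))))
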