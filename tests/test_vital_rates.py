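import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit

from quadratdyn.vital_rates import (GrowthParams, RecruitParams,
                                    SurvivalParams, climate_selector,
                                    effective_cover, fit_growth,
                                    fit_survival, growth_moments,
                                    recruit_intensity, sample_recruits,
                                    select_climate_covariates, survival_prob,
                                    variance_explained)


class TestSurvivalProb:
    def test_all_zero_coefficients_give_half(self):
        p = SurvivalParams()
        assert survival_prob(0.0, None, None, p) == 0.5

    def test_extreme_predictor_limits(self):
        p = SurvivalParams(intercept=-800.0)
        assert survival_prob(0.0, None, None, p) == pytest.approx(0.0)
        p.intercept = 800.0
        assert survival_prob(0.0, None, None, p) == pytest.approx(1.0)

    def test_hand_computed_inverse_logit(self):
        # γ=1, β=0.5, u=2 → logit⁻¹(2)
        p = SurvivalParams(intercept=1.0, size=0.5)
        assert survival_prob(2.0, None, None, p) == pytest.approx(expit(2.0))

    def test_unknown_year_is_hard_error_marginal_is_not(self):
        p = SurvivalParams(intercept=1.0, year_effects={2000: 0.3})
        with pytest.raises(KeyError):
            survival_prob(0.0, None, None, p, year=1999)
        assert survival_prob(0.0, None, None, p) == expit(1.0)
        assert survival_prob(0.0, None, None, p, year=2000) == expit(1.3)

    def test_invariant_to_crowding_vector_ordering(self):
        p = SurvivalParams(intercept=0.2, crowding={"A": -0.1, "B": -0.3},
                           crowding_size={"A": 0.01, "B": 0.0})
        w1 = {"A": 2.0, "B": 1.0}
        w2 = {"B": 1.0, "A": 2.0}
        assert survival_prob(1.0, None, w1, p) == survival_prob(
            1.0, None, w2, p)


class TestGrowthMoments:
    def test_identity_growth(self):
        p = GrowthParams(size=1.0, var_a=0.1)
        for u in (-1.0, 0.0, 2.5):
            vbar, _ = growth_moments(u, None, None, p)
            assert vbar == u

    def test_constant_variance_when_b_zero(self):
        p = GrowthParams(size=1.0, var_a=0.3, var_b=0.0)
        _, v1 = growth_moments(-1.0, None, None, p)
        _, v2 = growth_moments(3.0, None, None, p)
        assert v1 == v2 == 0.3

    def test_variance_function_evaluation(self):
        # a=0.1, b=0.5, v̄=2 → 0.1·e¹
        p = GrowthParams(intercept=2.0, size=0.0, var_a=0.1, var_b=0.5)
        vbar, var = growth_moments(0.0, None, None, p)
        assert vbar == 2.0
        assert var == pytest.approx(0.1 * np.e)


class TestEffectiveCover:
    @pytest.mark.parametrize("p,N,g,expected", [
        (1.0, 10.0, 30.0, 10.0),
        (0.0, 10.0, 30.0, 30.0),
        (0.5, 10.0, 30.0, 20.0),
    ])
    def test_mixture(self, p, N, g, expected):
        assert effective_cover(N, g, p) == expected

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_p_outside_unit_interval_is_hard_error(self, p):
        with pytest.raises(ValueError):
            effective_cover(10.0, 30.0, p)


class TestRecruitIntensity:
    def test_zero_cover_zero_intensity(self):
        p = RecruitParams(intercept=3.0)
        assert recruit_intensity("A", {"A": 0.0}, None, p) == 0.0

    def test_all_zero_coefficients_proportional_to_cover(self):
        p = RecruitParams()
        assert recruit_intensity("A", {"A": 4.0}, None, p) == pytest.approx(4.0)

    def test_ricker_sqrt_density_dependence(self):
        # ω_jj = −0.5, N′ = 4 → λ = 4·e^(−0.5·2) = 4/e
        p = RecruitParams(dd={"A": -0.5})
        lam = recruit_intensity("A", {"A": 4.0}, None, p)
        assert lam == pytest.approx(4.0 * np.exp(-1.0))


class TestSampleRecruits:
    def test_zero_intensity_always_zero(self, rng):
        assert all(sample_recruits(0.0, 1.0, rng) == 0 for _ in range(100))

    def test_moments_match_negative_binomial(self, rng):
        draws = sample_recruits(np.full(100_000, 3.0), 1.0, rng)
        # mean λ, variance λ + λ²/θ = 12
        assert draws.mean() == pytest.approx(3.0, abs=0.05)
        assert draws.var() == pytest.approx(12.0, rel=0.05)

    def test_invalid_theta_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_recruits(1.0, 0.0, rng)


class TestVarianceExplained:
    def test_direct_substitution(self):
        assert variance_explained(10, 4, 2) == pytest.approx(0.75)

    def test_boundaries(self):
        assert variance_explained(10, 2, 2) == 1.0
        assert variance_explained(10, 10, 2) == 0.0

    def test_degenerate_returns_nan(self):
        assert np.isnan(variance_explained(5, 5, 5))

    def test_noise_inversions_clip_into_unit_interval(self):
        assert variance_explained(10, 1, 2) == 1.0
        assert variance_explained(10, 11, 2) == 0.0

    @given(scale=st.floats(0.01, 1000.0))
    def test_scale_invariance(self, scale):
        base = variance_explained(10, 4, 2)
        assert variance_explained(10 * scale, 4 * scale,
                                  2 * scale) == pytest.approx(base)


def _simulate_transitions(n, rng, eta=0.0, year_sd=0.25, n_years=25):
    """Direct generative draw from the survival/growth models (no IBM)."""
    years = np.arange(2000, 2000 + n_years)
    clim = pd.DataFrame({
        "pptLag": 300 + 60 * rng.standard_normal(n_years),
        "ppt1": 150 + 40 * rng.standard_normal(n_years),
        "ppt2": 150 + 40 * rng.standard_normal(n_years),
        "T1": 10 + 1.2 * rng.standard_normal(n_years),
        "T2": 16 + 1.2 * rng.standard_normal(n_years)},
        index=pd.Index(years, name="year"))
    from quadratdyn.data_io import ClimateTable
    table = ClimateTable("S", clim)
    sp = SurvivalParams(intercept=0.6 - eta * 150, size=0.7,
                        crowding={"A": -0.03}, crowding_size={"A": 0.0},
                        climate={"ppt1": eta},
                        year_effects={int(y): rng.normal(0, year_sd)
                                      for y in years},
                        group_effects={"g0": 0.15, "g1": -0.15})
    gp = GrowthParams(intercept=0.3 - (eta / 2) * 150, size=0.85,
                      crowding={"A": -0.01}, crowding_size={"A": 0.0},
                      climate={"ppt1": eta / 2},
                      year_effects={int(y): rng.normal(0, year_sd / 2)
                                    for y in years},
                      group_effects={"g0": 0.1, "g1": -0.1},
                      var_a=0.2, var_b=0.1)
    rows = []
    for i in range(n):
        year = int(rng.choice(years))
        group = "g0" if i % 2 else "g1"
        u = rng.normal(1.5, 1.0)
        w = {"A": float(rng.gamma(2.0, 4.0))}
        C = table.row(year)
        s = survival_prob(u, C, w, sp, year=year, group=group)
        alive = rng.random() < s
        vbar, var = growth_moments(u, C, w, gp, year=year, group=group)
        rows.append({"site": "S", "quadrat": "q", "group": group,
                     "species": "A", "genet_id": i, "year": year,
                     "logarea": u, "w_A": w["A"],
                     "survives": float(alive),
                     "logarea_next": float(rng.normal(vbar, np.sqrt(var)))
                     if alive else np.nan})
    return pd.DataFrame(rows), table, sp, gp


class TestFitting:
    def test_survival_recovery_within_2se(self, rng):
        df, clim, sp_true, _ = _simulate_transitions(6000, rng, eta=0.004)
        fit = fit_survival(df, ["A"], clim, climate_covariates=["ppt1"])
        p = fit.params
        assert abs(p.size - sp_true.size) < 2 * fit.bse["size"]
        assert abs(p.crowding["A"] - sp_true.crowding["A"]) \
            < 2 * fit.bse["w_A"]
        assert abs(p.climate["ppt1"] - 0.004) < 2 * fit.bse["clim_ppt1"]
        # group deviations recovered (±0.15 contrast)
        assert p.group_effects["g0"] > p.group_effects["g1"]

    def test_growth_recovery_and_variance_function(self, rng):
        df, clim, _, gp_true = _simulate_transitions(6000, rng, eta=0.004)
        fit = fit_growth(df, ["A"], clim, climate_covariates=["ppt1"])
        p = fit.params
        assert abs(p.size - gp_true.size) < 2 * fit.bse["size"]
        assert abs(p.climate["ppt1"] - 0.002) < 2 * fit.bse["clim_ppt1"]
        assert p.var_a == pytest.approx(gp_true.var_a, rel=0.3)
        assert p.var_b == pytest.approx(gp_true.var_b, abs=0.1)

    def test_growth_noiseless_limit_r2_one(self, rng):
        df, clim, _, _ = _simulate_transitions(500, rng)
        gp = GrowthParams(intercept=0.3, size=0.85, crowding={"A": -0.01},
                          crowding_size={"A": 0.0})
        df["logarea_next"] = gp.linear_predictor(
            df["logarea"].to_numpy(), None, {"A": df["w_A"].to_numpy()})
        fit = fit_growth(df, ["A"])
        assert fit.params.size == pytest.approx(0.85, abs=1e-8)
        assert fit.fitted.rsquared > 0.999999

    def test_bias_shrinks_with_sample_size(self, rng):
        biases = []
        for n in (800, 8000):
            reps = []
            for _ in range(3):
                df, clim, sp_true, _ = _simulate_transitions(n, rng)
                fit = fit_survival(df, ["A"])
                reps.append(fit.params.size - sp_true.size)
            biases.append(np.mean(np.abs(reps)))
        assert biases[1] < biases[0]


class TestStepwiseSelection:
    def test_planted_signal_is_selected(self, rng):
        # strong ppt1 signal relative to year noise
        df, clim, _, _ = _simulate_transitions(6000, rng, eta=0.012,
                                               year_sd=0.15, n_years=30)
        fit = fit_survival(df, ["A"])
        sel = select_climate_covariates(
            climate_selector(fit.params.year_effects, clim))
        assert "ppt1" in sel.selected

    def test_single_candidate_reduces_to_aic_comparison(self, rng):
        df, clim, _, _ = _simulate_transitions(3000, rng, eta=0.012,
                                               year_sd=0.15, n_years=30)
        fit = fit_survival(df, ["A"])
        fit_fn = climate_selector(fit.params.year_effects, clim)
        sel = select_climate_covariates(fit_fn, candidates=["ppt1"])
        assert sel.selected in ([], ["ppt1"])
        if fit_fn(["ppt1"]) < fit_fn([]):
            assert sel.selected == ["ppt1"]

    def test_interactions_require_parents(self, rng):
        df, clim, _, _ = _simulate_transitions(2000, rng)
        fit = fit_growth(df, ["A"])
        sel = select_climate_covariates(
            climate_selector(fit.params.year_effects, clim))
        for inter, parents in {"ppt1T1": ("ppt1", "T1"),
                               "ppt2T2": ("ppt2", "T2")}.items():
            if inter in sel.selected:
                assert all(p in sel.selected for p in parents)
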