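"""Simulator: calibration, correlation structure, scoring rules."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from pgsace.synthetic_data import (
    ACE_LABELS,
    PGS_LABELS,
    SimulationConfig,
    calibrate_liability_effect,
    composite_mental_health_score,
    derive_ace_indicator,
    make_power_scenario,
    null_scenario,
    simulate_cohort,
)


class TestCalibration:
    def test_null_odds_ratio_gives_zero_slope(self):
        assert calibrate_liability_effect(1.0, 0.2) == 0.0

    def test_monotone_in_target(self):
        g1 = calibrate_liability_effect(1.07, 0.25)
        g2 = calibrate_liability_effect(1.16, 0.25)
        assert 0 < g1 < g2

    def test_inverse_symmetry(self):
        g = calibrate_liability_effect(1.10, 0.2)
        assert calibrate_liability_effect(1 / 1.10, 0.2) == pytest.approx(-g)

    def test_monte_carlo_oracle(self):
        """The calibrated slope reproduces the target OR in a brute-force
        liability simulation."""
        target, prev = 1.10, 0.2
        gamma = calibrate_liability_effect(target, prev)
        rng = np.random.default_rng(42)
        n = 400_000
        s = rng.standard_normal(n)
        liab = gamma * s + math.sqrt(1 - gamma**2) * rng.standard_normal(n)
        y = liab > stats.norm.ppf(1 - prev)
        fit = sm.Logit(y, sm.add_constant(s)).fit(disp=0)
        or_hat = math.exp(fit.params[1])
        # 3 MC standard errors of the fitted OR at this n
        tol = 3 * or_hat * fit.bse[1]
        assert abs(or_hat - target) < tol

    def test_errors(self):
        with pytest.raises(ValueError):
            calibrate_liability_effect(-1.0, 0.2)
        with pytest.raises(ValueError):
            calibrate_liability_effect(1.1, 1.5)


class TestSimulateCohort:
    def test_fixed_seed_reproducible(self):
        cfg = make_power_scenario("h1a", n=500)
        a = simulate_cohort(cfg, seed=7).frame
        b = simulate_cohort(cfg, seed=7).frame
        pd.testing.assert_frame_equal(a, b)

    def test_null_model_has_no_associations(self):
        cohort = simulate_cohort(null_scenario(n=100_000), seed=1)
        f = cohort.frame
        for pgs in PGS_LABELS[:3]:
            for ace in ACE_LABELS[:3]:
                assert abs(np.corrcoef(f[pgs], f[ace])[0, 1]) < 0.01
        for ace in ACE_LABELS[:3]:
            assert abs(np.corrcoef(f["int"], f[ace])[0, 1]) < 0.01

    def test_prevalence_within_two_binomial_se(self):
        n = 100_000
        cohort = simulate_cohort(make_power_scenario("h1a", n=n), seed=3)
        for ace, p in zip(ACE_LABELS, (0.20,) * 6):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(cohort.frame[ace].mean() - p) < 2.5 * se

    def test_pgs_standardized_and_correlated(self):
        cohort = simulate_cohort(make_power_scenario("h1a", n=80_000), seed=4)
        X = cohort.frame[list(PGS_LABELS)].to_numpy()
        assert np.allclose(X.mean(axis=0), 0, atol=0.02)
        assert np.allclose(X.std(axis=0), 1, atol=0.02)
        corr = np.corrcoef(X, rowvar=False)
        off = corr[np.triu_indices(8, 1)]
        assert abs(off.mean() - 0.06) < 0.01

    def test_single_pair_or_recovery(self):
        """A cohort generated with one targeted OR yields a logistic fit
        whose CI covers the target."""
        or_mat = [[1.0] * 6 for _ in range(8)]
        or_mat[0][0] = 1.10
        cfg = SimulationConfig(
            n=200_000, ace_prevalence=(0.2,) * 6, or_matrix=tuple(map(tuple, or_mat))
        )
        f = simulate_cohort(cfg, seed=9).frame
        fit = sm.Logit(
            f["ace_mal"], sm.add_constant(f[["pgs_dep", "sex"]])
        ).fit(disp=0)
        assert math.exp(fit.params["pgs_dep"]) == pytest.approx(1.10, abs=0.02)

    def test_inter_ace_tetrachoric_near_target(self):
        """Pairwise tetrachoric correlations of the ACEs sit near 0.30."""
        f = simulate_cohort(make_power_scenario("h1a", n=100_000), seed=5).frame
        tau = stats.norm.ppf(0.8)
        for a, b in [("ace_mal", "ace_dvi"), ("ace_pmi", "ace_sep")]:
            p11 = float(np.mean((f[a] == 1) & (f[b] == 1)))

            def implied_p11(r):
                return stats.multivariate_normal(
                    mean=[0, 0], cov=[[1, r], [r, 1]]
                ).cdf([-tau, -tau])

            from scipy.optimize import brentq

            r_hat = brentq(lambda r: implied_p11(r) - p11, -0.9, 0.9)
            assert r_hat == pytest.approx(0.30, abs=0.03)

    def test_outcome_heritability_share(self):
        """R^2 of the outcome on the latent genetic factor recovers h2."""
        cfg = SimulationConfig(n=100_000, or_matrix=((1.05,) * 6,) * 8)
        f = simulate_cohort(cfg, seed=6, include_latent=True).frame
        for outcome, h2 in (("int", 0.06), ("ext", 0.09)):
            r2 = np.corrcoef(f[outcome], f["g_latent"])[0, 1] ** 2
            assert r2 == pytest.approx(h2, abs=0.01)

    def test_controls_independent_of_everything(self):
        f = simulate_cohort(make_power_scenario("h1a", n=80_000), seed=8).frame
        for col in ("ace_mal", "int", "pgs_dep"):
            assert abs(np.corrcoef(f["pgs_hand"], f[col])[0, 1]) < 0.012

    def test_infeasible_structure_raises(self):
        # strong shared PGS effects already induce more inter-ACE correlation
        # than the target allows
        cfg = SimulationConfig(
            n=100, or_matrix=((2.5,) * 6,) * 8, r_ace=0.05
        )
        with pytest.raises(ValueError, match="adversity"):
            simulate_cohort(cfg, seed=0)

    def test_missingness_injection(self):
        cfg = SimulationConfig(n=2000, missing_rate=0.1)
        f = simulate_cohort(cfg, seed=11).frame
        frac = f[list(ACE_LABELS)].isna().to_numpy().mean()
        assert frac == pytest.approx(0.1, abs=0.02)


class TestPowerScenarios:
    def test_unknown_name_errors(self):
        with pytest.raises(ValueError):
            make_power_scenario("h9z")

    def test_h1a_encodes_average_or(self):
        cfg = make_power_scenario("h1a")
        assert cfg.n == 4700
        ors = np.asarray(cfg.or_matrix)
        assert ors.shape == (8, 6)
        assert float(ors.mean()) == pytest.approx(1.04)

    def test_h1b_extremes_and_spacing(self):
        ors = np.asarray(make_power_scenario("h1b").or_matrix)[:, 0]
        assert ors[0] == pytest.approx(1.05) and ors[-1] == pytest.approx(1.16)
        assert np.allclose(np.diff(ors), np.diff(ors)[0])

    def test_h2b_paths(self):
        cfg = make_power_scenario("h2b")
        assert cfg.r_pb_matrix == ((0.07,),)
        assert cfg.beta_pgs == ((0.24,),)
        assert cfg.ace_outcome_r == ((0.06,),)

    def test_h2a_agg_generating_proportion_is_five_percent(self):
        cfg = make_power_scenario("h2a_agg")
        a = np.asarray(cfg.r_pb_matrix)[:, 0]
        b = np.asarray(cfg.beta_pgs)[:, 0]
        assert float(a @ b) / 0.06 == pytest.approx(0.05, rel=1e-9)


class TestScoringRules:
    def test_insufficient_response_is_missing(self):
        resp = [1, 0, 0, 1] + [np.nan] * 6  # 4 of 10 answered
        assert math.isnan(derive_ace_indicator(resp))

    def test_complete_negative_is_zero(self):
        assert derive_ace_indicator([0] * 10) == 0.0

    def test_boundary_half_answered_counts(self):
        resp = [1, 0, 0, 0, 0] + [np.nan] * 5  # exactly 50%, one positive
        assert derive_ace_indicator(resp) == 1.0

    def test_empty_is_missing(self):
        assert math.isnan(derive_ace_indicator([]))

    def test_composite_constant_data_warns_zeros(self):
        items = pd.DataFrame({"a1": [1, 1, 1], "a2": [1, 1, 1]})
        with pytest.warns(UserWarning):
            out = composite_mental_health_score(items, {"anx": ["a1", "a2"]})
        assert np.allclose(out, 0.0)

    def test_composite_missing_subscale_propagates(self):
        items = pd.DataFrame(
            {
                "a1": [1.0, 2.0, np.nan, 0.0],
                "a2": [1.0, 2.0, np.nan, 1.0],
                "b1": [0.0, 1.0, 2.0, 3.0],
            }
        )
        out = composite_mental_health_score(
            items, {"anx": ["a1", "a2"], "dep": ["b1"]}
        )
        assert math.isnan(out.iloc[2])
        assert out.drop(index=2).notna().all()

    def test_composite_hand_computed(self):
        """Standardize-sum-standardize on a 4-person, two-subscale table."""
        items = pd.DataFrame(
            {"a1": [0.0, 1.0, 2.0, 3.0], "b1": [3.0, 1.0, 0.0, 2.0]}
        )
        out = composite_mental_health_score(items, {"s1": ["a1"], "s2": ["b1"]})
        a = np.array([0, 1, 2, 3], dtype=float)
        b = np.array([3, 1, 0, 2], dtype=float)
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        total = za + zb
        expected = (total - total.mean()) / total.std()
        assert np.allclose(out.to_numpy(), expected)
        assert out.mean() == pytest.approx(0, abs=1e-12)
        assert out.std(ddof=0) == pytest.approx(1, abs=1e-12)
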