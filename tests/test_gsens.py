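"""Latent-score sensitivity analysis: path solving, adjustment, bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pgsace.gsens import (
    GsensResult,
    GsensScenario,
    gsens_adjust,
    gsens_ci,
    observed_paths_from_corr,
    repool_excluding_unreliable,
)
from pgsace.statcore import EffectEstimate, aggregate_dependent_effects
from pgsace.synthetic_data import SimulationConfig, simulate_cohort


class TestObservedPaths:
    def test_orthogonal_predictors(self):
        a, b, cp = observed_paths_from_corr(0.0, 0.2, 0.06)
        assert (a, b, cp) == pytest.approx((0.0, 0.2, 0.06))

    def test_hand_linear_solve_and_conservation(self):
        r_ap, r_pm, r_am = 0.1, 0.2, 0.06
        a, b, cp = observed_paths_from_corr(r_ap, r_pm, r_am)
        b_hand, cp_hand = np.linalg.solve(
            [[1, r_ap], [r_ap, 1]], [r_pm, r_am]
        )
        assert (b, cp) == pytest.approx((b_hand, cp_hand))
        assert cp + a * b == pytest.approx(r_am, abs=1e-12)

    def test_against_simulated_regression(self):
        """Paths from the matrix equal regression coefficients on Gaussian
        data drawn with that correlation matrix."""
        r_ap, r_pm, r_am = 0.15, 0.25, 0.10
        corr = np.array([[1, r_ap, r_pm], [r_ap, 1, r_am], [r_pm, r_am, 1]])
        rng = np.random.default_rng(3)
        X = rng.multivariate_normal(np.zeros(3), corr, size=400_000)
        score, ace, out = X.T
        D = np.column_stack([np.ones(len(X)), score, ace])
        coefs = np.linalg.lstsq(D, out, rcond=None)[0]
        a, b, cp = observed_paths_from_corr(r_ap, r_pm, r_am)
        assert b == pytest.approx(coefs[1], abs=0.01)
        assert cp == pytest.approx(coefs[2], abs=0.01)

    def test_non_pd_matrix_errors(self):
        with pytest.raises(ValueError, match="positive definite"):
            observed_paths_from_corr(0.9, -0.9, 0.9)


class TestAdjust:
    def test_fixed_point_reproduces_observed(self):
        """h2 equal to the observed outcome-path variance returns the
        observed proportion exactly."""
        r_ap, r_pm, r_am = 0.08, 0.20, 0.06
        a, b, cp = observed_paths_from_corr(r_ap, r_pm, r_am)
        scen = GsensScenario(
            r_ap=r_ap, r_pm=r_pm, r_am=r_am, h2=b**2, k=a / b
        )
        res = gsens_adjust(scen)
        assert res.proportion_star == pytest.approx(a * b / r_am, abs=1e-10)
        assert res.b_star == pytest.approx(b, abs=1e-12)

    def test_zero_k_zero_proportion(self):
        scen = GsensScenario(r_ap=0.05, r_pm=0.2, r_am=0.06, h2=0.06, k=0.0)
        assert gsens_adjust(scen).proportion_star == 0.0

    def test_worked_example(self):
        """b* = sqrt(0.06) = 0.2449, a* = 0.33 b*, proportion = 0.330."""
        scen = GsensScenario(r_ap=0.02, r_pm=0.08, r_am=0.06, h2=0.06, k=0.33)
        res = gsens_adjust(scen)
        assert res.b_star == pytest.approx(math.sqrt(0.06), abs=1e-12)
        assert res.a_star == pytest.approx(0.0808, abs=2e-4)
        assert res.indirect_star == pytest.approx(0.0198, abs=2e-4)
        assert res.proportion_star == pytest.approx(0.330, abs=1e-3)

    def test_heritability_path_constants(self):
        """The latent outcome path prints as 0.24 (h2=6%) and 0.30 (h2=9%)."""
        for h2, shown in ((0.06, 0.24), (0.09, 0.30)):
            scen = GsensScenario(r_ap=0.02, r_pm=0.1, r_am=0.06, h2=h2, k=0.3)
            assert round(gsens_adjust(scen).b_star, 2) == shown

    def test_monotone_in_h2(self):
        props = []
        for h2 in np.linspace(0.02, 0.3, 10):
            scen = GsensScenario(r_ap=0.02, r_pm=0.1, r_am=0.06, h2=h2, k=0.25)
            props.append(gsens_adjust(scen).proportion_star)
        assert all(b >= a for a, b in zip(props, props[1:]))

    @given(
        st.floats(0.01, 0.3),
        st.floats(-0.3, 0.3),
        st.floats(0.01, 0.5),
        st.floats(-1.0, 1.0),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_path_tracing_conservation(self, r_am, r_ap, h2, k):
        scen = GsensScenario(r_ap=r_ap, r_pm=0.1, r_am=r_am, h2=h2, k=k)
        res = gsens_adjust(scen)
        assert res.cp_star + res.a_star * res.b_star == pytest.approx(
            scen.r_am, abs=1e-12
        )

    def test_matrix_mode_agrees_with_paths_mode(self):
        scen = GsensScenario(r_ap=0.05, r_pm=0.2, r_am=0.06, h2=0.06, k=0.33)
        p = gsens_adjust(scen, mode="paths")
        m = gsens_adjust(scen, mode="matrix")
        for attr in ("a_star", "b_star", "cp_star", "proportion_star"):
            assert getattr(p, attr) == pytest.approx(getattr(m, attr), abs=1e-9)

    def test_tiny_total_flagged_undefined(self):
        scen = GsensScenario(r_ap=0.05, r_pm=0.2, r_am=1e-12, h2=0.06, k=0.33)
        res = gsens_adjust(scen)
        assert res.undefined and math.isnan(res.proportion_star)


def _single_score_cohort(n, a_pb, b, total, seed):
    cfg = SimulationConfig(
        n=n,
        n_pgs=1,
        n_controls=0,
        rho_pgs=0.0,
        ace_prevalence=(0.2,),
        r_ace=0.0,
        r_pb_matrix=((a_pb,),),
        h2=(0.0,),
        beta_pgs=((b,),),
        ace_outcome_r=((total,),),
        pgs_labels=("pgs_one",),
        control_labels=(),
        ace_labels=("ace_mal",),
        outcome_labels=("int",),
    )
    return simulate_cohort(cfg, seed)


class TestGsensCi:
    def test_recovers_generating_latent_proportion(self):
        """Observed score *is* the latent score (h2 = b_obs^2): the adjusted
        proportion equals the generating one, here 0.5."""
        # a=0.2, b=0.3 -> indirect 0.06; total 0.12 -> proportion 0.5
        cohort = _single_score_cohort(
            n=10_000, a_pb=0.2, b=0.3, total=0.12, seed=61
        )
        res = gsens_ci(
            cohort, "ace_mal", "int", h2=0.09, B=300, seed=1,
            mediator_set=("pgs_one",),
        )
        assert res.reliable
        assert res.ci95[0] < 0.5 < res.ci95[1]
        assert res.proportion_star == pytest.approx(0.5, abs=0.12)

    def test_overexplained_association_unreliable(self):
        """Weak direct path + large h2 pushes the proportion past 1."""
        cohort = _single_score_cohort(
            n=10_000, a_pb=0.07, b=0.2, total=0.016, seed=62
        )
        res = gsens_ci(
            cohort, "ace_mal", "int", h2=0.09, B=200, seed=2,
            mediator_set=("pgs_one",),
        )
        assert res.proportion_star > 1.0
        assert not res.reliable

    def test_fixed_seed_identical_ci(self, small_cohort):
        a = gsens_ci(small_cohort, "ace_mal", "int", h2=0.06, B=150, seed=9)
        b = gsens_ci(small_cohort, "ace_mal", "int", h2=0.06, B=150, seed=9)
        assert a.ci95 == b.ci95
        assert a.proportion_star == b.proportion_star

    def test_too_few_resamples_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="at least 100"):
            gsens_ci(small_cohort, "ace_mal", "int", h2=0.06, B=50)


class TestRepool:
    def _res(self, prop, se, reliable=True):
        return GsensResult(
            a_star=0.1,
            b_star=0.2,
            cp_star=0.04,
            indirect_star=0.02,
            proportion_star=prop,
            ci95=(prop - 2 * se, prop + 2 * se),
            reliable=reliable,
            se_proportion=se,
        )

    def test_all_reliable_equals_plain_pool(self):
        results = [self._res(0.3, 0.05), self._res(0.4, 0.05)]
        pooled = repool_excluding_unreliable(results, rho=0.3)
        direct = aggregate_dependent_effects(
            [EffectEstimate(0.3, 0.05), EffectEstimate(0.4, 0.05)], rho=0.3
        )
        assert pooled.estimate == direct.estimate
        assert pooled.se == direct.se

    def test_exclusion_attenuates_toward_remaining(self):
        results = [
            self._res(0.30, 0.05),
            self._res(0.35, 0.05),
            self._res(2.50, 0.05, reliable=False),
        ]
        pooled = repool_excluding_unreliable(results, rho=0.3)
        assert pooled.estimate == pytest.approx((0.30 + 0.35) / 2)

    def test_hand_computed_shift(self):
        kept = [self._res(0.2, 0.1), self._res(0.6, 0.1)]
        dropped = self._res(1.4, 0.1, reliable=False)
        with_all = aggregate_dependent_effects(
            [EffectEstimate(r.proportion_star, 0.1) for r in kept + [dropped]],
            rho=0.0,
        )
        pooled = repool_excluding_unreliable(kept + [dropped], rho=0.0)
        assert with_all.estimate == pytest.approx(0.7333333333)
        assert pooled.estimate == pytest.approx(0.4)

    def test_none_reliable_errors(self):
        with pytest.raises(ValueError):
            repool_excluding_unreliable([self._res(0.5, 0.1, reliable=False)])
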