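"""Seeded Monte-Carlo power analyses for every pipeline stage.

Each function simulates cohorts of N=4,700 (the design's conservative
minimum sample size) under the matching scenario from
:mod:`pgsace.synthetic_data`, runs the corresponding analysis per
replicate, and reports the fraction of replicates rejecting at
``alpha = 0.05`` together with its Monte-Carlo standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import math

import numpy as np

from . import confounding, path_model, rge
from .statcore import aggregate_dependent_effects, EffectEstimate
from .synthetic_data import (
    SimulationConfig,
    make_power_scenario,
    null_scenario,
    simulate_cohort,
)

__all__ = [
    "PowerResult",
    "power_h1a",
    "power_wald",
    "power_mediation",
    "power_gsens",
]


@dataclass(frozen=True)
class PowerResult:
    scenario: str
    reps: int
    n_per_rep: int
    alpha: float
    power: float
    mc_se: float
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _finish(
    scenario: str, rejections: int, reps: int, n: int, alpha: float, seed: int
) -> PowerResult:
    p = rejections / reps
    return PowerResult(
        scenario=scenario,
        reps=reps,
        n_per_rep=n,
        alpha=alpha,
        power=p,
        mc_se=math.sqrt(p * (1.0 - p) / reps),
        seed=seed,
    )


def power_h1a(
    reps: int = 1000,
    n: int = 4700,
    seed: int = 0,
    alpha: float = 0.05,
    rho: float | str = "empirical",
    config: SimulationConfig | None = None,
) -> PowerResult:
    """Power of the pooled score→ACE association test.

    Per replicate: 48 logistic models (8 scores x 6 ACEs, generating
    average odds ratio 1.04), pooled with the dependent-effects composite;
    rejection when the pooled two-sided p-value is below ``alpha``.  By
    default the composite's ``rho`` is the influence-function estimate of
    the dependence actually present among the 48 estimates.
    """
    if reps < 100:
        raise ValueError("reps must be at least 100")
    cfg = config if config is not None else make_power_scenario("h1a", n=n)
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(reps):
        cohort = simulate_cohort(cfg, rng)
        res = rge.run_h1a(cohort, control_set=(), rho=rho)
        if res.pooled_main.p < alpha:
            rej += 1
    return _finish("h1a", rej, reps, cfg.n, alpha, seed)


def power_wald(
    scenario: str,
    reps: int = 1000,
    n: int = 4700,
    seed: int = 0,
    alpha: float = 0.05,
    config: SimulationConfig | None = None,
) -> PowerResult:
    """Power of the Wald equality test across averaged probit effects.

    ``scenario="h1b"`` tests the 8 per-score averages (generating odds
    ratios spanning 1.05–1.16); ``"h1c"`` the 6 per-ACE averages (odds
    ratios spanning 1.05–1.15).
    """
    if scenario not in ("h1b", "h1c", "null"):
        raise ValueError(f"unknown Wald power scenario {scenario!r}")
    if reps < 100:
        raise ValueError("reps must be at least 100")
    axis = "per_pgs" if scenario != "h1c" else "per_ace"
    cfg = config if config is not None else (
        null_scenario(n) if scenario == "null" else make_power_scenario(scenario, n=n)
    )
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(reps):
        cohort = simulate_cohort(cfg, rng)
        pm = path_model.fit_joint_probit(cohort)
        avg = path_model.average_effects(pm, axis)
        if path_model.wald_equality_test(avg)["p"] < alpha:
            rej += 1
    return _finish(scenario, rej, reps, cfg.n, alpha, seed)


def power_mediation(
    reps: int = 1000,
    n: int = 4700,
    seed: int = 0,
    alpha: float = 0.05,
    rho: float = 0.30,
) -> dict:
    """Power of the genetic-confounding tests.

    ``sem_power``: per-model test of a nonzero indirect effect, under the
    stated effect grids (ACE→score r 0.03–0.07, score→outcome r 0.01–0.05
    mapped evenly across the 8 scores, total ACE→outcome r 0.06).
    ``aggregate_power``: test of the pooled proportion across the 6 ACE
    models against zero, under the variant calibrated to a generating
    average proportion of 5%, pooling with ``rho`` (default 0.30).
    """
    if reps < 100:
        raise ValueError("reps must be at least 100")
    cfg_sem = make_power_scenario("h2a", n=n)
    cfg_agg = make_power_scenario("h2a_agg", n=n)
    rng = np.random.default_rng(seed)
    rej_sem = 0
    for _ in range(reps):
        cohort = simulate_cohort(cfg_sem, rng)
        res = confounding.fit_mediation_decomposition(cohort, "ace_mal", "int")
        if res.p_indirect < alpha:
            rej_sem += 1
    rej_agg = 0
    for _ in range(reps):
        cohort = simulate_cohort(cfg_agg, rng)
        results = [
            confounding.fit_mediation_decomposition(cohort, ace, "int")
            for ace in cohort.ace_labels
        ]
        pooled = confounding.pool_proportions(results, rho=rho)
        if pooled.p < alpha:
            rej_agg += 1
    return {
        "sem_power": _finish("h2a_sem", rej_sem, reps, cfg_sem.n, alpha, seed),
        "aggregate_power": _finish("h2a_agg", rej_agg, reps, cfg_agg.n, alpha, seed),
    }


def power_gsens(
    reps: int = 1000,
    n: int = 4700,
    seed: int = 0,
    alpha: float = 0.05,
    config: SimulationConfig | None = None,
) -> PowerResult:
    """Power of the latent-score sensitivity analysis to detect a nonzero
    confounded component.

    Single-score scenario with score→outcome path 0.24, score→ACE
    correlation 0.07 and ACE→outcome correlation 0.06; rejection by the
    normal-theory test of the indirect effect ``a * b = 0``.
    """
    if reps < 100:
        raise ValueError("reps must be at least 100")
    cfg = config if config is not None else make_power_scenario("h2b", n=n)
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(reps):
        cohort = simulate_cohort(cfg, rng)
        res = confounding.fit_mediation_decomposition(
            cohort, "ace_mal", "int", mediator_set=("pgs_latent",)
        )
        if res.p_indirect < alpha:
            rej += 1
    return _finish("h2b", rej, reps, cfg.n, alpha, seed)
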