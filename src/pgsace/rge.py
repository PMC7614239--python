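"""Gene–environment correlation stage: polygenic scores → ACE exposure.

One logistic regression per (polygenic score, ACE) pair — ACE on the score
plus covariates — gives odds ratios per SD of score.  The per-family
results are FDR-adjusted, pooled into a single dependent-effects composite
(mental-health scores and negative controls separately), and the pooled
log odds ratio is tested for equivalence with zero against bounds derived
from the meta-analytic literature (0.94–1.06 by default).

The correlation ``rho`` between the pooled log odds estimates can be fixed
by the user or, with ``rho="empirical"``, estimated from the data as the
average correlation between the per-model influence functions — the
estimates all come from the same individuals, so their sampling errors are
correlated through shared scores and shared ACEs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .statcore import (
    EffectEstimate,
    EquivalenceVerdict,
    PooledEffect,
    Z95,
    aggregate_dependent_effects,
    derive_equivalence_bounds,
    fdr_adjust,
    tost_equivalence,
)
from .synthetic_data import Cohort

__all__ = ["AssocResult", "fit_pgs_ace_logistic", "run_h1a", "H1aResult"]


@dataclass(frozen=True)
class AssocResult:
    """One logistic association: odds of ACE exposure per SD of score."""

    pgs_label: str
    ace_label: str
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p: float
    q: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _design(cohort: Cohort, pgs_label: str, covariates: Sequence[str]) -> np.ndarray:
    cols = [np.ones(cohort.n), cohort.frame[pgs_label].to_numpy(dtype=float)]
    cols += [cohort.frame[c].to_numpy(dtype=float) for c in covariates]
    return np.column_stack(cols)


def fit_pgs_ace_logistic(
    cohort: Cohort,
    pgs_label: str,
    ace_label: str,
    covariates: Sequence[str] = ("sex",),
    _return_fit: bool = False,
):
    """Maximum-likelihood logistic fit of one ACE on one score (+ covariates).

    Individuals with a missing ACE value are dropped.  Raises on a
    single-class ACE or (quasi-)separated fits rather than returning NaNs.
    """
    y = cohort.frame[ace_label].to_numpy(dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    x = _design(cohort, pgs_label, covariates)[keep]
    if y.min() == y.max():
        raise ValueError(
            f"degenerate outcome: ACE {ace_label!r} has a single class"
        )
    if np.ptp(x[:, 1]) == 0:
        raise ValueError(f"constant polygenic score column {pgs_label!r}")
    try:
        fit = sm.Logit(y, x).fit(disp=0)
    except Exception as exc:  # separation surfaces as PerfectSeparationError
        raise ValueError(
            f"logistic fit failed for ({pgs_label}, {ace_label}): {exc}"
        ) from exc
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not (math.isfinite(beta) and math.isfinite(se) and se > 0):
        raise ValueError(
            f"unstable logistic fit for ({pgs_label}, {ace_label}) "
            "(possible separation)"
        )
    res = AssocResult(
        pgs_label=pgs_label,
        ace_label=ace_label,
        beta=beta,
        se=se,
        or_=math.exp(beta),
        ci95=(math.exp(beta - Z95 * se), math.exp(beta + Z95 * se)),
        p=float(fit.pvalues[1]),
    )
    return (res, fit) if _return_fit else res


def _mean_influence_correlation(fits, cohort_n: int) -> float:
    """Average pairwise correlation of the score-coefficient estimates,
    from per-observation influence functions of each logistic fit."""
    cols = []
    for fit in fits:
        iob = fit.model.score_obs(fit.params) @ fit.cov_params()
        cols.append(iob[:, 1])  # influence on the PGS coefficient
    mat = np.column_stack(cols)
    corr = np.corrcoef(mat, rowvar=False)
    m = corr.shape[0]
    if m < 2:
        return 0.0
    rho = (corr.sum() - m) / (m * (m - 1))
    return float(min(max(rho, 0.0), 1.0))


@dataclass(frozen=True)
class H1aResult:
    """Per-pair associations plus pooled composites for both families."""

    main: list[AssocResult]
    control: list[AssocResult]
    pooled_main: PooledEffect
    pooled_control: PooledEffect | None
    verdict_main: EquivalenceVerdict
    verdict_control: EquivalenceVerdict | None
    bounds_or: tuple[float, float]
    rho_used: float

    def to_dict(self) -> dict:
        return {
            "main": [r.to_dict() for r in self.main],
            "control": [r.to_dict() for r in self.control],
            "pooled_main": self.pooled_main.to_dict(),
            "pooled_control": self.pooled_control.to_dict()
            if self.pooled_control
            else None,
            "verdict_main": self.verdict_main.to_dict(),
            "verdict_control": self.verdict_control.to_dict()
            if self.verdict_control
            else None,
            "bounds_or": list(self.bounds_or),
            "rho_used": self.rho_used,
        }


def _family(
    cohort: Cohort,
    pgs_set: Sequence[str],
    ace_set: Sequence[str],
    covariates: Sequence[str],
) -> tuple[list[AssocResult], list]:
    results, fits = [], []
    for pgs in pgs_set:
        for ace in ace_set:
            res, fit = fit_pgs_ace_logistic(
                cohort, pgs, ace, covariates, _return_fit=True
            )
            results.append(res)
            fits.append(fit)
    q = fdr_adjust([r.p for r in results])
    results = [
        AssocResult(**{**r.to_dict(), "q": float(qi), "ci95": r.ci95})
        for r, qi in zip(results, q)
    ]
    return results, fits


def run_h1a(
    cohort: Cohort,
    pgs_set: Sequence[str] | None = None,
    control_set: Sequence[str] | None = None,
    ace_set: Sequence[str] | None = None,
    rho: float | str = 0.30,
    bounds_lower_ci_or: float = 1.06,
    covariates: Sequence[str] = ("sex",),
) -> H1aResult:
    """Full first-stage analysis on one cohort.

    FDR adjustment is applied within the mental-health family and within
    the negative-control family separately.  Pooling uses
    :func:`pgsace.statcore.aggregate_dependent_effects` with ``rho`` either
    a fixed value in [0, 1] or the string ``"empirical"`` (influence-
    function estimate of the average dependence among the estimates).
    Equivalence bounds come from ``derive_equivalence_bounds``.
    """
    pgs_set = tuple(pgs_set if pgs_set is not None else cohort.pgs_labels)
    control_set = tuple(
        control_set if control_set is not None else cohort.control_labels
    )
    ace_set = tuple(ace_set if ace_set is not None else cohort.ace_labels)

    main, main_fits = _family(cohort, pgs_set, ace_set, covariates)
    if control_set:
        control, ctrl_fits = _family(cohort, control_set, ace_set, covariates)
    else:
        control, ctrl_fits = [], []

    if rho == "empirical":
        rho_main = _mean_influence_correlation(main_fits, cohort.n)
        rho_ctrl = _mean_influence_correlation(ctrl_fits, cohort.n) if ctrl_fits else 0.0
    else:
        rho_main = rho_ctrl = float(rho)

    def pool(results: list[AssocResult], r: float) -> PooledEffect:
        return aggregate_dependent_effects(
            [
                EffectEstimate(x.beta, x.se, n=cohort.n, label=f"{x.pgs_label}:{x.ace_label}")
                for x in results
            ],
            rho=r,
        )

    pooled_main = pool(main, rho_main)
    bounds_or = derive_equivalence_bounds(bounds_lower_ci_or)
    log_bounds = (math.log(bounds_or[0]), math.log(bounds_or[1]))
    pooled_control = verdict_control = None
    if control:
        pooled_control = pool(control, rho_ctrl)
        verdict_control = tost_equivalence(
            pooled_control.estimate, pooled_control.se, log_bounds
        )
    return H1aResult(
        main=main,
        control=control,
        pooled_main=pooled_main,
        pooled_control=pooled_control,
        verdict_main=tost_equivalence(pooled_main.estimate, pooled_main.se, log_bounds),
        verdict_control=verdict_control,
        bounds_or=bounds_or,
        rho_used=rho_main,
    )
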