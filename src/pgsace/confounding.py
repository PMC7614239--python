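"""Genetic confounding of ACE–mental-health associations via observed scores.

Mediation and confounding are statistically interchangeable here: treating
the polygenic scores as mediators of the ACE→outcome association, the
genetically confounded share is the indirect effect
``sum_i a_i * b_i`` where ``a_i`` is the standardized ACE→score path and
``b_i`` the score→outcome path adjusted for the ACE and the other scores.
The proportion explained is ``indirect / (indirect + cp)`` with ``cp`` the
adjusted (direct) ACE→outcome path.

All paths are standardized linear projections (OLS on z-scored variables,
the ACE as a z-scored 0/1 indicator), which gives point estimates identical
to the corresponding saturated path model and makes the decomposition
``total = indirect + cp`` an exact algebraic identity.  Standard errors of
the indirect effect and the proportion are delta-method values assembled
from per-observation influence functions; confidence intervals can instead
be nonparametric-bootstrap percentiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .statcore import EffectEstimate, PooledEffect, aggregate_dependent_effects
from .synthetic_data import Cohort

__all__ = ["MediationResult", "fit_mediation_decomposition", "pool_proportions", "run_h2a"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MediationResult:
    """Decomposition of one ACE→outcome association through a mediator set."""

    ace_label: str
    outcome_label: str
    mediator_labels: tuple[str, ...]
    a: np.ndarray
    b: np.ndarray
    cp: float
    indirect: float
    total: float
    proportion: float
    proportion_capped: float  # display value clipped to [0, 1]
    se_indirect: float
    se_total: float
    se_proportion: float
    p_indirect: float
    ci95_proportion: tuple[float, float] | None
    undefined: bool

    def to_dict(self) -> dict:
        return {
            "ace_label": self.ace_label,
            "outcome_label": self.outcome_label,
            "mediator_labels": list(self.mediator_labels),
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "cp": self.cp,
            "indirect": self.indirect,
            "total": self.total,
            "proportion": self.proportion,
            "proportion_capped": self.proportion_capped,
            "se_indirect": self.se_indirect,
            "se_total": self.se_total,
            "se_proportion": self.se_proportion,
            "p_indirect": self.p_indirect,
            "ci95_proportion": list(self.ci95_proportion)
            if self.ci95_proportion is not None
            else None,
            "undefined": self.undefined,
        }


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if not sd > 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def _ols_with_if(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients plus per-observation estimate contributions.

    Returns ``(theta, C)`` with ``C[t] = (X'X)^{-1} x_t e_t`` so that
    ``sum_t C[t] C[t]'`` is the HC0 sandwich covariance of ``theta``.
    """
    xtx_inv = np.linalg.inv(X.T @ X)
    theta = xtx_inv @ (X.T @ y)
    resid = y - X @ theta
    C = (X @ xtx_inv) * resid[:, None]
    return theta, C


def _decompose(
    y: np.ndarray, ace: np.ndarray, M: np.ndarray, covs: np.ndarray
):
    """Point estimates and influence columns for (a, b, cp, indirect, total)."""
    n = y.shape[0]
    ones = np.ones((n, 1))
    Z = np.column_stack([ones, ace[:, None], covs])  # mediator / total design
    X = np.column_stack([ones, ace[:, None], M, covs])  # joint outcome design
    k = M.shape[1]

    # a-paths: each mediator on ACE (+covariates); shared design
    xtx_inv = np.linalg.inv(Z.T @ Z)
    A = xtx_inv @ (Z.T @ M)  # (p, k); row 1 is the ACE coefficient
    a = A[1]
    h = (Z @ xtx_inv)[:, 1]  # per-obs weight giving the ACE coefficient
    resid_M = M - Z @ A
    if_a = h[:, None] * resid_M  # (n, k)

    theta, C = _ols_with_if(X, y)
    cp = float(theta[1])
    b = theta[2 : 2 + k]
    if_cp = C[:, 1]
    if_b = C[:, 2 : 2 + k]

    indirect = float(a @ b)
    total = cp + indirect  # exact identity with the total regression
    if_ind = if_a @ b + if_b @ a
    if_total = if_ind + if_cp
    return a, b, cp, indirect, total, if_ind, if_total


def fit_mediation_decomposition(
    cohort: Cohort,
    ace_label: str,
    outcome_label: str,
    mediator_set: Sequence[str] | None = None,
    covariates: Sequence[str] = ("sex",),
    bootstrap: int = 0,
    seed: int | np.random.Generator | None = None,
    total_tol: float = 1e-8,
) -> MediationResult:
    """Decompose one ACE→outcome association through the mediator scores.

    ``bootstrap > 0`` adds a percentile CI on the proportion from that many
    individual-level resamples (seeded); otherwise the CI is delta-method.
    A total effect smaller than ``total_tol`` in magnitude flags the
    proportion as undefined rather than reporting a meaningless ratio.
    """
    mediator_set = tuple(
        mediator_set if mediator_set is not None else cohort.pgs_labels
    )
    df = cohort.frame
    ace_raw = df[ace_label].to_numpy(dtype=float)
    keep = ~np.isnan(ace_raw)
    if ace_raw[keep].min() == ace_raw[keep].max():
        raise ValueError(f"degenerate outcome: ACE {ace_label!r} has a single class")
    y = _zscore(df[outcome_label].to_numpy(dtype=float)[keep])
    ace = _zscore(ace_raw[keep])
    M = np.column_stack([_zscore(df[c].to_numpy(dtype=float)[keep]) for c in mediator_set])
    covs = np.column_stack(
        [df[c].to_numpy(dtype=float)[keep] for c in covariates]
    ) if covariates else np.empty((keep.sum(), 0))

    a, b, cp, indirect, total, if_ind, if_total = _decompose(y, ace, M, covs)

    se_ind = math.sqrt(float(if_ind @ if_ind))
    se_total = math.sqrt(float(if_total @ if_total))
    undefined = abs(total) < total_tol
    if undefined:
        proportion = math.nan
        se_prop = math.nan
        ci95 = None
    else:
        proportion = indirect / total
        if_prop = if_ind / total - (indirect / total**2) * if_total
        se_prop = math.sqrt(float(if_prop @ if_prop))
        ci95 = (proportion - 1.959964 * se_prop, proportion + 1.959964 * se_prop)

    if bootstrap > 0 and not undefined:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        n = y.shape[0]
        props = np.empty(bootstrap)
        for rep in range(bootstrap):
            idx = rng.integers(0, n, n)
            try:
                *_, ind_r, tot_r, _, _ = _decompose(
                    y[idx], ace[idx], M[idx], covs[idx]
                )
                props[rep] = ind_r / tot_r if abs(tot_r) > total_tol else np.nan
            except (ValueError, np.linalg.LinAlgError):
                props[rep] = np.nan
        ok = props[~np.isnan(props)]
        if ok.size >= max(10, bootstrap // 2):
            ci95 = tuple(np.percentile(ok, [2.5, 97.5]))
        else:
            logger.warning(
                "bootstrap for (%s, %s): %d/%d resamples degenerate; "
                "keeping delta-method CI",
                ace_label,
                outcome_label,
                bootstrap - ok.size,
                bootstrap,
            )

    z = indirect / se_ind if se_ind > 0 else math.inf
    return MediationResult(
        ace_label=ace_label,
        outcome_label=outcome_label,
        mediator_labels=mediator_set,
        a=a,
        b=b,
        cp=cp,
        indirect=indirect,
        total=total,
        proportion=proportion,
        proportion_capped=float(np.clip(proportion, 0.0, 1.0))
        if not undefined
        else math.nan,
        se_indirect=se_ind,
        se_total=se_total,
        se_proportion=se_prop,
        p_indirect=float(2.0 * stats.norm.sf(abs(z))),
        ci95_proportion=ci95,
        undefined=undefined,
    )


def pool_proportions(
    results: Sequence[MediationResult], rho: float = 0.30
) -> PooledEffect:
    """Composite of raw proportions across ACE models.

    No variance-stabilising transform is applied: proportions may be
    negative (opposing direct and indirect effects), so the raw scale is
    pooled.  Results flagged undefined are excluded with a warning.
    """
    usable = [r for r in results if not r.undefined]
    dropped = len(results) - len(usable)
    if dropped:
        logger.warning(
            "excluding %d mediation result(s) with undefined proportion", dropped
        )
    if not usable:
        raise ValueError("no mediation results with a defined proportion to pool")
    return aggregate_dependent_effects(
        [
            EffectEstimate(
                r.proportion, r.se_proportion, label=f"{r.ace_label}:{r.outcome_label}"
            )
            for r in usable
        ],
        rho=rho,
    )


def run_h2a(
    cohort: Cohort,
    ace_set: Sequence[str] | None = None,
    outcome_set: Sequence[str] | None = None,
    mediator_set: Sequence[str] | None = None,
    control_set: Sequence[str] | None = None,
    rho: float = 0.30,
    covariates: Sequence[str] = ("sex",),
    bootstrap: int = 0,
    seed: int | None = None,
) -> dict:
    """Mediation decompositions for every (ACE, outcome) pair, for the
    mental-health mediator family and the negative-control family, with
    pooled proportions per outcome and family."""
    ace_set = tuple(ace_set if ace_set is not None else cohort.ace_labels)
    outcome_set = tuple(
        outcome_set if outcome_set is not None else cohort.outcome_labels
    )
    mediator_set = tuple(
        mediator_set if mediator_set is not None else cohort.pgs_labels
    )
    control_set = tuple(
        control_set if control_set is not None else cohort.control_labels
    )
    rng = np.random.default_rng(seed)
    out: dict = {"per_pair": {}, "pooled": {}}
    for family, meds in (("main", mediator_set), ("control", control_set)):
        if not meds:
            continue
        out["per_pair"][family] = []
        for outcome in outcome_set:
            results = []
            for ace in ace_set:
                try:
                    res = fit_mediation_decomposition(
                        cohort,
                        ace,
                        outcome,
                        meds,
                        covariates=covariates,
                        bootstrap=bootstrap,
                        seed=rng,
                    )
                except ValueError as exc:
                    raise ValueError(f"({ace}, {outcome}, {family}): {exc}") from exc
                results.append(res)
            out["per_pair"][family].extend(results)
            out["pooled"][f"{family}:{outcome}"] = pool_proportions(results, rho=rho)
    return out
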