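"""Shared statistical kernels.

The analyses in this package repeatedly reduce many correlated effect
estimates (log odds ratios, path proportions) from the *same* sample to a
single composite, test that composite for equivalence with zero, and control
the false discovery rate across families of tests.  This module provides
those four kernels:

* :func:`aggregate_dependent_effects` — the Borenstein/Hedges composite of
  ``m`` dependent effect sizes with an assumed (or estimated) common
  correlation ``rho`` between them,
* :func:`tost_equivalence` — two one-sided equivalence testing via the
  "90% CI inside the bounds" rule,
* :func:`derive_equivalence_bounds` — symmetric log-odds equivalence bounds
  from the lower confidence limit of a meta-analytic odds ratio,
* :func:`fdr_adjust` — Benjamini–Hochberg step-up adjustment.

Everything operates on plain floats / numpy arrays and small frozen
dataclasses so results serialize directly to JSON.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EffectEstimate",
    "PooledEffect",
    "EquivalenceVerdict",
    "aggregate_dependent_effects",
    "tost_equivalence",
    "derive_equivalence_bounds",
    "fdr_adjust",
]

Z90 = float(stats.norm.ppf(0.95))  # half-width multiplier of a 90% CI
Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class EffectEstimate:
    """One effect size on an additive scale (log odds, correlation, proportion)."""

    estimate: float
    se: float
    n: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.estimate):
            raise ValueError(f"estimate must be finite, got {self.estimate!r}")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"se must be positive and finite, got {self.se!r}")


@dataclass(frozen=True)
class PooledEffect:
    """Composite of dependent effect sizes: arithmetic mean with a
    correlation-aware variance."""

    estimate: float
    se: float
    ci90: tuple[float, float]
    ci95: tuple[float, float]
    p: float
    rho: float
    m: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EquivalenceVerdict:
    """Outcome of a two one-sided equivalence test on the log-odds scale.

    ``inside`` is the equivalence claim (90% CI entirely within the bounds);
    ``significant`` is the ordinary two-sided test at 5% (95% CI excludes 0).
    The two flags are deliberately independent: an effect can be both
    statistically significant and trivially small.
    """

    ci90: tuple[float, float]
    bounds: tuple[float, float]
    inside: bool
    significant: bool

    def to_dict(self) -> dict:
        return asdict(self)


def aggregate_dependent_effects(
    effects: Sequence[EffectEstimate], rho: float
) -> PooledEffect:
    """Pool ``m`` dependent effect sizes from the same sample.

    The composite is the unweighted arithmetic mean of the estimates.  Its
    variance treats every pair of estimates as correlated at ``rho``::

        var = (1/m^2) * ( sum_i se_i^2 + sum_{i != j} rho * se_i * se_j )

    which for equal standard errors reduces to ``se^2 (1 + (m-1) rho) / m``.
    Confidence intervals and the two-sided p-value are normal-theory, which
    is appropriate because the inputs are asymptotically normal maximum
    likelihood estimates.

    Parameters
    ----------
    effects
        Non-empty list of estimates; all standard errors must be positive.
    rho
        Assumed common correlation between the sampling errors of the
        estimates, in [0, 1].
    """
    if len(effects) == 0:
        raise ValueError("cannot pool an empty list of effects")
    if not (0.0 <= rho <= 1.0):
        raise ValueError(f"rho must lie in [0, 1], got {rho!r}")
    est = np.array([e.estimate for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    m = len(effects)
    pooled = float(est.mean())
    # sum_i se_i^2 + rho * ( (sum se)^2 - sum se^2 )
    s1 = float(np.sum(se**2))
    s2 = float(np.sum(se)) ** 2 - s1
    var = (s1 + rho * s2) / m**2
    pooled_se = math.sqrt(var)
    z = pooled / pooled_se
    p = 2.0 * stats.norm.sf(abs(z))
    return PooledEffect(
        estimate=pooled,
        se=pooled_se,
        ci90=(pooled - Z90 * pooled_se, pooled + Z90 * pooled_se),
        ci95=(pooled - Z95 * pooled_se, pooled + Z95 * pooled_se),
        p=float(p),
        rho=rho,
        m=m,
    )


def tost_equivalence(
    estimate: float,
    se: float,
    bounds: tuple[float, float],
    alpha: float = 0.05,
) -> EquivalenceVerdict:
    """Two one-sided equivalence test of a log-odds effect against ``bounds``.

    Equivalence is declared when the ``(1 - 2*alpha)`` CI (90% at the default
    alpha of 0.05) lies entirely inside the bounds; the CI level compensates
    for testing against the lower and upper bound separately.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError(f"degenerate equivalence bounds {bounds!r}")
    if not se > 0:
        raise ValueError("se must be positive")
    z_eq = stats.norm.ppf(1 - alpha)
    z_sig = stats.norm.ppf(1 - alpha / 2)
    ci90 = (estimate - z_eq * se, estimate + z_eq * se)
    ci95 = (estimate - z_sig * se, estimate + z_sig * se)
    inside = (lo <= ci90[0]) and (ci90[1] <= hi)
    significant = (ci95[0] > 0.0) or (ci95[1] < 0.0)
    return EquivalenceVerdict(
        ci90=ci90, bounds=(lo, hi), inside=inside, significant=significant
    )


def derive_equivalence_bounds(lower_ci_or: float) -> tuple[float, float]:
    """Equivalence bounds on the odds-ratio scale from a meta-analytic
    lower confidence limit.

    The upper bound is the lower confidence limit itself; the lower bound is
    its reflection through 1 on the log-odds scale, so the band is symmetric
    in log odds.  E.g. 1.06 yields (0.94, 1.06) at two-decimal display
    precision; full precision is returned.
    """
    if not (lower_ci_or > 0 and math.isfinite(lower_ci_or)):
        raise ValueError(f"lower CI odds ratio must be positive, got {lower_ci_or!r}")
    return (math.exp(-math.log(lower_ci_or)), lower_ci_or)


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
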