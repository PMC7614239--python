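"""Latent polygenic-score sensitivity analysis of genetic confounding.

Observed polygenic scores capture only a fraction of SNP heritability, so
the indirect effect through them underestimates genetic confounding.  This
sensitivity analysis replaces the observed composite score with a latent
score whose outcome path equals ``sqrt(h2)`` — the full SNP heritability
of the outcome — while scaling its ACE path by the observed ratio
``k = a / b`` of the ACE path to the outcome path.  The adjusted paths are

    b* = sqrt(h2),    a* = k * b*,    cp* = r_am - a* b*

so the observed total ACE→outcome correlation ``r_am`` is preserved and
the adjusted confounded proportion is ``a* b* / r_am``.

An alternative "matrix" mode writes the implied marginal correlations of
the latent score into the 3x3 correlation matrix and re-solves the path
model; with the implied-correlation construction the two modes coincide.

Bootstrap machinery recomputes the whole chain (composite score,
correlations, ``k``, adjustment) per resample and flags estimates whose
confidence intervals are unreliable (proportion at or beyond 1, direct
path changing sign across resamples, non-finite endpoints), mirroring the
robustness rule of excluding such estimates before re-pooling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .statcore import EffectEstimate, PooledEffect, aggregate_dependent_effects
from .synthetic_data import Cohort

__all__ = [
    "GsensScenario",
    "GsensResult",
    "observed_paths_from_corr",
    "gsens_adjust",
    "gsens_ci",
    "repool_excluding_unreliable",
]


@dataclass(frozen=True)
class GsensScenario:
    """Observed correlations and heritability input to the adjustment.

    ``r_ap``: composite score ↔ ACE; ``r_pm``: composite score ↔ outcome;
    ``r_am``: ACE ↔ outcome; ``h2``: SNP heritability of the outcome;
    ``k``: ratio of the observed ACE path to the observed outcome path.
    """

    r_ap: float
    r_pm: float
    r_am: float
    h2: float
    k: float
    n: int | None = None

    def __post_init__(self) -> None:
        for name in ("r_ap", "r_pm", "r_am"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1), got {v}")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError(f"h2 must lie in (0, 1), got {self.h2}")
        if not math.isfinite(self.k):
            raise ValueError("k must be finite")


@dataclass(frozen=True)
class GsensResult:
    """Latent-score adjusted paths and confounded proportion."""

    a_star: float
    b_star: float
    cp_star: float
    indirect_star: float
    proportion_star: float
    ci95: tuple[float, float] | None = None
    reliable: bool = True
    undefined: bool = False
    se_proportion: float | None = None

    def to_dict(self) -> dict:
        d = {
            "a_star": self.a_star,
            "b_star": self.b_star,
            "cp_star": self.cp_star,
            "indirect_star": self.indirect_star,
            "proportion_star": self.proportion_star,
            "reliable": self.reliable,
            "undefined": self.undefined,
        }
        d["ci95"] = list(self.ci95) if self.ci95 is not None else None
        d["se_proportion"] = self.se_proportion
        return d


def observed_paths_from_corr(
    r_ap: float, r_pm: float, r_am: float
) -> tuple[float, float, float]:
    """Path coefficients (a, b, cp) implied by the 3x3 correlation matrix.

    ``a`` is the score→ACE correlation; ``(b, cp)`` solve the two-predictor
    normal equations for the outcome on (score, ACE).  Path tracing then
    reproduces the observed ACE–outcome correlation exactly:
    ``cp + a*b = r_am``.
    """
    corr = np.array([[1.0, r_ap, r_pm], [r_ap, 1.0, r_am], [r_pm, r_am, 1.0]])
    if np.linalg.eigvalsh(corr)[0] <= 0:
        raise ValueError("correlation matrix (score, ACE, outcome) is not positive definite")
    b, cp = np.linalg.solve(
        np.array([[1.0, r_ap], [r_ap, 1.0]]), np.array([r_pm, r_am])
    )
    return float(r_ap), float(b), float(cp)


def gsens_adjust(
    scenario: GsensScenario,
    mode: str = "paths",
    total_tol: float = 1e-10,
) -> GsensResult:
    """Adjusted confounding under a latent score capturing SNP heritability.

    ``mode="paths"`` sets the paths directly (b* = sqrt(h2), a* = k b*,
    cp* = r_am - a* b*).  ``mode="matrix"`` writes the latent score's
    implied marginal correlations (r_ap' = a*, r_pm' = b* + a* cp*) into
    the correlation matrix and re-solves the path model; by construction
    of the implied correlations the solved paths coincide with the direct
    ones whenever the modified matrix is positive definite.
    """
    b_star = math.sqrt(scenario.h2)
    a_star = scenario.k * b_star
    cp_star = scenario.r_am - a_star * b_star
    if mode == "matrix":
        r_pm_new = b_star + a_star * cp_star
        a_chk, b_star, cp_star = observed_paths_from_corr(
            a_star, r_pm_new, scenario.r_am
        )
        a_star = a_chk
    elif mode != "paths":
        raise ValueError(f"unknown adjustment mode {mode!r}")
    indirect = a_star * b_star
    if abs(scenario.r_am) < total_tol:
        return GsensResult(
            a_star=a_star,
            b_star=b_star,
            cp_star=cp_star,
            indirect_star=indirect,
            proportion_star=math.nan,
            undefined=True,
            reliable=False,
        )
    return GsensResult(
        a_star=a_star,
        b_star=b_star,
        cp_star=cp_star,
        indirect_star=indirect,
        proportion_star=indirect / scenario.r_am,
    )


# ---------------------------------------------------------------------------
# cohort-level estimation with bootstrap


def _composite_scenario(
    y: np.ndarray, ace: np.ndarray, M: np.ndarray, h2: float
) -> GsensScenario:
    """Observed-path scenario with the composite score built as the
    b-weighted combination of the individual scores."""
    n, k = M.shape
    # partial outcome paths of each score given the ACE and other scores
    X = np.column_stack([np.ones(n), ace, M])
    theta = np.linalg.lstsq(X, y, rcond=None)[0]
    w = theta[2:]
    if np.allclose(w, 0):
        raise ValueError("all score→outcome paths are zero; composite undefined")
    comp = M @ w
    sd = comp.std()
    if not sd > 0:
        raise ValueError("degenerate composite score")
    comp = (comp - comp.mean()) / sd
    r_ap = float(np.corrcoef(comp, ace)[0, 1])
    r_pm = float(np.corrcoef(comp, y)[0, 1])
    r_am = float(np.corrcoef(ace, y)[0, 1])
    _, b_obs, _ = observed_paths_from_corr(r_ap, r_pm, r_am)
    a_obs = r_ap
    if b_obs == 0:
        raise ValueError("observed composite outcome path is zero; k undefined")
    return GsensScenario(
        r_ap=r_ap, r_pm=r_pm, r_am=r_am, h2=h2, k=a_obs / b_obs, n=n
    )


def gsens_ci(
    cohort: Cohort,
    ace_label: str,
    outcome_label: str,
    h2: float,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    mediator_set: Sequence[str] | None = None,
    mode: str = "paths",
) -> GsensResult:
    """Latent-score adjusted proportion with a bootstrap percentile CI.

    Per resample the composite score, the observed correlations, ``k`` and
    the adjusted proportion are all recomputed.  ``reliable`` is False when
    the point proportion reaches 1, the adjusted direct path changes sign
    in at least 5% of resamples, or a CI endpoint is non-finite.
    """
    if B < 100:
        raise ValueError("B must be at least 100 for a percentile CI")
    mediator_set = tuple(
        mediator_set if mediator_set is not None else cohort.pgs_labels
    )
    df = cohort.frame
    ace_raw = df[ace_label].to_numpy(dtype=float)
    keep = ~np.isnan(ace_raw)
    ace = ace_raw[keep]
    if ace.min() == ace.max():
        raise ValueError(f"degenerate outcome: ACE {ace_label!r} has a single class")
    ace = (ace - ace.mean()) / ace.std()
    y = df[outcome_label].to_numpy(dtype=float)[keep]
    y = (y - y.mean()) / y.std()
    M = df[list(mediator_set)].to_numpy(dtype=float)[keep]
    M = (M - M.mean(axis=0)) / M.std(axis=0)

    scen = _composite_scenario(y, ace, M, h2)
    point = gsens_adjust(scen, mode=mode)

    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    n = y.shape[0]
    props = np.full(B, np.nan)
    cp_signs = np.zeros(B)
    n_degenerate = 0
    for rep in range(B):
        idx = rng.integers(0, n, n)
        try:
            s = _composite_scenario(y[idx], ace[idx], M[idx], h2)
            r = gsens_adjust(s, mode=mode)
        except (ValueError, np.linalg.LinAlgError):
            n_degenerate += 1
            continue
        props[rep] = r.proportion_star
        cp_signs[rep] = math.copysign(1.0, r.cp_star) if r.cp_star != 0 else 0.0
    ok = ~np.isnan(props)
    if n_degenerate:
        import logging

        logging.getLogger(__name__).warning(
            "gsens bootstrap (%s, %s): %d/%d degenerate resamples",
            ace_label,
            outcome_label,
            n_degenerate,
            B,
        )
    if ok.sum() < B // 2:
        raise ValueError("more than half of the bootstrap resamples were degenerate")
    ci = tuple(np.percentile(props[ok], [2.5, 97.5]))
    se = float(np.std(props[ok]))

    sign_point = math.copysign(1.0, point.cp_star) if point.cp_star != 0 else 0.0
    frac_flip = float(np.mean(cp_signs[ok] != sign_point))
    reliable = (
        point.proportion_star < 1.0
        and frac_flip < 0.05
        and all(math.isfinite(c) for c in ci)
        and not point.undefined
    )
    return GsensResult(
        a_star=point.a_star,
        b_star=point.b_star,
        cp_star=point.cp_star,
        indirect_star=point.indirect_star,
        proportion_star=point.proportion_star,
        ci95=(float(ci[0]), float(ci[1])),
        reliable=bool(reliable),
        undefined=point.undefined,
        se_proportion=se,
    )


def repool_excluding_unreliable(
    results: Sequence[GsensResult], rho: float = 0.30
) -> PooledEffect:
    """Pooled adjusted proportion over the reliable results only."""
    usable = [
        r
        for r in results
        if r.reliable and not r.undefined and r.se_proportion is not None
    ]
    if not usable:
        raise ValueError("no reliable latent-score results to pool")
    return aggregate_dependent_effects(
        [EffectEstimate(r.proportion_star, r.se_proportion) for r in usable],
        rho=rho,
    )
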