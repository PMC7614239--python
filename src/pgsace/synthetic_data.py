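"""Synthetic cohorts with the statistical structure of the real analyses.

The downstream stages (gene–environment correlation, genetic confounding,
sensitivity and power analyses) were designed for access-restricted birth
cohorts.  This module generates cohorts with the same statistical anatomy so
every stage is testable end to end:

* standardized polygenic scores (PGS) with exchangeable inter-score
  correlation, all loading on one latent genetic factor ``G``;
* negative-control scores drawn independently of everything else;
* binary adverse childhood experiences (ACEs) generated on the liability
  (probit) scale: each liability is a linear combination of the PGS, a
  shared "adversity" factor ``A`` that induces the inter-ACE tetrachoric
  correlation, and Gaussian noise, thresholded at the target prevalence;
* continuous outcomes (internalising / externalising problems) built from
  ``sqrt(h2) * G``, optional direct PGS paths, and centred ACE effects.

PGS effects on ACEs are specified either as marginal odds ratios (the scale
used in the literature) and converted to liability-scale slopes by numeric
calibration (:func:`calibrate_liability_effect`), or directly as marginal
point-biserial correlations (the scale of the mediation analyses).

Also included are the cohort phenotype-scoring rules the real studies use:
the ">=50% of items answered" rule for deriving a binary ACE indicator, and
the standardize–sum–standardize construction of composite mental-health
scores from questionnaire subscales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PGS_LABELS",
    "CONTROL_LABELS",
    "ACE_LABELS",
    "OUTCOME_LABELS",
    "SimulationConfig",
    "Cohort",
    "simulate_cohort",
    "calibrate_liability_effect",
    "make_power_scenario",
    "derive_ace_indicator",
    "composite_mental_health_score",
]

# Column-label contract shared with the IO layer.  The eight mental-health
# scores cover depression, anxiety, bipolar disorder, autism, ADHD,
# antisocial behaviour, alcohol use disorder and schizophrenia; the two
# negative controls are handedness and cataracts.
PGS_LABELS = (
    "pgs_dep",
    "pgs_anx",
    "pgs_bip",
    "pgs_asd",
    "pgs_adhd",
    "pgs_asb",
    "pgs_alc",
    "pgs_scz",
)
CONTROL_LABELS = ("pgs_hand", "pgs_cat")
# maltreatment, domestic violence, parental mental illness, parental
# substance abuse, parental criminality, parental separation
ACE_LABELS = ("ace_mal", "ace_dvi", "ace_pmi", "ace_psu", "ace_pcr", "ace_sep")
OUTCOME_LABELS = ("int", "ext")

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of one synthetic cohort.

    Effects of the PGS on the ACEs are given either as ``or_matrix``
    (marginal odds ratios per SD of score, shape ``n_pgs x n_ace``) or as
    ``r_pb_matrix`` (marginal point-biserial correlations, same shape);
    exactly one may be non-None, and ``None`` for both means no effect.

    ACE effects on the outcomes are given either as ``delta_ace``, the
    *direct* standardized path from each centred ACE indicator to each
    outcome (shape ``n_ace x n_outcome``), or as ``ace_outcome_r``, the
    target *marginal* ACE–outcome correlations (same shape), from which the
    direct paths are solved given the ACE correlation structure; at most one
    may be non-None, and both ``None`` defaults to marginal correlations of
    0.06 everywhere.  ``beta_pgs`` holds optional direct standardized
    PGS->outcome paths (``n_pgs x n_outcome``).
    ``h2`` is the outcome variance carried by the latent genetic factor
    shared with the PGS (SNP heritability; defaults 0.06 internalising,
    0.09 externalising).
    """

    n: int = 4700
    n_pgs: int = 8
    n_controls: int = 2
    rho_pgs: float = 0.06
    ace_prevalence: tuple[float, ...] = (0.20,) * 6
    r_ace: float = 0.30
    or_matrix: tuple[tuple[float, ...], ...] | None = None
    r_pb_matrix: tuple[tuple[float, ...], ...] | None = None
    h2: tuple[float, ...] = (0.06, 0.09)
    delta_ace: tuple[tuple[float, ...], ...] | None = None
    ace_outcome_r: tuple[tuple[float, ...], ...] | None = None
    beta_pgs: tuple[tuple[float, ...], ...] | None = None
    sex_prevalence_female: float = 0.49
    missing_rate: float = 0.0
    pgs_labels: tuple[str, ...] = PGS_LABELS
    control_labels: tuple[str, ...] = CONTROL_LABELS
    ace_labels: tuple[str, ...] = ACE_LABELS
    outcome_labels: tuple[str, ...] = OUTCOME_LABELS

    @property
    def n_ace(self) -> int:
        return len(self.ace_prevalence)

    @property
    def n_outcomes(self) -> int:
        return len(self.h2)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if not -1.0 < self.rho_pgs < 1.0:
            raise ValueError("rho_pgs must lie in (-1, 1)")
        if not -1.0 < self.r_ace < 1.0:
            raise ValueError("r_ace must lie in (-1, 1)")
        for p in self.ace_prevalence:
            if not 0.0 < p < 1.0:
                raise ValueError(f"ACE prevalence {p} outside (0, 1)")
        for h in self.h2:
            if not 0.0 <= h < 1.0:
                raise ValueError(f"h2 {h} outside [0, 1)")
        if self.or_matrix is not None and self.r_pb_matrix is not None:
            raise ValueError("specify or_matrix or r_pb_matrix, not both")
        if self.delta_ace is not None and self.ace_outcome_r is not None:
            raise ValueError("specify delta_ace or ace_outcome_r, not both")
        if len(self.pgs_labels) != self.n_pgs:
            raise ValueError("pgs_labels length must equal n_pgs")
        if len(self.control_labels) != self.n_controls:
            raise ValueError("control_labels length must equal n_controls")
        if len(self.ace_labels) != self.n_ace:
            raise ValueError("ace_labels length must match ace_prevalence")

    # -- resolved numeric views ------------------------------------------

    def beta(self) -> np.ndarray:
        if self.beta_pgs is None:
            return np.zeros((self.n_pgs, self.n_outcomes))
        b = np.asarray(self.beta_pgs, dtype=float)
        if b.shape != (self.n_pgs, self.n_outcomes):
            raise ValueError("beta_pgs must have shape (n_pgs, n_outcomes)")
        return b


@dataclass
class Cohort:
    """A simulated or loaded cohort; ``frame`` is the canonical container."""

    frame: pd.DataFrame
    pgs_labels: tuple[str, ...] = PGS_LABELS
    control_labels: tuple[str, ...] = CONTROL_LABELS
    ace_labels: tuple[str, ...] = ACE_LABELS
    outcome_labels: tuple[str, ...] = OUTCOME_LABELS

    @property
    def n(self) -> int:
        return len(self.frame)

    def pgs(self, label: str) -> np.ndarray:
        return self.frame[label].to_numpy(dtype=float)

    def ace(self, label: str) -> np.ndarray:
        return self.frame[label].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# odds-ratio <-> liability-slope calibration


def _gauss_hermite_nodes(k: int = 64) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(k)
    return x * _SQRT2, w / math.sqrt(math.pi)


_GH_X, _GH_W = _gauss_hermite_nodes()


def _marginal_logistic_beta(gamma: float, prevalence: float) -> float:
    """Large-sample logistic slope of a thresholded liability on the score.

    The liability is ``L = gamma*S + sqrt(1-gamma^2)*eps`` with ``S, eps``
    standard normal, thresholded at the ``1 - prevalence`` quantile.  The
    population logistic MLE ``(alpha, beta)`` solves the score equations
    ``E[(p(S) - expit(a + b S)) * (1, S)] = 0`` with
    ``p(S) = Phi((gamma*S - tau)/sqrt(1-gamma^2))``, evaluated here by
    Gauss–Hermite quadrature.
    """
    if gamma == 0.0:
        return 0.0
    tau = stats.norm.ppf(1.0 - prevalence)
    s = _GH_X
    p_true = stats.norm.cdf((gamma * s - tau) / math.sqrt(1.0 - gamma**2))

    def score(ab: np.ndarray) -> np.ndarray:
        resid = p_true - 1.0 / (1.0 + np.exp(-(ab[0] + ab[1] * s)))
        return np.array([np.sum(_GH_W * resid), np.sum(_GH_W * resid * s)])

    x0 = np.array([math.log(prevalence / (1 - prevalence)), 1.7 * gamma])
    sol = optimize.root(score, x0, tol=1e-12)
    if not sol.success:  # pragma: no cover - quadrature root is well behaved
        raise RuntimeError(f"logistic calibration failed: {sol.message}")
    return float(sol.x[1])


def calibrate_liability_effect(
    target_or: float, prevalence: float, tol: float = 1e-3
) -> float:
    """Liability-scale slope producing a given marginal logistic odds ratio.

    Returns ``gamma`` such that the population logistic regression of the
    thresholded trait on a standard-normal score has ``exp(beta)`` equal to
    ``target_or`` within ``tol``.  For a single score, ``gamma`` equals the
    score–liability correlation, so the value doubles as the marginal
    liability correlation target when several correlated scores contribute
    to the same liability.
    """
    if not (target_or > 0 and math.isfinite(target_or)):
        raise ValueError(f"target_or must be positive, got {target_or!r}")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    if target_or == 1.0:
        return 0.0
    if target_or < 1.0:
        return -calibrate_liability_effect(1.0 / target_or, prevalence, tol)
    log_target = math.log(target_or)

    def f(g: float) -> float:
        return _marginal_logistic_beta(g, prevalence) - log_target

    hi = 0.95
    if f(hi) < 0:
        raise ValueError(
            f"no liability slope in (0, {hi}) achieves odds ratio {target_or}"
        )
    gamma = optimize.brentq(f, 0.0, hi, xtol=1e-10)
    achieved = math.exp(_marginal_logistic_beta(gamma, prevalence))
    if abs(achieved - target_or) > tol:  # pragma: no cover
        raise RuntimeError("calibration did not reach requested tolerance")
    return float(gamma)


# ---------------------------------------------------------------------------
# pieces of the generative model


def _pgs_corr(n_pgs: int, rho: float) -> np.ndarray:
    r = np.full((n_pgs, n_pgs), rho)
    np.fill_diagonal(r, 1.0)
    return r


def _biserial_factor(tau: float, p: float) -> float:
    """d corr(score, indicator) / d corr(score, liability): phi(tau)/sd."""
    return stats.norm.pdf(tau) / math.sqrt(p * (1.0 - p))


def _liability_targets(config: SimulationConfig) -> np.ndarray:
    """Marginal score–liability correlations r*[i, j] per (PGS i, ACE j)."""
    shape = (config.n_pgs, config.n_ace)
    if config.or_matrix is not None:
        ors = np.asarray(config.or_matrix, dtype=float)
        if ors.shape != shape:
            raise ValueError(f"or_matrix must have shape {shape}")
        out = np.zeros(shape)
        cache: dict[tuple[float, float], float] = {}
        for j, prev in enumerate(config.ace_prevalence):
            for i in range(config.n_pgs):
                key = (ors[i, j], prev)
                if key not in cache:
                    cache[key] = calibrate_liability_effect(*key)
                out[i, j] = cache[key]
        return out
    if config.r_pb_matrix is not None:
        rpb = np.asarray(config.r_pb_matrix, dtype=float)
        if rpb.shape != shape:
            raise ValueError(f"r_pb_matrix must have shape {shape}")
        taus = stats.norm.ppf(1.0 - np.asarray(config.ace_prevalence))
        fac = np.array(
            [_biserial_factor(t, p) for t, p in zip(taus, config.ace_prevalence)]
        )
        return rpb / fac[None, :]
    return np.zeros(shape)


def _tetrachoric_phi(r: float, tau1: float, tau2: float, p1: float, p2: float) -> float:
    """Pearson (phi) correlation of two thresholded liabilities with
    latent correlation ``r``."""
    if r == 0.0:
        return 0.0
    p11 = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]]
    ).cdf([-tau1, -tau2])
    # P(L1 > tau1, L2 > tau2) by symmetry of the centred normal
    return (p11 - p1 * p2) / math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


def _ace_structure(config: SimulationConfig) -> tuple[np.ndarray, float, np.ndarray]:
    """Solve liability loadings: returns (gamma [n_pgs x n_ace], lam, taus).

    ``gamma`` are the per-ACE PGS slopes solving ``R gamma = r*`` so each
    score hits its marginal target; ``lam`` is the common loading on the
    shared adversity factor chosen so the average cross-ACE liability
    correlation equals ``r_ace``.
    """
    R = _pgs_corr(config.n_pgs, config.rho_pgs)
    rstar = _liability_targets(config)
    gamma = np.linalg.solve(R, rstar)
    taus = stats.norm.ppf(1.0 - np.asarray(config.ace_prevalence))
    cross = gamma.T @ R @ gamma  # [j, k] = liability corr from shared PGS
    m = config.n_ace
    if m > 1:
        off = (cross.sum() - np.trace(cross)) / (m * (m - 1))
    else:
        off = 0.0
    lam_sq = config.r_ace - off
    if lam_sq < -1e-12:
        raise ValueError(
            "inter-ACE correlation target below the correlation already "
            f"induced by shared PGS effects ({off:.3f}); adversity-factor "
            "loading would be imaginary"
        )
    lam = math.sqrt(max(lam_sq, 0.0))
    for j, lbl in enumerate(config.ace_labels):
        resid = 1.0 - cross[j, j] - lam**2
        if resid <= 0:
            raise ValueError(
                f"liability variance of {lbl} exceeds 1 (non-PSD block): "
                f"PGS part {cross[j, j]:.3f} + adversity {lam ** 2:.3f}"
            )
    return gamma, lam, taus


@lru_cache(maxsize=32)
def _compiled(config: SimulationConfig) -> dict:
    """Deterministic model structure for a config (cached across draws)."""
    if config.rho_pgs < 0:
        raise ValueError("negative inter-PGS correlation is not supported")
    gamma, lam, taus = _ace_structure(config)
    R = _pgs_corr(config.n_pgs, config.rho_pgs)
    pgs_part_var = np.einsum("ij,ik,jk->k", R, gamma, gamma)
    ace_resid_sd = np.sqrt(1.0 - pgs_part_var - lam**2)

    beta = config.beta()
    rho = config.rho_pgs
    rstar = R @ gamma  # marginal score-liability correlations actually induced
    bis = np.array(
        [_biserial_factor(t, p) for t, p in zip(taus, config.ace_prevalence)]
    )
    a_pb = rstar * bis[None, :]  # marginal point-biserial corr(PGS_i, ACE*_j)
    g_pb = math.sqrt(rho) * gamma.sum(axis=0) * bis  # corr(G, ACE*_j)
    phi = np.eye(config.n_ace)
    liab_corr = gamma.T @ R @ gamma + lam**2
    for j in range(config.n_ace):
        for jj in range(j + 1, config.n_ace):
            phi[j, jj] = phi[jj, j] = _tetrachoric_phi(
                liab_corr[j, jj],
                taus[j],
                taus[jj],
                config.ace_prevalence[j],
                config.ace_prevalence[jj],
            )

    shape = (config.n_ace, config.n_outcomes)
    if config.delta_ace is not None:
        delta = np.asarray(config.delta_ace, dtype=float)
        if delta.shape != shape:
            raise ValueError("delta_ace must have shape (n_ace, n_outcomes)")
    else:
        if config.ace_outcome_r is not None:
            r_marg = np.asarray(config.ace_outcome_r, dtype=float)
            if r_marg.shape != shape:
                raise ValueError("ace_outcome_r must have shape (n_ace, n_outcomes)")
        else:
            r_marg = np.full(shape, 0.06)
        # marginal corr(outcome_m, ACE*_j) =
        #   sqrt(h2_m) g_pb_j + (a_pb' beta)_j + (phi delta)_j
        delta = np.empty(shape)
        for m, h2 in enumerate(config.h2):
            rhs = r_marg[:, m] - math.sqrt(h2) * g_pb - a_pb.T @ beta[:, m]
            delta[:, m] = np.linalg.solve(phi, rhs)

    outcome_resid_sd = np.empty(config.n_outcomes)
    for m, h2 in enumerate(config.h2):
        # model-implied variance of the systematic part, to size the residual
        v = h2 + beta[:, m] @ R @ beta[:, m]
        v += delta[:, m] @ phi @ delta[:, m]
        v += 2.0 * math.sqrt(h2) * float(g_pb @ delta[:, m])
        v += 2.0 * float(beta[:, m] @ a_pb @ delta[:, m])
        v += 2.0 * math.sqrt(h2) * math.sqrt(rho) * float(beta[:, m].sum())
        resid_var = 1.0 - v
        if resid_var <= 0.05:
            raise ValueError(
                f"outcome {config.outcome_labels[m]}: systematic variance "
                f"{v:.3f} leaves no room for residual noise"
            )
        outcome_resid_sd[m] = math.sqrt(resid_var)
    return {
        "gamma": gamma,
        "lam": lam,
        "taus": taus,
        "ace_resid_sd": ace_resid_sd,
        "delta": delta,
        "beta": beta,
        "a_pb": a_pb,
        "outcome_resid_sd": outcome_resid_sd,
    }


def simulate_cohort(
    config: SimulationConfig,
    seed: int | np.random.Generator,
    include_latent: bool = False,
) -> Cohort:
    """Draw one cohort under ``config``; bit-reproducible for a fixed seed.

    ``include_latent`` adds the latent genetic factor as a diagnostic column
    ``g_latent`` (useful for checking the heritability share of the
    outcomes); it is not part of the cohort file contract.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    model = _compiled(config)
    n, k, kc = config.n, config.n_pgs, config.n_controls
    rho = config.rho_pgs

    g = rng.standard_normal(n)
    pgs = math.sqrt(rho) * g[:, None] + math.sqrt(1.0 - rho) * rng.standard_normal(
        (n, k)
    )
    controls = rng.standard_normal((n, kc)) if kc else np.empty((n, 0))

    gamma, lam, taus = model["gamma"], model["lam"], model["taus"]
    adversity = rng.standard_normal(n)
    ace = np.empty((n, config.n_ace), dtype=float)
    for j in range(config.n_ace):
        liab = (
            pgs @ gamma[:, j]
            + lam * adversity
            + model["ace_resid_sd"][j] * rng.standard_normal(n)
        )
        ace[:, j] = (liab > taus[j]).astype(float)

    prev = np.asarray(config.ace_prevalence)
    ace_std = (ace - prev[None, :]) / np.sqrt(prev * (1 - prev))[None, :]

    delta, beta = model["delta"], model["beta"]
    outcomes = np.empty((n, config.n_outcomes))
    for m, h2 in enumerate(config.h2):
        sys = math.sqrt(h2) * g + pgs @ beta[:, m] + ace_std @ delta[:, m]
        y = sys + model["outcome_resid_sd"][m] * rng.standard_normal(n)
        outcomes[:, m] = (y - y.mean()) / y.std()

    sex = (rng.random(n) < config.sex_prevalence_female).astype(int)

    data: dict[str, np.ndarray] = {"id": np.arange(1, n + 1), "sex": sex}
    for i, lbl in enumerate(config.pgs_labels):
        data[lbl] = pgs[:, i]
    for i, lbl in enumerate(config.control_labels):
        data[lbl] = controls[:, i]
    for j, lbl in enumerate(config.ace_labels):
        data[lbl] = ace[:, j]
    for m, lbl in enumerate(config.outcome_labels):
        data[lbl] = outcomes[:, m]
    if include_latent:
        data["g_latent"] = g
    frame = pd.DataFrame(data)

    if config.missing_rate > 0:
        mask = rng.random((n, config.n_ace)) < config.missing_rate
        for j, lbl in enumerate(config.ace_labels):
            col = frame[lbl].to_numpy(dtype=float)
            col[mask[:, j]] = np.nan
            frame[lbl] = col

    return Cohort(
        frame=frame,
        pgs_labels=config.pgs_labels,
        control_labels=config.control_labels,
        ace_labels=config.ace_labels,
        outcome_labels=config.outcome_labels,
    )


# ---------------------------------------------------------------------------
# power-analysis scenarios


def _even_grid(lo: float, hi: float, k: int) -> np.ndarray:
    return np.linspace(lo, hi, k)


def make_power_scenario(name: str, n: int = 4700) -> SimulationConfig:
    """Configs encoding the pre-registered power-analysis conditions.

    All scenarios use N=4,700, inter-PGS correlation 0.06, inter-ACE
    tetrachoric correlation 0.30 and a common ACE prevalence of 0.20 (the
    prevalences used in the original power work are not published; 0.20 is
    a typical childhood-adversity prevalence and is configurable).

    ``h1a``   every PGS->ACE marginal odds ratio 1.04 (average OR 1.04).
    ``h1b``   per-PGS odds ratios evenly spaced 1.05..1.16.
    ``h1c``   per-ACE odds ratios evenly spaced 1.05..1.15.
    ``h2a``   mediation grids: ACE->PGS r 0.03..0.07, PGS->outcome r
              0.01..0.05 mapped evenly across the 8 scores, total ACE->
              outcome correlation 0.06.
    ``h2a_agg`` as ``h2a`` with the outcome paths rescaled so the
              generating proportion of the ACE–outcome association
              explained by the scores is exactly 5%.
    ``h2b``   one latent score: score->outcome path 0.24, score->ACE
              correlation 0.07, direct ACE->outcome path 0.06.
    """
    k, m = 8, 6
    prev = (0.20,) * m
    if name == "h1a":
        return SimulationConfig(
            n=n, ace_prevalence=prev, or_matrix=((1.04,) * m,) * k
        )
    if name == "h1b":
        ors = _even_grid(1.05, 1.16, k)
        return SimulationConfig(
            n=n,
            ace_prevalence=prev,
            or_matrix=tuple((float(o),) * m for o in ors),
        )
    if name == "h1c":
        ors = _even_grid(1.05, 1.15, m)
        return SimulationConfig(
            n=n,
            ace_prevalence=prev,
            or_matrix=(tuple(float(o) for o in ors),) * k,
        )
    if name in ("h2a", "h2a_agg"):
        a = _even_grid(0.03, 0.07, k)
        b = _even_grid(0.01, 0.05, k)
        total = 0.06
        if name == "h2a_agg":
            b = b * (0.05 * total) / float(a @ b)
        return SimulationConfig(
            n=n,
            ace_prevalence=prev,
            r_pb_matrix=tuple((float(x),) * m for x in a),
            h2=(0.0, 0.0),
            beta_pgs=tuple((float(x), float(x)) for x in b),
            ace_outcome_r=((total, total),) * m,
        )
    if name == "h2b":
        a, b, total = 0.07, 0.24, 0.06
        return SimulationConfig(
            n=n,
            n_pgs=1,
            n_controls=0,
            rho_pgs=0.0,
            ace_prevalence=(0.20,),
            r_ace=0.0,
            r_pb_matrix=((a,),),
            h2=(0.0,),
            beta_pgs=((b,),),
            ace_outcome_r=((total,),),
            pgs_labels=("pgs_latent",),
            control_labels=(),
            ace_labels=("ace_mal",),
            outcome_labels=("int",),
        )
    raise ValueError(f"unknown power scenario {name!r}")


def null_scenario(n: int = 4700) -> SimulationConfig:
    """All PGS->ACE and ACE->outcome effects zero; used for size control."""
    return SimulationConfig(
        n=n, or_matrix=((1.0,) * 6,) * 8, delta_ace=((0.0, 0.0),) * 6
    )


# ---------------------------------------------------------------------------
# phenotype-scoring rules


def derive_ace_indicator(
    responses: Sequence[float],
    min_prop: float = 0.5,
    rule: Literal["any", "all"] = "any",
) -> float:
    """Binary ACE indicator from item-level responses.

    Returns NaN when fewer than ``min_prop`` of the items were answered;
    otherwise 1.0 if any (default) or all answered items are positive,
    else 0.0.
    """
    if not 0.0 < min_prop <= 1.0:
        raise ValueError("min_prop must lie in (0, 1]")
    arr = np.asarray(responses, dtype=float)
    if arr.size == 0:
        return float("nan")
    answered = ~np.isnan(arr)
    if answered.sum() / arr.size < min_prop:
        return float("nan")
    vals = arr[answered]
    if rule == "any":
        return float(np.any(vals > 0))
    if rule == "all":
        return float(np.all(vals > 0))
    raise ValueError(f"unknown positivity rule {rule!r}")


def composite_mental_health_score(
    items: pd.DataFrame,
    subscales: Mapping[str, Sequence[str]],
    min_prop: float = 0.5,
) -> pd.Series:
    """Standardize–sum–standardize composite across questionnaire subscales.

    Per individual and subscale, the mean of answered items is taken when at
    least ``min_prop`` of the subscale's items were answered, else the
    subscale is missing.  Subscale scores are z-standardized across
    individuals, summed, and the sum is z-standardized again.  Individuals
    with any missing subscale get a missing composite (no imputation here).
    If a subscale or the final sum is constant, zeros are returned for it
    with a warning.
    """
    import warnings

    if not subscales:
        raise ValueError("subscale map must be non-empty")
    sub_scores = {}
    for name, cols in subscales.items():
        block = items.loc[:, list(cols)].astype(float)
        answered = block.notna().sum(axis=1)
        means = block.mean(axis=1)
        means[answered / len(cols) < min_prop] = np.nan
        sd = means.std(ddof=0)
        if not sd > 0:
            warnings.warn(
                f"subscale {name!r} is constant; standardized score set to 0",
                stacklevel=2,
            )
            sub_scores[name] = means * 0.0
        else:
            sub_scores[name] = (means - means.mean()) / sd
    total = pd.DataFrame(sub_scores).sum(axis=1, skipna=False)
    sd = total.std(ddof=0)
    if not sd > 0:
        warnings.warn("composite is constant; returning zeros", stacklevel=2)
        return total * 0.0
    return (total - total.mean()) / sd
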