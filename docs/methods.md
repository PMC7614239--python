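# Methods

This note documents the statistical models implemented in `pgsace`, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical decisions a user auditing results will want.

## Generative model for synthetic cohorts

All analyses were designed for access-restricted birth cohorts, so the
package carries a first-class simulator whose defaults encode the study
conditions of the design's power analyses.

**Polygenic scores.** The eight mental-health scores are
`PGS_i = √ρ·G + √(1−ρ)·u_i` with `G, u_i ~ N(0,1)` i.i.d. and ρ = 0.06,
giving an exchangeable inter-score correlation of 0.06 and a common latent
genetic factor `G`. The two negative-control scores are independent
standard normals, unrelated to `G`, the ACEs and the outcomes by
construction.

**ACEs.** Each ACE `j` is a thresholded liability
`L_j = Σ_i γ_ij·PGS_i + λ·A + ε_j`, `Var(L_j) = 1`, threshold
`Φ⁻¹(1−prevalence_j)`. `A` is a shared "adversity" factor; its loading λ is
solved so the average cross-ACE liability (tetrachoric) correlation equals
the target (default 0.30). Effects are specified on the scale the
literature uses:

* as **marginal odds ratios** per SD of score — converted to
  liability-scale slopes by `calibrate_liability_effect`, which root-finds
  the score–liability correlation whose implied population logistic slope
  (computed by Gauss–Hermite quadrature over the score distribution)
  matches the target OR to 1e-3; the per-score slope vector is then
  `γ = R⁻¹ r*` so each score hits its marginal target despite the
  inter-score correlation `R`; or
* as **marginal point-biserial correlations** — converted through the
  biserial factor `φ(τ)/√(p(1−p))` (used by the mediation scenarios, whose
  paths are correlations).

Infeasible requests (liability variance above 1, adversity loading
imaginary) raise errors naming the offending block.

**Outcomes.** `Y_m = √h²_m·G + Σ_i β_im·PGS_i + Σ_j δ_jm·ACE*_j + e`, with
`ACE*` the centred standardized indicator, then standardized. Defaults
`h² = 0.06` (internalising) and `0.09` (externalising) — the SNP
heritabilities the sensitivity analysis uses. ACE effects may be given as
direct paths `δ` or (default) as target **marginal** ACE–outcome
correlations, from which `δ` is solved through the model-implied ACE
phi-correlation matrix (computed from the bivariate normal over the
liability thresholds). The default marginal correlation is 0.06 per ACE.
The marginal reading was chosen because the design quotes the value from
observed-correlation literature and because the aggregate-power
calibration (5% = 0.003/0.06) is only coherent on that scale. The residual
variance is sized analytically so the outcome has unit variance and the
`G`-share equals `h²`.

**What is not emulated.** Genotypes, linkage disequilibrium, GWAS summary
statistics and score construction; assortative mating and passive-rGE
through parental genotypes (the liability model is agnostic about the
mechanism of the PGS→ACE path); informative missingness (the optional
missingness injector is MCAR, only to exercise the ≥50 % scoring rules);
family/site clustering. Tests passing on these cohorts therefore validate
the *statistical machinery* under the assumed correlation structure, not
substantive conclusions about real cohorts.

**Unstated quantities.** The per-ACE prevalences behind the original power
simulations are not published. The power scenarios use 0.20 for all six
ACEs — a typical childhood-adversity prevalence — exposed in
`SimulationConfig.ace_prevalence`. Wald-test power is mildly sensitive to
this choice (rarer ACEs mean noisier probit coefficients).

## Dependent-effect pooling and equivalence

The composite of `m` effect estimates is their unweighted mean with
variance `(1/m²)(Σ seᵢ² + ρ·Σ_{i≠j} seᵢseⱼ)`. ρ is always an explicit
parameter: the analysis default is 0.30, but the value used in the original
pooled analyses is not published. For the rGE stage the package can
estimate ρ from the data (`rho="empirical"`): the per-model influence
functions of the score coefficients are correlated across models sharing
individuals, and the average off-diagonal correlation of those columns is a
consistent estimate of the dependence the composite should carry. For 48
models sharing one sample the estimate is ≈ 0.04 (models share an ACE with
phi ≈ 0.19 or a score with r = 0.06, most pairs share neither), far below
0.30; the power simulation for the pooled test uses the empirical value,
since a fixed 0.30 would overstate the composite variance roughly
three-fold and misstate the test's operating characteristics.

Equivalence testing is the two-one-sided-tests rule: the effect is
declared no more than trivially small when its 90 % CI lies inside the
bounds. Bounds derive from the lower confidence limit of the meta-analytic
OR (1.06), reflected through 1 on the log-odds scale: (0.94, 1.06). CIs and
p-values are normal-theory throughout — inputs are asymptotically normal ML
estimates.

## Joint probit path model

Each ACE is regressed by probit ML on all eight scores plus sex; the
cross-equation covariance of the 48 coefficients is the stacked
M-estimation sandwich `B_j S_j' S_k B_k` (bread × cross-equation score
outer product × bread), which the tests verify against a nonparametric
bootstrap. This replaces a WLSMV/polychoric SEM engine: the estimand —
independent probit paths and their joint covariance — is the same in large
samples. Consequences: the printed F denominator degrees of freedom of an
SEM engine are not reproduced (the Wald statistic is reported as chi-square
with an `F = χ²/df₁` rescaling on `(df₁, n−k)`), and no latent measurement
structure is modelled.

Averages over rows/columns of the coefficient matrix are linear transforms
(covariance `L V Lᵀ`). Pairwise contrasts are converted to the log-odds
scale by the standard factor 1.8 (`OR = exp(1.8·β_probit)`) before being
compared with the pre-specified half-widths: 0.10 (per-score contrasts)
and 0.05 (per-ACE contrasts).

## Genetic confounding as mediation

All paths are OLS projections of standardized variables (ACE as a z-scored
0/1 indicator), with sex partialled out everywhere; point estimates are
identical to a saturated linear path model. Because the same covariates
appear in every projection, `total = cp + Σ aᵢbᵢ` holds to machine
precision (Frisch–Waugh), which the tests assert at 1e-10. Standard errors
of the indirect effect, the total and the proportion are delta-method
values assembled from per-observation influence functions (HC0-style);
bootstrap percentile CIs over individuals are available (`B` configurable,
seeded). Proportions are pooled raw — no Freeman–Tukey transform, since
negative proportions (opposing direct and indirect paths) are legitimate —
with an additional display value capped to [0, 1]. A proportion whose
denominator is below tolerance (default 1e-8) is flagged undefined and
excluded from pooling with a warning, never silently zeroed.

One structural caveat the simulations make visible: fitting one ACE at a
time while the six ACEs are correlated and all affect the outcome lets the
score paths absorb part of the omitted ACEs' effects, shifting per-model
proportions upward relative to a single-exposure generating value. This is
a property of the published one-exposure-at-a-time design itself, not of
this implementation.

## Latent-score sensitivity analysis

Observed scores capture a small fraction of SNP heritability, so the
observed indirect effect underestimates genetic confounding. The
adjustment sets the latent score's outcome path to `b* = √h²` (0.24 for
internalising h² = 0.06; 0.30 for externalising h² = 0.09), scales its ACE
path by the observed ratio `k = a/b` (`a* = k·b*`), and preserves the
observed total: `cp* = r_am − a*b*`. The adjusted proportion is
`a*b*/r_am`. The phrase defining the adjusted ACE path is ambiguous in the
design (`k·(0.06)` vs `k·√0.06`); `a* = k·√h²` is implemented, by analogy
with the outcome path and consistent with the design's own worked scenario
(a = 0.07 ≈ 0.33 × 0.24).

For eight observed scores, `k` defaults to the value computed from a
composite score — the b-weighted linear combination of the standardized
scores — since the adjustment is phrased for a single score; `k` may also
be supplied directly. A "matrix" mode writes the latent score's *implied
marginal* correlations (`r_pm' = b* + a*·cp*`) into the 3×3 matrix and
re-solves the path model; with that construction it agrees exactly with
the direct mode (naively overwriting `r_pm` with `b*` instead does not —
the re-solved `b` would differ from `b*` by `O(a*·r_am)`).

Bootstrap CIs recompute the entire chain per resample. An estimate is
flagged unreliable when the point proportion reaches 1 (over-explained
association), the adjusted direct path changes sign in ≥ 5 % of resamples,
or a CI endpoint is non-finite; re-pooling over reliable results mirrors
the robustness re-analysis.

## Power simulations

Every scenario uses N = 4,700 per replicate and α = 0.05, with seeded
`numpy` generators; default 1,000 replicates with a `--reps` flag. The
acceptance script uses 500–1,000 replicates per scenario (Monte-Carlo SE
≤ 0.01, total runtime a few minutes on one CPU); the test suite uses
200–300 with correspondingly wider asserted tolerances. Scenario
parameters: pooled rGE test at uniform OR 1.04; Wald scenarios with ORs
evenly spaced over 1.05–1.16 (across scores) and 1.05–1.15 (across ACEs);
mediation grids ACE→score r 0.03–0.07 and score→outcome r 0.01–0.05 mapped
evenly across the eight scores (the design gives ranges without placement);
an aggregate variant with the outcome paths rescaled so the generating
proportion is exactly 5 % of the 0.06 total; and the single-latent-score
scenario with paths (0.24, 0.07, 0.06).

Observed operating characteristics, recomputed by `scripts/acceptance.py`:
the pooled rGE, Wald and latent-score tests reach power ≈ 0.98–1.00, and
the per-model mediation test ≈ 1.00. The aggregate pooled-proportion test
reaches ≈ 0.85–0.88, not the design's 1.00: at N = 4,700 with a total
ACE→outcome correlation of 0.06, the per-model proportion estimates have
SEs around 0.035–0.08 (dominated by the noisy total effect), the ρ = 0.30
composite of six of them has SE ≈ 0.03 (matching the empirical replicate
SD, so the composite is correctly calibrated), and a true proportion of
0.05 therefore cannot be detected with near-certain power at this sample
size. The design's aggregate simulation must have assumed materially
smaller effect-size SEs, which were not published.

## Numerical choices

* OR calibration: 64-node Gauss–Hermite quadrature; `brentq` on [0, 0.95]
  with 1e-10 bracket tolerance; achieved-OR check at 1e-3.
* Probit/logistic fits: `statsmodels` ML with failure-on-separation
  surfaced as errors naming the (score, ACE) pair, never silent NaNs.
* Degenerate inputs: single-class ACEs, constant scores, rank-deficient
  designs and non-positive-definite correlation matrices raise immediately
  with the offending column(s) named.
* Ties in BH-FDR follow the standard step-up rule (stable sort).
* Constant subscales in the composite-score builder return zeros with a
  warning rather than dividing by zero.
* All randomness flows through `numpy.random.Generator`; a fixed seed
  reproduces cohorts, bootstraps and power estimates bit-for-bit.
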