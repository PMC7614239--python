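# pgsace

Gene–environment correlation and genetic-confounding analyses of polygenic
scores (PGS) and adverse childhood experiences (ACEs), on synthetic cohorts
with realistic statistical structure.

## The problem

Children's genetic liability to mental-health problems is associated with
their risk of exposure to ACEs (maltreatment, domestic violence, parental
mental illness, parental substance abuse, parental criminality, parental
separation) — a gene–environment correlation (rGE). The same liability also
raises internalising/externalising problems directly, so part of any
ACE–mental-health association may be *genetically confounded*. This package
implements, end to end and fully tested, the statistical pipeline for
quantifying both phenomena:

1. **rGE stage** — one logistic regression per (PGS, ACE) pair:
   `ACE ~ PGS + sex`, odds ratio per SD of score; Benjamini–Hochberg FDR
   within each family; the 48 log odds ratios pooled into a single
   dependent-effects composite
   `var = (1/m²)(Σᵢ seᵢ² + Σ_{i≠j} ρ·seᵢ·seⱼ)`; equivalence (TOST) verdict
   against bounds 0.94–1.06 on the OR scale (the meta-analytic lower
   confidence limit 1.06, reflected through 1 on the log-odds scale).
2. **Joint path model** — each ACE regressed (probit) on all 8 scores at
   once; a cross-equation sandwich covariance over the 48 coefficients;
   per-score and per-ACE averages; Wald equality tests; pairwise
   equivalence contrasts on the log-odds scale via `OR = exp(1.8·β_probit)`.
3. **Genetic confounding** — scores as mediators of each ACE→outcome
   association: indirect effect `Σ aᵢbᵢ`, direct path `cp`, proportion
   explained `Σ aᵢbᵢ / (Σ aᵢbᵢ + cp)`, with delta-method and bootstrap
   uncertainty, pooled across ACE models; negative-control scores
   (handedness, cataracts) as a bias check.
4. **Latent-score sensitivity analysis** — replaces the observed composite
   score with a latent score capturing full SNP heritability:
   `b* = √h²` (0.24 for h²=6 %, 0.30 for 9 %), `a* = k·b*` with
   `k = a/b` observed, `cp* = r_am − a*b*`; bootstrap CIs with reliability
   flags and re-pooling after excluding unreliable estimates.
5. **Power simulations** — seeded Monte-Carlo power for each stage at
   N = 4,700, α = 0.05.

Real cohort data (ALSPAC, ABCD) are access-restricted; the
`synthetic_data` module generates cohorts with the structure the analyses
assume — standardized PGS with exchangeable correlation 0.06 loading on a
latent genetic factor, liability-threshold ACEs calibrated by numeric
root-finding to target marginal odds ratios with inter-ACE tetrachoric
correlation 0.30, and outcomes carrying SNP heritabilities of 0.06/0.09 —
plus the cohort phenotype-scoring rules (≥50 %-answered item rule,
standardize–sum–standardize composites).

## Worked example

```bash
pgsace simulate --scenario h1a --n 4700 --seed 7 --out cohort.csv
pgsace h1a --cohort cohort.csv --rho 0.30 --out h1a.json
```

The cohort is generated with every PGS→ACE odds ratio equal to 1.04. The
run writes the 48 per-pair odds ratios with FDR-corrected p-values and the
pooled composite; for seed 7 the pooled section of `h1a.json` reads

```json
"pooled_main": {"estimate": 0.0371, "se": 0.0205,
                 "ci90": [0.0034, 0.0708], "p": 0.0701, "rho": 0.3, "m": 48},
"verdict_main": {"inside": false, "significant": false}
```

i.e. a pooled OR of `exp(0.0371) ≈ 1.04` per SD of score. With the fixed
ρ = 0.30 composite the two-sided p is 0.07 and the 90 % CI on the OR scale,
(1.003, 1.073), is not contained in the equivalence bounds (0.94, 1.06):
neither a significant association nor demonstrable equivalence at this
single-cohort precision — the inconclusive cell of the inference table.
The negative-control pooled OR is 0.994 (95 % CI 0.952–1.037), covering 1
as designed. A Python session gives the same numbers:

```python
from pgsace import simulate_cohort, make_power_scenario
from pgsace.rge import run_h1a

cohort = simulate_cohort(make_power_scenario("h1a"), seed=7)
res = run_h1a(cohort, rho=0.30)
print(res.pooled_main.estimate, res.pooled_main.p)
```

## Layout

| module | contents |
| --- | --- |
| `pgsace.statcore` | dependent-effect composite, TOST, bounds, BH-FDR |
| `pgsace.synthetic_data` | cohort simulator, OR↔liability calibration, power scenarios, scoring rules |
| `pgsace.rge` | per-pair logistic stage and pooled equivalence verdicts |
| `pgsace.path_model` | joint probit model, averages, Wald, contrasts |
| `pgsace.confounding` | mediation decomposition, proportions, pooling |
| `pgsace.gsens` | latent-score sensitivity analysis and re-pooling |
| `pgsace.power_sim` | Monte-Carlo power for every stage |
| `pgsace.io`, `pgsace.cli` | cohort file contract, JSON results, CLI |

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.
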