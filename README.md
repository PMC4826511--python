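# growthcontrasts

Regression models that link **patterns of early growth** — serial
anthropometric z-scores — to a **later health outcome**, for
epidemiologists and biostatisticians studying questions like: *is rapid
infant weight gain in a particular window associated with childhood
overweight?*

The same regression model, reparameterised by swapping sizes
(z<sub>t</sub>) and interval changes (Δ<sub>k</sub> = z<sub>t_k</sub> −
z<sub>t_{k−1}</sub>) in and out of the design, targets five different
growth-pattern contrasts. With z-scores at target ages t ∈ {0, 1.5, 3, 6,
12, 24} months and (for a binary outcome) a logit link:

| id | contrast | linear predictor (period k) | reported coefficient |
|----|----------|------------------------------|----------------------|
| a | conditional growth | β₀z₀ + … + β<sub>t_k</sub>z<sub>t_k</sub> | β<sub>t_k</sub>, the most contemporary size given all earlier sizes |
| b | being bigger v being smaller | γ₀z₀ + γ₁Δ₁ + … + γ<sub>k</sub>Δ<sub>k</sub> | γ₀, birth size controlling all future changes up to t_k |
| c | becoming bigger and staying bigger | δ₀z₀ + δ₁Δ₁ + … + δ₅Δ₅ | each δ<sub>k</sub>: a gain in period k maintained to 24 m |
| d | growing faster v being bigger | η₁Δ₁ + … + η<sub>k</sub>Δ<sub>k</sub> + η z<sub>t_k</sub> | the last Δ: growth to reach a given future size |
| e | becoming bigger v being bigger | θ₁Δ₁ + … + θ₅Δ₅ + θ z₂₄ | each θ<sub>k</sub>: becoming bigger in period k v having been bigger from birth |

These are linear reparameterisations of one another, so exact identities
hold at the MLE: η<sub>k</sub> = β<sub>k</sub> − γ₀ (model ending at the
same age), θ<sub>k</sub> = δ<sub>k</sub> − γ₀ (full span), and the final
period of (a)/(c) and of (d)/(e) is literally the same contrast. The
`validation` module checks all of them numerically on any dataset.

The package also provides:

* **data preparation** (`zscores`): LMS z-scoring of weight and length
  (z = ((x/M)<sup>L</sup> − 1)/(L·S)), linear interpolation of z-scores to
  the target ages with a nearest-window rule, conditional weight-for-length
  z-scores z(wt|len) = (z<sub>wt</sub> − r<sub>t</sub>·z<sub>len</sub>)/√(1 −
  r<sub>t</sub>²), BMI-cutoff overweight classification, and complete-case
  restriction with audit counts;
* **two-step residual fits** (`residuals`): regress each period's growth
  construct on its conditioning set by OLS, save the residual "growth
  scores", optionally divide by their SD, and regress the outcome on them —
  a 1-SD change then means the same amount of population re-ordering in
  every period, at the price of losing the algebraic identities;
* a **synthetic-cohort generator** (`simulate`): multivariate-normal serial
  z-scores with correlation decaying in time separation, covariates, a
  logistic outcome with known coefficients, and invertible unbalanced raw
  records for end-to-end pipeline tests;
* a **CLI**: `growthcontrasts simulate | prepare | fit | validate`.

## Worked example

```python
import growthcontrasts as gc

cohort = gc.simulate_cohort(900, gc.OutcomeSpec(parameterisation="c"), seed=42)
tables = [gc.fit_contrast(cohort.data, cohort.outcome, ("sex", "gest_age"), c)
          for c in "abcde"]
print(gc.render_or_table(gc.or_table(tables)))
```

prints (abridged) odds ratios for the later outcome per z-score of
weight-for-length, adjusted for sex and gestational age:

```
                                          OR          95% CI         p
(a) Conditional growth:
  Birth to 6w                           1.12      0.83, 1.51     0.472
  3 to 6 m                              1.58      1.11, 2.25     0.012
  12 to 24 m                            1.43      1.02, 2.00     0.037
(c) Becoming bigger and staying bigger:
  3 to 6 m                              1.70      1.18, 2.44     0.005
  12 to 24 m                            1.43      1.02, 2.00     0.037
(e) Becoming bigger v being bigger:
  12 to 24 m                            1.20      0.83, 1.74     0.342
```

This cohort was generated with its strongest persistent gains in the 3–6
month interval, and the becoming-and-staying-bigger contrast shows exactly
that (OR 1.70 per z-score). The 12–24 m rows of (a) and (c) agree (1.43) —
they are the same contrast — as do those of (d) and (e). The identity
checks confirm it:

```python
for r in gc.run_all_checks(cohort.data, cohort.outcome, ("sex", "gest_age")):
    print(f"{r.name:42s} max dev {r.max_abs_deviation:.2e}  {'OK' if r.passed else 'FAIL'}")
```

```
eta_equals_beta_minus_gamma0               max dev 9.16e-16  OK
theta_equals_delta_minus_gamma0            max dev 1.17e-15  OK
final_period_a_equals_c                    max dev 5.00e-16  OK
final_period_d_equals_e                    max dev 0.00e+00  OK
conditional_growth_residuals_orthogonal    max dev 1.06e-15  OK
same_span_fitted_values                    max dev 3.33e-15  OK
same_span_log_likelihood                   max dev 5.68e-14  OK
```

For fair cross-period comparison, `two_step_table(..., standardise=True)`
reports ORs per 1 SD of each period's residual growth score; with residual
SDs of 0.8z and 0.5z in two periods, a unit z-score gain in the tighter
period means 0.8/0.5 = 1.6 times more population re-ordering
(`score_sd_summary`).

The same pipeline runs from the shell:

```bash
growthcontrasts simulate --n 900 --seed 42 --out-dir sim
growthcontrasts prepare  --records sim/raw_records.csv --reference sim/reference.csv \
                         --outcome outcome.csv --out balanced.csv
growthcontrasts fit      --z balanced.csv --standardised --out-dir results
growthcontrasts validate --z balanced.csv --out identity_report.json
```

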