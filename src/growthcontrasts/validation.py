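"""Numerical verification of the algebraic relations between contrasts.

The five parameterisations are linear reparameterisations of one another,
so at the maximum likelihood estimate the following hold on any complete
dataset (with the same covariates in every model):

* eta_k (growing faster v being bigger, period k)
  = beta_k (conditional growth, period k)
  - gamma_0 (being bigger, model ending at the same age);
* theta_k (becoming bigger v being bigger)
  = delta_k (becoming-and-staying bigger) - gamma_0 (being bigger, full span);
* the 12-24 month reported coefficients of (a) and (c) coincide, as do those
  of (d) and (e) — they are the same contrast;
* all full-span models share one column space, hence identical fitted
  probabilities and log-likelihoods;
* conditional-growth residual scores are pairwise uncorrelated in-sample.

Each check returns an :class:`IdentityReport`; together they double as the
core of the test suite and as the ``validate`` CLI subcommand.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .design import build_design
from .models import ContrastModel, fit_glm
from .residuals import residual_scores
from .schedule import TARGET_AGES, n_periods, validate_ages
from .simulate import CorrelationSpec, OutcomeSpec, simulate_cohort

__all__ = [
    "IdentityReport",
    "check_reparam_identities",
    "check_residual_orthogonality",
    "check_fitted_invariance",
    "run_all_checks",
    "parameter_recovery_experiment",
]

TOL_MLE = 1e-6  # IRLS-convergence-limited reparameterisation identities
TOL_SAME_MODEL = 1e-8  # literally the same fitted model
TOL_ORTHO = 1e-10  # closed-form OLS orthogonality


@dataclass
class IdentityReport:
    name: str
    periods: list[int]
    max_abs_deviation: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return self.max_abs_deviation < self.tolerance

    def to_dict(self) -> dict:
        d = asdict(self)
        d["passed"] = self.passed
        return d


def _reported(Z, outcome, cov, contrast, period, link, ages) -> float:
    m = ContrastModel(contrast, period, link, cov, ages).fit(Z, outcome)
    return m.reported_["estimate"]


def _full_reported(Z, outcome, cov, contrast, link, ages) -> dict[int, float]:
    """Per-period reported coefficients of a full-span contrast (c or e)."""
    from .design import reported_column

    K = n_periods(ages)
    m = ContrastModel(contrast, None, link, cov, ages).fit(Z, outcome)
    return {k: float(m.params_[reported_column(contrast, k, ages)]) for k in range(1, K + 1)}


def check_reparam_identities(
    Z: pd.DataFrame,
    outcome,
    covariates: tuple[str, ...] = (),
    link: str = "logit",
    ages: tuple[float, ...] = TARGET_AGES,
    tol: float = TOL_MLE,
    equality_tol: float = TOL_SAME_MODEL,
) -> list[IdentityReport]:
    """Check eta = beta - gamma_0 and theta = delta - gamma_0 per period,
    plus the final-period equal-contrast equalities."""
    ages = validate_ages(ages)
    K = n_periods(ages)
    periods = list(range(1, K + 1))

    beta = {k: _reported(Z, outcome, covariates, "a", k, link, ages) for k in periods}
    gamma = {k: _reported(Z, outcome, covariates, "b", k, link, ages) for k in periods}
    eta = {k: _reported(Z, outcome, covariates, "d", k, link, ages) for k in periods}
    delta = _full_reported(Z, outcome, covariates, "c", link, ages)
    theta = _full_reported(Z, outcome, covariates, "e", link, ages)

    dev_eta = max(abs(eta[k] - (beta[k] - gamma[k])) for k in periods)
    dev_theta = max(abs(theta[k] - (delta[k] - gamma[K])) for k in periods)
    dev_ac = abs(beta[K] - delta[K])
    dev_de = abs(eta[K] - theta[K])

    return [
        IdentityReport("eta_equals_beta_minus_gamma0", periods, dev_eta, tol),
        IdentityReport("theta_equals_delta_minus_gamma0", periods, dev_theta, tol),
        IdentityReport("final_period_a_equals_c", [K], dev_ac, equality_tol),
        IdentityReport("final_period_d_equals_e", [K], dev_de, equality_tol),
    ]


def check_residual_orthogonality(
    Z: pd.DataFrame,
    ages: tuple[float, ...] = TARGET_AGES,
    tol: float = TOL_ORTHO,
) -> IdentityReport:
    """Pairwise correlations among conditional-growth residual scores."""
    ages = validate_ages(ages)
    K = n_periods(ages)
    if len(Z) < K + 3:
        raise ValueError(
            f"need at least {K + 3} children to residualise {K} periods"
        )
    cols = {
        k: residual_scores(Z, "a", k, ages).scores.to_numpy() for k in range(1, K + 1)
    }
    max_r = 0.0
    for i in range(1, K + 1):
        for j in range(i + 1, K + 1):
            r = abs(float(np.corrcoef(cols[i], cols[j])[0, 1]))
            max_r = max(max_r, r)
    return IdentityReport(
        "conditional_growth_residuals_orthogonal", list(range(1, K + 1)), max_r, tol
    )


def check_fitted_invariance(
    Z: pd.DataFrame,
    outcome,
    covariates: tuple[str, ...] = (),
    link: str = "logit",
    ages: tuple[float, ...] = TARGET_AGES,
    tol: float = TOL_SAME_MODEL,
) -> list[IdentityReport]:
    """Same-span models must have identical fitted values and likelihoods."""
    ages = validate_ages(ages)
    K = n_periods(ages)
    fits = [
        ContrastModel(c, K if c in "abd" else None, link, covariates, ages)
        .fit(Z, outcome)
        .glm_
        for c in ("a", "b", "c", "e")
    ]
    ref = fits[0]
    dev_fit = max(float(np.abs(f.fitted - ref.fitted).max()) for f in fits[1:])
    dev_llf = max(abs(f.llf - ref.llf) for f in fits[1:])
    return [
        IdentityReport("same_span_fitted_values", [K], dev_fit, tol),
        IdentityReport("same_span_log_likelihood", [K], dev_llf, tol),
    ]


def run_all_checks(
    Z: pd.DataFrame,
    outcome,
    covariates: tuple[str, ...] = (),
    link: str = "logit",
    ages: tuple[float, ...] = TARGET_AGES,
) -> list[IdentityReport]:
    reports = check_reparam_identities(Z, outcome, covariates, link, ages)
    reports.append(check_residual_orthogonality(Z, ages))
    reports.extend(check_fitted_invariance(Z, outcome, covariates, link, ages))
    return reports


def parameter_recovery_experiment(
    spec: OutcomeSpec,
    n: int = 2000,
    replicates: int = 200,
    seed: int = 0,
    corr: CorrelationSpec | None = None,
) -> pd.DataFrame:
    """Monte-Carlo recovery of the generating coefficients.

    Repeatedly simulates cohorts from ``spec``, refits the matching
    full-span contrast (adjusted for sex and gestational age), and reports
    per-coefficient mean estimate, empirical SE, mean model SE and 95% Wald
    CI coverage.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    spec = spec.validate()
    ages = validate_ages(tuple(spec.target_ages))
    K = n_periods(ages)
    design_cols = build_design(
        simulate_cohort(4, spec, corr, seed=seed).Z, spec.parameterisation, K, ages
    ).columns
    truth = dict(zip(design_cols, spec.coefficients))
    truth["sex"] = spec.covariate_effects.get("sex", 0.0)
    truth["gest_age"] = spec.covariate_effects.get("gest_age", 0.0)
    # gestational age enters the generator centred at 40 weeks
    truth["const"] = spec.intercept - 40.0 * truth["gest_age"]

    child_seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)
    est, se = [], []
    for rs in child_seeds:
        cohort = simulate_cohort(n, spec, corr, seed=int(rs))
        m = ContrastModel(
            spec.parameterisation, K, spec.link, ("sex", "gest_age"), ages
        ).fit(cohort.data, cohort.outcome)
        est.append(m.params_)
        se.append(m.se_)
    E = pd.DataFrame(est).reset_index(drop=True)
    S = pd.DataFrame(se).reset_index(drop=True)

    rows = []
    for term, true_val in truth.items():
        e, s = E[term], S[term]
        cover = ((e - 1.959963984540054 * s <= true_val) & (true_val <= e + 1.959963984540054 * s)).mean()
        rows.append(
            {
                "term": term,
                "truth": true_val,
                "mean_estimate": float(e.mean()),
                "empirical_se": float(e.std(ddof=1)) if replicates > 1 else np.nan,
                "mean_model_se": float(s.mean()),
                "coverage_95": float(cover),
                "replicates": replicates,
                "n": n,
            }
        )
    return pd.DataFrame(rows)
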