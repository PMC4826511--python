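"""Fitting growth-pattern contrast models and reporting odds-ratio tables.

The central object is :class:`ContrastModel`, a scikit-learn style estimator
wrapping a statsmodels GLM (logit link for a binary outcome, identity link
for a continuous one). Each contrast reports, per period, one coefficient —
the "most contemporary" one for conditional growth, the birth-size
coefficient for being bigger, and the interval-change coefficients for the
full-span parameterisations — as an odds ratio per z-score with a Wald 95%
confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .design import LabelledDesign, build_design, reported_column
from .schedule import (
    CONTRAST_NAMES,
    TARGET_AGES,
    cumulative_label,
    n_periods,
    period_label,
    validate_ages,
)

__all__ = ["GlmFit", "ContrastModel", "fit_glm", "fit_contrast", "or_table", "render_or_table"]

LINKS = ("logit", "identity")


@dataclass
class GlmFit:
    """Result of one maximum-likelihood GLM fit.

    Coefficients are on the linear (log-odds) scale; ``conf_int`` holds
    Wald 95% limits on that scale. ``converged`` is False when IRLS failed
    to converge or perfect separation was detected — never silently.
    """

    link: str
    params: pd.Series
    se: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    cov_params: pd.DataFrame
    llf: float
    converged: bool
    n: int
    fitted: np.ndarray
    design_columns: list[str]
    covariate_columns: list[str]
    flags: list[str] = field(default_factory=list)

    def odds_ratios(self) -> pd.DataFrame:
        if self.link != "logit":
            raise ValueError("odds ratios are defined for the logit link only")
        return pd.DataFrame(
            {
                "or": np.exp(self.params),
                "ci_low": np.exp(self.conf_int.iloc[:, 0]),
                "ci_high": np.exp(self.conf_int.iloc[:, 1]),
            }
        )


def _find_collinear(X: pd.DataFrame) -> list[str]:
    """Name columns that are (numerically) linear combinations of earlier ones."""
    bad = []
    arr = np.empty((len(X), 0))
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)[:, None]
        if arr.shape[1]:
            resid = v - arr @ np.linalg.lstsq(arr, v, rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(v)):
                bad.append(col)
                continue
        arr = np.hstack([arr, v])
    return bad


def _assemble(
    design: LabelledDesign | pd.DataFrame,
    covariates: pd.DataFrame | None,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    Xd = design.X if isinstance(design, LabelledDesign) else design
    parts = [Xd]
    cov_cols: list[str] = []
    if covariates is not None and covariates.shape[1]:
        cov = covariates.reset_index(drop=True)
        parts = [Xd.reset_index(drop=True), cov]
        cov_cols = list(cov.columns)
    X = pd.concat(parts, axis=1)
    X.insert(0, "const", 1.0)
    return X, list(Xd.columns), cov_cols


def fit_glm(
    design: LabelledDesign | pd.DataFrame,
    outcome: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    link: str = "logit",
) -> GlmFit:
    """Maximum-likelihood GLM of the outcome on a labelled design + covariates.

    An intercept is always included. Rank deficiency raises with the names of
    the offending columns; non-convergence and separation are flagged on the
    returned fit.
    """
    if link not in LINKS:
        raise ValueError(f"link must be one of {LINKS}")
    X, design_cols, cov_cols = _assemble(design, covariates)
    y = np.asarray(outcome, dtype=float)
    if len(y) != len(X):
        raise ValueError(f"outcome length {len(y)} != design rows {len(X)}")
    if link == "logit" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("logit link requires a binary 0/1 outcome")

    Xa = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        bad = _find_collinear(X)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    family = sm.families.Binomial() if link == "logit" else sm.families.Gaussian()
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.GLM(y, X, family=family).fit(maxiter=200, tol=1e-10)
    for w in caught:
        name = type(w.message).__name__
        if "Separation" in name or "Convergence" in name:
            flags.append(f"{name}: {w.message}")
    converged = bool(getattr(res, "converged", True)) and not flags

    return GlmFit(
        link=link,
        params=res.params,
        se=res.bse,
        conf_int=res.conf_int(alpha=0.05),
        pvalues=res.pvalues,
        cov_params=res.cov_params(),
        llf=float(res.llf),
        converged=converged,
        n=int(len(y)),
        fitted=np.asarray(res.fittedvalues),
        design_columns=design_cols,
        covariate_columns=cov_cols,
        flags=flags,
    )


class ContrastModel(BaseEstimator):
    """One growth-pattern contrast regression.

    Parameters
    ----------
    contrast : {'a','b','c','d','e'}
        Growth-pattern contrast: (a) conditional growth, (b) being bigger,
        (c) becoming bigger and staying bigger, (d) growing faster v being
        bigger, (e) becoming bigger v being bigger.
    period : int or None
        Period the model ends at; required for (a), (b), (d), ignored by the
        full-span contrasts (c) and (e).
    link : {'logit','identity'}
    covariates : tuple of str
        Column names in ``X`` entered as adjustment covariates (e.g.
        ``('sex', 'gest_age')``).
    ages : tuple of float
        Target-age schedule in months.

    Attributes
    ----------
    design_ : LabelledDesign
    glm_ : GlmFit
    params_, se_, conf_int_, pvalues_ : fitted coefficient summaries
    reported_ : dict
        The contrast's reported coefficient for this period (term, estimate,
        odds ratio and CI for the logit link, p-value).
    """

    def __init__(
        self,
        contrast: str = "a",
        period: int | None = None,
        link: str = "logit",
        covariates: tuple[str, ...] = (),
        ages: tuple[float, ...] = TARGET_AGES,
    ):
        self.contrast = contrast
        self.period = period
        self.link = link
        self.covariates = covariates
        self.ages = ages

    def fit(self, X: pd.DataFrame, y) -> "ContrastModel":
        ages = validate_ages(self.ages)
        design = build_design(X, self.contrast, self.period, ages)
        cov = None
        if self.covariates:
            missing = [c for c in self.covariates if c not in X.columns]
            if missing:
                raise ValueError(f"covariate columns not found: {missing}")
            cov = X[list(self.covariates)]
        self.design_ = design
        self.glm_ = fit_glm(design, y, cov, self.link)
        self.params_ = self.glm_.params
        self.se_ = self.glm_.se
        self.conf_int_ = self.glm_.conf_int
        self.pvalues_ = self.glm_.pvalues
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        term = design.reported
        rep = {
            "term": term,
            "estimate": float(self.params_[term]),
            "se": float(self.se_[term]),
            "ci_low": float(self.conf_int_.loc[term].iloc[0]),
            "ci_high": float(self.conf_int_.loc[term].iloc[1]),
            "p": float(self.pvalues_[term]),
        }
        if self.link == "logit":
            rep["or"] = float(np.exp(rep["estimate"]))
            rep["or_ci_low"] = float(np.exp(rep["ci_low"]))
            rep["or_ci_high"] = float(np.exp(rep["ci_high"]))
        self.reported_ = rep
        return self

    def _linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "glm_")
        design = build_design(X, self.contrast, self.period, validate_ages(self.ages))
        cov = X[list(self.covariates)] if self.covariates else None
        M, _, _ = _assemble(design, cov)
        return M.to_numpy(dtype=float) @ self.params_.to_numpy()

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        if self.link != "logit":
            raise ValueError("predict_proba requires the logit link")
        eta = self._linear_predictor(X)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = self._linear_predictor(X)
        if self.link == "logit":
            return (eta > 0).astype(int)
        return eta


def _iter_periods(contrast: str, ages: tuple[float, ...]):
    K = n_periods(ages)
    if contrast == "b":
        return range(0, K + 1)
    return range(1, K + 1)


def fit_contrast(
    Z: pd.DataFrame,
    outcome,
    covariates: tuple[str, ...] = (),
    contrast: str = "a",
    link: str = "logit",
    ages: tuple[float, ...] = TARGET_AGES,
) -> pd.DataFrame:
    """Fit one contrast across all its periods and tabulate reported values.

    Contrasts (a), (b) and (d) fit a sequence of models (one per period);
    (c) and (e) fit a single full-span model whose interval coefficients are
    all reported. Returns one row per (contrast, period).
    """
    ages = validate_ages(ages)
    rows = []
    if contrast in ("c", "e"):
        m = ContrastModel(contrast, None, link, covariates, ages).fit(Z, outcome)
        for k in range(1, n_periods(ages) + 1):
            term = reported_column(contrast, k, ages)
            rows.append(_row(m, contrast, k, term, ages, link))
    else:
        for k in _iter_periods(contrast, ages):
            m = ContrastModel(contrast, k, link, covariates, ages).fit(Z, outcome)
            rows.append(_row(m, contrast, k, m.design_.reported, ages, link))
    return pd.DataFrame(rows)


def _row(m: ContrastModel, contrast, k, term, ages, link) -> dict:
    label = cumulative_label(k, ages) if contrast == "b" else period_label(k, ages)
    est = float(m.params_[term])
    lo = float(m.conf_int_.loc[term].iloc[0])
    hi = float(m.conf_int_.loc[term].iloc[1])
    row = {
        "contrast": contrast,
        "period": k,
        "period_label": label,
        "term": term,
        "estimate": est,
        "se": float(m.se_[term]),
        "ci_low": lo,
        "ci_high": hi,
        "p": float(m.pvalues_[term]),
        "n": m.glm_.n,
        "converged": m.glm_.converged,
    }
    if link == "logit":
        row["or"] = float(np.exp(est))
        row["or_ci_low"] = float(np.exp(lo))
        row["or_ci_high"] = float(np.exp(hi))
    return row


def or_table(
    tables: list[pd.DataFrame] | pd.DataFrame,
) -> pd.DataFrame:
    """Stack per-contrast tables into one report ordered a..e by period."""
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    cols = [
        "contrast", "period", "period_label", "term", "estimate", "se",
        "ci_low", "ci_high", "p", "n", "converged", "or", "or_ci_low",
        "or_ci_high",
    ]
    if not tables:
        return pd.DataFrame(columns=cols)
    out = pd.concat(tables, ignore_index=True)
    out["contrast"] = pd.Categorical(out["contrast"], categories=list("abcde"))
    out = out.sort_values(["contrast", "period"], kind="stable").reset_index(drop=True)
    out["contrast"] = out["contrast"].astype(str)
    return out


def render_or_table(table: pd.DataFrame) -> str:
    """Plain-text rendering of a stacked contrast table."""
    lines = []
    value_col = "or" if "or" in table.columns and table["or"].notna().all() else "estimate"
    header = "OR" if value_col == "or" else "coef"
    lo = "or_ci_low" if value_col == "or" else "ci_low"
    hi = "or_ci_high" if value_col == "or" else "ci_high"
    lines.append(f"{'':38s}{header:>6s}  {'95% CI':>14s}  {'p':>8s}")
    for cid in sorted(table["contrast"].unique()) if len(table) else []:
        block = table[table["contrast"] == cid]
        lines.append(f"({cid}) {CONTRAST_NAMES.get(cid, cid)}:")
        for _, r in block.iterrows():
            ci = f"{r[lo]:.2f}, {r[hi]:.2f}"
            p = f"{r['p']:.3f}" if r["p"] >= 0.001 else "<0.001"
            lines.append(f"  {r['period_label']:36s}{r[value_col]:6.2f}  {ci:>14s}  {p:>8s}")
    return "\n".join(lines) + "\n"
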