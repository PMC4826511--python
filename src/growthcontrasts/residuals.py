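"""Two-step residual fits and SD-standardisation for fair period comparison.

Every contrast coefficient can equivalently be estimated in two steps:
first regress the period's growth construct on its conditioning set by OLS
and save the residuals (the per-child "growth scores"), then regress the
outcome on those scores (plus covariates) in a second analytical model.
Because the amount of population re-ordering differs between periods, the
residual SDs differ; dividing each score by its SD puts a 1-SD increase in
every period on the same population footing. The price is that the tidy
algebraic identities between parameterisations no longer hold after
standardisation.

First-step regressions per contrast, for period k (intervals delta_j):

====  ==========================  ==============================
id    response                    conditioning set
====  ==========================  ==============================
a     z_{t_k}                     z_0, ..., z_{t_{k-1}}
b     z_0                         delta_1, ..., delta_k
c     delta_k                     z_0 and all other deltas
d     delta_k                     z_{t_k}
e     delta_k                     all other deltas and z_{t_K}
====  ==========================  ==============================
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .design import add_deltas
from .models import fit_glm
from .schedule import (
    TARGET_AGES,
    cumulative_label,
    delta_columns,
    n_periods,
    period_label,
    validate_ages,
    z_columns,
)

__all__ = [
    "ResidualScoreSet",
    "ResidualScoreTransformer",
    "residual_scores",
    "standardise_scores",
    "two_step_fit",
    "two_step_table",
    "score_sd_summary",
    "density_summary",
]


#: residual SDs below this are numerically zero (perfect first-step fit)
_SD_FLOOR = 1e-12


@dataclass
class ResidualScoreSet:
    """Per-child residual growth scores for one contrast and period."""

    contrast: str
    period: int
    scores: pd.Series
    sd: float  # SD (n-1) of the *raw* residuals
    standardised: bool
    response: str
    conditioning: list[str]

    @property
    def label(self) -> str:
        if self.contrast == "b":
            return cumulative_label(self.period)
        return period_label(self.period)


def first_step_terms(
    contrast: str, period: int, ages: tuple[float, ...] = TARGET_AGES
) -> tuple[str, list[str]]:
    """(response, conditioning columns) of the first-step OLS regression."""
    ages = validate_ages(ages)
    K = n_periods(ages)
    zc, dc = z_columns(ages), delta_columns(ages)
    if contrast == "a":
        if not 1 <= period <= K:
            raise ValueError(f"period {period} invalid for contrast 'a'")
        return zc[period], zc[:period]
    if contrast == "b":
        if not 0 <= period <= K:
            raise ValueError(f"period {period} invalid for contrast 'b'")
        return zc[0], dc[:period]
    if not 1 <= period <= K:
        raise ValueError(f"period {period} invalid for contrast {contrast!r}")
    if contrast == "c":
        return dc[period - 1], [zc[0]] + [d for d in dc if d != dc[period - 1]]
    if contrast == "d":
        return dc[period - 1], [zc[period]]
    if contrast == "e":
        return dc[period - 1], [d for d in dc if d != dc[period - 1]] + [zc[K]]
    raise ValueError(f"unknown contrast {contrast!r}")


class ResidualScoreTransformer(BaseEstimator, TransformerMixin):
    """First-step OLS residualiser for one contrast and period.

    ``fit`` estimates the conditioning regression (always with an intercept)
    on the training matrix; ``transform`` returns the residual scores,
    divided by the training-sample residual SD when ``standardise`` is True.
    In-sample (fit_transform) scores have mean exactly zero.
    """

    def __init__(
        self,
        contrast: str = "a",
        period: int = 1,
        standardise: bool = True,
        ages: tuple[float, ...] = TARGET_AGES,
    ):
        self.contrast = contrast
        self.period = period
        self.standardise = standardise
        self.ages = ages

    def _design(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        ZD = add_deltas(X, validate_ages(self.ages))
        y = ZD[self.response_].to_numpy(dtype=float)
        M = np.column_stack(
            [np.ones(len(ZD))] + [ZD[c].to_numpy(dtype=float) for c in self.conditioning_]
        )
        return M, y

    def fit(self, X: pd.DataFrame, y=None) -> "ResidualScoreTransformer":
        self.response_, self.conditioning_ = first_step_terms(
            self.contrast, self.period, validate_ages(self.ages)
        )
        M, resp = self._design(X)
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise ValueError(
                f"rank-deficient first-step design for contrast "
                f"{self.contrast!r}, period {self.period}"
            )
        self.coef_, *_ = np.linalg.lstsq(M, resp, rcond=None)
        resid = resp - M @ self.coef_
        self.sd_ = float(resid.std(ddof=1))
        if self.standardise and self.sd_ < _SD_FLOOR:
            raise ValueError("zero residual SD: cannot standardise")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "coef_")
        M, resp = self._design(X)
        resid = resp - M @ self.coef_
        if self.standardise:
            resid = resid / self.sd_
        return resid.reshape(-1, 1)


def residual_scores(
    Z: pd.DataFrame,
    contrast: str,
    period: int,
    ages: tuple[float, ...] = TARGET_AGES,
) -> ResidualScoreSet:
    """In-sample (unstandardised) residual growth scores."""
    t = ResidualScoreTransformer(contrast, period, standardise=False, ages=ages)
    scores = t.fit_transform(Z).ravel()
    return ResidualScoreSet(
        contrast=contrast,
        period=period,
        scores=pd.Series(scores, index=Z.index, name="score"),
        sd=t.sd_,
        standardised=False,
        response=t.response_,
        conditioning=t.conditioning_,
    )


def standardise_scores(s: ResidualScoreSet) -> ResidualScoreSet:
    """Divide scores by their SD (n-1). Idempotent on standardised input."""
    if s.standardised:
        return replace(s)
    if s.sd < _SD_FLOOR:
        raise ValueError("zero residual SD: cannot standardise")
    return replace(s, scores=s.scores / s.sd, standardised=True)


def two_step_fit(
    scores: ResidualScoreSet,
    outcome,
    covariates: pd.DataFrame | None = None,
    link: str = "logit",
) -> dict:
    """Second analytical model: outcome on the growth score (+ covariates)."""
    X = pd.DataFrame({"score": scores.scores.to_numpy()})
    fit = fit_glm(X, outcome, covariates, link)
    row = {
        "contrast": scores.contrast,
        "period": scores.period,
        "period_label": scores.label,
        "term": "score",
        "standardised": scores.standardised,
        "score_sd": scores.sd,
        "estimate": float(fit.params["score"]),
        "se": float(fit.se["score"]),
        "ci_low": float(fit.conf_int.loc["score"].iloc[0]),
        "ci_high": float(fit.conf_int.loc["score"].iloc[1]),
        "p": float(fit.pvalues["score"]),
        "n": fit.n,
        "converged": fit.converged,
    }
    if link == "logit":
        row["or"] = float(np.exp(row["estimate"]))
        row["or_ci_low"] = float(np.exp(row["ci_low"]))
        row["or_ci_high"] = float(np.exp(row["ci_high"]))
    return row


def _contrast_periods(contrast: str, K: int) -> range:
    return range(0, K + 1) if contrast == "b" else range(1, K + 1)


def two_step_table(
    Z: pd.DataFrame,
    outcome,
    contrast: str,
    covariates: pd.DataFrame | None = None,
    standardise: bool = True,
    link: str = "logit",
    ages: tuple[float, ...] = TARGET_AGES,
) -> pd.DataFrame:
    """Per-period two-step fits for one contrast (standardised by default)."""
    ages = validate_ages(ages)
    rows = []
    for k in _contrast_periods(contrast, n_periods(ages)):
        s = residual_scores(Z, contrast, k, ages)
        if standardise:
            s = standardise_scores(s)
        rows.append(two_step_fit(s, outcome, covariates, link))
    return pd.DataFrame(rows)


def score_sd_summary(
    scores: list[ResidualScoreSet] | dict[str, float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-period residual SDs and all pairwise SD ratios.

    Accepts either fitted score sets or a mapping label -> SD (for working
    directly from reported SDs). Returns (sd_table, ratio_matrix); a ratio
    of 1.6 between two periods means a 1-z change in the first period is 1.6
    times as much population re-ordering as in the second.
    """
    if isinstance(scores, dict):
        sds = pd.Series(scores, dtype=float)
    else:
        if len(scores) < 2:
            raise ValueError("need at least two periods to compare")
        sds = pd.Series({s.label: s.sd for s in scores}, dtype=float)
    sd_table = sds.rename("sd").rename_axis("period").reset_index()
    ratios = pd.DataFrame(
        sds.to_numpy()[:, None] / sds.to_numpy()[None, :],
        index=sds.index,
        columns=sds.index,
    )
    return sd_table, ratios


def density_summary(
    scores: list[ResidualScoreSet], bin_width: float = 0.25
) -> pd.DataFrame:
    """Shared-bin density histogram of growth scores (plot-ready, long form)."""
    lo = min(float(s.scores.min()) for s in scores)
    hi = max(float(s.scores.max()) for s in scores)
    edges = np.arange(
        np.floor(lo / bin_width) * bin_width,
        np.ceil(hi / bin_width) * bin_width + bin_width / 2,
        bin_width,
    )
    rows = []
    for s in scores:
        dens, _ = np.histogram(s.scores, bins=edges, density=True)
        for left, d in zip(edges[:-1], dens):
            rows.append(
                {
                    "contrast": s.contrast,
                    "period_label": s.label,
                    "bin_left": float(left),
                    "bin_right": float(left + bin_width),
                    "density": float(d),
                }
            )
    return pd.DataFrame(rows)
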