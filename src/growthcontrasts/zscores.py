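"""From raw longitudinal anthropometry to a balanced conditional z matrix.

Routine-visit data are unbalanced: children are measured near, not at, the
scheduled target ages. The preparation chain converts each weight and length
measurement to an age- and sex-specific z-score with an LMS reference
(Box-Cox power L, median M, coefficient of variation S), linearly
interpolates the z-scores to the fixed target ages, combines weight and
length into a conditional weight-for-length z-score

    z(wt|len) = (z_wt - r_t * z_len) / sqrt(1 - r_t^2),

where r_t is the weight-length z-score correlation at target age t, and
restricts to complete cases. A later binary overweight outcome can be
attached directly or derived from a BMI measurement against an age- and
sex-specific cutoff table (e.g. IOTF), with BMI >= cutoff classed as
overweight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedule import TARGET_AGES, age_token, validate_ages, z_columns

logger = logging.getLogger(__name__)

__all__ = [
    "lms_z",
    "lms_inverse",
    "validate_reference",
    "lookup_lms",
    "fit_empirical_reference",
    "interpolate_to_targets",
    "wl_correlation",
    "weight_for_length_z",
    "classify_overweight",
    "prepare",
    "PreparedCohort",
]

_L_EPS = 1e-8

RECORD_COLUMNS = ["child_id", "sex", "gest_age", "age_months", "weight_kg", "length_cm"]


def lms_z(x, L, M, S):
    """LMS z-score: ((x/M)^L - 1)/(L*S), continuously extended to ln(x/M)/S at L=0."""
    x, L, M, S = (np.asarray(v, dtype=float) for v in (x, L, M, S))
    if np.any(x <= 0) or np.any(M <= 0):
        raise ValueError("measurements and medians must be positive")
    if np.any(S <= 0):
        raise ValueError("S must be positive")
    ratio = x / M
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            np.abs(L) > _L_EPS,
            (np.power(ratio, np.where(np.abs(L) > _L_EPS, L, 1.0)) - 1.0)
            / (np.where(np.abs(L) > _L_EPS, L, 1.0) * S),
            np.log(ratio) / S,
        )
    return z if z.ndim else float(z)


def lms_inverse(z, L, M, S):
    """Invert :func:`lms_z`: the measurement whose z-score is ``z``."""
    z, L, M, S = (np.asarray(v, dtype=float) for v in (z, L, M, S))
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("M and S must be positive")
    big = np.abs(L) > _L_EPS
    base = 1.0 + np.where(big, L, 1.0) * S * z
    if np.any(base[big] <= 0) if base.ndim else (big and base <= 0):
        raise ValueError("z outside the domain of the Box-Cox inverse (1 + L*S*z <= 0)")
    x = np.where(big, M * np.power(np.abs(base), 1.0 / np.where(big, L, 1.0)), M * np.exp(S * z))
    return x if x.ndim else float(x)


REFERENCE_COLUMNS = ["sex", "age", "measure", "L", "M", "S"]


def validate_reference(ref: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REFERENCE_COLUMNS if c not in ref.columns]
    if missing:
        raise ValueError(f"reference table missing columns {missing}")
    if (ref["M"] <= 0).any() or (ref["S"] <= 0).any():
        raise ValueError("reference requires M > 0 and S > 0")
    for (sex, measure), grp in ref.groupby(["sex", "measure"]):
        ages = grp["age"].to_numpy()
        if np.any(np.diff(np.sort(ages)) <= 0):
            raise ValueError(f"duplicate reference ages for sex={sex}, measure={measure}")
    return ref


def lookup_lms(
    ref: pd.DataFrame, sex, measure: str, ages
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate (L, M, S) linearly in age for one sex and measure."""
    grp = ref[(ref["sex"] == sex) & (ref["measure"] == measure)].sort_values("age")
    if grp.empty:
        raise ValueError(f"reference has no rows for sex={sex!r}, measure={measure!r}")
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    ga = grp["age"].to_numpy(dtype=float)
    if ages.min() < ga[0] - 1e-9 or ages.max() > ga[-1] + 1e-9:
        raise ValueError(
            f"age outside reference range [{ga[0]:g}, {ga[-1]:g}] for "
            f"sex={sex!r}, measure={measure!r}"
        )
    return tuple(np.interp(ages, ga, grp[c].to_numpy(dtype=float)) for c in ("L", "M", "S"))


def fit_empirical_reference(
    records: pd.DataFrame,
    age_bins,
    min_cell: int = 20,
) -> pd.DataFrame:
    """Bin-wise empirical reference: L = 1, M = cell mean, S = cell CV.

    A deliberately simple stand-in for smoothed LMS curve estimation; rows
    sit at bin midpoints so that downstream use interpolates between bins.
    Externally fitted L/M/S tables are accepted everywhere a reference is
    needed and are the recommended input when available.
    """
    edges = np.asarray(age_bins, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("age_bins must be increasing edges")
    rows = []
    for measure, col in (("weight", "weight_kg"), ("length", "length_cm")):
        for sex, grp in records.groupby("sex"):
            idx = np.digitize(grp["age_months"], edges) - 1
            for b in range(len(edges) - 1):
                cell = grp.loc[idx == b, col].to_numpy(dtype=float)
                if len(cell) < min_cell:
                    raise ValueError(
                        f"reference cell (sex={sex}, measure={measure}, "
                        f"bin [{edges[b]:g},{edges[b+1]:g})) has {len(cell)} < "
                        f"{min_cell} observations"
                    )
                m = cell.mean()
                s = cell.std(ddof=1) / m
                if s <= 0:
                    raise ValueError(
                        f"degenerate reference cell (sex={sex}, measure={measure}, "
                        f"bin [{edges[b]:g},{edges[b+1]:g})): S = 0"
                    )
                rows.append(
                    {
                        "sex": sex,
                        "age": 0.5 * (edges[b] + edges[b + 1]),
                        "measure": measure,
                        "L": 1.0,
                        "M": m,
                        "S": s,
                    }
                )
    return validate_reference(pd.DataFrame(rows))


def _target_windows(targets: np.ndarray) -> list[tuple[float, float]]:
    """Half-open assignment window per target: half-way to each neighbour."""
    wins = []
    for j, t in enumerate(targets):
        lo = -np.inf if j == 0 else t - (t - targets[j - 1]) / 2.0
        hi = np.inf if j == len(targets) - 1 else t + (targets[j + 1] - t) / 2.0
        wins.append((lo, hi))
    return wins


def interpolate_to_targets(ages, values, targets=TARGET_AGES) -> np.ndarray:
    """Adjust one child's (age, z) series to the target schedule.

    Only observations inside a target's assignment window (half the distance
    to each neighbouring target, lower-inclusive, unbounded at the schedule
    ends) can inform that target. For each target: an observation exactly at
    the target age is returned unchanged; a bracketing in-window pair gives
    linear interpolation in age; otherwise the nearest in-window observation
    is carried; with no in-window observation the target is missing (NaN).
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(ages)
    ages, values = ages[order], values[order]
    if np.any(np.diff(ages) <= 0):
        raise ValueError("duplicate measurement ages within child")
    targets = np.asarray(targets, dtype=float)
    out = np.full(len(targets), np.nan)
    for j, (t, (lo, hi)) in enumerate(zip(targets, _target_windows(targets))):
        exact = np.flatnonzero(np.isclose(ages, t, rtol=0, atol=1e-12))
        if exact.size:
            out[j] = values[exact[0]]
            continue
        inside = np.flatnonzero((ages >= lo) & (ages < hi))
        if not inside.size:
            continue
        a, v = ages[inside], values[inside]
        left, right = a < t, a > t
        if left.any() and right.any():
            out[j] = np.interp(t, a, v)
        else:
            out[j] = v[np.argmin(np.abs(a - t))]
    return out


def wl_correlation(zw, zl) -> float:
    """Pearson correlation between weight and length z-scores at one age."""
    zw = np.asarray(zw, dtype=float)
    zl = np.asarray(zl, dtype=float)
    if len(zw) != len(zl) or len(zw) < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(zw, ddof=1) == 0 or np.std(zl, ddof=1) == 0:
        raise ValueError("zero variance in weight or length z-scores")
    r = float(np.corrcoef(zw, zl)[0, 1])
    if abs(r) >= 1.0 - 1e-12:
        raise ValueError("degenerate input: |r| = 1 (weight and length z collinear)")
    return r


def weight_for_length_z(zw, zl, r) -> np.ndarray | float:
    """Conditional weight-for-length z: (z_wt - r*z_len)/sqrt(1 - r^2)."""
    if not abs(float(r)) < 1.0:
        raise ValueError("weight-length correlation must satisfy |r| < 1")
    zw = np.asarray(zw, dtype=float)
    zl = np.asarray(zl, dtype=float)
    out = (zw - r * zl) / np.sqrt(1.0 - r * r)
    return out if out.ndim else float(out)


CUTOFF_COLUMNS = ["sex", "age_years", "bmi_cutoff"]


def classify_overweight(
    weight_kg, height_cm, age_years, sex, cutoffs: pd.DataFrame
) -> np.ndarray:
    """Overweight indicator: BMI at or above the age/sex-interpolated cutoff.

    Cutoff values (e.g. the IOTF table) are user input, interpolated linearly
    in age within sex; the boundary BMI == cutoff classifies as overweight.
    """
    missing = [c for c in CUTOFF_COLUMNS if c not in cutoffs.columns]
    if missing:
        raise ValueError(f"cutoff table missing columns {missing}")
    if (cutoffs["bmi_cutoff"] <= 0).any():
        raise ValueError("cutoffs must be positive")
    weight = np.atleast_1d(np.asarray(weight_kg, dtype=float))
    height = np.atleast_1d(np.asarray(height_cm, dtype=float))
    age = np.atleast_1d(np.asarray(age_years, dtype=float))
    sex = np.atleast_1d(np.asarray(sex))
    bmi = weight / (height / 100.0) ** 2
    out = np.zeros(len(bmi), dtype=int)
    for s in np.unique(sex):
        grp = cutoffs[cutoffs["sex"] == s].sort_values("age_years")
        if grp.empty:
            raise ValueError(f"cutoff table has no rows for sex={s!r}")
        ga = grp["age_years"].to_numpy(dtype=float)
        mask = sex == s
        if age[mask].min() < ga[0] - 1e-9 or age[mask].max() > ga[-1] + 1e-9:
            raise ValueError(f"age outside cutoff table range [{ga[0]:g}, {ga[-1]:g}]")
        cut = np.interp(age[mask], ga, grp["bmi_cutoff"].to_numpy(dtype=float))
        out[mask] = (bmi[mask] >= cut).astype(int)
    return out


@dataclass
class PreparedCohort:
    """Balanced conditional-z matrix plus outcome, covariates and audit trail."""

    data: pd.DataFrame  # child_id, z*, sex, gest_age, outcome
    wl_correlations: pd.Series  # r_t per target age
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def Z(self) -> pd.DataFrame:
        return self.data[z_columns(tuple(self.targets))]

    @property
    def targets(self) -> list[float]:
        return list(self.wl_correlations.index)


def prepare(
    records: pd.DataFrame,
    reference: pd.DataFrame,
    outcome: pd.Series | pd.DataFrame | None = None,
    targets=TARGET_AGES,
    cutoffs: pd.DataFrame | None = None,
    outcome_measurements: pd.DataFrame | None = None,
    wl_correlations: pd.Series | dict | None = None,
) -> PreparedCohort:
    """Full preparation pipeline from long-format records to analysis data.

    Parameters
    ----------
    records : DataFrame
        Long format with columns ``child_id, sex, gest_age, age_months,
        weight_kg, length_cm``.
    reference : DataFrame
        L/M/S rows per (sex, age, measure).
    outcome : Series or DataFrame, optional
        Pre-computed outcome per child (Series indexed by child_id, or
        DataFrame with ``child_id``/``outcome`` columns).
    cutoffs, outcome_measurements : optional
        Alternative outcome route: a later measurement table
        (``child_id, sex, age_years, weight_kg, height_cm``) classified
        against a BMI cutoff table.
    wl_correlations : optional
        Externally supplied weight-length z correlations per target age;
        computed from the analysis sample when omitted.

    The result is complete-case: any child missing a target z-score, the
    outcome, or a covariate is dropped, and the counts are logged per reason.
    """
    targets = validate_ages(tuple(targets))
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns {missing}")
    if (records["age_months"] < 0).any():
        raise ValueError("ages must be nonnegative")
    if (records[["weight_kg", "length_cm"]] <= 0).any().any():
        raise ValueError("measurements must be positive")
    validate_reference(reference)

    rec = records.copy()
    for measure, col, zname in (
        ("weight", "weight_kg", "zw"),
        ("length", "length_cm", "zl"),
    ):
        rec[zname] = np.nan
        for sex in rec["sex"].unique():
            m = rec["sex"] == sex
            L, M, S = lookup_lms(reference, sex, measure, rec.loc[m, "age_months"])
            rec.loc[m, zname] = lms_z(rec.loc[m, col], L, M, S)

    zc = z_columns(targets)
    wide_w, wide_l, covs = {}, {}, {}
    for cid, grp in rec.groupby("child_id", sort=True):
        if grp["sex"].nunique() > 1 or grp["gest_age"].nunique() > 1:
            raise ValueError(f"inconsistent covariates for child {cid!r}")
        wide_w[cid] = interpolate_to_targets(grp["age_months"], grp["zw"], targets)
        wide_l[cid] = interpolate_to_targets(grp["age_months"], grp["zl"], targets)
        covs[cid] = (grp["sex"].iloc[0], grp["gest_age"].iloc[0])

    ids = sorted(wide_w)
    W = pd.DataFrame([wide_w[c] for c in ids], index=ids, columns=zc)
    Lz = pd.DataFrame([wide_l[c] for c in ids], index=ids, columns=zc)
    cov = pd.DataFrame([covs[c] for c in ids], index=ids, columns=["sex", "gest_age"])

    if outcome is None and outcome_measurements is not None:
        if cutoffs is None:
            raise ValueError("cutoffs required to classify outcome measurements")
        om = outcome_measurements
        y = pd.Series(
            classify_overweight(
                om["weight_kg"], om["height_cm"], om["age_years"], om["sex"], cutoffs
            ),
            index=om["child_id"].to_numpy(),
        )
    elif isinstance(outcome, pd.DataFrame):
        y = outcome.set_index("child_id")["outcome"]
    elif outcome is not None:
        y = pd.Series(outcome)
    else:
        raise ValueError("provide either outcome or outcome_measurements")
    y = y.reindex(ids)

    dropped = {
        "incomplete_exposures": int(
            ((W.isna().any(axis=1)) | (Lz.isna().any(axis=1))).sum()
        ),
        "missing_outcome": int(
            (y.isna() & ~(W.isna().any(axis=1) | Lz.isna().any(axis=1))).sum()
        ),
        "missing_covariates": int(cov.isna().any(axis=1).sum()),
    }
    keep = (
        ~W.isna().any(axis=1)
        & ~Lz.isna().any(axis=1)
        & ~y.isna()
        & ~cov.isna().any(axis=1)
    )
    if not keep.any():
        raise ValueError("no complete cases remain after restriction")
    for reason, cnt in dropped.items():
        if cnt:
            logger.info("prepare: dropped %d children (%s)", cnt, reason)
    W, Lz, cov, y = W[keep], Lz[keep], cov[keep], y[keep]

    if wl_correlations is not None:
        r_t = pd.Series(dict(wl_correlations)).reindex(targets)
        if r_t.isna().any():
            raise ValueError("wl_correlations must cover every target age")
    else:
        r_t = pd.Series(
            {t: wl_correlation(W[c], Lz[c]) for t, c in zip(targets, zc)}
        )

    Zc = pd.DataFrame(
        {
            c: weight_for_length_z(W[c], Lz[c], r_t[t])
            for t, c in zip(targets, zc)
        },
        index=W.index,
    )
    data = Zc.copy()
    data.insert(0, "child_id", data.index)
    data["sex"] = cov["sex"]
    data["gest_age"] = cov["gest_age"]
    data["outcome"] = y
    return PreparedCohort(
        data=data.reset_index(drop=True), wl_correlations=r_t, dropped=dropped
    )
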