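"""Synthetic cohorts with the dependence structure the contrast models assume.

Serial weight-for-length z-scores are drawn from a zero-mean, unit-variance
multivariate normal whose correlation decays with time separation,
corr(s, t) = exp(-rate * |g(s) - g(t)|) with g(t) = log(t + 1) by default —
adjacent-visit correlations of roughly 0.7-0.9 at the default rate of 0.35,
mirroring the stylised fact that measurements further apart in time are less
correlated. A binary (or continuous) later outcome is generated from a
logistic (or linear) model on the design of a chosen contrast
parameterisation, so every generating coefficient is recoverable by the
corresponding fit. The generator can also emit unbalanced long-format raw
weight/length records, built by inverting the z-scoring chain, for
end-to-end testing of the preparation pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import build_design
from .schedule import TARGET_AGES, n_periods, validate_ages, z_columns
from .zscores import lms_inverse, lookup_lms

__all__ = [
    "CorrelationSpec",
    "OutcomeSpec",
    "SyntheticCohort",
    "simulate_balanced_z",
    "simulate_outcome",
    "simulate_cohort",
    "simulate_unbalanced_raw",
    "synthetic_reference",
    "synthetic_cutoffs",
]


@dataclass
class CorrelationSpec:
    """Inter-age correlation of the serial z-scores.

    Either an explicit correlation ``matrix`` or a decay rule
    ``corr(s, t) = exp(-decay_rate * |log(s+1) - log(t+1)|)``.
    """

    target_ages: tuple[float, ...] = TARGET_AGES
    matrix: np.ndarray | None = None
    decay_rate: float = 0.35

    def correlation_matrix(self) -> np.ndarray:
        ages = np.asarray(validate_ages(tuple(self.target_ages)))
        if self.matrix is not None:
            C = np.asarray(self.matrix, dtype=float)
        else:
            if self.decay_rate < 0:
                raise ValueError("decay_rate must be nonnegative")
            g = np.log(ages + 1.0)
            C = np.exp(-self.decay_rate * np.abs(g[:, None] - g[None, :]))
        if C.shape != (len(ages), len(ages)):
            raise ValueError("correlation matrix shape does not match target ages")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have a unit diagonal")
        lam_min = float(np.linalg.eigvalsh(C)[0])
        if lam_min <= 1e-10:
            raise ValueError(
                f"correlation matrix is not positive definite "
                f"(smallest eigenvalue {lam_min:.3e})"
            )
        return C


@dataclass
class OutcomeSpec:
    """True outcome model: coefficients act on one contrast's full design.

    ``coefficients`` are log-odds (logit link) per column of the named
    contrast's full-span design; ``covariate_effects`` hold log-odds for sex
    (0/1) and per-week gestational age (centred at 40 weeks in the linear
    predictor so that ``intercept`` anchors prevalence); ``noise_sd`` is the
    residual SD for the identity link.
    """

    parameterisation: str = "c"
    coefficients: tuple[float, ...] = (0.3, 0.5, 0.4, 0.6, 0.4, 0.3)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.0, "gest_age": 0.0}
    )
    intercept: float = -2.0
    link: str = "logit"
    noise_sd: float = 1.0
    target_ages: tuple[float, ...] = TARGET_AGES

    def n_design_columns(self) -> int:
        return n_periods(validate_ages(tuple(self.target_ages))) + 1

    def validate(self) -> "OutcomeSpec":
        if self.parameterisation not in "abcde" or len(self.parameterisation) != 1:
            raise ValueError(f"unknown parameterisation {self.parameterisation!r}")
        if len(self.coefficients) != self.n_design_columns():
            raise ValueError(
                f"contrast {self.parameterisation!r} full design has "
                f"{self.n_design_columns()} columns; got "
                f"{len(self.coefficients)} coefficients"
            )
        if self.link not in ("logit", "identity"):
            raise ValueError("link must be 'logit' or 'identity'")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coefficients"] = [float(c) for c in self.coefficients]
        d["target_ages"] = [float(a) for a in self.target_ages]
        return d


@dataclass
class SyntheticCohort:
    """Simulated balanced cohort with its generating truth attached."""

    data: pd.DataFrame  # child_id, z*, sex, gest_age, outcome
    truth: OutcomeSpec
    seed: int

    @property
    def Z(self) -> pd.DataFrame:
        return self.data[z_columns(tuple(self.truth.target_ages))]

    @property
    def outcome(self) -> pd.Series:
        return self.data["outcome"]


def simulate_balanced_z(
    n: int,
    corr: CorrelationSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw n children's serial z-scores from MVN(0, C)."""
    if n < 2:
        raise ValueError("n must be at least 2")
    corr = corr or CorrelationSpec()
    C = corr.correlation_matrix()
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(C)
    Z = rng.standard_normal((n, C.shape[0])) @ chol.T
    return pd.DataFrame(Z, columns=z_columns(tuple(corr.target_ages)))


def simulate_outcome(
    Z: pd.DataFrame,
    spec: OutcomeSpec,
    seed: int = 0,
) -> SyntheticCohort:
    """Attach covariates and an outcome generated from the named design."""
    spec = spec.validate()
    ages = validate_ages(tuple(spec.target_ages))
    rng = np.random.default_rng(seed)
    n = len(Z)
    sex = rng.integers(0, 2, size=n)
    gest_age = rng.normal(40.0, 1.8, size=n)
    # plausible clinical support; resample the tails rather than clip
    for _ in range(100):
        out_of_range = (gest_age < 30.0) | (gest_age > 44.0)
        if not out_of_range.any():
            break
        gest_age[out_of_range] = rng.normal(40.0, 1.8, size=int(out_of_range.sum()))

    K = n_periods(ages)
    design = build_design(Z, spec.parameterisation, K, ages)
    beta = np.asarray(spec.coefficients, dtype=float)
    eta = (
        spec.intercept
        + design.X.to_numpy() @ beta
        + spec.covariate_effects.get("sex", 0.0) * sex
        + spec.covariate_effects.get("gest_age", 0.0) * (gest_age - 40.0)
    )
    if spec.link == "logit":
        p = 1.0 / (1.0 + np.exp(-eta))
        y = rng.binomial(1, p)
    else:
        y = eta + (rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0)

    data = Z.reset_index(drop=True).copy()
    data.insert(0, "child_id", [f"c{i:06d}" for i in range(n)])
    data["sex"] = sex
    data["gest_age"] = gest_age
    data["outcome"] = y
    return SyntheticCohort(data=data, truth=spec, seed=seed)


def simulate_cohort(
    n: int,
    spec: OutcomeSpec | None = None,
    corr: CorrelationSpec | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Convenience: z matrix + covariates + outcome in one call.

    Child-level randomness derives from a single seed: the z draw and the
    outcome draw use independent streams spawned from it.
    """
    spec = (spec or OutcomeSpec()).validate()
    corr = corr or CorrelationSpec(target_ages=spec.target_ages)
    ss = np.random.SeedSequence(seed).spawn(2)
    z_seed, y_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss)
    Z = simulate_balanced_z(n, corr, z_seed)
    cohort = simulate_outcome(Z, spec, y_seed)
    cohort.seed = seed
    return cohort


def _orthonormal_noise(rng, z_centered: np.ndarray) -> np.ndarray:
    """A vector with exact sample mean 0, SD 1, and zero covariance with z."""
    n = len(z_centered)
    e = rng.standard_normal(n)
    basis = np.column_stack([np.ones(n), z_centered])
    e = e - basis @ np.linalg.lstsq(basis, e, rcond=None)[0]
    return e / e.std(ddof=1)


def _embed_conditional(
    z: np.ndarray, r: float, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Construct (z_weight, z_length) whose in-sample conditional z equals z.

    The pair is built so that the *sample* Pearson correlation between the
    weight and length z columns equals ``r`` exactly; recomputing
    (zw - r_hat*zl)/sqrt(1 - r_hat^2) with the sample r_hat then returns
    ``z`` to machine precision.
    """
    if not 0 <= r < 1:
        raise ValueError("weight-length correlation must be in [0, 1)")
    m = z.mean()
    s2 = z.var(ddof=1)
    if s2 <= r * r:
        raise ValueError(
            "conditional z variance too small to embed the requested "
            f"weight-length correlation (var {s2:.3f} <= r^2 {r*r:.3f})"
        )
    u = np.sqrt(1.0 - r * r)
    q = r * (np.sqrt(s2 - r * r) - u)
    e = _orthonormal_noise(rng, z - m)
    zl = (q / s2) * (z - m) + np.sqrt(1.0 - q * q / s2) * e
    zw = r * zl + u * z
    return zw, zl


def simulate_unbalanced_raw(
    cohort: SyntheticCohort | pd.DataFrame,
    reference: pd.DataFrame,
    age_jitter_sd: float = 0.0,
    seed: int = 0,
    wl_r: float = 0.3,
    max_retries: int = 100,
) -> pd.DataFrame:
    """Long-format raw records whose preparation recovers the cohort's z.

    Weight and length z-score columns are constructed around the cohort's
    conditional z matrix (see :func:`_embed_conditional`), visit ages are
    jittered around the targets (birth stays at 0; order-violating draws are
    resampled, with a warning past ``max_retries``), and raw kilograms and
    centimetres are obtained by inverting the LMS transform at each actual
    age. At zero jitter, running :func:`growthcontrasts.zscores.prepare` on
    the result reproduces the generating z matrix to numerical precision.
    """
    if isinstance(cohort, SyntheticCohort):
        data = cohort.data
        ages = validate_ages(tuple(cohort.truth.target_ages))
    else:
        data = cohort
        ages = TARGET_AGES
    zc = z_columns(ages)
    n = len(data)
    rng = np.random.default_rng(seed)
    if "sex" in data.columns:
        sex = data["sex"].to_numpy()
    else:
        sex = rng.integers(0, 2, size=n)
    gest_age = (
        data["gest_age"].to_numpy()
        if "gest_age" in data.columns
        else rng.normal(40.0, 1.8, size=n)
    )
    child_id = (
        data["child_id"].to_numpy()
        if "child_id" in data.columns
        else np.array([f"c{i:06d}" for i in range(n)])
    )

    ZW = np.empty((n, len(ages)))
    ZL = np.empty((n, len(ages)))
    for j, col in enumerate(zc):
        ZW[:, j], ZL[:, j] = _embed_conditional(
            data[col].to_numpy(dtype=float), wl_r, rng
        )

    targets = np.asarray(ages)
    ref_max = float(reference["age"].max())
    actual = np.tile(targets, (n, 1)).astype(float)
    if age_jitter_sd > 0:
        warned = False
        for i in range(n):
            for attempt in range(max_retries):
                jit = rng.normal(0.0, age_jitter_sd, size=len(targets))
                jit[0] = 0.0  # birth measurement is at birth
                cand = targets + jit
                if np.all(np.diff(cand) > 0) and cand[0] >= 0 and cand[-1] <= ref_max:
                    actual[i] = cand
                    break
            else:
                if not warned:
                    warnings.warn(
                        "age jitter too large to preserve visit order; "
                        "clamping to half the inter-visit gap",
                        stacklevel=2,
                    )
                    warned = True
                half_gap = 0.49 * np.diff(targets).min()
                jit = np.clip(
                    rng.normal(0.0, age_jitter_sd, size=len(targets)),
                    -half_gap,
                    half_gap,
                )
                jit[0] = 0.0
                actual[i] = targets + jit

    rows = []
    for s in np.unique(sex):
        mask = sex == s
        a = actual[mask].ravel()
        Lw, Mw, Sw = lookup_lms(reference, s, "weight", a)
        Ll, Ml, Sl = lookup_lms(reference, s, "length", a)
        w = lms_inverse(ZW[mask].ravel(), Lw, Mw, Sw)
        ln = lms_inverse(ZL[mask].ravel(), Ll, Ml, Sl)
        rows.append(
            pd.DataFrame(
                {
                    "child_id": np.repeat(child_id[mask], len(targets)),
                    "sex": s,
                    "gest_age": np.repeat(gest_age[mask], len(targets)),
                    "age_months": a,
                    "weight_kg": w,
                    "length_cm": ln,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["child_id", "age_months"]).reset_index(drop=True)


def synthetic_reference(
    max_age: float = 30.0, step: float = 0.5
) -> pd.DataFrame:
    """A smooth, plausible infant L/M/S reference for simulation and tests.

    Median weight rises from ~3.5 kg at birth toward ~12 kg by 24 months and
    length from ~50 cm toward ~85 cm, with constant coefficients of
    variation (0.11 weight, 0.035 length) and mild positive skew for weight
    (L = 0.3). Labelled synthetic: it is generated from closed-form curves,
    not fitted to any population.
    """
    grid = np.arange(0.0, max_age + step / 2, step)
    rows = []
    for sex, (w0, wf, l0, lf) in {
        0: (3.4, 11.8, 49.5, 84.0),
        1: (3.6, 12.2, 50.0, 85.0),
    }.items():
        mw = w0 + (wf - w0) * (1.0 - np.exp(-grid / 7.0))
        ml = l0 + (lf - l0) * (1.0 - np.exp(-grid / 9.0))
        for age, m in zip(grid, mw):
            rows.append({"sex": sex, "age": age, "measure": "weight", "L": 0.3, "M": m, "S": 0.11})
        for age, m in zip(grid, ml):
            rows.append({"sex": sex, "age": age, "measure": "length", "L": 1.0, "M": m, "S": 0.035})
    return pd.DataFrame(rows)


def synthetic_cutoffs(lo: float = 17.0, hi: float = 18.5) -> pd.DataFrame:
    """A small synthetic BMI cutoff table (ages 7-10y) for tests and demos.

    Stands in for the user-supplied overweight cutoff table; values are
    round numbers rising linearly with age, not any published criteria.
    """
    ages = np.arange(7.0, 10.01, 0.5)
    rows = []
    for sex in (0, 1):
        cuts = lo + (hi - lo) * (ages - ages[0]) / (ages[-1] - ages[0]) + 0.2 * sex
        for a, c in zip(ages, cuts):
            rows.append({"sex": sex, "age_years": a, "bmi_cutoff": round(float(c), 2)})
    return pd.DataFrame(rows)
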