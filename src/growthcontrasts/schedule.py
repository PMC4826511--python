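"""Measurement schedule: target ages, interval periods and column naming.

The balanced exposure matrix holds one weight-for-length z-score per child
at each of six target ages (months): birth, 6 weeks, 3, 6, 12 and 24 months.
Growth periods are the five intervals between consecutive target ages.
Column names serialise 1.5 months as the token ``1p5`` so that headers stay
valid identifiers in CSV and formula contexts.
"""

from __future__ import annotations

TARGET_AGES: tuple[float, ...] = (0.0, 1.5, 3.0, 6.0, 12.0, 24.0)

#: Interval labels for periods 1..5 (period k spans target age k-1 to k).
PERIOD_LABELS: dict[int, str] = {
    1: "Birth to 6w",
    2: "6w to 3 m",
    3: "3 to 6 m",
    4: "6 to 12 m",
    5: "12 to 24 m",
}

#: Cumulative labels used by the being-bigger contrast (period 0 = birth only).
CUMULATIVE_LABELS: dict[int, str] = {
    0: "At birth",
    1: "birth to 6w",
    2: "birth to 3 m",
    3: "birth to 6 m",
    4: "birth to 12 m",
    5: "birth to 24 m",
}

CONTRASTS: tuple[str, ...] = ("a", "b", "c", "d", "e")

CONTRAST_NAMES: dict[str, str] = {
    "a": "Conditional growth",
    "b": "Being bigger",
    "c": "Becoming bigger and staying bigger",
    "d": "Growing faster v being bigger",
    "e": "Becoming bigger v being bigger",
}


def age_token(age: float) -> str:
    """Serialise an age in months for use in a column name (1.5 -> '1p5')."""
    if float(age) == int(age):
        return str(int(age))
    return str(float(age)).replace(".", "p")


def z_columns(ages: tuple[float, ...] = TARGET_AGES) -> list[str]:
    """Column names for size z-scores at each target age."""
    return [f"z{age_token(a)}" for a in ages]


def delta_columns(ages: tuple[float, ...] = TARGET_AGES) -> list[str]:
    """Column names for interval changes z_{t_k} - z_{t_{k-1}}, k = 1..K."""
    return [
        f"d_{age_token(a0)}_{age_token(a1)}" for a0, a1 in zip(ages[:-1], ages[1:])
    ]


def n_periods(ages: tuple[float, ...] = TARGET_AGES) -> int:
    return len(ages) - 1


def period_label(k: int, ages: tuple[float, ...] = TARGET_AGES) -> str:
    """Human-readable label for interval period k (1-based)."""
    if ages == TARGET_AGES and k in PERIOD_LABELS:
        return PERIOD_LABELS[k]
    return f"{ages[k - 1]:g} to {ages[k]:g} m"


def cumulative_label(k: int, ages: tuple[float, ...] = TARGET_AGES) -> str:
    """Label for the cumulative birth-to-age-k span (k = 0 means birth only)."""
    if ages == TARGET_AGES and k in CUMULATIVE_LABELS:
        return CUMULATIVE_LABELS[k]
    if k == 0:
        return "At birth"
    return f"birth to {ages[k]:g} m"


def validate_ages(ages: tuple[float, ...]) -> tuple[float, ...]:
    ages = tuple(float(a) for a in ages)
    if len(ages) < 2:
        raise ValueError("need at least two target ages")
    if ages[0] != 0.0:
        raise ValueError("target ages must start at 0 (birth)")
    if any(b <= a for a, b in zip(ages[:-1], ages[1:])):
        raise ValueError("target ages must be strictly increasing")
    return ages
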