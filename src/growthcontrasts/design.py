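"""Design matrices for the five growth-pattern contrasts.

Each contrast is a reparameterisation of a regression on the same underlying
size measurements, obtained by choosing which combination of sizes (z_t) and
interval changes (delta_k = z_{t_k} - z_{t_{k-1}}) enters the model:

====  ===================================  =========================================
id    contrast                             design columns (period k)
====  ===================================  =========================================
a     conditional growth                   z_0, ..., z_{t_k}
b     being bigger v being smaller         z_0, delta_1, ..., delta_k
c     becoming bigger and staying bigger   z_0, delta_1, ..., delta_K   (full span)
d     growing faster v being bigger        delta_1, ..., delta_k, z_{t_k}
e     becoming bigger v being bigger       delta_1, ..., delta_K, z_{t_K} (full span)
====  ===================================  =========================================

Contrasts (c) and (e) are single full-span models; (a), (b) and (d) are
sequences indexed by period. All designs ending at the final target age span
the same column space — they differ only in parameterisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedule import (
    CONTRASTS,
    TARGET_AGES,
    delta_columns,
    n_periods,
    validate_ages,
    z_columns,
)

__all__ = ["LabelledDesign", "build_design", "add_deltas", "reported_column"]


@dataclass
class LabelledDesign:
    """A design matrix with semantic column labels.

    Attributes
    ----------
    X : DataFrame of shape (n_children, n_columns)
        Design values; columns are size z-scores (``z*``) or interval
        differences (``d_*``).
    contrast : str
        Contrast id in {'a','b','c','d','e'}.
    period : int
        Period index the design ends at (0-based only for contrast b's
        "At birth" model; full-span contrasts use the last period).
    reported : str
        Name of the column whose coefficient the contrast reports for
        this period.
    """

    X: pd.DataFrame
    contrast: str
    period: int
    reported: str
    ages: tuple[float, ...] = field(default=TARGET_AGES)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


def add_deltas(Z: pd.DataFrame, ages: tuple[float, ...] = TARGET_AGES) -> pd.DataFrame:
    """Append interval-difference columns to a balanced z matrix."""
    zc = z_columns(ages)
    missing = [c for c in zc if c not in Z.columns]
    if missing:
        raise ValueError(f"balanced z matrix is missing columns {missing}")
    out = Z[zc].copy()
    for name, (c0, c1) in zip(delta_columns(ages), zip(zc[:-1], zc[1:])):
        out[name] = out[c1] - out[c0]
    return out


def _check_complete(Z: pd.DataFrame, cols: list[str]) -> None:
    if Z[cols].isna().any().any():
        raise ValueError("balanced z matrix must be complete (no missing cells)")


def reported_column(
    contrast: str, period: int, ages: tuple[float, ...] = TARGET_AGES
) -> str:
    """Which design column's coefficient is the contrast's reported value."""
    zc, dc = z_columns(ages), delta_columns(ages)
    K = n_periods(ages)
    if contrast == "a":
        return zc[period]
    if contrast == "b":
        return zc[0]
    if contrast in ("c", "e"):
        return dc[period - 1]
    if contrast == "d":
        return dc[period - 1] if period <= K else dc[-1]
    raise ValueError(f"unknown contrast {contrast!r}")


def build_design(
    Z: pd.DataFrame,
    contrast: str,
    period: int | None = None,
    ages: tuple[float, ...] = TARGET_AGES,
) -> LabelledDesign:
    """Build the labelled design matrix for one contrast and period.

    Parameters
    ----------
    Z : DataFrame
        Balanced z matrix containing the ``z*`` columns (extra columns such
        as covariates are ignored here).
    contrast : {'a','b','c','d','e'}
    period : int, optional
        1..K for contrasts (a) and (d); 0..K for (b) (0 = birth size only).
        Ignored by the full-span contrasts (c) and (e).
    """
    ages = validate_ages(ages)
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    K = n_periods(ages)
    zc, dc = z_columns(ages), delta_columns(ages)
    _check_complete(Z, zc)
    ZD = add_deltas(Z, ages)

    if contrast in ("c", "e"):
        period = K
    if period is None:
        raise ValueError(f"contrast {contrast!r} requires a period argument")
    lo = 0 if contrast == "b" else 1
    if not lo <= period <= K:
        raise ValueError(
            f"period {period} invalid for contrast {contrast!r} "
            f"(allowed {lo}..{K})"
        )

    if contrast == "a":
        cols = zc[: period + 1]
    elif contrast == "b":
        cols = [zc[0]] + dc[:period]
    elif contrast == "c":
        cols = [zc[0]] + dc
    elif contrast == "d":
        cols = dc[:period] + [zc[period]]
    else:  # e
        cols = dc + [zc[K]]

    X = ZD[cols].copy()
    return LabelledDesign(
        X=X,
        contrast=contrast,
        period=period,
        reported=reported_column(contrast, period, ages),
        ages=ages,
    )
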