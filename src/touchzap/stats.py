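"""Cohort summaries and hypothesis tests.

Summary tables report sample mean +/- SD (n-1 denominator) with the sample
size in parentheses.  The relative linear cell-size proxy L_rel is
sqrt(1/R_in) normalized to the cell-type mean (so the normalization cohort
averages to 1 by construction).  Hypothesis tests (pooled two-proportion z,
Student/Welch two-sample t, Pearson/Spearman correlations with a one-sided
Fisher-z p) are implemented in closed form; multivariate machinery (MANOVA)
is deliberately replaced by per-variable pairwise tests, which output
headers note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

TOUCH_ENDPOINTS = ("TZ", "TZS", "TS")


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


# ---------------------------------------------------------------------------
# relative cell size


@dataclass
class LRelResult:
    """Per-cell relative linear size and per-group means."""

    values: pd.Series
    group_means: Dict[str, float]


def l_rel(r_in_mohm: Sequence[float], cohort: Optional[Sequence[str]] = None) -> LRelResult:
    """Relative linear cell size: sqrt(1/R_in) over the normalization-cohort
    mean of the same quantity.

    ``cohort`` assigns each cell to its normalization group (e.g. cell type);
    omitted, all cells form one cohort.  The mean of L_rel over each cohort
    is 1 by construction.  Raises on non-positive R_in.
    """
    r = pd.Series(np.asarray(r_in_mohm, dtype=float))
    if np.any(~np.isfinite(r)) or np.any(r <= 0):
        raise ValueError("all R_in values must be finite and positive")
    raw = np.sqrt(1.0 / r)
    groups = pd.Series(["all"] * len(r)) if cohort is None else pd.Series(list(cohort))
    means = raw.groupby(groups).transform("mean")
    values = raw / means
    group_means = raw.groupby(groups).mean().to_dict()
    return LRelResult(values=values, group_means=group_means)


def relative_access_resistance(r_a_mohm: float, r_in_mohm: float) -> float:
    """Access resistance normalized to the cell input resistance, R_a/R_in —
    the figure of merit bounding voltage errors in current-injection
    protocols."""
    if r_in_mohm <= 0:
        raise ValueError("R_in must be positive")
    return r_a_mohm / r_in_mohm


# ---------------------------------------------------------------------------
# proportions


def endpoint_proportions(counts: pd.DataFrame, endpoints: Sequence[str] = TOUCH_ENDPOINTS) -> pd.DataFrame:
    """Endpoint proportions per row group, with touch-variant denominators.

    ``counts`` has one row per group (e.g. cell class) and one integer column
    per endpoint; the denominator for each row is the sum over ``endpoints``
    (TZ+TZS+TS by default).  A zero denominator yields NaN entries, not 0.
    """
    counts = counts[list(endpoints)]
    if (counts.to_numpy() < 0).any():
        raise ValueError("endpoint counts must be non-negative")
    denom = counts.sum(axis=1)
    out = counts.div(denom.where(denom > 0), axis=0)
    return out


def class_proportion(
    counts: pd.DataFrame,
    cell_class: str,
    endpoints: Sequence[str] = TOUCH_ENDPOINTS,
) -> Tuple[float, int, int]:
    """Fraction of recordings belonging to ``cell_class`` among the given
    access-method endpoints: returns (proportion, numerator, denominator)."""
    sub = counts[list(endpoints)]
    total = int(sub.to_numpy().sum())
    if total == 0:
        raise ValueError("zero recordings for the requested endpoints")
    x = int(sub.loc[counts.index.get_level_values("cell_class") == cell_class].to_numpy().sum())
    return x / total, x, total


# ---------------------------------------------------------------------------
# hypothesis tests


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> Tuple[float, float]:
    """Pooled two-proportion z test, two-sided normal-approximation p.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion.
    Raises when the pooled proportion is degenerate (0 or 1).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError("need 0 <= x <= n with n > 0")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("pooled proportion is degenerate (0 or 1): z undefined")
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    return z, 2.0 * _norm_sf(abs(z))


def two_sample_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: str = "student",
) -> Tuple[float, float, float]:
    """Two-sample t test: (t, df, two-sided p).

    ``student`` pools the variances (df = n1+n2-2); ``welch`` uses the
    Welch-Satterthwaite df.  Zero variance with unequal means reports an
    infinite t (p = 0) rather than raising.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    n1, n2 = a.size, b.size
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if mode == "student":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif mode == "welch":
        se2 = v1 / n1 + v2 / n2
        se = math.sqrt(se2)
        if se2 > 0:
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            df = n1 + n2 - 2
    else:
        raise ValueError("mode must be 'student' or 'welch'")
    if se == 0:
        if m1 == m2:
            return 0.0, float(df), 1.0
        return math.copysign(math.inf, m1 - m2), float(df), 0.0
    t = (m1 - m2) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), float(df), p


@dataclass
class CorrelationResult:
    pearson_r2: float
    spearman_rho: float
    p_one_sided: float  # Fisher-z test on the rank correlation


def correlations(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Squared Pearson correlation, Spearman rank correlation, and a
    one-sided normal (Fisher z) p for the rank correlation.

    Raises for n < 3, non-finite input, or constant input (undefined r).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlations need matched samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("correlations require finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")

    def _pearson(u, v):
        du, dv = u - u.mean(), v - v.mean()
        return float(np.dot(du, dv) / math.sqrt(np.dot(du, du) * np.dot(dv, dv)))

    r = _pearson(x, y)
    rho = _pearson(sps.rankdata(x), sps.rankdata(y))
    n = x.size
    rho_c = min(max(rho, -1 + 1e-15), 1 - 1e-15)
    z = math.atanh(rho_c) * math.sqrt(n - 3)
    return CorrelationResult(pearson_r2=r * r, spearman_rho=rho, p_one_sided=_norm_sf(abs(z)))


# ---------------------------------------------------------------------------
# tables


def summarize(
    records: pd.DataFrame,
    values: Sequence[str],
    by: Sequence[str] = ("cell_class", "endpoint"),
) -> pd.DataFrame:
    """Grouped summary: mean, SD (n-1) and n per value column, plus a
    formatted 'mean +/- SD (n)' presentation column."""
    out = []
    for keys, grp in records.groupby(list(by)):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(by, keys))
        for col in values:
            vals = grp[col].dropna().to_numpy(dtype=float)
            n = vals.size
            mean = float(vals.mean()) if n else float("nan")
            sd = float(vals.std(ddof=1)) if n > 1 else float("nan")
            row[f"{col}_mean"] = mean
            row[f"{col}_sd"] = sd
            row[f"{col}_n"] = n
            row[f"{col}"] = f"{mean:.3g}±{sd:.2g} ({n})" if n else "n/a"
        out.append(row)
    return pd.DataFrame(out)


def round_half_away(x: float) -> int:
    """Presentation rounding of percentages: half away from zero."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


__all__ = [
    "TOUCH_ENDPOINTS",
    "LRelResult",
    "CorrelationResult",
    "l_rel",
    "relative_access_resistance",
    "endpoint_proportions",
    "class_proportion",
    "two_proportion_z",
    "two_sample_t",
    "correlations",
    "summarize",
    "round_half_away",
]
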