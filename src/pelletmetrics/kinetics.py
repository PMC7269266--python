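"""Cultivation kinetics and per-day condition comparisons.

Two jobs live here: the biomass-specific productivity

    q_P(t) = (1/X) * dP/dt        [mg g^-1 d^-1]

computed from daily product (P, mg L^-1) and cell-dry-weight (X, g L^-1)
series, and single-factor ANOVA used to compare cultivation conditions day by
day at alpha = 0.05.  dP/dt is discretized with central differences on
interior points and one-sided differences at the ends; the sampling grid may
be non-uniform.  Days where X = 0 yield NaN (flagged, never infinite).

The F statistic is computed from unequal-n sums of squares; only the tail
probability is delegated to the F distribution's survival function.  No
multiple-testing correction is applied across days (recorded in the output
metadata of :func:`compare_conditions_per_day`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CultivationSeries",
    "AnovaResult",
    "DegenerateDataError",
    "specific_productivity",
    "anova_oneway",
    "compare_conditions_per_day",
]


class DegenerateDataError(ValueError):
    """Raised when group structure leaves the F statistic undefined."""


@dataclass(frozen=True)
class CultivationSeries:
    """Daily cultivation observables for one condition.

    t_days must be strictly increasing; concentrations are non-negative.
    Glucose is optional (None when not assayed).
    """

    t_days: np.ndarray
    P_mg_per_L: np.ndarray
    X_g_per_L: np.ndarray
    S_g_per_L: np.ndarray | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t_days, float)
        p = np.asarray(self.P_mg_per_L, float)
        x = np.asarray(self.X_g_per_L, float)
        if not (len(t) == len(p) == len(x)):
            raise ValueError("t, P and X must have equal lengths")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_days must be strictly increasing")
        if np.any(p < 0) or np.any(x < 0):
            raise ValueError("concentrations must be >= 0")
        s = self.S_g_per_L
        if s is not None:
            s = np.asarray(s, float)
            if len(s) != len(t):
                raise ValueError("S length mismatch")
            if np.any(s < 0):
                raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "t_days", t)
        object.__setattr__(self, "P_mg_per_L", p)
        object.__setattr__(self, "X_g_per_L", x)
        object.__setattr__(self, "S_g_per_L", s)

    def to_frame(self) -> pd.DataFrame:
        d = {"t_days": self.t_days, "P_mg_per_L": self.P_mg_per_L,
             "X_g_per_L": self.X_g_per_L}
        if self.S_g_per_L is not None:
            d["S_g_per_L"] = self.S_g_per_L
        return pd.DataFrame(d)


@dataclass(frozen=True)
class AnovaResult:
    f_value: float
    p_value: float
    df_between: int
    df_within: int
    group_ns: tuple[int, ...]
    alpha: float = 0.05
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "significant", bool(self.p_value < self.alpha))


def specific_productivity(series: CultivationSeries) -> np.ndarray:
    """Biomass-specific productivity q_P at each sampling time.

    Returns an array aligned with ``series.t_days``; entries where X = 0 are
    NaN.  Raises on series shorter than two points.
    """
    t, p, x = series.t_days, series.P_mg_per_L, series.X_g_per_L
    if len(t) < 2:
        raise ValueError("need at least 2 time points for dP/dt")
    dpdt = np.gradient(p, t)  # central interior, one-sided ends
    with np.errstate(divide="ignore", invalid="ignore"):
        qp = np.where(x > 0, dpdt / np.where(x > 0, x, 1.0), np.nan)
    return qp


def anova_oneway(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> AnovaResult:
    """Single-factor ANOVA with unequal group sizes.

    Every group must contain at least two observations (small-n results are
    rejected rather than silently reported).  A design with zero between- and
    zero within-group variance is degenerate and raises, as is zero
    within-group variance alone (F undefined/infinite).
    """
    arrs = [np.asarray(g, float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    for g in arrs:
        if g.ndim != 1 or len(g) < 2:
            raise ValueError("every group needs >= 2 observations")
    ns = np.array([len(g) for g in arrs])
    n_total = int(ns.sum())
    k = len(arrs)
    grand = np.concatenate(arrs).mean()
    means = np.array([g.mean() for g in arrs])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - m) ** 2) for g, m in zip(arrs, means)))
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        raise DegenerateDataError(
            "degenerate: zero within-group variance (F undefined)")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(f_value=float(f), p_value=p, df_between=df_b,
                       df_within=df_w, group_ns=tuple(int(n) for n in ns),
                       alpha=alpha)


def compare_conditions_per_day(table: pd.DataFrame, alpha: float = 0.05,
                               value_col: str = "value") -> pd.DataFrame:
    """Run one ANOVA per day across conditions.

    ``table`` is long-format with columns ``day``, ``condition`` and
    ``value_col``.  Days where any condition has fewer than two replicates, or
    fewer than two conditions are present, are reported as skipped with a
    reason; degenerate designs (zero within-group variance) likewise.

    Returns a frame with one row per day: day, n_groups, f_value, p_value,
    significant, status, reason.  ``attrs['multiple_testing']`` documents that
    no across-day correction is applied.
    """
    required = {"day", "condition", value_col}
    if not required.issubset(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    rows = []
    for day, sub in table.groupby("day", sort=True):
        groups = [g[value_col].to_numpy(float) for _, g in sub.groupby("condition")]
        base = {"day": day, "n_groups": len(groups),
                "f_value": np.nan, "p_value": np.nan, "significant": False}
        if len(groups) < 2:
            rows.append({**base, "status": "skipped",
                         "reason": "fewer than 2 conditions"})
            continue
        if any(len(g) < 2 for g in groups):
            rows.append({**base, "status": "skipped",
                         "reason": "a condition has fewer than 2 replicates"})
            continue
        try:
            res = anova_oneway(groups, alpha=alpha)
        except DegenerateDataError as exc:
            rows.append({**base, "status": "degenerate", "reason": str(exc)})
            continue
        rows.append({**base, "f_value": res.f_value, "p_value": res.p_value,
                     "significant": res.significant, "status": "ok",
                     "reason": ""})
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["multiple_testing"] = "none (per-day tests are uncorrected)"
    return out
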