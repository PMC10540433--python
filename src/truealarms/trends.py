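"""Trend analyses over the specificity sweep.

Two regressions summarize the audit: (1) the relative risk of the
false-positive group as a linear function of the target specificity
level, and (2) per severity scale, the difference between the
true-positive and false-positive normalized group means as a function of
specificity — a negative slope means the two groups converge as the
threshold rises.

Simple OLS is implemented in closed form (slope = S_xy / S_xx) with its
full inference set: R-squared, adjusted R-squared, the F statistic on
(1, n-2) degrees of freedom and its p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .audit import RRResult
from .cohort import CohortTable
from .thresholds import SweepEntry

__all__ = [
    "TrendFit",
    "ols_trend",
    "rr_trend",
    "minmax_normalize",
    "severity_profiles",
    "convergence_trends",
]


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "f_stat": self.f_stat,
            "df1": self.df1,
            "df2": self.df2,
            "p_value": self.p_value,
            "n_points": self.n_points,
        }


def ols_trend(x, y) -> TrendFit:
    """Closed-form simple linear regression of y on x with F inference.

    Degenerate cases: constant x fails; constant y yields slope 0,
    F = 0, p = 1; an exact fit yields R^2 = 1, F = +inf, p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y differ in length")
    n = x.size
    if n < 3:
        raise ValueError("ols_trend requires at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("ols_trend requires finite inputs")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    syy = float(np.sum((y - ybar) ** 2))
    if sxx == 0.0:
        raise ValueError("x is constant; slope undefined")
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    df1, df2 = 1, n - 2
    if syy == 0.0:
        return TrendFit(slope, intercept, 0.0, 0.0, 0.0, df1, df2, 1.0, n)
    ss_reg = slope * sxy
    ss_res = max(syy - ss_reg, 0.0)
    r2 = ss_reg / syy
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if ss_res == 0.0:
        return TrendFit(slope, intercept, 1.0, 1.0, math.inf, df1, df2, 0.0, n)
    f_stat = (ss_reg / df1) / (ss_res / df2)
    p = float(f_dist.sf(f_stat, df1, df2))
    return TrendFit(slope, intercept, r2, adj_r2, f_stat, df1, df2, p, n)


def rr_trend(audit: list[RRResult]) -> tuple[TrendFit, int]:
    """OLS of relative risk on specificity level, excluding unusable levels.

    Degenerate and non-finite RR levels are dropped; the count of
    exclusions is returned alongside the fit.  Fewer than 3 usable
    points is a failure with diagnostics.
    """
    x, y, excluded = [], [], 0
    for r in audit:
        if r.degenerate or not np.isfinite(r.rr):
            excluded += 1
            continue
        x.append(r.level)
        y.append(r.rr)
    if len(x) < 3:
        raise ValueError(
            f"rr_trend needs >= 3 usable levels, got {len(x)} "
            f"({excluded} excluded of {len(audit)})"
        )
    return ols_trend(np.array(x), np.array(y)), excluded


def minmax_normalize(values, reference) -> np.ndarray:
    """Map values through (v - min_ref) / (max_ref - min_ref).

    Reference statistics come from the full evaluation split so all
    groups share one scale; a constant reference is a failure.
    """
    ref = np.asarray(reference, dtype=float)
    lo, hi = np.nanmin(ref), np.nanmax(ref)
    if hi == lo:
        raise ValueError("reference values are constant; normalization undefined")
    return (np.asarray(values, dtype=float) - lo) / (hi - lo)


def severity_profiles(
    cohort: CohortTable, entries: list[SweepEntry], scales: list[str]
) -> pd.DataFrame:
    """Normalized FP and TP group means per scale and specificity level.

    Normalization reference is the union of all confusion groups (the
    evaluation split).  Empty groups emit no row.  Columns:
    level, group, scale, normalized_mean, group_n.
    """
    for s in scales:
        if s not in cohort.data.columns:
            raise ValueError(f"scale {s!r} not present in cohort")
    if not entries:
        return pd.DataFrame(columns=["level", "group", "scale", "normalized_mean", "group_n"])
    e0 = entries[0].split
    test_ids = np.concatenate([e0.tp_ids, e0.fp_ids, e0.tn_ids, e0.fn_ids])
    df = cohort.data.set_index("subject_id")
    normalized = {}
    for s in scales:
        ref = df.loc[test_ids, s].to_numpy(dtype=float)
        normalized[s] = pd.Series(
            minmax_normalize(ref, ref), index=pd.Index(test_ids)
        )
    rows = []
    for e in entries:
        for group, ids in (("FP", e.split.fp_ids), ("TP", e.split.tp_ids)):
            if len(ids) == 0:
                continue
            for s in scales:
                vals = normalized[s].loc[ids]
                rows.append(
                    {
                        "level": e.level,
                        "group": group,
                        "scale": s,
                        "normalized_mean": float(vals.mean()),
                        "group_n": int(len(ids)),
                    }
                )
    return pd.DataFrame(rows)


def convergence_trends(profiles: pd.DataFrame) -> dict[str, tuple[TrendFit, int]]:
    """Per scale: OLS of d(level) = TP mean - FP mean on specificity level.

    Only levels where both groups are present enter the fit; a scale with
    fewer than 3 common levels fails individually while others proceed.
    Returns {scale: (fit, n_common_levels)}.
    """
    out: dict[str, tuple[TrendFit, int]] = {}
    errors: dict[str, str] = {}
    for scale, sub in profiles.groupby("scale"):
        wide = sub.pivot_table(
            index="level", columns="group", values="normalized_mean"
        )
        if not {"FP", "TP"}.issubset(wide.columns):
            errors[scale] = "a group is absent at every level"
            continue
        wide = wide.dropna(subset=["FP", "TP"])
        if len(wide) < 3:
            errors[scale] = f"only {len(wide)} common levels"
            continue
        d = (wide["TP"] - wide["FP"]).to_numpy()
        out[scale] = (ols_trend(wide.index.to_numpy(dtype=float), d), len(wide))
    if errors and not out:
        raise ValueError(f"no scale had enough common levels: {errors}")
    for scale, msg in errors.items():
        out[scale] = (None, 0)  # type: ignore[arg-type]
    return out
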