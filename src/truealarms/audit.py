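"""Follow-up risk audit of false positives against true negatives.

At each specificity level the false-positive and true-negative groups
(both wave-1 negatives by construction) are linked to their wave-2
first-attempt outcomes, restricted to wave-2 responders, and compared via
the relative risk

    RR = (a / (a+b)) / (c / (c+d)),

where a, b count first-attempters / non-attempters among FP responders
and c, d the same among TN responders.  Evidence that RR > 1 is assessed
with the one-sided Fisher exact test (hypergeometric tail with fixed
margins), and two lower confidence bounds are reported: the exact
conditional odds-ratio bound from inverting the noncentral hypergeometric
tail, and a Wald bound on the log relative risk.  The two estimands
differ; both are emitted so neither is silently conflated with the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from .cohort import CohortTable
from .thresholds import ConfusionSplit, SweepEntry

__all__ = [
    "FollowupTable2x2",
    "RRResult",
    "UndefinedRRError",
    "link_followup",
    "relative_risk",
    "fisher_one_sided",
    "exact_ci_lower",
    "audit_sweep",
    "audit_table",
]

#: FP responder counts below this raise a small-cell flag (never dropped).
MIN_COUNT_FLAG = 5


class UndefinedRRError(ValueError):
    """Relative risk undefined: an empty FP or TN responder group."""

    def __init__(self, message: str, level: float | None = None):
        super().__init__(message)
        self.level = level


@dataclass(frozen=True)
class FollowupTable2x2:
    """Wave-2 outcome counts: rows FP/TN (responders only), columns attempt yes/no."""

    a: int  # FP responders with a first-time attempt
    b: int  # FP responders without
    c: int  # TN responders with a first-time attempt
    d: int  # TN responders without

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def fp_responders(self) -> int:
        return self.a + self.b

    @property
    def tn_responders(self) -> int:
        return self.c + self.d

    @property
    def degenerate(self) -> bool:
        return self.fp_responders == 0 or self.tn_responders == 0


@dataclass
class RRResult:
    level: float
    achieved_specificity: float
    cutoff: float
    table: FollowupTable2x2
    rr: float
    p_one_sided: float
    or_ci_lower: float
    rr_wald_ci_lower: float
    degenerate: bool
    small_fp_flag: bool


def link_followup(split: ConfusionSplit, cohort: CohortTable) -> FollowupTable2x2:
    """Count wave-2 first attempts among FP and TN wave-2 responders.

    FP and TN members have y1 = 0 by construction, so y2_first is defined
    for every counted subject; non-responders are never counted.
    """
    df = cohort.data.set_index("subject_id")

    def counts(ids: np.ndarray) -> tuple[int, int]:
        sub = df.loc[np.asarray(ids)]
        resp = sub[sub["t2_responded"] == 1]
        y2 = resp["y2_first"]
        if y2.isna().any():
            raise ValueError("y2_first undefined for a counted responder")
        yes = int((y2 == 1).sum())
        return yes, len(resp) - yes

    a, b = counts(split.fp_ids)
    c, d = counts(split.tn_ids)
    return FollowupTable2x2(a=a, b=b, c=c, d=d)


def relative_risk(table: FollowupTable2x2) -> float:
    """(a/(a+b)) / (c/(c+d)); 0 when a=0, +inf when c=0 with a>0."""
    if table.degenerate:
        raise UndefinedRRError(
            f"relative risk undefined: FP responders={table.fp_responders}, "
            f"TN responders={table.tn_responders}"
        )
    p_fp = table.a / table.fp_responders
    p_tn = table.c / table.tn_responders
    if table.a == 0:
        return 0.0
    if table.c == 0:
        return math.inf
    return p_fp / p_tn


def _log_hyper_weights(table: FollowupTable2x2) -> tuple[np.ndarray, np.ndarray]:
    """Support and log C(r1,k) + C(r2, c1-k) for the conditional distribution."""
    r1, r2 = table.fp_responders, table.tn_responders
    c1 = table.a + table.c
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    k = np.arange(k_min, k_max + 1)
    logw = (
        gammaln(r1 + 1)
        - gammaln(k + 1)
        - gammaln(r1 - k + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(r2 - (c1 - k) + 1)
    )
    return k, logw


def fisher_one_sided(table: FollowupTable2x2) -> float:
    """Exact one-sided (greater) p-value: P(X >= a) with margins fixed.

    Hypergeometric terms are accumulated on the log scale via log-gamma,
    then normalized, so large margins stay numerically safe.  A zero
    margin makes the table degenerate and returns p = 1.
    """
    c1 = table.a + table.c
    if table.degenerate or c1 == 0 or (table.b + table.d) == 0:
        return 1.0
    k, logw = _log_hyper_weights(table)
    m = logw.max()
    w = np.exp(logw - m)
    total = w.sum()
    tail = w[k >= table.a].sum()
    return float(min(1.0, tail / total))


def _noncentral_tail(table: FollowupTable2x2, log_psi: float) -> float:
    """P_psi(X >= a) under the noncentral hypergeometric distribution."""
    k, logw = _log_hyper_weights(table)
    logw = logw + k * log_psi
    m = logw.max()
    w = np.exp(logw - m)
    return float(w[k >= table.a].sum() / w.sum())


def exact_ci_lower(
    table: FollowupTable2x2, level: float = 0.95, tol: float = 1e-6
) -> tuple[float, float]:
    """One-sided lower confidence bounds at ``level``: (exact OR, Wald log-RR).

    The exact bound inverts the noncentral hypergeometric tail test —
    the psi with P_psi(X >= a) = 1 - level, found by monotone bisection
    (the tail probability is strictly increasing in psi).  The companion
    Wald bound is exp(log RR - z * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))).
    Both are 0 when a = 0.
    """
    if table.degenerate:
        raise UndefinedRRError("confidence bound undefined for a degenerate table")
    if table.a == 0:
        return 0.0, 0.0
    z = norm.ppf(level)

    # Wald bound on log RR (undefined when c = 0).
    if table.c > 0:
        log_rr = math.log(relative_risk(table))
        se = math.sqrt(
            1 / table.a
            - 1 / table.fp_responders
            + 1 / table.c
            - 1 / table.tn_responders
        )
        wald = math.exp(log_rr - z * se)
    else:
        wald = math.inf

    k, _ = _log_hyper_weights(table)
    if table.a <= k[0]:
        return 0.0, wald  # tail is the whole support; any psi is consistent
    alpha = 1.0 - level
    lo, hi = -1.0, 1.0
    while _noncentral_tail(table, lo) > alpha:
        lo *= 2
        if lo < -200:
            return 0.0, wald
    while _noncentral_tail(table, hi) < alpha:
        hi *= 2
        if hi > 200:
            return math.inf, wald
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if _noncentral_tail(table, mid) < alpha:
            lo = mid
        else:
            hi = mid
    return float(math.exp((lo + hi) / 2)), wald


def audit_sweep(
    entries: list[SweepEntry],
    cohort: CohortTable,
    ci_level: float = 0.95,
    min_count: int = MIN_COUNT_FLAG,
) -> list[RRResult]:
    """One RRResult per sweep level; degenerate levels are flagged, not dropped."""
    results = []
    for e in entries:
        table = link_followup(e.split, cohort)
        degenerate = table.degenerate
        if degenerate:
            rr, p, or_lo, wald_lo = math.nan, 1.0, math.nan, math.nan
        else:
            rr = relative_risk(table)
            p = fisher_one_sided(table)
            or_lo, wald_lo = exact_ci_lower(table, level=ci_level)
        results.append(
            RRResult(
                level=e.level,
                achieved_specificity=e.achieved_specificity,
                cutoff=e.cutoff,
                table=table,
                rr=rr,
                p_one_sided=p,
                or_ci_lower=or_lo,
                rr_wald_ci_lower=wald_lo,
                degenerate=degenerate,
                small_fp_flag=table.fp_responders < min_count,
            )
        )
    return results


def audit_table(results: list[RRResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "level": r.level,
                "achieved_specificity": r.achieved_specificity,
                "cutoff": r.cutoff,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "rr": r.rr,
                "p_one_sided": r.p_one_sided,
                "or_ci_lower": r.or_ci_lower,
                "rr_wald_ci_lower": r.rr_wald_ci_lower,
                "degenerate_flag": r.degenerate,
                "small_fp_flag": r.small_fp_flag,
            }
        )
    return pd.DataFrame(rows)
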