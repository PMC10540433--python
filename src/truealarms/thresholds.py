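"""Specificity-indexed threshold selection and confusion-group membership.

A classification threshold is chosen not as a score value but as a target
specificity: the cutoff is the smallest candidate whose achieved
specificity on the evaluation split is at least the target.  Candidate
cutoffs are midpoints between consecutive distinct scores plus sentinels
below the minimum and above the maximum, and the decision rule is
"positive iff score >= cutoff".  Both the target and the achieved
specificity are carried through all downstream tables, because on a
finite sample the two differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import _scores_labels

__all__ = [
    "RocPoint",
    "SpecificityGrid",
    "ConfusionSplit",
    "SweepEntry",
    "candidate_cutoffs",
    "roc_points",
    "cutoff_for_specificity",
    "classify_at",
    "sweep",
]


@dataclass(frozen=True)
class RocPoint:
    cutoff: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class SpecificityGrid:
    """Ascending target specificity levels in (0, 1)."""

    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        if lv.size == 0:
            raise ValueError("grid must contain at least one level")
        if not (np.all(lv > 0) and np.all(lv < 1)):
            raise ValueError("levels must lie in (0, 1)")
        if not np.all(np.diff(lv) > 0):
            raise ValueError("levels must be strictly ascending")

    @classmethod
    def coarse(cls) -> "SpecificityGrid":
        """16 levels, 0.600 to 0.975 in steps of 0.025 (relative-risk sweep)."""
        return cls(tuple(np.round(np.arange(0.600, 0.9751, 0.025), 4)))

    @classmethod
    def fine(cls) -> "SpecificityGrid":
        """38 levels, 0.60 to 0.97 in steps of 0.01 (severity convergence)."""
        return cls(tuple(np.round(np.arange(0.60, 0.9701, 0.01), 4)))

    @classmethod
    def from_spec(cls, spec: str) -> "SpecificityGrid":
        if spec == "coarse":
            return cls.coarse()
        if spec == "fine":
            return cls.fine()
        return cls(tuple(float(x) for x in spec.split(",")))


@dataclass
class ConfusionSplit:
    """Disjoint subject-id sets at one cutoff (positive iff score >= cutoff)."""

    cutoff: float
    tp_ids: np.ndarray
    fp_ids: np.ndarray
    tn_ids: np.ndarray
    fn_ids: np.ndarray

    @property
    def achieved_specificity(self) -> float:
        n_neg = len(self.fp_ids) + len(self.tn_ids)
        return len(self.tn_ids) / n_neg if n_neg else float("nan")

    @property
    def sensitivity(self) -> float:
        n_pos = len(self.tp_ids) + len(self.fn_ids)
        return len(self.tp_ids) / n_pos if n_pos else float("nan")

    def sizes(self) -> dict[str, int]:
        return {
            "n_tp": len(self.tp_ids),
            "n_fp": len(self.fp_ids),
            "n_tn": len(self.tn_ids),
            "n_fn": len(self.fn_ids),
        }


@dataclass
class SweepEntry:
    level: float
    cutoff: float
    achieved_specificity: float
    split: ConfusionSplit


def candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus two sentinels."""
    distinct = np.unique(np.asarray(scores, dtype=float))
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))


def roc_points(scores, labels) -> list[RocPoint]:
    """Empirical ROC at every candidate cutoff, ascending in cutoff."""
    s, y = _scores_labels(scores, labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_points requires both classes")
    pts = []
    for c in candidate_cutoffs(s):
        pred_pos = s >= c
        sens = float((pred_pos & (y == 1)).sum() / n_pos)
        spec = float((~pred_pos & (y == 0)).sum() / n_neg)
        pts.append(RocPoint(cutoff=float(c), sensitivity=sens, specificity=spec))
    return pts


def cutoff_for_specificity(scores, labels, target: float) -> tuple[float, float]:
    """Smallest candidate cutoff whose achieved specificity is >= target.

    The sentinel above the maximum score classifies everyone negative and
    achieves specificity 1, so a solution always exists for target < 1.
    """
    if not (0.0 < target < 1.0):
        raise ValueError("target specificity must lie in (0, 1)")
    s, y = _scores_labels(scores, labels)
    neg = s[y == 0]
    if neg.size == 0:
        raise ValueError("no negative subjects; specificity undefined")
    for c in candidate_cutoffs(s):
        achieved = float((neg < c).sum() / neg.size)
        if achieved >= target:
            return float(c), achieved
    raise AssertionError("unreachable: sentinel cutoff achieves specificity 1")


def classify_at(scores, labels, cutoff: float) -> ConfusionSplit:
    """Confusion-group memberships at one cutoff (positive iff score >= cutoff)."""
    if isinstance(scores, pd.Series):
        ids = scores.index.to_numpy()
    else:
        ids = np.arange(len(scores))
    s, y = _scores_labels(scores, labels)
    pred = s >= cutoff
    return ConfusionSplit(
        cutoff=float(cutoff),
        tp_ids=ids[pred & (y == 1)],
        fp_ids=ids[pred & (y == 0)],
        tn_ids=ids[~pred & (y == 0)],
        fn_ids=ids[~pred & (y == 1)],
    )


def sweep(scores, labels, grid: SpecificityGrid) -> list[SweepEntry]:
    """Classify at the cutoff matching each target specificity level."""
    entries = []
    for level in grid.levels:
        cutoff, achieved = cutoff_for_specificity(scores, labels, level)
        split = classify_at(scores, labels, cutoff)
        entries.append(
            SweepEntry(
                level=float(level),
                cutoff=cutoff,
                achieved_specificity=achieved,
                split=split,
            )
        )
    return entries


def sweep_table(entries: list[SweepEntry]) -> pd.DataFrame:
    """Flat summary of a sweep: one row per target level."""
    rows = []
    for e in entries:
        row = {
            "level": e.level,
            "target_specificity": e.level,
            "achieved_specificity": e.achieved_specificity,
            "cutoff": e.cutoff,
        }
        row.update(e.split.sizes())
        rows.append(row)
    return pd.DataFrame(rows)
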