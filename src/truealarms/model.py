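"""Wave-1 risk classifier: split, tune, select, score, and ranking metrics.

The classifier is a plug-in behind a minimal contract (fit on a feature
matrix and a binary label, emit class-1 probabilities).  The default is a
gradient-boosted tree ensemble tuned by random search with stratified
cross-validation, selecting the candidate with the highest mean
cross-validated area under the precision-recall curve — the appropriate
selection metric when the positive class is rare.

AUROC and AUPRC are implemented here from their definitions (pairwise
concordance; step-integrated average precision with tie blocks) rather
than delegated, because downstream threshold semantics are pinned to the
same conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cohort import CohortTable

__all__ = [
    "SplitParams",
    "SplitIndex",
    "ModelSpec",
    "ModelMetrics",
    "FittedModel",
    "LEARNERS",
    "register_learner",
    "split_cohort",
    "tune_and_select",
    "score",
    "auroc",
    "auprc",
]

#: Columns a wave-1 model must never see (leakage guard).
WAVE2_COLUMNS = ("t2_responded", "y2_first", "latent_z1", "latent_z2")


@dataclass(frozen=True)
class SplitParams:
    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class SplitIndex:
    """Disjoint train/test partition of subject ids."""

    train_ids: np.ndarray
    test_ids: np.ndarray
    train_fraction: float
    stratified: bool
    seed: int

    def validate_against(self, cohort: CohortTable) -> None:
        all_ids = set(cohort.data["subject_id"].tolist())
        tr, te = set(self.train_ids.tolist()), set(self.test_ids.tolist())
        if tr & te:
            raise ValueError("train and test ids overlap")
        if tr | te != all_ids:
            raise ValueError("train/test ids do not partition the cohort")


def split_cohort(cohort: CohortTable, params: SplitParams) -> SplitIndex:
    """Randomly partition subjects into train/test, optionally stratified on y1."""
    params.validate()
    if cohort.n < 10:
        raise ValueError("cohort too small to split (n < 10)")
    y1 = cohort.data["y1"].to_numpy()
    if y1.min() == y1.max():
        raise ValueError("cohort has a single wave-1 class; cannot split")
    ids = cohort.data["subject_id"].to_numpy()
    train_ids, test_ids = train_test_split(
        ids,
        train_size=params.train_fraction,
        stratify=y1 if params.stratified else None,
        random_state=params.seed,
        shuffle=True,
    )
    for name, chosen in (("train", train_ids), ("test", test_ids)):
        sub = y1[np.isin(ids, chosen)]
        if sub.sum() == 0:
            raise ValueError(f"{name} split contains no positive subjects")
    return SplitIndex(
        train_ids=np.sort(train_ids),
        test_ids=np.sort(test_ids),
        train_fraction=params.train_fraction,
        stratified=params.stratified,
        seed=params.seed,
    )


# ---------------------------------------------------------------------------
# Learner plug-ins


def _make_gbm(params: dict, seed: int):
    import lightgbm as lgb

    return lgb.LGBMClassifier(
        n_estimators=int(params.get("n_estimators", 200)),
        max_depth=int(params.get("max_depth", 4)),
        learning_rate=float(params.get("learning_rate", 0.1)),
        subsample=float(params.get("subsample", 1.0)),
        subsample_freq=1,
        min_child_samples=int(params.get("min_child_samples", 20)),
        random_state=seed,
        n_jobs=1,
        deterministic=True,
        force_row_wise=True,
        verbosity=-1,
    )


def _make_logistic(params: dict, seed: int):
    from sklearn.linear_model import LogisticRegression

    return LogisticRegression(
        C=float(params.get("C", 1.0)), max_iter=1000, random_state=seed
    )


def _sample_gbm_space(rng: np.random.Generator) -> dict:
    return {
        "n_estimators": int(rng.integers(50, 501)),
        "max_depth": int(rng.integers(2, 9)),
        "learning_rate": float(np.exp(rng.uniform(np.log(0.01), np.log(0.3)))),
        "subsample": float(rng.uniform(0.5, 1.0)),
    }


def _sample_logistic_space(rng: np.random.Generator) -> dict:
    return {"C": float(np.exp(rng.uniform(np.log(1e-2), np.log(1e2))))}


LEARNERS: dict[str, tuple[Callable, Callable]] = {
    "gbm": (_make_gbm, _sample_gbm_space),
    "logistic": (_make_logistic, _sample_logistic_space),
}


def register_learner(
    name: str, factory: Callable[[dict, int], Any], sampler: Callable
) -> None:
    """Register a learner plug-in: factory(params, seed) -> estimator."""
    LEARNERS[name] = (factory, sampler)


@dataclass(frozen=True)
class ModelSpec:
    learner_name: str = "gbm"
    hyperparameters: dict | None = None  # fixed overrides applied to every draw
    n_candidates: int = 50
    cv_folds: int = 10
    selection_metric: str = "auprc"
    seed: int = 0

    def validate(self) -> None:
        if self.learner_name not in LEARNERS:
            raise ValueError(f"unknown learner {self.learner_name!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.selection_metric != "auprc":
            raise ValueError("selection_metric must be 'auprc'")


@dataclass
class ModelMetrics:
    auprc: float
    auroc: float
    per_fold: list[float] = field(default_factory=list)
    selected_hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "auprc": self.auprc,
            "auroc": self.auroc,
            "per_fold": list(self.per_fold),
            "selected_hyperparameters": dict(self.selected_hyperparameters),
            "seed": self.seed,
        }


@dataclass
class FittedModel:
    """A fitted probabilistic classifier bound to its feature schema."""

    estimator: Any
    feature_names: list[str]
    learner_name: str
    hyperparameters: dict

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict_proba(X[self.feature_names])[:, 1]


def _feature_matrix(cohort: CohortTable) -> tuple[pd.DataFrame, np.ndarray]:
    """Extract (X, y1), asserting wave-2 columns can never leak in."""
    leaked = set(cohort.feature_names) & set(WAVE2_COLUMNS)
    if leaked:
        raise ValueError(f"wave-2 columns {sorted(leaked)} may not be features")
    X = cohort.features.astype(float)
    if X.isna().to_numpy().any():
        raise ValueError("features contain missing values; impute first")
    return X.reset_index(drop=True), cohort.data["y1"].to_numpy()


def tune_and_select(
    train: CohortTable, spec: ModelSpec
) -> tuple[FittedModel, ModelMetrics]:
    """Random-search hyperparameters, select by mean CV AUPRC, refit on train.

    Candidates are drawn independently from the learner's search space;
    each is evaluated by stratified ``cv_folds``-fold cross-validation on
    the training split, scoring held-out folds with AUPRC.  The candidate
    with the highest mean wins (ties broken by earlier draw order) and is
    refit on the full training split.  Candidates that fail to fit are
    logged and skipped.
    """
    spec.validate()
    factory, sampler = LEARNERS[spec.learner_name]
    X, y = _feature_matrix(train)
    if y.min() == y.max():
        raise ValueError("training split has a single class")
    rng = np.random.default_rng(spec.seed)
    candidates = []
    for _ in range(spec.n_candidates):
        params = sampler(rng)
        if spec.hyperparameters:
            params.update(spec.hyperparameters)
        candidates.append(params)

    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    folds = list(cv.split(X, y))

    best_idx, best_mean, best_folds = -1, -np.inf, []
    for i, params in enumerate(candidates):
        fold_scores = []
        try:
            for tr_idx, va_idx in folds:
                est = factory(params, spec.seed)
                est.fit(X.iloc[tr_idx], y[tr_idx])
                p = est.predict_proba(X.iloc[va_idx])[:, 1]
                fold_scores.append(auprc(p, y[va_idx]))
        except Exception as exc:  # noqa: BLE001 - candidate failure is data
            warnings.warn(f"candidate {i} failed to fit ({exc}); skipped")
            continue
        mean_score = float(np.mean(fold_scores))
        if mean_score > best_mean:
            best_idx, best_mean, best_folds = i, mean_score, fold_scores
    if best_idx < 0:
        raise RuntimeError("every hyperparameter candidate failed to fit")

    best_params = candidates[best_idx]
    final = factory(best_params, spec.seed)
    final.fit(X, y)
    model = FittedModel(
        estimator=final,
        feature_names=list(train.feature_names),
        learner_name=spec.learner_name,
        hyperparameters=best_params,
    )
    # CV AUROC of the winning candidate, for reporting only.
    roc_folds = []
    for tr_idx, va_idx in folds:
        est = factory(best_params, spec.seed)
        est.fit(X.iloc[tr_idx], y[tr_idx])
        roc_folds.append(auroc(est.predict_proba(X.iloc[va_idx])[:, 1], y[va_idx]))
    metrics = ModelMetrics(
        auprc=best_mean,
        auroc=float(np.mean(roc_folds)),
        per_fold=[float(s) for s in best_folds],
        selected_hyperparameters=best_params,
        seed=spec.seed,
    )
    return model, metrics


def score(model: FittedModel, subjects: CohortTable) -> pd.Series:
    """Risk scores in [0, 1], indexed by subject_id."""
    X = subjects.features
    if X.isna().to_numpy().any():
        raise ValueError("features contain missing values; impute first")
    p = model.predict_proba(subjects.data)
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("model emitted scores outside [0, 1]")
    return pd.Series(p, index=pd.Index(subjects.data["subject_id"], name="subject_id"))


def _scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(scores, pd.Series) and isinstance(labels, pd.Series):
        labels = labels.reindex(scores.index)
        if labels.isna().any():
            raise ValueError("labels missing for some scored subjects")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    return s, y


def auroc(scores, labels) -> float:
    """P(score_pos > score_neg) + 0.5 * P(tie) over all positive-negative pairs.

    Computed via average ranks, which is algebraically identical to the
    pairwise concordance count with half-credit for ties.
    """
    s, y = _scores_labels(scores, labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc requires both classes")
    ranks = rankdata(s, method="average")
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Average precision by step integration, with equal scores as one block.

    Ranked by descending score, each block of tied scores contributes
    (positives in block) * (precision at block end); the sum is divided
    by the total number of positives.
    """
    s, y = _scores_labels(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("auprc requires at least one positive")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # block boundaries: last index of each tie block
    boundary = np.flatnonzero(np.diff(s_sorted) != 0)
    block_ends = np.append(boundary, len(s_sorted) - 1)
    tp_cum = np.cumsum(y_sorted)[block_ends]
    n_cum = block_ends + 1
    tp_block = np.diff(np.concatenate(([0], tp_cum)))
    precision_at_end = tp_cum / n_cum
    return float(np.sum(tp_block * precision_at_end) / n_pos)
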