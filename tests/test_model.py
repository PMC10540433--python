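"""Classifier plumbing and ranking metrics against brute-force oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from truealarms.cohort import GeneratorConfig, generate_cohort, impute_simple
from truealarms.model import (
    ModelSpec,
    SplitParams,
    auprc,
    auroc,
    register_learner,
    score,
    split_cohort,
    tune_and_select,
)

from .conftest import toy_cohort


def brute_force_auroc(scores, labels):
    """Pairwise concordance count with half credit for ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_auprc(scores, labels):
    """Average precision via per-threshold recount (distinct scores as blocks)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = y.sum()
    ap = 0.0
    prev_tp = 0
    for t in sorted(set(s), reverse=True):
        taken = s >= t
        tp = int(y[taken].sum())
        precision = tp / int(taken.sum())
        ap += (tp - prev_tp) * precision
        prev_tp = tp
    return ap / n_pos


class TestSplit:
    def test_partition_arithmetic(self):
        c = toy_cohort(
            y1=[0] * 7 + [1] * 3,
            t2=[1] * 10,
            y2=[0] * 7 + [None] * 3,
        )
        idx = split_cohort(c, SplitParams(train_fraction=0.7, seed=0))
        assert len(idx.train_ids) == 7 and len(idx.test_ids) == 3
        assert not set(idx.train_ids) & set(idx.test_ids)
        idx.validate_against(c)

    def test_stratification_preserves_prevalence(self):
        cfg = dataclasses.replace(
            GeneratorConfig(), n_subjects=1000, missing_rate=0.0, seed=5
        )
        c = generate_cohort(cfg)
        idx = split_cohort(c, SplitParams(seed=3, stratified=True))
        df = c.data.set_index("subject_id")
        p_train = df.loc[idx.train_ids, "y1"].mean()
        p_test = df.loc[idx.test_ids, "y1"].mean()
        assert abs(p_train - p_test) < 0.005

    def test_same_seed_identical(self, small_cohort):
        a = split_cohort(small_cohort, SplitParams(seed=9))
        b = split_cohort(small_cohort, SplitParams(seed=9))
        assert np.array_equal(a.train_ids, b.train_ids)
        assert np.array_equal(a.test_ids, b.test_ids)


def _quality_learner():
    """Test learner whose ranking quality is set by its 'noise' hyperparameter."""

    class Quality:
        def __init__(self, noise, seed):
            self.noise, self.seed = noise, seed

        def fit(self, X, y):
            self.y_mean_ = float(np.mean(y))
            return self

        def predict_proba(self, X):
            x = np.asarray(X)[:, 0]
            rng = np.random.default_rng(self.seed)
            p = 1 / (1 + np.exp(-(x + self.noise * rng.standard_normal(len(x)))))
            return np.column_stack([1 - p, p])

    draws = iter([{"noise": 10.0}, {"noise": 0.0}, {"noise": 10.0}])
    return (lambda params, seed: Quality(params["noise"], seed)), (
        lambda rng: next(draws)
    )


class TestTuneAndSelect:
    def test_single_candidate_degenerate_search(self, small_cohort):
        spec = ModelSpec(
            learner_name="logistic", n_candidates=1, cv_folds=2, seed=0
        )
        model, metrics = tune_and_select(small_cohort, spec)
        assert model.learner_name == "logistic"
        assert set(metrics.selected_hyperparameters) == {"C"}
        assert 0 <= metrics.auprc <= 1

    def test_selects_highest_cv_auprc(self):
        factory, sampler = _quality_learner()
        register_learner("quality", factory, sampler)
        rng = np.random.default_rng(0)
        x = rng.standard_normal(400)
        y1 = (rng.random(400) < 1 / (1 + np.exp(-3 * x))).astype(int)
        c = toy_cohort(
            y1=list(y1),
            t2=[1] * 400,
            y2=[0 if v == 0 else None for v in y1],
            features={"scale_1": list(x)},
        )
        spec = ModelSpec(learner_name="quality", n_candidates=3, cv_folds=2, seed=1)
        model, _ = tune_and_select(c, spec)
        assert model.hyperparameters == {"noise": 0.0}  # the informative candidate

    def test_null_cohort_cv_auprc_near_prevalence(self):
        cfg = dataclasses.replace(
            GeneratorConfig(),
            n_subjects=4000,
            beta1=0.0,
            beta2=0.0,
            missing_rate=0.0,
            seed=23,
        )
        c = generate_cohort(cfg)
        spec = ModelSpec(learner_name="logistic", n_candidates=1, cv_folds=5, seed=2)
        _, metrics = tune_and_select(c, spec)
        prev = c.data["y1"].mean()
        se = np.std(metrics.per_fold) / np.sqrt(len(metrics.per_fold))
        assert abs(metrics.auprc - prev) < max(3 * se, 0.02)

    def test_wave2_columns_never_visible(self, small_cohort):
        """Erasing wave-2 outcomes must not change the fitted model's scores."""
        spec = ModelSpec(learner_name="logistic", n_candidates=2, cv_folds=3, seed=4)
        model_a, _ = tune_and_select(small_cohort, spec)
        censored = small_cohort.copy()
        censored.data["t2_responded"] = 1
        censored.data["y2_first"] = pd.array([0] * censored.n, dtype="Int8")
        censored.data.loc[censored.data["y1"] == 1, "y2_first"] = pd.NA
        model_b, _ = tune_and_select(censored, spec)
        sa = score(model_a, small_cohort)
        sb = score(model_b, small_cohort)
        assert np.array_equal(sa.to_numpy(), sb.to_numpy())


class TestScore:
    def test_one_score_per_subject_and_repeatable(self, small_cohort):
        spec = ModelSpec(learner_name="logistic", n_candidates=1, cv_folds=2, seed=0)
        model, _ = tune_and_select(small_cohort, spec)
        s1 = score(model, small_cohort)
        s2 = score(model, small_cohort)
        assert len(s1) == small_cohort.n
        assert s1.index.is_unique
        assert np.array_equal(s1.to_numpy(), s2.to_numpy())
        assert (s1 >= 0).all() and (s1 <= 1).all()

    def test_separable_toy_orders_classes(self):
        c = toy_cohort(
            y1=[0] * 10 + [1] * 10,
            t2=[1] * 20,
            y2=[0] * 10 + [None] * 10,
            features={"scale_1": list(np.r_[np.zeros(10), np.ones(10) * 10.0])},
        )
        model, _ = tune_and_select(
            c, ModelSpec(learner_name="logistic", n_candidates=1, cv_folds=2, seed=0)
        )
        s = score(model, c).to_numpy()
        assert s[10:].min() > s[:10].max()

    def test_missing_features_rejected(self, small_cohort):
        model, _ = tune_and_select(
            small_cohort,
            ModelSpec(learner_name="logistic", n_candidates=1, cv_folds=2, seed=0),
        )
        broken = small_cohort.copy()
        broken.data.loc[0, "scale_1"] = np.nan
        with pytest.raises(ValueError, match="impute"):
            score(model, broken)


class TestAuroc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 1.0),
            ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),
            ([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], 0.75),  # 3 of 4 pairs concordant
        ],
    )
    def test_examples(self, scores, labels, expected):
        assert auroc(scores, labels) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_pairwise_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 201))
        s = rng.choice(np.round(rng.random(30), 2), size=n)  # ties likely
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert auroc(s, y) == pytest.approx(brute_force_auroc(s, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        s = rng.random(100)
        y = rng.integers(0, 2, size=100)
        assert auroc(np.exp(3 * s) + 7, y) == pytest.approx(auroc(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])


class TestAuprc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),  # perfect ranking
            ([0.9, 0.8, 0.2, 0.1], [0, 0, 0, 1], 0.25),  # 1 positive ranked last
        ],
    )
    def test_examples(self, scores, labels, expected):
        assert auprc(scores, labels) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_sklearn_average_precision(self, seed):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        s = rng.choice(np.round(rng.random(25), 2), size=n)
        y = (rng.random(n) < 0.3).astype(int)
        if y.sum() == 0:
            y[0] = 1
        assert auprc(s, y) == pytest.approx(average_precision_score(y, s), abs=1e-12)

    def test_reversed_perfect_ranking_is_oracle_minimum(self):
        """Positives ranked last gives the smallest AP for that label multiset."""
        y = np.array([1, 1, 0, 0, 0, 0])
        worst_scores = np.arange(6)[::-1] * 1.0  # descending: negatives first
        worst = auprc(worst_scores, y[::-1])
        from itertools import permutations

        oracle_min = min(
            brute_force_auprc(np.arange(6) * 1.0, np.array(p))
            for p in set(permutations(y))
        )
        assert worst == pytest.approx(oracle_min, abs=1e-12)

    def test_zero_positives_rejected(self):
        with pytest.raises(ValueError):
            auprc([0.1, 0.2], [0, 0])
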