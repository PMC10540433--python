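"""Train and select the wave-1 attempt classifier on the simulated cohort.

Reads results/cohort.csv, splits 70/30 stratified on the wave-1 label,
imputes missing items with training-split means, random-searches the
gradient-boosted learner with stratified cross-validation selecting by
AUPRC, and scores the held-out test split.  Writes scores.csv,
split.json and model_metrics.json under results/.
"""

import argparse
import json
from pathlib import Path

from truealarms.cohort import impute_simple, read_cohort
from truealarms.model import (
    ModelSpec,
    SplitParams,
    auprc,
    auroc,
    score,
    split_cohort,
    tune_and_select,
)
from truealarms.pipeline import stage_seed


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--n-candidates", type=int, default=8)
    parser.add_argument("--cv-folds", type=int, default=5)
    args = parser.parse_args()

    cohort = read_cohort(args.out / "cohort.csv")
    split = split_cohort(cohort, SplitParams(seed=stage_seed(args.seed, "split")))
    imputed = impute_simple(cohort, train_ids=split.train_ids)
    spec = ModelSpec(
        learner_name="gbm",
        n_candidates=args.n_candidates,
        cv_folds=args.cv_folds,
        seed=stage_seed(args.seed, "model"),
    )
    model, cv_metrics = tune_and_select(imputed.subset(split.train_ids), spec)
    test = imputed.subset(split.test_ids)
    scores = score(model, test)
    labels = test.data.set_index("subject_id")["y1"]

    (args.out / "split.json").write_text(
        json.dumps({"train_ids": split.train_ids.tolist(), "test_ids": split.test_ids.tolist()})
    )
    scores.rename("score").to_csv(args.out / "scores.csv")
    metrics = {
        "cv": cv_metrics.to_dict(),
        "test_auprc": auprc(scores, labels),
        "test_auroc": auroc(scores, labels),
    }
    (args.out / "model_metrics.json").write_text(json.dumps(metrics, indent=2))

    print(f"selected hyperparameters : {cv_metrics.selected_hyperparameters}")
    print(f"cross-validated AUPRC    : {cv_metrics.auprc:.4f}")
    print(f"test AUPRC               : {metrics['test_auprc']:.4f}")
    print(f"test AUROC               : {metrics['test_auroc']:.4f}")


if __name__ == "__main__":
    main()
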