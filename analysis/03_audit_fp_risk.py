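"""Audit the follow-up attempt risk of false positives across specificity.

Reads the scored test split, classifies at cutoffs matching specificity
0.600-0.975 (step 0.025), links each false-positive and true-negative
group to wave-2 first attempts among responders, and prints the per-level
2x2 counts, relative risk, one-sided Fisher p, and lower confidence
bounds.  Writes results/audit.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from truealarms.audit import audit_sweep, audit_table
from truealarms.cohort import read_cohort
from truealarms.thresholds import SpecificityGrid, sweep


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    cohort = read_cohort(args.out / "cohort.csv")
    scores = pd.read_csv(args.out / "scores.csv", index_col="subject_id")["score"]
    labels = cohort.data.set_index("subject_id")["y1"].reindex(scores.index)

    entries = sweep(scores, labels, SpecificityGrid.coarse())
    results = audit_sweep(entries, cohort)
    table = audit_table(results)
    table.to_csv(args.out / "audit.csv", index=False)

    cols = ["level", "achieved_specificity", "a", "b", "c", "d", "rr",
            "p_one_sided", "or_ci_lower", "rr_wald_ci_lower", "small_fp_flag"]
    print(table[cols].round(4).to_string(index=False))
    n_sig = int((table["p_one_sided"] < 0.05).sum())
    print(f"\nlevels with RR significantly > 1 (p < 0.05): {n_sig} of {len(table)}")


if __name__ == "__main__":
    main()
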