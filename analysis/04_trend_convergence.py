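"""Trend analyses: RR vs specificity, and FP-TP severity convergence.

Fits the OLS regression of the audited relative risk on the 16-level
specificity grid, then — on the finer 38-level grid — computes the
normalized mean severity of each signal scale within the FP and TP
groups and fits the per-scale difference trend.  A negative difference
slope means false positives come to resemble true positives as the
threshold rises.  Writes results/trends.json and results/profiles.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from truealarms.audit import audit_sweep
from truealarms.cohort import read_cohort
from truealarms.thresholds import SpecificityGrid, sweep
from truealarms.trends import convergence_trends, rr_trend, severity_profiles


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    cohort = read_cohort(args.out / "cohort.csv")
    scores = pd.read_csv(args.out / "scores.csv", index_col="subject_id")["score"]
    labels = cohort.data.set_index("subject_id")["y1"].reindex(scores.index)

    coarse = sweep(scores, labels, SpecificityGrid.coarse())
    fit, excluded = rr_trend(audit_sweep(coarse, cohort))
    print("relative risk vs specificity (16-level grid)")
    print(f"  slope={fit.slope:.3f}  adj R2={fit.adj_r2:.3f}  "
          f"F({fit.df1},{fit.df2})={fit.f_stat:.2f}  p={fit.p_value:.4g}  "
          f"excluded levels={excluded}")

    fine = sweep(scores, labels, SpecificityGrid.fine())
    scales = [f for f in cohort.feature_names if f.startswith("scale_")]
    profiles = severity_profiles(cohort, fine, scales)
    profiles.to_csv(args.out / "profiles.csv", index=False)
    conv = convergence_trends(profiles)

    print("severity convergence, TP mean - FP mean on specificity (38-level grid)")
    payload = {"rr_trend": {**fit.to_dict(), "excluded_levels": excluded}, "convergence": {}}
    for scale, (f, n) in sorted(conv.items()):
        if f is None:
            print(f"  {scale}: insufficient common levels")
            payload["convergence"][scale] = {"error": "insufficient common levels"}
            continue
        print(f"  {scale}: slope={f.slope:+.3f}  adj R2={f.adj_r2:.3f}  p={f.p_value:.3g}")
        payload["convergence"][scale] = {**f.to_dict(), "n_levels": n}
    (args.out / "trends.json").write_text(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
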