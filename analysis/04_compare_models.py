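#!/usr/bin/env python
"""Pairwise Wilcoxon signed-rank comparison of the nested-CV fold RMSEs.

Each fusion model is tested against each single-sensor model on the 50 paired
folds; p-values are Holm-adjusted within the panel and rendered as a star
matrix (a '!' prefix marks differences favouring a non-fusion model). Run
03_nested_cv.py first.
"""

from pathlib import Path

import pandas as pd

from spoilfuse.model_comparison import compare_models, render_star_matrix

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    folds = pd.read_csv(RESULTS / "nested_cv_folds_chicken.csv")
    models = sorted(folds["model_id"].unique())
    fusion = {m for m in models if "-" in m}
    singles = [m for m in models if m not in fusion]
    pairs = [(f, s) for f in sorted(fusion) for s in singles]

    report = compare_models(folds, pairs, fusion_models=fusion)
    report.to_csv(RESULTS / "comparison_report_chicken.csv", index=False)
    star = render_star_matrix(report)
    (RESULTS / "star_matrix_chicken.txt").write_text(star + "\n")
    print(star)

    sig = report[(report["tier"] != "ns") & ~report["favours_non_fusion"]]
    print(
        f"\n{len(sig)}/{len(report)} pairwise comparisons significantly "
        "favour a fusion model after Holm adjustment"
    )
    print(f"wrote {RESULTS / 'comparison_report_chicken.csv'}")


if __name__ == "__main__":
    main()
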