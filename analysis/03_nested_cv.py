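#!/usr/bin/env python
"""Repeated nested cross-validation (10 repeats x 5 outer folds).

Gives the generalised out-of-sample view of every model on the whole chicken
dataset: 50 seed-matched assessments per model, so per-fold results are
paired across models for the signed-rank comparison in the next step. Uses
the trimmed LV grids; run 01_simulate_datasets.py first.
"""

from pathlib import Path

from spoilfuse.dataset_io import load_dataset
from spoilfuse.evaluation import nested_cv
from spoilfuse.experiments import reduced_roster

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data" / "chicken"
RESULTS = ROOT / "results"


def main() -> None:
    ds = load_dataset(
        {m: DATA / f"{m.lower()}.csv" for m in ("MSI", "FTIR", "MSIF")},
        DATA / "metadata.csv",
    )
    specs = reduced_roster(include_early=True)
    folds = nested_cv(ds, specs, repeats=10, outer_k=5, inner_k=5, seed=11)
    folds.to_csv(RESULTS / "nested_cv_folds_chicken.csv", index=False)

    summary = (
        folds.assign(acc_pct=folds["accuracy"] * 100.0)
        .groupby("model_id")
        .agg(
            rmse_mean=("rmse", "mean"),
            rmse_sd=("rmse", "std"),
            acc_pct_mean=("acc_pct", "mean"),
            acc_pct_sd=("acc_pct", "std"),
            r2_mean=("r2", "mean"),
            r2_sd=("r2", "std"),
        )
        .round(4)
        .sort_values("rmse_mean")
        .reset_index()
    )
    summary.to_csv(RESULTS / "nested_cv_summary_chicken.csv", index=False)
    print(summary.to_string(index=False))
    singles = summary[summary["model_id"].isin(["MSI", "FTIR", "MSIF"])]
    best_single = singles.iloc[singles["rmse_mean"].argmin()]
    best = summary.iloc[0]
    print(
        f"\nbest single sensor: {best_single['model_id']} "
        f"(RMSE {best_single['rmse_mean']:.3f}); "
        f"best overall: {best['model_id']} (RMSE {best['rmse_mean']:.3f})"
    )
    print(f"wrote {RESULTS / 'nested_cv_summary_chicken.csv'}")


if __name__ == "__main__":
    main()
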