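#!/usr/bin/env python
"""Batch-on-batch validation: train on sourcing batch 1, test on batch 2.

For each scenario (aerobic, vacuum, combined) every model is tuned with
3 x 10-fold cross-validation on the batch-1 rows, refit, and scored on the
batch-2 rows of its own and the opposing packaging condition — the study's
robustness probe against batch effects. Uses trimmed LV grids to keep the
driver quick; run 01_simulate_datasets.py first.
"""

import json
from pathlib import Path

import pandas as pd

from spoilfuse.dataset_io import load_dataset, make_partition
from spoilfuse.evaluation import batch_on_batch_evaluate
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
    rows = []
    scenarios = {
        "aerobic": ("batch_on_batch", ["aerobic"]),
        "vacuum": ("batch_on_batch", ["vacuum"]),
        "combined": ("combined_conditions", None),
    }
    for scenario, (scheme, conds) in scenarios.items():
        plan = make_partition(ds, scheme, conditions=conds)
        for spec in specs:
            res = batch_on_batch_evaluate(ds, spec, plan, repeats=3, k=10, seed=11)
            for test_name, m in res["tests"].items():
                rows.append(
                    {
                        "scenario": scenario,
                        "model_id": spec.model_id,
                        "test_set": test_name,
                        "rmsecv_mean": round(res["rmsecv_mean"], 4),
                        "rmsecv_sd": round(res["rmsecv_sd"], 4),
                        "lvs": json.dumps(res["params"]),
                        "rmsep": round(m.rmse, 4),
                        "acc_pct": round(100 * m.accuracy, 2),
                        "r2": round(m.r2, 4),
                        "n": m.n,
                    }
                )
        print(f"scenario {scenario}: evaluated {len(specs)} models")
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "batch_validation_chicken.csv", index=False)

    own = table[table["test_set"] == "test"]
    for scenario, sub in own.groupby("scenario"):
        best = sub.loc[sub["rmsep"].idxmin()]
        print(
            f"{scenario}: best batch-2 RMSEp {best['rmsep']:.3f} log CFU/g "
            f"({best['model_id']}, acc {best['acc_pct']:.1f}%)"
        )
    print(f"wrote {RESULTS / 'batch_validation_chicken.csv'}")


if __name__ == "__main__":
    main()
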