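"""Metrics, LV tuning, repeated k-fold, batch validation, and nested CV."""

import json

import numpy as np
import pandas as pd
import pytest

from spoilfuse.evaluation import (
    ModelSpec,
    accuracy_1log,
    batch_on_batch_evaluate,
    build_fold_scheme,
    candidate_grid,
    evaluate_predictions,
    nested_cv,
    r2,
    repeated_kfold_folds,
    repeated_kfold_rmse,
    rmse,
    standard_roster,
    tune,
)
from spoilfuse.dataset_io import make_partition

CHEAP_GRID = {
    "MSI": (2, 3), "FTIR": (2, 3), "MSIF": (2, 3), "early": (2, 3), "meta": (2, 3),
}


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([5.0, 6.0, 7.5])
        assert rmse(y, y) == 0.0
        assert r2(y, y) == 1.0
        assert accuracy_1log(y, y) == 1.0

    def test_accuracy_counts_inclusive_one_log_window(self):
        y = np.array([5.5, 8.0])
        yhat = np.array([5.0, 6.5])
        assert accuracy_1log(y, yhat) == 0.5  # errors 0.5 (in) and 1.5 (out)
        assert accuracy_1log(np.array([5.0]), np.array([6.0])) == 1.0  # boundary

    def test_mean_predictor_has_zero_r2(self):
        y = np.array([4.0, 6.0, 8.0, 9.0])
        yhat = np.full(4, y.mean())
        assert r2(y, yhat) == pytest.approx(0.0, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmse([1.0, 2.0], [1.0])
        with pytest.raises(ValueError, match="constant"):
            r2([3.0, 3.0], [1.0, 2.0])

    def test_evaluate_predictions_bundles_n(self):
        m = evaluate_predictions([5.0, 6.0, 7.0], [5.1, 6.2, 6.5])
        assert m.n == 3 and m.rmse > 0 and m.accuracy == 1.0


def _linear_blocks(seed=0, n=60, p=6, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + noise * rng.normal(size=n)
    return {"MSI": X}, y


class TestRepeatedKFold:
    def test_default_fold_count_is_thirty(self):
        folds = repeated_kfold_folds(50, repeats=3, k=10, seed=0)
        assert len(folds) == 30
        # each repeat's validation folds partition the data
        for r in range(3):
            chunk = folds[r * 10 : (r + 1) * 10]
            united = sorted(np.concatenate([va for _, va in chunk]).tolist())
            assert united == list(range(50))

    def test_noiseless_linear_data_has_zero_rmsecv(self):
        blocks, y = _linear_blocks(noise=0.0)
        spec = ModelSpec("MSI", "single", ("MSI",), {"MSI": (6,)})
        mean, sd, vals = repeated_kfold_rmse(blocks=blocks, y=y, spec=spec,
                                             params={"MSI": 6}, repeats=3, k=10, seed=1)
        assert mean < 1e-8
        assert len(vals) == 30

    def test_different_seeds_give_different_valid_partitions(self):
        f1 = repeated_kfold_folds(30, 1, 5, seed=0)
        f2 = repeated_kfold_folds(30, 1, 5, seed=1)
        assert not all(np.array_equal(a[1], b[1]) for a, b in zip(f1, f2))
        for folds in (f1, f2):
            assert sorted(np.concatenate([va for _, va in folds]).tolist()) == list(range(30))


class TestTune:
    def test_recovers_intrinsic_dimension(self):
        rng = np.random.default_rng(0)
        n = 80
        T = rng.normal(size=(n, 2))
        X = T @ rng.normal(size=(2, 10)) + 1e-4 * rng.normal(size=(n, 10))
        y = T @ np.array([1.0, -2.0])
        spec = ModelSpec("MSI", "single", ("MSI",), {"MSI": (1, 2, 3)})
        folds = repeated_kfold_folds(n, 1, 5, seed=0)
        res = tune(spec, {"MSI": X}, y, folds)
        assert res.params == {"MSI": 2}

    def test_exact_tie_broken_toward_fewer_lvs(self):
        # rank-2 noiseless data: every LV count >= 2 gives identical
        # predictions via path clipping, so 2 must win the tie.
        rng = np.random.default_rng(1)
        T = rng.normal(size=(60, 2))
        X = T @ rng.normal(size=(2, 8))
        y = T @ np.array([0.5, 1.5])
        spec = ModelSpec("MSI", "single", ("MSI",), {"MSI": (2, 3, 4)})
        folds = repeated_kfold_folds(60, 1, 5, seed=0)
        res = tune(spec, {"MSI": X}, y, folds)
        assert res.params == {"MSI": 2}

    def test_random_search_with_full_budget_equals_exhaustive(self):
        blocks, y = _linear_blocks(seed=3, noise=0.5)
        grid = {"MSI": tuple(range(1, 7))}
        folds = repeated_kfold_folds(len(y), 1, 5, seed=2)
        ex = tune(ModelSpec("a", "single", ("MSI",), grid), blocks, y, folds)
        rnd = tune(
            ModelSpec("b", "single", ("MSI",), grid, search="random", n_iter=6),
            blocks, y, folds,
        )
        assert ex.params == rnd.params
        assert ex.rmsecv == pytest.approx(rnd.rmsecv)

    def test_random_search_subsamples_without_replacement(self):
        spec = ModelSpec(
            "m", "mid", ("MSI", "FTIR"),
            {"MSI": tuple(range(2, 10)), "FTIR": tuple(range(2, 10)),
             "meta": tuple(range(2, 10))},
            search="random", n_iter=20,
        )
        cands = candidate_grid(spec, seed=0)
        assert len(cands) == 20
        assert len(set(cands)) == 20

    def test_mid_candidates_respect_meta_bound(self):
        spec = ModelSpec(
            "m", "mid", ("MSI", "FTIR"),
            {"MSI": (2, 3), "FTIR": (2, 3), "meta": (2, 6)},
        )
        for c in candidate_grid(spec):
            assert c[-1] <= c[0] + c[1]


class TestNestedCV:
    def test_record_counts_and_seed_matched_folds(self, small_dataset):
        specs = [
            ModelSpec("MSI", "single", ("MSI",), CHEAP_GRID),
            ModelSpec("MSIF", "single", ("MSIF",), CHEAP_GRID),
        ]
        res = nested_cv(small_dataset, specs, repeats=2, outer_k=3, inner_k=3, seed=4)
        counts = res.groupby("model_id").size()
        assert (counts == 6).all()
        # identical held-out rows across models per (repeat, fold)
        piv = res.pivot_table(index=["repeat", "fold"], columns="model_id", values="n")
        assert (piv["MSI"] == piv["MSIF"]).all()

    def test_outer_folds_partition_each_repeat(self, small_dataset):
        scheme = build_fold_scheme(small_dataset.sample_ids, repeats=2, outer_k=5, seed=0)
        for r in range(2):
            ids = sum((scheme.assignment[(r, f)] for f in range(5)), [])
            assert sorted(ids) == sorted(small_dataset.sample_ids)

    def test_adding_repeats_preserves_earlier_splits(self, small_dataset):
        s2 = build_fold_scheme(small_dataset.sample_ids, repeats=2, outer_k=5, seed=3)
        s5 = build_fold_scheme(small_dataset.sample_ids, repeats=5, outer_k=5, seed=3)
        for key, ids in s2.assignment.items():
            assert s5.assignment[key] == ids

    def test_rerun_is_deterministic(self, small_dataset):
        spec = [ModelSpec("MSI", "single", ("MSI",), CHEAP_GRID)]
        a = nested_cv(small_dataset, spec, repeats=1, outer_k=3, inner_k=3, seed=7)
        b = nested_cv(small_dataset, spec, repeats=1, outer_k=3, inner_k=3, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestBatchOnBatch:
    def test_reports_all_condition_test_sets(self, small_dataset):
        plan = make_partition(small_dataset, "batch_on_batch", conditions=["aerobic"])
        spec = ModelSpec("MSI", "single", ("MSI",), CHEAP_GRID)
        res = batch_on_batch_evaluate(
            small_dataset, spec, plan, repeats=1, k=5, seed=0
        )
        assert set(res["tests"]) == {"test", "condition:aerobic", "condition:vacuum"}
        assert res["tests"]["test"].n == len(plan.test_ids)
        assert res["rmsecv_mean"] > 0
        assert res["params"]["MSI"] in (2, 3)

    def test_determinism(self, small_dataset):
        plan = make_partition(small_dataset, "combined_conditions")
        spec = ModelSpec("MSIF", "single", ("MSIF",), CHEAP_GRID)
        a = batch_on_batch_evaluate(small_dataset, spec, plan, repeats=1, k=5, seed=2)
        b = batch_on_batch_evaluate(small_dataset, spec, plan, repeats=1, k=5, seed=2)
        assert a["tests"]["test"] == b["tests"]["test"]
        assert a["params"] == b["params"]


def test_standard_roster_matches_study_design():
    specs = standard_roster()
    ids = [s.model_id for s in specs]
    assert ids[:3] == ["MSI", "FTIR", "MSIF"]
    assert len(specs) == 9  # 3 singles + 2 fusion sets x 3 strategies
    by_id = {s.model_id: s for s in specs}
    assert by_id["MSI"].lv_grid["MSI"] == tuple(range(2, 18))
    assert by_id["FTIR"].lv_grid["FTIR"] == tuple(range(2, 21))
    assert by_id["MSIF"].lv_grid["MSIF"] == tuple(range(2, 8))
    assert by_id["MSI+FTIR-mid"].search == "random"
    assert by_id["MSI+FTIR-mid"].n_iter == 1500
    assert by_id["MSI+FTIR+MSIF-mid"].n_iter == 2500
    assert by_id["MSI+FTIR+MSIF-late"].n_iter == 400
    assert by_id["MSI+FTIR-late"].search == "exhaustive"
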