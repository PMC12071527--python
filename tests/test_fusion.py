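"""Early, mid-level (feature) and late (decision) fusion architectures."""

import numpy as np
import pytest

from spoilfuse.fusion import (
    FusionModel,
    fit_early_fusion,
    fit_late_fusion,
    fit_mid_fusion,
    oof_fold_indices,
    predict_fusion,
)
from spoilfuse.pls_core import PLSModel, fit_pls, pls_predict
from spoilfuse.preprocessing import apply_standardiser, fit_standardiser, preprocess_pipeline


def _two_blocks(seed=0, n=60):
    """Two modalities, each observing y through an independent distortion."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(4, 9, n)
    L1, L2 = rng.normal(size=12), rng.normal(size=9)
    b1 = (y + 0.4 * rng.normal(size=n))[:, None] * L1 + 0.05 * rng.normal(size=(n, 12))
    b2 = (y + 0.3 * rng.normal(size=n))[:, None] * L2 + 0.05 * rng.normal(size=(n, 9))
    return {"MSI": b1, "FTIR": b2}, y


class TestEarlyFusion:
    def test_single_block_degenerates_to_plain_pls(self):
        blocks, y = _two_blocks()
        model = fit_early_fusion({"MSI": blocks["MSI"]}, y, 3)
        s = fit_standardiser(blocks["MSI"])
        plain = fit_pls(apply_standardiser(s, blocks["MSI"]), y, 3)
        np.testing.assert_allclose(
            predict_fusion(model, blocks), pls_predict(plain, apply_standardiser(s, blocks["MSI"])),
            atol=1e-10,
        )

    def test_concatenated_width_is_sum_of_block_widths(self, small_dataset):
        pre = preprocess_pipeline(small_dataset)
        blocks = pre.block_matrices(("MSI", "FTIR"))
        model = fit_early_fusion(blocks, pre.y, 4)
        assert model.meta_pls.x_mean.shape[0] == 36 + 1141 == 1177

    def test_block_supply_order_is_irrelevant(self):
        blocks, y = _two_blocks()
        a = fit_early_fusion({"FTIR": blocks["FTIR"], "MSI": blocks["MSI"]}, y, 3)
        b = fit_early_fusion({"MSI": blocks["MSI"], "FTIR": blocks["FTIR"]}, y, 3)
        np.testing.assert_array_equal(
            predict_fusion(a, blocks), predict_fusion(b, blocks)
        )

    def test_row_order_invariance(self):
        blocks, y = _two_blocks()
        perm = np.random.default_rng(1).permutation(len(y))
        a = fit_early_fusion(blocks, y, 3)
        b = fit_early_fusion({m: X[perm] for m, X in blocks.items()}, y[perm], 3)
        np.testing.assert_allclose(
            predict_fusion(a, blocks), predict_fusion(b, blocks), atol=1e-9
        )


class TestMidFusion:
    def test_meta_input_width_is_sum_of_base_lvs(self):
        blocks, y = _two_blocks()
        model = fit_mid_fusion(blocks, y, {"MSI": 9, "FTIR": 6}, meta_lv=6)
        assert model.meta_pls.x_mean.shape[0] == 15

    def test_full_meta_rank_equals_ols_on_scores(self):
        blocks, y = _two_blocks()
        model = fit_mid_fusion(blocks, y, {"MSI": 4, "FTIR": 5}, meta_lv=9)
        Z = np.hstack([model.base_models[m].scores for m in model.modalities])
        b, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(y)), Z]), y, rcond=None)
        np.testing.assert_allclose(
            predict_fusion(model, blocks), b[0] + Z @ b[1:], atol=1e-8
        )

    def test_single_modality_equals_base_pls(self):
        blocks, y = _two_blocks()
        model = fit_mid_fusion({"MSI": blocks["MSI"]}, y, {"MSI": 4}, meta_lv=4)
        plain = fit_pls(blocks["MSI"], y, 4)
        np.testing.assert_allclose(
            predict_fusion(model, blocks), pls_predict(plain, blocks["MSI"]), atol=1e-8
        )

    def test_meta_lv_exceeding_score_width_rejected(self):
        blocks, y = _two_blocks()
        with pytest.raises(ValueError, match="meta_lv"):
            fit_mid_fusion(blocks, y, {"MSI": 2, "FTIR": 2}, meta_lv=5)

    def test_row_order_invariance(self):
        blocks, y = _two_blocks()
        perm = np.random.default_rng(2).permutation(len(y))
        a = fit_mid_fusion(blocks, y, {"MSI": 3, "FTIR": 3}, meta_lv=4)
        b = fit_mid_fusion(
            {m: X[perm] for m, X in blocks.items()}, y[perm], {"MSI": 3, "FTIR": 3}, 4
        )
        np.testing.assert_allclose(
            predict_fusion(a, blocks), predict_fusion(b, blocks), atol=1e-8
        )


class TestLateFusion:
    def test_oof_matrix_shape_and_meta_equals_lstsq(self):
        blocks, y = _two_blocks(n=80)
        model = fit_late_fusion(blocks, y, {"MSI": 4, "FTIR": 4}, oof_folds=20, seed=5)
        assert model.oof_matrix.shape == (80, 2)
        A = np.column_stack([np.ones(80), model.oof_matrix])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(model.meta_intercept, coef[0], atol=1e-10)
        np.testing.assert_allclose(model.meta_weights, coef[1:], atol=1e-10)

    def test_perfect_base_model_gets_identity_weights(self):
        rng = np.random.default_rng(0)
        n = 60
        y = rng.uniform(4, 9, n)
        L = rng.normal(size=6)
        X = y[:, None] * L  # noiseless: OOF predictions equal y exactly
        model = fit_late_fusion({"MSI": X}, y, {"MSI": 1}, oof_folds=10, seed=0)
        np.testing.assert_allclose(model.oof_matrix[:, 0], y, atol=1e-8)
        np.testing.assert_allclose(model.meta_intercept, 0.0, atol=1e-6)
        np.testing.assert_allclose(model.meta_weights, [1.0], atol=1e-7)

    def test_weighted_average_prediction_arithmetic(self):
        # Hand-built identity base models: prediction = 0 + 0.5*6 + 0.5*8 = 7.
        def identity_model():
            one = np.ones((1, 1))
            return PLSModel(
                n_lv=1, x_mean=np.zeros(1), y_mean=0.0, weights=one,
                x_loadings=one, y_loadings=np.ones(1), rotations=one,
                coef=np.ones(1), coef_path=one, scores=np.zeros((1, 1)),
            )

        model = FusionModel(
            strategy="late",
            modalities=("MSI", "FTIR"),
            base_models={"MSI": identity_model(), "FTIR": identity_model()},
            meta_intercept=0.0,
            meta_weights=np.array([0.5, 0.5]),
        )
        pred = predict_fusion(model, {"MSI": [[6.0]], "FTIR": [[8.0]]})
        np.testing.assert_allclose(pred, [7.0])

    def test_missing_modality_block_rejected(self):
        blocks, y = _two_blocks()
        model = fit_late_fusion(blocks, y, {"MSI": 3, "FTIR": 3}, oof_folds=10, seed=1)
        with pytest.raises(ValueError, match="missing modality"):
            predict_fusion(model, {"MSI": blocks["MSI"]})

    def test_too_few_rows_for_folds_rejected(self):
        blocks, y = _two_blocks(n=20)
        with pytest.raises(ValueError, match="folds"):
            fit_late_fusion(blocks, y, {"MSI": 2, "FTIR": 2}, oof_folds=20, seed=0)

    def test_oof_folds_partition_and_are_seeded(self):
        folds = oof_fold_indices(50, 10, seed=3)
        assert sorted(np.concatenate(folds).tolist()) == list(range(50))
        folds2 = oof_fold_indices(50, 10, seed=3)
        assert all(np.array_equal(a, b) for a, b in zip(folds, folds2))


def test_json_roundtrip_preserves_predictions():
    rng = np.random.default_rng(4)
    blocks = {"MSI": rng.normal(size=(30, 5)), "FTIR": rng.normal(size=(30, 8))}
    y = rng.uniform(4, 9, 30)
    for fitted in (
        fit_early_fusion(blocks, y, 3),
        fit_mid_fusion(blocks, y, {"MSI": 2, "FTIR": 3}, meta_lv=3),
        fit_late_fusion(blocks, y, {"MSI": 2, "FTIR": 2}, oof_folds=10, seed=2),
    ):
        clone = FusionModel.from_json(fitted.to_json())
        np.testing.assert_array_equal(
            predict_fusion(clone, blocks), predict_fusion(fitted, blocks)
        )
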