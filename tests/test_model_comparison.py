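"""Wilcoxon signed-rank (exact, tie-aware) and Holm-Bonferroni correction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from spoilfuse.model_comparison import (
    compare_models,
    holm_bonferroni,
    render_star_matrix,
    significance_tier,
    wilcoxon_signed_rank,
)


def _brute_force_two_sided_p(d):
    """Enumerate all 2^n sign assignments of |d| midranks (independent oracle)."""
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    d = d[d != 0.0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in
         itertools.product([True, False], repeat=len(d))]
    )
    p_le = np.mean(w_all <= w_obs + 1e-12)
    p_ge = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_positive_n5_exact_p(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0], [0.5, 1.5, 2.5, 3.0, 4.0])
        assert res.p_value == pytest.approx(2.0 / 32.0)
        assert res.statistic == 0.0
        assert res.method == "exact"

    @pytest.mark.parametrize("seed,n", [(0, 6), (1, 9), (2, 12), (3, 12)])
    def test_exact_p_matches_brute_force_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        # quarter-step values force tied |differences| (midranks exercised)
        # while keeping the a - b arithmetic exact in binary floating point
        d = np.round(4.0 * rng.normal(0.2, 1.0, n)) / 4.0
        d = d[d != 0.0]
        if d.size < 5:
            d = np.concatenate([d, [0.25, -0.5, 0.25]])
        a = np.cumsum(np.abs(d)) + 5.0
        b = a - d
        res = wilcoxon_signed_rank(a, b)
        assert res.p_value == pytest.approx(_brute_force_two_sided_p(d), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_on_tie_free_data(self, seed):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(seed)
        a = rng.normal(size=15)
        b = a - rng.normal(0.3, 1.0, 15)
        res = wilcoxon_signed_rank(a, b)
        ref = scipy_wilcoxon(a, b, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)
        assert res.statistic == pytest.approx(ref.statistic)

    def test_argument_swap_flips_direction_not_p(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=10)
        b = a - rng.normal(0.4, 0.5, 10)
        r1 = wilcoxon_signed_rank(a, b)
        r2 = wilcoxon_signed_rank(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.w_plus == pytest.approx(r2.w_minus)

    def test_identical_inputs_rejected(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(x, x)

    def test_too_few_nonzero_differences_rejected(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [1.0, 2.0, 3.0, 4.0, 4.5]
        with pytest.raises(ValueError, match=">= 5"):
            wilcoxon_signed_rank(a, b)

    def test_large_n_normal_approximation_close_to_scipy(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(9)
        a = rng.normal(size=50)
        b = a - rng.normal(0.2, 1.0, 50)
        res = wilcoxon_signed_rank(a, b)
        ref = scipy_wilcoxon(a, b, alternative="two-sided", method="approx",
                             correction=True)
        assert res.method == "normal"
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestHolm:
    def test_hand_computed_step_down_cases(self):
        np.testing.assert_allclose(
            holm_bonferroni([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )
        np.testing.assert_allclose(holm_bonferroni([0.5, 0.9]), [1.0, 1.0])
        np.testing.assert_allclose(holm_bonferroni([0.2]), [0.2])

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 12)
        _, ref, *_ = sm.multipletests(p, method="holm")
        np.testing.assert_allclose(holm_bonferroni(p), ref, atol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 10)
        perm = rng.permutation(10)
        adjusted = holm_bonferroni(p)
        np.testing.assert_allclose(holm_bonferroni(p[perm])[np.argsort(perm)], adjusted)

    def test_adjustment_never_increases_significance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 0.2, 15)
        adj = holm_bonferroni(p)
        assert np.all(adj >= p)
        for alpha in (0.05, 0.01, 0.001):
            assert (adj < alpha).sum() <= (p < alpha).sum()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])


def _fold_results(models: dict, repeats=10, outer_k=5, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for model_id, level in models.items():
        for r in range(repeats):
            for f in range(outer_k):
                rows.append(
                    {"model_id": model_id, "repeat": r, "fold": f,
                     "rmse": level + (jitter * rng.normal() if jitter else 0.0)}
                )
    return pd.DataFrame(rows)


class TestCompareModels:
    def test_single_pair_adjusted_equals_raw(self):
        res = _fold_results({"MSI": 0.7, "late": 0.6}, jitter=0.05, seed=1)
        rep = compare_models(res, [("late", "MSI")])
        assert rep.loc[0, "p_holm"] == pytest.approx(rep.loc[0, "p_raw"])

    def test_identical_folds_annotated_not_crashed(self):
        res = _fold_results({"a": 0.7, "b": 0.7})
        rep = compare_models(res, [("a", "b")])
        assert rep.loc[0, "note"] == "no-difference"
        assert rep.loc[0, "tier"] == "ns"

    def test_dominant_fusion_reaches_three_stars_at_fifty_folds(self):
        # late fusion lower on every one of the 50 paired folds
        res = _fold_results({"MSI": 0.7, "late": 0.55}, jitter=0.02, seed=2)
        rep = compare_models(res, [("late", "MSI")], fusion_models={"late"})
        assert rep.loc[0, "n_pairs"] == 50
        assert rep.loc[0, "p_raw"] < 0.001
        assert rep.loc[0, "tier"] == "***"
        assert rep.loc[0, "favours"] == "late"
        assert not rep.loc[0, "favours_non_fusion"]

    def test_missing_model_rejected(self):
        res = _fold_results({"a": 0.7})
        with pytest.raises(KeyError):
            compare_models(res, [("a", "zz")])

    def test_empty_family_gives_empty_report(self):
        rep = compare_models(_fold_results({"a": 0.7}), [])
        assert len(rep) == 0

    def test_star_matrix_rendering_contains_tiers(self):
        res = _fold_results({"MSI": 0.9, "late": 0.5, "mid": 0.55}, jitter=0.02, seed=3)
        rep = compare_models(res, [("late", "MSI"), ("mid", "MSI")],
                             fusion_models={"late", "mid"})
        text = render_star_matrix(rep)
        assert "MSI" in text and "***" in text


@pytest.mark.parametrize(
    "p,tier", [(0.0005, "***"), (0.005, "**"), (0.04, "*"), (0.2, "ns")]
)
def test_significance_tiers(p, tier):
    assert significance_tier(p) == tier
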