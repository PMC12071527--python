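"""Paired statistical comparison of model RMSE across seed-matched CV folds.

Because every model in a nested-CV run is evaluated on the identical series
of outer folds, per-fold RMSE values are paired observations and pairwise
differences can be tested with the Wilcoxon signed-rank test. Family-wise
error across the pairs tested within one scenario panel is controlled with
the Holm-Bonferroni step-down procedure; significance tiers follow the usual
0.05 / 0.01 / 0.001 thresholds ('*', '**', '***', else 'ns').

The signed-rank test here drops zero differences (Wilcoxon's classical
treatment, recorded in the report metadata), uses midranks for ties, and
computes the two-sided p exactly — by dynamic programming over all 2^n sign
assignments, tie-aware — for n <= 25, falling back to the normal
approximation with continuity correction and tie-corrected variance for
larger samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "holm_bonferroni",
    "compare_models",
    "render_star_matrix",
    "significance_tier",
    "EXACT_LIMIT",
]

#: largest sample size for which the exact null distribution is enumerated.
EXACT_LIMIT = 25

ZERO_POLICY = "zero differences dropped (classical Wilcoxon, not Pratt)"


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W = min(W+, W-)
    p_value: float
    n: int            # pairs remaining after zero-difference removal
    w_plus: float
    w_minus: float
    method: str       # "exact" | "normal"


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided p from the exact tie-aware null distribution of W+.

    Doubling ranks makes midranks integral; the distribution of 2*W+ over all
    equiprobable sign assignments is built by convolution (dynamic
    programming), and p = min(1, 2 * min(P(W+ <= obs), P(W+ >= obs))).
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    upto = 0
    for r in r2:
        prev = counts[: upto + 1].copy()
        counts[r : upto + r + 1] += prev
        upto += r
    counts /= counts.sum()
    s = int(np.rint(2.0 * w_plus))
    p_le = float(counts[: s + 1].sum())
    p_ge = float(counts[s:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def _normal_two_sided_p(d_abs: np.ndarray, n: int, w_plus: float) -> float:
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(d_abs, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    dev = w_plus - mu
    # continuity correction toward the mean
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var) if dev != 0 else 0.0
    return min(1.0, 2.0 * float(norm.sf(abs(z))))


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Requires at least 5 nonzero differences; raises if all differences are
    zero (no information about a location shift).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    if d.size < 5:
        raise ValueError(
            f"need >= 5 nonzero differences, got {d.size}"
        )
    n = d.size
    d_abs = np.abs(d)
    ranks = rankdata(d_abs)  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    if n <= EXACT_LIMIT:
        p = _exact_two_sided_p(ranks, w_plus)
        method = "exact"
    else:
        p = _normal_two_sided_p(d_abs, n, w_plus)
        method = "normal"
    return WilcoxonResult(
        statistic=min(w_plus, w_minus),
        p_value=p,
        n=n,
        w_plus=w_plus,
        w_minus=w_minus,
        method=method,
    )


def holm_bonferroni(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order.

    Sort ascending, multiply p_(i) by (m - i), take the running maximum so
    the adjusted values are monotone in the raw order statistics, cap at 1,
    and map back to the original positions.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(1.0, np.maximum.accumulate(scaled))
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_models(
    results: pd.DataFrame,
    pairs: Sequence[tuple],
    fusion_models: set | None = None,
) -> pd.DataFrame:
    """Pairwise Wilcoxon tests on paired fold RMSEs with Holm adjustment.

    ``results`` is a nested-CV fold table (columns model_id, repeat, fold,
    rmse) whose models share fold assignments. The declared ``pairs`` form
    one correction family. A pair with identical RMSE on every fold is
    annotated ``no-difference`` (raw p set to 1) instead of raising.

    Returns one row per pair with the statistic, raw and Holm-adjusted
    two-sided p, the direction (which model has the lower median RMSE), the
    significance tier on the adjusted p, and — when ``fusion_models`` is
    given — whether the favoured model is a non-fusion approach.
    """
    if not pairs:
        return pd.DataFrame(
            columns=[
                "model_a", "model_b", "n_pairs", "statistic", "p_raw",
                "p_holm", "favours", "favours_non_fusion", "tier", "note",
            ]
        )
    wide = results.pivot_table(
        index=["repeat", "fold"], columns="model_id", values="rmse"
    )
    rows = []
    for a, b in pairs:
        for name in (a, b):
            if name not in wide.columns:
                raise KeyError(f"model {name!r} missing from results")
        pair_vals = wide[[a, b]].dropna()
        va, vb = pair_vals[a].to_numpy(), pair_vals[b].to_numpy()
        note = ""
        try:
            res = wilcoxon_signed_rank(va, vb)
            stat, p_raw, n_pairs = res.statistic, res.p_value, res.n
        except ValueError as exc:
            if "zero" in str(exc):
                stat, p_raw, n_pairs, note = np.nan, 1.0, len(va), "no-difference"
            else:
                raise
        med_a, med_b = float(np.median(va)), float(np.median(vb))
        favours = a if med_a < med_b else b
        rows.append(
            {
                "model_a": a,
                "model_b": b,
                "n_pairs": n_pairs,
                "statistic": stat,
                "p_raw": p_raw,
                "favours": favours,
                "note": note,
            }
        )
    report = pd.DataFrame(rows)
    report["p_holm"] = holm_bonferroni(report["p_raw"].to_numpy())
    report["tier"] = [significance_tier(p) for p in report["p_holm"]]
    if fusion_models is not None:
        report["favours_non_fusion"] = ~report["favours"].isin(set(fusion_models))
    else:
        report["favours_non_fusion"] = pd.NA
    report.attrs["zero_policy"] = ZERO_POLICY
    return report


def render_star_matrix(report: pd.DataFrame) -> str:
    """Text rendering of the pairwise significance-tier matrix.

    Cells show the tier of each tested pair; a ``!`` prefix marks pairs whose
    difference favours a non-fusion model (the panels' red colouring).
    """
    models = sorted(set(report["model_a"]) | set(report["model_b"]))
    cell = {}
    for _, row in report.iterrows():
        tier = row["tier"]
        if row["favours_non_fusion"] is True and tier != "ns":
            tier = "!" + tier
        cell[(row["model_a"], row["model_b"])] = tier
        cell[(row["model_b"], row["model_a"])] = tier
    width = max(len(m) for m in models) + 2
    lines = [" " * width + "".join(m.rjust(width) for m in models)]
    for a in models:
        row_cells = [cell.get((a, b), "-" if a != b else ".") for b in models]
        lines.append(a.rjust(width) + "".join(c.rjust(width) for c in row_cells))
    return "\n".join(lines)
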