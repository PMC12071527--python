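"""Metrics, hyperparameter search, batch-on-batch validation, and the
repeated nested cross-validation driver with seed-matched folds.

Evaluation designs
------------------
* ``batch_on_batch_evaluate`` tunes on batch-1 rows with repeated k-fold
  cross-validation (default 3 x 10), refits on the whole training batch, and
  reports test metrics on batch 2 of each storage condition.
* ``nested_cv`` runs repeats x outer-fold nested cross-validation (default
  10 x 5): per outer fold, hyperparameters are chosen by inner k-fold
  cross-validation on the remaining data, the winner is refit on all inner
  data and scored on the held-out fold. Every model specification is
  evaluated on the *identical* series of outer splits derived from one seed,
  so per-fold results are paired across models and suitable for signed-rank
  comparison.

Hyperparameter search
---------------------
The only hyperparameters are latent-variable counts. NIPALS components are
nested, so a single PLS decomposition at the largest candidate LV count
yields validation predictions for every smaller count (the coefficient path);
the grid evaluators below exploit this per fold, which makes exhaustive
search over the default ranges cheap. Random search draws candidates
uniformly without replacement. Ties are broken toward fewer total LVs, then
lexicographically.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset_io import MultiModalDataset, PartitionPlan
from .fusion import (
    canonical_order,
    fit_early_fusion,
    fit_late_fusion,
    fit_mid_fusion,
    oof_fold_indices,
    predict_fusion,
)
from .pls_core import fit_pls, pls_predict, pls_predict_path, pls_transform
from .preprocessing import apply_standardiser, fit_standardiser, preprocess_pipeline

__all__ = [
    "rmse",
    "r2",
    "accuracy_1log",
    "EvalMetrics",
    "evaluate_predictions",
    "ModelSpec",
    "DEFAULT_LV_GRID",
    "standard_roster",
    "candidate_grid",
    "cv_rmse_matrix",
    "tune",
    "repeated_kfold_folds",
    "repeated_kfold_rmse",
    "fit_model",
    "predict_model",
    "build_fold_scheme",
    "FoldScheme",
    "nested_cv",
    "batch_on_batch_evaluate",
]


# -- metrics -----------------------------------------------------------------

def _paired(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} vs {yhat.shape[0]}")
    if y.size == 0:
        raise ValueError("empty vectors")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean squared error (log CFU/g)."""
    y, yhat = _paired(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r2(y, yhat) -> float:
    """Test-set coefficient of determination, 1 - SS_res/SS_tot (may be < 0)."""
    y, yhat = _paired(y, yhat)
    if y.size < 2:
        raise ValueError("r2 needs at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r2 undefined for constant y")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def accuracy_1log(y, yhat) -> float:
    """Fraction of predictions within +/-1 log CFU/g of observed (inclusive)."""
    y, yhat = _paired(y, yhat)
    return float(np.mean(np.abs(y - yhat) <= 1.0))


@dataclass(frozen=True)
class EvalMetrics:
    rmse: float
    r2: float
    accuracy: float
    n: int


def evaluate_predictions(y, yhat) -> EvalMetrics:
    y, yhat = _paired(y, yhat)
    return EvalMetrics(
        rmse=rmse(y, yhat), r2=r2(y, yhat), accuracy=accuracy_1log(y, yhat), n=y.size
    )


# -- model specifications ----------------------------------------------------

#: Default LV search ranges per parameter (inclusive integer grids).
DEFAULT_LV_GRID = {
    "MSI": tuple(range(2, 18)),
    "FTIR": tuple(range(2, 21)),
    "MSIF": tuple(range(2, 8)),
    "early": tuple(range(2, 21)),
    "meta": tuple(range(2, 18)),
}


@dataclass(frozen=True)
class ModelSpec:
    """One model family to evaluate: a single sensor or a fusion strategy.

    ``lv_grid`` maps parameter name -> candidate LV values; parameter names
    are the modality labels for base models, ``"lv"`` for the early-fusion
    PLS, plus ``"meta"`` for the mid-fusion second layer. ``search`` is
    ``"exhaustive"`` or ``"random"`` (``n_iter`` draws without replacement).
    """

    model_id: str
    strategy: str  # single | early | mid | late
    modalities: tuple
    lv_grid: Mapping[str, tuple] = field(default_factory=dict)
    oof_folds: int = 20
    search: str = "exhaustive"
    n_iter: int | None = None

    def __post_init__(self) -> None:
        if self.strategy not in ("single", "early", "mid", "late"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy != "single" and len(self.modalities) < 2:
            raise ValueError("fusion requires at least 2 modalities")
        if self.search == "random" and (self.n_iter is None or self.n_iter < 1):
            raise ValueError("random search requires n_iter >= 1")
        object.__setattr__(self, "modalities", canonical_order(self.modalities))
        grid = {k: tuple(int(v) for v in vals) for k, vals in self.lv_grid.items()}
        for name in self.param_names():
            if name not in grid:
                default_key = name if name in DEFAULT_LV_GRID else None
                if self.strategy == "early":
                    default_key = "early"
                if default_key is None:
                    raise ValueError(f"no LV grid for parameter {name!r}")
                grid[name] = DEFAULT_LV_GRID[default_key]
            if not grid[name]:
                raise ValueError(f"empty LV grid for parameter {name!r}")
        object.__setattr__(self, "lv_grid", grid)

    def param_names(self) -> tuple:
        if self.strategy == "single":
            return (self.modalities[0],)
        if self.strategy == "early":
            return ("lv",)
        if self.strategy == "mid":
            return tuple(self.modalities) + ("meta",)
        return tuple(self.modalities)


def standard_roster(
    singles: Sequence[str] = ("MSI", "FTIR", "MSIF"),
    fusion_sets: Sequence[tuple] = (("MSI", "FTIR"), ("MSI", "FTIR", "MSIF")),
    strategies: Sequence[str] = ("early", "mid", "late"),
    lv_grid: Mapping[str, tuple] | None = None,
    oof_folds: int = 20,
) -> list:
    """The study's model roster: single sensors plus fusion variants.

    Random search (without replacement) replaces exhaustive search for the
    large fusion grids: 1500 draws for two-sensor mid fusion, 2500 for
    three-sensor mid fusion, and 400 for three-sensor late fusion; all other
    families are searched exhaustively.
    """
    grid = dict(DEFAULT_LV_GRID)
    if lv_grid:
        grid.update({k: tuple(v) for k, v in lv_grid.items()})
    specs = [
        ModelSpec(model_id=m, strategy="single", modalities=(m,), lv_grid=grid)
        for m in singles
    ]
    for mods in fusion_sets:
        label = "+".join(canonical_order(mods))
        for strat in strategies:
            search, n_iter = "exhaustive", None
            if strat == "mid" and len(mods) == 2:
                search, n_iter = "random", 1500
            elif strat == "mid" and len(mods) == 3:
                search, n_iter = "random", 2500
            elif strat == "late" and len(mods) == 3:
                search, n_iter = "random", 400
            specs.append(
                ModelSpec(
                    model_id=f"{label}-{strat}",
                    strategy=strat,
                    modalities=tuple(mods),
                    lv_grid=grid,
                    oof_folds=oof_folds,
                    search=search,
                    n_iter=n_iter,
                )
            )
    return specs


def candidate_grid(spec: ModelSpec, seed: int = 0) -> list:
    """Enumerate candidate LV tuples (random mode: seeded subsample)."""
    names = spec.param_names()
    cands = list(itertools.product(*[spec.lv_grid[n] for n in names]))
    if spec.strategy == "mid":
        # meta LV cannot exceed the concatenated score width
        cands = [c for c in cands if c[-1] <= sum(c[:-1])]
    if spec.search == "random" and spec.n_iter is not None and spec.n_iter < len(cands):
        rng = np.random.default_rng([seed, 7])
        idx = rng.choice(len(cands), size=spec.n_iter, replace=False)
        cands = [cands[i] for i in np.sort(idx)]
    return cands


# -- fold construction -------------------------------------------------------

def _kfold(n: int, k: int, rng: np.random.Generator) -> list:
    if n < k:
        raise ValueError(f"cannot split {n} rows into {k} folds")
    perm = rng.permutation(n)
    folds = []
    for va in np.array_split(perm, k):
        va = np.sort(va)
        folds.append((np.setdiff1d(np.arange(n), va), va))
    return folds


def repeated_kfold_folds(n: int, repeats: int = 3, k: int = 10, seed: int = 0) -> list:
    """(train, validation) index pairs for ``repeats`` seeded k-fold rounds."""
    folds = []
    for r in range(repeats):
        folds.extend(_kfold(n, k, np.random.default_rng([seed, r])))
    return folds


# -- grid evaluation ---------------------------------------------------------

def _path_col(path: np.ndarray, lv: int) -> np.ndarray:
    """Prediction/score column for ``lv`` components, clipped to path width."""
    return path[:, min(lv, path.shape[1]) - 1]


def _fit_path(X: np.ndarray, y: np.ndarray, max_lv: int):
    k = max(1, min(max_lv, X.shape[1], X.shape[0] - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank truncation is handled via paths
        return fit_pls(X, y, k)


def cv_rmse_matrix(
    spec: ModelSpec,
    blocks: Mapping[str, np.ndarray],
    y: np.ndarray,
    folds: Sequence[tuple],
    candidates: Sequence[tuple],
    seed: int = 0,
) -> np.ndarray:
    """Per-candidate, per-fold validation RMSE, shape (n_candidates, n_folds).

    One PLS decomposition per (fold, block) serves every LV candidate via the
    coefficient path, so exhaustive grids cost barely more than a single fit.
    """
    y = np.asarray(y, dtype=float).ravel()
    out = np.empty((len(candidates), len(folds)))
    mods = spec.modalities
    for fi, (tr, va) in enumerate(folds):
        ytr, yva = y[tr], y[va]
        if spec.strategy == "single":
            X = blocks[mods[0]]
            model = _fit_path(X[tr], ytr, max(c[0] for c in candidates))
            P = pls_predict_path(model, X[va])
            for ci, c in enumerate(candidates):
                out[ci, fi] = rmse(yva, _path_col(P, c[0]))
        elif spec.strategy == "early":
            ss = {m: fit_standardiser(blocks[m][tr]) for m in mods}
            Ztr = np.hstack([apply_standardiser(ss[m], blocks[m][tr]) for m in mods])
            Zva = np.hstack([apply_standardiser(ss[m], blocks[m][va]) for m in mods])
            model = _fit_path(Ztr, ytr, max(c[0] for c in candidates))
            P = pls_predict_path(model, Zva)
            for ci, c in enumerate(candidates):
                out[ci, fi] = rmse(yva, _path_col(P, c[0]))
        elif spec.strategy == "mid":
            base_max = {
                m: max(c[j] for c in candidates) for j, m in enumerate(mods)
            }
            base = {m: _fit_path(blocks[m][tr], ytr, base_max[m]) for m in mods}
            Tva = {m: pls_transform(base[m], blocks[m][va]) for m in mods}
            by_base: dict = {}
            for ci, c in enumerate(candidates):
                by_base.setdefault(c[:-1], []).append((ci, c[-1]))
            for base_lvs, members in by_base.items():
                eff = {m: min(a, base[m].n_lv) for m, a in zip(mods, base_lvs)}
                Ztr = np.hstack([base[m].scores[:, : eff[m]] for m in mods])
                Zva = np.hstack([Tva[m][:, : eff[m]] for m in mods])
                meta = _fit_path(Ztr, ytr, max(u for _, u in members))
                P = pls_predict_path(meta, Zva)
                for ci, u in members:
                    out[ci, fi] = rmse(yva, _path_col(P, u))
        elif spec.strategy == "late":
            ntr = len(tr)
            n_oof = min(spec.oof_folds, ntr // 2)
            subfolds = oof_fold_indices(ntr, n_oof, [seed, 11, fi])
            base_max = {
                m: max(c[j] for c in candidates) for j, m in enumerate(mods)
            }
            oof = {}
            for m in mods:
                X = blocks[m][tr]
                M = np.empty((ntr, base_max[m]))
                for sub in subfolds:
                    comp = np.setdiff1d(np.arange(ntr), sub)
                    bm = _fit_path(X[comp], ytr[comp], base_max[m])
                    P = pls_predict_path(bm, X[sub])
                    M[sub] = np.pad(
                        P, ((0, 0), (0, base_max[m] - P.shape[1])), mode="edge"
                    )
                oof[m] = M
            full = {m: _fit_path(blocks[m][tr], ytr, base_max[m]) for m in mods}
            Pva = {m: pls_predict_path(full[m], blocks[m][va]) for m in mods}
            ones = np.ones(ntr)
            for ci, c in enumerate(candidates):
                A = np.column_stack(
                    [ones] + [_path_col(oof[m], a) for m, a in zip(mods, c)]
                )
                coef, *_ = np.linalg.lstsq(A, ytr, rcond=None)
                pred = coef[0] + sum(
                    w * _path_col(Pva[m], a)
                    for w, (m, a) in zip(coef[1:], zip(mods, c))
                )
                out[ci, fi] = rmse(yva, pred)
        else:  # pragma: no cover
            raise ValueError(spec.strategy)
    return out


@dataclass(frozen=True)
class TuneResult:
    params: dict
    rmsecv: float
    rmsecv_sd: float
    fold_rmse: np.ndarray = field(repr=False)


def tune(
    spec: ModelSpec,
    blocks: Mapping[str, np.ndarray],
    y: np.ndarray,
    folds: Sequence[tuple],
    seed: int = 0,
) -> TuneResult:
    """Argmin-RMSEcv hyperparameter selection over the spec's LV grid."""
    candidates = candidate_grid(spec, seed=seed)
    mat = cv_rmse_matrix(spec, blocks, y, folds, candidates, seed=seed)
    means = mat.mean(axis=1)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (means[i], sum(candidates[i]), candidates[i]),
    )
    best = order[0]
    params = dict(zip(spec.param_names(), candidates[best]))
    return TuneResult(
        params=params,
        rmsecv=float(means[best]),
        rmsecv_sd=float(mat[best].std(ddof=1)) if mat.shape[1] > 1 else 0.0,
        fold_rmse=mat[best].copy(),
    )


def repeated_kfold_rmse(
    spec: ModelSpec,
    blocks: Mapping[str, np.ndarray],
    y: np.ndarray,
    params: Mapping[str, int],
    repeats: int = 3,
    k: int = 10,
    seed: int = 0,
) -> tuple:
    """RMSEcv mean and SD of one configuration over repeats x k seeded folds."""
    y = np.asarray(y, dtype=float).ravel()
    folds = repeated_kfold_folds(y.shape[0], repeats, k, seed)
    cand = tuple(int(params[n]) for n in spec.param_names())
    mat = cv_rmse_matrix(spec, blocks, y, folds, [cand], seed=seed)
    vals = mat[0]
    return float(vals.mean()), float(vals.std(ddof=1)), vals


# -- fitting and prediction --------------------------------------------------

def fit_model(
    spec: ModelSpec,
    blocks: Mapping[str, np.ndarray],
    y: np.ndarray,
    params: Mapping[str, int],
    seed: int | Sequence[int] = 0,
):
    """Fit the spec's final model with chosen hyperparameters."""
    y = np.asarray(y, dtype=float).ravel()
    sub = {m: blocks[m] for m in spec.modalities}
    if spec.strategy == "single":
        return fit_pls(sub[spec.modalities[0]], y, int(params[spec.modalities[0]]))
    if spec.strategy == "early":
        return fit_early_fusion(sub, y, int(params["lv"]))
    if spec.strategy == "mid":
        base = {m: int(params[m]) for m in spec.modalities}
        return fit_mid_fusion(sub, y, base, int(params["meta"]))
    base = {m: int(params[m]) for m in spec.modalities}
    n_oof = min(spec.oof_folds, y.shape[0] // 2)
    return fit_late_fusion(sub, y, base, oof_folds=n_oof, seed=seed)


def predict_model(spec: ModelSpec, model, blocks: Mapping[str, np.ndarray]) -> np.ndarray:
    if spec.strategy == "single":
        return pls_predict(model, blocks[spec.modalities[0]])
    return predict_fusion(model, blocks)


# -- nested cross-validation -------------------------------------------------

@dataclass
class FoldScheme:
    """Outer-fold assignment: (repeat, fold) -> held-out sample IDs.

    Depends only on (dataset IDs, repeats, outer_k, seed); repeat-level seeds
    are derived as ``seed + repeat``, so adding repeats never changes earlier
    splits.
    """

    repeats: int
    outer_k: int
    seed: int
    assignment: dict


def build_fold_scheme(
    ids: Sequence[str], repeats: int, outer_k: int, seed: int
) -> FoldScheme:
    n = len(ids)
    if n < outer_k:
        raise ValueError(f"cannot split {n} samples into {outer_k} outer folds")
    assignment = {}
    for r in range(repeats):
        rng = np.random.default_rng(seed + r)
        perm = rng.permutation(n)
        for f, idx in enumerate(np.array_split(perm, outer_k)):
            assignment[(r, f)] = [ids[i] for i in np.sort(idx)]
    return FoldScheme(repeats=repeats, outer_k=outer_k, seed=seed, assignment=assignment)


def nested_cv(
    dataset: MultiModalDataset,
    specs: Sequence[ModelSpec],
    repeats: int = 10,
    outer_k: int = 5,
    inner_k: int = 5,
    seed: int = 0,
    recipe: Mapping | None = None,
) -> pd.DataFrame:
    """Repeated nested cross-validation with seed-matched outer splits.

    Returns a tidy frame with one record per (model_id, repeat, outer fold):
    ``repeats * outer_k`` records per model, every model scored on the
    identical held-out rows for each (repeat, fold). Preprocessing is applied
    to the training and held-out partitions separately; hyperparameters are
    tuned by ``inner_k``-fold CV on the training partition only.
    """
    ids = dataset.sample_ids
    pos = {s: i for i, s in enumerate(ids)}
    scheme = build_fold_scheme(ids, repeats, outer_k, seed)
    records = []
    for (r, f), test_ids in scheme.assignment.items():
        test_idx = np.asarray([pos[s] for s in test_ids], dtype=int)
        train_idx = np.setdiff1d(np.arange(len(ids)), test_idx)
        ds_tr = preprocess_pipeline(dataset.select(train_idx), recipe)
        ds_te = preprocess_pipeline(dataset.select(test_idx), recipe)
        y_tr, y_te = ds_tr.y, ds_te.y
        inner = _kfold(len(train_idx), inner_k, np.random.default_rng([seed, r, f]))
        for spec in specs:
            blocks_tr = ds_tr.block_matrices(spec.modalities)
            blocks_te = ds_te.block_matrices(spec.modalities)
            res = tune(spec, blocks_tr, y_tr, inner, seed=seed)
            model = fit_model(
                spec, blocks_tr, y_tr, res.params, seed=[seed, r, f, 9]
            )
            m = evaluate_predictions(y_te, predict_model(spec, model, blocks_te))
            records.append(
                {
                    "model_id": spec.model_id,
                    "repeat": r,
                    "fold": f,
                    "rmse": m.rmse,
                    "r2": m.r2,
                    "accuracy": m.accuracy,
                    "n": m.n,
                    "params": json.dumps(res.params),
                    "rmsecv": res.rmsecv,
                }
            )
    return pd.DataFrame(records)


def batch_on_batch_evaluate(
    dataset: MultiModalDataset,
    spec: ModelSpec,
    plan: PartitionPlan,
    recipe: Mapping | None = None,
    repeats: int = 3,
    k: int = 10,
    seed: int = 0,
) -> dict:
    """Train/tune on the plan's training IDs, test on each configured test set.

    Tuning uses repeated k-fold CV (default 3 x 10) on the preprocessed
    training partition; the winner is refit on all training rows and scored
    on the primary test set plus every auxiliary (cross-condition) test set.
    """
    ds_tr = preprocess_pipeline(dataset.subset_ids(plan.train_ids), recipe)
    y_tr = ds_tr.y
    blocks_tr = ds_tr.block_matrices(spec.modalities)
    folds = repeated_kfold_folds(len(y_tr), repeats, k, seed)
    res = tune(spec, blocks_tr, y_tr, folds, seed=seed)
    model = fit_model(spec, blocks_tr, y_tr, res.params, seed=[seed, 3])

    test_sets = {"test": list(plan.test_ids)}
    for cond, aux_ids in plan.aux_test_ids.items():
        if aux_ids:
            test_sets[f"condition:{cond}"] = list(aux_ids)
    out = {
        "model_id": spec.model_id,
        "params": res.params,
        "rmsecv_mean": res.rmsecv,
        "rmsecv_sd": res.rmsecv_sd,
        "tests": {},
    }
    for name, tids in test_sets.items():
        ds_te = preprocess_pipeline(dataset.subset_ids(tids), recipe)
        yhat = predict_model(spec, model, ds_te.block_matrices(spec.modalities))
        out["tests"][name] = evaluate_predictions(ds_te.y, yhat)
    return out
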