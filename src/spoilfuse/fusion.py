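"""Multi-sensor fusion architectures over PLS base learners.

Three strategies for combining modalities:

* **early** — each block is z-scored with train-fitted statistics, the
  standardised blocks are concatenated in a fixed modality order, and a
  single PLS model is fit on the combined matrix;
* **mid / feature** — one PLS model per modality is fit on the full training
  partition, its latent scores are extracted, the score matrices are
  concatenated (width = sum of base LV counts), and a second PLS model with
  ``u`` latent variables is fit on that feature space;
* **late / decision** — stacked generalisation: base PLS models generate
  out-of-fold (OOF) predictions under a seeded k-fold split of the training
  rows, an ordinary least-squares meta-learner (intercept + one weight per
  base model, unconstrained) is fit on the OOF prediction matrix, and the
  base models are refit on all training rows for inference.

Modality order is fixed as (MSI, FTIR, MSIF) everywhere, so column layouts —
and therefore fitted models — are invariant to the order in which blocks are
supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .pls_core import PLSModel, fit_pls, pls_predict, pls_transform
from .preprocessing import Standardiser, apply_standardiser, fit_standardiser

__all__ = [
    "FusionModel",
    "fit_early_fusion",
    "fit_mid_fusion",
    "fit_late_fusion",
    "predict_fusion",
    "MODALITY_ORDER",
    "canonical_order",
    "oof_fold_indices",
]

MODALITY_ORDER = ("MSI", "FTIR", "MSIF")


def canonical_order(modalities: Sequence[str]) -> tuple:
    """Fixed (MSI, FTIR, MSIF) ordering; unknown labels follow, sorted."""
    known = [m for m in MODALITY_ORDER if m in modalities]
    extra = sorted(set(modalities) - set(MODALITY_ORDER))
    return tuple(known + extra)


@dataclass
class FusionModel:
    """A fitted early/mid/late composite."""

    strategy: str
    modalities: tuple
    standardisers: dict | None = None          # early
    base_models: dict | None = None            # mid, late
    meta_pls: PLSModel | None = None           # early (the single PLS), mid
    meta_intercept: float | None = None        # late
    meta_weights: np.ndarray | None = None     # late, one per base model
    oof_folds: int | None = None               # late
    oof_matrix: np.ndarray | None = field(default=None, repr=False)  # late, audit

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "modalities": list(self.modalities),
            "standardisers": None
            if self.standardisers is None
            else {m: s.to_dict() for m, s in self.standardisers.items()},
            "base_models": None
            if self.base_models is None
            else {m: b.to_dict() for m, b in self.base_models.items()},
            "meta_pls": None if self.meta_pls is None else self.meta_pls.to_dict(),
            "meta_intercept": self.meta_intercept,
            "meta_weights": None
            if self.meta_weights is None
            else self.meta_weights.tolist(),
            "oof_folds": self.oof_folds,
            "oof_matrix": None if self.oof_matrix is None else self.oof_matrix.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FusionModel":
        return cls(
            strategy=d["strategy"],
            modalities=tuple(d["modalities"]),
            standardisers=None
            if d["standardisers"] is None
            else {m: Standardiser.from_dict(s) for m, s in d["standardisers"].items()},
            base_models=None
            if d["base_models"] is None
            else {m: PLSModel.from_dict(b) for m, b in d["base_models"].items()},
            meta_pls=None if d["meta_pls"] is None else PLSModel.from_dict(d["meta_pls"]),
            meta_intercept=d["meta_intercept"],
            meta_weights=None
            if d["meta_weights"] is None
            else np.asarray(d["meta_weights"], dtype=float),
            oof_folds=d["oof_folds"],
            oof_matrix=None
            if d["oof_matrix"] is None
            else np.asarray(d["oof_matrix"], dtype=float),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "FusionModel":
        return cls.from_dict(json.loads(s))


def _require_blocks(blocks: Mapping[str, np.ndarray], modalities: Sequence[str]) -> None:
    missing = [m for m in modalities if m not in blocks]
    if missing:
        raise ValueError(f"missing modality block(s): {missing}")


def fit_early_fusion(
    blocks: Mapping[str, np.ndarray], y: np.ndarray, n_lv: int
) -> FusionModel:
    """Standardise each block on the training rows, concatenate, fit one PLS."""
    mods = canonical_order(list(blocks))
    standardisers = {m: fit_standardiser(blocks[m]) for m in mods}
    Z = np.hstack([apply_standardiser(standardisers[m], blocks[m]) for m in mods])
    meta = fit_pls(Z, y, n_lv)
    return FusionModel(
        strategy="early", modalities=mods, standardisers=standardisers, meta_pls=meta
    )


def fit_mid_fusion(
    blocks: Mapping[str, np.ndarray],
    y: np.ndarray,
    base_lvs: Mapping[str, int],
    meta_lv: int,
) -> FusionModel:
    """Per-modality PLS -> concatenated latent scores -> second PLS with u LVs."""
    mods = canonical_order(list(blocks))
    total = sum(int(base_lvs[m]) for m in mods)
    if meta_lv > total:
        raise ValueError(
            f"meta_lv={meta_lv} exceeds the concatenated score width {total}"
        )
    base = {m: fit_pls(blocks[m], y, int(base_lvs[m])) for m in mods}
    Z = np.hstack([base[m].scores for m in mods])
    meta = fit_pls(Z, y, meta_lv)
    return FusionModel(strategy="mid", modalities=mods, base_models=base, meta_pls=meta)


def oof_fold_indices(n: int, n_folds: int, seed: int) -> list:
    """Seeded shuffled partition of ``range(n)`` into ``n_folds`` folds."""
    if n_folds < 2:
        raise ValueError("need at least 2 OOF folds")
    if n < 2 * n_folds:
        raise ValueError(
            f"{n} training rows cannot form {n_folds} folds of >= 2 rows"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, n_folds)]


def fit_late_fusion(
    blocks: Mapping[str, np.ndarray],
    y: np.ndarray,
    base_lvs: Mapping[str, int],
    oof_folds: int = 20,
    seed: int = 0,
) -> FusionModel:
    """Stacked generalisation with an OLS meta-learner on OOF predictions."""
    mods = canonical_order(list(blocks))
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    folds = oof_fold_indices(n, oof_folds, seed)

    oof = np.empty((n, len(mods)))
    for fold in folds:
        comp = np.setdiff1d(np.arange(n), fold)
        for j, m in enumerate(mods):
            bm = fit_pls(blocks[m][comp], y[comp], int(base_lvs[m]))
            oof[fold, j] = pls_predict(bm, blocks[m][fold])

    design = np.column_stack([np.ones(n), oof])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    base = {m: fit_pls(blocks[m], y, int(base_lvs[m])) for m in mods}
    return FusionModel(
        strategy="late",
        modalities=mods,
        base_models=base,
        meta_intercept=float(coef[0]),
        meta_weights=coef[1:],
        oof_folds=oof_folds,
        oof_matrix=oof,
    )


def predict_fusion(model: FusionModel, blocks: Mapping[str, np.ndarray]) -> np.ndarray:
    """Route new blocks through the strategy-specific prediction path."""
    _require_blocks(blocks, model.modalities)
    if model.strategy == "early":
        Z = np.hstack(
            [
                apply_standardiser(model.standardisers[m], blocks[m])
                for m in model.modalities
            ]
        )
        return pls_predict(model.meta_pls, Z)
    if model.strategy == "mid":
        Z = np.hstack(
            [pls_transform(model.base_models[m], blocks[m]) for m in model.modalities]
        )
        return pls_predict(model.meta_pls, Z)
    if model.strategy == "late":
        preds = np.column_stack(
            [pls_predict(model.base_models[m], blocks[m]) for m in model.modalities]
        )
        return model.meta_intercept + preds @ model.meta_weights
    raise ValueError(f"unknown fusion strategy {model.strategy!r}")
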