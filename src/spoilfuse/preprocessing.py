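"""Spectral preprocessing: SNV, Savitzky-Golay smoothing, fingerprint-region
restriction, and train-fitted z-score standardisation.

The default recipe mirrors common chemometric practice for spoilage spectra:

* FTIR: SNV -> Savitzky-Golay(window 11, polynomial order 1) -> restriction to
  the 2000-900 cm^-1 "spoilage fingerprint" region (restriction last, so any
  smoothing edge effects fall outside the retained window);
* MSI / MSIF: SNV only.

SNV and Savitzky-Golay are pure row statistics (no fitted state), so they can
be applied to any partition's rows independently without leakage. The
z-score :class:`Standardiser` is the only fitted transform and must be fit on
training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .dataset_io import MultiModalDataset, SpectralBlock

__all__ = [
    "snv",
    "savitzky_golay",
    "restrict_range",
    "Standardiser",
    "fit_standardiser",
    "apply_standardiser",
    "preprocess_pipeline",
    "DEFAULT_RECIPE",
]

# Per-modality ordered step lists; each entry is (step name, parameters).
DEFAULT_RECIPE: dict = {
    "FTIR": [
        ("snv", {}),
        ("savgol", {"window": 11, "polyorder": 1}),
        ("restrict", {"lo": 900.0, "hi": 2000.0}),
    ],
    "MSI": [("snv", {})],
    "MSIF": [("snv", {})],
}


def _snv_matrix(X: np.ndarray, ids: Sequence[str] | None = None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("SNV needs at least 2 features per row")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0.0)
    if bad.size:
        names = [ids[i] for i in bad[:5]] if ids is not None else bad[:5].tolist()
        raise ValueError(f"SNV: zero-variance row(s): {names}")
    return (X - mu) / sd


def snv(block: SpectralBlock) -> SpectralBlock:
    """Standard Normal Variate: per-row centering and scaling to unit sd.

    Removes multiplicative gain and additive offset artifacts exactly:
    ``snv(a*x + b) == snv(x)`` for any ``a > 0``. The sd uses the n-1
    denominator, which makes the transform exactly idempotent.
    """
    return SpectralBlock(
        modality=block.modality,
        feature_axis=list(block.feature_axis),
        matrix=_snv_matrix(block.matrix, block.sample_ids),
        sample_ids=list(block.sample_ids),
    )


def savitzky_golay(
    block: SpectralBlock, window: int = 11, polyorder: int = 1
) -> SpectralBlock:
    """Per-row local least-squares polynomial smoothing on a uniform grid.

    Edge rows are handled by fitting the edge polynomial to the outermost
    window (scipy ``mode="interp"``), which reproduces polynomial signals of
    degree <= ``polyorder`` exactly everywhere, edges included.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    if block.n_features < window:
        raise ValueError(
            f"window {window} >= feature count {block.n_features}"
        )
    axis = block.numeric_axis()
    steps = np.diff(axis)
    # tolerance admits axes whose labels were rounded to 4 decimals on disk
    if steps.size and not np.allclose(steps, steps[0], rtol=1e-3, atol=1e-6):
        raise ValueError(f"{block.modality}: feature grid is not uniform")
    smoothed = savgol_filter(
        block.matrix, window_length=window, polyorder=polyorder, axis=1, mode="interp"
    )
    return SpectralBlock(
        modality=block.modality,
        feature_axis=list(block.feature_axis),
        matrix=smoothed,
        sample_ids=list(block.sample_ids),
    )


def restrict_range(
    block: SpectralBlock, lo: float = 900.0, hi: float = 2000.0
) -> SpectralBlock:
    """Keep features whose wavenumber lies in the closed interval [lo, hi]."""
    axis = block.numeric_axis()
    mask = (axis >= lo) & (axis <= hi)
    if not mask.any():
        raise ValueError(
            f"{block.modality}: no features in [{lo}, {hi}] "
            f"(axis spans [{axis.min()}, {axis.max()}])"
        )
    keep = np.flatnonzero(mask)
    return SpectralBlock(
        modality=block.modality,
        feature_axis=[block.feature_axis[i] for i in keep],
        matrix=block.matrix[:, keep],
        sample_ids=list(block.sample_ids),
    )


@dataclass
class Standardiser:
    """Per-feature z-score statistics, fit on training rows only."""

    mean: np.ndarray
    sd: np.ndarray
    fitted_on: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "fitted_on": int(self.fitted_on),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardiser":
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            fitted_on=int(d["fitted_on"]),
        )


def fit_standardiser(matrix: np.ndarray) -> Standardiser:
    """Fit column means and sds (n-1 denominator); constant columns are rejected."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a standardiser")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise ValueError(f"constant training column(s) at index {bad[:5].tolist()}")
    return Standardiser(mean=mean, sd=sd, fitted_on=X.shape[0])


def apply_standardiser(s: Standardiser, matrix: np.ndarray) -> np.ndarray:
    """Apply train-fitted statistics to any matrix (no re-fit on test rows)."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] != s.mean.shape[0]:
        raise ValueError("feature axis mismatch with fitted standardiser")
    return (X - s.mean) / s.sd


_STEP_FUNCS = {
    "snv": lambda b, **kw: snv(b, **kw),
    "savgol": lambda b, **kw: savitzky_golay(b, **kw),
    "restrict": lambda b, **kw: restrict_range(b, **kw),
}


def preprocess_pipeline(
    dataset: MultiModalDataset, recipe: Mapping[str, Sequence] | None = None
) -> MultiModalDataset:
    """Apply a per-modality ordered recipe of row-statistic transforms.

    The recipe maps modality -> list of ``(step_name, params)`` (or
    ``{"name": ..., **params}`` dicts, as parsed from YAML). Only stateless
    row transforms are admitted here; fitted transforms (standardisers) are
    handled by the models that need them, fit on training rows only.
    """
    if recipe is None:
        recipe = DEFAULT_RECIPE
    blocks = {}
    for name, block in dataset.blocks.items():
        for step in recipe.get(name, []):
            if isinstance(step, Mapping):
                params = dict(step)
                step_name = params.pop("name")
            else:
                step_name, params = step
            try:
                fn = _STEP_FUNCS[step_name]
            except KeyError:
                raise ValueError(f"unknown preprocessing step {step_name!r}") from None
            block = fn(block, **params)
        blocks[name] = block
    return MultiModalDataset(blocks=blocks, metadata=dataset.metadata.copy())
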