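"""One-response partial least squares regression (PLS1) via NIPALS.

This is the base learner for every model in the pipeline: single-sensor
regressions, the early-fusion model on the concatenated standardised matrix,
and both layers of mid-level (feature) fusion.

The implementation centres X and y but applies no per-feature variance
scaling: spectra are row-normalised upstream (SNV), and explicit z-scoring is
applied exactly where the fusion pipeline calls for it (early fusion), so the
regression itself must not rescale features. PLS1 needs no iterative inner
loop — each weight vector has the closed form ``w = X'y / ||X'y||`` — so the
fit is fully deterministic.

Beyond the fitted coefficient vector, the model retains the *coefficient
path*: the coefficients that would result from truncating the decomposition
at every ``k <= n_lv``. NIPALS components are nested, so hyperparameter
searches over the latent-variable count can evaluate the whole range from a
single decomposition (see :mod:`spoilfuse.evaluation`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

__all__ = ["PLSModel", "fit_pls", "pls_transform", "pls_predict", "pls_predict_path"]

#: relative tolerance on ||X'y|| below which the residual is considered
#: rank-exhausted and the component sequence is truncated with a warning.
RANK_TOL = 1e-12


@dataclass
class PLSModel:
    """A fitted one-response PLS regression.

    Attributes
    ----------
    n_lv:
        Number of latent variables actually retained (may be smaller than
        requested if the residual rank was exhausted).
    x_mean, y_mean:
        Training centering vectors.
    weights:
        ``W`` (features x n_lv), unit-norm NIPALS weight vectors.
    x_loadings, y_loadings:
        ``P`` (features x n_lv) and ``q`` (n_lv,).
    rotations:
        ``R = W (P'W)^{-1}`` so that new scores are ``(X - x_mean) R``.
    coef:
        Assembled regression vector ``b`` such that prediction is the single
        affine map ``y_mean + (X - x_mean) b``.
    coef_path:
        (features x n_lv); column ``k-1`` is the coefficient vector of the
        model truncated to the first ``k`` components.
    scores:
        Training score matrix ``T`` (kept for diagnostics; its columns are
        mutually orthogonal).
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    rotations: np.ndarray
    coef: np.ndarray
    coef_path: np.ndarray
    scores: np.ndarray = field(repr=False)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_lv": int(self.n_lv),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "rotations": self.rotations.tolist(),
            "coef": self.coef.tolist(),
            "coef_path": self.coef_path.tolist(),
            "scores": self.scores.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            n_lv=int(d["n_lv"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            rotations=np.asarray(d["rotations"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            coef_path=np.asarray(d["coef_path"], dtype=float),
            scores=np.asarray(d["scores"], dtype=float),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "PLSModel":
        return cls.from_dict(json.loads(s))


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit a PLS1 regression with ``n_lv`` latent variables.

    Parameters
    ----------
    X : (n, p) matrix, y : (n,) response, n_lv : requested component count.

    Raises
    ------
    ValueError
        On fewer than 3 rows, zero-variance y, or ``n_lv`` outside
        ``1 <= n_lv <= min(p, n - 1)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be a 2-d matrix")
    n, p = X.shape
    if n != y.shape[0]:
        raise ValueError(f"row mismatch: X has {n} rows, y has {y.shape[0]}")
    if n < 3:
        raise ValueError("need at least 3 training rows")
    if not (1 <= n_lv <= min(p, n - 1)):
        raise ValueError(
            f"n_lv={n_lv} outside valid range [1, {min(p, n - 1)}] "
            f"for {n} rows x {p} features"
        )
    y_mean = float(y.mean())
    yd = y - y_mean
    if np.allclose(yd, 0.0):
        raise ValueError("y has zero variance; nothing to regress on")
    x_mean = X.mean(axis=0)
    E = X - x_mean

    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    q = np.empty(n_lv)
    T = np.empty((n, n_lv))

    norm0 = None
    k_done = 0
    for k in range(n_lv):
        v = E.T @ yd
        nv = float(np.linalg.norm(v))
        if norm0 is None:
            norm0 = nv
        if nv < RANK_TOL * norm0 or nv == 0.0:
            warnings.warn(
                f"rank exhausted after {k_done} components "
                f"(requested {n_lv}); truncating",
                stacklevel=2,
            )
            break
        w = v / nv
        t = E @ w
        tt = float(t @ t)
        pk = E.T @ t / tt
        qk = float(yd @ t / tt)
        E = E - np.outer(t, pk)
        W[:, k] = w
        P[:, k] = pk
        q[k] = qk
        T[:, k] = t
        k_done = k + 1

    if k_done == 0:
        raise ValueError("X'y is numerically zero; no PLS component extractable")
    W, P, q, T = W[:, :k_done], P[:, :k_done], q[:k_done], T[:, :k_done]

    # R = W (P'W)^{-1}; P'W is unit upper triangular under NIPALS.
    M = P.T @ W
    R = solve_triangular(M, W.T, trans="T", lower=False).T
    coef_path = np.cumsum(R * q[np.newaxis, :], axis=1)

    return PLSModel(
        n_lv=k_done,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        rotations=R,
        coef=coef_path[:, -1].copy(),
        coef_path=coef_path,
        scores=T,
    )


def _check_axis(model: PLSModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[np.newaxis, :]
    if X.shape[1] != model.x_mean.shape[0]:
        raise ValueError(
            f"feature axis mismatch: model has {model.x_mean.shape[0]} "
            f"features, X has {X.shape[1]}"
        )
    return X


def pls_transform(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Project rows of ``X`` into the model's latent space: ``(X - mu) R``."""
    X = _check_axis(model, X)
    return (X - model.x_mean) @ model.rotations


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict the response: ``y_mean + (X - mu) b``."""
    X = _check_axis(model, X)
    return model.y_mean + (X - model.x_mean) @ model.coef


def pls_predict_path(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predictions for every truncation 1..n_lv, as an (n, n_lv) matrix.

    Column ``k-1`` equals the prediction of the model refitted with only the
    first ``k`` latent variables (NIPALS components are nested).
    """
    X = _check_axis(model, X)
    return model.y_mean + (X - model.x_mean) @ model.coef_path
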