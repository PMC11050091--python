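"""Ridge-regression BLUP (rrBLUP) genomic prediction.

The model is y = mu + X u + e with i.i.d. normal marker effects
u ~ N(0, sigma_u2 I) and e ~ N(0, sigma_e2 I); the ridge parameter
lambda = sigma_e2 / sigma_u2 is estimated by REML through the equivalent
GBLUP form (kinship K = Xc Xc'), which keeps the spectral decomposition at
n x n even when markers vastly outnumber samples. Marker effects are then

    u = Xc' (K + lambda I)^{-1} (y - mu)

so marker-effect and kinship formulations give identical predictions.
Missing genotype cells are mean-imputed per marker and columns are centered
(no variance standardization); an imputed cell therefore contributes exactly
zero after centering, and a fully missing sample predicts at the intercept.
The same code serves all three genome parametrizations — values in [0, 1],
{0..4} or {0..2} only change the column means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._reml import profiled_reml, random_effect_blup
from .parametrization import GenotypeMatrix

#: lambda assigned when y carries no variance (effects are exactly zero).
_LAMBDA_DEGENERATE = 1e12


def _as_matrix(X):
    if isinstance(X, GenotypeMatrix):
        return np.asarray(X.values, dtype=float), list(X.markers)
    M = np.asarray(X, dtype=float)
    if M.ndim != 2:
        raise ValueError("genotype input must be 2-D")
    return M, [f"M{j}" for j in range(M.shape[1])]


@dataclass
class RRBLUPModel:
    """Fitted rrBLUP model: intercept, marker effects, ridge parameter, and
    the column means used for imputation and centering."""

    mu: float
    effects: np.ndarray
    markers: list
    lam: float
    col_means: np.ndarray

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mu": self.mu,
                    "lambda": self.lam,
                    "markers": list(self.markers),
                    "effects": self.effects.tolist(),
                    "col_means": self.col_means.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "RRBLUPModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mu=d["mu"],
            effects=np.asarray(d["effects"], float),
            markers=list(d["markers"]),
            lam=d["lambda"],
            col_means=np.asarray(d["col_means"], float),
        )


def _impute_center(M: np.ndarray, col_means: np.ndarray | None = None):
    if col_means is None:
        with np.errstate(invalid="ignore"):
            col_means = np.nanmean(M, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
    Xc = np.where(np.isnan(M), col_means[None, :], M) - col_means[None, :]
    return Xc, col_means


def fit_rrblup(X, y, lam: float | None = None) -> RRBLUPModel:
    """Fit rrBLUP; lambda is REML-estimated unless given explicitly."""
    M, markers = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = M.shape
    if n != y.size:
        raise ValueError("rows of X must align with y")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if p < 2:
        raise ValueError("need at least 2 markers")

    Xc, col_means = _impute_center(M)
    if np.all(y == y[0]):
        return RRBLUPModel(
            mu=float(y.mean()), effects=np.zeros(p), markers=markers,
            lam=_LAMBDA_DEGENERATE, col_means=col_means,
        )
    K = Xc @ Xc.T
    ones = np.ones((n, 1))
    if lam is None:
        fit = profiled_reml(y, ones, K)
        lam = 1.0 / fit["gamma"]
        mu = float(fit["beta"][0])
        u = random_effect_blup(fit, Xc.T)
    else:
        if lam <= 0:
            raise ValueError("lambda must be > 0")
        A = K + lam * np.eye(n)
        Ainv_y = np.linalg.solve(A, y)
        Ainv_1 = np.linalg.solve(A, ones[:, 0])
        mu = float(ones[:, 0] @ Ainv_y / (ones[:, 0] @ Ainv_1))
        u = Xc.T @ np.linalg.solve(A, y - mu)
    return RRBLUPModel(
        mu=mu, effects=np.asarray(u, float), markers=markers,
        lam=float(lam), col_means=col_means,
    )


def predict(model: RRBLUPModel, X_new) -> np.ndarray:
    """Predict phenotypes for new samples: y_hat = mu + Xc u.

    Markers must match the training set by id; missing cells are imputed
    with the training column means (so an all-missing sample predicts mu).
    """
    M, markers = _as_matrix(X_new)
    if markers != list(model.markers):
        extra = sorted(set(markers) - set(model.markers))[:5]
        missing = sorted(set(model.markers) - set(markers))[:5]
        if extra or missing:
            raise ValueError(
                f"marker mismatch: unseen {extra}, absent {missing}"
            )
        # same set, different order: align
        order = [markers.index(m) for m in model.markers]
        M = M[:, order]
    Xc, _ = _impute_center(M, model.col_means)
    return model.mu + Xc @ model.effects
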