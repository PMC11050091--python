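"""Profiled REML for a single-random-effect mixed model.

Model: y = X beta + g + e with g ~ N(0, sigma_g2 K) and e ~ N(0, sigma_e2 I).
The likelihood is profiled over gamma = sigma_g2 / sigma_e2 using one
eigendecomposition of K, so each candidate gamma costs O(n p) after the
initial O(n^3) factorization. Used both for trial BLUPs (K = Z Z') and for
rrBLUP's variance-ratio estimation (K = Xc Xc', the marker kinship).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar


def profiled_reml(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    log_gamma_bounds: tuple = (-12.0, 12.0),
    tol: float = 1e-8,
) -> dict:
    """Maximize the restricted likelihood over gamma = sigma_g2 / sigma_e2.

    Returns a dict with gamma, sigma_g2, sigma_e2, beta, the REML
    log-likelihood (up to a constant), and the rotated quantities needed to
    form BLUPs: U (eigenvectors of K), eigvals, w = 1/(1 + gamma*eigvals),
    yt = U'y, Xt = U'X.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than fixed effects")
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def components(log_gamma):
        gamma = math.exp(log_gamma)
        w = 1.0 / (1.0 + gamma * d)
        XtWX = (Xt * w[:, None]).T @ Xt
        beta = np.linalg.solve(XtWX, Xt.T @ (w * yt))
        r = yt - Xt @ beta
        rss = float(r @ (w * r))
        s2e = max(rss / (n - p), 1e-300)
        return gamma, w, XtWX, beta, s2e

    def neg_reml(log_gamma):
        gamma, w, XtWX, beta, s2e = components(log_gamma)
        sign, logdet = np.linalg.slogdet(XtWX)
        ll = -0.5 * (
            (n - p) * math.log(s2e)
            - np.log(w).sum()
            + logdet
            + (n - p)
        )
        return -ll

    res = minimize_scalar(
        neg_reml,
        bounds=log_gamma_bounds,
        method="bounded",
        options={"xatol": tol},
    )
    gamma, w, XtWX, beta, s2e = components(res.x)
    return {
        "gamma": gamma,
        "sigma_g2": gamma * s2e,
        "sigma_e2": s2e,
        "beta": beta,
        "reml_ll": -res.fun,
        "U": U,
        "eigvals": d,
        "w": w,
        "yt": yt,
        "Xt": Xt,
    }


def random_effect_blup(fit: dict, Zt: np.ndarray) -> np.ndarray:
    """BLUP of the random coefficients for a design whose contribution to K
    is Z Z' (or Xc Xc'): u = gamma * Z' U (w * (yt - Xt beta))."""
    resid_t = fit["w"] * (fit["yt"] - fit["Xt"] @ fit["beta"])
    return fit["gamma"] * (Zt @ (fit["U"] @ resid_t))
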