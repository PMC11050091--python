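"""Trial solution: family BLUPs, broad-sense heritability, genetic correlation.

A replicated trial (families x replicates, optionally per environment) is
solved with the mixed model

    value = mu + rep + g + e,        g ~ N(0, sigma_g2 I), e ~ N(0, sigma_e2 I)

where the family (genotype) effect g is random and replicates are fixed with
sum-to-zero contrasts, so the intercept is the overall mean. Variance
components come from profiled REML; family BLUPs are mu + g_hat. Broad-sense
heritability on an entry-mean basis is

    H2 = sigma_g2 / (sigma_g2 + sigma_e2 / n_reps)

and the genetic coefficients of variation are CVg = 100*sqrt(sigma_g2)/mean,
CVe = 100*sqrt(sigma_e2)/mean.

The cross-environment genetic correlation uses the variance-component
estimator r_g = cov_g(1,2) / sqrt(sigma_g2(1) * sigma_g2(2)): the genetic
covariance is the between-family covariance of per-environment family means
(plot errors are independent across environments, so that covariance is
unbiased for cov(g1, g2)), and the per-environment genetic variances come
from the REML fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._reml import profiled_reml, random_effect_blup


def heritability(sigma_g2: float, sigma_e2: float, n_reps: int) -> float:
    """Entry-mean broad-sense heritability sigma_g2/(sigma_g2 + sigma_e2/nr)."""
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variances must be non-negative")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if sigma_g2 == 0 and sigma_e2 == 0:
        raise ValueError("heritability undefined when both variances are zero")
    return sigma_g2 / (sigma_g2 + sigma_e2 / n_reps)


@dataclass
class HeritabilityEstimate:
    """Variance components and derived trial statistics for one trait."""

    sigma_g2: float
    sigma_e2: float
    n_reps: int
    mean: float

    @property
    def H2(self) -> float:
        return heritability(self.sigma_g2, self.sigma_e2, self.n_reps)

    @property
    def CVg(self) -> float:
        return 100.0 * np.sqrt(self.sigma_g2) / self.mean

    @property
    def CVe(self) -> float:
        return 100.0 * np.sqrt(self.sigma_e2) / self.mean


def _design(df: pd.DataFrame):
    families = sorted(df["genotype"].unique())
    reps = sorted(df["rep"].unique())
    fam_idx = pd.Categorical(df["genotype"], categories=families).codes
    rep_idx = pd.Categorical(df["rep"], categories=reps).codes
    n = len(df)
    Z = np.zeros((n, len(families)))
    Z[np.arange(n), fam_idx] = 1.0
    # intercept + sum-to-zero replicate contrasts: intercept = overall mean
    X = np.ones((n, len(reps)))
    for r in range(len(reps) - 1):
        X[:, r + 1] = (rep_idx == r).astype(float) - (
            rep_idx == len(reps) - 1
        ).astype(float)
    return families, reps, X, Z


def fit_blup(
    table: pd.DataFrame, trait: str, env: str | None = None
):
    """Solve the replicated trial for one trait (and environment).

    Returns (blups, estimate): ``blups`` is a Series of per-family predicted
    values (intercept + shrunken random effect) indexed by family id;
    ``estimate`` carries the REML variance components and H2/CVg/CVe.
    A trait with no genetic variance yields H2 ~ 0 and all BLUPs at the
    overall mean; that is a valid result, not an error.
    """
    df = table[table["trait"] == trait]
    if env is not None:
        df = df[df["env"] == env]
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}" +
                         (f" in env {env!r}" if env else ""))
    families, reps, X, Z = _design(df)
    if len(families) < 2 or len(reps) < 2:
        raise ValueError("need >= 2 families and >= 2 replicates")
    y = df["value"].to_numpy(dtype=float)

    if np.var(y) < 1e-300:
        blups = pd.Series(np.full(len(families), y.mean()), index=families)
        est = HeritabilityEstimate(0.0, 0.0, len(reps), float(y.mean()))
        return blups, est

    fit = profiled_reml(y, X, Z @ Z.T)
    g_hat = random_effect_blup(fit, Z.T)
    mu = fit["beta"][0]
    blups = pd.Series(mu + g_hat, index=families)
    est = HeritabilityEstimate(
        sigma_g2=float(fit["sigma_g2"]),
        sigma_e2=float(fit["sigma_e2"]),
        n_reps=len(reps),
        mean=float(y.mean()),
    )
    return blups, est


def heritability_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(trait, env) trial summary: H2, CVg, CVe, mean, range."""
    rows = []
    for (trait, env), grp in table.groupby(["trait", "env"]):
        blups, est = fit_blup(table, trait, env)
        rows.append(
            {
                "trait": trait,
                "env": env,
                "H2": est.H2,
                "CVg": est.CVg,
                "CVe": est.CVe,
                "mean": est.mean,
                "range_low": float(blups.min()),
                "range_high": float(blups.max()),
            }
        )
    return pd.DataFrame(rows)


def genetic_correlation(
    table: pd.DataFrame, trait: str, env_pair: tuple
) -> float:
    """Genetic correlation of family effects across two environments.

    Returns NaN when either per-environment genetic variance is ~ 0 (the
    correlation is then undefined); the estimate is clipped to [-1, 1].
    """
    e1, e2 = env_pair
    df = table[table["trait"] == trait]
    m1 = (
        df[df["env"] == e1].groupby("genotype")["value"].mean()
    )
    m2 = (
        df[df["env"] == e2].groupby("genotype")["value"].mean()
    )
    shared = m1.index.intersection(m2.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared families across environments")
    cov12 = float(np.cov(m1.loc[shared], m2.loc[shared], ddof=1)[0, 1])
    _, est1 = fit_blup(table, trait, e1)
    _, est2 = fit_blup(table, trait, e2)
    if est1.sigma_g2 <= 1e-12 or est2.sigma_g2 <= 1e-12:
        return float("nan")
    r_g = cov12 / np.sqrt(est1.sigma_g2 * est2.sigma_g2)
    return float(np.clip(r_g, -1.0, 1.0))


def write_blups_csv(blups_by_trait: dict, path) -> None:
    """Write per-family BLUPs, one column per trait."""
    pd.DataFrame(blups_by_trait).rename_axis("genotype").to_csv(path)


def read_blups_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
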