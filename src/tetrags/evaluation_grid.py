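"""Configuration grid: filters x parametrization x SNP subset x trait.

Predictive ability of each configuration is the Pearson correlation between
the phenotype vector (family BLUPs) and its out-of-fold genomic predictions
under k-fold cross-validation, repeated with reshuffled folds and averaged
for numerical stability. The grid runner reuses each depth-masked ratio
matrix and each per-depth dosage calling across the missing-rate levels and
subsets that share them, and is fully deterministic given its seed.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import ReadCountMatrix
from .genomic_prediction import fit_rrblup, predict
from .parametrization import (
    FilterConfig,
    GenotypeMatrix,
    collapse_diploid,
    call_dosage_unfiltered,
    masked_allele_ratio,
    missing_filter,
    subset_markers,
)

logger = logging.getLogger(__name__)

RESULT_COLUMNS = (
    "trait", "subset", "parametrization", "max_missing", "min_reads",
    "n_markers", "pred_ability_mean", "pred_ability_sd",
)


@dataclass
class GridConfig:
    """The evaluation grid and cross-validation settings."""

    min_reads: tuple = (10, 20, 30, 40)
    max_missing: tuple = (0.05, 0.10, 0.20)
    parametrizations: tuple = ("ratio", "tetraploid", "diploid")
    subsets: tuple = ("all", "genic", "non_genic")
    traits: tuple | None = None
    k: int = 10
    repeats: int = 10
    seed: int = 0
    pooled: bool = True
    base_filter: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not (self.min_reads and self.max_missing and self.parametrizations
                and self.subsets):
            raise ValueError("grid must be non-empty")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) < 1e-300 or np.std(b) < 1e-300:
        warnings.warn("zero-variance vector in predictive ability; r set to 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def predictive_ability(
    X, y, k: int = 10, repeats: int = 10, seed: int = 0,
    pooled: bool = True, predictor=None,
):
    """Repeated k-fold cross-validated predictive ability.

    For each repeat the samples are reshuffled (seed + repeat index), split
    into k nearly equal folds, and each fold is predicted by a model trained
    on the rest. Per repeat, r is the Pearson correlation between the full
    observed vector and the pooled out-of-fold predictions (set
    ``pooled=False`` to average per-fold correlations instead). Returns
    (mean r, sd r) over repeats.

    ``predictor(train_X, train_y, test_X) -> y_hat`` may replace the default
    rrBLUP fit (used for calibration checks).
    """
    M = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X, float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if M.shape[0] != n:
        raise ValueError("rows of X must align with y")
    if n < k:
        raise ValueError("need at least k samples")

    if predictor is None:
        def predictor(train_X, train_y, test_X):
            model = fit_rrblup(train_X, train_y)
            return predict(model, test_X)

    rs = []
    for rep in range(repeats):
        rng = np.random.default_rng(seed + rep)
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        y_hat = np.empty(n)
        fold_rs = []
        for fold in folds:
            train = np.setdiff1d(np.arange(n), fold)
            y_hat[fold] = predictor(M[train], y[train], M[fold])
            if not pooled:
                fold_rs.append(_pearson(y[fold], y_hat[fold]))
        if pooled:
            rs.append(_pearson(y, y_hat))
        else:
            rs.append(float(np.mean(fold_rs)))
    rs = np.asarray(rs)
    sd = float(rs.std(ddof=1)) if repeats > 1 else 0.0
    return float(rs.mean()), sd


def _config_seed(seed: int, *parts) -> int:
    tag = "|".join(str(p) for p in parts)
    return (seed * 1000003 + zlib.crc32(tag.encode())) % (2**31 - 1)


def run_grid(
    gc: GridConfig,
    rc: ReadCountMatrix,
    ann: pd.DataFrame,
    phenos: dict,
) -> pd.DataFrame:
    """Evaluate every (min_reads, max_missing, parametrization, subset,
    trait) cell of the grid.

    ``phenos`` maps trait name -> per-sample phenotype Series (family BLUPs)
    indexed by sample id. Configurations yielding fewer than 2 markers are
    recorded with NA predictive ability and the run continues.
    """
    traits = list(gc.traits) if gc.traits else list(phenos)
    ys = {}
    for t in traits:
        y = phenos[t].reindex(rc.samples)
        if y.isna().any():
            raise ValueError(f"phenotype {t!r} missing for some samples")
        ys[t] = y.to_numpy(dtype=float)

    # cache per-depth work shared across missing levels / subsets / traits
    ratio_raw, dosage_raw = {}, {}
    for mr in gc.min_reads:
        if "ratio" in gc.parametrizations:
            ratio_raw[mr] = masked_allele_ratio(rc, mr)
        if {"tetraploid", "diploid"} & set(gc.parametrizations):
            dosage_raw[mr] = call_dosage_unfiltered(rc, mr, gc.base_filter)

    rows = []
    for mr in gc.min_reads:
        for mm in gc.max_missing:
            mats = {}
            if "ratio" in gc.parametrizations:
                vals, keep = missing_filter(ratio_raw[mr], mm)
                if keep.any():
                    mats["ratio"] = GenotypeMatrix(
                        values=vals, samples=rc.samples,
                        markers=[m for m, kk in zip(rc.loci, keep) if kk],
                        parametrization="ratio",
                    )
            if "tetraploid" in gc.parametrizations or "diploid" in gc.parametrizations:
                calls, keep_b, _ = dosage_raw[mr]
                vals = calls[:, keep_b]
                loci_b = [m for m, kk in zip(rc.loci, keep_b) if kk]
                vals, keep2 = missing_filter(vals, mm)
                if keep2.any():
                    tetra = GenotypeMatrix(
                        values=vals, samples=rc.samples,
                        markers=[m for m, kk in zip(loci_b, keep2) if kk],
                        parametrization="tetraploid",
                    )
                    if "tetraploid" in gc.parametrizations:
                        mats["tetraploid"] = tetra
                    if "diploid" in gc.parametrizations:
                        mats["diploid"] = collapse_diploid(tetra)
            for par in gc.parametrizations:
                for sub in gc.subsets:
                    g = mats.get(par)
                    if g is not None:
                        try:
                            g_sub = subset_markers(g, ann, sub)
                        except ValueError:
                            g_sub = None
                    else:
                        g_sub = None
                    for t in traits:
                        if g_sub is None or g_sub.n_markers < 2:
                            logger.info(
                                "config dropped (no markers): mr=%s mm=%s %s %s %s",
                                mr, mm, par, sub, t,
                            )
                            rows.append(
                                dict(zip(RESULT_COLUMNS,
                                         (t, sub, par, mm, mr, 0,
                                          np.nan, np.nan)))
                            )
                            continue
                        cs = _config_seed(gc.seed, t, sub, par, mm, mr)
                        mean_r, sd_r = predictive_ability(
                            g_sub, ys[t], k=gc.k, repeats=gc.repeats,
                            seed=cs, pooled=gc.pooled,
                        )
                        rows.append(
                            dict(zip(RESULT_COLUMNS,
                                     (t, sub, par, mm, mr,
                                      g_sub.n_markers, mean_r, sd_r)))
                        )
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def pairwise_improvement(mean_x: float, mean_y: float) -> float:
    """Percent improvement of x over y: 100 * (mean_x - mean_y) / mean_y."""
    return 100.0 * (mean_x - mean_y) / mean_y


def _improvement_table(means: pd.Series) -> pd.DataFrame:
    out = pd.DataFrame(index=means.index, columns=means.index, dtype=float)
    for a in means.index:
        for b in means.index:
            out.loc[a, b] = pairwise_improvement(means[a], means[b])
    return out


def summarize(gr: pd.DataFrame) -> dict:
    """Summary tables from a grid result.

    Returns a dict with:
    * ``best`` — per-trait best configuration (ties broken by fewer markers,
      then lexicographic configuration id);
    * ``marginal_parametrization`` / ``marginal_subset`` — predictive-ability
      means marginalized over all other factors;
    * ``improvement_parametrization`` / ``improvement_subset`` — pairwise
      percent-improvement matrices between those marginal means.
    """
    if gr.empty:
        raise ValueError("empty grid result")
    gr = gr.dropna(subset=["pred_ability_mean"]).copy()
    gr["_config_id"] = (
        gr["subset"].astype(str) + "|" + gr["parametrization"].astype(str)
        + "|" + gr["max_missing"].astype(str) + "|" + gr["min_reads"].astype(str)
    )
    best_rows = []
    for t, grp in gr.groupby("trait"):
        ordered = grp.sort_values(
            ["pred_ability_mean", "n_markers", "_config_id"],
            ascending=[False, True, True],
        )
        best_rows.append(ordered.iloc[0].drop("_config_id"))
    best = pd.DataFrame(best_rows).reset_index(drop=True)
    marg_par = gr.groupby("parametrization")["pred_ability_mean"].mean()
    marg_sub = gr.groupby("subset")["pred_ability_mean"].mean()
    return {
        "best": best,
        "marginal_parametrization": marg_par,
        "marginal_subset": marg_sub,
        "improvement_parametrization": _improvement_table(marg_par),
        "improvement_subset": _improvement_table(marg_sub),
    }


def write_results_csv(gr: pd.DataFrame, path) -> None:
    gr.to_csv(path, index=False)


def plot_grid(gr: pd.DataFrame, trait: str, parametrization: str = "ratio",
              path=None):
    """Line plot of predictive ability vs min_reads, one line per
    (subset, max_missing). Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sel = gr[(gr["trait"] == trait) & (gr["parametrization"] == parametrization)]
    fig, ax = plt.subplots(figsize=(6, 4))
    for (sub, mm), grp in sel.groupby(["subset", "max_missing"]):
        grp = grp.sort_values("min_reads")
        ax.plot(grp["min_reads"], grp["pred_ability_mean"],
                marker="o", label=f"{sub}, missing<={mm:g}")
    ax.set_xlabel("minimum reads per locus")
    ax.set_ylabel("predictive ability (Pearson r)")
    ax.set_title(f"{trait} ({parametrization})")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
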