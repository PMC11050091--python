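"""Genome parametrizations and the depth/missing/bias filter stack.

A tetraploid read-count matrix can be represented for genomic regression in
three ways:

* **allele ratio** — the continuous fraction of alternative reads,
  AR = a / (A + a) in [0, 1];
* **tetraploid dosage** — the inferred integer count of alternative alleles
  in {0..4}, called per locus by an EM-fitted five-component binomial
  mixture with a per-locus allele-detection bias and a sequencing error
  floor/ceiling at the homozygous classes;
* **diploid dosage** — the tetraploid calls with the three heterozygote
  classes collapsed into one intermediate bin, {0, 1, 2}.

Filters are applied in a fixed order: per-cell depth mask (total reads below
``min_reads`` is missing) -> for dosage, the EM call with its bias filter
(loci whose fitted bias falls outside [e^-1, e^1] are discarded) and a
posterior-confidence mask -> per-marker missing-rate filter (markers whose
missing fraction exceeds ``max_missing`` are dropped). Because dosage calling
only adds missingness and locus drops on top of the ratio mask, the ratio
marker set is always a superset of the dosage marker set for the same filter
settings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genotype_io import ReadCountMatrix, make_annotation
from .synthetic_data import dosage_to_alt_fraction

logger = logging.getLogger(__name__)

PARAMETRIZATIONS = ("ratio", "tetraploid", "diploid")
SUBSET_MODES = ("all", "genic", "non_genic")
_DOSAGES = np.arange(5)


@dataclass
class FilterConfig:
    """One cell of the filter grid plus dosage-caller settings."""

    min_reads: int = 10
    max_missing: float = 0.10
    bias_low: float = math.exp(-1)
    bias_high: float = math.e
    call_threshold: float = 0.9
    min_cells: int = 10
    em_max_iter: int = 200
    em_tol: float = 1e-6

    def __post_init__(self):
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not 0 < self.max_missing < 1:
            raise ValueError("max_missing must be in (0, 1)")
        if not self.bias_low < self.bias_high:
            raise ValueError("bias_low must be < bias_high")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GenotypeMatrix:
    """Samples x markers matrix under one parametrization; NaN is missing."""

    values: np.ndarray
    samples: list
    markers: list
    parametrization: str
    filter: FilterConfig | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.samples = list(self.samples)
        self.markers = list(self.markers)
        if self.values.shape != (len(self.samples), len(self.markers)):
            raise ValueError("values must be (n_samples, n_markers)")
        if self.parametrization not in PARAMETRIZATIONS:
            raise ValueError(f"unknown parametrization {self.parametrization!r}")
        finite = self.values[~np.isnan(self.values)]
        if self.parametrization == "ratio":
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("ratio values must lie in [0, 1]")
        else:
            top = 4 if self.parametrization == "tetraploid" else 2
            if finite.size and (
                (finite != np.round(finite)).any()
                or finite.min() < 0
                or finite.max() > top
            ):
                raise ValueError(
                    f"{self.parametrization} values must be integers in [0, {top}]"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            values=self.values[idx],
            samples=[self.samples[i] for i in idx],
            markers=self.markers,
            parametrization=self.parametrization,
            filter=self.filter,
        )


@dataclass
class LocusFit:
    """Per-locus EM dosage-model fit."""

    bias: float
    error: float
    prior: np.ndarray
    posterior: np.ndarray  # (n_cells, 5)
    converged: bool
    n_iter: int
    loglik: float


def masked_allele_ratio(rc: ReadCountMatrix, min_reads: int) -> np.ndarray:
    """Allele-ratio matrix with cells below the depth threshold set to NaN."""
    tot = rc.total_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = rc.alt_depth / np.where(tot > 0, tot, 1)
    return np.where(tot >= min_reads, vals, np.nan)


def missing_filter(values: np.ndarray, max_missing: float):
    """Drop markers whose missing fraction exceeds ``max_missing``.

    Returns (filtered values, boolean keep mask over markers).
    """
    miss_frac = np.isnan(values).mean(axis=0)
    keep = miss_frac <= max_missing
    return values[:, keep], keep


def allele_ratio(rc: ReadCountMatrix, f: FilterConfig) -> GenotypeMatrix:
    """Allele-ratio parametrization: a / (A + a) per cell, depth-masked."""
    vals = masked_allele_ratio(rc, f.min_reads)
    vals, keep = missing_filter(vals, f.max_missing)
    if not keep.any():
        raise ValueError("allele_ratio: no markers survive the filters")
    return GenotypeMatrix(
        values=vals,
        samples=rc.samples,
        markers=[m for m, k in zip(rc.loci, keep) if k],
        parametrization="ratio",
        filter=f,
    )


#: deterministic EM restarts over the bias initialization; the likelihood
#: surface has shifted-assignment local optima when the true bias is large.
_BIAS_INITS = (1.0, math.exp(1.5), math.exp(-1.5))


def _fit_locus_em(a: np.ndarray, n: np.ndarray, f: FilterConfig) -> LocusFit:
    """Fit the five-class binomial mixture at one locus.

    Runs EM from several fixed bias initializations and keeps the highest
    restricted log-likelihood: strong allele bias creates local optima in
    which every dosage class is shifted by one.
    """
    best = None
    for b0 in _BIAS_INITS:
        fit = _em_single_start(a, n, f, b0)
        if best is None or (fit.converged and not best.converged) or (
            fit.converged == best.converged and fit.loglik > best.loglik
        ):
            best = fit
    return best


def _em_single_start(
    a: np.ndarray, n: np.ndarray, f: FilterConfig, b_init: float
) -> LocusFit:
    """One EM run for the five-class binomial mixture.

    Classes d in {0..4} have alternative-read fraction
    xi_d = (d/4) b / ((1 - d/4) + (d/4) b), with xi_0 = e and xi_4 = 1 - e.
    The class prior is a discretized normal over {0..4} whose mean and sd are
    re-estimated each M-step; bias b is updated by bounded 1-D optimization
    of the expected complete-data log-likelihood over the heterozygote
    classes, and the error rate e in closed form from the homozygote classes.
    """
    a = a.astype(float)
    n = n.astype(float)
    m = a.size
    b, e = b_init, 0.005
    # initialize the prior from dosages implied by the observed ratios under
    # the initial bias: f_hat = ar / (ar + b * (1 - ar)), lightly smoothed
    ar = a / n
    f_hat = ar / (ar + b * (1.0 - ar))
    rounded = np.clip(np.round(4.0 * f_hat).astype(int), 0, 4)
    counts = np.bincount(rounded, minlength=5).astype(float)
    prior = (counts + 0.5) / (counts.sum() + 2.5)
    het = np.array([1, 2, 3])

    ll_old = -np.inf
    converged = False
    post = np.full((m, 5), 0.2)
    ll = ll_old
    for it in range(1, f.em_max_iter + 1):
        xi = dosage_to_alt_fraction(_DOSAGES, b, e)
        # binomial log-likelihood up to the data-only constant
        lg = (
            a[:, None] * np.log(xi)[None, :]
            + (n - a)[:, None] * np.log1p(-xi)[None, :]
            + np.log(prior)[None, :]
        )
        mx = lg.max(axis=1, keepdims=True)
        w = np.exp(lg - mx)
        s = w.sum(axis=1, keepdims=True)
        post = w / s
        ll = float((np.log(s) + mx).sum())
        if abs(ll - ll_old) < f.em_tol:
            converged = True
            break
        ll_old = ll

        # M-step: discretized-normal prior moments
        mu = float((post * _DOSAGES).sum() / m)
        var = float((post * (_DOSAGES - mu) ** 2).sum() / m)
        sd = min(max(math.sqrt(max(var, 1e-12)), 0.25), 4.0)
        prior = np.exp(-0.5 * ((_DOSAGES - mu) / sd) ** 2)
        prior /= prior.sum()

        # error rate from the homozygote classes
        den = float((post[:, 0] + post[:, 4]) @ n)
        if den > 0:
            num = float(post[:, 0] @ a + post[:, 4] @ (n - a))
            e = min(max(num / den, 1e-4), 0.45)

        # bias from the heterozygote classes
        s_alt = post[:, het].T @ a
        s_ref = post[:, het].T @ (n - a)
        if (s_alt + s_ref).sum() > 1e-8:
            def neg_q(logb):
                xi_h = dosage_to_alt_fraction(het, math.exp(logb), e)
                return -float(
                    s_alt @ np.log(xi_h) + s_ref @ np.log1p(-xi_h)
                )

            res = minimize_scalar(
                neg_q, bounds=(-3.0, 3.0), method="bounded",
                options={"xatol": 1e-5},
            )
            b = math.exp(res.x)

    return LocusFit(
        bias=b, error=e, prior=prior, posterior=post,
        converged=converged, n_iter=it, loglik=ll,
    )


def call_dosage_unfiltered(rc: ReadCountMatrix, min_reads: int, f: FilterConfig):
    """EM dosage calls for every locus, before the missing-rate filter.

    Returns (calls, keep, bias): ``calls`` is a full-width (samples x loci)
    float matrix of posterior-mode dosages with NaN for depth-masked or
    low-confidence cells; ``keep`` flags loci that survived the EM fit and
    the bias filter; ``bias`` holds the fitted per-locus bias (NaN where the
    fit was not attempted).
    """
    tot = rc.total_depth
    mask = tot >= min_reads
    n_s, n_l = rc.n_samples, rc.n_loci
    calls = np.full((n_s, n_l), np.nan)
    bias = np.full(n_l, np.nan)
    keep = np.zeros(n_l, dtype=bool)
    drops = {"too_few_cells": 0, "no_convergence": 0, "bias": 0}
    for j in range(n_l):
        cells = mask[:, j]
        if int(cells.sum()) < f.min_cells:
            drops["too_few_cells"] += 1
            continue
        fit = _fit_locus_em(rc.alt_depth[cells, j], tot[cells, j], f)
        if not fit.converged:
            drops["no_convergence"] += 1
            continue
        bias[j] = fit.bias
        if not f.bias_low <= fit.bias <= f.bias_high:
            drops["bias"] += 1
            continue
        keep[j] = True
        call = fit.posterior.argmax(axis=1).astype(float)
        conf = fit.posterior.max(axis=1)
        call[conf < f.call_threshold] = np.nan
        col = np.full(n_s, np.nan)
        col[cells] = call
        calls[:, j] = col
    if any(drops.values()):
        logger.info(
            "dosage calling dropped loci: %s",
            ", ".join(f"{k}={v}" for k, v in drops.items() if v),
        )
    return calls, keep, bias


def call_tetraploid_dosage(
    rc: ReadCountMatrix, f: FilterConfig, ann: pd.DataFrame | None = None
):
    """Tetraploid dosage parametrization with the full filter stack.

    Returns (GenotypeMatrix, MarkerAnnotation): the annotation covers all
    input loci with the fitted per-locus bias filled in; the matrix holds the
    loci that survived the EM fit, bias filter, and missing-rate filter.
    """
    calls, keep, bias = call_dosage_unfiltered(rc, f.min_reads, f)
    if ann is None:
        ann = make_annotation(rc.loci, "", np.zeros(rc.n_loci, dtype=int))
    ann = ann.copy()
    ann.loc[rc.loci, "bias"] = bias
    vals = calls[:, keep]
    vals, keep2 = missing_filter(vals, f.max_missing)
    kept_loci = [m for m, k in zip(rc.loci, keep) if k]
    markers = [m for m, k in zip(kept_loci, keep2) if k]
    if not markers:
        raise ValueError("call_tetraploid_dosage: no markers survive the filters")
    g = GenotypeMatrix(
        values=vals,
        samples=rc.samples,
        markers=markers,
        parametrization="tetraploid",
        filter=f,
    )
    return g, ann


def collapse_diploid(tetra: GenotypeMatrix) -> GenotypeMatrix:
    """Collapse tetraploid dosages to the diploid coding 0/1/2.

    The three heterozygote classes {1, 2, 3} map to the single intermediate
    value 1; homozygotes map to 0 and 2. The marker set is unchanged by
    construction.
    """
    if tetra.parametrization != "tetraploid":
        raise ValueError("collapse_diploid requires a tetraploid matrix")
    v = tetra.values
    out = np.full_like(v, np.nan)
    out[v == 0] = 0.0
    out[(v >= 1) & (v <= 3)] = 1.0
    out[v == 4] = 2.0
    return GenotypeMatrix(
        values=out,
        samples=tetra.samples,
        markers=tetra.markers,
        parametrization="diploid",
        filter=tetra.filter,
    )


def subset_markers(
    g: GenotypeMatrix, ann: pd.DataFrame, mode: str
) -> GenotypeMatrix:
    """Restrict to genic or non-genic markers (``mode='all'`` is identity)."""
    if mode not in SUBSET_MODES:
        raise ValueError(f"unknown subset mode {mode!r}")
    if mode == "all":
        return g
    genic = ann.loc[g.markers, "genic"].to_numpy(dtype=bool)
    keep = genic if mode == "genic" else ~genic
    if not keep.any():
        raise ValueError(f"subset_markers: empty {mode!r} subset")
    return GenotypeMatrix(
        values=g.values[:, keep],
        samples=g.samples,
        markers=[m for m, k in zip(g.markers, keep) if k],
        parametrization=g.parametrization,
        filter=g.filter,
    )


def write_genotype_csv(g: GenotypeMatrix, path) -> None:
    """Write samples x markers CSV (NA for missing) plus a sidecar JSON with
    the parametrization tag and filter provenance."""
    import json

    df = pd.DataFrame(g.values, index=g.samples, columns=g.markers)
    df.index.name = "sample"
    df.to_csv(path, na_rep="NA")
    meta = {
        "parametrization": g.parametrization,
        "filter": g.filter.to_dict() if g.filter else None,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_genotype_csv(path) -> GenotypeMatrix:
    import json
    import os

    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    meta_path = str(path) + ".json"
    tag, filt = "ratio", None
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = json.load(fh)
        tag = meta.get("parametrization", tag)
        if meta.get("filter"):
            filt = FilterConfig(**meta["filter"])
    return GenotypeMatrix(
        values=df.to_numpy(dtype=float),
        samples=list(df.index.astype(str)),
        markers=list(df.columns.astype(str)),
        parametrization=tag,
        filter=filt,
    )
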