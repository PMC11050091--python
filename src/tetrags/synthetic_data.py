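"""Synthetic autotetraploid GBS and field-trial data with known ground truth.

The generator emulates the statistical structure of a genomic-selection study
in an autotetraploid outbreeder (alfalfa-like): a panel of ~100-150 genotyped
parent plants scored at thousands of GBS SNPs with depth-variable,
bias-affected allelic read counts, and replicated two-environment phenotype
trials on their half-sib progenies with broad-sense heritabilities in the
0.30-0.69 range and a cross-environment genetic correlation near 0.8.

Model summary
-------------
* per-locus alternative-allele frequency p ~ Uniform(maf_range);
* per-sample dosage d ~ Binomial(4, p) (Hardy-Weinberg autotetraploid,
  random chromosome pairing, no double reduction);
* per-cell total depth ~ NegativeBinomial(mean_depth, depth_dispersion);
* alternative reads ~ Binomial(depth, xi) with
  xi = (d/4) b / ((1 - d/4) + (d/4) b), b = exp(Normal(0, bias_log_sd)) the
  per-locus allele-detection bias, and xi floored/ceiled at the sequencing
  error rate for the two homozygous classes;
* a missing_cell_rate fraction of cells is dropped to zero depth;
* genic flags are Bernoulli(genic_fraction), and gene intervals are laid out
  so that positional overlap recovers exactly those flags;
* traits are polygenic: n_qtl additive QTL effects define true breeding
  values; trial plots get value = mean + g(sample, env) + error where the
  genotype effect g mixes a (transmitted) additive component with a
  non-additive deviation, has cross-environment correlation r_g_target, and
  the error variance is set so that the entry-mean broad-sense heritability
  sigma_g^2 / (sigma_g^2 + sigma_e^2 / n_reps) equals h2_target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotype_io import ReadCountMatrix, make_annotation

TRIAL_COLUMNS = ("genotype", "env", "rep", "trait", "value")


@dataclass
class SimConfig:
    """Parameters of the synthetic population, sequencing, and trial."""

    n_genotypes: int = 143
    n_loci: int = 5000
    ploidy: int = 4
    maf_range: tuple = (0.05, 0.5)
    mean_depth: float = 60.0
    depth_dispersion: float = 2.0
    bias_log_sd: float = 0.3
    seq_error: float = 0.005
    missing_cell_rate: float = 0.05
    genic_fraction: float = 0.739
    n_qtl: int = 100
    h2_target: dict = field(default_factory=lambda: {"dry_matter": 0.529})
    trait_mean: float = 20.0
    sigma_g2: float = 1.0
    additive_fraction: float = 0.5
    n_reps: int = 3
    n_envs: int = 2
    r_g_target: float = 0.82
    n_chromosomes: int = 8
    locus_spacing: int = 1000
    seed: int = 0

    @property
    def traits(self) -> list:
        return list(self.h2_target)

    def validate(self) -> None:
        if self.ploidy != 4:
            raise ValueError("only ploidy=4 is supported")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.n_genotypes < 2:
            raise ValueError("n_genotypes must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 < self.genic_fraction < 1:
            raise ValueError("genic_fraction must be in (0, 1)")
        if self.n_qtl > self.n_loci:
            raise ValueError("n_qtl must not exceed n_loci")
        for trait, h2 in self.h2_target.items():
            if not 0 < h2 < 1:
                raise ValueError(f"h2_target[{trait!r}] must be in (0, 1)")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must be in [0, 0.5)")
        if self.bias_log_sd < 0 or self.depth_dispersion <= 0:
            raise ValueError("bias_log_sd >= 0 and depth_dispersion > 0 required")
        if not 0 <= self.missing_cell_rate < 1:
            raise ValueError("missing_cell_rate must be in [0, 1)")
        if not 0 < self.additive_fraction < 1:
            raise ValueError("additive_fraction must be in (0, 1)")
        if not -1 <= self.r_g_target <= 1:
            raise ValueError("r_g_target must be in [-1, 1]")
        if self.n_envs > 1:
            rho = self._nonadditive_corr()
            if not -1 <= rho <= 1:
                raise ValueError(
                    "r_g_target incompatible with additive_fraction: the "
                    "implied non-additive cross-environment correlation "
                    f"{rho:.3f} is outside [-1, 1]"
                )
        if self.n_reps < 1 or self.n_envs < 1:
            raise ValueError("n_reps and n_envs must be >= 1")

    def _nonadditive_corr(self) -> float:
        # additive component is shared across environments, so
        # r_g = f_a + (1 - f_a) * rho_delta
        f_a = self.additive_fraction
        return (self.r_g_target - f_a) / (1.0 - f_a)


@dataclass
class GroundTruth:
    """Latent state of a simulated population, for recovery tests."""

    true_dosages: np.ndarray          # (n_genotypes, n_loci) int in 0..4
    qtl_indices: np.ndarray           # locus indices
    qtl_effects: np.ndarray           # (n_qtl, n_traits)
    true_breeding_values: np.ndarray  # (n_genotypes, n_traits)
    bias: np.ndarray                  # per-locus multiplicative factor
    allele_freq: np.ndarray           # per-locus drawn p
    trait_names: list
    samples: list
    loci: list


def dosage_to_alt_fraction(dosage, bias, seq_error) -> np.ndarray:
    """Expected alternative-read fraction for a dosage under bias ``b``.

    xi = (d/4) b / ((1 - d/4) + (d/4) b); the homozygous classes (d = 0, 4)
    are floored/ceiled at the sequencing error rate.
    """
    d = np.asarray(dosage, dtype=float)
    frac = d / 4.0
    xi = frac * bias / ((1.0 - frac) + frac * bias)
    xi = np.where(d == 0, seq_error, xi)
    xi = np.where(d == 4, 1.0 - seq_error, xi)
    return xi


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(stream,))
    )


def simulate_population(cfg: SimConfig):
    """Draw a tetraploid population with GBS-like read counts.

    Returns (GroundTruth, ReadCountMatrix, MarkerAnnotation). All quantities
    are reproducible from ``cfg.seed`` alone.
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    n_g, n_l = cfg.n_genotypes, cfg.n_loci

    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n_l)
    dosages = rng.binomial(cfg.ploidy, p, size=(n_g, n_l))
    bias = np.exp(rng.normal(0.0, cfg.bias_log_sd, size=n_l))

    k = cfg.depth_dispersion
    depth = rng.negative_binomial(k, k / (k + cfg.mean_depth), size=(n_g, n_l))
    xi = dosage_to_alt_fraction(dosages, bias[None, :], cfg.seq_error)
    alt = rng.binomial(depth, xi)
    missing = rng.random((n_g, n_l)) < cfg.missing_cell_rate
    depth = np.where(missing, 0, depth)
    alt = np.where(missing, 0, alt)
    ref = depth - alt

    genic = rng.random(n_l) < cfg.genic_fraction
    qual = 40.0 + 60.0 * rng.random(n_l)

    # contiguous chromosome blocks with evenly spaced positions
    chrom_idx = (np.arange(n_l) * cfg.n_chromosomes) // n_l
    chroms = np.array([f"chr{i + 1}" for i in chrom_idx], dtype=object)
    pos = np.empty(n_l, dtype=np.int64)
    for c in range(cfg.n_chromosomes):
        m = chrom_idx == c
        pos[m] = (np.arange(m.sum()) + 1) * cfg.locus_spacing

    samples = [f"G{i + 1:03d}" for i in range(n_g)]
    loci = [f"L{j + 1:05d}" for j in range(n_l)]

    qtl_idx = np.sort(rng.choice(n_l, size=cfg.n_qtl, replace=False))
    n_traits = len(cfg.traits)
    qtl_eff = rng.normal(0.0, 1.0, size=(cfg.n_qtl, n_traits))
    tbv = dosages[:, qtl_idx].astype(float) @ qtl_eff

    gt = GroundTruth(
        true_dosages=dosages,
        qtl_indices=qtl_idx,
        qtl_effects=qtl_eff,
        true_breeding_values=tbv,
        bias=bias,
        allele_freq=p,
        trait_names=cfg.traits,
        samples=samples,
        loci=loci,
    )
    rc = ReadCountMatrix(samples=samples, loci=loci, ref_depth=ref, alt_depth=alt)
    ann = make_annotation(loci, chroms, pos, qual=qual, genic=genic)
    return gt, rc, ann


def gene_intervals(ann: pd.DataFrame, half_width: int = 300) -> pd.DataFrame:
    """Gene intervals (1-based inclusive) covering exactly the genic markers.

    Each genic marker gets one interval of ``2*half_width + 1`` bp centred on
    it; with the default marker spacing this covers no neighbouring marker,
    so positional annotation round-trips the simulated genic flags.
    """
    g = ann[ann["genic"]]
    return pd.DataFrame(
        {
            "chrom": g["chrom"].to_numpy(),
            "start": np.maximum(1, g["pos"].to_numpy() - half_width),
            "end": g["pos"].to_numpy() + half_width,
        }
    )


def error_variance_for_h2(sigma_g2: float, h2: float, n_reps: int) -> float:
    """Plot-error variance giving entry-mean heritability ``h2``.

    Inverts H2 = sigma_g2 / (sigma_g2 + sigma_e2 / n_reps).
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1)")
    return n_reps * sigma_g2 * (1.0 - h2) / h2


def simulate_trial(gt: GroundTruth, cfg: SimConfig) -> pd.DataFrame:
    """Replicated multi-environment trial phenotypes for a population.

    Returns a TrialTable with columns genotype, env, rep, trait, value. The
    genotype effect per environment is the (standardized) true breeding value
    scaled to carry ``additive_fraction`` of the genetic variance, plus a
    non-additive deviation whose cross-environment correlation is set so the
    total genetic correlation equals ``r_g_target``.
    """
    cfg.validate()
    if cfg.n_reps < 2:
        raise ValueError("n_reps must be >= 2 for a replicated trial")
    rng = _rng(cfg, 1)
    n_g = len(gt.samples)
    f_a, sg2 = cfg.additive_fraction, cfg.sigma_g2

    if cfg.n_envs > 1:
        rho = cfg._nonadditive_corr()
        corr = np.full((cfg.n_envs, cfg.n_envs), rho)
        np.fill_diagonal(corr, 1.0)
        chol = np.linalg.cholesky(corr)
    else:
        chol = np.ones((1, 1))

    envs = [f"E{e + 1}" for e in range(cfg.n_envs)]
    reps = [f"R{r + 1}" for r in range(cfg.n_reps)]
    rows = []
    for t, trait in enumerate(gt.trait_names):
        tbv = gt.true_breeding_values[:, t]
        sd = tbv.std()
        a = (tbv - tbv.mean()) / sd if sd > 0 else np.zeros(n_g)
        additive = a * math.sqrt(f_a * sg2)
        delta = (
            rng.normal(0.0, 1.0, size=(n_g, cfg.n_envs)) @ chol.T
        ) * math.sqrt((1.0 - f_a) * sg2)
        g_eff = additive[:, None] + delta
        se2 = error_variance_for_h2(sg2, cfg.h2_target[trait], cfg.n_reps)
        noise = rng.normal(0.0, math.sqrt(se2), size=(n_g, cfg.n_envs, cfg.n_reps))
        for e, env in enumerate(envs):
            for r, rep in enumerate(reps):
                vals = cfg.trait_mean + g_eff[:, e] + noise[:, e, r]
                rows.append(
                    pd.DataFrame(
                        {
                            "genotype": gt.samples,
                            "env": env,
                            "rep": rep,
                            "trait": trait,
                            "value": vals,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def write_trial_csv(trial: pd.DataFrame, path) -> None:
    trial.to_csv(path, index=False)


def read_trial_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"genotype": str, "env": str, "rep": str})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df


def config_from_yaml(path) -> SimConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "maf_range" in data:
        data["maf_range"] = tuple(data["maf_range"])
    return SimConfig(**data)


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["maf_range"] = list(d["maf_range"])
    return d
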