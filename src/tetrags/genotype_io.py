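"""Read-count and marker-annotation I/O.

Genotype data enter the pipeline as a VCF carrying per-sample allelic depths
(the ``AD`` FORMAT field) for a biallelic SNP panel, typically produced by a
GBS SNP-calling pipeline. This module loads such files into a
:class:`ReadCountMatrix` (reference/alternative read counts per sample and
locus), applies import-time site-quality and minor-allele-frequency filters,
and qualifies markers as genic or non-genic by positional overlap with gene
intervals from BED or GFF3 files.

Coordinate conventions: positions are 1-based (VCF convention) everywhere in
memory; BED input (0-based half-open) and GFF3 input (1-based inclusive) are
converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Columns of a MarkerAnnotation frame (indexed by locus id).
ANN_COLUMNS = ("chrom", "pos", "genic", "qual", "bias")


@dataclass
class ReadCountMatrix:
    """Per-(sample, locus) reference and alternative read depths.

    A cell with zero total depth is the canonical missing state. Only
    biallelic loci are representable: one reference and one alternative
    allele per locus.
    """

    samples: list
    loci: list
    ref_depth: np.ndarray
    alt_depth: np.ndarray

    def __post_init__(self):
        self.samples = list(self.samples)
        self.loci = list(self.loci)
        self.ref_depth = np.asarray(self.ref_depth, dtype=np.int64)
        self.alt_depth = np.asarray(self.alt_depth, dtype=np.int64)
        if self.ref_depth.shape != self.alt_depth.shape:
            raise ValueError("ref_depth and alt_depth must share shape")
        if self.ref_depth.shape != (len(self.samples), len(self.loci)):
            raise ValueError("depth matrices must be (n_samples, n_loci)")
        if (self.ref_depth < 0).any() or (self.alt_depth < 0).any():
            raise ValueError("read depths must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def total_depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    def subset_loci(self, keep) -> "ReadCountMatrix":
        """Return a copy restricted to loci selected by a boolean mask or
        integer index array (order preserved)."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return ReadCountMatrix(
            samples=self.samples,
            loci=[self.loci[i] for i in idx],
            ref_depth=self.ref_depth[:, idx],
            alt_depth=self.alt_depth[:, idx],
        )


def make_annotation(loci, chrom, pos, qual=None, genic=False) -> pd.DataFrame:
    """Build a MarkerAnnotation frame (one row per locus, indexed by id)."""
    n = len(loci)
    ann = pd.DataFrame(
        {
            "chrom": np.broadcast_to(np.asarray(chrom, dtype=object), (n,)).copy(),
            "pos": np.asarray(pos, dtype=np.int64),
            "genic": np.broadcast_to(np.asarray(genic, dtype=bool), (n,)).copy(),
            "qual": np.full(n, np.nan) if qual is None else np.asarray(qual, float),
            "bias": np.full(n, np.nan),
        },
        index=pd.Index(loci, name="locus"),
    )
    return ann


def _folded_read_frequency(rc: ReadCountMatrix) -> np.ndarray:
    """Pooled alternative-read frequency per locus, folded to the minor allele."""
    alt = rc.alt_depth.sum(axis=0).astype(float)
    tot = rc.total_depth.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(tot > 0, alt / np.where(tot > 0, tot, 1), np.nan)
    return np.minimum(f, 1.0 - f)


def read_vcf(path, min_qual: float = 40.0, maf_min: float = 0.05):
    """Read a VCF with AD fields into (ReadCountMatrix, MarkerAnnotation).

    Import-time filters: loci with QUAL < ``min_qual`` are removed, as are
    loci whose pooled, folded alternative-read frequency is below ``maf_min``.
    Multi-allelic sites are skipped (with a logged count); a missing AD field
    is a hard error naming the offending locus.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci, chroms, positions, quals = [], [], [], []
    ref_cols, alt_cols = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ValueError(
                f"AD FORMAT field missing at {var.CHROM}:{var.POS}"
            )
        ad = np.asarray(ad, dtype=np.int64)
        if ad.ndim != 2 or ad.shape[1] < 2:
            raise ValueError(
                f"AD FORMAT field malformed at {var.CHROM}:{var.POS}"
            )
        ad = np.clip(ad[:, :2], 0, None)  # cyvcf2 encodes missing as negatives
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci.append(vid)
        chroms.append(var.CHROM)
        positions.append(var.POS)
        quals.append(var.QUAL if var.QUAL is not None else 0.0)
        ref_cols.append(ad[:, 0])
        alt_cols.append(ad[:, 1])
    vcf.close()
    if n_multi:
        logger.info("skipped %d multi-allelic sites", n_multi)
    if not loci:
        raise ValueError("no biallelic loci found in VCF")

    rc = ReadCountMatrix(
        samples=samples,
        loci=loci,
        ref_depth=np.column_stack(ref_cols),
        alt_depth=np.column_stack(alt_cols),
    )
    ann = make_annotation(loci, chroms, positions, qual=quals)

    qual_ok = ann["qual"].to_numpy() >= min_qual
    maf = _folded_read_frequency(rc)
    maf_ok = maf >= maf_min
    keep = qual_ok & maf_ok
    logger.info(
        "import filters: %d/%d loci kept (QUAL>=%g removed %d, MAF>=%g removed %d)",
        int(keep.sum()), rc.n_loci, min_qual, int((~qual_ok).sum()),
        maf_min, int((qual_ok & ~maf_ok).sum()),
    )
    if not keep.any():
        raise ValueError("all loci removed by import filters")
    return rc.subset_loci(keep), ann.loc[keep]


def write_vcf(rc: ReadCountMatrix, ann: pd.DataFrame, path) -> None:
    """Write a minimal VCF 4.2 with QUAL and per-sample AD/DP fields.

    Reference and alternative alleles are written as placeholder A/T bases:
    the pipeline consumes read counts, not sequence context.
    """
    ann = ann.loc[rc.loci]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tetrags\n")
        for chrom in pd.unique(ann["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref,alt)">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in rc.samples) + "\n")
        tot = rc.total_depth
        for j, locus in enumerate(rc.loci):
            row = ann.iloc[j]
            qual = row["qual"]
            qual_s = "." if pd.isna(qual) else f"{qual:.4f}"
            cells = "\t".join(
                f"{rc.ref_depth[i, j]},{rc.alt_depth[i, j]}:{tot[i, j]}"
                for i in range(rc.n_samples)
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{locus}\tA\tT\t{qual_s}\t"
                f"PASS\t.\tAD:DP\t{cells}\n"
            )


def read_bed(path) -> pd.DataFrame:
    """Read BED intervals (0-based half-open) into a 1-based inclusive frame
    with columns chrom, start, end."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    out = df.copy()
    out["start"] = df["start"] + 1  # half-open [s, e) -> 1-based [s+1, e]
    return out


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    out = intervals[["chrom", "start", "end"]].copy()
    out["start"] = out["start"] - 1
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gff3(path, feature_type: str = "gene") -> pd.DataFrame:
    """Read GFF3 features of one type into a 1-based inclusive interval frame."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = [(f.seqid, f.start, f.end) for f in db.features_of_type(feature_type)]
    if not rows:
        raise ValueError(f"no features of type {feature_type!r} in {path}")
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def annotate_genic(ann: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Set the genic flag: True iff the SNP position lies within any interval.

    ``intervals`` uses 1-based inclusive coordinates (as returned by
    :func:`read_bed` / :func:`read_gff3`). Chromosomes present in the
    annotation but absent from the interval set trigger a warning and their
    SNPs stay non-genic.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in intervals.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e) + 1) for s, e in zip(grp["start"], grp["end"])
        )
    out = ann.copy()
    genic = np.zeros(len(ann), dtype=bool)
    missing_chroms = set()
    for i, (chrom, pos) in enumerate(zip(ann["chrom"], ann["pos"])):
        tree = trees.get(chrom)
        if tree is None:
            missing_chroms.add(chrom)
            continue
        genic[i] = bool(tree[int(pos)])
    if missing_chroms:
        logger.warning(
            "chromosomes absent from interval annotation (genic=False): %s",
            ", ".join(sorted(missing_chroms)),
        )
    out["genic"] = genic
    logger.info(
        "genic annotation: %d genic / %d non-genic markers",
        int(genic.sum()), int((~genic).sum()),
    )
    return out
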