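"""Gene models, PA-site pairs, 3'UTR segmentation and per-base coverage.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open ``[start, end)``. GTF input
(1-based inclusive) is converted on read; BED and bedGraph input are taken
as-is. Per-base coverage vectors are always emitted in transcript 5'->3'
order, i.e. reversed relative to the genome for minus-strand genes, so that
downstream code never needs to re-check strand.

A gene enters APA analysis with exactly one proximal and one distal
cleavage/polyadenylation site (CPS) in its last-exon 3'UTR. Using the
proximal site confines the 3'UTR to the constitutive UTR (cUTR); using the
distal site additionally includes the alternative UTR (aUTR) that lies
between the two CPSs.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Raised for malformed or internally inconsistent annotation input."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to the features APA analysis needs.

    ``utr3`` is the 3'UTR of the transcript with the 3'-most stop codon;
    ``cds`` spans that transcript's coding region; ``introns`` are the gaps
    between its exons (genomic order).
    """

    gene_id: str
    chrom: str
    strand: str
    utr3: Interval
    cds: Interval
    introns: tuple[Interval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.utr3[1] - self.utr3[0] < 1:
            raise AnnotationError(f"{self.gene_id}: empty 3'UTR")
        if max(self.utr3[0], self.cds[0]) < min(self.utr3[1], self.cds[1]):
            raise AnnotationError(f"{self.gene_id}: 3'UTR overlaps CDS")

    @property
    def utr3_length(self) -> int:
        return self.utr3[1] - self.utr3[0]


@dataclass(frozen=True)
class PaSitePair:
    """Proximal and distal CPS for one gene.

    Coordinates are genomic. In transcript 5'->3' order the proximal CPS
    precedes the distal one, so on the minus strand ``proximal_cps`` is the
    genomically larger coordinate.
    """

    gene_id: str
    proximal_cps: int
    distal_cps: int
    source: str = "annotated"  # {"annotated", "fitted"}


@dataclass(frozen=True)
class UtrSegmentation:
    """cUTR/aUTR split of a 3'UTR; intervals genomic, lengths in nt."""

    gene_id: str
    cutr: Interval
    autr: Interval
    cutr_length: int
    autr_length: int


@dataclass
class RegionCoverage:
    """Per-base counts over one gene region for one replicate.

    ``per_base_counts`` is in transcript 5'->3' order. ``library_size`` is
    the scaling total for RPM; ``library_size_source`` records whether it
    was supplied or summed from the coverage file.
    """

    gene_id: str
    replicate_id: str
    condition: str
    per_base_counts: np.ndarray
    library_size: float
    library_size_source: str = "file_sum"

    def __post_init__(self) -> None:
        self.per_base_counts = np.asarray(self.per_base_counts, dtype=float)
        if np.any(self.per_base_counts < 0):
            raise AnnotationError(f"{self.gene_id}: negative coverage values")
        if self.library_size <= 0:
            raise AnnotationError(f"{self.gene_id}: library_size must be > 0")

    @property
    def density(self) -> np.ndarray:
        """RPM per base."""
        return self.per_base_counts * 1e6 / self.library_size


# ---------------------------------------------------------------------------
# GTF / BED readers
# ---------------------------------------------------------------------------

def _validate_gtf(gtf_path: str) -> None:
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(
                    f"{gtf_path}: unparsable GTF line {lineno}: "
                    f"expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"{gtf_path}: unparsable GTF line {lineno}: "
                    "non-integer coordinates"
                ) from None
            if start < 1 or end < start:
                raise AnnotationError(
                    f"{gtf_path}: unparsable GTF line {lineno}: "
                    f"invalid interval {start}-{end}"
                )


def load_gene_models(gtf_path: str, min_utr_len: int = 150) -> list[GeneModel]:
    """Read a GTF and return one :class:`GeneModel` per retained gene.

    For each gene, the transcript whose stop codon (CDS 3' end) is 3'-most
    is used as the reference isoform; its 3'UTR is the part of its last
    exon downstream of the CDS. Genes without an annotated CDS/3'UTR or
    with a 3'UTR shorter than ``min_utr_len`` are skipped (counted in the
    log). Raises :class:`AnnotationError` on unparsable lines or when no
    gene is retained.
    """
    import gffutils

    _validate_gtf(gtf_path)
    db = gffutils.create_db(
        gtf_path, ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )

    models: list[GeneModel] = []
    n_skipped = 0
    for gene in db.features_of_type("gene"):
        best = None  # (3'-most stop coordinate in transcript orientation, tx)
        for tx in db.children(gene, featuretype="transcript"):
            cds = list(db.children(tx, featuretype="CDS"))
            if not cds:
                continue
            if gene.strand == "+":
                stop = max(c.end for c in cds)  # 1-based inclusive
                key = stop
            else:
                stop = min(c.start for c in cds)
                key = -stop
            if best is None or key > best[0]:
                best = (key, tx, cds)
        if best is None:
            n_skipped += 1
            logger.info("skip %s: no CDS-bearing transcript", gene.id)
            continue
        _, tx, cds = best
        exons = sorted(
            ((e.start - 1, e.end) for e in db.children(tx, featuretype="exon")),
            key=lambda iv: iv[0],
        )
        if not exons:
            n_skipped += 1
            logger.info("skip %s: transcript without exons", gene.id)
            continue
        cds_iv = (min(c.start for c in cds) - 1, max(c.end for c in cds))
        if gene.strand == "+":
            last_exon = exons[-1]
            utr3 = (max(cds_iv[1], last_exon[0]), last_exon[1])
        else:
            last_exon = exons[0]
            utr3 = (last_exon[0], min(cds_iv[0], last_exon[1]))
        if utr3[1] - utr3[0] < max(1, min_utr_len):
            n_skipped += 1
            logger.info("skip %s: 3'UTR shorter than %d nt", gene.id, min_utr_len)
            continue
        introns = tuple(
            (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
        )
        models.append(
            GeneModel(
                gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
                utr3=utr3, cds=cds_iv, introns=introns,
            )
        )
    if not models:
        raise AnnotationError(f"{gtf_path}: no genes retained after filtering")
    if n_skipped:
        logger.info("load_gene_models: retained %d genes, skipped %d",
                    len(models), n_skipped)
    models.sort(key=lambda g: g.gene_id)
    return models


def load_pa_sites(
    bed_path: str, genes: Iterable[GeneModel]
) -> dict[str, PaSitePair]:
    """Read BED6 PA sites (name column = gene_id, one row per CPS).

    Each gene must have exactly two sites inside its 3'UTR; they are
    ordered proximal/distal in transcript orientation using the gene's
    strand.
    """
    by_id = {g.gene_id: g for g in genes}
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    pairs: dict[str, PaSitePair] = {}
    for gene_id, grp in bed.groupby("name", sort=True):
        gene = by_id.get(str(gene_id))
        if gene is None:
            continue
        positions = sorted(int(s) for s in grp["start"])
        if len(positions) != 2:
            raise AnnotationError(
                f"{gene_id}: expected 2 PA sites, found {len(positions)}"
            )
        lo, hi = positions
        s, e = gene.utr3
        for pos in positions:
            if not (s <= pos <= e):
                raise AnnotationError(
                    f"{gene_id}: PA site {pos} outside 3'UTR [{s},{e})"
                )
        if gene.strand == "+":
            proximal, distal = lo, hi
        else:
            proximal, distal = hi, lo
        pairs[str(gene_id)] = PaSitePair(str(gene_id), proximal, distal)
    return pairs


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_utr(gene: GeneModel, pa: PaSitePair) -> UtrSegmentation:
    """Split the 3'UTR at the proximal CPS into cUTR and aUTR.

    The cUTR runs from the UTR start (transcript orientation) to the
    proximal CPS; the aUTR from the proximal to the distal CPS. The aUTR
    length is the distance between the two CPSs.
    """
    s, e = gene.utr3
    p, d = pa.proximal_cps, pa.distal_cps
    if p == d:
        raise AnnotationError(f"{gene.gene_id}: proximal CPS equals distal CPS")
    if gene.strand == "+":
        if not (s < p < d <= e):
            raise AnnotationError(
                f"{gene.gene_id}: inconsistent PA annotation "
                f"(p={p}, d={d}, utr3=[{s},{e}), strand +)"
            )
        cutr, autr = (s, p), (p, d)
        cutr_len, autr_len = p - s, d - p
    else:
        if not (s <= d < p < e):
            raise AnnotationError(
                f"{gene.gene_id}: inconsistent PA annotation "
                f"(p={p}, d={d}, utr3=[{s},{e}), strand -)"
            )
        cutr, autr = (p, e), (d, p)
        cutr_len, autr_len = e - p, p - d
    return UtrSegmentation(gene.gene_id, cutr, autr, cutr_len, autr_len)


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def _read_bedgraph(path: str) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    bg = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
        skiprows=lambda i: False,
    )
    # drop optional track line
    bg = bg[~bg["chrom"].str.startswith("track")]
    out = {}
    for chrom, grp in bg.groupby("chrom", sort=False):
        out[str(chrom)] = (
            grp["start"].to_numpy(np.int64),
            grp["end"].to_numpy(np.int64),
            grp["value"].to_numpy(float),
        )
    return out


def _region_of(gene: GeneModel, region) -> Interval:
    if region == "utr3":
        return gene.utr3
    if callable(region):
        return region(gene)
    raise ValueError(f"unknown region spec: {region!r}")


def load_coverage(
    source: str,
    genes: Sequence[GeneModel],
    condition: str = "",
    replicate_id: str = "",
    library_size: float | None = None,
    region="utr3",
) -> dict[str, RegionCoverage]:
    """Per-base coverage over each gene's region from bedGraph or BAM.

    Vectors come back in transcript 5'->3' order; bases with no record are
    0. ``library_size`` overrides the default total (sum of base coverage
    over the bedGraph, or mapped-read count for BAM); the provenance is
    recorded on each :class:`RegionCoverage`.
    """
    if source.endswith(".bam"):
        return _load_coverage_bam(
            source, genes, condition, replicate_id, library_size, region
        )
    per_chrom = _read_bedgraph(source)
    gene_chroms = {g.chrom for g in genes}
    missing = sorted(gene_chroms - set(per_chrom))
    if missing:
        raise AnnotationError(
            f"{source}: contigs in annotation but absent from coverage: "
            + ", ".join(missing)
        )
    if library_size is None:
        lib = float(
            sum(((e - s) * v).sum() for s, e, v in per_chrom.values())
        )
        lib_src = "file_sum"
    else:
        lib = float(library_size)
        lib_src = "supplied"

    # expand interval records to dense per-chrom arrays via delta-encoding
    dense: dict[str, np.ndarray] = {}
    for chrom in gene_chroms:
        starts, ends, vals = per_chrom[chrom]
        length = max(
            int(ends.max()),
            max(_region_of(g, region)[1] for g in genes if g.chrom == chrom),
        )
        delta = np.zeros(length + 1)
        np.add.at(delta, starts, vals)
        np.add.at(delta, ends, -vals)
        dense[chrom] = np.cumsum(delta)[:length]

    out: dict[str, RegionCoverage] = {}
    for g in genes:
        s, e = _region_of(g, region)
        vec = dense[g.chrom][s:e].copy()
        if g.strand == "-":
            vec = vec[::-1]
        out[g.gene_id] = RegionCoverage(
            g.gene_id, replicate_id, condition, vec, lib, lib_src
        )
    return out


def _load_coverage_bam(
    source, genes, condition, replicate_id, library_size, region
):
    import pysam

    def keep(read):  # primary alignments only
        return not (read.is_secondary or read.is_supplementary
                    or read.is_unmapped or read.is_qcfail)

    with pysam.AlignmentFile(source, "rb") as bam:
        contigs = set(bam.references)
        missing = sorted({g.chrom for g in genes} - contigs)
        if missing:
            raise AnnotationError(
                f"{source}: contigs in annotation but absent from BAM: "
                + ", ".join(missing)
            )
        lib = float(library_size) if library_size is not None else float(bam.mapped)
        lib_src = "supplied" if library_size is not None else "file_sum"
        out = {}
        for g in genes:
            s, e = _region_of(g, region)
            acgt = bam.count_coverage(g.chrom, s, e, read_callback=keep)
            vec = np.asarray(acgt, dtype=float).sum(axis=0)
            if g.strand == "-":
                vec = vec[::-1]
            out[g.gene_id] = RegionCoverage(
                g.gene_id, replicate_id, condition, vec, lib, lib_src
            )
    return out


def pool_coverage(covs: Sequence[RegionCoverage]) -> RegionCoverage:
    """Pool replicates by summing counts and library sizes."""
    if not covs:
        raise ValueError("pool_coverage: empty input")
    gene_ids = {c.gene_id for c in covs}
    if len(gene_ids) != 1:
        raise ValueError(f"pool_coverage: mixed genes {sorted(gene_ids)}")
    counts = np.sum([c.per_base_counts for c in covs], axis=0)
    lib = float(sum(c.library_size for c in covs))
    return RegionCoverage(
        covs[0].gene_id, "pooled", covs[0].condition, counts, lib,
        covs[0].library_size_source,
    )


def rpm(value: float, library_size: float) -> float:
    """Reads-per-million scaling: value * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return value * 1e6 / library_size
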