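"""Transposon-tag read processing and insertion-site accounting.

Covers the desk-scale steps between raw library reads and per-gene
insertion statistics: selecting reads that carry the transposon
primer+tail junction, exact mapping of the genomic remainder onto small
(synthetic-scale) genomes, derivation of per-gene unique-insertion
counts, and the CDS/intergenic partition of unique sites.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from Bio.Seq import reverse_complement
from Bio.SeqRecord import SeqRecord

from .io_formats import GeneModel, GenomeAnnotation, InsertionSiteTable

__all__ = [
    "PRIMER",
    "TAIL",
    "SelectionReport",
    "MappingReport",
    "GeneInsertionStats",
    "PartitionCounts",
    "select_transposon_reads",
    "map_reads_exact",
    "gene_insertion_stats",
    "partition_sites",
]

log = logging.getLogger(__name__)

#: Tn5 junction primer and transposon tail used for positive selection.
PRIMER = "GTTCGAAATGAGATGTGTATAAGAG"
TAIL = "ACAG"


@dataclass
class SelectionReport:
    n_input: int = 0
    n_selected: int = 0
    n_no_tag: int = 0
    n_too_short: int = 0

    @property
    def n_discarded(self) -> int:
        return self.n_no_tag + self.n_too_short


@dataclass
class MappingReport:
    n_reads: int = 0
    n_mapped: int = 0
    n_multimapped: int = 0
    n_unmapped: int = 0
    n_too_long: int = 0


@dataclass(frozen=True)
class GeneInsertionStats:
    """Unique-insertion count and insertion index for one gene.

    The insertion index is unique insertions divided by gene length
    (insertions per bp), computed exactly.
    """

    gene_id: str
    unique_insertions: int
    length_bp: int

    @property
    def insertion_index(self) -> float:
        return self.unique_insertions / self.length_bp


@dataclass(frozen=True)
class PartitionCounts:
    """Unique sites split into CDS vs intergenic (everything else)."""

    cds_sites: int
    intergenic_sites: int

    @property
    def total(self) -> int:
        return self.cds_sites + self.intergenic_sites


def _find_with_mismatches(seq: str, tag: str, max_mismatch: int) -> int:
    """First index where ``tag`` occurs in ``seq`` with <= max_mismatch
    substitutions, or -1."""
    n, m = len(seq), len(tag)
    for i in range(n - m + 1):
        mism = 0
        for a, b in zip(seq[i : i + m], tag):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return i
    return -1


def select_transposon_reads(
    reads: Iterable[SeqRecord],
    primer: str = PRIMER,
    tail: str = TAIL,
    min_len: int = 20,
    max_mismatch: int = 0,
) -> tuple[list[SeqRecord], SelectionReport]:
    """Positively select reads carrying the transposon junction tag.

    A read is retained iff it contains ``primer`` immediately followed by
    ``tail`` (exact match by default; the tag may sit anywhere in the
    read).  The tag and everything 5' of it are removed, and the genomic
    remainder is kept only if strictly longer than ``min_len`` bases.
    """
    if not primer:
        raise ValueError("primer must be a non-empty sequence")
    tag = (primer + tail).upper()
    report = SelectionReport()
    selected: list[SeqRecord] = []
    for rec in reads:
        report.n_input += 1
        seq = str(rec.seq).upper()
        if max_mismatch == 0:
            idx = seq.find(tag)
        else:
            idx = _find_with_mismatches(seq, tag, max_mismatch)
        if idx < 0:
            report.n_no_tag += 1
            continue
        trimmed = rec[idx + len(tag) :]
        if len(trimmed) > min_len:
            report.n_selected += 1
            selected.append(trimmed)
        else:
            report.n_too_short += 1
    return selected, report


def map_reads_exact(
    reads: Iterable[SeqRecord | str],
    genome: Mapping[str, str],
    collapse_strand: bool = True,
) -> tuple[InsertionSiteTable, MappingReport]:
    """Exact-match mapper for synthetic-scale genomes.

    Each read must be an exact substring of the genome on either strand.
    The reported insertion position is the genomic coordinate of the
    read's first (5'-most) base — the base adjacent to the transposon
    junction — so a reverse-strand read maps to the *higher* end of its
    alignment footprint.  Reads matching two or more loci are dropped and
    counted as multi-mapping.
    """
    seqs = [str(r.seq) if isinstance(r, SeqRecord) else str(r) for r in reads]
    seqs = [s.upper() for s in seqs]
    genome = {c: s.upper() for c, s in genome.items()}
    max_contig = max((len(s) for s in genome.values()), default=0)

    report = MappingReport(n_reads=len(seqs))
    lengths = sorted({len(s) for s in seqs if 0 < len(s) <= max_contig})
    # One k-mer index per distinct read length, both strands served by
    # looking up the read and its reverse complement in the forward index.
    indexes: dict[int, dict[str, list[tuple[str, int]]]] = {}
    for k in lengths:
        idx: dict[str, list[tuple[str, int]]] = {}
        for contig, seq in genome.items():
            for i in range(len(seq) - k + 1):
                idx.setdefault(seq[i : i + k], []).append((contig, i))
        indexes[k] = idx

    records: list[tuple[str, int, str, int]] = []
    for s in seqs:
        if len(s) > max_contig:
            report.n_too_long += 1
            log.warning("read longer than any contig (%d bp): dropped", len(s))
            continue
        idx = indexes[len(s)]
        fwd = idx.get(s, [])
        rc = reverse_complement(s)
        rev = idx.get(rc, []) if rc != s else fwd  # palindrome: ambiguous strand
        n_loci = len(fwd) + len(rev)
        if n_loci == 0:
            report.n_unmapped += 1
        elif n_loci > 1:
            report.n_multimapped += 1
        elif fwd:
            contig, i = fwd[0]
            records.append((contig, i, "+", 1))
            report.n_mapped += 1
        else:
            contig, i = rev[0]
            # 5'-most read base sits at the high end of the footprint
            records.append((contig, i + len(s) - 1, "-", 1))
            report.n_mapped += 1
    table = InsertionSiteTable.from_records(records, collapse_strand=collapse_strand)
    return table, report


def _check_contig_namespace(
    sites: InsertionSiteTable, annotation: GenomeAnnotation
) -> None:
    unknown = set(sites.sites) - set(annotation.contigs)
    if unknown:
        raise ValueError(
            f"insertion sites on contig(s) absent from the annotation: "
            f"{sorted(unknown)}"
        )


def gene_insertion_stats(
    sites: InsertionSiteTable, annotation: GenomeAnnotation
) -> list[GeneInsertionStats]:
    """Per-gene unique-insertion counts and insertion indices.

    A site at position ``p`` counts for gene ``g`` iff
    ``g.start <= p < g.end`` (half-open membership, no 5'/3' trimming);
    a site inside overlapping genes counts once for each of them.
    """
    _check_contig_namespace(sites, annotation)
    by_contig = {c: sites.positions(c) for c in sites.sites}
    out: list[GeneInsertionStats] = []
    for g in annotation.genes:
        positions = by_contig.get(g.contig, [])
        n = bisect_left(positions, g.end) - bisect_left(positions, g.start)
        out.append(
            GeneInsertionStats(
                gene_id=g.gene_id, unique_insertions=n, length_bp=g.length_bp
            )
        )
    return out


def partition_sites(
    sites: InsertionSiteTable, annotation: GenomeAnnotation
) -> PartitionCounts:
    """Assign every unique site to exactly one of CDS or intergenic.

    Only CDS-class features count as coding here; sites inside RNA genes
    or pseudogenes (and outside every CDS) fall to the intergenic bucket,
    while those genes still receive insertion indices for classification.
    The two counts always sum to the table's total unique sites.
    """
    _check_contig_namespace(sites, annotation)
    cds_total = 0
    total = 0
    for contig, entries in sites.sites.items():
        positions = np.array([p for p, _ in entries], dtype=np.int64)
        total += len(positions)
        intervals = sorted(
            (g.start, g.end)
            for g in annotation.genes_on(contig)
            if g.feature_class == "CDS"
        )
        if not intervals:
            continue
        # merge overlapping CDS intervals so each site is tested once
        merged: list[list[int]] = []
        for s, e in intervals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.array([s for s, _ in merged], dtype=np.int64)
        ends = np.array([e for _, e in merged], dtype=np.int64)
        idx = np.searchsorted(starts, positions, side="right") - 1
        inside = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        cds_total += int(inside.sum())
    return PartitionCounts(cds_sites=cds_total, intergenic_sites=total - cds_total)
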