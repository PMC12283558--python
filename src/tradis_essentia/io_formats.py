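"""Readers and writers for the external formats the pipeline touches.

Internally every genomic interval is 0-based, half-open ``[start, end)``.
GFF3 is 1-based inclusive; the conversion happens here, at the file
boundary, and nowhere else.  All tabular writers emit tab-separated UTF-8
with a single header line prefixed ``#``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FEATURE_CLASSES",
    "GeneModel",
    "GenomeAnnotation",
    "InsertionSiteTable",
    "TabularHit",
    "FunctionalAnnotationRow",
    "read_annotation",
    "write_annotation",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_site_table",
    "write_site_table",
    "read_hits",
    "write_hits",
    "read_functional_annotation",
    "write_functional_annotation",
    "read_calls",
]

log = logging.getLogger(__name__)

FEATURE_CLASSES = ("CDS", "tRNA", "rRNA", "other_RNA", "pseudogene")

#: GFF3 feature types folded onto the five internal feature classes.
#: Anything else is skipped with a logged warning.
_FEATURE_TYPE_MAP = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "tmRNA": "other_RNA",
    "SRP_RNA": "other_RNA",
    "RNase_P_RNA": "other_RNA",
    "ncRNA": "other_RNA",
    "pseudogene": "pseudogene",
}

#: Inverse map used when writing: internal class -> GFF3 feature type.
_FEATURE_CLASS_TO_TYPE = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "other_RNA": "ncRNA",
    "pseudogene": "pseudogene",
}


@dataclass(frozen=True)
class GeneModel:
    """A gene on a named contig, 0-based half-open coordinates."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    feature_class: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.gene_id}: negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"{self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"{self.gene_id}: unknown feature class {self.feature_class!r}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Contig lengths plus the gene models that live on them."""

    contigs: dict[str, int]
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.contig not in self.contigs:
                raise ValueError(f"{g.gene_id}: unknown contig {g.contig!r}")
            if g.end > self.contigs[g.contig]:
                raise ValueError(
                    f"{g.gene_id}: extends past end of contig {g.contig} "
                    f"({g.end} > {self.contigs[g.contig]})"
                )

    def class_counts(self) -> dict[str, int]:
        counts = Counter(g.feature_class for g in self.genes)
        return {cls: counts.get(cls, 0) for cls in FEATURE_CLASSES}

    def genes_on(self, contig: str) -> list[GeneModel]:
        return [g for g in self.genes if g.contig == contig]

    @property
    def n_genes(self) -> int:
        """Number of annotated features excluding pseudogenes.

        This is the genome's gene inventory in the conventional sense
        (CDS + RNA genes); pseudogenes are classified alongside it but
        reported separately.
        """
        return sum(1 for g in self.genes if g.feature_class != "pseudogene")

    @property
    def n_pseudogenes(self) -> int:
        return sum(1 for g in self.genes if g.feature_class == "pseudogene")


@dataclass
class InsertionSiteTable:
    """Deduplicated unique transposon insertion positions per contig.

    ``sites`` maps contig -> sorted list of ``(position, read_count)``.
    With the default strand-collapsed convention positions are strictly
    increasing; without collapsing a position observed on both strands
    appears twice (once per strand), sorted.
    """

    sites: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    strand_collapsed: bool = True

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, int, str, int]],
        collapse_strand: bool = True,
    ) -> "InsertionSiteTable":
        """Build a table from (contig, position, strand, read_count) rows.

        Rows identical on the merge key — ``(contig, position)`` when
        collapsing strand, ``(contig, position, strand)`` otherwise — are
        merged by summing read counts.
        """
        merged: dict[tuple, int] = {}
        for contig, pos, strand, count in records:
            if pos < 0:
                raise ValueError(f"negative insertion position {pos} on {contig}")
            if count < 1:
                raise ValueError(f"read_count must be >= 1 (got {count})")
            key = (contig, pos) if collapse_strand else (contig, pos, strand)
            merged[key] = merged.get(key, 0) + count
        sites: dict[str, list[tuple[int, int]]] = {}
        for key in sorted(merged):
            contig, pos = key[0], key[1]
            sites.setdefault(contig, []).append((pos, merged[key]))
        return cls(sites=sites, strand_collapsed=collapse_strand)

    def positions(self, contig: str) -> list[int]:
        return [pos for pos, _ in self.sites.get(contig, [])]

    def contig_ids(self) -> list[str]:
        return sorted(self.sites)

    @property
    def total_sites(self) -> int:
        return sum(len(v) for v in self.sites.values())

    @property
    def total_reads(self) -> int:
        return sum(c for v in self.sites.values() for _, c in v)


@dataclass(frozen=True)
class TabularHit:
    """One row of 14-column tabular protein-similarity output.

    The standard 12 columns (query, subject, percent identity, alignment
    length, mismatches, gap opens, q/s start/end 1-based inclusive,
    E-value, bit score) extended with query and subject sequence lengths,
    which coverage filtering requires.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    q_len: int
    s_len: int

    def __post_init__(self) -> None:
        if self.q_end < self.q_start:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: q_end < q_start"
            )
        if self.q_len <= 0 or self.s_len <= 0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: non-positive sequence length"
            )
        if self.evalue < 0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: negative E-value"
            )

    @property
    def query_coverage_pct(self) -> float:
        return (self.q_end - self.q_start + 1) / self.q_len * 100.0

    @property
    def subject_coverage_pct(self) -> float:
        return (abs(self.s_end - self.s_start) + 1) / self.s_len * 100.0


@dataclass(frozen=True)
class FunctionalAnnotationRow:
    """One gene's functional annotation: COG letters + orthology groups."""

    gene_id: str
    cog_labels: str
    og_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.cog_labels and not (
            self.cog_labels.isalpha() and self.cog_labels.isupper()
        ):
            raise ValueError(
                f"{self.gene_id}: COG labels must be upper-case letters, "
                f"got {self.cog_labels!r}"
            )


# ---------------------------------------------------------------------------
# GFF3

def read_annotation(
    gff_path: str | Path, fasta_path: str | Path | None = None
) -> GenomeAnnotation:
    """Read a GFF3 annotation into internal 0-based half-open coordinates.

    Contig lengths come from ``##sequence-region`` directives, or from a
    companion FASTA when the directives are absent.  Feature types are
    folded onto the five internal classes; unknown types are skipped with
    a logged warning, and records with end < start are rejected with a
    logged warning.
    """
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    contigs: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            contigs[parts[1]] = int(parts[3]) - int(parts[2]) + 1
    if fasta_path is not None:
        for contig, seq in read_fasta(fasta_path).items():
            contigs.setdefault(contig, len(seq))

    genes: list[GeneModel] = []
    skipped: Counter = Counter()
    for feat in db.all_features(order_by=("seqid", "start")):
        cls = _FEATURE_TYPE_MAP.get(feat.featuretype)
        if cls is None:
            skipped[feat.featuretype] += 1
            continue
        if feat.end < feat.start:
            log.warning(
                "rejecting malformed record %s on %s: end (%d) < start (%d)",
                feat.id, feat.seqid, feat.end, feat.start,
            )
            continue
        if feat.seqid not in contigs:
            raise ValueError(
                f"no length known for contig {feat.seqid!r}; add a "
                "##sequence-region directive or supply the genome FASTA"
            )
        attrs = feat.attributes
        gene_id = (attrs.get("locus_tag") or attrs.get("ID") or [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                contig=feat.seqid,
                start=feat.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                feature_class=cls,
            )
        )
    for ftype, n in skipped.items():
        log.warning("skipped %d GFF3 record(s) of unhandled type %r", n, ftype)
    return GenomeAnnotation(contigs=contigs, genes=genes)


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for contig, length in annotation.contigs.items():
            fh.write(f"##sequence-region {contig} 1 {length}\n")
        for g in annotation.genes:
            ftype = _FEATURE_CLASS_TO_TYPE[g.feature_class]
            fh.write(
                f"{g.contig}\ttradis_essentia\t{ftype}\t{g.start + 1}\t{g.end}"
                f"\t.\t{g.strand}\t.\tID={g.gene_id};locus_tag={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {contig_id: upper-case sequence}."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=contig, description="") for contig, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fastq"))


def write_fastq(reads: Iterable[SeqRecord], path: str | Path) -> int:
    return SeqIO.write(list(reads), str(path), "fastq")


# ---------------------------------------------------------------------------
# Insertion-site table (TSV: contig, position, strand, read_count)

def read_site_table(
    path: str | Path, collapse_strand: bool = True
) -> InsertionSiteTable:
    records = []
    with open(path, encoding="utf-8") as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                continue
            fields = line.split("\t")
            if header is None:
                # headerless table: fixed column order
                header = ["contig", "position", "strand", "read_count"]
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            row = dict(zip(header, fields))
            records.append(
                (
                    row["contig"],
                    int(row["position"]),
                    row.get("strand", "."),
                    int(row["read_count"]),
                )
            )
    return InsertionSiteTable.from_records(records, collapse_strand=collapse_strand)


def write_site_table(table: InsertionSiteTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#contig\tposition\tstrand\tread_count\n")
        for contig in table.contig_ids():
            for pos, count in table.sites[contig]:
                fh.write(f"{contig}\t{pos}\t.\t{count}\n")


# ---------------------------------------------------------------------------
# 14-column tabular hits

def read_hits(path: str | Path) -> list[TabularHit]:
    hits: list[TabularHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 14:
                raise ValueError(
                    f"{path}:{lineno}: expected 14 tab-separated fields "
                    f"(std 12 + qlen + slen), got {len(fields)}"
                )
            hits.append(
                TabularHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    q_len=int(fields[12]),
                    s_len=int(fields[13]),
                )
            )
    return hits


def write_hits(hits: Iterable[TabularHit], path: str | Path) -> None:
    cols = (
        "qseqid\tsseqid\tpident\tlength\tmismatch\tgapopen\tqstart\tqend"
        "\tsstart\tsend\tevalue\tbitscore\tqlen\tslen"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#{cols}\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:g}"
                f"\t{h.alignment_length}\t{h.mismatches}\t{h.gap_opens}"
                f"\t{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}"
                f"\t{h.evalue:g}\t{h.bitscore:g}\t{h.q_len}\t{h.s_len}\n"
            )


# ---------------------------------------------------------------------------
# Functional annotation (eggNOG-mapper-style TSV)

_NO_ASSIGNMENT = "-"


def read_functional_annotation(path: str | Path) -> list[FunctionalAnnotationRow]:
    """Read an emapper-style TSV (header lines prefixed ``#``).

    Recognised columns: ``query`` (or ``gene_id``), ``COG_category`` and
    ``eggNOG_OGs`` (or ``og_ids``); the no-assignment marker ``-`` maps
    onto an empty label / empty group set.
    """
    rows: list[FunctionalAnnotationRow] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                continue
            if header is None:
                raise ValueError(f"{path}: missing '#'-prefixed header line")
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            row = dict(zip(header, fields))
            gene_id = row.get("query") or row.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}: no 'query'/'gene_id' column in header")
            cog = row.get("COG_category", _NO_ASSIGNMENT)
            cog = "" if cog == _NO_ASSIGNMENT else cog
            og_field = row.get("eggNOG_OGs", row.get("og_ids", _NO_ASSIGNMENT))
            ogs: frozenset[str] = (
                frozenset()
                if og_field == _NO_ASSIGNMENT
                else frozenset(x for x in og_field.split(",") if x)
            )
            rows.append(
                FunctionalAnnotationRow(gene_id=gene_id, cog_labels=cog, og_ids=ogs)
            )
    return rows


def write_functional_annotation(
    rows: Iterable[FunctionalAnnotationRow], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#query\tCOG_category\teggNOG_OGs\n")
        for r in rows:
            cog = r.cog_labels or _NO_ASSIGNMENT
            ogs = ",".join(sorted(r.og_ids)) if r.og_ids else _NO_ASSIGNMENT
            fh.write(f"{r.gene_id}\t{cog}\t{ogs}\n")


# ---------------------------------------------------------------------------
# Per-gene call tables (as written by the classifier / other studies)

def read_calls(path: str | Path) -> dict[str, str]:
    """Read a per-gene call table into {gene_id: call}.

    Accepts any '#'-headed TSV with ``gene_id`` and ``call`` columns,
    which is the format the classifier itself writes.
    """
    calls: dict[str, str] = {}
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                continue
            if header is None:
                raise ValueError(f"{path}: missing '#'-prefixed header line")
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            row = dict(zip(header, fields))
            calls[row["gene_id"]] = row["call"]
    return calls
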