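"""Synthetic transposon-library generator with ground-truth manifest.

Emulates the statistical structure a saturated transposon-insertion
screen produces: a random genome with non-overlapping genes, a bimodal
insertion-index distribution (an insertion-free essential mode and a
gamma-shaped non-essential mode whose mean density is one unique
insertion per 12 bp), genes whose essential core is insertion-free
while the flanks tolerate insertions, junction-tagged reads, and —
for the comparative layers — homology hit tables with planted ortholog
pairs and emapper-style functional annotations with planted phyletic
block structure.  Every emitted artefact is recorded in a
:class:`TruthManifest` so recovery tests can compare pipeline output
against known truth.

The insertion process is site-level: each base of tolerant sequence
becomes a unique insertion site independently, with a per-gene rate
drawn from a gamma distribution around the configured density.  All
randomness flows from the single configured seed through named,
stage-separated generators.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

from .insertions import PRIMER, TAIL
from .io_formats import (
    FunctionalAnnotationRow,
    GeneModel,
    GenomeAnnotation,
    InsertionSiteTable,
    TabularHit,
    write_annotation,
    write_fasta,
    write_fastq,
    write_functional_annotation,
    write_hits,
    write_site_table,
)

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "HomologyTruth",
    "simulate_genome",
    "simulate_insertions",
    "emit_reads",
    "simulate_homology",
    "simulate_annotations",
    "simulate_presence_blocks",
    "write_bundle",
]

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_COG_LETTERS = "CDEFGHIJKLMNOPQSTUV"

# RNG stage tags: every operation derives its generator from
# (seed, stage) so stages are independent and individually reproducible.
_STAGE_GENOME = 1
_STAGE_INSERTIONS = 2
_STAGE_READS = 3
_STAGE_HOMOLOGY = 4
_STAGE_ANNOTATIONS = 5


@dataclass
class SimulationConfig:
    """Study-scale defaults for the synthetic library.

    The defaults mirror the statistical regime of a saturated screen:
    ~10% essential genes, a mean unique-insertion density of 1/12 bp^-1
    over tolerant sequence (so synthetic insertion indices sit on the
    same scale as the 0.006/0.03 classifier cut-offs without retuning),
    no leakage into essential genes, and a small fraction of genes
    whose essentiality is confined to an insertion-free core domain.
    """

    seed: int = 42
    genome_length_bp: int = 2_500_000
    n_genes: int = 2_000
    gene_length_mean: float = 1_000.0
    gene_length_sd: float = 250.0
    min_gene_length_bp: int = 200
    essential_fraction: float = 0.10
    #: fraction of genes essential only through an insertion-free core
    #: domain; saturated screens report these at a few per thousand genes
    domain_essential_fraction: float = 0.0025
    #: insertion-free core length for domain-essential genes; at least
    #: window + step - 1 guarantees the sliding scan sees an empty window
    domain_core_bp: int = 450
    feature_class_weights: dict[str, float] = field(
        default_factory=lambda: {
            "CDS": 0.970,
            "tRNA": 0.012,
            "rRNA": 0.006,
            "other_RNA": 0.002,
            "pseudogene": 0.010,
        }
    )
    insertion_density: float = 1.0 / 12.0
    #: gamma shape of the per-gene insertion-rate distribution of
    #: non-essential genes (mean fixed at insertion_density)
    nonessential_shape: float = 5.0
    leakage_rate: float = 0.0
    mean_reads_per_site: float = 9.0
    read_length: int = 50
    primer: str = PRIMER
    tail: str = TAIL
    decoy_fraction: float = 0.1
    contig_id: str = "sim_contig_1"
    #: gene-id prefix; give each simulated species its own namespace
    gene_prefix: str = "SIM"

    def __post_init__(self) -> None:
        if self.essential_fraction + self.domain_essential_fraction > 1:
            raise ValueError(
                "essential_fraction + domain_essential_fraction must be <= 1"
            )
        if not 0 <= self.insertion_density <= 1:
            raise ValueError("insertion_density must be a per-base probability")
        if self.leakage_rate < 0 or self.leakage_rate > 1:
            raise ValueError("leakage_rate must be a per-base probability")

    @property
    def true_gamma_shape(self) -> float:
        return self.nonessential_shape

    @property
    def true_gamma_scale(self) -> float:
        return self.insertion_density / self.nonessential_shape


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


@dataclass
class TruthManifest:
    """Ground truth for every emitted fixture, keyed by gene id."""

    config: SimulationConfig
    true_class: dict[str, str] = field(default_factory=dict)
    feature_class: dict[str, str] = field(default_factory=dict)
    gene_length: dict[str, int] = field(default_factory=dict)
    #: genome coordinates of the insertion-free core of domain-essential genes
    domain_core: dict[str, tuple[int, int]] = field(default_factory=dict)
    true_sites: dict[str, int] = field(default_factory=dict)
    total_unique_sites: int | None = None
    ortholog_truth: list[tuple[str, str]] = field(default_factory=list)
    cog_labels: dict[str, str] = field(default_factory=dict)

    def expected_final_call(self, gene_id: str) -> str:
        """The call the full pipeline (classifier + domain correction)
        should produce for this gene."""
        cls = self.true_class[gene_id]
        return "essential" if cls in ("essential", "domain_essential") else "non_essential"

    def expected_exp_rate(self, cutoff_low: float = 0.006) -> float:
        """The exponential rate the classifier's fit should recover.

        Mirrors the fit's estimator on the *true* per-gene site counts:
        the reciprocal mean insertion index of the low section, or — when
        the section is entirely insertion-free — one pseudo-insertion
        over the section's combined gene length.
        """
        low_ii = []
        low_len = []
        for gid, n in self.true_sites.items():
            ii = n / self.gene_length[gid]
            if ii <= cutoff_low:
                low_ii.append(ii)
                low_len.append(self.gene_length[gid])
        if not low_ii:
            raise ValueError("no genes in the low section")
        mean = float(np.mean(low_ii))
        return float(sum(low_len)) if mean == 0.0 else 1.0 / mean

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "true_class": self.true_class,
            "feature_class": self.feature_class,
            "gene_length": self.gene_length,
            "domain_core": {k: list(v) for k, v in self.domain_core.items()},
            "true_sites": self.true_sites,
            "total_unique_sites": self.total_unique_sites,
            "ortholog_truth": [list(p) for p in self.ortholog_truth],
            "cog_labels": self.cog_labels,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            config=SimulationConfig(**payload["config"]),
            true_class=payload["true_class"],
            feature_class=payload["feature_class"],
            gene_length={k: int(v) for k, v in payload["gene_length"].items()},
            domain_core={
                k: (int(v[0]), int(v[1]))
                for k, v in payload["domain_core"].items()
            },
            true_sites={k: int(v) for k, v in payload["true_sites"].items()},
            total_unique_sites=payload["total_unique_sites"],
            ortholog_truth=[tuple(p) for p in payload["ortholog_truth"]],
            cog_labels=payload["cog_labels"],
        )


# ---------------------------------------------------------------------------
# Genome + annotation

def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], GenomeAnnotation, TruthManifest]:
    """Random genome with non-overlapping genes and class assignments."""
    rng = _rng(config, _STAGE_GENOME)
    n = config.n_genes
    lengths = np.maximum(
        rng.normal(config.gene_length_mean, config.gene_length_sd, n).astype(int),
        config.min_gene_length_bp,
    )
    total_gene_bp = int(lengths.sum())
    slack = config.genome_length_bp - total_gene_bp
    if slack < n + 1:
        raise ValueError(
            f"{n} genes totalling {total_gene_bp} bp cannot fit in a "
            f"{config.genome_length_bp} bp genome with intergenic gaps"
        )
    # distribute the slack over n+1 intergenic gaps, each >= 1 bp
    gaps = rng.multinomial(slack - (n + 1), np.full(n + 1, 1.0 / (n + 1))) + 1

    seq = "".join(_BASES[rng.integers(0, 4, config.genome_length_bp)])
    genome = {config.contig_id: seq}

    classes = np.array(["non_essential"] * n, dtype=object)
    n_ess = int(round(n * config.essential_fraction))
    n_dom = int(round(n * config.domain_essential_fraction))
    order = rng.permutation(n)
    classes[order[:n_ess]] = "essential"
    classes[order[n_ess : n_ess + n_dom]] = "domain_essential"

    weights = config.feature_class_weights
    fclasses = rng.choice(
        list(weights), size=n, p=np.array(list(weights.values())) / sum(weights.values())
    )
    strands = rng.choice(["+", "-"], size=n)

    manifest = TruthManifest(config=config)
    genes: list[GeneModel] = []
    cursor = 0
    for i in range(n):
        cursor += int(gaps[i])
        start = cursor
        end = start + int(lengths[i])
        cursor = end
        gid = f"{config.gene_prefix}_{i:05d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                contig=config.contig_id,
                start=start,
                end=end,
                strand=str(strands[i]),
                feature_class=str(fclasses[i]),
            )
        )
        manifest.true_class[gid] = str(classes[i])
        manifest.feature_class[gid] = str(fclasses[i])
        manifest.gene_length[gid] = int(lengths[i])
        if classes[i] == "domain_essential":
            core_len = min(config.domain_core_bp, int(lengths[i]))
            core_off = int(rng.integers(0, int(lengths[i]) - core_len + 1))
            manifest.domain_core[gid] = (start + core_off, start + core_off + core_len)
    annotation = GenomeAnnotation(
        contigs={config.contig_id: config.genome_length_bp}, genes=genes
    )
    return genome, annotation, manifest


# ---------------------------------------------------------------------------
# Insertions

def simulate_insertions(
    annotation: GenomeAnnotation,
    manifest: TruthManifest,
    config: SimulationConfig,
) -> InsertionSiteTable:
    """Draw unique insertion sites and record per-gene truth.

    Tolerant sequence (intergenic plus non-essential gene bodies plus
    domain-essential flanks) receives sites at the configured density —
    per-gene rates for gene bodies are gamma-distributed around it —
    while essential genes and domain-essential cores receive only the
    leakage rate (zero by default, i.e. insertion-free).
    """
    rng = _rng(config, _STAGE_INSERTIONS)
    contig = config.contig_id
    L = annotation.contigs[contig]
    rate = np.full(L, config.insertion_density)
    for g in annotation.genes_on(contig):
        cls = manifest.true_class[g.gene_id]
        if cls == "essential":
            rate[g.start : g.end] = config.leakage_rate
        elif cls == "non_essential":
            rate[g.start : g.end] = rng.gamma(
                config.nonessential_shape, config.true_gamma_scale
            )
        else:  # domain_essential: tolerant flanks, insertion-free core
            rate[g.start : g.end] = rng.gamma(
                config.nonessential_shape, config.true_gamma_scale
            )
            core_start, core_end = manifest.domain_core[g.gene_id]
            rate[core_start:core_end] = config.leakage_rate

    hits = rng.random(L) < rate
    positions = np.nonzero(hits)[0]
    counts = rng.poisson(max(config.mean_reads_per_site - 1.0, 0.0), len(positions)) + 1

    for g in annotation.genes_on(contig):
        lo = np.searchsorted(positions, g.start, side="left")
        hi = np.searchsorted(positions, g.end, side="left")
        manifest.true_sites[g.gene_id] = int(hi - lo)
    manifest.total_unique_sites = int(len(positions))

    return InsertionSiteTable.from_records(
        (contig, int(p), "+", int(c)) for p, c in zip(positions, counts)
    )


def emit_reads(
    genome: Mapping[str, str],
    sites: InsertionSiteTable,
    config: SimulationConfig,
) -> list[SeqRecord]:
    """Junction-tagged reads reproducing the site table, plus decoys.

    Every unique site emits ``read_count`` reads of the form
    primer + tail + read_length bases of genomic flank, on a random
    strand; the read's first genomic base is the insertion position, so
    tag selection followed by exact mapping reproduces the site table.
    Tag-less decoy reads (random sequence) are mixed in to exercise the
    positive-selection step.
    """
    rng = _rng(config, _STAGE_READS)
    tag = config.primer + config.tail
    rl = config.read_length
    reads: list[SeqRecord] = []
    i = 0
    for contig in sites.contig_ids():
        seq = genome[contig]
        for pos, count in sites.sites[contig]:
            for _ in range(count):
                forward = bool(rng.random() < 0.5)
                if forward and pos + rl <= len(seq):
                    genomic = seq[pos : pos + rl]
                elif pos - rl + 1 >= 0:
                    genomic = reverse_complement(seq[pos - rl + 1 : pos + 1])
                elif pos + rl <= len(seq):
                    genomic = seq[pos : pos + rl]
                else:
                    log.warning("site %s:%d too close to both contig ends", contig, pos)
                    continue
                rec = SeqRecord(
                    Seq(tag + genomic), id=f"sim_read_{i:07d}", description=""
                )
                rec.letter_annotations["phred_quality"] = [40] * len(rec)
                reads.append(rec)
                i += 1
    n_decoys = int(round(len(reads) * config.decoy_fraction))
    decoy_len = len(tag) + rl
    for j in range(n_decoys):
        while True:
            s = "".join(_BASES[rng.integers(0, 4, decoy_len)])
            if config.primer not in s:
                break
        rec = SeqRecord(Seq(s), id=f"sim_decoy_{j:07d}", description="")
        rec.letter_annotations["phred_quality"] = [40] * decoy_len
        reads.append(rec)
    perm = rng.permutation(len(reads))
    return [reads[k] for k in perm]


# ---------------------------------------------------------------------------
# Homology fixture

@dataclass
class HomologyTruth:
    hits_ab: list[TabularHit]
    hits_ba: list[TabularHit]
    self_hits_a: list[TabularHit]
    self_hits_b: list[TabularHit]
    truth_pairs: list[tuple[str, str]]
    paralog_genes_a: list[str]


def _hit(
    q: str, s: str, qlen: int, slen: int,
    bitscore: float, evalue: float = 1e-80, pident: float = 85.0,
    qcov: float = 1.0, scov: float = 1.0,
) -> TabularHit:
    q_end = max(1, int(round(qlen * qcov)))
    s_end = max(1, int(round(slen * scov)))
    aln = max(q_end, s_end)
    return TabularHit(
        query_id=q, subject_id=s, percent_identity=pident,
        alignment_length=aln, mismatches=int(aln * (100 - pident) / 100),
        gap_opens=0, q_start=1, q_end=q_end, s_start=1, s_end=s_end,
        evalue=evalue, bitscore=bitscore, q_len=qlen, s_len=slen,
    )


def simulate_homology(
    manifest_a: TruthManifest,
    manifest_b: TruthManifest,
    config: SimulationConfig | None = None,
    ortholog_fraction: float = 0.6,
    n_secondary: int = 30,
    n_paralog_pairs: int = 0,
    n_near_threshold: int = 0,
) -> HomologyTruth:
    """Directional + self hit tables with planted reciprocal orthologs.

    True pairs get reciprocal top-score full-coverage hits; optional
    confounders are secondary (lower-score) cross hits, planted paralogs
    (within-proteome hits passing the filters, which the paralog filter
    must remove), and near-threshold hits (qcov just under 70%) that the
    coverage filter must reject.
    """
    config = config or manifest_a.config
    rng = _rng(config, _STAGE_HOMOLOGY)
    cds_a = sorted(g for g, c in manifest_a.feature_class.items() if c == "CDS")
    cds_b = sorted(g for g, c in manifest_b.feature_class.items() if c == "CDS")
    n_pairs = int(min(len(cds_a), len(cds_b)) * ortholog_fraction)
    pick_a = list(rng.choice(cds_a, size=n_pairs, replace=False))
    pick_b = list(rng.choice(cds_b, size=n_pairs, replace=False))
    plen_a = {g: max(50, manifest_a.gene_length[g] // 3) for g in cds_a}
    plen_b = {g: max(50, manifest_b.gene_length[g] // 3) for g in cds_b}

    hits_ab: list[TabularHit] = []
    hits_ba: list[TabularHit] = []
    truth: list[tuple[str, str]] = []
    for a, b in zip(pick_a, pick_b):
        score = float(rng.uniform(300, 800))
        hits_ab.append(_hit(a, b, plen_a[a], plen_b[b], score))
        hits_ba.append(_hit(b, a, plen_b[b], plen_a[a], score + float(rng.normal(0, 5))))
        truth.append((a, b))

    # secondary lower-score hits exercise best-hit selection
    for _ in range(min(n_secondary, n_pairs)):
        i = int(rng.integers(0, n_pairs))
        j = int(rng.integers(0, n_pairs))
        if i == j:
            continue
        a, wrong_b = pick_a[i], pick_b[j]
        hits_ab.append(_hit(a, wrong_b, plen_a[a], plen_b[wrong_b], 100.0))

    # near-threshold hits: coverage just below the floor -> filtered out
    for _ in range(n_near_threshold):
        i = int(rng.integers(0, n_pairs))
        j = int(rng.integers(0, n_pairs))
        a, b = pick_a[i], pick_b[j]
        hits_ab.append(_hit(a, b, plen_a[a], plen_b[b], 900.0, qcov=0.69))

    self_a = [_hit(g, g, plen_a[g], plen_a[g], 2 * plen_a[g]) for g in cds_a]
    self_b = [_hit(g, g, plen_b[g], plen_b[g], 2 * plen_b[g]) for g in cds_b]

    paralogs: list[str] = []
    if n_paralog_pairs:
        others = [g for g in cds_a if g not in set(pick_a)]
        for m in range(min(n_paralog_pairs, n_pairs, len(others))):
            g, partner = pick_a[m], others[m]
            self_a.append(_hit(g, partner, plen_a[g], plen_a[partner], 400.0, pident=95.0))
            self_a.append(_hit(partner, g, plen_a[partner], plen_a[g], 400.0, pident=95.0))
            paralogs.append(g)

    manifest_a.ortholog_truth = truth
    return HomologyTruth(
        hits_ab=hits_ab,
        hits_ba=hits_ba,
        self_hits_a=self_a,
        self_hits_b=self_b,
        truth_pairs=truth,
        paralog_genes_a=paralogs,
    )


# ---------------------------------------------------------------------------
# Functional annotations + phyletic blocks

def simulate_annotations(
    manifest: TruthManifest,
    config: SimulationConfig | None = None,
    unannotated_fraction: float = 0.15,
    multi_label_fraction: float = 0.10,
) -> list[FunctionalAnnotationRow]:
    """emapper-style rows for the manifest's CDS genes.

    A configurable fraction of genes has no orthology group (and hence
    no label); labelled genes carry one COG letter, or two for the
    multi-label fraction.  Labels are recorded in the manifest.
    """
    config = config or manifest.config
    rng = _rng(config, _STAGE_ANNOTATIONS)
    rows: list[FunctionalAnnotationRow] = []
    letters = list(_COG_LETTERS)
    for i, gid in enumerate(sorted(
        g for g, c in manifest.feature_class.items() if c == "CDS"
    )):
        if rng.random() < unannotated_fraction:
            rows.append(FunctionalAnnotationRow(gid, "", frozenset()))
            manifest.cog_labels[gid] = ""
            continue
        n_labels = 2 if rng.random() < multi_label_fraction else 1
        label = "".join(rng.choice(letters, size=n_labels, replace=False))
        rows.append(
            FunctionalAnnotationRow(gid, label, frozenset({f"OG{i:05d}"}))
        )
        manifest.cog_labels[gid] = label
    return rows


def simulate_presence_blocks(
    n_proteomes: int = 12,
    groups_per_block: int = 6,
    n_blocks: int = 3,
    n_core_groups: int = 2,
    seed: int = 0,
) -> tuple[dict[str, list[FunctionalAnnotationRow]], list[str], dict[str, int]]:
    """Proteome annotation sets with planted phyletic block structure.

    Proteomes split into ``n_blocks`` groups; each block's proteomes
    carry that block's orthology groups plus a shared core, so clustering
    the presence matrix at k = n_blocks should recover the blocks
    exactly.  Returns (annotations per proteome, group universe, true
    block label per proteome).
    """
    rng = np.random.default_rng(seed)
    universe = [f"COREOG{c}" for c in range(n_core_groups)]
    block_groups: list[list[str]] = []
    for b in range(n_blocks):
        groups = [f"BLK{b}_OG{j}" for j in range(groups_per_block)]
        block_groups.append(groups)
        universe.extend(groups)
    annotations: dict[str, list[FunctionalAnnotationRow]] = {}
    truth: dict[str, int] = {}
    for p in range(n_proteomes):
        block = p % n_blocks
        name = f"proteome_{p:02d}"
        truth[name] = block
        present = universe[:n_core_groups] + block_groups[block]
        rows = []
        for j, og in enumerate(present):
            letter = str(rng.choice(list(_COG_LETTERS)))
            rows.append(
                FunctionalAnnotationRow(f"{name}_g{j}", letter, frozenset({og}))
            )
            if rng.random() < 0.2:  # duplicated occurrence: presence still 1
                rows.append(
                    FunctionalAnnotationRow(
                        f"{name}_g{j}_dup", letter, frozenset({og})
                    )
                )
        annotations[name] = rows
    return annotations, universe, truth


# ---------------------------------------------------------------------------
# Bundle writer

def write_bundle(
    outdir: str | Path,
    config: SimulationConfig | None = None,
    with_fastq: bool = True,
    with_comparative: bool = False,
) -> TruthManifest:
    """Generate and write a complete fixture bundle to ``outdir``.

    Emits genome FASTA, GFF3, the unique-site TSV, optionally the tagged
    FASTQ, optionally homology/annotation fixtures (using a second,
    independent genome as the partner species), and the manifest JSON.
    """
    config = config or SimulationConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotation, manifest = simulate_genome(config)
    sites = simulate_insertions(annotation, manifest, config)
    write_fasta(genome, outdir / "genome.fasta")
    write_annotation(annotation, outdir / "annotation.gff3")
    write_site_table(sites, outdir / "sites.tsv")
    if with_fastq:
        reads = emit_reads(genome, sites, config)
        write_fastq(reads, outdir / "library.fastq")
    if with_comparative:
        partner_cfg = dataclasses.replace(
            config, seed=config.seed + 1, contig_id="sim_contig_b",
            gene_prefix=config.gene_prefix + "B",
        )
        _, annotation_b, manifest_b = simulate_genome(partner_cfg)
        homology = simulate_homology(manifest, manifest_b, config)
        write_hits(homology.hits_ab, outdir / "hits_ab.tsv")
        write_hits(homology.hits_ba, outdir / "hits_ba.tsv")
        write_hits(homology.self_hits_a, outdir / "self_a.tsv")
        write_hits(homology.self_hits_b, outdir / "self_b.tsv")
        rows = simulate_annotations(manifest, config)
        write_functional_annotation(rows, outdir / "annotations.tsv")
    manifest.to_json(outdir / "manifest.json")
    return manifest
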