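"""End-to-end orchestration: one configured run from inputs to reports.

Runs tag selection / mapping (or site-table ingestion), per-gene
statistics, mode fitting and classification, the essential-domain
correction, and — when the inputs are present — the ortholog agreement
and COG/presence profiling layers.  Writes per-stage TSVs and a single
JSON summary with a provenance block (config echo, package version,
seed).  Defaults reproduce the published analysis settings exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .domains import STEP_BP, WINDOW_BP, domain_correction
from .essentiality import (
    CUTOFF_HIGH,
    CUTOFF_LOW,
    THRESHOLD_FOLD,
    call_genome,
)
from .insertions import (
    PRIMER,
    TAIL,
    gene_insertion_stats,
    map_reads_exact,
    partition_sites,
    select_transposon_reads,
)
from .io_formats import (
    read_annotation,
    read_calls,
    read_fasta,
    read_fastq,
    read_functional_annotation,
    read_hits,
    read_site_table,
    write_site_table,
)
from .orthologs import (
    MAX_EVALUE,
    MIN_COVERAGE_PCT,
    best_hits,
    compare_essentiality,
    exclude_paralogs,
    filter_hits,
    reciprocal_pairs,
)
from .profiles import cog_distribution

__all__ = ["RunConfig", "PipelineError", "run_all"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and parameters of a pipeline run.

    Parameter defaults are the published analysis settings (junction
    primer/tail, 20 bp minimum read length, 0.006/0.03 section cut-offs,
    12-fold likelihood threshold, 300/150 bp sliding window, 1e-5
    E-value and 70% coverage for orthology).
    """

    outdir: str = "tradis_run"
    seed: int = 0
    # inputs
    gff: str | None = None
    fasta: str | None = None
    sites: str | None = None
    fastq: str | None = None
    hits_ab: str | None = None
    hits_ba: str | None = None
    self_a: str | None = None
    self_b: str | None = None
    calls_b: str | None = None
    annotations: str | None = None
    # tag selection / mapping
    primer: str = PRIMER
    tail: str = TAIL
    min_len: int = 20
    max_mismatch: int = 0
    collapse_strand: bool = True
    # classifier
    cutoff_low: float = CUTOFF_LOW
    cutoff_high: float = CUTOFF_HIGH
    threshold_fold: float = THRESHOLD_FOLD
    # domain scan
    window: int = WINDOW_BP
    step: int = STEP_BP
    terminal_window: bool = True
    promote_domains: bool = True
    # orthology
    max_evalue: float = MAX_EVALUE
    min_coverage: float = MIN_COVERAGE_PCT
    paralog_filter: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute every configured stage; returns (and writes) the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "provenance": {
            "package": "tradis-essentia",
            "version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
        }
    }

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                log.info("stage %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    _write_summary(summary, outdir)  # retain partial outputs
                    raise PipelineError(name, exc) from exc

        return _Ctx()

    with stage("annotation"):
        if config.gff is None:
            raise ValueError("config.gff is required")
        annotation = read_annotation(config.gff, fasta_path=config.fasta)
        summary["annotation"] = {
            "n_features": len(annotation.genes),
            "n_genes": annotation.n_genes,
            "n_pseudogenes": annotation.n_pseudogenes,
            "class_counts": annotation.class_counts(),
        }

    with stage("sites"):
        if config.sites is not None:
            sites = read_site_table(config.sites, collapse_strand=config.collapse_strand)
        elif config.fastq is not None:
            if config.fasta is None:
                raise ValueError("mapping from FASTQ requires config.fasta")
            genome = read_fasta(config.fasta)
            selected, sel_report = select_transposon_reads(
                read_fastq(config.fastq),
                primer=config.primer,
                tail=config.tail,
                min_len=config.min_len,
                max_mismatch=config.max_mismatch,
            )
            sites, map_report = map_reads_exact(
                selected, genome, collapse_strand=config.collapse_strand
            )
            summary["tag_selection"] = dataclasses.asdict(sel_report)
            summary["mapping"] = dataclasses.asdict(map_report)
            write_site_table(sites, outdir / "sites.tsv")
        else:
            raise ValueError("either config.sites or config.fastq is required")
        partition = partition_sites(sites, annotation)
        summary["sites"] = {
            "total_unique_sites": sites.total_sites,
            "total_reads": sites.total_reads,
            "cds_sites": partition.cds_sites,
            "intergenic_sites": partition.intergenic_sites,
            "partition_total": partition.total,
        }

    with stage("stats"):
        stats = gene_insertion_stats(sites, annotation)
        _write_stats(stats, outdir / "gene_stats.tsv")

    with stage("call"):
        result = call_genome(
            stats,
            cutoff_low=config.cutoff_low,
            cutoff_high=config.cutoff_high,
            threshold_fold=config.threshold_fold,
            annotation=annotation,
        )
        summary["calls_before_domain_correction"] = result.summary

    with stage("domains"):
        calls, flagged = domain_correction(
            result.calls,
            annotation,
            sites,
            window=config.window,
            step=config.step,
            terminal_window=config.terminal_window,
            promote=config.promote_domains,
        )
        _write_calls(calls, outdir / "calls.tsv")
        _write_domain_report(flagged, outdir / "domain_report.tsv")
        counts = {
            c: sum(1 for gc in calls if gc.call == c)
            for c in ("essential", "non_essential", "unclear")
        }
        from .essentiality import summarize_calls

        summary["calls"] = summarize_calls(counts, n_genes=annotation.n_genes)
        summary["domain_correction"] = {
            "n_flagged": len(flagged),
            "flagged_genes": [r.gene_id for r in flagged],
            "promoted": config.promote_domains,
        }

    ortholog_inputs = (config.hits_ab, config.hits_ba, config.calls_b)
    if all(x is not None for x in ortholog_inputs):
        with stage("orthologs"):
            calls_a = {gc.gene_id: gc.call for gc in calls}
            calls_b = read_calls(config.calls_b)
            fa = filter_hits(
                read_hits(config.hits_ab),
                config.max_evalue, config.min_coverage, config.min_coverage,
            )
            fb = filter_hits(
                read_hits(config.hits_ba),
                config.max_evalue, config.min_coverage, config.min_coverage,
            )
            pairs = reciprocal_pairs(best_hits(fa), best_hits(fb))
            if config.paralog_filter:
                if config.self_a is None or config.self_b is None:
                    raise ValueError(
                        "paralog filtering requires self_a and self_b hit tables "
                        "(or disable paralog_filter)"
                    )
                pairs = exclude_paralogs(
                    pairs,
                    read_hits(config.self_a),
                    read_hits(config.self_b),
                    config.max_evalue, config.min_coverage, config.min_coverage,
                )
            comparison = compare_essentiality(pairs, calls_a, calls_b)
            _write_pairs(comparison, outdir / "ortholog_pairs.tsv")
            summary["orthologs"] = comparison.summary()

    if config.annotations is not None:
        with stage("cog"):
            rows = read_functional_annotation(config.annotations)
            calls_map = {gc.gene_id: gc.call for gc in calls}
            table = cog_distribution(rows, calls_map)
            table.to_csv(outdir / "cog_table.tsv", sep="\t", index=False)
            summary["cog"] = {
                "n_label_counts": int(table["count"].sum()),
                "n_labels": int(table["cog_label"].nunique()),
            }

    _write_summary(summary, outdir)
    return summary


def _write_stats(stats, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene_id\tunique_insertions\tlength_bp\tinsertion_index\n")
        for s in stats:
            fh.write(
                f"{s.gene_id}\t{s.unique_insertions}\t{s.length_bp}"
                f"\t{s.insertion_index:.6g}\n"
            )


def _write_calls(calls, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene_id\tinsertion_index\tllr\tcall\tdomain_flag\n")
        for c in calls:
            fh.write(
                f"{c.gene_id}\t{c.insertion_index:.6g}\t{c.llr:.6g}"
                f"\t{c.call}\t{int(c.domain_flag)}\n"
            )


def _write_domain_report(flagged, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene_id\tn_windows\tn_zero_windows\tfirst_zero_offset\n")
        for r in flagged:
            fh.write(
                f"{r.gene_id}\t{len(r.windows)}\t{r.n_zero_windows}"
                f"\t{r.first_zero_offset}\n"
            )


def _write_pairs(comparison, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene_a\tgene_b\tbitscore_ab\tbitscore_ba\tcall_a\tcall_b\n")
        for pair, ca, cb in comparison.pairs:
            fh.write(
                f"{pair.gene_a}\t{pair.gene_b}\t{pair.bitscore_ab:g}"
                f"\t{pair.bitscore_ba:g}\t{ca}\t{cb}\n"
            )


def _write_summary(summary: dict, outdir: Path) -> None:
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
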