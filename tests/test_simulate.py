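"""Synthetic-data generator: determinism, manifest consistency, structure."""

import numpy as np
import pytest

from tradis_essentia import (
    SimulationConfig,
    TruthManifest,
    best_hits,
    emit_reads,
    exclude_paralogs,
    filter_hits,
    gene_insertion_stats,
    map_reads_exact,
    reciprocal_pairs,
    select_transposon_reads,
    simulate_annotations,
    simulate_genome,
    simulate_homology,
    simulate_insertions,
    write_bundle,
)
from tradis_essentia.io_formats import (
    read_annotation,
    read_fasta,
    read_site_table,
)


class TestSimulateGenome:
    def test_deterministic_under_fixed_seed(self, small_config, tmp_path):
        b1 = write_bundle(tmp_path / "r1", small_config, with_fastq=False)
        b2 = write_bundle(tmp_path / "r2", small_config, with_fastq=False)
        for name in ("genome.fasta", "annotation.gff3", "sites.tsv",
                     "manifest.json"):
            assert (tmp_path / "r1" / name).read_bytes() == \
                (tmp_path / "r2" / name).read_bytes()

    def test_zero_essential_fraction(self):
        config = SimulationConfig(seed=3, n_genes=40, genome_length_bp=80_000,
                                  essential_fraction=0.0,
                                  domain_essential_fraction=0.0)
        _, _, manifest = simulate_genome(config)
        assert set(manifest.true_class.values()) == {"non_essential"}

    def test_total_gene_span_matches_configured_distribution(self):
        config = SimulationConfig(seed=4, n_genes=500,
                                  gene_length_mean=900.0,
                                  genome_length_bp=700_000)
        _, annotation, manifest = simulate_genome(config)
        span = sum(manifest.gene_length.values())
        assert span == pytest.approx(500 * 900, rel=0.05)
        assert len(annotation.genes) == 500

    def test_genes_do_not_overlap_and_fit_contig(self):
        config = SimulationConfig(seed=5, n_genes=100, genome_length_bp=150_000)
        _, annotation, _ = simulate_genome(config)
        genes = sorted(annotation.genes, key=lambda g: g.start)
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start
        assert genes[-1].end <= config.genome_length_bp

    def test_genes_that_cannot_fit_error(self):
        with pytest.raises(ValueError, match="cannot fit"):
            simulate_genome(SimulationConfig(seed=1, n_genes=100,
                                             genome_length_bp=50_000))

    def test_impossible_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(essential_fraction=0.8,
                             domain_essential_fraction=0.3)


class TestSimulateInsertions:
    def test_zero_leakage_means_essential_genes_insertion_free(
        self, small_bundle
    ):
        _, _, manifest, _ = small_bundle
        for gid, cls in manifest.true_class.items():
            if cls == "essential":
                assert manifest.true_sites[gid] == 0

    def test_domain_core_is_insertion_free(self, small_bundle):
        _, _, manifest, sites = small_bundle
        positions = np.array(sites.positions(manifest.config.contig_id))
        for gid, (lo, hi) in manifest.domain_core.items():
            inside = ((positions >= lo) & (positions < hi)).sum()
            assert inside == 0

    def test_site_count_tracks_density(self, small_bundle):
        _, annotation, manifest, sites = small_bundle
        config = manifest.config
        # non-essential span: everything except essential gene bodies and
        # domain cores
        blocked = sum(manifest.gene_length[g]
                      for g, c in manifest.true_class.items()
                      if c == "essential")
        blocked += sum(hi - lo for lo, hi in manifest.domain_core.values())
        span = config.genome_length_bp - blocked
        expected = span * config.insertion_density
        # binomial noise plus per-gene gamma rate dispersion: 3 sd of the
        # compound process
        gene_var = sum(
            (manifest.gene_length[g] * config.true_gamma_scale) ** 2
            * config.nonessential_shape
            for g, c in manifest.true_class.items()
            if c != "essential"
        )
        sd = np.sqrt(expected + gene_var)
        assert abs(sites.total_sites - expected) < 3 * sd

    def test_manifest_counts_match_recomputed_stats(self, small_bundle):
        _, annotation, manifest, sites = small_bundle
        stats = {s.gene_id: s.unique_insertions
                 for s in gene_insertion_stats(sites, annotation)}
        assert stats == manifest.true_sites
        assert sites.total_sites == manifest.total_unique_sites


class TestEmitReads:
    def test_fastq_roundtrip_reproduces_site_table(self, small_config,
                                                   small_bundle):
        genome, _, _, sites = small_bundle
        reads = emit_reads(genome, sites, small_config)
        selected, report = select_transposon_reads(
            reads, primer=small_config.primer, tail=small_config.tail
        )
        # decoys carry no tag
        assert report.n_no_tag > 0
        table, map_report = map_reads_exact(selected, genome)
        assert map_report.n_unmapped == 0
        assert table.sites == sites.sites

    def test_read_count_copies_emitted_per_site(self, small_config,
                                                small_bundle):
        genome, _, _, sites = small_bundle
        reads = emit_reads(genome, sites, small_config)
        n_tagged = sum(1 for r in reads
                       if small_config.primer in str(r.seq))
        assert n_tagged == sites.total_reads


class TestRoundTripThroughFiles:
    def test_bundle_files_reload_consistently(self, small_config, tmp_path):
        manifest = write_bundle(tmp_path / "b", small_config, with_fastq=False)
        genome = read_fasta(tmp_path / "b" / "genome.fasta")
        annotation = read_annotation(tmp_path / "b" / "annotation.gff3")
        sites = read_site_table(tmp_path / "b" / "sites.tsv")
        assert {c: len(s) for c, s in genome.items()} == annotation.contigs
        assert sites.total_sites == manifest.total_unique_sites
        assert {g.gene_id for g in annotation.genes} == set(manifest.true_class)
        reloaded = TruthManifest.from_json(tmp_path / "b" / "manifest.json")
        assert reloaded.true_sites == manifest.true_sites
        assert reloaded.config == manifest.config


@pytest.fixture(scope="module")
def two_manifests():
    cfg_a = SimulationConfig(seed=21, n_genes=60, genome_length_bp=90_000,
                             gene_prefix="SPA")
    cfg_b = SimulationConfig(seed=22, n_genes=60, genome_length_bp=90_000,
                             contig_id="sim_contig_b", gene_prefix="SPB")
    _, _, ma = simulate_genome(cfg_a)
    _, _, mb = simulate_genome(cfg_b)
    return ma, mb


class TestSimulateHomology:

    def test_no_confounders_recovers_exact_truth(self, two_manifests):
        ma, mb = two_manifests
        hom = simulate_homology(ma, mb)
        fa = filter_hits(hom.hits_ab)
        fb = filter_hits(hom.hits_ba)
        pairs = reciprocal_pairs(best_hits(fa), best_hits(fb))
        assert {(p.gene_a, p.gene_b) for p in pairs} == set(hom.truth_pairs)

    def test_planted_paralog_removed(self, two_manifests):
        ma, mb = two_manifests
        hom = simulate_homology(ma, mb, n_paralog_pairs=3)
        pairs = reciprocal_pairs(best_hits(filter_hits(hom.hits_ab)),
                                 best_hits(filter_hits(hom.hits_ba)))
        kept = exclude_paralogs(pairs, hom.self_hits_a, hom.self_hits_b)
        kept_a = {p.gene_a for p in kept}
        assert hom.paralog_genes_a
        for g in hom.paralog_genes_a:
            assert g not in kept_a

    def test_near_threshold_coverage_hits_filtered(self, two_manifests):
        ma, mb = two_manifests
        hom = simulate_homology(ma, mb, n_near_threshold=5)
        low_cov = [h for h in hom.hits_ab if h.query_coverage_pct < 70]
        assert low_cov
        assert all(h not in filter_hits(hom.hits_ab) for h in low_cov)


class TestSimulateAnnotations:
    def test_labels_recorded_in_manifest(self, small_config, small_bundle):
        _, _, manifest, _ = small_bundle
        rows = simulate_annotations(manifest, small_config)
        for r in rows:
            assert manifest.cog_labels[r.gene_id] == r.cog_labels

    def test_multilabel_fraction_inflates_label_count(self, small_config,
                                                      small_bundle):
        _, _, manifest, _ = small_bundle
        rows = simulate_annotations(manifest, small_config,
                                    unannotated_fraction=0.0,
                                    multi_label_fraction=0.5)
        n_labels = sum(len(r.cog_labels) for r in rows)
        # about half the genes carry two letters
        assert n_labels == pytest.approx(1.5 * len(rows), rel=0.2)
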