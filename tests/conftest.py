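import pytest

from tradis_essentia import (
    GeneModel,
    GenomeAnnotation,
    InsertionSiteTable,
    SimulationConfig,
    simulate_genome,
    simulate_insertions,
)


def make_annotation(genes, contig_length=100_000, contig="c1"):
    return GenomeAnnotation(contigs={contig: contig_length}, genes=list(genes))


def make_gene(gene_id="g1", start=0, end=1000, contig="c1", strand="+",
              feature_class="CDS"):
    return GeneModel(gene_id=gene_id, contig=contig, start=start, end=end,
                     strand=strand, feature_class=feature_class)


def make_sites(positions, contig="c1", count=1):
    return InsertionSiteTable.from_records(
        (contig, p, "+", count) for p in positions
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_genes=150, genome_length_bp=220_000)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """A small simulated genome + insertions, shared across tests."""
    genome, annotation, manifest = simulate_genome(small_config)
    sites = simulate_insertions(annotation, manifest, small_config)
    return genome, annotation, manifest, sites
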