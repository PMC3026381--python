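import pytest

from splicepep.fixtures import FixtureConfig, build_fixture
from splicepep.genome_model import CodingExon, GeneModel, GenomeAssembly
from splicepep.preprocess import build_exon_comb_kb


def make_exon(seq_map, exon_id="G1.E1", gene_id="G1", chrom="chr1", start=1,
              end=None, strand="+", frame=0):
    """Convenience for handcrafted single-exon setups; ``seq_map`` is the
    assembly dict so bounds can be validated by the caller."""
    if end is None:
        end = len(seq_map[chrom])
    return CodingExon(exon_id, gene_id, chrom, start, end, strand, frame)


@pytest.fixture
def tiny_assembly():
    return GenomeAssembly({"chr1": "ACGTAC"})


@pytest.fixture
def stop_free_fixture():
    """Two stop-free genes (mixed strands across seeds), with SNPs."""
    return build_fixture(FixtureConfig(n_genes=2, seed=11, snps_per_gene=3))


@pytest.fixture
def cassette_fixture():
    """One gene with a cassette-exon skip transcript and two proteins."""
    return build_fixture(FixtureConfig(
        n_genes=1, seed=5, exons_per_gene=(3, 3), exon_len=(18, 45),
        minus_strand_prob=0.0, cassette=True, snps_per_gene=0))


def gene_adjacency(genes):
    return build_exon_comb_kb(genes)


def single_exon_gene(assembly_seq, strand="+", frame=0, gene_id="G1"):
    """One gene, one exon spanning the whole chromosome."""
    chrom = "chr1"
    assembly = GenomeAssembly({chrom: assembly_seq})
    exon = CodingExon(f"{gene_id}.E1", gene_id, chrom, 1, len(assembly_seq), strand, frame)
    gene = GeneModel(gene_id, gene_id, chrom, strand, [exon],
                     {"T1": [exon.exon_id]}, [f"{gene_id}_P1"])
    return assembly, gene
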