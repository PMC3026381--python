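import random

import pytest

from splicepep.genome_model import AdjacencyKB, CodingExon, GeneModel, GenomeAssembly
from splicepep.preprocess import build_exon_comb_kb
from splicepep.region_gen import (
    RegionConfig,
    RejectionLog,
    eeth_candidate_pairs,
    estimate_peptide,
    gen_eekb_region,
    gen_eeth_regions,
    gen_eith_regions,
    gen_exon_region,
    gen_ieth_regions,
    generate_all,
    intron_between,
    segment_frame_offset,
)


def two_exon_gene(exon1, intron, exon2, strand="+", frame1=0, gene_id="G1"):
    """Lay exon1|intron|exon2 on one chromosome in transcription order."""
    if strand == "+":
        chrom_seq = exon1 + intron + exon2
        e1 = (1, len(exon1))
        e2 = (len(exon1) + len(intron) + 1, len(chrom_seq))
    else:
        from Bio.Seq import Seq

        fwd = str(Seq(exon1 + intron + exon2).reverse_complement())
        chrom_seq = fwd
        n = len(fwd)
        e1 = (n - len(exon1) + 1, n)
        e2 = (1, len(exon2))
    frame2 = (3 - ((len(exon1) - frame1) % 3)) % 3
    assembly = GenomeAssembly({"chr1": chrom_seq})
    ex1 = CodingExon(f"{gene_id}.E1", gene_id, "chr1", e1[0], e1[1], strand, frame1)
    ex2 = CodingExon(f"{gene_id}.E2", gene_id, "chr1", e2[0], e2[1], strand, frame2)
    gene = GeneModel(gene_id, gene_id, "chr1", strand, [ex1, ex2],
                     {"T1": [ex1.exon_id, ex2.exon_id]}, ["P1"])
    return assembly, gene


class TestSegmentFrameOffset:
    @pytest.mark.parametrize("frame,trim,expected", [
        (0, 3, 0),
        (0, 2, 1),   # first codon boundary of a frame-0 exon at/after base 2 is 3
        (2, 0, 2),
        (1, 4, 0),
        (0, 0, 0),
    ])
    def test_values(self, frame, trim, expected):
        assert segment_frame_offset(frame, trim) == expected

    def test_matches_enumerated_codon_boundaries(self):
        # independently: boundaries of a frame-f exon are f, f+3, f+6, ...;
        # a segment starting at `trim` must skip until the next boundary
        for frame in range(3):
            for trim in range(12):
                boundaries = [frame + 3 * k for k in range(10)]
                next_b = min(b for b in boundaries if b >= trim)
                assert segment_frame_offset(frame, trim) == next_b - trim


class TestExonRegions:
    def _exon(self, cds, frame=0):
        assembly = GenomeAssembly({"chr1": cds})
        exon = CodingExon("G1.E1", "G1", "chr1", 1, len(cds), "+", frame)
        return assembly, exon

    def test_simple_translation(self):
        assembly, exon = self._exon("ATGGCAGGG")
        region = gen_exon_region(exon, assembly)
        assert region.wild_peptide == "MAG"
        assert region.cdna == "ATGGCAGGG"
        assert region.junction_offset is None

    def test_internal_stop_rejected(self):
        assembly, exon = self._exon("ATGTAAGGG")
        log = RejectionLog()
        assert gen_exon_region(exon, assembly, rejections=log) is None
        assert log.entries[0].reason == "internal_stop"

    def test_terminal_stop_stripped(self):
        assembly, exon = self._exon("ATGGGGTAA")
        region = gen_exon_region(exon, assembly)
        assert region.wild_peptide == "MG"

    def test_ambiguous_rejected(self):
        assembly, exon = self._exon("ATGNNNGGG")
        log = RejectionLog()
        assert gen_exon_region(exon, assembly, rejections=log) is None
        assert log.entries[0].reason == "ambiguous"

    def test_annotated_frame_used(self):
        assembly, exon = self._exon("TTATGGCA", frame=2)
        region = gen_exon_region(exon, assembly)
        assert region.wild_peptide == "MA"


class TestEEKB:
    def test_flank_truncation_to_120(self):
        exon1 = "GGC" * 100          # 300 nt
        exon2 = "GCA" * 16 + "GC"    # 50 nt
        assembly, gene = two_exon_gene(exon1, "T" * 30, exon2)
        region = gen_eekb_region((gene.exons[0], gene.exons[1]), assembly)
        assert len(region.cdna) == 170
        assert region.junction_offset == 120
        # trimming 180 bases off a frame-0 exon leaves frame 0 (180 % 3 == 0)
        assert region.orf == 0

    def test_terminal_stop_stripped(self):
        assembly, gene = two_exon_gene("ATGGCA", "TTTTTT", "GGGTAG")
        region = gen_eekb_region((gene.exons[0], gene.exons[1]), assembly)
        assert region.wild_peptide == "MAG"

    def test_junction_spanning_stop_rejected(self):
        # exon1 "ATGTA" + exon2 "ACCGGG": in-frame TAA spans the junction
        assembly, gene = two_exon_gene("ATGTA", "TTTTTT", "ACCGGG")
        log = RejectionLog()
        assert gen_eekb_region((gene.exons[0], gene.exons[1]), assembly,
                               rejections=log) is None
        assert log.entries[0].reason == "internal_stop"

    def test_frame_carried_from_5prime_exon(self):
        # 7-nt frame-0 exon: trim 0, but a 7-nt exon with flank 3 trims 4 -> orf 2
        assembly, gene = two_exon_gene("ATGGCAG", "TTTTTT", "GGGCCC")
        config = RegionConfig(flank_nt=3)
        region = gen_eekb_region((gene.exons[0], gene.exons[1]), assembly, config)
        assert region.orf == segment_frame_offset(0, 7 - 3) == 2


class TestEITH:
    def test_no_stop_keeps_full_peptide(self):
        assembly, gene = two_exon_gene("ATGGCA", "GTTAACGG", "GGGCCC")
        intron = intron_between(gene.exons[0], gene.exons[1])
        regions = gen_eith_regions(gene.exons[0], intron, assembly)
        frame0 = [r for r in regions if r.orf == 0]
        assert frame0 and frame0[0].wild_peptide.startswith("MAVN")

    def test_intron_stop_truncates_then_coverage_rejects(self):
        # stop codon is the first intron codon: truncation leaves "MA", which
        # no longer reaches across the junction
        assembly, gene = two_exon_gene("ATGGCA", "TAAGGG", "GGGCCC")
        intron = intron_between(gene.exons[0], gene.exons[1])
        log = RejectionLog()
        regions = gen_eith_regions(gene.exons[0], intron, assembly, rejections=log)
        assert all(r.orf != 0 for r in regions)
        assert any(e.orf == 0 and e.reason == "junction_not_covered"
                   for e in log.entries)

    def test_intron_stop_truncates_and_keeps_when_spanning(self):
        # junction codon GAG crosses into the intron before the TAA stop
        assembly, gene = two_exon_gene("ATGGCAG", "AGTAAGGG", "GGGCCC")
        intron = intron_between(gene.exons[0], gene.exons[1])
        regions = gen_eith_regions(gene.exons[0], intron, assembly)
        frame0 = [r for r in regions if r.orf == 0]
        assert frame0 and frame0[0].wild_peptide == "MAE"

    def test_exon_stop_rejects_frame(self):
        assembly, gene = two_exon_gene("TAAGCA", "GGGGGG", "GGGCCC")
        intron = intron_between(gene.exons[0], gene.exons[1])
        log = RejectionLog()
        regions = gen_eith_regions(gene.exons[0], intron, assembly, rejections=log)
        assert all(r.orf != 0 for r in regions)
        assert any(e.orf == 0 and e.reason == "stop_in_5prime_segment"
                   for e in log.entries)


class TestIETH:
    def test_clean_intron_kept(self):
        assembly, gene = two_exon_gene("GGGCCC", "CCCCCC", "ATGGCA")
        intron = intron_between(gene.exons[0], gene.exons[1])
        regions = gen_ieth_regions(intron, gene.exons[1], assembly)
        frame0 = [r for r in regions if r.orf == 0]
        assert frame0 and frame0[0].wild_peptide == "PPMA"

    def test_intron_stop_not_tolerated(self):
        # frame 0 reads CCC TAA ... -> internal stop; frame 1 reads
        # CCT AAA TGG CA -> "PKW" and survives
        assembly, gene = two_exon_gene("GGGCCC", "CCCTAA", "ATGGCA")
        intron = intron_between(gene.exons[0], gene.exons[1])
        log = RejectionLog()
        regions = gen_ieth_regions(intron, gene.exons[1], assembly, rejections=log)
        assert any(e.orf == 0 and e.reason == "internal_stop" for e in log.entries)
        frame1 = [r for r in regions if r.orf == 1]
        assert frame1 and frame1[0].wild_peptide == "PKW"


def four_exon_gene(strand="+", alphabet="ACG", seed=0, gene_id="G1",
                   transcripts=None):
    """Four 9-nt exons separated by 12-nt introns; the default alphabet has no
    T, so no reading frame anywhere can contain a stop codon."""
    rng = random.Random(seed)

    def rand(n):
        return "".join(rng.choice(alphabet) for _ in range(n))

    parts, exon_iv, cursor = [], [], 1
    for i in range(4):
        exon_iv.append((cursor, cursor + 8))
        parts.append(rand(9))
        cursor += 9
        if i < 3:
            parts.append(rand(12))
            cursor += 12
    chrom_seq = "".join(parts)
    if strand == "-":
        from Bio.Seq import Seq

        n = len(chrom_seq)
        chrom_seq = str(Seq(chrom_seq).reverse_complement())
        exon_iv = [(n - e + 1, n - s + 1) for s, e in exon_iv]
    assembly = GenomeAssembly({"chr1": chrom_seq})
    exons = [CodingExon(f"{gene_id}.E{i + 1}", gene_id, "chr1", s, e, strand, 0)
             for i, (s, e) in enumerate(exon_iv)]
    tx = transcripts or {"T1": [e.exon_id for e in exons]}
    gene = GeneModel(gene_id, gene_id, "chr1", strand, exons, tx, ["P1"])
    return assembly, gene


class TestEETH:
    def test_candidate_pairs_skip_annotated(self):
        assembly, gene = four_exon_gene()
        adjacency = build_exon_comb_kb([gene])
        pairs = eeth_candidate_pairs(gene, adjacency)
        assert [(a.exon_id, b.exon_id) for a, b in pairs] == [
            ("G1.E1", "G1.E3"), ("G1.E1", "G1.E4"), ("G1.E2", "G1.E4")]
        regions = gen_eeth_regions(gene, adjacency, assembly)
        assert len(regions) <= 9

    def test_two_exon_gene_has_none(self):
        assembly, gene = two_exon_gene("ATGGCA", "TTTTTT", "GGGCCC")
        adjacency = build_exon_comb_kb([gene])
        assert gen_eeth_regions(gene, adjacency, assembly) == []

    def test_overlapping_alternative_exons_excluded(self):
        assembly = GenomeAssembly({"chr1": "ACG" * 30})
        e1a = CodingExon("e1a", "G1", "chr1", 1, 9, "+", 0)
        e1b = CodingExon("e1b", "G1", "chr1", 4, 12, "+", 0)
        e2 = CodingExon("e2", "G1", "chr1", 30, 38, "+", 0)
        gene = GeneModel("G1", "G1", "chr1", "+", [e1a, e1b, e2],
                         {"T1": ["e1a", "e2"], "T2": ["e1b", "e2"]}, ["P1"])
        pairs = eeth_candidate_pairs(gene, build_exon_comb_kb([gene]))
        assert ("e1a", "e1b") not in [(a.exon_id, b.exon_id) for a, b in pairs]
        assert pairs == []  # both non-overlapping pairs are annotated


class TestGenerateAll:
    def test_empty_input(self):
        regions, log = generate_all([], AdjacencyKB(set()), GenomeAssembly({"c": "A"}))
        assert regions == [] and log.entries == []

    def test_stop_free_gene_counts(self):
        # no T anywhere -> no stop in any frame -> every candidate survives
        assembly, gene = four_exon_gene()
        adjacency = build_exon_comb_kb([gene])
        regions, log = generate_all([gene], adjacency, assembly)
        counts = {}
        for r in regions:
            counts[r.region_type] = counts.get(r.region_type, 0) + 1
        assert counts == {"EXON_KB": 4, "E_E_KB": 3, "E_I_TH": 9,
                          "I_E_TH": 9, "E_E_TH": 9}
        assert log.entries == []

    def test_serial_ids_and_determinism(self):
        assembly, gene = four_exon_gene(seed=7)
        adjacency = build_exon_comb_kb([gene])
        r1, _ = generate_all([gene], adjacency, assembly)
        r2, _ = generate_all([gene], adjacency, assembly)
        assert [r.region_id for r in r1] == [f"REG{i:09d}" for i in range(1, len(r1) + 1)]
        assert r1 == r2

    def test_enabled_types_respected(self):
        assembly, gene = four_exon_gene()
        adjacency = build_exon_comb_kb([gene])
        config = RegionConfig(enabled_region_types=("EXON_KB", "E_E_KB"))
        regions, _ = generate_all([gene], adjacency, assembly, config)
        assert {r.region_type for r in regions} == {"EXON_KB", "E_E_KB"}

    def test_min_peptide_len(self):
        assembly, gene = four_exon_gene()
        adjacency = build_exon_comb_kb([gene])
        config = RegionConfig(min_peptide_len=4)
        regions, log = generate_all([gene], adjacency, assembly, config)
        assert all(len(r.wild_peptide) >= 4 for r in regions)


class TestInvariants:
    def test_junction_cdna_bounded_and_exon_cdna_exact(self):
        assembly, gene = four_exon_gene(seed=3)
        adjacency = build_exon_comb_kb([gene])
        regions, _ = generate_all([gene], adjacency, assembly)
        for r in regions:
            if r.region_type == "EXON_KB":
                exon = next(e for e in gene.exons
                            if (e.start, e.end) == (r.segments[0].start, r.segments[0].end))
                assert len(r.cdna) == exon.length
            else:
                assert len(r.cdna) <= 240

    def test_no_stop_or_x_in_wild_peptides(self, stop_free_fixture):
        fx = stop_free_fixture
        adjacency = build_exon_comb_kb(fx.genes)
        regions, _ = generate_all(fx.genes, adjacency, fx.assembly)
        for r in regions:
            assert "*" not in r.wild_peptide and "X" not in r.wild_peptide

    def test_cdna_equals_concatenated_segments(self, stop_free_fixture):
        from splicepep.genome_model import extract_oriented

        fx = stop_free_fixture
        adjacency = build_exon_comb_kb(fx.genes)
        regions, _ = generate_all(fx.genes, adjacency, fx.assembly)
        for r in regions:
            joined = "".join(
                extract_oriented(fx.assembly, s.chrom, s.start, s.end, s.strand)
                for s in r.segments)
            assert r.cdna == joined
            if r.junction_offset is not None:
                assert r.junction_offset == r.segments[0].length


def test_estimate_peptide_orf_beyond_cdna():
    assert estimate_peptide("AT", 2, "EXON_KB", None) == (None, "too_short")
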