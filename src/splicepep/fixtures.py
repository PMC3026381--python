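"""Synthetic genome / annotation / SNP fixtures with known ground truth, and
an independent brute-force oracle for the region-enumeration rules.

``build_fixture`` constructs everything in memory; ``make_genome`` writes the
same content as standard-format files (FASTA / GFF3 / VCF / JSON truth /
protein FASTA). Both are pure functions of the config, so the same seed
always reproduces identical output.

The oracle (:func:`oracle_enumerate`, :func:`oracle_estimate`) re-applies the
generation protocols literally using Biopython primitives and shares no code
with :mod:`splicepep.region_gen`; fixture SNP consequences are likewise
classified at plant time by local translation, independent of
:mod:`splicepep.snp_variants`.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Dict, List, Optional, Sequence, Set, Tuple

from Bio.Seq import Seq

from .genome_model import (
    AdjacencyKB,
    CodingExon,
    GeneModel,
    GenomeAssembly,
    SNPRecord,
)

_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class FixtureConfig:
    n_genes: int = 1
    exons_per_gene: Tuple[int, int] = (2, 5)
    exon_len: Tuple[int, int] = (9, 60)
    intron_len: Tuple[int, int] = (12, 90)
    minus_strand_prob: float = 0.5
    stop_free: bool = True
    snps_per_gene: int = 2
    cassette: bool = False          # add a skip-transcript around a middle exon
    pad: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exon_len[0] < 3 or self.intron_len[0] < 1:
            raise ValueError("infeasible fixture config: lengths too short")
        if self.cassette and self.exons_per_gene[0] < 3:
            raise ValueError("cassette fixtures need >= 3 exons per gene")


@dataclass
class FixtureTruth:
    seed: int
    config: dict
    genes: Dict[str, dict] = field(default_factory=dict)
    snps: List[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "config": self.config,
             "genes": self.genes, "snps": self.snps},
            indent=2, sort_keys=True)


@dataclass
class Fixture:
    assembly: GenomeAssembly
    genes: List[GeneModel]
    snps: List[SNPRecord]
    proteins: Dict[str, str]
    truth: FixtureTruth


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_cds(rng: random.Random, length: int, stop_free: bool) -> str:
    if stop_free:
        n_codons = -(-length // 3)
        return "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons))[:length]
    return "".join(rng.choice("ACGT") for _ in range(length))


def _classify_snp(exon_seq: str, phase: int, local_idx: int, alt_local: str) -> Tuple[str, str, str]:
    """Consequence of substituting ``alt_local`` at ``local_idx`` of an exon's
    transcription-oriented sequence, relative to that exon's own peptide.

    Returns (consequence, ref_aa, alt_aa) with consequence in
    {synonymous, nonsynonymous, stop_internal, stop_terminal}.
    """
    if local_idx < phase:
        return "synonymous", "-", "-"
    codon_idx = (local_idx - phase) // 3
    cs = phase + 3 * codon_idx
    codon = exon_seq[cs:cs + 3]
    if len(codon) < 3:
        return "synonymous", "-", "-"  # dropped incomplete tail
    within = local_idx - cs
    mutated = codon[:within] + alt_local + codon[within + 1:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mutated).translate())
    if ref_aa == alt_aa:
        return "synonymous", ref_aa, alt_aa
    n_complete = (len(exon_seq) - phase) // 3
    if alt_aa == "*":
        kind = "stop_terminal" if codon_idx == n_complete - 1 else "stop_internal"
        return kind, ref_aa, alt_aa
    return "nonsynonymous", ref_aa, alt_aa


def build_fixture(config: FixtureConfig) -> Fixture:
    """Generate genes with chained CDS phases, one chromosome per gene, SNPs
    with plant-time consequence classification, and per-transcript proteins."""
    rng = random.Random(config.seed)
    sequences: Dict[str, str] = {}
    genes: List[GeneModel] = []
    snps: List[SNPRecord] = []
    proteins: Dict[str, str] = {}
    truth = FixtureTruth(seed=config.seed, config={
        "n_genes": config.n_genes,
        "exons_per_gene": list(config.exons_per_gene),
        "exon_len": list(config.exon_len),
        "intron_len": list(config.intron_len),
        "stop_free": config.stop_free,
        "cassette": config.cassette,
    })

    for gi in range(config.n_genes):
        gene_id = f"G{gi + 1}"
        chrom = f"chr{gi + 1}"
        strand = "-" if rng.random() < config.minus_strand_prob else "+"
        n = rng.randint(*config.exons_per_gene)

        exon_lens = [rng.randint(*config.exon_len) for _ in range(n)]
        cassette_idx: Optional[int] = None
        if config.cassette:
            cassette_idx = n // 2
            exon_lens[cassette_idx] -= exon_lens[cassette_idx] % 3
            if exon_lens[cassette_idx] < 3:
                exon_lens[cassette_idx] = 3
        intron_lens = [rng.randint(*config.intron_len) for _ in range(n - 1)]

        cds = _random_cds(rng, sum(exon_lens), config.stop_free)
        exon_seqs: List[str] = []
        pos = 0
        for length in exon_lens:
            exon_seqs.append(cds[pos:pos + length])
            pos += length
        intron_seqs = ["".join(rng.choice("ACGT") for _ in range(length))
                       for length in intron_lens]

        phases = [0]
        for length in exon_lens[:-1]:
            phases.append((3 - ((length - phases[-1]) % 3)) % 3)

        # transcription-oriented gene region and 1-based offsets within it
        region_parts: List[str] = []
        exon_tx_start: List[int] = []  # 1-based within region
        cursor = 1
        for j in range(n):
            exon_tx_start.append(cursor)
            region_parts.append(exon_seqs[j])
            cursor += exon_lens[j]
            if j < n - 1:
                region_parts.append(intron_seqs[j])
                cursor += intron_lens[j]
        region = "".join(region_parts)
        m = len(region)

        pad5 = "".join(rng.choice("ACGT") for _ in range(config.pad))
        pad3 = "".join(rng.choice("ACGT") for _ in range(config.pad))
        if strand == "+":
            sequences[chrom] = pad5 + region + pad3
        else:
            sequences[chrom] = pad5 + _revcomp(region) + pad3

        def genomic_interval(tx_start: int, length: int) -> Tuple[int, int]:
            t1, t2 = tx_start, tx_start + length - 1
            if strand == "+":
                return config.pad + t1, config.pad + t2
            return config.pad + (m - t2) + 1, config.pad + (m - t1) + 1

        exons: List[CodingExon] = []
        for j in range(n):
            start, end = genomic_interval(exon_tx_start[j], exon_lens[j])
            exons.append(CodingExon(
                exon_id=f"{gene_id}.E{j + 1}",
                gene_id=gene_id, chrom=chrom, start=start, end=end,
                strand=strand, frame_offset=phases[j],
            ))

        transcripts: Dict[str, List[str]] = {"T1": [e.exon_id for e in exons]}
        if cassette_idx is not None:
            transcripts["T2"] = [e.exon_id for j, e in enumerate(exons) if j != cassette_idx]

        protein_ids = []
        for tx_id, exon_ids in sorted(transcripts.items()):
            idx = {e.exon_id: j for j, e in enumerate(exons)}
            spliced = "".join(exon_seqs[idx[eid]] for eid in exon_ids)
            spliced = spliced[: len(spliced) - len(spliced) % 3]
            prot = str(Seq(spliced).translate()).rstrip("*")
            pid = f"{gene_id}_{tx_id}"
            proteins[pid] = prot
            protein_ids.append(pid)

        genes.append(GeneModel(
            gene_id=gene_id, symbol=gene_id, chrom=chrom, strand=strand,
            exons=exons, transcripts=transcripts, protein_ids=protein_ids,
        ))

        # plant SNPs with independent consequence classification
        used_positions: Set[int] = set()
        for si in range(config.snps_per_gene):
            for _ in range(50):  # re-draw until a usable site is found
                j = rng.randrange(n)
                li = rng.randrange(exon_lens[j])
                cons = _classify_snp(exon_seqs[j], phases[j], li, "A")
                # avoid sites whose wild codon is a stop (possible when not stop_free)
                if cons[1] == "*":
                    continue
                ref_local = exon_seqs[j][li]
                alt_local = rng.choice([b for b in "ACGT" if b != ref_local])
                if strand == "+":
                    pos_g = exons[j].start + li
                    ref_fwd, alt_fwd = ref_local, alt_local
                else:
                    pos_g = exons[j].end - li
                    ref_fwd = ref_local.translate(_COMPLEMENT)
                    alt_fwd = alt_local.translate(_COMPLEMENT)
                if pos_g in used_positions:
                    continue
                used_positions.add(pos_g)
                consequence, ref_aa, alt_aa = _classify_snp(
                    exon_seqs[j], phases[j], li, alt_local)
                snp_id = f"rs{gi + 1}{si + 1:03d}"
                snps.append(SNPRecord(snp_id, chrom, pos_g, ref_fwd, (alt_fwd,)))
                truth.snps.append({
                    "snp_id": snp_id, "gene_id": gene_id,
                    "exon_id": exons[j].exon_id, "chrom": chrom, "pos": pos_g,
                    "ref": ref_fwd, "alt": alt_fwd, "consequence": consequence,
                    "ref_aa": ref_aa, "alt_aa": alt_aa,
                })
                break

        adjacency_pairs = set()
        for exon_ids in transcripts.values():
            adjacency_pairs.update(zip(exon_ids, exon_ids[1:]))
        truth.genes[gene_id] = {
            "n_exons": n,
            "strand": strand,
            "cassette_exon": exons[cassette_idx].exon_id if cassette_idx is not None else None,
            "candidate_counts": {
                "EXON_KB": n,
                "E_E_KB": len(adjacency_pairs),
                "E_I_TH": 3 * (n - 1),
                "I_E_TH": 3 * (n - 1),
                "E_E_TH": 3 * (comb(n, 2) - len(adjacency_pairs)),
            },
        }

    snps.sort(key=lambda s: (s.chrom, s.pos, s.snp_id))
    return Fixture(GenomeAssembly(sequences), genes, snps, proteins, truth)


# ---------------------------------------------------------------------------
# File writers (same dialects genome_model reads back)
# ---------------------------------------------------------------------------

def _write_fasta(path: str, records: Dict[str, str], width: int = 60) -> None:
    with open(path, "wt") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(fixture: Fixture, path: str) -> None:
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for gene in fixture.genes:
            for tx_id in sorted(gene.transcripts):
                pid = f"{gene.gene_id}_{tx_id}"
                for exon_id in gene.transcripts[tx_id]:
                    exon = gene.exon_by_id(exon_id)
                    attrs = (f"ID=cds-{tx_id}-{exon_id};gene_id={gene.gene_id};"
                             f"transcript_id={tx_id};gene_name={gene.symbol};"
                             f"protein_id={pid}")
                    fh.write("\t".join([
                        gene.chrom, "splicepep_sim", "CDS",
                        str(exon.start), str(exon.end), ".", gene.strand,
                        str(exon.frame_offset), attrs,
                    ]) + "\n")


def write_vcf(fixture: Fixture, path: str) -> None:
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in fixture.assembly.sequences:
            fh.write(f"##contig=<ID={chrom},length={fixture.assembly.length(chrom)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        # merge alleles of the same snp_id/position into one record
        merged: Dict[Tuple[str, int, str, str], List[str]] = {}
        for snp in fixture.snps:
            key = (snp.chrom, snp.pos, snp.snp_id, snp.ref)
            merged.setdefault(key, []).extend(snp.alts)
        for (chrom, pos, snp_id, ref), alts in sorted(merged.items()):
            fh.write(f"{chrom}\t{pos}\t{snp_id}\t{ref}\t{','.join(alts)}\t.\t.\t.\n")


def make_genome(config: FixtureConfig, outdir: str) -> Dict[str, str]:
    """Build a fixture and write genome.fasta, annotation.gff3, snps.vcf,
    proteins.fasta and truth.json under ``outdir``. Returns the path map."""
    import os

    fixture = build_fixture(config)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fasta"),
        "annotation": os.path.join(outdir, "annotation.gff3"),
        "vcf": os.path.join(outdir, "snps.vcf"),
        "proteins": os.path.join(outdir, "proteins.fasta"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    _write_fasta(paths["genome"], fixture.assembly.sequences)
    write_gff3(fixture, paths["annotation"])
    write_vcf(fixture, paths["vcf"])
    _write_fasta(paths["proteins"], fixture.proteins)
    with open(paths["truth"], "wt") as fh:
        fh.write(fixture.truth.to_json() + "\n")
    return paths


# ---------------------------------------------------------------------------
# Independent brute-force oracle
# ---------------------------------------------------------------------------

RegionKey = Tuple[str, Tuple[Tuple[str, int, int, str], ...], int, str]


def oracle_estimate(cdna: str, orf: int, mode: str, junction: Optional[int],
                    min_len: int = 1) -> Optional[str]:
    """Literal re-application of the per-type peptide estimation protocol.

    ``mode`` is "strict" (no stop tolerated except a stripped terminal one)
    or "tolerant" (a stop reaching the 3' segment truncates; a stop wholly in
    the 5' segment is fatal).
    """
    if orf >= len(cdna):
        return None
    codons = [cdna[i:i + 3] for i in range(orf, len(cdna) - 2, 3)]
    if not codons:
        return None
    aas = [str(Seq(c).translate()) for c in codons]
    residues: List[str] = []
    if mode == "strict":
        for k, aa in enumerate(aas):
            if aa == "*":
                if k == len(aas) - 1:
                    break
                return None
            residues.append(aa)
    elif mode == "tolerant":
        for k, aa in enumerate(aas):
            if aa == "*":
                codon_last_base = orf + 3 * k + 2
                if codon_last_base < junction:
                    return None
                break
            residues.append(aa)
    else:
        raise ValueError(mode)
    peptide = "".join(residues)
    if "X" in peptide:
        return None
    if junction is not None:
        if not peptide:
            return None
        first_base = orf
        last_base = orf + 3 * len(peptide) - 1
        if not (first_base < junction and last_base >= junction):
            return None
    if len(peptide) < max(1, min_len):
        return None
    return peptide


def _oracle_fetch(assembly: GenomeAssembly, chrom: str, start: int, end: int,
                  strand: str) -> str:
    sub = assembly[chrom][start - 1:end]
    return sub if strand == "+" else str(Seq(sub).reverse_complement())


def oracle_enumerate(gene: GeneModel, assembly: GenomeAssembly,
                     flank_nt: int = 120, min_peptide_len: int = 1) -> Set[RegionKey]:
    """Exhaustively enumerate all valid regions of one gene by brute force.

    Returns a set of (region_type, ((chrom, start, end, strand), ...), orf,
    peptide) keys for direct comparison with the main pipeline's output.
    """
    out: Set[RegionKey] = set()
    strand = gene.strand
    chrom = gene.chrom
    n = len(gene.exons)

    adjacency: Set[Tuple[str, str]] = set()
    for exon_ids in gene.transcripts.values():
        adjacency.update(zip(exon_ids, exon_ids[1:]))

    def tail(start: int, end: int, take: int) -> Tuple[int, int]:
        return (end - take + 1, end) if strand == "+" else (start, start + take - 1)

    def head(start: int, end: int, take: int) -> Tuple[int, int]:
        return (start, start + take - 1) if strand == "+" else (end - take + 1, end)

    # EXON_KB
    for exon in gene.exons:
        pep = oracle_estimate(
            _oracle_fetch(assembly, chrom, exon.start, exon.end, strand),
            exon.frame_offset, "strict", None, min_peptide_len)
        if pep is not None:
            out.add(("EXON_KB", ((chrom, exon.start, exon.end, strand),),
                     exon.frame_offset, pep))

    by_id = {e.exon_id: e for e in gene.exons}

    def junction_region(rtype: str, e5_iv: Tuple[int, int], e3_iv: Tuple[int, int],
                        take5: int, take3: int, orfs: Sequence[int], mode: str) -> None:
        s5 = tail(e5_iv[0], e5_iv[1], take5)
        s3 = head(e3_iv[0], e3_iv[1], take3)
        cdna = (_oracle_fetch(assembly, chrom, s5[0], s5[1], strand)
                + _oracle_fetch(assembly, chrom, s3[0], s3[1], strand))
        for orf in orfs:
            pep = oracle_estimate(cdna, orf, mode, take5, min_peptide_len)
            if pep is not None:
                out.add((rtype, ((chrom, s5[0], s5[1], strand),
                                 (chrom, s3[0], s3[1], strand)), orf, pep))

    # E_E_KB (annotated adjacencies, frame carried from 5' exon)
    for a_id, b_id in adjacency:
        a, b = by_id[a_id], by_id[b_id]
        take5 = min(flank_nt, a.end - a.start + 1)
        take3 = min(flank_nt, b.end - b.start + 1)
        trim = (a.end - a.start + 1) - take5
        orf = (a.frame_offset - trim) % 3
        junction_region("E_E_KB", (a.start, a.end), (b.start, b.end),
                        take5, take3, [orf], "strict")

    # introns between transcription-consecutive gene-level exons
    for i in range(n - 1):
        e5, e3 = gene.exons[i], gene.exons[i + 1]
        if strand == "+":
            ia, ib = e5.end + 1, e3.start - 1
        else:
            ia, ib = e3.end + 1, e5.start - 1
        if ia > ib:
            continue
        ilen = ib - ia + 1
        # E_I_TH: exon tail + intron head, three frames, tolerant
        junction_region("E_I_TH", (e5.start, e5.end), (ia, ib),
                        min(flank_nt, e5.end - e5.start + 1), min(flank_nt, ilen),
                        [0, 1, 2], "tolerant")
        # I_E_TH: intron tail + exon head, three frames, strict
        junction_region("I_E_TH", (ia, ib), (e3.start, e3.end),
                        min(flank_nt, ilen), min(flank_nt, e3.end - e3.start + 1),
                        [0, 1, 2], "strict")

    # E_E_TH: unannotated, non-overlapping ordered pairs, three frames, tolerant
    for i, j in combinations(range(n), 2):
        a, b = gene.exons[i], gene.exons[j]
        if a.start <= b.end and b.start <= a.end:
            continue
        if (a.exon_id, b.exon_id) in adjacency:
            continue
        junction_region("E_E_TH", (a.start, a.end), (b.start, b.end),
                        min(flank_nt, a.end - a.start + 1),
                        min(flank_nt, b.end - b.start + 1),
                        [0, 1, 2], "tolerant")
    return out


def region_key(region) -> RegionKey:
    """Comparison key matching :func:`oracle_enumerate` output."""
    return (
        region.region_type,
        tuple((s.chrom, s.start, s.end, s.strand) for s in region.segments),
        region.orf,
        region.wild_peptide,
    )
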