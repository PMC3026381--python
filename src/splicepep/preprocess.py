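"""Pre-processing: coding-gene filter, exon knowledgebase, exon-adjacency
knowledgebase, and the exonic-SNP filter."""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

from .genome_model import AdjacencyKB, CodingExon, GeneModel, GenomeAssembly, SNPRecord

log = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    genes_in: int = 0
    genes_coding: int = 0
    snps_in: int = 0
    snps_exonic: int = 0


def read_protein_map(path: str) -> Dict[str, List[str]]:
    """Read a two-column (gene_id, protein_id) TSV into a gene->proteins map."""
    mapping: Dict[str, List[str]] = {}
    with open(path, "rt", newline="") as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#") or len(row) < 2:
                continue
            mapping.setdefault(row[0], [])
            if row[1] not in mapping[row[0]]:
                mapping[row[0]].append(row[1])
    return mapping


def filter_coding_genes(genes: List[GeneModel],
                        protein_map: Optional[Dict[str, List[str]]] = None,
                        report: Optional[PreprocessReport] = None) -> List[GeneModel]:
    """Keep genes mapped to at least one protein; genes without any protein
    mapping are treated as non-coding and dropped. Order is preserved.

    A gene qualifies through its own ``protein_ids`` or through an entry in
    the optional gene->protein table (the table augments absent attributes).
    """
    kept: List[GeneModel] = []
    for gene in genes:
        proteins = list(gene.protein_ids)
        if protein_map and gene.gene_id in protein_map:
            for pid in protein_map[gene.gene_id]:
                if pid not in proteins:
                    proteins.append(pid)
        if proteins:
            if proteins != gene.protein_ids:
                gene.protein_ids = proteins
            kept.append(gene)
    if report is not None:
        report.genes_in = len(genes)
        report.genes_coding = len(kept)
    if not kept:
        log.warning("filter_coding_genes: no coding genes remain")
    return kept


def build_exon_kb(genes: List[GeneModel]) -> List[CodingExon]:
    """All distinct coding exons across genes in deterministic order
    (chrom, start, end, strand, gene_id)."""
    seen: Set[Tuple[str, int, int, str, str, int]] = set()
    exons: List[CodingExon] = []
    for gene in genes:
        for exon in gene.exons:
            key = (exon.chrom, exon.start, exon.end, exon.strand, exon.gene_id, exon.frame_offset)
            if key not in seen:
                seen.add(key)
                exons.append(exon)
    exons.sort(key=lambda e: (e.chrom, e.start, e.end, e.strand, e.gene_id))
    return exons


def build_exon_comb_kb(genes: List[GeneModel]) -> AdjacencyKB:
    """The set of consecutive (5' exon, 3' exon) pairs over all transcripts."""
    pairs: Set[Tuple[str, str]] = set()
    for gene in genes:
        for exon_ids in gene.transcripts.values():
            for a, b in zip(exon_ids, exon_ids[1:]):
                pairs.add((a, b))
    return AdjacencyKB(pairs)


def filter_exonic_snps(snps: List[SNPRecord], exon_kb: List[CodingExon],
                       assembly: Optional[GenomeAssembly] = None,
                       report: Optional[PreprocessReport] = None) -> List[SNPRecord]:
    """Keep SNPs whose position falls within at least one coding exon
    (boundaries inclusive).

    If *assembly* is given, a SNP whose ref allele disagrees with the genome
    base at its position is kept but flagged with a warning — variation and
    assembly releases can disagree, and variant application substitutes the
    alt allele regardless.
    """
    by_chrom: Dict[str, List[CodingExon]] = {}
    for exon in exon_kb:
        by_chrom.setdefault(exon.chrom, []).append(exon)

    kept: List[SNPRecord] = []
    for snp in snps:
        exons = by_chrom.get(snp.chrom, ())
        if any(e.start <= snp.pos <= e.end for e in exons):
            if assembly is not None and snp.chrom in assembly:
                genome_base = assembly[snp.chrom][snp.pos - 1]
                if genome_base != snp.ref:
                    log.warning(
                        "SNP %s: ref allele %s disagrees with genome base %s at %s:%d (kept)",
                        snp.snp_id, snp.ref, genome_base, snp.chrom, snp.pos,
                    )
            kept.append(snp)
    if report is not None:
        report.snps_in = len(snps)
        report.snps_exonic = len(kept)
    return kept
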