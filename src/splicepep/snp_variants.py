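"""Insertion of exonic SNPs into wild-type region cDNA and generation of
single-SNP variant peptides with peptide-SNP links."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .genome_model import SNPRecord, translate
from .region_gen import PeptideRegion, estimate_peptide

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_EXON_ROLES = {"exon", "exon5", "exon3"}


@dataclass(frozen=True)
class PeptideSNPLink:
    snp_id: str
    local_pos: int        # 1-based position within the region cDNA
    genomic_pos: int
    ref_base_local: str   # region orientation
    alt_base_local: str
    aa_pos: int           # 1-based residue position within the peptide
    ref_aa: str
    alt_aa: str


@dataclass
class PeptideEntry:
    peptide_id: str
    region_id: str
    sequence: str
    is_wild_type: bool
    snp_links: Tuple[PeptideSNPLink, ...] = ()


@dataclass(frozen=True)
class Placement:
    """A SNP allele positioned within a region's cDNA (region orientation)."""

    snp_id: str
    local_pos: int  # 1-based
    genomic_pos: int
    ref_base_local: str
    alt_base_local: str


def _complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def place_snps(region: PeptideRegion, snps: Iterable[SNPRecord]) -> List[Placement]:
    """Locate SNPs within the exon-role segments of a region.

    Returns one placement per (SNP, alt allele) whose genomic position falls
    inside an exon segment; intron segments never receive placements. For
    minus-strand regions the alleles are complemented into region orientation.
    Placements are ordered by (local position, alt base).
    """
    placements: List[Placement] = []
    offsets: List[int] = []
    cum = 0
    for seg in region.segments:
        offsets.append(cum)
        cum += seg.length
    for snp in snps:
        for seg, offset in zip(region.segments, offsets):
            if seg.role not in _EXON_ROLES:
                continue
            if snp.chrom != seg.chrom or not (seg.start <= snp.pos <= seg.end):
                continue
            if seg.strand == "+":
                local0 = offset + (snp.pos - seg.start)
                ref_local, alts_local = snp.ref, snp.alts
            else:
                local0 = offset + (seg.end - snp.pos)
                ref_local = _complement(snp.ref)
                alts_local = tuple(_complement(a) for a in snp.alts)
            for alt in alts_local:
                placements.append(Placement(snp.snp_id, local0 + 1, snp.pos, ref_local, alt))
            break
    placements.sort(key=lambda p: (p.local_pos, p.alt_base_local, p.snp_id))
    return placements


def apply_snp(region: PeptideRegion, placement: Placement):
    """Substitute one SNP allele into the region cDNA and re-run the region's
    peptide-estimation protocol.

    Returns a :class:`PeptideEntry` (peptide_id unassigned) or a rejection
    reason string in {"synonymous", "invalid_peptide"}.
    """
    i = placement.local_pos - 1
    if not (0 <= i < len(region.cdna)):
        raise ValueError(f"placement position {placement.local_pos} outside region cDNA")
    if region.cdna[i] != placement.ref_base_local:
        log.warning(
            "SNP %s: cDNA base %s at local pos %d of %s differs from expected ref %s; substituting anyway",
            placement.snp_id, region.cdna[i], placement.local_pos, region.region_id,
            placement.ref_base_local,
        )
    variant_cdna = region.cdna[:i] + placement.alt_base_local + region.cdna[i + 1:]
    peptide, reason = estimate_peptide(variant_cdna, region.orf, region.region_type,
                                       region.junction_offset)
    if peptide is None:
        return "invalid_peptide"
    if peptide == region.wild_peptide:
        return "synonymous"

    codon_idx = (i - region.orf) // 3 if i >= region.orf else -1
    ref_aa = alt_aa = "-"
    if codon_idx >= 0:
        ref_full = translate(region.cdna, region.orf)
        alt_full = translate(variant_cdna, region.orf)
        if codon_idx < len(ref_full):
            ref_aa = ref_full[codon_idx]
            alt_aa = alt_full[codon_idx]
    link = PeptideSNPLink(
        snp_id=placement.snp_id,
        local_pos=placement.local_pos,
        genomic_pos=placement.genomic_pos,
        ref_base_local=placement.ref_base_local,
        alt_base_local=placement.alt_base_local,
        aa_pos=codon_idx + 1,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )
    return PeptideEntry("", region.region_id, peptide, is_wild_type=False, snp_links=(link,))


def generate_peptides(regions: List[PeptideRegion], snps: List[SNPRecord],
                      include_snps: bool = True) -> List[PeptideEntry]:
    """Emit one wild-type peptide per region plus, when ``include_snps``, one
    variant peptide per surviving (SNP, alt) placement.

    Peptide ids are serial from PEP000000001 in region order, wild type first,
    then variants ordered by (local position, alt base).
    """
    by_chrom: Dict[str, List[SNPRecord]] = {}
    for snp in snps:
        by_chrom.setdefault(snp.chrom, []).append(snp)

    entries: List[PeptideEntry] = []
    n_synonymous = n_invalid = 0
    for region in regions:
        entries.append(PeptideEntry("", region.region_id, region.wild_peptide, True))
        if not include_snps:
            continue
        for placement in place_snps(region, by_chrom.get(region.chrom, ())):
            result = apply_snp(region, placement)
            if isinstance(result, PeptideEntry):
                entries.append(result)
            elif result == "synonymous":
                n_synonymous += 1
            else:
                n_invalid += 1
    for i, entry in enumerate(entries, start=1):
        entry.peptide_id = f"PEP{i:09d}"
    if include_snps:
        log.info("variant peptides: %d kept, %d synonymous, %d invalid",
                 sum(1 for e in entries if not e.is_wild_type), n_synonymous, n_invalid)
    return entries


def snp_map_rows(entries: Iterable[PeptideEntry]) -> List[Tuple[str, str, int, int, str, str]]:
    """Flatten peptide-SNP links into TSV-ready rows
    (peptide_id, snp_id, local_pos, genomic_pos, nt_change, aa_change)."""
    rows = []
    for entry in entries:
        for link in entry.snp_links:
            nt_change = f"{link.ref_base_local}>{link.alt_base_local}"
            aa_change = f"{link.ref_aa}{link.aa_pos}{link.alt_aa}"
            rows.append((entry.peptide_id, link.snp_id, link.local_pos,
                         link.genomic_pos, nt_change, aa_change))
    return rows
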