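"""Peptide-region enumeration.

Five region types are generated per gene:

========  =============================================  ==========  =====================
type      source                                         cDNA        frames
========  =============================================  ==========  =====================
EXON_KB   each coding exon                               full exon   annotated frame only
E_E_KB    annotated exon-exon adjacencies                <= 240 bp   annotated frame only
E_I_TH    exon + immediately downstream intron           <= 240 bp   all three
I_E_TH    immediately upstream intron + exon             <= 240 bp   all three
E_E_TH    unannotated, non-overlapping exon pairs        <= 240 bp   all three
========  =============================================  ==========  =====================

Junction cDNAs take at most ``flank_nt`` (default 120) bases on each side of
the splice site; shorter segments contribute their full sequence.

Stop-codon protocol:

* EXON_KB, E_E_KB, I_E_TH — a stop anywhere but the final complete codon
  invalidates the candidate; a final stop is stripped and the region kept.
* E_I_TH, E_E_TH — a stop whose codon lies wholly in the 5' segment
  invalidates the frame; a stop whose codon has at least one base in the 3'
  segment truncates the peptide there.

After stop handling, a junction region whose peptide no longer covers at
least one residue on each side of the splice site is rejected — a
non-crossing remnant would only duplicate EXON_KB content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .genome_model import (
    AdjacencyKB,
    CodingExon,
    GeneModel,
    GenomeAssembly,
    extract_oriented,
    translate,
)

log = logging.getLogger(__name__)

REGION_TYPES = ("EXON_KB", "E_E_KB", "E_I_TH", "I_E_TH", "E_E_TH")
_TYPE_RANK = {t: i for i, t in enumerate(REGION_TYPES)}

# region types whose stop protocol tolerates (truncating) stops in the 3' segment
_TOLERATES_3PRIME_STOP = {"E_I_TH", "E_E_TH"}


@dataclass(frozen=True)
class Segment:
    """One oriented genomic piece of a region, in transcription order."""

    chrom: str
    start: int
    end: int
    strand: str
    role: str  # exon | exon5 | exon3 | intron5 | intron3

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PeptideRegion:
    region_id: str
    gene_id: str
    region_type: str
    segments: Tuple[Segment, ...]
    orf: int
    cdna: str
    wild_peptide: str
    junction_offset: Optional[int] = None  # 0-based cdna index of first 3' segment base

    @property
    def chrom(self) -> str:
        return self.segments[0].chrom

    @property
    def strand(self) -> str:
        return self.segments[0].strand


@dataclass(frozen=True)
class Rejection:
    gene_id: str
    region_type: str
    descriptor: str
    orf: int
    reason: str


@dataclass
class RejectionLog:
    entries: List[Rejection] = field(default_factory=list)

    def add(self, gene_id: str, region_type: str, descriptor: str, orf: int, reason: str) -> None:
        self.entries.append(Rejection(gene_id, region_type, descriptor, orf, reason))

    def counts_by_type(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for entry in self.entries:
            out[entry.region_type] = out.get(entry.region_type, 0) + 1
        return out

    def write_tsv(self, path: str) -> None:
        with open(path, "wt") as fh:
            fh.write("gene_id\tregion_type\tcandidate\torf\treason\n")
            for e in self.entries:
                fh.write(f"{e.gene_id}\t{e.region_type}\t{e.descriptor}\t{e.orf}\t{e.reason}\n")


@dataclass
class RegionConfig:
    flank_nt: int = 120
    min_peptide_len: int = 1
    enabled_region_types: Tuple[str, ...] = REGION_TYPES

    def __post_init__(self) -> None:
        for t in self.enabled_region_types:
            if t not in REGION_TYPES:
                raise ValueError(f"unknown region type {t!r}")


# ---------------------------------------------------------------------------
# Frame arithmetic
# ---------------------------------------------------------------------------

def segment_frame_offset(exon_frame: int, trim: int) -> int:
    """Bases to skip at the start of a segment that begins ``trim`` bases into
    an exon whose own frame offset is ``exon_frame``, so that codons realign
    with the annotated reading frame."""
    return (exon_frame - trim) % 3


# ---------------------------------------------------------------------------
# Peptide estimation protocol
# ---------------------------------------------------------------------------

def estimate_peptide(cdna: str, orf: int, region_type: str,
                     junction_offset: Optional[int],
                     min_peptide_len: int = 1) -> Tuple[Optional[str], Optional[str]]:
    """Apply the region-type stop/validity protocol to ``translate(cdna, orf)``.

    Returns ``(peptide, None)`` on success or ``(None, reason)`` on rejection.
    Reasons: internal_stop, stop_in_5prime_segment, junction_not_covered,
    ambiguous, too_short.
    """
    if orf >= len(cdna):
        return None, "too_short"
    aa = translate(cdna, orf)
    n = len(aa)

    if region_type in _TOLERATES_3PRIME_STOP:
        assert junction_offset is not None
        peptide = aa
        for k in range(n):
            if aa[k] == "*":
                codon_end = orf + 3 * k + 2
                if codon_end < junction_offset:
                    # stop codon wholly within the 5' segment
                    return None, "stop_in_5prime_segment"
                peptide = aa[:k]
                break
    else:
        internal = [k for k in range(n) if aa[k] == "*" and k != n - 1]
        if internal:
            return None, "internal_stop"
        peptide = aa[:-1] if aa.endswith("*") else aa

    if "X" in peptide:
        return None, "ambiguous"
    if junction_offset is not None:
        m = len(peptide)
        covers_5p = m >= 1 and orf < junction_offset
        covers_3p = m >= 1 and orf + 3 * m - 1 >= junction_offset
        if not (covers_5p and covers_3p):
            return None, "junction_not_covered"
    if len(peptide) < max(1, min_peptide_len):
        return None, "too_short"
    return peptide, None


# ---------------------------------------------------------------------------
# Segment construction helpers (transcription-oriented flanks)
# ---------------------------------------------------------------------------

def _tail_interval(start: int, end: int, strand: str, take: int) -> Tuple[int, int]:
    """Genomic interval of the last ``take`` bases in transcription orientation."""
    if strand == "+":
        return end - take + 1, end
    return start, start + take - 1


def _head_interval(start: int, end: int, strand: str, take: int) -> Tuple[int, int]:
    """Genomic interval of the first ``take`` bases in transcription orientation."""
    if strand == "+":
        return start, start + take - 1
    return end - take + 1, end


def _segment_seq(assembly: GenomeAssembly, seg: Segment) -> str:
    return extract_oriented(assembly, seg.chrom, seg.start, seg.end, seg.strand)


def intron_between(exon5: CodingExon, exon3: CodingExon) -> Optional[Tuple[int, int]]:
    """Genomic interval of the intron between two transcription-consecutive
    exons, or None when they abut or overlap."""
    if exon5.strand == "+":
        start, end = exon5.end + 1, exon3.start - 1
    else:
        start, end = exon3.end + 1, exon5.start - 1
    if start > end:
        return None
    return start, end


# ---------------------------------------------------------------------------
# Per-type generators. Each returns (regions, rejections) where region_ids
# are still unassigned (empty string).
# ---------------------------------------------------------------------------

def _reject(rejections: RejectionLog, gene_id: str, region_type: str,
            segments: Sequence[Segment], orf: int, reason: str) -> None:
    desc = ";".join(f"{s.role}:{s.chrom}:{s.start}-{s.end}({s.strand})" for s in segments)
    rejections.add(gene_id, region_type, desc, orf, reason)


def gen_exon_region(exon: CodingExon, assembly: GenomeAssembly,
                    config: RegionConfig = RegionConfig(),
                    rejections: Optional[RejectionLog] = None) -> Optional[PeptideRegion]:
    """EXON_KB: the whole exon translated in its annotated frame."""
    seg = Segment(exon.chrom, exon.start, exon.end, exon.strand, "exon")
    cdna = _segment_seq(assembly, seg)
    peptide, reason = estimate_peptide(cdna, exon.frame_offset, "EXON_KB", None,
                                       config.min_peptide_len)
    if peptide is None:
        if rejections is not None:
            _reject(rejections, exon.gene_id, "EXON_KB", [seg], exon.frame_offset, reason)
        return None
    return PeptideRegion("", exon.gene_id, "EXON_KB", (seg,), exon.frame_offset, cdna, peptide)


def _junction_segments(exon5: CodingExon, int5: Optional[Tuple[int, int]],
                       exon3: Optional[CodingExon], int3: Optional[Tuple[int, int]],
                       flank: int) -> Tuple[Segment, Segment]:
    """Build the (5' segment, 3' segment) pair for a junction region; exactly
    one of ``exon5``/``int5`` and one of ``exon3``/``int3`` must be given."""
    if exon5 is not None:
        strand = exon5.strand
        take5 = min(flank, exon5.length)
        s, e = _tail_interval(exon5.start, exon5.end, strand, take5)
        seg5 = Segment(exon5.chrom, s, e, strand, "exon5")
    else:
        a, b = int5
        strand = exon3.strand
        take5 = min(flank, b - a + 1)
        s, e = _tail_interval(a, b, strand, take5)
        seg5 = Segment(exon3.chrom, s, e, strand, "intron5")
    if exon3 is not None:
        take3 = min(flank, exon3.length)
        s, e = _head_interval(exon3.start, exon3.end, exon3.strand, take3)
        seg3 = Segment(exon3.chrom, s, e, exon3.strand, "exon3")
    else:
        a, b = int3
        take3 = min(flank, b - a + 1)
        s, e = _head_interval(a, b, strand, take3)
        seg3 = Segment(exon5.chrom, s, e, strand, "intron3")
    return seg5, seg3


def gen_eekb_region(pair: Tuple[CodingExon, CodingExon], assembly: GenomeAssembly,
                    config: RegionConfig = RegionConfig(),
                    rejections: Optional[RejectionLog] = None) -> Optional[PeptideRegion]:
    """E_E_KB: annotated exon-exon junction in the frame carried over from the
    5' exon's annotated ORF."""
    exon5, exon3 = pair
    seg5, seg3 = _junction_segments(exon5, None, exon3, None, config.flank_nt)
    trim = exon5.length - seg5.length
    orf = segment_frame_offset(exon5.frame_offset, trim)
    cdna = _segment_seq(assembly, seg5) + _segment_seq(assembly, seg3)
    junction = seg5.length
    peptide, reason = estimate_peptide(cdna, orf, "E_E_KB", junction, config.min_peptide_len)
    if peptide is None:
        if rejections is not None:
            _reject(rejections, exon5.gene_id, "E_E_KB", [seg5, seg3], orf, reason)
        return None
    return PeptideRegion("", exon5.gene_id, "E_E_KB", (seg5, seg3), orf, cdna, peptide,
                         junction_offset=junction)


def _three_frame_regions(gene_id: str, region_type: str, seg5: Segment, seg3: Segment,
                         assembly: GenomeAssembly, config: RegionConfig,
                         rejections: Optional[RejectionLog]) -> List[PeptideRegion]:
    cdna = _segment_seq(assembly, seg5) + _segment_seq(assembly, seg3)
    junction = seg5.length
    out: List[PeptideRegion] = []
    for orf in (0, 1, 2):
        peptide, reason = estimate_peptide(cdna, orf, region_type, junction,
                                           config.min_peptide_len)
        if peptide is None:
            if rejections is not None:
                _reject(rejections, gene_id, region_type, [seg5, seg3], orf, reason)
            continue
        out.append(PeptideRegion("", gene_id, region_type, (seg5, seg3), orf, cdna,
                                 peptide, junction_offset=junction))
    return out


def gen_eith_regions(exon: CodingExon, downstream_intron: Tuple[int, int],
                     assembly: GenomeAssembly, config: RegionConfig = RegionConfig(),
                     rejections: Optional[RejectionLog] = None) -> List[PeptideRegion]:
    """E_I_TH: exon tail + downstream-intron head, all three frames; intron
    stops truncate, exon stops reject."""
    seg5, seg3 = _junction_segments(exon, None, None, downstream_intron, config.flank_nt)
    return _three_frame_regions(exon.gene_id, "E_I_TH", seg5, seg3, assembly, config, rejections)


def gen_ieth_regions(upstream_intron: Tuple[int, int], exon: CodingExon,
                     assembly: GenomeAssembly, config: RegionConfig = RegionConfig(),
                     rejections: Optional[RejectionLog] = None) -> List[PeptideRegion]:
    """I_E_TH: upstream-intron tail + exon head, all three frames; no stop
    tolerated except a stripped terminal one."""
    seg5, seg3 = _junction_segments(None, upstream_intron, exon, None, config.flank_nt)
    return _three_frame_regions(exon.gene_id, "I_E_TH", seg5, seg3, assembly, config, rejections)


def _intervals_overlap(a: CodingExon, b: CodingExon) -> bool:
    return a.start <= b.end and b.start <= a.end


def eeth_candidate_pairs(gene: GeneModel, adjacency: AdjacencyKB) -> List[Tuple[CodingExon, CodingExon]]:
    """Ordered exon pairs (5' strictly upstream in transcription order) that
    are genomically non-overlapping and not annotated as adjacent."""
    pairs = []
    for i, a in enumerate(gene.exons):
        for b in gene.exons[i + 1:]:
            if _intervals_overlap(a, b):
                continue
            if (a.exon_id, b.exon_id) in adjacency:
                continue
            pairs.append((a, b))
    return pairs


def gen_eeth_regions(gene: GeneModel, adjacency: AdjacencyKB, assembly: GenomeAssembly,
                     config: RegionConfig = RegionConfig(),
                     rejections: Optional[RejectionLog] = None) -> List[PeptideRegion]:
    """E_E_TH: hypothetical exon-exon junctions, all three frames; stops in
    the 5' exon segment reject the frame, stops reaching the 3' segment
    truncate."""
    out: List[PeptideRegion] = []
    for exon5, exon3 in eeth_candidate_pairs(gene, adjacency):
        seg5, seg3 = _junction_segments(exon5, None, exon3, None, config.flank_nt)
        out.extend(_three_frame_regions(gene.gene_id, "E_E_TH", seg5, seg3,
                                        assembly, config, rejections))
    return out


# ---------------------------------------------------------------------------
# Top-level enumeration
# ---------------------------------------------------------------------------

def _gene_regions(gene: GeneModel, adjacency: AdjacencyKB, assembly: GenomeAssembly,
                  config: RegionConfig, rejections: RejectionLog) -> List[PeptideRegion]:
    regions: List[PeptideRegion] = []
    enabled = set(config.enabled_region_types)
    exon_by_id = {e.exon_id: e for e in gene.exons}

    if "EXON_KB" in enabled:
        for exon in gene.exons:
            r = gen_exon_region(exon, assembly, config, rejections)
            if r:
                regions.append(r)
    if "E_E_KB" in enabled:
        gene_pairs = sorted(
            p for p in adjacency.pairs if p[0] in exon_by_id and p[1] in exon_by_id
        )
        for a, b in gene_pairs:
            r = gen_eekb_region((exon_by_id[a], exon_by_id[b]), assembly, config, rejections)
            if r:
                regions.append(r)
    if "E_I_TH" in enabled or "I_E_TH" in enabled:
        for upstream, downstream in zip(gene.exons, gene.exons[1:]):
            intron = intron_between(upstream, downstream)
            if intron is None:
                continue
            if "E_I_TH" in enabled:
                regions.extend(gen_eith_regions(upstream, intron, assembly, config, rejections))
            if "I_E_TH" in enabled:
                regions.extend(gen_ieth_regions(intron, downstream, assembly, config, rejections))
    if "E_E_TH" in enabled:
        regions.extend(gen_eeth_regions(gene, adjacency, assembly, config, rejections))
    return regions


def _region_sort_key(region: PeptideRegion):
    seg5 = region.segments[0]
    seg3 = region.segments[1] if len(region.segments) > 1 else None
    return (
        region.gene_id,
        _TYPE_RANK[region.region_type],
        seg5.start,
        seg5.end,
        seg3.start if seg3 else -1,
        seg3.end if seg3 else -1,
        region.orf,
    )


def generate_all(genes: Iterable[GeneModel], adjacency: AdjacencyKB,
                 assembly: GenomeAssembly,
                 config: Optional[RegionConfig] = None) -> Tuple[List[PeptideRegion], RejectionLog]:
    """Enumerate all enabled region types over all genes.

    Regions are deterministically ordered by (gene_id, region type, genomic
    coordinates of the 5' segment, orf) and assigned serial ids starting at
    REG000000001. Every discarded candidate is recorded in the returned
    :class:`RejectionLog`.
    """
    config = config or RegionConfig()
    rejections = RejectionLog()
    regions: List[PeptideRegion] = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        regions.extend(_gene_regions(gene, adjacency, assembly, config, rejections))
    regions.sort(key=_region_sort_key)
    for i, region in enumerate(regions, start=1):
        region.region_id = f"REG{i:09d}"
    counts: Dict[str, int] = {}
    for region in regions:
        counts[region.region_type] = counts.get(region.region_type, 0) + 1
    log.info("regions per type: %s",
             ", ".join(f"{t}={counts.get(t, 0)}" for t in REGION_TYPES))
    return regions, rejections
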