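"""FASTA / TSV writers for the generated peptide database."""

from __future__ import annotations

import logging
import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .region_gen import REGION_TYPES, PeptideRegion
from .snp_variants import PeptideEntry, snp_map_rows

log = logging.getLogger(__name__)

PRESETS = {
    # preset -> (enabled region types, include SNP variants)
    "PEPPI_KB": (("EXON_KB", "E_E_KB"), False),
    "PEPPI_without_SNP": (REGION_TYPES, False),
    "PEPPI_with_SNP": (REGION_TYPES, True),
}


def fasta_header(entry: PeptideEntry, region: PeptideRegion) -> str:
    seg5 = region.segments[0]
    loc = f"{seg5.chrom}:{seg5.start}-{seg5.end}"
    if len(region.segments) > 1:
        seg3 = region.segments[1]
        loc += f"|{seg3.start}-{seg3.end}"
    loc += f"({seg5.strand})"
    snp = entry.snp_links[0].snp_id if entry.snp_links else "-"
    return (f">{entry.peptide_id} REG={region.region_id} TYPE={region.region_type} "
            f"GENE={region.gene_id} ORF={region.orf} SNP={snp} LOC={loc}")


def write_fasta(peptides: Sequence[PeptideEntry], regions: Sequence[PeptideRegion],
                path: str, width: int = 60) -> None:
    """One record per peptide, in peptide_id order, 60-column wrapped."""
    region_by_id = {r.region_id: r for r in regions}
    with open(path, "wt") as fh:
        for entry in sorted(peptides, key=lambda e: e.peptide_id):
            region = region_by_id[entry.region_id]
            fh.write(fasta_header(entry, region) + "\n")
            for i in range(0, len(entry.sequence), width):
                fh.write(entry.sequence[i:i + width] + "\n")


def parse_peptide_fasta(path: str) -> Tuple[List[PeptideEntry], List[PeptideRegion]]:
    """Read back a FASTA written by :func:`write_fasta`, recovering peptide
    ids, sequences and minimal region metadata (enough for mapping/search)."""
    from .region_gen import Segment
    from .snp_variants import PeptideSNPLink

    peptides: List[PeptideEntry] = []
    regions: Dict[str, PeptideRegion] = {}
    with open(path, "rt") as fh:
        header: Optional[str] = None
        chunks: List[str] = []

        def flush() -> None:
            if header is None:
                return
            fields = header.split()
            peptide_id = fields[0]
            meta = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
            seq = "".join(chunks)
            loc = meta["LOC"]
            strand = loc[-2]
            chrom, intervals = loc[:-3].split(":", 1)
            segs = []
            parts = intervals.split("|")
            roles = (["exon"] if len(parts) == 1 else ["exon5", "exon3"])
            for part, role in zip(parts, roles):
                a, b = part.split("-")
                segs.append(Segment(chrom, int(a), int(b), strand, role))
            rid = meta["REG"]
            if rid not in regions:
                junction = segs[0].length if len(segs) > 1 else None
                regions[rid] = PeptideRegion(
                    rid, meta["GENE"], meta["TYPE"], tuple(segs), int(meta["ORF"]),
                    cdna="", wild_peptide="", junction_offset=junction)
            links: Tuple[PeptideSNPLink, ...] = ()
            if meta.get("SNP", "-") != "-":
                links = (PeptideSNPLink(meta["SNP"], 0, 0, "N", "N", 0, "-", "-"),)
            peptides.append(PeptideEntry(peptide_id, rid, seq,
                                         is_wild_type=not links, snp_links=links))
            if not links:
                regions[rid].wild_peptide = seq

        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            elif line:
                chunks.append(line.strip())
        flush()
    return peptides, list(regions.values())


def _segments_str(region: PeptideRegion) -> str:
    return ";".join(f"{s.role}:{s.chrom}:{s.start}-{s.end}({s.strand})"
                    for s in region.segments)


def write_tables(regions: Sequence[PeptideRegion], peptides: Sequence[PeptideEntry],
                 outdir: str, hits=None) -> Dict[str, str]:
    """Write regions.tsv, peptides.tsv, peptide_snp_map.tsv and
    peptide_protein_hits.tsv under ``outdir`` (deterministic row order) and
    log per-type counts."""
    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, f"{name}.tsv")
             for name in ("regions", "peptides", "peptide_snp_map", "peptide_protein_hits")}

    with open(paths["regions"], "wt") as fh:
        fh.write("region_id\tgene_id\tregion_type\torf\tchrom\tstrand\tsegments\t"
                 "junction_offset\tcdna_len\twild_peptide\n")
        for r in regions:
            junc = "" if r.junction_offset is None else str(r.junction_offset)
            fh.write(f"{r.region_id}\t{r.gene_id}\t{r.region_type}\t{r.orf}\t"
                     f"{r.chrom}\t{r.strand}\t{_segments_str(r)}\t{junc}\t"
                     f"{len(r.cdna)}\t{r.wild_peptide}\n")

    with open(paths["peptides"], "wt") as fh:
        fh.write("peptide_id\tregion_id\tis_wild_type\tsnp_id\tsequence\n")
        for p in peptides:
            snp = p.snp_links[0].snp_id if p.snp_links else "-"
            fh.write(f"{p.peptide_id}\t{p.region_id}\t{int(p.is_wild_type)}\t{snp}\t{p.sequence}\n")

    with open(paths["peptide_snp_map"], "wt") as fh:
        fh.write("peptide_id\tsnp_id\tlocal_pos\tgenomic_pos\tnt_change\taa_change\n")
        for row in snp_map_rows(peptides):
            fh.write("\t".join(str(x) for x in row) + "\n")

    with open(paths["peptide_protein_hits"], "wt") as fh:
        fh.write("peptide_id\tprotein_id\toffset\n")
        for hit in (hits or ()):
            fh.write(f"{hit.peptide_id}\t{hit.protein_id}\t{hit.offset}\n")

    counts = {t: 0 for t in REGION_TYPES}
    for r in regions:
        counts[r.region_type] += 1
    wild = {t: 0 for t in REGION_TYPES}
    variant = {t: 0 for t in REGION_TYPES}
    rtype = {r.region_id: r.region_type for r in regions}
    for p in peptides:
        (wild if p.is_wild_type else variant)[rtype[p.region_id]] += 1
    log.info("Region Type\tRegions / Peptides without SNP\tPeptides with SNP\tAll Peptides")
    for t in REGION_TYPES:
        log.info("%s\t%d\t%d\t%d", t, counts[t], variant[t], wild[t] + variant[t])
    log.info("Total\t%d\t%d\t%d", sum(counts.values()), sum(variant.values()),
             sum(wild.values()) + sum(variant.values()))
    return paths


def summarize_counts(per_type: Dict[str, int]) -> int:
    """Total entries across a per-type count table (the shape of the published
    database-statistics and novel-peptide summaries)."""
    return sum(int(v) for v in per_type.values())
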