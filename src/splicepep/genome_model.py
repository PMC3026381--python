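"""Domain types, coordinate conventions and readers for genome / annotation / SNP inputs.

Conventions used throughout the package:

* All genomic coordinates are **1-based inclusive** (Ensembl / GFF3 / VCF style).
  Any half-open arithmetic is strictly internal to a function.
* An "exon" always means the **coding (CDS) part** of an exon; UTRs are excluded
  at read time.
* ``frame_offset`` follows GFF3 *phase* semantics: the number of 5' bases of the
  exon's coding sequence to skip so that translation starts on a codon boundary.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Set, Tuple

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")


class InputError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeAssembly:
    """Chromosome name -> uppercase nucleotide sequence."""

    sequences: Dict[str, str]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


@dataclass(frozen=True)
class CodingExon:
    """One coding (CDS) interval of a gene.

    ``frame_offset`` is the number of leading bases of the exon's coding
    sequence to skip before the first complete codon (GFF3 phase semantics).
    """

    exon_id: str
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str  # '+' or '-'
    frame_offset: int  # 0, 1 or 2

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(f"exon {self.exon_id}: start > end ({self.start} > {self.end})")
        if self.frame_offset not in (0, 1, 2):
            raise InputError(f"exon {self.exon_id}: frame_offset {self.frame_offset} not in {{0,1,2}}")
        if self.strand not in ("+", "-"):
            raise InputError(f"exon {self.exon_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class GeneModel:
    """A gene as a set of coding exons plus per-transcript exon orderings.

    ``exons`` is ordered 5'->3' in transcription order (ascending genomic
    coordinate on '+', descending on '-').
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    exons: List[CodingExon]
    transcripts: Dict[str, List[str]]
    protein_ids: List[str] = field(default_factory=list)

    def exon_by_id(self, exon_id: str) -> CodingExon:
        for exon in self.exons:
            if exon.exon_id == exon_id:
                return exon
        raise KeyError(exon_id)

    def exon_index(self, exon_id: str) -> int:
        for i, exon in enumerate(self.exons):
            if exon.exon_id == exon_id:
                return i
        raise KeyError(exon_id)


@dataclass
class AdjacencyKB:
    """All (5' exon, 3' exon) pairs that occur consecutively in any transcript."""

    pairs: Set[Tuple[str, str]]

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[Tuple[str, str]]:
        return iter(sorted(self.pairs))


@dataclass(frozen=True)
class SNPRecord:
    """A single-nucleotide substitution on the forward strand."""

    snp_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES:
            raise InputError(f"SNP {self.snp_id}: bad ref base {self.ref!r}")
        for alt in self.alts:
            if alt not in VALID_BASES:
                raise InputError(f"SNP {self.snp_id}: bad alt base {alt!r}")
            if alt == self.ref:
                raise InputError(f"SNP {self.snp_id}: alt equals ref ({alt})")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_genome(path: str) -> GenomeAssembly:
    """Read a genome FASTA into a :class:`GenomeAssembly`.

    The chromosome name is the first whitespace-delimited token of the header.
    Sequences are uppercased. Duplicate chromosome names and empty files are
    errors.
    """
    sequences: Dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            name = record.id
            if name in sequences:
                raise InputError(f"duplicate chromosome name {name!r} in {path}")
            seq = str(record.seq).upper()
            if not seq:
                raise InputError(f"empty sequence for chromosome {name!r}")
            sequences[name] = seq
    if not sequences:
        raise InputError(f"no FASTA records found in {path}")
    return GenomeAssembly(sequences)


def _gff_attr(attrs, *names: str) -> Optional[str]:
    for name in names:
        if name in attrs:
            val = attrs[name]
            if isinstance(val, (list, tuple)):
                return val[0] if val else None
            return val
    return None


def read_annotation(path: str, assembly: Optional[GenomeAssembly] = None) -> List[GeneModel]:
    """Read CDS features from a GFF3/GTF file into :class:`GeneModel` objects.

    Only ``CDS`` features are used; each must carry ``gene_id`` and
    ``transcript_id`` attributes (or ``Parent``-style equivalents) and a
    numeric phase column. Identical CDS intervals shared by several
    transcripts are deduplicated into one :class:`CodingExon` with a stable
    exon id derived from the transcription order within the gene.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    # gene_id -> {(start, end, frame): set of transcript_ids}, plus metadata
    per_gene: Dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        gene_id = _gff_attr(feat.attributes, "gene_id", "geneID", "gene")
        tx_id = _gff_attr(feat.attributes, "transcript_id", "transcriptID", "Parent")
        if gene_id is None or tx_id is None:
            raise InputError(f"CDS at {feat.seqid}:{feat.start}-{feat.end} lacks gene_id/transcript_id")
        if feat.frame not in ("0", "1", "2"):
            raise InputError(f"CDS at {feat.seqid}:{feat.start}-{feat.end} has no frame/phase")
        if assembly is not None and feat.seqid not in assembly:
            raise InputError(f"CDS references unknown chromosome {feat.seqid!r}")
        info = per_gene.setdefault(gene_id, {
            "chrom": feat.seqid,
            "strand": feat.strand,
            "symbol": _gff_attr(feat.attributes, "gene_name", "Name") or gene_id,
            "intervals": {},
            "tx_intervals": {},
            "protein_ids": [],
        })
        if feat.seqid != info["chrom"]:
            raise InputError(f"gene {gene_id}: CDS on multiple chromosomes")
        key = (feat.start, feat.end, int(feat.frame))
        info["intervals"].setdefault(key, set()).add(tx_id)
        info["tx_intervals"].setdefault(tx_id, []).append(key)
        protein_id = _gff_attr(feat.attributes, "protein_id")
        if protein_id and protein_id not in info["protein_ids"]:
            info["protein_ids"].append(protein_id)

    genes: List[GeneModel] = []
    for gene_id in sorted(per_gene):
        info = per_gene[gene_id]
        strand = info["strand"]
        reverse = strand == "-"
        # transcription order: ascending start on '+', descending on '-'
        ordered = sorted(info["intervals"], key=lambda k: (k[0], k[1]), reverse=reverse)
        exon_ids = {key: f"{gene_id}.E{i + 1}" for i, key in enumerate(ordered)}
        exons = [
            CodingExon(
                exon_id=exon_ids[key],
                gene_id=gene_id,
                chrom=info["chrom"],
                start=key[0],
                end=key[1],
                strand=strand,
                frame_offset=key[2],
            )
            for key in ordered
        ]
        transcripts = {}
        for tx_id in sorted(info["tx_intervals"]):
            keys = sorted(info["tx_intervals"][tx_id], key=lambda k: (k[0], k[1]), reverse=reverse)
            transcripts[tx_id] = [exon_ids[key] for key in keys]
        genes.append(GeneModel(
            gene_id=gene_id,
            symbol=info["symbol"],
            chrom=info["chrom"],
            strand=strand,
            exons=exons,
            transcripts=transcripts,
            protein_ids=list(info["protein_ids"]),
        ))
    return genes


def read_snps(path: str) -> List[SNPRecord]:
    """Read simple SNVs from a VCF 4.x file.

    Multi-allelic records are expanded one alt per :class:`SNPRecord` under
    the same snp id. Records whose REF or any ALT is not a single A/C/G/T
    base (indels, MNVs) are skipped and counted in a log message.
    """
    import pysam

    records: List[SNPRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
            if rec.ref is None or len(rec.ref) != 1 or rec.ref.upper() not in VALID_BASES:
                skipped += 1
                continue
            alts = tuple(
                a.upper() for a in (rec.alts or ())
                if a is not None and len(a) == 1 and a.upper() in VALID_BASES
            )
            if not alts:
                skipped += 1
                continue
            if len(alts) != len(rec.alts or ()):
                skipped += 1  # a non-SNV allele was dropped from a mixed record
            for alt in alts:
                records.append(SNPRecord(snp_id, rec.chrom, rec.pos, rec.ref.upper(), (alt,)))
    if skipped:
        log.info("read_snps: skipped %d non-SNV record(s) in %s", skipped, path)
    return records


# ---------------------------------------------------------------------------
# Sequence primitives
# ---------------------------------------------------------------------------

def extract_oriented(assembly: GenomeAssembly, chrom: str, start: int, end: int,
                     strand: str) -> str:
    """Return the 1-based inclusive [start, end] substring of *chrom*,
    reverse-complemented when ``strand`` is '-'."""
    if chrom not in assembly:
        raise InputError(f"unknown chromosome {chrom!r}")
    seq = assembly[chrom]
    if not (1 <= start <= end <= len(seq)):
        raise InputError(f"interval {chrom}:{start}-{end} out of bounds (len {len(seq)})")
    sub = seq[start - 1:end]
    if strand == "+":
        return sub
    if strand == "-":
        return str(Seq(sub).reverse_complement())
    raise InputError(f"bad strand {strand!r}")


def translate(cdna: str, offset: int = 0) -> str:
    """Translate ``cdna`` starting ``offset`` bases in, dropping any
    incomplete trailing codon. Stops are '*'; codons containing N become 'X'.
    """
    if not cdna:
        raise InputError("translate: empty input")
    if offset not in (0, 1, 2):
        raise InputError(f"translate: offset {offset} not in {{0,1,2}}")
    if offset >= len(cdna):
        raise InputError("translate: offset beyond sequence")
    trimmed = cdna[offset:]
    trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
    if not trimmed:
        return ""
    return str(Seq(trimmed).translate())
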