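"""Peptide -> protein mapping, peptide-sequence queries, and the
differential-mapping comparison used to infer cassette-exon events.

Multi-pattern matching uses an Aho-Corasick automaton (linear in total
pattern size plus text size plus matches), so mapping stays sub-quadratic
even for large peptide sets. Matching is exact and case-insensitive; I/L and
K/Q mass ambiguities are deliberately not collapsed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .genome_model import InputError
from .region_gen import PeptideRegion
from .snp_variants import PeptideEntry

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PeptideProteinHit:
    peptide_id: str
    protein_id: str
    offset: int  # 1-based start of the peptide within the protein


@dataclass
class MappingDiff:
    peptide_a: str
    peptide_b: str
    proteins_only_a: Set[str]
    proteins_only_b: Set[str]
    proteins_shared: Set[str]
    explanation: Optional[str] = None


class AhoCorasick:
    """Minimal Aho-Corasick automaton over uppercase strings.

    ``find(text)`` yields (start_index_0based, pattern) for every occurrence
    of every pattern, including overlapping ones.
    """

    def __init__(self, patterns: Iterable[str]):
        self._goto: List[Dict[str, int]] = [{}]
        self._out: List[List[str]] = [[]]
        self._fail: List[int] = [0]
        for pat in patterns:
            self._add(pat)
        self._build()

    def _add(self, pattern: str) -> None:
        node = 0
        for ch in pattern:
            nxt = self._goto[node].get(ch)
            if nxt is None:
                self._goto.append({})
                self._out.append([])
                self._fail.append(0)
                nxt = len(self._goto) - 1
                self._goto[node][ch] = nxt
            node = nxt
        self._out[node].append(pattern)

    def _build(self) -> None:
        queue: deque[int] = deque()
        for child in self._goto[0].values():
            self._fail[child] = 0
            queue.append(child)
        while queue:
            node = queue.popleft()
            for ch, child in self._goto[node].items():
                queue.append(child)
                fail = self._fail[node]
                while fail and ch not in self._goto[fail]:
                    fail = self._fail[fail]
                self._fail[child] = self._goto[fail].get(ch, 0)
                if self._fail[child] == child:
                    self._fail[child] = 0
                self._out[child].extend(self._out[self._fail[child]])

    def find(self, text: str):
        node = 0
        for i, ch in enumerate(text):
            while node and ch not in self._goto[node]:
                node = self._fail[node]
            node = self._goto[node].get(ch, 0)
            for pattern in self._out[node]:
                yield i - len(pattern) + 1, pattern


def read_protein_fasta(path: str) -> Dict[str, str]:
    """Protein FASTA -> {id: uppercase sequence}; id is the first header token."""
    from .genome_model import read_genome

    return dict(read_genome(path).sequences)


def map_peptides_to_proteins(peptides: Sequence[PeptideEntry],
                             proteins: Dict[str, str]) -> List[PeptideProteinHit]:
    """Exact-substring mapping of every peptide against every protein.

    All occurrences are reported (overlaps included). ``proteins`` maps
    protein id -> amino-acid sequence (use :func:`read_protein_fasta` for
    FASTA input).
    """
    if not peptides:
        return []
    by_seq: Dict[str, List[str]] = {}
    for entry in peptides:
        by_seq.setdefault(entry.sequence.upper(), []).append(entry.peptide_id)
    automaton = AhoCorasick(by_seq.keys())
    hits: List[PeptideProteinHit] = []
    for protein_id in sorted(proteins):
        seq = proteins[protein_id].upper()
        for start0, pattern in automaton.find(seq):
            for peptide_id in by_seq[pattern]:
                hits.append(PeptideProteinHit(peptide_id, protein_id, start0 + 1))
    hits.sort(key=lambda h: (h.peptide_id, h.protein_id, h.offset))
    return hits


def search_sequence(query: str, peptides: Sequence[PeptideEntry]) -> List[Tuple[str, int]]:
    """All (peptide_id, 1-based offset) occurrences of ``query`` within the
    peptide set."""
    if not query:
        raise InputError("empty query")
    query = query.upper()
    bad = set(query) - AMINO_ACIDS
    if bad:
        raise InputError(f"non-amino-acid characters in query: {sorted(bad)}")
    results: List[Tuple[str, int]] = []
    for entry in peptides:
        seq = entry.sequence.upper()
        start = seq.find(query)
        while start != -1:
            results.append((entry.peptide_id, start + 1))
            start = seq.find(query, start + 1)
    return results


def regions_for_protein(protein_id: str, hits: Sequence[PeptideProteinHit],
                        peptides: Sequence[PeptideEntry]) -> List[Tuple[str, int]]:
    """Regions whose peptides map to ``protein_id``, each at its minimal
    offset, ordered by offset then region_id (N- to C-terminal)."""
    region_of = {p.peptide_id: p.region_id for p in peptides}
    best: Dict[str, int] = {}
    for hit in hits:
        if hit.protein_id != protein_id:
            continue
        region_id = region_of.get(hit.peptide_id)
        if region_id is None:
            continue
        if region_id not in best or hit.offset < best[region_id]:
            best[region_id] = hit.offset
    return sorted(best.items(), key=lambda kv: (kv[1], kv[0]))


def _flanking_exon_regions(junction_region: PeptideRegion,
                           regions: Sequence[PeptideRegion]) -> Optional[Tuple[str, str]]:
    """EXON_KB region ids whose exon contains each side of a junction region."""
    if len(junction_region.segments) != 2:
        return None
    found = []
    for seg in junction_region.segments:
        match = None
        for region in regions:
            if region.region_type != "EXON_KB":
                continue
            exon_seg = region.segments[0]
            if (exon_seg.chrom == seg.chrom and exon_seg.strand == seg.strand
                    and exon_seg.start <= seg.start and seg.end <= exon_seg.end):
                match = region.region_id
                break
        if match is None:
            return None
        found.append(match)
    return found[0], found[1]


def diff_mappings(pep_a: PeptideEntry, pep_b: PeptideEntry,
                  hits: Sequence[PeptideProteinHit],
                  peptides: Optional[Sequence[PeptideEntry]] = None,
                  regions: Optional[Sequence[PeptideRegion]] = None) -> MappingDiff:
    """Partition the proteins mapped by two peptides into only-A / only-B /
    shared sets.

    When ``peptides`` and ``regions`` are supplied and peptide A comes from a
    junction region, each protein mapped only by B is inspected for an extra
    region lying between A's two flanking exon regions; if found, the
    explanation names it as a candidate cassette-exon insertion.
    """
    prots_a = {h.protein_id for h in hits if h.peptide_id == pep_a.peptide_id}
    prots_b = {h.protein_id for h in hits if h.peptide_id == pep_b.peptide_id}
    diff = MappingDiff(
        peptide_a=pep_a.peptide_id,
        peptide_b=pep_b.peptide_id,
        proteins_only_a=prots_a - prots_b,
        proteins_only_b=prots_b - prots_a,
        proteins_shared=prots_a & prots_b,
    )
    if peptides is None or regions is None or not diff.proteins_only_b:
        return diff
    region_by_id = {r.region_id: r for r in regions}
    region_a = region_by_id.get(pep_a.region_id)
    if region_a is None or region_a.junction_offset is None:
        return diff
    flanks = _flanking_exon_regions(region_a, regions)
    if flanks is None:
        return diff
    for protein_id in sorted(diff.proteins_only_b):
        chain = regions_for_protein(protein_id, hits, peptides)
        # the insertion test runs over exonic regions only; junction regions
        # straddling the candidate exon would otherwise inflate the chain
        region_ids = [rid for rid, _ in chain
                      if rid in region_by_id
                      and region_by_id[rid].region_type == "EXON_KB"]
        if flanks[0] in region_ids and flanks[1] in region_ids:
            i, j = region_ids.index(flanks[0]), region_ids.index(flanks[1])
            if j < i:
                i, j = j, i
            inserted = region_ids[i + 1:j]
            if len(inserted) == 1:
                diff.explanation = (
                    f"candidate cassette-exon event in {protein_id}: region "
                    f"{inserted[0]} inserted between {flanks[0]} and {flanks[1]}"
                )
                break
    return diff
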