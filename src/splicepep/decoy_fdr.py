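"""Decoy database construction and multi-level target-decoy FDR arithmetic.

Levels and their estimators:

* ``ms2`` (spectrum), ``protein_gene`` and ``peppi`` (database-peptide entry)
  use the concatenated-search estimator ``2 * decoys / (targets + decoys)``,
  capped at 1.
* ``peptide`` (distinct peptide sequence) uses the simple estimator
  ``decoys / (targets + decoys)``.

This per-level assignment is the one that reproduces the published search
summaries; neither formula is universal and both are exposed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .genome_model import InputError

DECOY_PREFIX = "DECOY_"

LEVELS = ("ms2", "peptide", "protein_gene", "peppi")


@dataclass(frozen=True)
class HitRecord:
    sample_id: str
    spectrum_id: str
    peptide: str
    protein_id: str
    peptide_id: str
    evalue: float
    is_decoy: bool


@dataclass
class FDRSummary:
    level: str
    target_hits: int
    decoy_hits: int
    fdr: float


# ---------------------------------------------------------------------------
# Decoy construction
# ---------------------------------------------------------------------------

def make_decoy(fasta_in: str, fasta_out: str, width: int = 60) -> int:
    """Write a decoy FASTA with every sequence reversed and every id prefixed
    ``DECOY_``; record order is preserved. Returns the number of records."""
    from Bio import SeqIO

    from .genome_model import _open_text

    n = 0
    with _open_text(fasta_in) as handle, open(fasta_out, "wt") as out:
        for record in SeqIO.parse(handle, "fasta"):
            seq = str(record.seq)[::-1]
            out.write(f">{DECOY_PREFIX}{record.id}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")
            n += 1
    if n == 0:
        raise InputError(f"no FASTA records in {fasta_in}")
    return n


# ---------------------------------------------------------------------------
# FDR estimators
# ---------------------------------------------------------------------------

def fdr_simple(targets: int, decoys: int) -> float:
    """d / (t + d) — used for the peptide level."""
    if targets + decoys <= 0:
        raise InputError("fdr_simple: no hits")
    return decoys / (targets + decoys)


def fdr_concatenated(targets: int, decoys: int) -> float:
    """2d / (t + d), capped at 1 — used for ms2, protein/gene and database-
    peptide (peppi) levels."""
    if targets + decoys <= 0:
        raise InputError("fdr_concatenated: no hits")
    return min(1.0, 2.0 * decoys / (targets + decoys))


_LEVEL_ESTIMATOR: Dict[str, Callable[[int, int], float]] = {
    "ms2": fdr_concatenated,
    "peptide": fdr_simple,
    "protein_gene": fdr_concatenated,
    "peppi": fdr_concatenated,
}


def _entity_key(hit: HitRecord, level: str):
    if level == "ms2":
        return (hit.sample_id, hit.spectrum_id)
    if level == "peptide":
        return hit.peptide.upper()
    if level == "protein_gene":
        return hit.protein_id
    if level == "peppi":
        return hit.peptide_id
    raise InputError(f"unknown level {level!r}")


# ---------------------------------------------------------------------------
# Filtering and summarization
# ---------------------------------------------------------------------------

def two_sample_filter(hits: Sequence[HitRecord], level: str) -> List[HitRecord]:
    """Keep hits whose level-entity was observed in >= 2 distinct samples."""
    samples: Dict[object, Set[str]] = {}
    for hit in hits:
        samples.setdefault(_entity_key(hit, level), set()).add(hit.sample_id)
    return [h for h in hits if len(samples[_entity_key(h, level)]) >= 2]


def summarize(hits: Sequence[HitRecord], level: str,
              estimator: Optional[Callable[[int, int], float]] = None,
              two_sample: Optional[bool] = None) -> FDRSummary:
    """Count distinct level-entities per target/decoy class and estimate FDR.

    ``two_sample`` defaults to True for every level except ``ms2`` (spectrum
    hits are intrinsically per-sample). The estimator defaults to the level's
    published formula.
    """
    if level not in LEVELS:
        raise InputError(f"unknown level {level!r}")
    if not hits:
        raise InputError("summarize: empty hit list")
    if two_sample is None:
        two_sample = level != "ms2"
    if two_sample:
        hits = two_sample_filter(hits, level)
    targets = {_entity_key(h, level) for h in hits if not h.is_decoy}
    decoys = {_entity_key(h, level) for h in hits if h.is_decoy}
    estimator = estimator or _LEVEL_ESTIMATOR[level]
    if not targets and not decoys:
        return FDRSummary(level, 0, 0, 0.0)
    fdr = estimator(len(targets), len(decoys))
    return FDRSummary(level, len(targets), len(decoys), fdr)


def filter_at_max_fdr(hits: Sequence[HitRecord], level: str,
                      max_fdr: float) -> List[HitRecord]:
    """Target-decoy E-value sweep: return the largest prefix of hits (sorted
    by ascending E-value) whose estimated FDR at ``level`` is <= ``max_fdr``."""
    ranked = sorted(hits, key=lambda h: (h.evalue, h.is_decoy))
    estimator = _LEVEL_ESTIMATOR[level]
    targets: Set[object] = set()
    decoys: Set[object] = set()
    best = 0
    for i, hit in enumerate(ranked):
        (decoys if hit.is_decoy else targets).add(_entity_key(hit, level))
        # keep the threshold between distinct E-values only
        if i + 1 < len(ranked) and ranked[i + 1].evalue == hit.evalue:
            continue
        if targets or decoys:
            if estimator(len(targets), len(decoys)) <= max_fdr:
                best = i + 1
    return ranked[:best]


# ---------------------------------------------------------------------------
# Hit-table I/O
# ---------------------------------------------------------------------------

_HIT_COLUMNS = ("sample_id", "spectrum_id", "peptide", "protein_id",
                "peptide_id", "evalue", "is_decoy")


def read_hits(path: str) -> List[HitRecord]:
    """Read a hit TSV. ``is_decoy`` may be given explicitly (0/1/true/false)
    or inferred from a ``DECOY_`` prefix on protein_id/peptide_id."""
    hits: List[HitRecord] = []
    with open(path, "rt", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            raw = (row.get("is_decoy") or "").strip().lower()
            if raw in ("1", "true", "yes"):
                is_decoy = True
            elif raw in ("0", "false", "no"):
                is_decoy = False
            else:
                is_decoy = (row.get("protein_id", "").startswith(DECOY_PREFIX)
                            or row.get("peptide_id", "").startswith(DECOY_PREFIX))
            hits.append(HitRecord(
                sample_id=row.get("sample_id", ""),
                spectrum_id=row.get("spectrum_id", ""),
                peptide=row.get("peptide", ""),
                protein_id=row.get("protein_id", ""),
                peptide_id=row.get("peptide_id", ""),
                evalue=float(row.get("evalue", "0") or 0),
                is_decoy=is_decoy,
            ))
    return hits


def write_summary(summaries: Iterable[FDRSummary], path: str) -> None:
    with open(path, "wt") as fh:
        fh.write("level\ttarget_hits\tdecoy_hits\tfdr\n")
        for s in summaries:
            fh.write(f"{s.level}\t{s.target_hits}\t{s.decoy_hits}\t{s.fdr:.5f}\n")
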