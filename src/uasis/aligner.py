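"""Mismatch-tolerant gapless placement of flanking reads on a reference.

The aligner is a k-mer seed-and-extend scheme over an in-memory
reference: every k-mer of each chromosome (default k = 12) is indexed;
a query is anchored by its exact-matching seeds and each candidate
placement is scored by Hamming distance on both strands.  Alignment is
gapless — indel *variants* are handled upstream by how the query is
constructed from the flanks, never by gapped dynamic programming.

Completeness: a placement with at most m mismatches leaves at least one
of ⌊L/k⌋ non-overlapping seeds exact whenever L ≥ (m+1)·k (pigeonhole).
Shorter queries fall back to an exhaustive scan of every offset on both
strands, so reported hit sets are always complete up to the mismatch
cap.  ``N`` matches nothing — in query or reference it always counts as
a mismatch — except at explicitly declared free positions (the variant
placeholder), whose mismatch is excluded from the count.

Defaults ``max_mismatch=3`` and ``max_hits=2`` mirror standard
short-read practice (report at most two best hits allowing three
mismatches); both are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

from .errors import ReadLengthError, ReferenceFormatError
from .flanking_io import FlankingRecord
from .nomenclature import (
    DEFAULT_BUILD,
    UasisName,
    VariantClass,
    canonicalize_alleles,
)
from .sequences import is_nucleotide_string, reverse_complement

__all__ = [
    "ReferenceIndex",
    "AlignmentHit",
    "LocalizationResult",
    "NOT_ALIGNED",
    "build_index",
    "align_read",
    "localize_variant",
]

#: Status string for a read with no genome placement.
NOT_ALIGNED = "Not Aligned"

MIN_READ_LENGTH = 4
MAX_READ_LENGTH = 1024


@dataclass(frozen=True)
class AlignmentHit:
    """One gapless placement of a query on the reference."""

    chromosome: str
    start: int  # 1-based leftmost reference position
    strand: str  # "+" or "-"
    mismatches: int
    query_id: str = ""


class ReferenceIndex:
    """Per-chromosome sequences plus an exact k-mer position index.

    The minus strand is never indexed; queries are reverse-complemented
    at alignment time instead.  k-mers containing N are not indexed
    (N matches nothing).
    """

    def __init__(self, sequences: Dict[str, str], k: int = 12):
        if k < 4:
            raise ValueError(f"seed length k must be >= 4, got {k}")
        if not sequences:
            raise ReferenceFormatError("reference contains no sequences")
        self.k = k
        self.chromosomes: List[str] = []
        self.sequences: Dict[str, str] = {}
        self._arrays: Dict[str, np.ndarray] = {}
        self._kmers: Dict[str, Dict[str, List[int]]] = {}
        for name, seq in sequences.items():
            name = name.removeprefix("chr").removeprefix("Chr").removeprefix("CHR")
            seq = seq.upper()
            if not seq:
                raise ReferenceFormatError(f"chromosome {name!r} is empty")
            if not is_nucleotide_string(seq):
                raise ReferenceFormatError(
                    f"chromosome {name!r} contains non-nucleotide characters"
                )
            self.chromosomes.append(name)
            self.sequences[name] = seq
            self._arrays[name] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            index: Dict[str, List[int]] = {}
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append(i)
            self._kmers[name] = index
        self._chrom_rank = {c: i for i, c in enumerate(self.chromosomes)}

    def length(self, chromosome: str) -> int:
        return len(self.sequences[chromosome])

    def lengths(self) -> Dict[str, int]:
        return {c: len(self.sequences[c]) for c in self.chromosomes}

    def base_at(self, chromosome: str, locus: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequences[chromosome][locus - 1]

    def chrom_rank(self, chromosome: str) -> int:
        return self._chrom_rank[chromosome]


def build_index(reference_fasta: str | Path | Dict[str, str], k: int = 12) -> ReferenceIndex:
    """Index a reference genome from FASTA (or a name→sequence dict).

    Chromosome names are matched after stripping an optional ``chr``
    prefix; lowercase bases are accepted and uppercased.
    """
    if isinstance(reference_fasta, dict):
        return ReferenceIndex(reference_fasta, k=k)
    path = Path(reference_fasta)
    sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not sequences:
        raise ReferenceFormatError(f"{path}: empty or unreadable FASTA")
    return ReferenceIndex(sequences, k=k)


_N_CODE = ord("N")


def _window_mismatches(
    chrom_arr: np.ndarray,
    read_arr: np.ndarray,
    start0: int,
    free_mask: Optional[np.ndarray],
    cap: int,
) -> Optional[int]:
    """Hamming mismatches of read vs reference window, or None if > cap."""
    L = len(read_arr)
    window = chrom_arr[start0 : start0 + L]
    mism = (window != read_arr) | (window == _N_CODE) | (read_arr == _N_CODE)
    if free_mask is not None:
        mism &= ~free_mask
    n = int(mism.sum())
    return n if n <= cap else None


def _exhaustive_strand(
    chrom_arr: np.ndarray,
    read_arr: np.ndarray,
    free_mask: Optional[np.ndarray],
    cap: int,
) -> List[Tuple[int, int]]:
    """All (start0, mismatches) with mismatches <= cap, vectorized."""
    L = len(read_arr)
    G = len(chrom_arr)
    if G < L:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(chrom_arr, L)
    mism = (windows != read_arr) | (windows == _N_CODE) | (read_arr == _N_CODE)
    if free_mask is not None:
        mism = mism & ~free_mask
    counts = mism.sum(axis=1)
    hits = np.nonzero(counts <= cap)[0]
    return [(int(i), int(counts[i])) for i in hits]


def align_read(
    index: ReferenceIndex,
    read: str,
    max_mismatch: int = 3,
    max_hits: int = 2,
    chromosome_filter: Optional[Sequence[str]] = None,
    free_positions: FrozenSet[int] = frozenset(),
    query_id: str = "",
) -> List[AlignmentHit]:
    """Place a read on the reference, reporting up to ``max_hits`` hits.

    Hits are sorted by ascending mismatch count, ties broken by
    reference chromosome order, then ascending start, then ``+`` before
    ``-``.  An empty list means "Not Aligned".

    ``free_positions`` are 0-based offsets into ``read`` (as given,
    forward orientation) whose mismatches are excluded from the count —
    used for the variant placeholder, so a clean substitution read
    aligns with 0 counted mismatches.
    """
    read = read.upper()
    L = len(read)
    if L < MIN_READ_LENGTH or L > MAX_READ_LENGTH:
        raise ReadLengthError(
            f"read length {L} outside {MIN_READ_LENGTH}..{MAX_READ_LENGTH}"
        )
    if not is_nucleotide_string(read):
        raise ReadLengthError("read contains non-nucleotide characters")
    k = index.k
    chroms = [
        c
        for c in index.chromosomes
        if chromosome_filter is None or c in set(chromosome_filter)
    ]
    # worst case a true placement mismatches at every free position too
    budget = max_mismatch + len(free_positions)
    use_seeds = L >= (budget + 1) * k

    found: Dict[Tuple[str, int, str], int] = {}
    for strand in ("+", "-"):
        q = read if strand == "+" else reverse_complement(read)
        q_arr = np.frombuffer(q.encode("ascii"), dtype=np.uint8)
        if free_positions:
            mask = np.zeros(L, dtype=bool)
            for p in free_positions:
                mask[p if strand == "+" else L - 1 - p] = True
        else:
            mask = None
        for chrom in chroms:
            chrom_arr = index._arrays[chrom]
            if not use_seeds:
                for start0, mm in _exhaustive_strand(chrom_arr, q_arr, mask, max_mismatch):
                    found[(chrom, start0 + 1, strand)] = mm
                continue
            kmer_index = index._kmers[chrom]
            candidates = set()
            for s in range(0, L - k + 1, k):
                seed = q[s : s + k]
                for pos0 in kmer_index.get(seed, ()):
                    start0 = pos0 - s
                    if 0 <= start0 <= len(chrom_arr) - L:
                        candidates.add(start0)
            for start0 in candidates:
                key = (chrom, start0 + 1, strand)
                if key in found:
                    continue
                mm = _window_mismatches(chrom_arr, q_arr, start0, mask, max_mismatch)
                if mm is not None:
                    found[key] = mm

    hits = [
        AlignmentHit(chrom, start, strand, mm, query_id)
        for (chrom, start, strand), mm in found.items()
    ]
    hits.sort(
        key=lambda h: (h.mismatches, index.chrom_rank(h.chromosome), h.start, h.strand)
    )
    return hits[:max_hits]


@dataclass
class LocalizationResult:
    """Outcome of projecting a marked variant site onto the genome.

    ``status`` is ``"ok"``, ``"ambiguous"`` (two equally good placements
    at different variant loci; both hits reported, name taken from the
    first) or ``"not_aligned"``.
    """

    query_id: str
    status: str
    name: Optional[UasisName] = None
    hit: Optional[AlignmentHit] = None
    hits: List[AlignmentHit] = field(default_factory=list)
    reference_base: Optional[str] = None

    @property
    def aligned(self) -> bool:
        return self.status != "not_aligned"


def _build_query(rec: FlankingRecord) -> Tuple[str, FrozenSet[int]]:
    """Alignable query string and its free positions for a marked record.

    substitution → five + N + three  (placeholder mismatch is free)
    deletion     → five + deleted_base + three  (base exists on reference)
    insertion    → five + three  (inserted base absent from reference)
    """
    if rec.variant_class is VariantClass.SUBSTITUTION:
        return rec.five_prime + "N" + rec.three_prime, frozenset({len(rec.five_prime)})
    if rec.variant_class is VariantClass.DELETION:
        return rec.five_prime + rec.alleles[0] + rec.three_prime, frozenset()
    return rec.five_prime + rec.three_prime, frozenset()


def _variant_locus(rec: FlankingRecord, hit: AlignmentHit, query_length: int) -> int:
    """Project the marked site of ``rec`` through ``hit`` to a 1-based locus."""
    n5 = len(rec.five_prime)
    if rec.variant_class is VariantClass.INSERTION:
        if hit.strand == "+":
            return hit.start + n5
        return hit.start + query_length - n5
    if hit.strand == "+":
        return hit.start + n5
    return hit.start + query_length - 1 - n5


def localize_variant(
    index: ReferenceIndex,
    rec: FlankingRecord,
    max_mismatch: int = 3,
    max_hits: int = 2,
    chromosome_filter: Optional[Sequence[str]] = None,
    build: int = DEFAULT_BUILD,
) -> LocalizationResult:
    """Align a marked flanking record and name the variant it carries.

    The best placement projects the marked site to a genomic locus; on
    ``-`` strand hits the locus is mirrored through the alignment and
    alleles are reverse-complemented, so the resulting name is
    strand-invariant.  For substitutions, the base read off the
    reference at the locus is moved to the leftmost allele slot.

    Insertions follow the nomenclature convention: the reported locus is
    where the inserted base is written, the displaced reference base
    sits at locus + 1.
    """
    if not rec.has_variant:
        raise ValueError(f"{rec.query_id}: record carries no marked variant site")
    query, free = _build_query(rec)
    hits = align_read(
        index,
        query,
        max_mismatch=max_mismatch,
        max_hits=max(max_hits, 2),  # need a runner-up to detect ambiguity
        chromosome_filter=chromosome_filter,
        free_positions=free,
        query_id=rec.query_id,
    )
    if not hits:
        return LocalizationResult(rec.query_id, "not_aligned")

    best = hits[0]
    locus = _variant_locus(rec, best, len(query))
    status = "ok"
    reported = [best]
    if len(hits) > 1 and hits[1].mismatches == best.mismatches:
        other_locus = _variant_locus(rec, hits[1], len(query))
        if (hits[1].chromosome, other_locus) != (best.chromosome, locus):
            status = "ambiguous"
            reported = [h for h in hits if h.mismatches == best.mismatches]

    alleles = rec.alleles
    if best.strand == "-":
        # order preserved: complementing each allele is its own inverse,
        # which keeps localization strand-invariant
        alleles = tuple(reverse_complement(a) for a in alleles)

    ref_base: Optional[str] = None
    if rec.variant_class is VariantClass.SUBSTITUTION:
        ref_base = index.base_at(best.chromosome, locus)
        name = UasisName(build, best.chromosome, locus, VariantClass.SUBSTITUTION, alleles)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # disagreement is carried in the result
            name = canonicalize_alleles(name, ref_base)
    else:
        name = UasisName(build, best.chromosome, locus, rec.variant_class, alleles)

    return LocalizationResult(
        rec.query_id, status, name=name, hit=best, hits=reported, reference_base=ref_base
    )
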