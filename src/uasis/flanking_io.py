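"""Reading and writing query sequences that carry a marked variant site.

Flanking sequences are the bases surrounding a variant, submitted so the
variant can be placed on the reference genome independently of any
database coordinate.  Inside a FASTA sequence the variant site is marked
with a bracket group, the dialect used by dbSNP's rs_fasta dumps:

    ``ACGT[G/A]TTCA``   substitution (2-4 alleles)
    ``ACGT[-/T]TTCA``   insertion of T between the flanks
    ``ACGT[T/-]TTCA``   deletion of the T between the flanks

FASTQ cannot carry in-sequence markup without breaking the format, so a
FASTQ record is a plain read unless its description line carries
``variant_at=<offset>;alleles=<X/Y>`` (0-based offset into the
sequence).  Plain reads may be aligned but not localized.

Only files with extensions fa, fas, fast, fasta, fq, fastq are accepted,
and batches above a configurable size cap (default 5 MB) are rejected
before parsing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from Bio import SeqIO

from .errors import (
    BatchSizeError,
    ExtensionError,
    FlankingFormatError,
    ValidationError,
)
from .nomenclature import VariantClass, format_allele_token, parse_allele_token
from .sequences import is_nucleotide_string, reverse_complement

__all__ = [
    "FlankingRecord",
    "ALLOWED_EXTENSIONS",
    "MAX_BATCH_BYTES",
    "MAX_QUERY_LENGTH",
    "read_flanking",
    "write_bracket_fasta",
    "write_sam",
]

ALLOWED_EXTENSIONS = ("fa", "fas", "fast", "fasta", "fq", "fastq")
_FASTQ_EXTENSIONS = ("fq", "fastq")
MAX_BATCH_BYTES = 5 * 1024 * 1024  # 5 MB upload cap
MAX_QUERY_LENGTH = 1024  # longest supported query


@dataclass(frozen=True)
class FlankingRecord:
    """A query read with the variant site and candidate alleles marked.

    ``variant_class`` is ``None`` for a plain read with no marked site
    (alignable, not localizable).  ``quality`` carries FASTQ per-base
    scores opaquely (flank bases only, in flank order).
    """

    query_id: str
    five_prime: str
    alleles: Tuple[str, ...]
    variant_class: Optional[VariantClass]
    three_prime: str
    quality: Optional[str] = None
    description: str = ""
    truncated: bool = False

    def __post_init__(self):
        for flank, label in ((self.five_prime, "5'"), (self.three_prime, "3'")):
            if not is_nucleotide_string(flank):
                raise FlankingFormatError(
                    f"{self.query_id}: {label} flank contains non-nucleotide characters"
                )
        object.__setattr__(self, "five_prime", self.five_prime.upper())
        object.__setattr__(self, "three_prime", self.three_prime.upper())
        if not self.five_prime and not self.three_prime:
            raise FlankingFormatError(f"{self.query_id}: both flanks empty")
        if len(self.five_prime) + len(self.three_prime) > MAX_QUERY_LENGTH:
            raise FlankingFormatError(
                f"{self.query_id}: flanks exceed {MAX_QUERY_LENGTH} bases"
            )

    @property
    def has_variant(self) -> bool:
        return self.variant_class is not None

    def bracket_sequence(self) -> str:
        """The sequence with the variant site re-serialized as a bracket group."""
        if not self.has_variant:
            return self.five_prime + self.three_prime
        if self.variant_class is VariantClass.SUBSTITUTION:
            inner = "/".join(self.alleles)
        elif self.variant_class is VariantClass.INSERTION:
            inner = f"-/{self.alleles[0]}"
        else:
            inner = f"{self.alleles[0]}/-"
        return f"{self.five_prime}[{inner}]{self.three_prime}"

    def reverse_complemented(self) -> "FlankingRecord":
        """The same variant read off the opposite strand."""
        return replace(
            self,
            five_prime=reverse_complement(self.three_prime),
            three_prime=reverse_complement(self.five_prime),
            alleles=tuple(reverse_complement(a) for a in self.alleles),
            quality=self.quality[::-1] if self.quality else None,
        )


_BRACKET_RE = re.compile(r"\[([^\[\]]*)\]")


def _parse_bracket(query_id: str, inner: str) -> Tuple[VariantClass, Tuple[str, ...]]:
    parts = inner.split("/")
    if len(parts) == 2 and parts[0] == "-" and parts[1] != "-":
        vc, alleles = VariantClass.INSERTION, (parts[1],)
    elif len(parts) == 2 and parts[1] == "-" and parts[0] != "-":
        vc, alleles = VariantClass.DELETION, (parts[0],)
    elif "-" in parts:
        raise FlankingFormatError(
            f"{query_id}: malformed bracket group [{inner}]"
        )
    else:
        vc = VariantClass.SUBSTITUTION
        alleles = tuple(parts)
    try:
        from .nomenclature import _check_alleles

        alleles = _check_alleles(vc, alleles)
    except ValidationError as e:
        raise FlankingFormatError(f"{query_id}: bad bracket group [{inner}]: {e}") from e
    return vc, alleles


def _record_from_bracket_sequence(
    query_id: str, seq: str, description: str = ""
) -> FlankingRecord:
    groups = _BRACKET_RE.findall(seq)
    if len(groups) > 1:
        raise FlankingFormatError(
            f"{query_id}: {len(groups)} bracket groups; exactly one variant site allowed"
        )
    if not groups:
        if "[" in seq or "]" in seq:
            raise FlankingFormatError(f"{query_id}: unbalanced bracket")
        return FlankingRecord(query_id, seq, (), None, "", description=description)
    m = _BRACKET_RE.search(seq)
    vc, alleles = _parse_bracket(query_id, m.group(1))
    return FlankingRecord(
        query_id,
        seq[: m.start()],
        alleles,
        vc,
        seq[m.end():],
        description=description,
        truncated="truncated" in description,
    )


_ANNOT_RE = re.compile(r"variant_at=(\d+);alleles=(\S+)")


def _record_from_fastq(rec) -> FlankingRecord:
    seq = str(rec.seq)
    qual = "".join(chr(q + 33) for q in rec.letter_annotations.get("phred_quality", []))
    m = _ANNOT_RE.search(rec.description or "")
    if m is None:
        return FlankingRecord(
            rec.id, seq, (), None, "", quality=qual or None,
            description=rec.description or "",
        )
    offset = int(m.group(1))
    try:
        vc, alleles = parse_allele_token(m.group(2))
    except ValidationError as e:
        raise FlankingFormatError(f"{rec.id}: bad alleles annotation: {e}") from e
    if offset > len(seq):
        raise FlankingFormatError(f"{rec.id}: variant_at={offset} beyond read end")
    if vc is VariantClass.DELETION:
        # the deleted base is absent from the read; offset marks the junction
        five, three = seq[:offset], seq[offset:]
        q5, q3 = qual[:offset], qual[offset:]
    else:
        if offset >= len(seq):
            raise FlankingFormatError(f"{rec.id}: variant_at={offset} beyond read end")
        five, three = seq[:offset], seq[offset + 1:]
        q5, q3 = qual[:offset], qual[offset + 1:]
    return FlankingRecord(
        rec.id, five, alleles, vc, three, quality=(q5 + q3) or None,
        description=rec.description or "",
    )


def _check_extension(path: Path) -> str:
    ext = path.suffix.lstrip(".").lower()
    if ext not in ALLOWED_EXTENSIONS:
        raise ExtensionError(
            f"{path.name}: only files with extensions "
            f"{', '.join(ALLOWED_EXTENSIONS)} are allowed"
        )
    return ext


def read_flanking(
    path: str | Path,
    format: str = "auto",
    max_batch_bytes: Optional[int] = MAX_BATCH_BYTES,
) -> List[FlankingRecord]:
    """Read a batch of flanking-sequence records.

    ``format`` is ``fasta``, ``fastq`` or ``auto`` (from the extension).
    Extension and batch-size checks run before any parsing.
    """
    path = Path(path)
    ext = _check_extension(path)
    if max_batch_bytes is not None and path.stat().st_size > max_batch_bytes:
        raise BatchSizeError(
            f"{path.name}: batch exceeds the {max_batch_bytes} byte cap"
        )
    if format == "auto":
        format = "fastq" if ext in _FASTQ_EXTENSIONS else "fasta"
    if format not in ("fasta", "fastq"):
        raise ValueError(f"format must be fasta, fastq or auto, got {format!r}")

    records: List[FlankingRecord] = []
    if format == "fastq":
        for rec in SeqIO.parse(str(path), "fastq"):
            records.append(_record_from_fastq(rec))
    else:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(
                _record_from_bracket_sequence(
                    rec.id, str(rec.seq), rec.description or ""
                )
            )
    return records


def write_bracket_fasta(records: Sequence[FlankingRecord], path: str | Path) -> None:
    """Serialize records in the bracket-FASTA dialect (round-trippable)."""
    with open(path, "w") as fh:
        for r in records:
            desc = f" {r.description}" if r.description and r.description != r.query_id else ""
            fh.write(f">{r.query_id}{desc}\n{r.bracket_sequence()}\n")


def write_sam(
    alignments: Sequence[tuple],
    reference_lengths: dict,
    path: str | Path,
) -> None:
    """Write alignments as SAM v1 for downstream analysis.

    ``alignments`` is a sequence of ``(query_id, sequence, hit)`` tuples
    where ``hit`` is an :class:`~uasis.aligner.AlignmentHit` or ``None``
    for an unaligned read.  ``sequence`` is the aligned query on the
    forward read orientation; for ``-`` strand hits it is stored
    reverse-complemented with FLAG bit 16 set, per SAM convention.
    Mismatch counts go to the ``NM`` tag.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in reference_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for query_id, seq, hit in alignments:
            if hit is None:
                fh.write(
                    f"{query_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n"
                )
                continue
            flag = 16 if hit.strand == "-" else 0
            out_seq = reverse_complement(seq) if hit.strand == "-" else seq
            fh.write(
                f"{query_id}\t{flag}\t{hit.chromosome}\t{hit.start}\t255\t"
                f"{len(seq)}M\t*\t0\t0\t{out_seq}\t*\tNM:i:{hit.mismatches}\n"
            )
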