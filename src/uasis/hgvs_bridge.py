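"""Bridge between universal names and genomic-level HGVS names.

HGVS genomic names such as ``NT_021937.19:g.7871183G>A`` place a variant
on a specific accessioned reference sequence (a contig or scaffold), not
on the genome as a whole.  One SNP therefore has as many legal HGVS names
as there are accessions covering it — the reverse translation is
one-to-many.  Translating between the two worlds needs to know where each
accession sits on the genome; that placement is supplied explicitly as an
:class:`AccessionMap` (a 6-column TSV), since accession placements are
not derivable from the name strings themselves.

Scope: genomic (``g.``) single-base forms only.  Coding (``c.``),
protein (``p.``), mitochondrial/non-coding prefixes, position ranges and
multi-base payloads are recognized and rejected with
:class:`~uasis.errors.UnsupportedHgvsError` — translating them would
require transcript models that are deliberately out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

from .errors import (
    HgvsSyntaxError,
    UnmappedAccessionError,
    UnsupportedHgvsError,
    XrefFormatError,
)
from .nomenclature import UasisName, VariantClass, _check_chromosome
from .sequences import complement

__all__ = [
    "GenomicHgvsName",
    "AccessionEntry",
    "AccessionMap",
    "parse_hgvs_g",
    "format_hgvs_g",
    "hgvs_to_uasis",
    "uasis_to_hgvs",
    "load_accession_map",
]


@dataclass(frozen=True)
class GenomicHgvsName:
    """A single-base genomic (``g.``) HGVS name, decomposed."""

    accession: str
    version: int
    position: int  # 1-based on the accession's own coordinate system
    variant_class: VariantClass
    ref_base: Optional[str] = None  # substitution only
    alt_base: Optional[str] = None  # substitution only
    payload: Optional[str] = None  # ins/del single-base payload

    @property
    def key(self) -> str:
        return f"{self.accession}.{self.version}"

    def __str__(self) -> str:
        return format_hgvs_g(self)


@dataclass(frozen=True)
class AccessionEntry:
    """Placement of one accession on the genome.

    ``genome_start`` is the 1-based genome position of the accession's
    first covered base; the accession spans
    ``genome_start .. genome_start + length - 1``.  On the ``-`` strand
    the accession's base 1 corresponds to the span's *last* genome
    position and bases are complemented.
    """

    accession: str
    version: int
    chromosome: str
    genome_start: int
    strand: str  # "+" or "-"
    length: int

    def __post_init__(self):
        object.__setattr__(self, "chromosome", _check_chromosome(self.chromosome))
        if self.strand not in ("+", "-"):
            raise XrefFormatError(f"strand must be + or -, got {self.strand!r}")
        if self.genome_start < 1 or self.length < 1:
            raise XrefFormatError("genome_start and length must be >= 1")

    @property
    def key(self) -> str:
        return f"{self.accession}.{self.version}"

    @property
    def genome_end(self) -> int:
        return self.genome_start + self.length - 1

    def covers(self, chromosome: str, locus: int) -> bool:
        return (
            chromosome == self.chromosome
            and self.genome_start <= locus <= self.genome_end
        )

    def to_genome(self, position: int) -> int:
        """Genome locus of accession position ``position`` (1..length)."""
        if not 1 <= position <= self.length:
            raise UnmappedAccessionError(
                f"position {position} outside accession span 1..{self.length} "
                f"of {self.key}"
            )
        if self.strand == "+":
            return self.genome_start + position - 1
        return self.genome_start + self.length - position

    def to_accession(self, locus: int) -> int:
        """Accession position of genome locus ``locus`` (must be covered)."""
        if not self.genome_start <= locus <= self.genome_end:
            raise UnmappedAccessionError(
                f"locus {locus} outside genome span of {self.key}"
            )
        if self.strand == "+":
            return locus - self.genome_start + 1
        return self.genome_start + self.length - locus


class AccessionMap:
    """Accession.version → genome placement lookup table."""

    def __init__(self, entries: List[AccessionEntry] = ()):
        self._entries: Dict[str, AccessionEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: AccessionEntry) -> None:
        if entry.key in self._entries:
            raise XrefFormatError(f"duplicate accession key {entry.key}")
        self._entries[entry.key] = entry

    def get(self, key: str) -> Optional[AccessionEntry]:
        return self._entries.get(key)

    def entries(self) -> List[AccessionEntry]:
        return list(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: str) -> bool:
        return key in self._entries


_UNSUPPORTED_PREFIX_RE = re.compile(
    r"^\s*(?P<acc>[A-Za-z0-9_]+)\.(?P<ver>\d+)\s*:\s*(?P<type>[cpmnr])\.", re.IGNORECASE
)
_G_RE = re.compile(
    r"""^\s*(?P<acc>[A-Za-z0-9_]+)\.(?P<ver>\d+)\s*:\s*g\.
        (?P<pos>\d+)
        (?P<rest>\S+)\s*$""",
    re.VERBOSE,
)
_SUB_RE = re.compile(r"^(?P<ref>[ACGTN])>(?P<alt>[ACGTN])$", re.IGNORECASE)
_INDEL_RE = re.compile(r"^(?P<kind>ins|del)(?P<base>[ACGTN])$", re.IGNORECASE)


def parse_hgvs_g(text: str) -> GenomicHgvsName:
    """Parse a genomic single-base HGVS name.

    ``>`` is read as "changed to": the left base is the accession's
    reference base, the right the alternate.
    """
    if not isinstance(text, str) or not text.strip():
        raise HgvsSyntaxError("empty HGVS string")
    m_bad = _UNSUPPORTED_PREFIX_RE.match(text)
    if m_bad:
        raise UnsupportedHgvsError(
            f"{text!r}: only genomic (g.) names are supported, "
            f"not {m_bad.group('type')}. coordinates"
        )
    m = _G_RE.match(text)
    if m is None:
        raise HgvsSyntaxError(f"{text!r} does not match <acc>.<ver>:g.<pos><change>")
    rest = m.group("rest")
    if "_" in rest or "_" in m.group("pos"):
        raise UnsupportedHgvsError(f"{text!r}: position ranges are not supported")
    pos = int(m.group("pos"))
    if pos < 1:
        raise HgvsSyntaxError(f"{text!r}: position must be >= 1")
    acc, ver = m.group("acc"), int(m.group("ver"))
    m_sub = _SUB_RE.match(rest)
    if m_sub:
        ref, alt = m_sub.group("ref").upper(), m_sub.group("alt").upper()
        if ref == alt:
            raise HgvsSyntaxError(f"{text!r}: reference and alternate bases are equal")
        return GenomicHgvsName(acc, ver, pos, VariantClass.SUBSTITUTION, ref, alt)
    m_indel = _INDEL_RE.match(rest)
    if m_indel:
        vc = (
            VariantClass.INSERTION
            if m_indel.group("kind").lower() == "ins"
            else VariantClass.DELETION
        )
        return GenomicHgvsName(acc, ver, pos, vc, payload=m_indel.group("base").upper())
    if re.match(r"^(ins|del)", rest, re.IGNORECASE):
        raise UnsupportedHgvsError(f"{text!r}: multi-base payloads are not supported")
    raise HgvsSyntaxError(f"{text!r}: unrecognized change description {rest!r}")


def format_hgvs_g(h: GenomicHgvsName) -> str:
    if h.variant_class is VariantClass.SUBSTITUTION:
        change = f"{h.ref_base}>{h.alt_base}"
    elif h.variant_class is VariantClass.INSERTION:
        change = f"ins{h.payload}"
    else:
        change = f"del{h.payload}"
    return f"{h.accession}.{h.version}:g.{h.position}{change}"


def hgvs_to_uasis(h: GenomicHgvsName, accession_map: AccessionMap, build: int) -> UasisName:
    """Project an accession-based name onto genome coordinates.

    On the ``-`` strand the position is mirrored through the accession's
    span and bases are complemented.  Alleles come out ordered
    [reference, alternate].
    """
    entry = accession_map.get(h.key)
    if entry is None:
        raise UnmappedAccessionError(f"accession {h.key} not present in the map")
    locus = entry.to_genome(h.position)
    if h.variant_class is VariantClass.SUBSTITUTION:
        ref, alt = h.ref_base, h.alt_base
        if entry.strand == "-":
            ref, alt = complement(ref), complement(alt)
        return UasisName(build, entry.chromosome, locus, VariantClass.SUBSTITUTION, (ref, alt))
    # Indel payloads on the - strand would shift the insertion point in
    # genome coordinates; restricted to + strand placements.
    if entry.strand == "-":
        raise UnsupportedHgvsError(
            f"{h}: ins/del translation through a - strand accession is not supported"
        )
    return UasisName(build, entry.chromosome, locus, h.variant_class, (h.payload,))


def uasis_to_hgvs(u: UasisName, accession_map: AccessionMap) -> List[GenomicHgvsName]:
    """All accession-based names for a universal name; possibly empty.

    One name per accession whose mapped span covers the locus.  For
    substitutions the leftmost allele is taken as the reference base and
    the second as the alternate; alleles beyond the second are dropped in
    the HGVS rendering.  Indels translate only through ``+`` strand
    accessions (skipped silently otherwise).
    """
    out: List[GenomicHgvsName] = []
    for entry in accession_map.entries():
        if not entry.covers(u.chromosome, u.locus):
            continue
        pos = entry.to_accession(u.locus)
        if u.variant_class is VariantClass.SUBSTITUTION:
            ref, alt = u.alleles[0], u.alleles[1]
            if entry.strand == "-":
                ref, alt = complement(ref), complement(alt)
            out.append(
                GenomicHgvsName(
                    entry.accession, entry.version, pos, VariantClass.SUBSTITUTION, ref, alt
                )
            )
        else:
            if entry.strand == "-":
                continue
            out.append(
                GenomicHgvsName(
                    entry.accession, entry.version, pos, u.variant_class,
                    payload=u.alleles[0],
                )
            )
    return out


def load_accession_map(path: str | Path) -> AccessionMap:
    """Load an accession map TSV.

    Columns: ``accession  version  chromosome  genome_start  strand
    length``; tab-separated; header line required; ``#`` comments
    ignored.
    """
    path = Path(path)
    amap = AccessionMap()
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # first non-comment line is the header
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise XrefFormatError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(parts)}"
                )
            acc, ver, chrom, start, strand, length = parts
            try:
                entry = AccessionEntry(
                    acc, int(ver), chrom, int(start), strand, int(length)
                )
            except ValueError as e:
                raise XrefFormatError(f"{path}:{lineno}: {e}") from e
            amap.add(entry)
    if not header_seen:
        raise XrefFormatError(f"{path}: missing header line")
    return amap
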