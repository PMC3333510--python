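"""Universal SNP names: parse, format, validate, canonicalize.

A universal name pins a single-nucleotide variant to the reference genome
itself rather than to any database accession or arbitrary contig:

    HG<build>.<chromosome>:<locus>:<alleles>

e.g. ``HG19.1:11789038:G/A`` — alleles G and A at 1-based position
11789038 of chromosome 1, coordinates on human reference genome build 19.
Substitutions list 2-4 distinct alleles separated by ``/`` (a ``>`` symbol
would lose clarity for tri-/tetra-allelic sites); single-base insertions
and deletions are written ``insX`` / ``delX``.

Indel position convention: the polymorphism occurs *at* the stated locus.
``1234:insT`` places T at position 1234 and displaces the pre-existing
reference base to position 1235.

All positions are 1-based.  Database dump files are frequently 0-based;
:func:`to_one_based` / :func:`to_zero_based` convert explicitly.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .errors import (
    AlleleSetError,
    InvalidAlleleError,
    InvalidBuildError,
    InvalidChromosomeError,
    InvalidLocusError,
    NameSyntaxError,
    ReferenceAlleleMismatchWarning,
)

__all__ = [
    "VariantClass",
    "UasisName",
    "VariantDescriptor",
    "CHROMOSOMES",
    "NUCLEOTIDES",
    "parse_uasis",
    "format_uasis",
    "validate_descriptor",
    "canonicalize_alleles",
    "displaced_reference_position",
    "to_zero_based",
    "to_one_based",
    "parse_allele_token",
    "format_allele_token",
    "DEFAULT_BUILD",
]

#: Legal chromosome tokens, in canonical sort order.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

#: Legal single-base allele characters (N = unclear nucleotide).
NUCLEOTIDES = frozenset("ACGTN")

#: The genome build assumed when none is stated.
DEFAULT_BUILD = 19


class VariantClass(enum.Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"


def _check_build(build: object) -> int:
    if isinstance(build, bool) or not isinstance(build, int):
        raise InvalidBuildError(f"genome build must be an integer, got {build!r}")
    if build < 1:
        raise InvalidBuildError(f"genome build must be positive, got {build}")
    return build


def _check_chromosome(chromosome: object) -> str:
    token = str(chromosome).upper()
    if token.startswith("CHR"):  # never legal inside a canonical name
        raise InvalidChromosomeError(
            f"chromosome token {chromosome!r} carries a 'chr' prefix; "
            "canonical names use the bare token"
        )
    if token not in _CHROM_RANK:
        raise InvalidChromosomeError(
            f"chromosome must be one of 1..22, X, Y; got {chromosome!r}"
        )
    return token


def _check_locus(locus: object) -> int:
    if isinstance(locus, bool) or not isinstance(locus, int):
        raise InvalidLocusError(f"locus must be an integer, got {locus!r}")
    if locus < 1:
        raise InvalidLocusError(f"locus must be >= 1 (positions are 1-based), got {locus}")
    return locus


def _check_alleles(variant_class: VariantClass, alleles: Sequence[str]) -> tuple[str, ...]:
    cleaned = []
    for a in alleles:
        token = str(a).upper()
        if len(token) != 1 or token not in NUCLEOTIDES:
            raise InvalidAlleleError(
                f"allele {a!r} is not a single character in A/C/G/T/N"
            )
        cleaned.append(token)
    if variant_class is VariantClass.SUBSTITUTION:
        if len(cleaned) < 2:
            raise AlleleSetError(
                f"substitution needs at least two alleles, got {len(cleaned)}"
            )
        if len(cleaned) > 4:
            raise AlleleSetError(
                f"substitution accepts at most four alleles, got {len(cleaned)}"
            )
        if len(set(cleaned)) != len(cleaned):
            raise AlleleSetError(f"substitution alleles must be distinct, got {cleaned}")
    else:
        if len(cleaned) != 1:
            raise AlleleSetError(
                f"{variant_class.value} carries exactly one allele, got {len(cleaned)}"
            )
    return tuple(cleaned)


@dataclass(frozen=True)
class UasisName:
    """A fully validated universal SNP name.

    Invariants are enforced at construction; instances are immutable, so a
    ``UasisName`` in hand is always well-formed.
    """

    build: int
    chromosome: str
    locus: int
    variant_class: VariantClass
    alleles: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "build", _check_build(self.build))
        object.__setattr__(self, "chromosome", _check_chromosome(self.chromosome))
        object.__setattr__(self, "locus", _check_locus(self.locus))
        if not isinstance(self.variant_class, VariantClass):
            object.__setattr__(self, "variant_class", VariantClass(self.variant_class))
        object.__setattr__(
            self, "alleles", _check_alleles(self.variant_class, self.alleles)
        )

    @property
    def has_ambiguous_allele(self) -> bool:
        """True when an ``N`` allele makes the name non-canonical."""
        return "N" in self.alleles

    @property
    def chromosome_rank(self) -> int:
        """Position of the chromosome in canonical 1..22, X, Y order."""
        return _CHROM_RANK[self.chromosome]

    def __str__(self) -> str:
        return format_uasis(self)


@dataclass
class VariantDescriptor:
    """Pivot features of a SNP before validation.

    Mirrors :class:`UasisName` field-for-field but enforces nothing; it is
    the raw user input of the name generator.  :func:`validate_descriptor`
    promotes it to a :class:`UasisName`.
    """

    build: int
    chromosome: str
    locus: int
    variant_class: VariantClass | str
    alleles: Sequence[str] = field(default_factory=tuple)


_NAME_RE = re.compile(
    r"""^\s*HG(?P<build>\d+)\.(?P<chrom>[0-9XYxy]{1,2})
        :(?P<locus>-?\d+)
        :(?P<alleles>\S+)\s*$""",
    re.IGNORECASE | re.VERBOSE,
)


def parse_allele_token(token: str) -> tuple[VariantClass, tuple[str, ...]]:
    """Decompose the allele part of a name: ``G/A``, ``insA`` or ``delT``.

    Case-insensitive; validates allele characters and counts.
    """
    t = token.strip()
    low = t.lower()
    if low.startswith("ins"):
        return VariantClass.INSERTION, _check_alleles(
            VariantClass.INSERTION, [t[3:]] if t[3:] else []
        )
    if low.startswith("del"):
        return VariantClass.DELETION, _check_alleles(
            VariantClass.DELETION, [t[3:]] if t[3:] else []
        )
    parts = t.split("/")
    if len(parts) == 1:
        raise AlleleSetError(
            f"substitution needs at least two /-separated alleles, got {token!r}"
        )
    return VariantClass.SUBSTITUTION, _check_alleles(VariantClass.SUBSTITUTION, parts)


def format_allele_token(variant_class: VariantClass, alleles: Sequence[str]) -> str:
    if variant_class is VariantClass.INSERTION:
        return f"ins{alleles[0]}"
    if variant_class is VariantClass.DELETION:
        return f"del{alleles[0]}"
    return "/".join(alleles)


def parse_uasis(name_string: str) -> UasisName:
    """Parse a universal name string into its components.

    Accepts lower- or mixed-case input; the canonical rendering
    (:func:`format_uasis`) is upper-case with lower-case ``ins``/``del``.

    Raises a field-specific :class:`~uasis.errors.ValidationError`
    subclass on every malformation; no failure is a generic exception.
    """
    if not isinstance(name_string, str) or not name_string.strip():
        raise NameSyntaxError("empty name string")
    m = _NAME_RE.match(name_string)
    if m is None:
        raise NameSyntaxError(
            f"{name_string!r} does not match HG<build>.<chrom>:<locus>:<alleles>"
        )
    locus = int(m.group("locus"))
    variant_class, alleles = parse_allele_token(m.group("alleles"))
    return UasisName(
        build=int(m.group("build")),
        chromosome=m.group("chrom").upper(),
        locus=locus,
        variant_class=variant_class,
        alleles=alleles,
    )


def format_uasis(name: UasisName) -> str:
    """Render the canonical string form; inverse of :func:`parse_uasis`."""
    return (
        f"HG{name.build}.{name.chromosome}:{name.locus}:"
        f"{format_allele_token(name.variant_class, name.alleles)}"
    )


def validate_descriptor(d: VariantDescriptor) -> UasisName:
    """Strictly validate user-supplied pivot features.

    Same rule set as :func:`parse_uasis`, applied to structured input.
    Chromosome may arrive as an int or string; alleles may arrive
    lower-case.
    """
    vc = d.variant_class
    if not isinstance(vc, VariantClass):
        try:
            vc = VariantClass(str(vc).lower())
        except ValueError:
            raise AlleleSetError(f"unknown variant class {d.variant_class!r}") from None
    return UasisName(
        build=d.build,
        chromosome=d.chromosome,
        locus=d.locus,
        variant_class=vc,
        alleles=tuple(d.alleles),
    )


def canonicalize_alleles(
    name: UasisName, reference_base: Optional[str] = None
) -> UasisName:
    """Move the reference-genome allele to the leftmost slot.

    The leftmost allele is conventionally the one on the reference genome
    (ideally the major allele, but allele frequencies are not modeled
    here).  Other alleles keep their relative order.  Idempotent; never
    changes the allele multiset.

    If ``reference_base`` is absent the name is returned untouched.  If it
    is supplied but not among the recorded alleles, the name is returned
    unchanged and a :class:`ReferenceAlleleMismatchWarning` is issued —
    allele observations differ between populations and laboratories, so
    this is not an error.
    """
    if name.variant_class is not VariantClass.SUBSTITUTION or reference_base is None:
        return name
    ref = str(reference_base).upper()
    if ref not in name.alleles:
        warnings.warn(
            f"reference base {ref!r} is not among recorded alleles "
            f"{'/'.join(name.alleles)} at {name.chromosome}:{name.locus}",
            ReferenceAlleleMismatchWarning,
            stacklevel=2,
        )
        return name
    if name.alleles[0] == ref:
        return name
    reordered = (ref,) + tuple(a for a in name.alleles if a != ref)
    return replace(name, alleles=reordered)


def displaced_reference_position(name: UasisName) -> Optional[int]:
    """Where the pre-existing reference base lands after an insertion.

    An insertion written at locus p puts the new base at p, pushing the
    base that previously occupied p to p+1.  Returns ``None`` for
    substitutions and deletions, where no base is displaced.
    """
    if name.variant_class is VariantClass.INSERTION:
        return name.locus + 1
    return None


def to_zero_based(locus_1based: int) -> int:
    """Convert a 1-based position to 0-based (dump-file convention)."""
    if locus_1based < 1:
        raise InvalidLocusError(f"1-based locus must be >= 1, got {locus_1based}")
    return locus_1based - 1


def to_one_based(locus_0based: int) -> int:
    """Convert a 0-based position to the 1-based convention used here."""
    if locus_0based < 0:
        raise InvalidLocusError(f"0-based locus must be >= 0, got {locus_0based}")
    return locus_0based + 1
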