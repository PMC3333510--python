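"""Exception and warning taxonomy.

Every validation failure carries the name of the offending field so callers
(and the CLI) can report field-level messages instead of a generic parse
error.
"""

from __future__ import annotations


class UasisError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(UasisError, ValueError):
    """A name, descriptor or record violated an invariant.

    Attributes
    ----------
    field : str
        The name of the offending field (``"locus"``, ``"alleles"``, ...).
    """

    field: str = ""

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        if field is not None:
            self.field = field


class NameSyntaxError(ValidationError):
    """The name string does not match the universal-name grammar."""

    field = "name"


class InvalidChromosomeError(ValidationError):
    """Chromosome token outside {1..22, X, Y}."""

    field = "chromosome"


class InvalidLocusError(ValidationError):
    """Locus below the 1-based floor, or otherwise not a positive integer."""

    field = "locus"


class InvalidAlleleError(ValidationError):
    """An allele token is not a single character in {A, C, G, T, N}."""

    field = "alleles"


class AlleleSetError(ValidationError):
    """Wrong number of alleles for the variant class, or duplicates."""

    field = "alleles"


class InvalidBuildError(ValidationError):
    """Genome build is not a positive integer."""

    field = "build"


class HgvsSyntaxError(ValidationError):
    """Text does not parse as a genomic-level HGVS name."""

    field = "hgvs"


class UnsupportedHgvsError(UasisError):
    """A recognized HGVS form outside the genomic single-base scope.

    Coding (``c.``), protein (``p.``), mitochondrial (``m.``) and
    non-coding (``n.``) coordinates, ranges and multi-base payloads are
    recognized but not translated.
    """


class UnmappedAccessionError(UasisError):
    """The accession.version is absent from the supplied accession map."""


class XrefFormatError(UasisError):
    """A cross-reference snapshot row is malformed (reports line number)."""


class FlankingFormatError(UasisError):
    """A flanking-sequence record is malformed (bad bracket group, etc.)."""


class ExtensionError(UasisError):
    """Input file extension is not one of fa/fas/fast/fasta/fq/fastq."""


class BatchSizeError(UasisError):
    """Input batch exceeds the configured size cap."""


class ReferenceFormatError(UasisError):
    """Reference FASTA is empty or contains non-nucleotide characters."""


class ReadLengthError(UasisError):
    """Query read shorter than 4 or longer than 1024 bases."""


class FixtureSpecError(UasisError):
    """Synthetic-fixture parameters are infeasible (e.g. SNPs too dense)."""


class ReferenceAlleleMismatchWarning(UserWarning):
    """The supplied reference base is not among the recorded alleles.

    Allele observations are population-dependent, so a disagreement with
    the reference genome is reported as a warning, never an error.
    """


class NonCanonicalAlleleWarning(UserWarning):
    """An ``N`` allele appears where a concrete base is conventional."""
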