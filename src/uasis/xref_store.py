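"""Local cross-database identifier snapshot and the name mapper.

Each record links one genomic position (chromosome, 1-based locus) and
its allele string to the identifiers the major SNP databases assign it:
dbSNP rs#, JSNP ``IMS-JST`` ids, HapMap ids and GWAS ``HGVM`` ids.  The
snapshot is a flat TSV standing in for the server-side relational store
a production deployment would use; structure and lookup semantics are
the same at any scale.

Lookup semantics follow the cross-referencing rule that two databases
record "the same SNP" when they record a SNP at the same locus —
alleles are deliberately NOT compared.

Three distinct negative outcomes, rendered exactly:

* ``"Not Aligned"`` — a read found no genome placement (aligner's job);
* ``"none"``        — a specific database holds no identifier (per field);
* ``"None"``        — the input name itself could not be resolved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .errors import NameSyntaxError, ValidationError, XrefFormatError
from .nomenclature import (
    DEFAULT_BUILD,
    UasisName,
    format_uasis,
    parse_allele_token,
    parse_uasis,
    to_one_based,
)

__all__ = [
    "XrefRecord",
    "XrefStore",
    "MappingReport",
    "load_xref",
    "write_xref",
    "lookup_by_position",
    "map_name",
    "uasis_id_for_record",
    "NONE_FIELD",
    "NONE_NAME",
]

#: Rendered when a single database holds no identifier for a record.
NONE_FIELD = "none"
#: Rendered when an input name cannot be resolved at all.
NONE_NAME = "None"

_ID_COLUMNS = ("rs_id", "jsnp_id", "hapmap_id", "gwas_id")


@dataclass(frozen=True)
class XrefRecord:
    """One snapshot row: a genomic position plus its database identifiers.

    ``alleles`` is kept as stored text (e.g. ``"G/A"``); it may be absent
    (None) — some sources deposit positions without allele information.
    At least one identifier must be present.
    """

    chromosome: str
    locus: int
    alleles: Optional[str] = None
    rs_id: Optional[str] = None
    jsnp_id: Optional[str] = None
    hapmap_id: Optional[str] = None
    gwas_id: Optional[str] = None

    def __post_init__(self):
        if self.locus < 1:
            raise XrefFormatError(f"locus must be >= 1, got {self.locus}")
        if all(getattr(self, c) is None for c in _ID_COLUMNS):
            raise XrefFormatError(
                f"record at {self.chromosome}:{self.locus} carries no identifier"
            )

    def identifiers(self) -> List[str]:
        return [getattr(self, c) for c in _ID_COLUMNS if getattr(self, c) is not None]


class XrefStore:
    """Snapshot records indexed by position and by every identifier."""

    def __init__(self, records: List[XrefRecord] = ()):
        self._records: List[XrefRecord] = []
        self._by_position: Dict[Tuple[str, int], List[XrefRecord]] = {}
        self._by_id: Dict[str, List[XrefRecord]] = {}
        self._seen: set = set()
        for r in records:
            self.add(r)

    def add(self, record: XrefRecord) -> None:
        if record in self._seen:  # identical duplicates dropped silently
            return
        self._seen.add(record)
        self._records.append(record)
        self._by_position.setdefault((record.chromosome, record.locus), []).append(record)
        for ident in record.identifiers():
            self._by_id.setdefault(ident.upper(), []).append(record)

    def records(self) -> List[XrefRecord]:
        return list(self._records)

    def by_identifier(self, ident: str) -> List[XrefRecord]:
        return list(self._by_id.get(ident.upper(), []))

    def __len__(self) -> int:
        return len(self._records)


def load_xref(tsv_path: str | Path) -> XrefStore:
    """Load a cross-reference snapshot TSV.

    Columns ``chrom  pos  alleles  rs  jsnp  hapmap  gwas``; ``-`` marks
    an absent value; an optional directive line ``#coord=0based`` (or
    ``1based``, the default) states the file's coordinate convention —
    0-based positions are converted on load so the store is always
    1-based.  Other ``#`` lines and a literal header line are ignored.
    """
    path = Path(tsv_path)
    zero_based = False
    store = XrefStore()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                directive = stripped.lstrip("#").replace(" ", "").lower()
                if directive == "coord=0based":
                    zero_based = True
                elif directive == "coord=1based":
                    zero_based = False
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise XrefFormatError(
                    f"{path}:{lineno}: expected 7 tab-separated columns, got {len(parts)}"
                )
            if parts[0].lower() in ("chrom", "chromosome"):  # header
                continue
            chrom, pos_s, alleles, rs, jsnp, hapmap, gwas = (p.strip() for p in parts)
            try:
                pos = int(pos_s)
            except ValueError:
                raise XrefFormatError(
                    f"{path}:{lineno}: position {pos_s!r} is not an integer"
                ) from None
            if zero_based:
                pos = to_one_based(pos)
            opt = lambda v: None if v in ("-", "") else v
            try:
                record = XrefRecord(
                    chromosome=chrom.upper().removeprefix("CHR"),
                    locus=pos,
                    alleles=opt(alleles),
                    rs_id=opt(rs),
                    jsnp_id=opt(jsnp),
                    hapmap_id=opt(hapmap),
                    gwas_id=opt(gwas),
                )
            except XrefFormatError as e:
                raise XrefFormatError(f"{path}:{lineno}: {e}") from None
            store.add(record)
    return store


def write_xref(store: XrefStore, tsv_path: str | Path, coord: str = "1based") -> None:
    """Write a store back out in the snapshot TSV dialect."""
    if coord not in ("1based", "0based"):
        raise ValueError(f"coord must be '1based' or '0based', got {coord!r}")
    with open(tsv_path, "w") as fh:
        fh.write(f"#coord={coord}\n")
        fh.write("chrom\tpos\talleles\trs\tjsnp\thapmap\tgwas\n")
        for r in store.records():
            pos = r.locus if coord == "1based" else r.locus - 1
            cells = [r.chromosome, str(pos)] + [
                (getattr(r, c) or "-") for c in ("alleles",) + _ID_COLUMNS
            ]
            fh.write("\t".join(cells) + "\n")


def lookup_by_position(store: XrefStore, chromosome: str, locus: int) -> List[XrefRecord]:
    """All records at an exact (chromosome, locus).

    Alleles are NOT compared: a record whose stored alleles differ from
    the query's is still a positional match.
    """
    if locus < 1:
        raise XrefFormatError(f"locus must be >= 1, got {locus}")
    chrom = str(chromosome).upper().removeprefix("CHR")
    return list(store._by_position.get((chrom, locus), []))


def uasis_id_for_record(r: XrefRecord, build: int = DEFAULT_BUILD) -> Optional[UasisName]:
    """Universal name for a snapshot record, when derivable.

    Requires chromosome, locus AND alleles; allele information is absent
    from many deposits, in which case no universal name is generated.
    """
    if r.alleles is None:
        return None
    try:
        variant_class, alleles = parse_allele_token(r.alleles)
        return UasisName(build, r.chromosome, r.locus, variant_class, alleles)
    except ValidationError:
        return None


@dataclass
class MappingReport:
    """Outcome of resolving one input name across the snapshot.

    ``status`` is ``"OK"`` when anything was resolved and ``"None"``
    when the input is unparseable or matches nothing.  Per-database
    fields hold the identifier or the literal ``"none"``.
    """

    query: str
    status: str = NONE_NAME
    namespace: Optional[str] = None
    uasis: str = NONE_FIELD
    rs: str = NONE_FIELD
    jsnp: str = NONE_FIELD
    hapmap: str = NONE_FIELD
    gwas: str = NONE_FIELD
    records: List[XrefRecord] = field(default_factory=list)

    def as_row(self) -> List[str]:
        return [self.query, self.status, self.uasis, self.rs, self.jsnp,
                self.hapmap, self.gwas]


_RS_RE = re.compile(r"^rs\d+$", re.IGNORECASE)
_SS_RE = re.compile(r"^ss\d+$", re.IGNORECASE)
_JSNP_RE = re.compile(r"^IMS-JST\d+$", re.IGNORECASE)
_GWAS_RE = re.compile(r"^HGVM\d+$", re.IGNORECASE)
_PHARMGKB_RE = re.compile(r"^(rs\d+)@\S+$", re.IGNORECASE)
# genome-browser style: Chr19:11,087,877[-11,087,877] G/T
_BROWSER_RE = re.compile(
    r"""^chr\s*(?P<chrom>[0-9XYxy]{1,2})
        \s*:\s*(?P<start>[\d,]+)
        (?:\s*-\s*(?P<end>[\d,]+))?
        \s+(?P<alleles>\S+)$""",
    re.IGNORECASE | re.VERBOSE,
)


def _detect_namespace(text: str) -> Tuple[Optional[str], Optional[object]]:
    """(namespace label, parsed payload) for a raw input name."""
    t = text.strip()
    if _RS_RE.match(t):
        return "dbsnp", t.lower()
    if _SS_RE.match(t):
        return "dbsnp-ss", t.lower()
    if _JSNP_RE.match(t):
        return "jsnp", t.upper()
    if _GWAS_RE.match(t):
        return "gwas", t.upper()
    m = _PHARMGKB_RE.match(t)
    if m:
        return "pharmgkb", m.group(1).lower()
    m = _BROWSER_RE.match(t)
    if m:
        start = int(m.group("start").replace(",", ""))
        end = m.group("end")
        if end is not None and int(end.replace(",", "")) != start:
            return None, None  # a range is not a single-base variant
        try:
            vc, alleles = parse_allele_token(m.group("alleles"))
        except ValidationError:
            return None, None
        return "browser", (m.group("chrom").upper(), start, vc, alleles)
    try:
        return "uasis", parse_uasis(t)
    except (ValidationError, NameSyntaxError):
        return None, None


def _fill_from_records(report: MappingReport, records: List[XrefRecord], build: int) -> None:
    report.records = records
    for r in records:
        if report.rs == NONE_FIELD and r.rs_id:
            report.rs = r.rs_id
        if report.jsnp == NONE_FIELD and r.jsnp_id:
            report.jsnp = r.jsnp_id
        if report.hapmap == NONE_FIELD and r.hapmap_id:
            report.hapmap = r.hapmap_id
        if report.gwas == NONE_FIELD and r.gwas_id:
            report.gwas = r.gwas_id
        if report.uasis == NONE_FIELD:
            name = uasis_id_for_record(r, build)
            if name is not None:
                report.uasis = format_uasis(name)


def map_name(store: XrefStore, name_text: str, build: int = DEFAULT_BUILD) -> MappingReport:
    """Resolve an existing SNP name (any recognized namespace).

    Recognized namespaces: dbSNP ``rs#``/``ss#``, JSNP ``IMS-JST…``,
    GWAS ``HGVM…``, HapMap (rs-style ids resolve through the hapmap
    column too), a PharmGKB-style ``rs#@chr:pos`` (through its embedded
    rs#), the universal grammar itself, and lenient genome-browser
    syntax ``Chr19:11,087,877 G/T`` (commas stripped, single-position
    ranges collapsed).  Unresolvable input yields status ``"None"``
    rather than an exception.
    """
    report = MappingReport(query=name_text)
    namespace, payload = _detect_namespace(name_text)
    if namespace is None:
        # last-chance: private databases use arbitrary id shapes, so any
        # token stored verbatim in the snapshot still resolves
        records = store.by_identifier(name_text.strip())
        if records:
            report.namespace = "snapshot"
            report.status = "OK"
            _fill_from_records(report, records, build)
        return report
    report.namespace = namespace

    if namespace in ("dbsnp", "dbsnp-ss", "jsnp", "gwas", "pharmgkb"):
        records = store.by_identifier(str(payload))
        if not records:
            return report
        report.status = "OK"
        _fill_from_records(report, records, build)
        return report

    if namespace == "browser":
        chrom, locus, vc, alleles = payload
        try:
            name = UasisName(build, chrom, locus, vc, alleles)
        except ValidationError:
            return report
        report.status = "OK"
        report.uasis = format_uasis(name)
        _fill_from_records(report, lookup_by_position(store, chrom, locus), build)
        report.uasis = format_uasis(name)  # input alleles take precedence
        return report

    # universal name input: reverse lookup by position
    name = payload
    report.status = "OK"
    report.uasis = format_uasis(name)
    _fill_from_records(
        report, lookup_by_position(store, name.chromosome, name.locus), build
    )
    report.uasis = format_uasis(name)
    return report
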