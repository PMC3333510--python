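"""Synthetic study materials: genome, planted SNPs, snapshots, reads.

Stands in for the external inputs a deployment would download — a
reference genome, database dump files and read simulators — with fully
seeded synthetic equivalents:

* a uniform-random A/C/G/T genome (no repeat structure; an optional
  segment-duplication knob creates multi-hit reads to exercise
  ambiguity flagging);
* planted variants whose reference alleles are read off the genome, so
  every truth row is consistent by construction;
* a cross-reference snapshot TSV with fabricated rs/JSNP/HapMap/GWAS
  identifiers for a configurable fraction of the truth rows (the rest
  stay absent, to exercise "none" reporting);
* flanking reads centered on each variant, written in the
  bracket-allele dialect, with uniform per-base substitution errors on
  the flanks (never inside the bracket) and a random 50% strand flip.

Everything is reproducible byte-for-byte under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import FixtureSpecError
from .flanking_io import FlankingRecord, write_bracket_fasta
from .nomenclature import VariantClass
from .xref_store import XrefRecord, XrefStore, write_xref

__all__ = [
    "FixtureSpec",
    "PlantedVariant",
    "generate_genome",
    "plant_snps",
    "emit_flanking_reads",
    "write_genome_fasta",
    "write_truth_tsv",
    "generate_fixture_set",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: The read lengths exercised throughout: typical short-read (35, 76),
#: mid-length (128) and long capillary-style (512) queries.
DEFAULT_READ_LENGTHS = (35, 76, 128, 512)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults define the standard desk-scale conditions: one 100 kb
    chromosome, 500 planted variants (10% indels), read lengths
    35/76/128/512 and a 1% uniform flank substitution-error rate.
    """

    genome_length: int = 100_000
    n_chromosomes: int = 1
    n_snps: int = 500
    read_lengths: Tuple[int, ...] = DEFAULT_READ_LENGTHS
    substitution_error_rate: float = 0.01
    indel_fraction: float = 0.1
    xref_fraction: float = 0.5
    duplicate_segment: Optional[Tuple[int, int]] = None  # (start0, length) to copy
    seed: int = 0

    def __post_init__(self):
        if self.genome_length < 1 or self.n_chromosomes < 1 or self.n_snps < 1:
            raise FixtureSpecError("all counts must be positive")
        if not 0 <= self.substitution_error_rate < 1:
            raise FixtureSpecError("error rate must be in [0, 1)")
        if not 0 <= self.indel_fraction <= 1 or not 0 <= self.xref_fraction <= 1:
            raise FixtureSpecError("fractions must be in [0, 1]")
        if any(l < 20 for l in self.read_lengths):
            raise FixtureSpecError("read lengths must be >= 20")


@dataclass(frozen=True)
class PlantedVariant:
    """One truth-table row."""

    chromosome: str
    locus: int  # 1-based
    variant_class: VariantClass
    alleles: Tuple[str, ...]  # substitutions: (reference, alternate)
    snp_id: str  # synthetic rs-style identifier


def generate_genome(spec: FixtureSpec) -> Dict[str, str]:
    """Uniform-random genome, one entry per chromosome, seeded."""
    rng = np.random.default_rng(spec.seed)
    genome: Dict[str, str] = {}
    for i in range(1, spec.n_chromosomes + 1):
        arr = rng.choice(_BASES, size=spec.genome_length)
        genome[str(i)] = arr.tobytes().decode("ascii")
    if spec.duplicate_segment is not None:
        start0, length = spec.duplicate_segment
        first = genome["1"]
        if start0 < 0 or start0 + 2 * length > len(first):
            raise FixtureSpecError("duplicate segment does not fit twice on chromosome 1")
        # copy the segment to the far end of chromosome 1
        seg = first[start0 : start0 + length]
        genome["1"] = first[: len(first) - length] + seg
    return genome


def plant_snps(
    genome: Dict[str, str], spec: FixtureSpec
) -> Tuple[List[PlantedVariant], XrefStore]:
    """Plant variants at random distinct loci; build the truth + snapshot.

    Loci keep a margin of max(read_lengths)/2 + 2 from contig ends so
    centered reads are never truncated at default settings.  Density is
    capped at one variant per 10 bases of genome.
    """
    total_len = sum(len(s) for s in genome.values())
    if spec.n_snps > total_len // 10:
        raise FixtureSpecError(
            f"{spec.n_snps} variants on a {total_len} bp genome is too dense "
            "(max 1 per 10 bp)"
        )
    rng = np.random.default_rng(spec.seed + 1)
    margin = max(spec.read_lengths) // 2 + 2
    truth: List[PlantedVariant] = []
    xrefs: List[XrefRecord] = []
    counter = 1
    for chrom in sorted(genome, key=lambda c: (len(c), c)):
        seq = genome[chrom]
        share = round(spec.n_snps * len(seq) / total_len)
        if chrom == sorted(genome, key=lambda c: (len(c), c))[-1]:
            share = spec.n_snps - len(truth)
        lo, hi = margin + 1, len(seq) - margin  # 1-based inclusive bounds
        if hi - lo + 1 < share:
            raise FixtureSpecError(f"chromosome {chrom} too short for {share} variants")
        loci = rng.choice(np.arange(lo, hi + 1), size=share, replace=False)
        loci.sort()
        for locus in map(int, loci):
            ref = seq[locus - 1]
            u = rng.random()
            if u < spec.indel_fraction:
                if rng.random() < 0.5:
                    vc = VariantClass.INSERTION
                    alleles = (str(rng.choice(list("ACGT"))),)
                else:
                    vc = VariantClass.DELETION
                    alleles = (ref,)
            else:
                vc = VariantClass.SUBSTITUTION
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                alleles = (ref, alt)
            snp_id = f"rs9{counter:06d}"
            truth.append(PlantedVariant(chrom, locus, vc, alleles, snp_id))
            if rng.random() < spec.xref_fraction:
                allele_text = (
                    "/".join(alleles)
                    if vc is VariantClass.SUBSTITUTION
                    else ("ins" if vc is VariantClass.INSERTION else "del") + alleles[0]
                )
                xrefs.append(
                    XrefRecord(
                        chromosome=chrom,
                        locus=locus,
                        alleles=allele_text if rng.random() < 0.8 else None,
                        rs_id=snp_id,
                        jsnp_id=f"IMS-JST{counter:06d}" if rng.random() < 0.5 else None,
                        hapmap_id=snp_id if rng.random() < 0.5 else None,
                        gwas_id=f"HGVM{counter:06d}" if rng.random() < 0.5 else None,
                    )
                )
            counter += 1
    return truth, XrefStore(xrefs)


def _apply_errors(flank: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0 or not flank:
        return flank
    out = list(flank)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in map(int, hits):
        out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


def emit_flanking_reads(
    genome: Dict[str, str],
    truth: Sequence[PlantedVariant],
    read_length: int,
    error_rate: float = 0.0,
    seed: int = 0,
    strand_flip: bool = True,
) -> List[FlankingRecord]:
    """Centered bracket-dialect reads for every truth variant.

    The window spans ``read_length`` bases of the variant region
    (flanks plus, for substitution/deletion, the variant base itself;
    an insertion contributes no reference base, so its flanks sum to
    ``read_length - 1``).  Substitution errors hit flank bases only.
    Half the reads (seeded coin) are emitted from the minus strand,
    properly reverse-complemented.  Reads clipped by a contig end are
    flagged ``truncated`` in their description.
    """
    if read_length < 20:
        raise FixtureSpecError(f"read_length must be >= 20, got {read_length}")
    rng = np.random.default_rng(seed + 2)
    reads: List[FlankingRecord] = []
    n5_target = (read_length - 1) // 2
    n3_target = read_length - 1 - n5_target
    for v in truth:
        seq = genome[v.chromosome]
        if v.variant_class is VariantClass.INSERTION:
            # inserted base is written at v.locus: 5' flank ends at locus-1,
            # 3' flank starts at the displaced base (old occupant of locus)
            five_start = max(0, v.locus - 1 - n5_target)
            five = seq[five_start : v.locus - 1]
            three = seq[v.locus - 1 : v.locus - 1 + n3_target]
        elif v.variant_class is VariantClass.DELETION:
            five_start = max(0, v.locus - 1 - n5_target)
            five = seq[five_start : v.locus - 1]
            three = seq[v.locus : v.locus + n3_target]
        else:
            five_start = max(0, v.locus - 1 - n5_target)
            five = seq[five_start : v.locus - 1]
            three = seq[v.locus : v.locus + n3_target]
        truncated = len(five) < n5_target or len(three) < n3_target
        five = _apply_errors(five, rng, error_rate)
        three = _apply_errors(three, rng, error_rate)
        rec = FlankingRecord(
            query_id=f"q_{v.snp_id}_L{read_length}",
            five_prime=five,
            alleles=v.alleles,
            variant_class=v.variant_class,
            three_prime=three,
            description="truncated" if truncated else "",
            truncated=truncated,
        )
        if strand_flip and rng.random() < 0.5:
            rec = rec.reverse_complemented()
        reads.append(rec)
    return reads


def write_genome_fasta(genome: Dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_tsv(truth: Sequence[PlantedVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlocus\tclass\talleles\tid\n")
        for v in truth:
            fh.write(
                f"{v.chromosome}\t{v.locus}\t{v.variant_class.value}\t"
                f"{'/'.join(v.alleles)}\t{v.snp_id}\n"
            )


def generate_fixture_set(spec: FixtureSpec, out_dir: str | Path) -> Dict[str, Path]:
    """Write the four study files; returns their paths.

    ``reference.fa`` (genome), ``reads_L<length>.fa`` per read length
    (bracket dialect, at the spec's error rate), ``xref.tsv``
    (snapshot) and ``truth.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(spec)
    truth, store = plant_snps(genome, spec)
    paths: Dict[str, Path] = {}
    paths["reference"] = out / "reference.fa"
    write_genome_fasta(genome, paths["reference"])
    paths["xref"] = out / "xref.tsv"
    write_xref(store, paths["xref"])
    paths["truth"] = out / "truth.tsv"
    write_truth_tsv(truth, paths["truth"])
    for L in spec.read_lengths:
        reads = emit_flanking_reads(
            genome, truth, L, spec.substitution_error_rate, seed=spec.seed
        )
        p = out / f"reads_L{L}.fa"
        write_bracket_fasta(reads, p)
        paths[f"reads_L{L}"] = p
    return paths
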