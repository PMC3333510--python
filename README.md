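# uasis — universal SNP nomenclature toolkit

Researchers describe the same single-nucleotide polymorphism in many
incompatible ways: a dbSNP `rs#`, a JSNP `IMS-JST` id, a HapMap or
GWAS id, half a dozen equally legal HGVS names on different reference
sequences, or a lab-private label. None of these is informative,
database-independent *and* unique, which makes cross-referencing SNPs
between databases and tracking them through the literature painful.

This package implements a universal, database-independent SNP name
anchored directly on the reference genome,

```
HG<build>.<chromosome>:<locus>:<alleles>
```

e.g. `HG19.1:11789038:G/A` — alleles G and A at 1-based position
11789038 of chromosome 1, human genome build 19; indels are written
`insX`/`delX` (an insertion at locus *p* places the new base at *p*
and displaces the old occupant to *p*+1). Around the name sit the
tools that make it useful:

* **nomenclature** — parse, format, strictly validate and canonicalize
  names (reference allele leftmost, explicit 0-based/1-based
  conversion);
* **hgvs_bridge** — translate genomic (`g.`) HGVS names to and from
  universal names through an explicit accession→genome map;
* **xref_store** — a local cross-database snapshot (TSV) with
  position-based lookup and a name mapper that resolves `rs#`, JSNP,
  HapMap, GWAS, PharmGKB-style and genome-browser-style names;
* **aligner** — a mismatch-tolerant, gapless k-mer seed-and-extend
  aligner that places flanking sequences on a reference and projects
  the marked variant site to a genomic coordinate (≤3 mismatches, ≤2
  reported hits by default, both configurable);
* **flanking_io** — bracket-dialect FASTA (`ACGT[G/A]TTCA`), annotated
  FASTQ, and SAM export;
* **fixtures** — a seeded synthetic-study generator (genome, planted
  SNPs, snapshot, reads) so everything is testable end to end with no
  downloads;
* **cli** — `uasis name | map | align | fixtures`.

It is a library first: see `examples/` for short narrative scripts,
one per capability.

## Worked example

```python
>>> from uasis import parse_uasis, displaced_reference_position
>>> n = parse_uasis("HG19.1:11789038:G/A")
>>> n.chromosome, n.locus, n.alleles
('1', 11789038, ('G', 'A'))
>>> displaced_reference_position(parse_uasis("HG19.1:1234:insT"))
1235
```

End to end on synthetic data (`python examples/align_flanks.py`):

```
first read (bracket dialect): GTGGCAAACACGTGAGAGTCTAACGGACATCTATGCTC[T/A]ACTCCTGAAGCAGCCGT ...
recovered 100/100 planted variants exactly
example: q_rs9000001_L76 -> HG19.1:460:A/T (strand -, 0 mismatches)
```

100 SNPs were planted on a seeded 50 kb genome, 76-base flanking reads
were emitted (half reverse-complemented), and every variant was
localized back to its exact planted locus; the printed name is the
canonical universal identifier with the reference allele leftmost.

From the shell:

```bash
uasis fixtures --out-dir demo --genome-length 20000 --n-snps 50 --seed 7
uasis align demo/reads_L76.fa --reference demo/reference.fa --xref demo/xref.tsv
uasis name --chrom 1 --pos 11789038 --alleles G/A
uasis map rs3737965 --xref demo/xref.tsv
```

The aligner output is a TSV with one row per read: query id, placement
(chromosome, position, strand, mismatches), alleles, the universal
identifier, and the rs/JSNP/HapMap/GWAS columns — `none` where a
database has no record, `Not Aligned` where the read has no placement,
and `None` when an input name cannot be resolved at all.

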