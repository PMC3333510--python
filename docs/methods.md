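# Methods

## The naming model

A single-nucleotide variant is identified by its position on the human
reference genome itself, not by a database accession or an arbitrary
contig:

```
HG<build>.<chromosome>:<locus>:<alleles>
```

`build` is the UCSC human-genome version number (HG19 is the default
and the only build bundled with the synthetic fixtures); `chromosome`
is one of `1..22, X, Y`; `locus` is a **1-based** position; `alleles`
is either a `/`-separated list of 2–4 distinct bases (substitution), or
`insX` / `delX` for single-base indels. `N` denotes an unclear
nucleotide and is accepted anywhere a base is, including substitution
allele lists and indel payloads — by symmetry with its status as a
nucleotide token — but names containing `N` are flagged non-canonical
(`UasisName.has_ambiguous_allele`).

Two conventions do the real work:

* **Allele order.** The leftmost substitution allele is the one on the
  reference genome (ideally the major allele, but allele frequencies
  are population-dependent and are not modeled).
  `canonicalize_alleles` enforces this given a reference base; if the
  supplied reference base is not among the recorded alleles the name is
  returned unchanged with a `ReferenceAlleleMismatchWarning` — a
  disagreement between a lab's observed alleles and the reference
  genome is an observation, not an error.
* **Indel position.** The polymorphism occurs *at* the stated locus:
  `1234:insT` writes T at position 1234 and displaces the base that
  previously occupied 1234 to 1235 (`displaced_reference_position`).
  Deletions delete the base at the stated locus.

All internal coordinates are 1-based. Database dump files are often
0-based; `to_zero_based`/`to_one_based` convert explicitly, and the
snapshot loader honors a `#coord=0based` directive so stores are always
1-based in memory.

Scope is deliberately single-base: multi-base deletions/insertions,
ranges, inversions, CNVs and transcript-level (`c.`/`p.`) forms are out
of scope. HGVS genomic (`g.`) single-base names are translated through
a user-supplied accession map (see below); coding-coordinate names are
recognized and rejected with a distinct `UnsupportedHgvsError` because
translating them would require transcript models.

## HGVS bridging

An accession map (6-column TSV: accession, version, chromosome,
genome_start, strand, length) states where each accessioned sequence
sits on the genome. For a `+` strand accession, genome locus =
genome_start + position − 1; for `−` strand the position is mirrored
through the span (locus = genome_start + length − position) and bases
are complemented; the mirror is an involution, which the tests check
directly against a planted reverse-complemented accession. The reverse
direction (universal → HGVS) is one-to-many: one name per covering
accession. Indel payload translation through `−` strand accessions is
rejected rather than risking an off-by-one on the insertion point; for
multi-allelic substitutions only the first ref/alt pair renders into
the `>` form, which cannot express more than two alleles.

## Cross-reference snapshot and mapping

The snapshot (7-column TSV) links a position to dbSNP rs#, JSNP,
HapMap and GWAS identifiers, replacing a server-side SQL store with a
flat file of identical structure; identical duplicate rows are dropped
silently, and every record must carry at least one identifier.
Position lookup is deliberately allele-blind: two databases record
"the same SNP" when they record a SNP at the same locus, whatever
alleles they deposited.

Name mapping detects the input namespace by pattern (`rs\d+`,
`ss\d+`, `IMS-JST\d+`, `HGVM\d+`, the universal grammar, a
PharmGKB-style `rs#@…` resolved through its embedded rs#, and lenient
genome-browser syntax `Chr19:11,087,877[-11,087,877] G/T` with commas
stripped), with a final fallback that matches arbitrary stored tokens
so private-database ids resolve too. Three negative outcomes are kept
verbatim distinct: per-database `none` (no identifier in that
database), whole-report `None` (the input name is unresolvable — also
returned when a syntactically valid id simply is not in the snapshot),
and `Not Aligned` (a read with no genome placement). A universal name
is emitted for a record only when chromosome, locus *and* alleles are
all recoverable; records without allele information get `none`.

## Flanking reads and the bracket dialect

The variant site inside an uploaded FASTA sequence is marked with a
bracket group (`[G/A]`, `[-/T]` insertion, `[T/-]` deletion) — the
rs_fasta dump convention — with exactly one group per record. FASTQ
stays standard-conformant: a plain read unless the description carries
`variant_at=<0-based offset>;alleles=<token>` (for deletions the
offset marks the junction, since the deleted base is absent from the
read). Accepted extensions are fa/fas/fast/fasta/fq/fastq and batches
above 5 MB (configurable) are rejected before parsing. Flanks are
capped at 1024 bases, the longest query the aligner accepts.

## Alignment

Gapless seed-and-extend over an in-memory reference: every k-mer
(default k = 12) of each chromosome is indexed; k-mers containing N
are not. A query's non-overlapping k-mer seeds anchor candidate
placements, each scored by Hamming distance on both strands (the minus
strand is handled by reverse-complementing the query). By pigeonhole a
placement with ≤ m mismatching positions leaves at least one of
⌊L/k⌋ seeds exact whenever L ≥ (m+1)·k; shorter queries fall back to a
vectorized exhaustive scan of every offset, so reported hit sets are
complete up to the mismatch cap either way — the tests verify this
against an independently coded brute-force scan. Defaults
`max_mismatch=3`, `max_hits=2` follow standard short-read reporting
practice ("at most two best hits, three mismatches"); both are
CLI-configurable. Ties are broken deterministically: ascending
mismatch count, then reference chromosome order, then leftmost start,
then `+` before `−` (the choice among equally good placements is
otherwise arbitrary, so it is fixed rather than left to hash order).

`N` matches nothing — in query or reference it always counts as a
mismatch — except at declared *free positions*. Variant localization
builds its query as:

* substitution → `five + N + three`, with the N offset free, so a
  clean substitution read aligns with 0 counted mismatches and the
  mismatch budget is spent only on sequencing errors;
* deletion → `five + deleted_base + three` (the base exists on the
  reference);
* insertion → `five + three` (the inserted base is absent from the
  reference).

The free position raises the worst-case number of mismatching columns
by one, so the seeding threshold uses m + (number of free positions).

From the best hit, the variant locus is `start + |five|` on the `+`
strand; on `−` strand hits the locus is mirrored through the alignment
(`start + L − 1 − |five|` for substitution/deletion, `start + L −
|five|` for insertion, where L is the query length) and alleles are
complemented in place — complementing each allele is its own inverse,
which makes localization strand-invariant, a property the tests check
record-by-record. The substitution's reference base is then read off
the genome and moved leftmost. If a second placement with the same
mismatch count projects to a *different* locus the result is flagged
`ambiguous` and both hits are reported — the toolkit surfaces the
ambiguity rather than silently picking one.

## Synthetic study materials

The fixture generator replaces external inputs (a downloaded genome,
database dumps, a read simulator) with seeded synthetic equivalents;
every output is byte-reproducible under its seed.

* **Genome**: uniform i.i.d. A/C/G/T. Real-genome repeat structure is
  absent; multi-hit ambiguity is exercised instead through an explicit
  segment-duplication knob. A 100 kb genome keeps a 35-base query
  (34 informative bases around the placeholder) unique with
  overwhelming probability, so error-free recovery is expected to be
  exact.
* **Planted variants**: default 500 on 100 kb (one chromosome),
  10% indels, at distinct loci kept max(read length)/2 + 2 bases from
  contig ends so centered reads are not truncated; substitution truth
  rows store (reference base, alternate), read off the genome, so the
  truth table is consistent by construction. Density is capped at one
  variant per 10 bases.
* **Snapshot**: about half the truth rows (configurable) receive
  fabricated identifiers; within a row the non-rs columns are present
  with probability 0.5 and the allele column with probability 0.8, so
  `none` reporting is exercised naturally.
* **Reads**: windows of 35/76/128/512 bases centered on each variant,
  written in the bracket dialect; uniform per-base substitution errors
  (default rate 1%) on flank bases only, never inside the bracket; a
  fair seeded coin reverse-complements each read. This is a simplified
  error model — it has no quality profile, no position-dependent error
  rate and no indel errors — so recovery rates here characterize the
  toolkit under uniform noise, not any sequencing platform.

## What the measurements mean

With error-free flanks, localization recovers 100% of planted variants
exactly at every read length — the expected behavior on a repeat-free
genome, and the end-to-end consistency check of the whole pipeline.

With 1% uniform flank errors and the default 3-mismatch cap, the
number of errors on a read of length L is Binomial(L−1, 0.01), so the
probability that a read stays within the cap *falls* as reads get
longer: ≈ 1.00 at 35 bp, ≈ 0.99 at 76 bp, ≈ 0.96 at 128 bp, but
≈ 0.26 at 512 bp (mean ≈ 5.1 errors). Measured recovery matches this
arithmetic. Under a fixed mismatch cap and a uniform per-base error
model, recovery is therefore *not* monotone in read length — longer
reads only help if the allowed mismatches scale with length (e.g.
`--max-mismatch` proportional to L) or errors concentrate where the
aligner is tolerant. Reported accuracies of production pipelines that
improve with read length reflect different error models and gapped
aligners, not this setting.

## Numerical and engineering choices

* Problem sizes: tests and examples use 10–100 kb genomes, 100–500
  variants and up to 512-base reads — big enough that seeding,
  fallback scanning, strand handling and ambiguity all trigger, small
  enough to iterate on quickly.
* The exhaustive fallback and per-candidate scoring are vectorized
  with NumPy byte arrays; the k-mer index is a plain dict (genomes at
  this scale need no succinct index).
* FASTA/FASTQ parsing goes through Biopython; SAM output is written
  directly (header + 11 mandatory fields + `NM` tag) and validated in
  the tests by re-parsing with pysam.
* Seeds: every stochastic component takes an explicit integer seed;
  derived generators use fixed small offsets from it.

## Known limitations

* Single-base variants only; gapless alignment only (indel *variants*
  are handled by query construction, not gapped DP).
* No genome-scale indexing: the in-memory dict index targets desk-
  scale references, not 3 Gb genomes.
* No quality-aware alignment; FASTQ qualities are carried opaquely.
* Cross-build liftover is not modeled; one build per name.
* The accession map must be supplied; nothing fetches real contig
  placements from the outside.
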