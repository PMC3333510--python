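"""Seed-and-extend alignment and variant localization.

The independent oracle throughout is an exhaustive Hamming-distance
scan over every offset of every chromosome on both strands, written as
a plain per-offset loop with no shared code with the aligner.
"""

import numpy as np
import pytest

from uasis import (
    FixtureSpec,
    FlankingRecord,
    VariantClass,
    align_read,
    build_index,
    emit_flanking_reads,
    generate_genome,
    localize_variant,
    plant_snps,
)
from uasis.errors import ReadLengthError, ReferenceFormatError
from uasis.sequences import reverse_complement

from conftest import random_sequence


def brute_force_hits(genome: dict, read: str, max_mismatch: int):
    """Oracle: all (chrom, start1, strand, mismatches) within the cap."""
    out = []
    for chrom, seq in genome.items():
        for strand in ("+", "-"):
            q = read if strand == "+" else reverse_complement(read)
            for start0 in range(len(seq) - len(q) + 1):
                mm = 0
                for a, b in zip(q, seq[start0 : start0 + len(q)]):
                    if a != b or a == "N" or b == "N":
                        mm += 1
                        if mm > max_mismatch:
                            break
                else:
                    out.append((chrom, start0 + 1, strand, mm))
    return sorted(out)


class TestBuildIndex:
    def test_kmer_positions_bounded_by_length(self):
        rng = np.random.default_rng(0)
        seq = random_sequence(rng, 10_000)
        index = build_index({"1": seq}, k=12)
        n_positions = sum(len(v) for v in index._kmers["1"].values())
        assert n_positions == 10_000 - 12 + 1

    def test_lowercase_accepted_and_uppercased(self):
        index = build_index({"1": "acgtacgtacgtacgt"})
        assert index.sequences["1"] == "ACGTACGTACGTACGT"

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ReferenceFormatError):
            build_index({"1": "ACGTXACGT"})

    def test_empty_reference_rejected(self):
        with pytest.raises(ReferenceFormatError):
            build_index({})

    def test_chr_prefix_stripped(self):
        index = build_index({"chr1": "ACGTACGTACGT"})
        assert index.chromosomes == ["1"]

    def test_fasta_loading(self, tmp_path):
        p = tmp_path / "ref.fa"
        p.write_text(">chr1\nACGTACGTACGT\nACGT\n")
        index = build_index(p)
        assert index.length("1") == 16


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(5)
    return {"1": random_sequence(rng, 10_000)}


@pytest.fixture(scope="module")
def index(genome):
    return build_index(genome)


@pytest.fixture(scope="module")
def loc_genome():
    rng = np.random.default_rng(9)
    return {"1": random_sequence(rng, 10_000)}


@pytest.fixture(scope="module")
def loc_index(loc_genome):
    return build_index(loc_genome)


class TestAlignRead:
    def test_exact_self_match(self, genome, index):
        read = genome["1"][500:576]  # 1-based start 501
        (hit,) = align_read(index, read, max_hits=1)
        assert (hit.chromosome, hit.start, hit.strand, hit.mismatches) == ("1", 501, "+", 0)

    def test_reverse_complement_same_locus(self, genome, index):
        read = reverse_complement(genome["1"][500:576])
        (hit,) = align_read(index, read, max_hits=1)
        assert (hit.start, hit.strand, hit.mismatches) == (501, "-", 0)

    def test_over_threshold_not_aligned(self, genome, index):
        read = list(genome["1"][500:576])
        for i in (5, 20, 40, 60):  # 4 substitutions > cap of 3
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        assert align_read(index, "".join(read), max_mismatch=3) == []

    @pytest.mark.parametrize("bad", ["ACG", "A" * 1025])
    def test_read_length_limits(self, index, bad):
        with pytest.raises(ReadLengthError):
            align_read(index, bad)

    def test_n_counts_as_mismatch(self, genome, index):
        read = genome["1"][500:548]
        noisy = "N" * 4 + read[4:]
        assert align_read(index, noisy, max_mismatch=3) == []
        assert align_read(index, noisy, max_mismatch=4, max_hits=1)[0].start == 501

    def test_free_positions_exclude_placeholder(self, genome, index):
        read = genome["1"][500:548]
        noisy = read[:10] + "N" + read[11:]
        (hit,) = align_read(index, noisy, max_hits=1, free_positions=frozenset({10}))
        assert (hit.start, hit.mismatches) == (501, 0)

    def test_monotone_in_mismatch_cap(self, genome, index):
        rng = np.random.default_rng(17)
        for _ in range(10):
            s = int(rng.integers(0, 9900))
            read = list(genome["1"][s : s + 76])
            for i in rng.choice(75, size=3, replace=False):
                read[i] = str(rng.choice([b for b in "ACGT" if b != read[i]]))
            read = "".join(read)
            previous: set = set()
            for cap in range(5):
                hits = {
                    (h.chromosome, h.start, h.strand)
                    for h in align_read(index, read, max_mismatch=cap, max_hits=10_000)
                }
                assert previous <= hits
                previous = hits

    def test_tie_break_order(self):
        # identical 40-base segment planted twice on two chromosomes
        rng = np.random.default_rng(23)
        seg = random_sequence(rng, 40)
        g = {
            "1": random_sequence(rng, 200) + seg + random_sequence(rng, 200) + seg,
            "2": seg + random_sequence(rng, 100),
        }
        index = build_index(g)
        hits = align_read(index, seg, max_hits=10)
        keys = [(h.chromosome, h.start) for h in hits]
        assert keys == [("1", 201), ("1", 441), ("2", 1)]

    @pytest.mark.parametrize("length", [35, 76, 128, 512])
    def test_matches_exhaustive_oracle(self, genome, index, length):
        rng = np.random.default_rng(length)
        for trial in range(8):
            n_mut = trial % 5  # 0..4 planted substitutions
            s = int(rng.integers(0, len(genome["1"]) - length))
            read = list(genome["1"][s : s + length])
            for i in rng.choice(length, size=n_mut, replace=False):
                read[i] = str(rng.choice([b for b in "ACGT" if b != read[i]]))
            read = "".join(read)
            if rng.random() < 0.5:
                read = reverse_complement(read)
            got = {
                (h.chromosome, h.start, h.strand, h.mismatches)
                for h in align_read(index, read, max_mismatch=3, max_hits=10_000)
            }
            assert got == set(brute_force_hits(genome, read, 3))


class TestLocalizeVariant:
    def test_planted_substitution_recovered(self, loc_genome, loc_index):
        seq = loc_genome["1"]
        ref = seq[4999]  # 1-based position 5000
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
        rec = FlankingRecord(
            "q1", seq[4962:4999], (ref, alt), VariantClass.SUBSTITUTION, seq[5000:5038]
        )
        res = localize_variant(loc_index, rec)
        assert res.status == "ok"
        assert str(res.name) == f"HG19.1:5000:{ref}/{alt}"
        assert res.reference_base == ref

    def test_reference_allele_moved_leftmost(self, loc_genome, loc_index):
        seq = loc_genome["1"]
        ref = seq[4999]
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
        rec = FlankingRecord(
            "q1", seq[4962:4999], (alt, ref), VariantClass.SUBSTITUTION, seq[5000:5038]
        )
        res = localize_variant(loc_index, rec)
        assert res.name.alleles == (ref, alt)

    def test_strand_invariance(self, loc_genome, loc_index):
        seq = loc_genome["1"]
        ref = seq[2999]
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
        rec = FlankingRecord(
            "q", seq[2960:2999], (ref, alt), VariantClass.SUBSTITUTION, seq[3000:3040]
        )
        assert localize_variant(loc_index, rec).name == localize_variant(
            loc_index, rec.reverse_complemented()
        ).name

    def test_insertion_convention_displaced_base(self, loc_genome, loc_index):
        # an insertion between reference positions 1233 and 1234 is
        # written at 1234; the old occupant of 1234 moves to 1235
        from uasis import displaced_reference_position

        seq = loc_genome["1"]
        rec = FlankingRecord(
            "qins", seq[1203:1233], ("T",), VariantClass.INSERTION, seq[1233:1263]
        )
        res = localize_variant(loc_index, rec)
        assert res.status == "ok"
        assert res.name.locus == 1234
        assert displaced_reference_position(res.name) == 1235
        # and the 3' flank indeed starts with the displaced base
        assert seq[1233] == rec.three_prime[0]

    def test_deletion_recovered(self, loc_genome, loc_index):
        seq = loc_genome["1"]
        rec = FlankingRecord(
            "qdel", seq[6960:6999], (seq[6999],), VariantClass.DELETION, seq[7000:7040]
        )
        res = localize_variant(loc_index, rec)
        assert res.name.locus == 7000
        assert res.name.alleles == (seq[6999],)

    def test_unplaceable_read_not_aligned(self, loc_index):
        rng = np.random.default_rng(99)
        rec = FlankingRecord(
            "qrand", random_sequence(rng, 40), ("G", "A"),
            VariantClass.SUBSTITUTION, random_sequence(rng, 40),
        )
        res = localize_variant(loc_index, rec)
        assert res.status == "not_aligned" and not res.aligned

    def test_plain_read_cannot_be_localized(self, loc_index):
        rec = FlankingRecord("plain", "ACGT" * 10, (), None, "")
        with pytest.raises(ValueError):
            localize_variant(loc_index, rec)

    def test_duplicated_segment_flags_ambiguity(self):
        rng = np.random.default_rng(31)
        seg = random_sequence(rng, 120)
        g = {"1": random_sequence(rng, 2000) + seg + random_sequence(rng, 2000) + seg
             + random_sequence(rng, 500)}
        index = build_index(g)
        ref = seg[60]
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
        rec = FlankingRecord(
            "amb", seg[20:60], (ref, alt), VariantClass.SUBSTITUTION, seg[61:100]
        )
        res = localize_variant(index, rec)
        assert res.status == "ambiguous"
        assert len(res.hits) == 2


class TestEndToEndFixtures:
    def test_error_free_truth_recovery(self, small_genome, small_truth, small_index):
        for length in (35, 76):
            reads = emit_flanking_reads(small_genome, small_truth, length, 0.0, seed=7)
            for v, rec in zip(small_truth, reads):
                if rec.truncated:
                    continue
                res = localize_variant(small_index, rec)
                assert res.status == "ok"
                assert res.name.chromosome == v.chromosome
                assert res.name.locus == v.locus
                assert res.name.variant_class == v.variant_class
                assert res.name.alleles == v.alleles
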