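"""Universal-name grammar: parsing, formatting, validation, conventions."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uasis import (
    UasisName,
    VariantClass,
    VariantDescriptor,
    canonicalize_alleles,
    displaced_reference_position,
    format_uasis,
    parse_uasis,
    to_one_based,
    to_zero_based,
    validate_descriptor,
)
from uasis.errors import (
    AlleleSetError,
    InvalidAlleleError,
    InvalidChromosomeError,
    InvalidLocusError,
    NameSyntaxError,
    ReferenceAlleleMismatchWarning,
    ValidationError,
)


@pytest.mark.parametrize(
    "text,build,chrom,locus,vc,alleles",
    [
        ("HG19.1:11789038:G/A", 19, "1", 11789038, VariantClass.SUBSTITUTION, ("G", "A")),
        ("HG19.X:1:insA", 19, "X", 1, VariantClass.INSERTION, ("A",)),
        ("HG19.Y:5:delT", 19, "Y", 5, VariantClass.DELETION, ("T",)),
        ("HG19.22:123:insN", 19, "22", 123, VariantClass.INSERTION, ("N",)),
        ("HG18.2:77:A/C/G", 18, "2", 77, VariantClass.SUBSTITUTION, ("A", "C", "G")),
        # case-insensitive input, tri-allelic, mixed case
        ("hg19.x:42:g/a", 19, "X", 42, VariantClass.SUBSTITUTION, ("G", "A")),
        ("Hg19.1:9:DELt", 19, "1", 9, VariantClass.DELETION, ("T",)),
    ],
)
def test_parse_decomposes_fields(text, build, chrom, locus, vc, alleles):
    n = parse_uasis(text)
    assert (n.build, n.chromosome, n.locus, n.variant_class, n.alleles) == (
        build, chrom, locus, vc, alleles,
    )


@pytest.mark.parametrize(
    "text,exc",
    [
        ("HG19.1:0:G/A", InvalidLocusError),
        ("HG19.1:-5:G/A", InvalidLocusError),
        ("HG19.1:100:G/G", AlleleSetError),
        ("HG19.1:100:G", AlleleSetError),
        ("HG19.1:100:insAT", InvalidAlleleError),
        ("HG19.1:100:G/Z", InvalidAlleleError),
        ("HG19.25:100:G/A", InvalidChromosomeError),
        ("HG19.1:100:A/C/G/T/N", AlleleSetError),
        ("rs3737965", NameSyntaxError),
        ("", NameSyntaxError),
        ("HG19.1:11789038", NameSyntaxError),
    ],
)
def test_parse_failures_are_field_specific(text, exc):
    with pytest.raises(exc):
        parse_uasis(text)
    # every failure is part of the validation taxonomy, never generic
    with pytest.raises(ValidationError):
        parse_uasis(text)


def test_format_worked_example():
    n = UasisName(19, "1", 11789038, VariantClass.SUBSTITUTION, ("G", "A"))
    assert format_uasis(n) == "HG19.1:11789038:G/A"


@pytest.mark.parametrize(
    "fields,expected",
    [
        ((19, "Y", 5, VariantClass.DELETION, ("T",)), "HG19.Y:5:delT"),
        ((19, "22", 123, VariantClass.INSERTION, ("N",)), "HG19.22:123:insN"),
        ((18, "X", 1, VariantClass.SUBSTITUTION, ("A", "C", "G")), "HG18.X:1:A/C/G"),
    ],
)
def test_format_canonical_casing(fields, expected):
    assert format_uasis(UasisName(*fields)) == expected


class TestValidateDescriptor:
    def test_accepts_worked_example(self):
        d = VariantDescriptor(19, "1", 11789038, "substitution", ["G", "A"])
        assert format_uasis(validate_descriptor(d)) == "HG19.1:11789038:G/A"

    def test_rejects_mitochondrial_chromosome(self):
        d = VariantDescriptor(19, "MT", 100, VariantClass.SUBSTITUTION, ["G", "A"])
        with pytest.raises(InvalidChromosomeError):
            validate_descriptor(d)

    def test_insertion_carries_exactly_one_allele(self):
        d = VariantDescriptor(19, "2", 50, VariantClass.INSERTION, ["A", "C"])
        with pytest.raises(AlleleSetError):
            validate_descriptor(d)

    def test_lowercase_alleles_normalized(self):
        d = VariantDescriptor(19, 3, 50, VariantClass.SUBSTITUTION, ["g", "a"])
        assert validate_descriptor(d).alleles == ("G", "A")


class TestCanonicalizeAlleles:
    def test_reference_moves_leftmost(self):
        n = UasisName(19, "1", 10, VariantClass.SUBSTITUTION, ("A", "G"))
        assert canonicalize_alleles(n, "G").alleles == ("G", "A")

    def test_idempotent_and_noop_cases(self):
        n = UasisName(19, "1", 10, VariantClass.SUBSTITUTION, ("G", "A"))
        assert canonicalize_alleles(n, "G") == n
        assert canonicalize_alleles(n, None) == n
        once = canonicalize_alleles(
            UasisName(19, "1", 10, VariantClass.SUBSTITUTION, ("A", "C", "G")), "C"
        )
        assert canonicalize_alleles(once, "C") == once

    def test_relative_order_of_others_kept(self):
        n = UasisName(19, "1", 10, VariantClass.SUBSTITUTION, ("A", "C", "G"))
        assert canonicalize_alleles(n, "G").alleles == ("G", "A", "C")

    def test_disagreeing_reference_warns_not_errors(self):
        n = UasisName(19, "1", 10, VariantClass.SUBSTITUTION, ("G", "A"))
        with pytest.warns(ReferenceAlleleMismatchWarning):
            out = canonicalize_alleles(n, "T")
        assert out == n

    def test_never_changes_allele_multiset(self):
        n = UasisName(19, "1", 10, VariantClass.SUBSTITUTION, ("T", "A", "C"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for ref in "ACGT":
                assert sorted(canonicalize_alleles(n, ref).alleles) == sorted(n.alleles)


@pytest.mark.parametrize(
    "name,expected",
    [
        (UasisName(19, "1", 1234, VariantClass.INSERTION, ("T",)), 1235),
        (UasisName(19, "1", 1, VariantClass.INSERTION, ("A",)), 2),
        (UasisName(19, "1", 1234, VariantClass.SUBSTITUTION, ("G", "A")), None),
        (UasisName(19, "1", 1234, VariantClass.DELETION, ("C",)), None),
    ],
)
def test_displaced_reference_position(name, expected):
    assert displaced_reference_position(name) == expected


class TestCoordinateConversion:
    def test_examples(self):
        assert to_zero_based(11789038) == 11789037
        assert to_one_based(0) == 1

    def test_out_of_range(self):
        with pytest.raises(InvalidLocusError):
            to_zero_based(0)
        with pytest.raises(InvalidLocusError):
            to_one_based(-1)

    @given(st.integers(min_value=1, max_value=3_000_000_000))
    @settings(derandomize=True, max_examples=200)
    def test_round_trip(self, p):
        assert to_one_based(to_zero_based(p)) == p


def valid_names() -> st.SearchStrategy:
    chromosomes = st.sampled_from([str(i) for i in range(1, 23)] + ["X", "Y"])
    substitution = st.lists(
        st.sampled_from("ACGTN"), min_size=2, max_size=4, unique=True
    ).map(tuple)
    single = st.sampled_from("ACGTN").map(lambda a: (a,))

    def build_name(build, chrom, locus, vc, sub, one):
        alleles = sub if vc is VariantClass.SUBSTITUTION else one
        return UasisName(build, chrom, locus, vc, alleles)

    return st.builds(
        build_name,
        st.integers(min_value=1, max_value=99),
        chromosomes,
        st.integers(min_value=1, max_value=300_000_000),
        st.sampled_from(list(VariantClass)),
        substitution,
        single,
    )


@given(valid_names())
@settings(derandomize=True, max_examples=500)
def test_parse_format_round_trip(name):
    assert parse_uasis(format_uasis(name)) == name


@given(valid_names())
@settings(derandomize=True, max_examples=200)
def test_canonical_text_is_a_fixed_point(name):
    text = format_uasis(name)
    assert format_uasis(parse_uasis(text)) == text
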