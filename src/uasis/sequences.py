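"""Small nucleotide-string helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def complement(base: str) -> str:
    """Complement of a single base (N stays N)."""
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_nucleotide_string(seq: str) -> bool:
    """True when every character is A/C/G/T/N (either case)."""
    return all(c in VALID_BASES for c in seq.upper())
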