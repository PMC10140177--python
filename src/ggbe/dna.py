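"""Small DNA sequence helpers shared across the package."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

BASES = ("A", "C", "G", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def check_dna(seq: str, name: str = "sequence", allow_n: bool = False) -> str:
    """Validate that *seq* is upper-case DNA; return it unchanged.

    Raises ``ValueError`` naming the offending argument otherwise.
    """
    alphabet = set("ACGTN") if allow_n else set("ACGT")
    if not seq or not set(seq) <= alphabet:
        raise ValueError(
            f"{name} must be non-empty DNA over "
            f"{'ACGTN' if allow_n else 'ACGT'}, got {seq!r}"
        )
    return seq


def is_ngg(pam: str) -> bool:
    """True when a 3-mer matches the SpCas9 NGG protospacer-adjacent motif."""
    return len(pam) == 3 and pam[1:] == "GG" and pam[0] in "ACGTN"
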