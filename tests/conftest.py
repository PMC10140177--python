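import numpy as np
import pytest

from ggbe.synth import AmpliconReference, ReadSet, make_reference

# protospacer with an editable A at position 5 and C at position 6,
# non-repetitive so deletion placements are unambiguous
PROTO = "GTCGACTTAGCATGACTGAA"


def _random_flank(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def ref() -> AmpliconReference:
    rng = np.random.default_rng(20240901)
    flank5 = _random_flank(rng, 45)
    flank3 = "CGG" + _random_flank(rng, 42)
    return make_reference("toy_locus", PROTO, flank5, flank3)


@pytest.fixture(scope="session")
def ref_minus() -> AmpliconReference:
    rng = np.random.default_rng(20240902)
    flank5 = _random_flank(rng, 45)
    flank3 = "TGG" + _random_flank(rng, 42)
    return make_reference("toy_minus", PROTO, flank5, flank3, strand="-")


def reads_from_seqs(seqs, name="manual") -> ReadSet:
    return ReadSet(
        reads=[(f"r{i}", s, "I" * len(s)) for i, s in enumerate(seqs)],
        source_reference=name,
    )


def edit_at(ref: AmpliconReference, proto_pos: int, new_base: str) -> str:
    """Amplicon sequence with one protospacer-strand substitution."""
    i = ref.amplicon_index(proto_pos)
    b = new_base if ref.strand == "+" else new_base.translate(
        str.maketrans("ACGT", "TGCA"))
    return ref.sequence[:i] + b + ref.sequence[i + 1:]
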