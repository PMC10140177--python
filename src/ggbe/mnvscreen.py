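"""Screen multi-nucleotide variants (MNVs) for dual-editor targetability.

A dual C-to-G / A-to-G editor can revert ("correct") or install
("create") a two-base variant within a trinucleotide in a single round of
editing, provided the two editable bases read A and C on one protospacer
strand and both fall inside the high-efficiency editing window
(protospacer positions 5-7) with an NGG PAM correctly placed.

The eligible trinucleotide patterns are:

* disease-correcting (variant -> wild type):
  ``GNG>ANC  GGN>ACN  NGG>NAC  GNG>CNA  GGN>CAN  NGG>NCA``
* disease-creating (wild type -> variant):
  ``ACN>GGN  ANC>GNG  CAN>GGN  CNA>GNG  NAC>NGG  NCA>NGG``

where the arrow points from wild type to variant and ``N`` is any base,
identical on both sides. The two sets are each other's mirror image under
arrow reversal. Patterns are also evaluated on the reverse complement of
the pair, since a guide may sit on either genomic strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pyfaidx

from .dna import check_dna, revcomp

CORRECTING_PATTERNS = (
    "GNG>ANC", "GGN>ACN", "NGG>NAC", "GNG>CNA", "GGN>CAN", "NGG>NCA",
)
CREATING_PATTERNS = (
    "ACN>GGN", "ANC>GNG", "CAN>GGN", "CNA>GNG", "NAC>NGG", "NCA>NGG",
)

#: protospacer positions both edits must occupy
RESTRICTED_POSITIONS = (5, 6, 7)

GUIDE_LEN = 20
SITE_LEN = 23  # protospacer + PAM


@dataclass(frozen=True)
class PatternMatch:
    """Result of classifying a ref/alt trinucleotide pair."""

    direction: str  # correcting | creating | none
    pattern_id: str | None = None
    strand: str | None = None  # strand of the pattern match
    edited_positions: tuple[int, ...] = ()  # 1-based, original orientation
    #: (source base on the matched strand, trinucleotide position)
    required_conversions: tuple[tuple[str, int], ...] = ()


@dataclass(frozen=True)
class MNVRecord:
    id: str
    contig: str
    position: int  # 1-based start of the trinucleotide
    ref_tri: str
    alt_tri: str
    annotation: str = ""

    def __post_init__(self):
        check_dna(self.ref_tri, "ref_tri")
        check_dna(self.alt_tri, "alt_tri")
        if len(self.ref_tri) != 3 or len(self.alt_tri) != 3:
            raise ValueError("ref_tri and alt_tri must be trinucleotides")
        if self.ref_tri == self.alt_tri:
            raise ValueError("ref_tri equals alt_tri")


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer + NGG PAM placement that edits both MNV bases."""

    protospacer: str
    strand: str  # relative to the supplied context
    pam: str
    edited_protospacer_positions: tuple[int, ...]
    start: int  # 0-based offset of the 23-mer on the context + strand
    mnv_id: str = ""
    bystanders: tuple[int, ...] = field(default=())  # other A/C at pos 5-7


def _pattern_of(wild: str, variant: str, diffs: tuple[int, ...]) -> str:
    w = "".join(wild[i] if i + 1 in diffs else "N" for i in range(3))
    v = "".join(variant[i] if i + 1 in diffs else "N" for i in range(3))
    return f"{w}>{v}"


def _direction_on_strand(
    ref_tri: str, alt_tri: str
) -> tuple[str, str, tuple[int, ...], tuple[tuple[str, int], ...]] | None:
    """Match the pair on this strand orientation; returns
    (direction, pattern_id, edited_positions, conversions) or None."""
    diffs = tuple(i + 1 for i in range(3) if ref_tri[i] != alt_tri[i])
    if len(diffs) != 2:
        return None
    ref_d = "".join(sorted(ref_tri[i - 1] for i in diffs))
    alt_d = "".join(sorted(alt_tri[i - 1] for i in diffs))
    # correcting: edit the variant back to wild type via A->G + C->G
    if ref_d == "GG" and alt_d == "AC":
        conversions = tuple(
            (alt_tri[i - 1], i) for i in diffs
        )
        return ("correcting", _pattern_of(ref_tri, alt_tri, diffs),
                diffs, conversions)
    # creating: edit the wild type into the variant via A->G + C->G
    if ref_d == "AC" and alt_d == "GG":
        conversions = tuple(
            (ref_tri[i - 1], i) for i in diffs
        )
        return ("creating", _pattern_of(ref_tri, alt_tri, diffs),
                diffs, conversions)
    return None


def classify_mnv(ref_tri: str, alt_tri: str) -> PatternMatch:
    """Classify a trinucleotide variant against the 12 targetable patterns.

    ``correcting``: the variant can be reverted to the reference by one
    A-to-G plus one C-to-G edit; ``creating``: the reference can be turned
    into the variant the same way; ``none`` otherwise (including pairs
    differing at one or three positions). Both strand orientations are
    tried; a reverse-complement match carries ``strand='-'`` with
    positions mapped back to the supplied orientation.
    """
    ref_tri, alt_tri = ref_tri.upper(), alt_tri.upper()
    check_dna(ref_tri, "ref_tri")
    check_dna(alt_tri, "alt_tri")
    if len(ref_tri) != 3 or len(alt_tri) != 3:
        raise ValueError("ref_tri and alt_tri must be trinucleotides")
    hit = _direction_on_strand(ref_tri, alt_tri)
    if hit is not None:
        direction, pattern, positions, conversions = hit
        return PatternMatch(direction, pattern, "+", positions, conversions)
    hit = _direction_on_strand(revcomp(ref_tri), revcomp(alt_tri))
    if hit is not None:
        direction, pattern, positions, conversions = hit
        # map positions/conversions back to the supplied orientation
        mapped_pos = tuple(sorted(4 - p for p in positions))
        mapped_conv = tuple(
            sorted(((b, 4 - p) for b, p in conversions), key=lambda t: t[1])
        )
        return PatternMatch(direction, pattern, "-", mapped_pos, mapped_conv)
    return PatternMatch("none")


def editable_tri(record: MNVRecord, direction: str) -> str:
    """The allele that carries the editable A/C bases: the variant for
    correcting (editing reverts it), the reference for creating."""
    if direction == "correcting":
        return record.alt_tri
    if direction == "creating":
        return record.ref_tri
    raise ValueError(f"direction must be correcting or creating, got {direction!r}")


def enumerate_placements(
    context: str, sites: tuple[int, int], mnv_id: str = ""
) -> list[GuideCandidate]:
    """All 20-nt + NGG placements on either strand of ``context`` putting
    both 0-based ``sites`` at protospacer positions 5-7 as one A and one C.

    Returned sorted by strand (+ first) then 23-mer start on the + strand.
    """
    context = context.upper()
    found: dict[tuple, GuideCandidate] = {}
    n = len(context)
    for strand in "+-":
        seq = context if strand == "+" else revcomp(context)
        mapped = [s if strand == "+" else n - 1 - s for s in sites]
        for start in range(0, n - SITE_LEN + 1):
            positions = [m - start + 1 for m in mapped]
            if not all(p in RESTRICTED_POSITIONS for p in positions):
                continue
            pam = seq[start + GUIDE_LEN: start + SITE_LEN]
            if pam[1:] != "GG":
                continue
            bases = sorted(seq[m] for m in mapped)
            if bases != ["A", "C"]:
                continue
            proto = seq[start: start + GUIDE_LEN]
            edited = tuple(sorted(positions))
            bystanders = tuple(
                p for p in RESTRICTED_POSITIONS
                if p not in edited and proto[p - 1] in "AC"
            )
            orig_start = start if strand == "+" else n - (start + SITE_LEN)
            key = (strand, orig_start)
            found[key] = GuideCandidate(
                protospacer=proto, strand=strand, pam=pam,
                edited_protospacer_positions=edited, start=orig_start,
                mnv_id=mnv_id, bystanders=bystanders,
            )
    return sorted(found.values(), key=lambda c: (c.strand, c.start))


def find_guides(
    record: MNVRecord,
    context: str,
    direction: str,
    tri_offset: int | None = None,
) -> list[GuideCandidate]:
    """Enumerate guide placements for one MNV in its sequence context.

    ``context`` must contain the *editable* allele (variant trinucleotide
    for correcting, reference for creating) at ``tri_offset`` (default:
    centered) with >= 30 nt flanking each side. Returns an empty list when
    no PAM placement satisfies the position-5-7 constraint.
    """
    context = context.upper()
    match = classify_mnv(record.ref_tri, record.alt_tri)
    if match.direction != direction:
        raise ValueError(
            f"MNV {record.id} classifies as {match.direction!r}, "
            f"not {direction!r}"
        )
    if tri_offset is None:
        tri_offset = (len(context) - 3) // 2
    target = editable_tri(record, direction)
    if context[tri_offset: tri_offset + 3] != target:
        raise ValueError(
            f"context does not carry the editable allele {target} at "
            f"offset {tri_offset}"
        )
    if tri_offset < 30 or len(context) - (tri_offset + 3) < 30:
        raise ValueError("context must extend >= 30 nt on each side")
    sites = tuple(tri_offset + p - 1 for _b, p in match.required_conversions)
    return enumerate_placements(context, sites, mnv_id=record.id)


# --------------------------------------------------------------------------
# table-level screen


_EMPTY_GUIDE = {
    "guide": "", "guide_strand": "", "pam": "",
    "edited_protospacer_positions": "", "bystanders": "",
}


def screen_table(
    records: list[MNVRecord],
    genome: str | Path | pyfaidx.Fasta,
    flank: int = 30,
) -> pd.DataFrame:
    """Classify every MNV and enumerate guides against a genome FASTA.

    The genomic context is fetched around each record's position (it must
    carry the reference trinucleotide) and the editable allele is
    substituted in before scanning. One row per record x candidate;
    records classifying ``none``, lacking candidates, or failing lookup
    get a single row with empty guide fields and, where applicable, an
    ``error`` message. The screen continues past per-record errors.
    """
    fasta = genome if isinstance(genome, pyfaidx.Fasta) else pyfaidx.Fasta(
        str(genome), sequence_always_upper=True
    )
    rows: list[dict] = []

    def base_row(rec: MNVRecord, match: PatternMatch) -> dict:
        return {
            "id": rec.id, "contig": rec.contig, "position": rec.position,
            "ref_tri": rec.ref_tri, "alt_tri": rec.alt_tri,
            "direction": match.direction,
            "pattern_id": match.pattern_id or "",
            "pattern_strand": match.strand or "",
            **_EMPTY_GUIDE, "error": "",
        }

    for rec in records:
        match = classify_mnv(rec.ref_tri, rec.alt_tri)
        row = base_row(rec, match)
        if match.direction == "none":
            rows.append(row)
            continue
        if rec.contig not in fasta:
            row["error"] = f"contig {rec.contig!r} not in FASTA"
            rows.append(row)
            continue
        start0 = rec.position - 1
        ctx_start = max(0, start0 - flank)
        fetched = str(fasta[rec.contig][ctx_start: start0 + 3 + flank])
        tri_offset = start0 - ctx_start
        observed = fetched[tri_offset: tri_offset + 3]
        if observed != rec.ref_tri:
            row["error"] = (
                f"genome has {observed} at {rec.contig}:{rec.position}, "
                f"expected ref {rec.ref_tri}"
            )
            rows.append(row)
            continue
        editable = editable_tri(rec, match.direction)
        context = (
            fetched[:tri_offset] + editable + fetched[tri_offset + 3:]
        )
        try:
            candidates = find_guides(
                rec, context, match.direction, tri_offset=tri_offset
            )
        except ValueError as exc:
            row["error"] = str(exc)
            rows.append(row)
            continue
        if not candidates:
            rows.append(row)
            continue
        for cand in candidates:
            crow = dict(row)
            crow.update(
                guide=cand.protospacer,
                guide_strand=cand.strand,
                pam=cand.pam,
                edited_protospacer_positions=",".join(
                    map(str, cand.edited_protospacer_positions)
                ),
                bystanders=",".join(map(str, cand.bystanders)),
            )
            rows.append(crow)
    columns = [
        "id", "contig", "position", "ref_tri", "alt_tri", "direction",
        "pattern_id", "pattern_strand", "guide", "guide_strand", "pam",
        "edited_protospacer_positions", "bystanders", "error",
    ]
    return pd.DataFrame(rows, columns=columns)


def read_mnv_table(path: str | Path) -> list[MNVRecord]:
    """Read MNVs from TSV (``id contig pos ref_tri alt_tri [annotation]``)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"id", "contig", "pos", "ref_tri", "alt_tri"}
    if not required <= set(df.columns):
        raise ValueError(
            f"MNV table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return [
        MNVRecord(
            id=r["id"], contig=r["contig"], position=int(r["pos"]),
            ref_tri=r["ref_tri"].upper(), alt_tri=r["alt_tri"].upper(),
            annotation=str(r.get("annotation", "") or ""),
        )
        for _, r in df.iterrows()
    ]
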