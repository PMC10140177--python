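"""Read alignment and editing quantification for amplicon sequencing.

Mirrors the quantification a base-editing experiment gets from amplicon
deep sequencing: each read is globally aligned to its amplicon, then
summarised as (i) a per-position nucleotide percentage table, (ii) an
indel frequency over a quantification window anchored at the cut site,
and (iii) a genotype (allele) table over the protospacer region.

Alignment is global with affine gaps (match +5, mismatch -4, gap open
-20, gap extend -1; a gap of length n costs open + (n-1)*extend). Reads
whose identity over the reference falls below 60% are discarded as junk.

Internally all coordinates are 0-based half-open on the amplicon strand;
reported positions are 1-based, and protospacer position labels (1 =
PAM-distal) are mapped through the reference's strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .dna import complement
from .synth import PROTOSPACER_LEN, AmpliconReference, ReadSet
from . import report

MATCH_SCORE = 5
MISMATCH_SCORE = -4
GAP_OPEN = -20
GAP_EXTEND = -1
MIN_IDENTITY = 0.60

_FRACTION_COLS = ["A", "C", "G", "T", "N", "-"]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


@dataclass
class AlignedRead:
    """One read's global alignment against the amplicon.

    ``base_at[i]`` is the read base aligned to reference offset ``i``,
    ``'-'`` when the position is deleted, or ``None`` when an end gap
    leaves it uncovered. ``insertions`` holds ``(junction, seq)`` pairs
    where the inserted bases sit between reference offsets ``junction``
    and ``junction + 1`` (``junction == -1`` = before the reference).
    """

    read_id: str
    base_at: list[str | None]
    insertions: list[tuple[int, str]] = field(default_factory=list)
    deletions: list[tuple[int, int]] = field(default_factory=list)
    score: float = 0.0
    identity: float = 0.0

    def covers(self, start: int, end: int) -> bool:
        return all(self.base_at[i] is not None for i in range(start, end))

    def has_indel_overlapping(self, start: int, end: int) -> bool:
        """Any insertion or deletion touching the half-open interval."""
        for d0, d1 in self.deletions:
            if d0 < end and d1 > start:
                return True
        for junction, _ in self.insertions:
            if start - 1 <= junction <= end - 1:
                return True
        return False

    @property
    def has_indel(self) -> bool:
        return bool(self.deletions or self.insertions)


class AlignedReads(list):
    """List of :class:`AlignedRead` plus discard accounting."""

    def __init__(self, reads=(), n_discarded: int = 0, n_input: int = 0):
        super().__init__(reads)
        self.n_discarded = n_discarded
        self.n_input = n_input


def _parse_alignment(
    read_id: str, seq: str, refseq: str, aln, score: float
) -> AlignedRead:
    blocks_t, blocks_q = aln.aligned
    base_at: list[str | None] = [None] * len(refseq)
    insertions: list[tuple[int, str]] = []
    deletions: list[tuple[int, int]] = []
    prev_t = prev_q = None
    first_t = blocks_t[0][0] if len(blocks_t) else 0
    last_t = blocks_t[-1][1] if len(blocks_t) else 0
    for (t0, t1), (q0, q1) in zip(blocks_t, blocks_q):
        if prev_t is not None:
            if t0 > prev_t:  # reference advanced with no read bases
                deletions.append((prev_t, t0))
                for i in range(prev_t, t0):
                    base_at[i] = "-"
            if q0 > prev_q:  # read advanced with no reference bases
                insertions.append((prev_t - 1, seq[prev_q:q0]))
        for i in range(t0, t1):
            base_at[i] = seq[q0 + (i - t0)]
        prev_t, prev_q = t1, q1
    # end gaps leave positions uncovered rather than deleted
    if len(blocks_q) and blocks_q[0][0] > 0:
        insertions.insert(0, (first_t - 1, seq[: blocks_q[0][0]]))
    if len(blocks_q) and blocks_q[-1][1] < len(seq):
        insertions.append((last_t - 1, seq[blocks_q[-1][1]:]))
    matches = sum(
        1 for i, b in enumerate(base_at) if b is not None and b == refseq[i]
    )
    return AlignedRead(
        read_id=read_id,
        base_at=base_at,
        insertions=insertions,
        deletions=deletions,
        score=float(score),
        identity=matches / len(refseq),
    )


def align_reads(rs: ReadSet, ref: AmpliconReference | str) -> AlignedReads:
    """Globally align every read; discard those below 60% identity.

    Accepts an :class:`AmpliconReference` or a bare sequence. Identical
    read sequences share one alignment, so deeply sequenced amplicons
    align in time proportional to the number of distinct reads.
    """
    if len(rs) == 0:
        raise ValueError("cannot align an empty ReadSet")
    refseq = ref.sequence if isinstance(ref, AmpliconReference) else str(ref)
    aligner = _make_aligner()
    cache: dict[str, AlignedRead | None] = {}
    out = AlignedReads(n_input=len(rs))
    for rid, seq, _qual in rs:
        template = cache.get(seq)
        if seq not in cache:
            alns = aligner.align(refseq, seq)
            parsed = _parse_alignment(rid, seq, refseq, alns[0], alns.score)
            template = parsed if parsed.identity >= MIN_IDENTITY else None
            cache[seq] = template
        if template is None:
            out.n_discarded += 1
            continue
        out.append(
            AlignedRead(
                read_id=rid,
                base_at=template.base_at,
                insertions=template.insertions,
                deletions=template.deletions,
                score=template.score,
                identity=template.identity,
            )
        )
    return out


# --------------------------------------------------------------------------
# quantification window


@dataclass(frozen=True)
class QuantWindow:
    """Quantification window anchored on the protospacer.

    ``center_offset`` (the ``-wc`` analog) counts back from the
    PAM-proximal protospacer end: the window centre is protospacer
    position ``20 - center_offset``. ``width`` (``-w``) positions are
    taken around it. The defaults (10, 20) resolve to protospacer
    positions 1-20.
    """

    center_offset: int = 10
    width: int = 20

    def __post_init__(self):
        if self.width < 1:
            raise ValueError("window width must be >= 1")

    def proto_interval(self) -> tuple[int, int]:
        """Closed interval of (possibly extrapolated) protospacer positions."""
        center = PROTOSPACER_LEN - self.center_offset
        lo = center - self.width // 2 + 1
        return lo, lo + self.width - 1

    def resolve(self, ref: AmpliconReference) -> tuple[int, int]:
        """0-based half-open amplicon interval covered by the window."""
        lo_p, hi_p = self.proto_interval()
        if ref.strand == "+":
            idx = [ref.protospacer_start + p - 1 for p in (lo_p, hi_p)]
        else:
            idx = [ref.protospacer_start + PROTOSPACER_LEN - p for p in (lo_p, hi_p)]
        start, end = min(idx), max(idx) + 1
        if start < 0 or end > len(ref.sequence):
            raise ValueError("quantification window falls outside the reference")
        return start, end


# --------------------------------------------------------------------------
# nucleotide percentage table


@dataclass
class NucleotidePercentageTable:
    """Per-position base/deletion fractions over aligned reads.

    ``df`` columns: ``position`` (1-based amplicon), ``ref_base``,
    ``proto_pos`` (protospacer label 1-20 or <NA>), fraction columns
    ``A C G T N -``, and ``denominator`` (reads covering the position).
    """

    df: pd.DataFrame
    strand: str = "+"
    reference_name: str = ""

    def row_for_proto(self, proto_pos: int) -> pd.Series:
        hit = self.df[self.df["proto_pos"] == proto_pos]
        if hit.empty:
            raise KeyError(f"protospacer position {proto_pos} not in table")
        return hit.iloc[0]

    @property
    def proto_positions(self) -> list[int]:
        return sorted(int(p) for p in self.df["proto_pos"].dropna())


def nucleotide_percentages(
    aligned: AlignedReads,
    ref: AmpliconReference,
    region: tuple[int, int] | None = None,
) -> NucleotidePercentageTable:
    """Count aligned bases per reference position and normalise to fractions.

    A read contributes its aligned base at every position it covers, or the
    deletion mark where the position is deleted; insertions do not create
    positions. ``region`` is a 0-based half-open amplicon interval
    (default: the whole amplicon).
    """
    if len(aligned) == 0:
        raise ValueError("no retained reads to quantify")
    start, end = region if region is not None else (0, len(ref.sequence))
    idx = {b: k for k, b in enumerate(_FRACTION_COLS)}
    counts = np.zeros((end - start, len(_FRACTION_COLS)), dtype=np.int64)
    for ar in aligned:
        for i in range(start, end):
            b = ar.base_at[i]
            if b is not None:
                counts[i - start, idx.get(b, idx["N"])] += 1
    denom = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom[:, None] > 0, counts / denom[:, None], 0.0)
    rows = {
        "position": np.arange(start + 1, end + 1),
        "ref_base": list(ref.sequence[start:end]),
        "proto_pos": pd.array(
            [ref.proto_position(i) for i in range(start, end)], dtype="Int64"
        ),
    }
    for k, b in enumerate(_FRACTION_COLS):
        rows[b] = frac[:, k]
    rows["denominator"] = denom
    return NucleotidePercentageTable(
        df=pd.DataFrame(rows), strand=ref.strand, reference_name=ref.name
    )


def conversion_frequency(
    table: NucleotidePercentageTable,
    from_base: str,
    to_base: str,
    position: int,
) -> float:
    """Percent of reads converted ``from_base``->``to_base`` at a
    protospacer position (bases given on the protospacer strand)."""
    if from_base not in "CA":
        raise ValueError(f"source base must be C or A, got {from_base!r}")
    if to_base not in "ACGT" or to_base == from_base:
        raise ValueError(f"invalid product base {to_base!r}")
    row = table.row_for_proto(position)
    ref_b, prod_b = from_base, to_base
    if table.strand == "-":
        ref_b, prod_b = complement(from_base), complement(to_base)
    if row["ref_base"] != ref_b:
        raise ValueError(
            f"reference base at protospacer position {position} is not {from_base} "
            "on the protospacer strand"
        )
    return 100.0 * float(row[prod_b])


def indel_frequency(
    aligned: AlignedReads,
    ref: AmpliconReference,
    window: QuantWindow | None = None,
) -> float:
    """Percent of retained reads with >=1 insertion/deletion overlapping
    the quantification window (default: the full protospacer)."""
    if len(aligned) == 0:
        raise ValueError("no retained reads")
    start, end = (window or QuantWindow()).resolve(ref)
    n = sum(1 for ar in aligned if ar.has_indel_overlapping(start, end))
    return 100.0 * n / len(aligned)


# --------------------------------------------------------------------------
# genotype table


@dataclass
class GenotypeTable:
    """Protospacer-region alleles with counts, frequencies and annotations.

    ``df`` columns: ``allele`` (gapped protospacer-strand sequence),
    ``count``, ``frequency_pct``, ``annotations`` (comma-joined
    ``C6>G``-style labels, empty for reference or indel alleles),
    ``has_indel``. Rows sorted by count descending, then allele.
    """

    df: pd.DataFrame
    reference_allele: str = ""
    total_classified: int = 0
    n_unclassified: int = 0


def _allele_string(ar: AlignedRead, ref: AmpliconReference) -> str | None:
    s = ref.protospacer_start
    e = s + PROTOSPACER_LEN
    if not ar.covers(s, e):
        return None
    ins_at: dict[int, str] = {}
    for junction, seq in ar.insertions:
        if s <= junction < e - 1:
            ins_at[junction] = ins_at.get(junction, "") + seq
    parts = []
    for i in range(s, e):
        parts.append(ar.base_at[i])
        if i in ins_at:
            parts.append(ins_at[i])
    allele = "".join(parts)
    if ref.strand == "-":
        allele = allele[::-1].translate(str.maketrans("ACGTN-", "TGCAN-"))
    return allele


def genotype_table(aligned: AlignedReads, ref: AmpliconReference) -> GenotypeTable:
    """Group reads by their aligned protospacer-region sequence.

    Reads whose alignment does not cover the full protospacer are left
    unclassified. Indel-bearing alleles keep their literal gapped
    sequence; substitution alleles are annotated per differing position.
    """
    if len(aligned) == 0:
        raise ValueError("no retained reads")
    proto = ref.protospacer
    s, e = ref.protospacer_start, ref.protospacer_start + PROTOSPACER_LEN
    counts: dict[str, int] = {}
    indel_flags: dict[str, bool] = {}
    n_unclassified = 0
    for ar in aligned:
        allele = _allele_string(ar, ref)
        if allele is None:
            n_unclassified += 1
            continue
        counts[allele] = counts.get(allele, 0) + 1
        if allele not in indel_flags:
            indel_flags[allele] = ar.has_indel_overlapping(s, e)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no reads cover the protospacer region")
    rows = []
    for allele, n in counts.items():
        has_indel = indel_flags[allele] or len(allele) != PROTOSPACER_LEN
        if has_indel:
            ann = ""
        else:
            ann = ",".join(
                f"{proto[k]}{k + 1}>{allele[k]}"
                for k in range(PROTOSPACER_LEN)
                if allele[k] != proto[k]
            )
        rows.append((allele, n, 100.0 * n / total, ann, has_indel))
    df = pd.DataFrame(
        rows, columns=["allele", "count", "frequency_pct", "annotations", "has_indel"]
    ).sort_values(
        ["count", "allele"], ascending=[False, True], ignore_index=True
    )
    return GenotypeTable(
        df=df,
        reference_allele=proto,
        total_classified=total,
        n_unclassified=n_unclassified,
    )


# --------------------------------------------------------------------------
# report files


def write_nucleotide_percentage_summary(
    table: NucleotidePercentageTable, path, **params
) -> None:
    report.write_tsv(table.df, path, reference=table.reference_name,
                     strand=table.strand, **params)


def write_editing_frequency(
    aligned: AlignedReads, ref: AmpliconReference, path,
    window: QuantWindow | None = None, **params,
) -> None:
    """Batch-style per-amplicon read accounting and indel rate."""
    w = window or QuantWindow()
    df = pd.DataFrame(
        [{
            "amplicon": ref.name,
            "reads_input": aligned.n_input,
            "reads_aligned": len(aligned),
            "reads_discarded": aligned.n_discarded,
            "indel_pct": indel_frequency(aligned, ref, w),
        }]
    )
    report.write_tsv(df, path, wc=w.center_offset, w=w.width, **params)


def write_genotype_table(gt: GenotypeTable, path, **params) -> None:
    report.write_tsv(
        gt.df, path, reference_allele=gt.reference_allele,
        total=gt.total_classified, unclassified=gt.n_unclassified, **params,
    )


def read_nucleotide_percentage_summary(path) -> NucleotidePercentageTable:
    df, params = report.read_tsv_with_params(path)
    df["proto_pos"] = df["proto_pos"].astype("Int64")
    return NucleotidePercentageTable(
        df=df,
        strand=params.get("strand", "+"),
        reference_name=params.get("reference", ""),
    )


def read_genotype_table(path) -> GenotypeTable:
    df, params = report.read_tsv_with_params(path)
    df["allele"] = df["allele"].astype(str)
    df["annotations"] = df["annotations"].fillna("")
    return GenotypeTable(
        df=df,
        reference_allele=params.get("reference_allele", ""),
        total_classified=int(params.get("total", df["count"].sum())),
        n_unclassified=int(params.get("unclassified", 0)),
    )
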