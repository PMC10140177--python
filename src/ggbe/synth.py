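"""Synthetic amplicon references and read sets with known editing outcomes.

This module generates the inputs the quantification pipeline consumes:
a reference amplicon carrying a located protospacer + NGG PAM, and FASTQ
read sets drawn from an explicit generative model of base-editing outcomes
(per-position substitution rates or an explicit genotype list, indels
anchored at the Cas9 cut site, uniform per-base sequencing error).

Because every read is drawn from known parameters, downstream estimates
(conversion frequencies, indel rate, genotype frequencies) can be checked
against the generating values — the simulator is the ground truth for the
whole pipeline.

Coordinate conventions: protospacer positions are 1-based, 5'->3' on the
protospacer strand, position 1 PAM-distal, positions 21-23 the PAM. The
SpCas9 blunt cut sits between protospacer positions 17 and 18 (3 bp 5' of
the PAM).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .dna import check_dna, is_ngg, revcomp

PROTOSPACER_LEN = 20
#: cut falls between protospacer positions CUT_AFTER and CUT_AFTER+1
CUT_AFTER = 17

# realistic single-read amplicon bounds (typical deep-sequencing PCR product)
MIN_AMPLICON = 100
MAX_AMPLICON = 400

_RATE_KEY = re.compile(r"^([CA])(\d{1,2})([GTAC])$")


@dataclass(frozen=True)
class AmpliconReference:
    """An amplicon sequence with a located protospacer and PAM.

    ``protospacer_start`` is the 0-based amplicon offset of the
    protospacer's 5'-most base *on the amplicon strand* (for ``strand ==
    '-'`` this is the base pairing with protospacer position 20).
    """

    name: str
    sequence: str
    protospacer_start: int
    strand: str = "+"
    pam: str = ""

    def __post_init__(self) -> None:
        check_dna(self.sequence, "amplicon sequence", allow_n=True)
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.protospacer_start <= len(self.sequence) - PROTOSPACER_LEN:
            raise ValueError("protospacer does not fit in the amplicon")
        if self.strand == "+":
            if self.protospacer_start + PROTOSPACER_LEN + 3 > len(self.sequence):
                raise ValueError("no room for the PAM 3' of the protospacer")
        else:
            if self.protospacer_start < 3:
                raise ValueError("no room for the PAM 3' of the protospacer")
        if not is_ngg(self.pam):
            raise ValueError(f"PAM {self.pam!r} does not match NGG")

    # -- coordinate mapping ------------------------------------------------

    @property
    def protospacer(self) -> str:
        """20-nt protospacer on the protospacer strand, position 1 first."""
        s, e = self.protospacer_start, self.protospacer_start + PROTOSPACER_LEN
        region = self.sequence[s:e]
        return region if self.strand == "+" else revcomp(region)

    def amplicon_index(self, proto_pos: int) -> int:
        """0-based amplicon offset of protospacer position ``proto_pos`` (1-20)."""
        if not 1 <= proto_pos <= PROTOSPACER_LEN:
            raise ValueError(f"protospacer position {proto_pos} outside 1-20")
        if self.strand == "+":
            return self.protospacer_start + proto_pos - 1
        return self.protospacer_start + PROTOSPACER_LEN - proto_pos

    def proto_position(self, amplicon_index: int) -> int | None:
        """Protospacer position (1-20) of an amplicon offset, or None."""
        off = amplicon_index - self.protospacer_start
        if not 0 <= off < PROTOSPACER_LEN:
            return None
        return off + 1 if self.strand == "+" else PROTOSPACER_LEN - off

    @property
    def cut_index(self) -> int:
        """The cut lies between amplicon offsets ``cut_index`` and ``cut_index + 1``."""
        left = self.amplicon_index(CUT_AFTER)
        right = self.amplicon_index(CUT_AFTER + 1)
        return min(left, right)


def make_reference(
    name: str,
    protospacer: str,
    flank5: str,
    flank3: str,
    pam: str | None = None,
    strand: str = "+",
) -> AmpliconReference:
    """Build an amplicon reference around a 20-nt protospacer.

    ``flank5``/``flank3`` are given on the protospacer strand; the PAM is
    taken from the first three bases of ``flank3`` unless ``pam`` overrides
    it (it must still match NGG). With ``strand == '-'`` the amplicon is the
    reverse complement of ``flank5 + protospacer + flank3``.
    """
    if len(protospacer) != PROTOSPACER_LEN:
        raise ValueError(
            f"protospacer must be {PROTOSPACER_LEN} nt, got {len(protospacer)}"
        )
    check_dna(protospacer, "protospacer")
    check_dna(flank5, "flank5")
    check_dna(flank3, "flank3")
    effective_pam = pam if pam is not None else flank3[:3]
    if not is_ngg(effective_pam):
        raise ValueError(
            f"PAM {effective_pam!r} does not match NGG "
            "(pass pam=... to override the first bases of flank3)"
        )
    plus = flank5 + protospacer + flank3
    if not MIN_AMPLICON <= len(plus) <= MAX_AMPLICON:
        raise ValueError(
            f"amplicon length {len(plus)} outside the supported "
            f"{MIN_AMPLICON}-{MAX_AMPLICON} nt range"
        )
    if strand == "+":
        start = len(flank5)
        seq = plus
    elif strand == "-":
        start = len(flank3)
        seq = revcomp(plus)
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return AmpliconReference(
        name=name, sequence=seq, protospacer_start=start,
        strand=strand, pam=effective_pam,
    )


# --------------------------------------------------------------------------
# editing profile


def _default_indel_sizes() -> dict[int, float]:
    # deletion-dominated spectrum typical of Cas9 repair outcomes
    return {
        -1: 0.35, -2: 0.18, -3: 0.12, -4: 0.08, -5: 0.05,
        -6: 0.03, -7: 0.02, -8: 0.015, -9: 0.01, -10: 0.005,
        1: 0.09, 2: 0.04, 3: 0.01,
    }


@dataclass
class EditingProfile:
    """Generative model for per-read editing outcomes.

    ``rates`` maps ``(protospacer position, source base, product base)`` to
    a per-read probability; draws are independent per position unless
    ``genotypes`` supplies explicit alleles ``(20-nt sequence, frequency)``
    whose frequencies sum to 1. With probability ``indel_rate`` a read
    carries an indel (size drawn from ``indel_size_dist``, negative =
    deletion) anchored at the cut site instead of substitution edits.
    ``seq_error_rate`` is a uniform per-base substitution error applied to
    the final read.
    """

    rates: dict[tuple[int, str, str], float] = field(default_factory=dict)
    indel_rate: float = 0.0
    indel_size_dist: dict[int, float] = field(default_factory=_default_indel_sizes)
    seq_error_rate: float = 0.0
    genotypes: list[tuple[str, float]] | None = None

    def validate(self) -> None:
        by_site: dict[tuple[int, str], float] = {}
        for (pos, src, prod), p in self.rates.items():
            if not 1 <= pos <= PROTOSPACER_LEN:
                raise ValueError(f"rate position {pos} outside 1-20")
            if src not in "CA":
                raise ValueError(f"editable source base must be C or A, got {src!r}")
            if prod not in "ACGT" or prod == src:
                raise ValueError(f"invalid product base {prod!r} for source {src!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"rate {src}{pos}{prod}={p} outside [0,1]")
            by_site[pos, src] = by_site.get((pos, src), 0.0) + p
        for (pos, src), total in by_site.items():
            if total > 1.0 + 1e-9:
                raise ValueError(
                    f"product probabilities at {src}{pos} sum to {total} > 1"
                )
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate outside [0,1]")
        if not 0.0 <= self.seq_error_rate <= 1.0:
            raise ValueError("seq_error_rate outside [0,1]")
        if self.indel_rate > 0:
            if not self.indel_size_dist:
                raise ValueError("indel_rate > 0 requires indel_size_dist")
            if 0 in self.indel_size_dist:
                raise ValueError("indel size 0 is not an indel")
            if any(p < 0 for p in self.indel_size_dist.values()):
                raise ValueError("negative indel size probability")
            tot = sum(self.indel_size_dist.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"indel size probabilities sum to {tot}, not 1")
        if self.genotypes is not None:
            if not self.genotypes:
                raise ValueError("genotype list is empty")
            for allele, freq in self.genotypes:
                if len(allele) != PROTOSPACER_LEN:
                    raise ValueError(
                        f"genotype allele {allele!r} is not {PROTOSPACER_LEN} nt"
                    )
                check_dna(allele, "genotype allele")
                if freq < 0:
                    raise ValueError("negative genotype frequency")
            tot = sum(f for _, f in self.genotypes)
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"genotype frequencies sum to {tot}, not 1")

    @classmethod
    def from_dict(cls, cfg: dict) -> "EditingProfile":
        """Build a profile from config keys (rates as ``C6G: 0.5`` strings)."""
        rates: dict[tuple[int, str, str], float] = {}
        for key, val in (cfg.get("rates") or {}).items():
            m = _RATE_KEY.match(str(key))
            if not m:
                raise ValueError(
                    f"rate key {key!r} is not of the form <src><pos><prod>, e.g. C6G"
                )
            src, pos, prod = m.group(1), int(m.group(2)), m.group(3)
            rates[pos, src, prod] = float(val)
        sizes = cfg.get("indel_size_dist")
        genotypes = None
        if cfg.get("genotypes"):
            genotypes = [
                (str(g["allele"]).upper(), float(g["frequency"]))
                for g in cfg["genotypes"]
            ]
        profile = cls(
            rates=rates,
            indel_rate=float(cfg.get("indel_rate", 0.0)),
            indel_size_dist=(
                {int(k): float(v) for k, v in sizes.items()}
                if sizes else _default_indel_sizes()
            ),
            seq_error_rate=float(cfg.get("seq_error_rate", 0.0)),
            genotypes=genotypes,
        )
        profile.validate()
        return profile


def load_profile(path: str | Path) -> EditingProfile:
    """Read an :class:`EditingProfile` from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return EditingProfile.from_dict(cfg)


# --------------------------------------------------------------------------
# read set


@dataclass
class ReadSet:
    """Sequencing reads (id, sequence, Phred+33 quality) from one amplicon."""

    reads: list[tuple[str, str, str]]
    source_reference: str = ""

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


def _sample_allele(
    proto: str,
    profile: EditingProfile,
    rng: np.random.Generator,
) -> str:
    if profile.genotypes is not None:
        u = rng.random()
        acc = 0.0
        for allele, freq in profile.genotypes:
            acc += freq
            if u < acc:
                return allele
        return profile.genotypes[-1][0]
    allele = list(proto)
    for pos in range(1, PROTOSPACER_LEN + 1):
        src = proto[pos - 1]
        outcomes = [
            (prod, p) for (rpos, rsrc, prod), p in profile.rates.items()
            if rpos == pos and rsrc == src and p > 0
        ]
        if not outcomes:
            continue
        u = rng.random()
        acc = 0.0
        for prod, p in outcomes:
            acc += p
            if u < acc:
                allele[pos - 1] = prod
                break
    return "".join(allele)


def _apply_indel(
    seq: str, cut_index: int, size: int, rng: np.random.Generator
) -> str:
    """Apply a deletion (size<0, symmetric around the cut, left-biased for
    odd sizes) or an insertion (size>0, random bases at the cut)."""
    if size < 0:
        n = -size
        left = (n + 1) // 2
        right = n - left
        lo = max(0, cut_index + 1 - left)
        hi = min(len(seq), cut_index + 1 + right)
        return seq[:lo] + seq[hi:]
    ins = "".join(rng.choice(list("ACGT"), size=size))
    return seq[: cut_index + 1] + ins + seq[cut_index + 1:]


def simulate_reads(
    ref: AmpliconReference,
    profile: EditingProfile,
    n_reads: int,
    seed: int,
) -> ReadSet:
    """Draw ``n_reads`` full-length amplicon reads from the editing model.

    Per read: sample a protospacer allele (independent per-position draws or
    one explicit genotype); with probability ``indel_rate`` replace the
    allele outcome with an indel anchored at the cut site; embed in the
    amplicon; apply uniform sequencing error. Same seed, same output.
    """
    if n_reads <= 0:
        raise ValueError(f"n_reads must be >= 1, got {n_reads}")
    profile.validate()
    proto = ref.protospacer
    if profile.genotypes is None:
        for (pos, src, _prod) in profile.rates:
            if proto[pos - 1] != src:
                raise ValueError(
                    f"profile edits {src} at protospacer position {pos} but the "
                    f"reference has {proto[pos - 1]} there"
                )
    rng = np.random.default_rng(seed)
    s = ref.protospacer_start
    sizes = sorted(profile.indel_size_dist)
    size_p = np.array([profile.indel_size_dist[k] for k in sizes], dtype=float)
    if size_p.size:
        size_p = size_p / size_p.sum()
    bases = np.frombuffer(b"ACGT", dtype="S1")
    reads: list[tuple[str, str, str]] = []
    for i in range(n_reads):
        if profile.indel_rate > 0 and rng.random() < profile.indel_rate:
            size = int(rng.choice(np.array(sizes), p=size_p))
            seq = _apply_indel(ref.sequence, ref.cut_index, size, rng)
        else:
            allele = _sample_allele(proto, profile, rng)
            region = allele if ref.strand == "+" else revcomp(allele)
            seq = ref.sequence[:s] + region + ref.sequence[s + PROTOSPACER_LEN:]
        if profile.seq_error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            hits = np.nonzero(rng.random(len(arr)) < profile.seq_error_rate)[0]
            for j in hits:
                alts = bases[bases != arr[j]]
                arr[j] = alts[rng.integers(len(alts))]
            seq = arr.tobytes().decode()
        reads.append((f"{ref.name}_read{i}", seq, "I" * len(seq)))
    return ReadSet(reads=reads, source_reference=ref.name)


# --------------------------------------------------------------------------
# FASTQ / FASTA I/O


def write_fastq(rs: ReadSet, path: str | Path) -> None:
    """Write a read set as 4-line Sanger FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in rs.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path, source_reference: str = "") -> ReadSet:
    """Read Sanger FASTQ into a :class:`ReadSet`; malformed records raise."""
    reads: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for rid, seq, qual in FastqGeneralIterator(fh):
            seq = seq.upper()
            check_dna(seq, f"read {rid}", allow_n=True)
            reads.append((rid, seq, qual))
    return ReadSet(reads=reads, source_reference=source_reference)


def write_reference_fasta(refs: Iterable[AmpliconReference], path: str | Path) -> None:
    """Write amplicon references as FASTA; placement metadata goes in the
    description so :func:`read_reference_fasta` can reconstruct it."""
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(
                f">{ref.name} protospacer_start={ref.protospacer_start} "
                f"strand={ref.strand} pam={ref.pam}\n{ref.sequence}\n"
            )


def locate_protospacer(sequence: str, protospacer: str) -> tuple[int, str, str]:
    """Locate a 20-nt protospacer (+ NGG PAM) on either strand of an amplicon.

    Returns ``(protospacer_start, strand, pam)``; raises ``ValueError`` when
    the protospacer with a valid PAM occurs zero or multiple times.
    """
    if len(protospacer) != PROTOSPACER_LEN:
        raise ValueError("protospacer must be 20 nt")
    hits: list[tuple[int, str, str]] = []
    for strand, probe in (("+", protospacer), ("-", revcomp(protospacer))):
        start = sequence.find(probe)
        while start != -1:
            if strand == "+":
                pam = sequence[start + PROTOSPACER_LEN: start + PROTOSPACER_LEN + 3]
            else:
                pam = revcomp(sequence[max(0, start - 3): start])
            if is_ngg(pam):
                hits.append((start, strand, pam))
            start = sequence.find(probe, start + 1)
    if not hits:
        raise ValueError("protospacer with NGG PAM not found in amplicon")
    if len(hits) > 1:
        raise ValueError("protospacer occurs more than once in amplicon")
    return hits[0]


def read_reference_fasta(
    path: str | Path, protospacer: str | None = None
) -> list[AmpliconReference]:
    """Read amplicon references from FASTA.

    Placement comes from ``protospacer_start=``/``strand=``/``pam=`` tokens
    in the description when present, otherwise by locating ``protospacer``
    on either strand.
    """
    refs: list[AmpliconReference] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        tokens = dict(
            t.split("=", 1) for t in rec.description.split() if "=" in t
        )
        if {"protospacer_start", "strand", "pam"} <= tokens.keys():
            refs.append(AmpliconReference(
                name=rec.id, sequence=seq,
                protospacer_start=int(tokens["protospacer_start"]),
                strand=tokens["strand"], pam=tokens["pam"],
            ))
        elif protospacer is not None:
            start, strand, pam = locate_protospacer(seq, protospacer.upper())
            refs.append(AmpliconReference(
                name=rec.id, sequence=seq, protospacer_start=start,
                strand=strand, pam=pam,
            ))
        else:
            raise ValueError(
                f"record {rec.id}: no placement metadata and no protospacer given"
            )
    return refs
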