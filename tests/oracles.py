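"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive computation, sharing
no code with the package implementation they check.
"""

from __future__ import annotations

NEG_INF = float("-inf")


def gotoh_score(
    ref: str,
    read: str,
    match: int = 5,
    mismatch: int = -4,
    gap_open: int = -20,
    gap_extend: int = -1,
) -> float:
    """Optimal global affine-gap alignment score by explicit Gotoh DP.

    End gaps are penalized. A gap of length L costs
    ``-(gap_open + (L-1) * gap_extend)`` (both arguments are negative
    scores here, so: ``gap_open + (L-1)*gap_extend``).
    """
    n, m = len(ref), len(read)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in read (deletion)
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in ref (insertion)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == read[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open,
            )
    return max(M[n][m], X[n][m], Y[n][m])


_RC = str.maketrans("ACGTN", "TGCAN")


def _rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def brute_force_placements(
    context: str, sites: tuple[int, int]
) -> set[tuple[str, int, str, str, tuple[int, ...]]]:
    """Every valid 20-nt + NGG placement, by literal enumeration.

    Returns ``{(strand, start_on_plus, protospacer, pam, edited_positions)}``
    where a placement is valid when both 0-based ``sites`` sit at
    protospacer positions 5-7 on the scanned strand with one reading A
    and the other C there.
    """
    out = set()
    n = len(context)
    for strand in ("+", "-"):
        seq = context if strand == "+" else _rc(context)
        ssites = [s if strand == "+" else n - 1 - s for s in sites]
        for start in range(n - 23 + 1):
            proto = seq[start: start + 20]
            pam = seq[start + 20: start + 23]
            if not (len(pam) == 3 and pam[1] == "G" and pam[2] == "G"):
                continue
            pos = [s - start + 1 for s in ssites]
            if not all(5 <= p <= 7 for p in pos):
                continue
            if sorted(seq[s] for s in ssites) != ["A", "C"]:
                continue
            plus_start = start if strand == "+" else n - (start + 23)
            out.add((strand, plus_start, proto, pam, tuple(sorted(pos))))
    return out


CORRECTING = ("GNG>ANC", "GGN>ACN", "NGG>NAC", "GNG>CNA", "GGN>CAN", "NGG>NCA")
CREATING = ("ACN>GGN", "ANC>GNG", "CAN>GGN", "CNA>GNG", "NAC>NGG", "NCA>NGG")


def expand_patterns() -> dict[tuple[str, str], tuple[str, str]]:
    """Expand the 12 printed patterns into explicit (ref, alt) pairs.

    Returns ``{(ref_tri, alt_tri): (direction, pattern)}`` for plus-strand
    matches; the N base iterates over ACGT and is identical on both sides.
    """
    table: dict[tuple[str, str], tuple[str, str]] = {}
    for direction, patterns in (("correcting", CORRECTING), ("creating", CREATING)):
        for pat in patterns:
            left, right = pat.split(">")
            for nbase in "ACGT":
                ref = left.replace("N", nbase)
                alt = right.replace("N", nbase)
                table[(ref, alt)] = (direction, pat)
    return table


def classify_oracle(ref: str, alt: str) -> tuple[str, str | None, str | None]:
    """(direction, pattern, strand) by membership in the expanded tables."""
    table = expand_patterns()
    if (ref, alt) in table:
        d, p = table[(ref, alt)]
        return d, p, "+"
    if (_rc(ref), _rc(alt)) in table:
        d, p = table[(_rc(ref), _rc(alt))]
        return d, p, "-"
    return "none", None, None
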