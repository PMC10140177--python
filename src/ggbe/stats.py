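"""Derived editing statistics for dual-function base editors.

A dual C-to-G / A-to-G editor is judged on more than raw efficiency:

* **total editing** — the sum of a conversion's per-position frequencies
  over all 20 protospacer positions;
* **D-value** — the absolute difference between total A-to-G and total
  C-to-G editing, a balance measure for the two deaminase activities
  (0 = perfectly balanced);
* **window efficiency** — the mean conversion frequency over the
  source-base positions inside the editing window (positions 4-7 for
  GGBE1.0, 5-7 for GGBE1.3);
* **purity** — among edited cytosines at a position, the proportions
  ending up as G vs A vs T (deletions and N excluded);
* **concurrent fraction** — the percentage of reads whose allele carries
  at least one C-to-G *and* one A-to-G edit within the window, the
  defining outcome of a dual editor.

All operations consume the quantification outputs of :mod:`ggbe.quant`;
conversion arguments are written ``"C2G"`` / ``"A2G"`` (``"C>G"`` and
``("C", "G")`` are also accepted).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dna import complement
from .quant import GenotypeTable, NucleotidePercentageTable
from .synth import PROTOSPACER_LEN
from . import report

#: editing-window defaults per editor label
EDITOR_WINDOWS: dict[str, tuple[int, int]] = {
    "GGBE1.0": (4, 7),
    "GGBE1.3": (5, 7),
}


def _parse_conversion(conversion) -> tuple[str, str]:
    if isinstance(conversion, (tuple, list)) and len(conversion) == 2:
        src, prod = conversion
    else:
        text = str(conversion).upper().replace("->", "2").replace(">", "2")
        src, _, prod = text.partition("2")
    src, prod = src.strip(), prod.strip()
    if src not in "CA" or prod not in "ACGT" or src == prod:
        raise ValueError(f"unsupported conversion {conversion!r}")
    return src, prod


def _proto_base(table: NucleotidePercentageTable, row: pd.Series) -> str:
    base = row["ref_base"]
    return base if table.strand == "+" else complement(base)


def _proto_rows(table: NucleotidePercentageTable) -> dict[int, pd.Series]:
    rows = {}
    for _, row in table.df.iterrows():
        if pd.notna(row["proto_pos"]):
            rows[int(row["proto_pos"])] = row
    return rows


def _check_full_protospacer(rows: dict[int, pd.Series]) -> None:
    missing = set(range(1, PROTOSPACER_LEN + 1)) - rows.keys()
    if missing:
        raise ValueError(
            f"table does not cover protospacer positions {sorted(missing)}"
        )


def _frequency(table, row, src: str, prod: str) -> float:
    ref_prod = prod if table.strand == "+" else complement(prod)
    return 100.0 * float(row[ref_prod])


def total_editing(
    table: NucleotidePercentageTable,
    conversion,
    window: tuple[int, int] | None = None,
) -> float:
    """Sum of conversion frequencies over all protospacer positions whose
    reference base is the conversion source (optionally restricted to a
    closed position ``window``)."""
    src, prod = _parse_conversion(conversion)
    rows = _proto_rows(table)
    _check_full_protospacer(rows)
    lo, hi = window if window is not None else (1, PROTOSPACER_LEN)
    return sum(
        _frequency(table, row, src, prod)
        for pos, row in rows.items()
        if lo <= pos <= hi and _proto_base(table, row) == src
    )


def d_value(table: NucleotidePercentageTable) -> float:
    """|total A-to-G - total C-to-G| over the protospacer: the editing-
    balance statistic for a dual editor."""
    return abs(total_editing(table, "A2G") - total_editing(table, "C2G"))


def window_efficiency(
    table: NucleotidePercentageTable,
    conversion,
    window: tuple[int, int],
) -> float:
    """Unweighted mean conversion frequency over source-base positions
    inside the closed window; errors when the window has no source base."""
    src, prod = _parse_conversion(conversion)
    lo, hi = window
    if not (1 <= lo <= hi <= PROTOSPACER_LEN):
        raise ValueError(f"window {window} outside protospacer positions 1-20")
    rows = _proto_rows(table)
    vals = [
        _frequency(table, row, src, prod)
        for pos, row in rows.items()
        if lo <= pos <= hi and _proto_base(table, row) == src
    ]
    if not vals:
        raise ValueError(f"no {src} base at protospacer positions {lo}-{hi}")
    return sum(vals) / len(vals)


def purity(
    table: NucleotidePercentageTable, position: int
) -> dict[str, float] | None:
    """Proportions of G/A/T among edited reads at a cytosine position.

    Deletions and N are excluded from the denominator. Returns ``None``
    (undefined) when no editing is observed at the position.
    """
    row = table.row_for_proto(position)
    if _proto_base(table, row) != "C":
        raise ValueError(
            f"protospacer position {position} is not a cytosine"
        )
    fracs = {
        prod: row[prod if table.strand == "+" else complement(prod)]
        for prod in "GAT"
    }
    edited = sum(fracs.values())
    if edited <= 0.0:
        return None
    return {prod: float(f / edited) for prod, f in fracs.items()}


def concurrent_fraction(
    gt: GenotypeTable, window: tuple[int, int] = (1, PROTOSPACER_LEN)
) -> float:
    """Percent of classified reads whose (indel-free) allele carries >=1
    C-to-G and >=1 A-to-G edit within the closed protospacer window."""
    lo, hi = window
    ref = gt.reference_allele
    n_concurrent = 0
    for _, row in gt.df.iterrows():
        if row["has_indel"] or len(row["allele"]) != PROTOSPACER_LEN:
            continue
        allele = row["allele"]
        has_c2g = any(
            ref[k] == "C" and allele[k] == "G"
            for k in range(lo - 1, hi)
        )
        has_a2g = any(
            ref[k] == "A" and allele[k] == "G"
            for k in range(lo - 1, hi)
        )
        if has_c2g and has_a2g:
            n_concurrent += int(row["count"])
    return 100.0 * n_concurrent / gt.total_classified


def aggregate_positions(
    tables: list[NucleotidePercentageTable],
) -> pd.DataFrame:
    """Mean C-to-G and A-to-G frequency per protospacer position across loci.

    For each position 1-20 the mean is taken over loci whose reference
    base there is the source base; positions with no qualifying locus get
    ``NaN`` (absent). Columns: ``proto_pos, c2g_mean, n_c_loci, a2g_mean,
    n_a_loci``.
    """
    if not tables:
        raise ValueError("need at least one table to aggregate")
    records = []
    for pos in range(1, PROTOSPACER_LEN + 1):
        acc = {"C": [], "A": []}
        for table in tables:
            rows = _proto_rows(table)
            if pos not in rows:
                continue
            row = rows[pos]
            base = _proto_base(table, row)
            if base in acc:
                acc[base].append(_frequency(table, row, base, "G"))
        records.append({
            "proto_pos": pos,
            "c2g_mean": sum(acc["C"]) / len(acc["C"]) if acc["C"] else float("nan"),
            "n_c_loci": len(acc["C"]),
            "a2g_mean": sum(acc["A"]) / len(acc["A"]) if acc["A"] else float("nan"),
            "n_a_loci": len(acc["A"]),
        })
    return pd.DataFrame(records)


def cumulative_offtarget(
    tables: list[NucleotidePercentageTable], conversion
) -> tuple[list[float], float]:
    """Total editing per off-target amplicon plus the cumulative sum."""
    totals = [total_editing(t, conversion) for t in tables]
    return totals, sum(totals)


# --------------------------------------------------------------------------
# summary


@dataclass
class EditingSummary:
    """All per-locus editing statistics for one editor."""

    editor: str
    locus: str
    window: tuple[int, int]
    a2g_window_eff: float
    c2g_window_eff: float
    total_a2g: float
    total_c2g: float
    d_value: float
    concurrent_pct: float
    indel_pct: float
    purity: dict[int, dict[str, float] | None]

    def to_row(self) -> dict:
        purity_txt = ";".join(
            f"{pos}:" + (
                "|".join(f"{b}={p[b]:.4f}" for b in "GAT") if p else "NA"
            )
            for pos, p in sorted(self.purity.items())
        )
        return {
            "editor": self.editor,
            "locus": self.locus,
            "window": f"{self.window[0]}-{self.window[1]}",
            "a2g_window_eff": self.a2g_window_eff,
            "c2g_window_eff": self.c2g_window_eff,
            "total_a2g": self.total_a2g,
            "total_c2g": self.total_c2g,
            "d_value": self.d_value,
            "concurrent_pct": self.concurrent_pct,
            "indel_pct": self.indel_pct,
            "purity": purity_txt,
        }


def summarize(
    table: NucleotidePercentageTable,
    gt: GenotypeTable,
    indel_pct: float,
    editor: str = "GGBE1.0",
    locus: str = "",
    window: tuple[int, int] | None = None,
) -> EditingSummary:
    """Assemble the full :class:`EditingSummary` for one editor x locus.

    ``window`` defaults to the editor's known editing window
    (:data:`EDITOR_WINDOWS`); unknown editors must pass one explicitly.
    """
    if window is None:
        try:
            window = EDITOR_WINDOWS[editor]
        except KeyError:
            raise ValueError(
                f"no default editing window for editor {editor!r}; pass window="
            ) from None
    rows = _proto_rows(table)
    _check_full_protospacer(rows)

    def _eff(src):
        try:
            return window_efficiency(table, (src, "G"), window)
        except ValueError:
            return float("nan")

    pur = {
        pos: purity(table, pos)
        for pos, row in sorted(rows.items())
        if _proto_base(table, row) == "C"
    }
    return EditingSummary(
        editor=editor,
        locus=locus or table.reference_name,
        window=window,
        a2g_window_eff=_eff("A"),
        c2g_window_eff=_eff("C"),
        total_a2g=total_editing(table, "A2G"),
        total_c2g=total_editing(table, "C2G"),
        d_value=d_value(table),
        concurrent_pct=concurrent_fraction(gt, window),
        indel_pct=indel_pct,
        purity=pur,
    )


def write_editing_summary(summaries: list[EditingSummary], path, **params) -> None:
    df = pd.DataFrame([s.to_row() for s in summaries])
    report.write_tsv(df, path, **params)
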