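"""TSV report I/O with a provenance header line.

Every table the pipeline writes starts with a single ``#``-prefixed header
recording the tool version and the parameters that produced it, so outputs
are self-describing and byte-identical for identical runs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__


def provenance_line(**params) -> str:
    items = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# ggbe v{__version__} {items}".rstrip()


def write_tsv(df: pd.DataFrame, path: str | Path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(**params) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_tsv_with_params(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a report TSV plus the key=value pairs of its provenance line."""
    params: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first.lstrip("#").split():
            if "=" in token:
                k, _, v = token.partition("=")
                params[k] = v
    return read_tsv(path), params
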