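"""Readers and writers for the plain-text interchange formats.

Expression matrices travel as TSV (first column ``gene_id``, remaining
columns sample IDs), sample-to-stage tables as two-column TSV
(``sample_id``, ``stage``), and gene-set collections as standard GMT
(one set per line: name, description, then member genes, tab-separated).
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_sample_table",
    "write_sample_table",
    "read_gmt",
    "write_gmt",
]


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes x samples expression matrix (log2 scale assumed)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df

def write_expression_tsv(expr: pd.DataFrame, path: str | os.PathLike) -> None:
    out = expr.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_sample_table(path: str | os.PathLike) -> pd.Series:
    """Read sample -> stage assignments; returns a Series indexed by sample id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "stage"}.issubset(df.columns):
        raise ValueError("sample table must have columns 'sample_id' and 'stage'")
    return df.set_index("sample_id")["stage"]

def write_sample_table(stage_of: Mapping[str, str] | pd.Series, path: str | os.PathLike) -> None:
    s = pd.Series(dict(stage_of)) if not isinstance(stage_of, pd.Series) else stage_of
    df = pd.DataFrame({"sample_id": s.index, "stage": s.values})
    df.to_csv(path, sep="\t", index=False)


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | os.PathLike,
              descriptions: Mapping[str, str] | None = None) -> None:
    """Write gene sets to GMT.

    Every set must be nonempty, and neither names, descriptions nor gene ids
    may contain the tab delimiter or a newline.
    """
    lines = []
    for name, genes in sets.items():
        genes = list(genes)
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        desc = (descriptions or {}).get(name, "na")
        for token in [name, desc, *genes]:
            if "\t" in token or "\n" in token:
                raise ValueError(f"GMT token contains delimiter: {token!r}")
        lines.append("\t".join([name, desc, *genes]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT file into an ordered name -> gene-list mapping."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {raw[:80]!r}")
            name, _desc, *genes = fields
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            sets[name] = genes
    return sets
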