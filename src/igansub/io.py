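"""Plain-text readers/writers for the formats the pipeline exchanges.

Everything is TSV or GMT; expression matrices are genes x samples with the
gene id in the first column.
"""

from __future__ import annotations

import os
from typing import Dict, List, Mapping, Sequence

import pandas as pd


def write_expression_tsv(expr: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a genes x samples matrix; index = gene ids, columns = sample ids."""
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotation_tsv(ann: pd.DataFrame, path: str | os.PathLike) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | os.PathLike,
              descriptions: Mapping[str, str] | None = None) -> None:
    """Write gene sets in GMT format: name <tab> description <tab> genes..."""
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *map(str, genes)]) + "\n")


def read_gmt(path: str | os.PathLike) -> Dict[str, List[str]]:
    """Read a GMT file into an ordered name -> gene-list mapping.

    Duplicate gene ids within a set are dropped (first occurrence kept), as
    required by the GeneSetCollection contract.
    """
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            seen: Dict[str, None] = {}
            for g in parts[2:]:
                if g and g not in seen:
                    seen[g] = None
            sets[name] = list(seen)
    return sets
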