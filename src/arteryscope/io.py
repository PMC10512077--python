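"""TSV / GMT readers and writers for every table the pipeline exchanges.

All on-disk formats are plain text: counts and metadata as TSV, gene sets as
GMT (one set per line: name, description, member genes, tab-separated).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List

import pandas as pd

from .containers import CountMatrix, validate_roi_meta

NEGPROBE_COLUMN = "is_negprobe"
TARGET_COLUMN = "target"


def write_counts(matrix: CountMatrix, path) -> None:
    out = matrix.counts.copy()
    out.insert(0, NEGPROBE_COLUMN, matrix.is_negprobe.values)
    out.index.name = TARGET_COLUMN
    out.to_csv(path, sep="\t")


def read_counts(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if NEGPROBE_COLUMN not in df.columns:
        raise ValueError(f"counts file {path} lacks the '{NEGPROBE_COLUMN}' column")
    flags = df[NEGPROBE_COLUMN].astype(bool)
    counts = df.drop(columns=[NEGPROBE_COLUMN])
    return CountMatrix(counts, flags)


def write_roi_meta(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "roi"
    out.to_csv(path, sep="\t")


def read_roi_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    return validate_roi_meta(meta)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_gmt(sets: Dict[str, List[str]], path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *map(str, genes)]) + "\n")


def read_gmt(path) -> Dict[str, List[str]]:
    sets: Dict[str, List[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = fields[2:]
    return sets


def read_edge_table(path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    required = {"geneA", "geneB", "score"}
    if not required.issubset(edges.columns):
        raise ValueError(f"edge table needs columns {sorted(required)}")
    return edges


def read_drug_table(path) -> pd.DataFrame:
    drugs = pd.read_csv(path, sep="\t")
    required = {"gene", "drug", "approved"}
    if not required.issubset(drugs.columns):
        raise ValueError(f"drug table needs columns {sorted(required)}")
    return drugs
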