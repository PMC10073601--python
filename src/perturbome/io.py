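"""Plain-text readers and writers for the pipeline's tabular formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_annotation_bed",
    "write_annotation_bed",
    "read_design_tsv",
    "read_growth_csv",
    "write_growth_csv",
    "read_function_map_tsv",
]

BED_COLUMNS = ["chrom", "start", "end", "gene_id", "score", "strand"]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x samples matrix; first column is the gene id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation_bed(path: str | Path) -> pd.DataFrame:
    """6-column BED-like annotation; adds length and circular midpoint."""
    annot = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)
    annot["length"] = annot["end"] - annot["start"]
    annot["midpoint"] = (annot["start"] + annot["end"]) / 2.0
    return annot


def write_annotation_bed(annot: pd.DataFrame, path: str | Path) -> None:
    annot[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    """Sample design table indexed by sample name."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_growth_csv(path: str | Path) -> pd.DataFrame:
    """Long-format growth curves: well, time_h, od600."""
    return pd.read_csv(path)


def write_growth_csv(curves, path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, od in zip(c.times, c.od):
            rows.append({"well": c.label, "time_h": t, "od600": od})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_function_map_tsv(path: str | Path) -> pd.DataFrame:
    """2-column (category_id, gene_id) membership table."""
    return pd.read_csv(path, sep="\t", header=None, names=["category_id", "gene_id"])
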