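"""Readers and writers for the plain-text interval formats the pipeline uses.

Formats: BED3/BED6, ENCODE narrowPeak (10 columns), bedGraph, two-column
chrom.sizes, a headered gene-table TSV and a headered peak-stats TSV.
Parsing is line-wise so malformed input is reported with its file name and
line number. All coordinates are converted to 0-based half-open on read; a
gene table may declare ``coordinate_system=1`` (column with constant value)
to mark 1-based TSS positions, which are shifted down on read.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ChromSizes, DE_LABELS

__all__ = [
    "read_bed",
    "read_narrowpeak",
    "read_bedgraph",
    "read_chrom_sizes",
    "read_gene_table",
    "read_peak_stats",
    "write_bed",
    "write_table",
]

BED6_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")
NARROWPEAK_COLUMNS = BED6_COLUMNS + ("signal_value", "p_value", "q_value", "summit")


class ParseError(ValueError):
    """A malformed line, annotated with file and line number."""

    def __init__(self, path: str | os.PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _check_interval(path, lineno, start: int, end: int) -> None:
    if start < 0:
        raise ParseError(path, lineno, f"negative start {start}")
    if start >= end:
        raise ParseError(path, lineno, f"empty or inverted interval [{start}, {end})")


def read_bed(path, sizes: ChromSizes | None = None) -> pd.DataFrame:
    """Read BED (>=3 columns); returns columns chrom/start/end and, when
    present, name/score/strand."""
    rows = []
    ncols = None
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(path, lineno, f"BED needs >=3 columns, got {len(fields)}")
        if ncols is None:
            ncols = min(len(fields), 6)
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(path, lineno, f"non-integer coordinates {fields[1:3]}") from None
        _check_interval(path, lineno, start, end)
        row = [fields[0], start, end] + fields[3:6]
        rows.append(row[: 3 + (ncols - 3)])
    cols = list(BED6_COLUMNS[: ncols or 3])
    df = pd.DataFrame(rows, columns=cols)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    if sizes is not None:
        sizes.validate_frame(df)
    return df


def read_narrowpeak(path, sizes: ChromSizes | None = None) -> pd.DataFrame:
    """Read ENCODE narrowPeak (exactly 10 columns)."""
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 10:
            raise ParseError(path, lineno, f"narrowPeak needs 10 columns, got {len(fields)}")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(path, lineno, f"non-integer coordinates {fields[1:3]}") from None
        _check_interval(path, lineno, start, end)
        rows.append([fields[0], start, end] + fields[3:])
    df = pd.DataFrame(rows, columns=list(NARROWPEAK_COLUMNS))
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    for col in ("score", "signal_value", "p_value", "q_value"):
        df[col] = pd.to_numeric(df[col])
    df["summit"] = df["summit"].astype(np.int64)
    if sizes is not None:
        sizes.validate_frame(df)
    return df


def read_bedgraph(path, sizes: ChromSizes | None = None) -> pd.DataFrame:
    """Read a 4-column bedGraph track (chrom, start, end, value)."""
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 4:
            raise ParseError(path, lineno, f"bedGraph needs 4 columns, got {len(fields)}")
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError:
            raise ParseError(path, lineno, "non-numeric fields") from None
        _check_interval(path, lineno, start, end)
        rows.append([fields[0], start, end, value])
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if sizes is not None:
        sizes.validate_frame(df)
    return df


def read_chrom_sizes(path) -> ChromSizes:
    sizes: dict[str, int] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ParseError(path, lineno, "chrom.sizes needs 2 columns")
        chrom = fields[0]
        if chrom in sizes:
            raise ParseError(path, lineno, f"duplicate chromosome {chrom}")
        try:
            sizes[chrom] = int(fields[1])
        except ValueError:
            raise ParseError(path, lineno, f"non-integer length {fields[1]!r}") from None
    return ChromSizes(sizes)


GENE_TABLE_REQUIRED = ("gene_id", "chrom", "strand", "tss", "de_label")


def read_gene_table(path, sizes: ChromSizes | None = None) -> pd.DataFrame:
    """Read a headered gene TSV (gene_id, chrom, strand, tss, de_label
    [, chromatin_class][, coordinate_system])."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in GENE_TABLE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene table missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        gid = df.loc[bad_strand, "gene_id"].iloc[0]
        raise ValueError(f"{path}: gene {gid!r} has invalid strand")
    bad_label = ~df["de_label"].isin(DE_LABELS)
    if bad_label.any():
        gid = df.loc[bad_label, "gene_id"].iloc[0]
        raise ValueError(f"{path}: gene {gid!r} has invalid de_label")
    df["tss"] = df["tss"].astype(np.int64)
    if "coordinate_system" in df.columns:
        cs = set(df["coordinate_system"].astype(int).unique())
        if not cs <= {0, 1}:
            raise ValueError(f"{path}: coordinate_system must be 0 or 1")
        if cs == {1}:
            df["tss"] = df["tss"] - 1
        elif 1 in cs:
            raise ValueError(f"{path}: mixed coordinate_system values")
        df = df.drop(columns=["coordinate_system"])
    if "chromatin_class" not in df.columns:
        df["chromatin_class"] = pd.NA
    if (df["tss"] < 0).any():
        gid = df.loc[df["tss"] < 0, "gene_id"].iloc[0]
        raise ValueError(f"{path}: gene {gid!r} has negative TSS")
    if sizes is not None:
        for chrom, grp in df.groupby("chrom"):
            if (grp["tss"] >= sizes[chrom]).any():
                gid = grp.loc[grp["tss"] >= sizes[chrom], "gene_id"].iloc[0]
                raise ValueError(f"{path}: gene {gid!r} TSS beyond chromosome end")
    return df


def read_peak_stats(path) -> pd.DataFrame:
    """Read a headered peak-stats TSV: chrom, start, end, depth,
    group_mean_<condition>..., q_value, fold_change."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: stats table missing columns {missing}")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: empty or inverted interval in stats table")
    return df


def write_bed(df: pd.DataFrame, path, columns: Sequence[str] | None = None) -> None:
    """Write BED (no header). Writes chrom/start/end plus any of
    name/score/strand present, unless ``columns`` restricts them."""
    if columns is None:
        columns = [c for c in BED6_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=list(columns))


def write_table(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Write a headered TSV with stable float formatting."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
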