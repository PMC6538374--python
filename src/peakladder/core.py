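"""Interval data model and overlap engine.

All coordinates are 0-based, half-open ``[start, end)`` — the BED-native
convention. Bookended intervals (``a.end == b.start``) do NOT overlap.
Strand is ignored in every overlap computation (ATAC/ChIP peaks are
unstranded); it matters only for resolving a gene's TSS and for orienting
metaprofiles.

Interval *collections* are plain :class:`pandas.DataFrame` objects with at
least the columns ``chrom``, ``start``, ``end`` (optionally ``name``,
``score``, ``strand``); gene tables additionally carry ``gene_id``,
``strand``, ``tss``, ``de_label`` and optionally ``chromatin_class``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneRecord",
    "ChromSizes",
    "tss_of",
    "tss_from_body",
    "expand_interval",
    "overlaps",
    "merge_intervals",
    "overlap_any",
    "count_region_hits",
    "closest_gene",
    "closest_genes",
    "intervals_to_frame",
]

_STRANDS = {"+", "-", "."}

DE_LABELS = ("up", "down", "unchanged")
CHROMATIN_CLASSES = ("bivalent", "k4_only", "k27_only", "neither")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its strand-resolved TSS and analysis labels."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    de_label: str = "unchanged"
    chromatin_class: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")
        if self.de_label not in DE_LABELS:
            raise ValueError(f"gene {self.gene_id}: bad de_label {self.de_label!r}")


class ChromSizes(Mapping[str, int]):
    """Chromosome name -> length (bp). Used to clip expanded ranges."""

    def __init__(self, sizes: Mapping[str, int]):
        for chrom, length in sizes.items():
            if int(length) <= 0:
                raise ValueError(f"non-positive length for {chrom}")
        self._sizes = {str(c): int(n) for c, n in sizes.items()}

    def __getitem__(self, chrom: str) -> int:
        try:
            return self._sizes[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} absent from sizes table") from None

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def validate_frame(self, df: pd.DataFrame) -> None:
        """Check every interval fits inside its chromosome."""
        for chrom, grp in df.groupby("chrom", sort=False):
            length = self[chrom]
            if (grp["start"] < 0).any() or (grp["end"] > length).any():
                bad = grp[(grp["start"] < 0) | (grp["end"] > length)].iloc[0]
                raise ValueError(
                    f"interval {chrom}:{bad['start']}-{bad['end']} outside "
                    f"chromosome of length {length}"
                )


def tss_of(gene: GeneRecord) -> int:
    """Return the stored (already strand-resolved) TSS of a gene."""
    if gene.strand not in {"+", "-"}:
        raise ValueError(f"gene {gene.gene_id}: unknown strand {gene.strand!r}")
    return gene.tss


def tss_from_body(start: int, end: int, strand: str) -> int:
    """Resolve the TSS from a half-open gene body: 5' base is ``start`` on +,
    ``end - 1`` on -."""
    if start >= end:
        raise ValueError("empty gene body")
    if strand == "+":
        return start
    if strand == "-":
        return end - 1
    raise ValueError(f"unknown strand {strand!r}")


def expand_interval(iv: GenomicInterval, radius: int, sizes: ChromSizes) -> GenomicInterval:
    """Symmetrically widen an interval by ``radius`` bp, clipped to the chromosome."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    length = sizes[iv.chrom]
    return GenomicInterval(
        chrom=iv.chrom,
        start=max(0, iv.start - radius),
        end=min(length, iv.end + radius),
        strand=iv.strand,
        name=iv.name,
        score=iv.score,
    )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base (strand ignored)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def intervals_to_frame(ivs: Iterable[GenomicInterval]) -> pd.DataFrame:
    ivs = list(ivs)
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in ivs],
            "start": np.array([iv.start for iv in ivs], dtype=np.int64),
            "end": np.array([iv.end for iv in ivs], dtype=np.int64),
            "strand": [iv.strand for iv in ivs],
        }
    )


# ---------------------------------------------------------------------------
# collection engine (sorted-array sweep; oracles in the test suite are the
# brute-force all-pairs scans)
# ---------------------------------------------------------------------------


def _chrom_arrays(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        order = np.lexsort((ends, starts))
        out[str(chrom)] = (starts[order], ends[order])
    return out


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coalesce sorted-by-start intervals that share >=1 base (bookended stay
    separate). Returns disjoint, sorted (starts, ends)."""
    if len(starts) == 0:
        return starts, ends
    cummax = np.maximum.accumulate(ends)
    # a new block begins where the next start reaches past everything so far
    new_block = np.empty(len(starts), dtype=bool)
    new_block[0] = True
    new_block[1:] = starts[1:] >= cummax[:-1]
    block = np.cumsum(new_block) - 1
    merged_starts = starts[new_block]
    merged_ends = np.maximum.reduceat(ends, np.flatnonzero(new_block))
    assert len(merged_starts) == block[-1] + 1
    return merged_starts, merged_ends


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of a set of intervals: strictly overlapping intervals coalesced,
    bookended intervals kept separate; output sorted by (chrom, start)."""
    rows = []
    for chrom in sorted(df["chrom"].unique()):
        sub = df[df["chrom"] == chrom]
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        order = np.lexsort((ends, starts))
        ms, me = _merge_sorted(starts[order], ends[order])
        rows.append(pd.DataFrame({"chrom": chrom, "start": ms, "end": me}))
    if not rows:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    return pd.concat(rows, ignore_index=True)


def overlap_any(queries: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Boolean vector: does each query share >=1 base with any feature?"""
    merged = {c: _merge_sorted(*se) for c, se in _chrom_arrays(features).items()}
    out = np.zeros(len(queries), dtype=bool)
    qs = queries["start"].to_numpy(dtype=np.int64)
    qe = queries["end"].to_numpy(dtype=np.int64)
    chroms = queries["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        if chrom not in merged:
            continue
        fs, fe = merged[chrom]
        mask = chroms == chrom
        j = np.searchsorted(fs, qe[mask], side="left")
        hit = (j > 0) & (fe[np.maximum(j - 1, 0)] > qs[mask])
        out[np.flatnonzero(mask)] = hit
    return out


def count_region_hits(
    queries: pd.DataFrame, features: pd.DataFrame, mode: str = "query_centric"
) -> int:
    """Count overlap hits.

    ``query_centric``: queries overlapping >=1 feature (each counted once).
    ``feature_centric``: features overlapped by >=1 query.
    """
    if mode == "query_centric":
        return int(overlap_any(queries, features).sum())
    if mode == "feature_centric":
        return int(overlap_any(features, queries).sum())
    raise ValueError(f"unknown counting mode {mode!r}")


# ---------------------------------------------------------------------------
# nearest gene
# ---------------------------------------------------------------------------


@dataclass
class _GeneIndex:
    """Per-chromosome TSS positions sorted ascending, with gene ids."""

    tss: dict[str, np.ndarray] = field(default_factory=dict)
    gene_id: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def build(cls, genes: pd.DataFrame) -> "_GeneIndex":
        idx = cls()
        for chrom, grp in genes.groupby("chrom", sort=False):
            t = grp["tss"].to_numpy(dtype=np.int64)
            g = grp["gene_id"].to_numpy()
            order = np.lexsort((g, t))
            idx.tss[str(chrom)] = t[order]
            idx.gene_id[str(chrom)] = g[order]
        return idx


def _closest_on_chrom(
    start: int, end: int, tss: np.ndarray, gene_id: np.ndarray
) -> tuple[str, int]:
    lo = np.searchsorted(tss, start, side="left")
    hi = np.searchsorted(tss, end, side="left")
    if hi > lo:  # >=1 TSS inside the peak: distance 0, tie-break on gene_id
        return min(gene_id[lo:hi]), 0
    best: tuple[int, str] | None = None
    if lo > 0:
        v = tss[lo - 1]
        d = int(start - v)
        i0 = np.searchsorted(tss, v, side="left")
        cand = min(gene_id[i0:lo])
        best = (d, cand)
    if lo < len(tss):
        v = tss[lo]
        d = int(v - (end - 1))
        i1 = np.searchsorted(tss, v, side="right")
        cand = min(gene_id[lo:i1])
        if best is None or (d, cand) < best:
            best = (d, cand)
    assert best is not None
    return best[1], best[0]


def closest_gene(peak: GenomicInterval, genes: pd.DataFrame) -> tuple[str, int]:
    """Nearest gene to a peak by TSS distance.

    Distance is 0 when the TSS lies inside the peak, otherwise the distance
    from the TSS to the nearer peak edge (the last base of the peak on the
    right). Ties break to the lexicographically smallest gene_id. Returns
    ``(gene_id, distance)``.
    """
    idx = _GeneIndex.build(genes)
    if peak.chrom not in idx.tss:
        raise ValueError(f"no gene on chromosome {peak.chrom!r}")
    return _closest_on_chrom(peak.start, peak.end, idx.tss[peak.chrom], idx.gene_id[peak.chrom])


def closest_genes(peaks: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Vectorised closest-gene assignment: one row per peak with columns
    ``gene_id`` and ``distance`` (peak order preserved)."""
    idx = _GeneIndex.build(genes)
    out_gene = []
    out_dist = []
    for chrom, start, end in zip(peaks["chrom"], peaks["start"], peaks["end"]):
        if chrom not in idx.tss:
            raise ValueError(f"no gene on chromosome {chrom!r}")
        g, d = _closest_on_chrom(int(start), int(end), idx.tss[chrom], idx.gene_id[chrom])
        out_gene.append(g)
        out_dist.append(d)
    return pd.DataFrame({"gene_id": out_gene, "distance": out_dist}, index=peaks.index)
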