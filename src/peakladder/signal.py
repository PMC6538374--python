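"""Signal normalization and summarization over region sets.

Median equalization rescales each condition so the median read count over a
filtered set of high-signal regions coincides across conditions; the filter
drops regions whose cross-condition mean signal does not exceed the median
of those means (signal indistinguishable from background). Downstream, the
factors feed per-region normalized read counts (e.g. transcription over
super-enhancers) and binned metaprofiles.

bedGraph tracks are DataFrames with columns chrom/start/end/value, segments
disjoint within a chromosome; absent coverage counts as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean

__all__ = [
    "ScaleFactors",
    "Metaprofile",
    "median_equalization_factors",
    "apply_factors",
    "region_read_counts",
    "metaplot",
    "region_matrix",
]


@dataclass(frozen=True)
class ScaleFactors:
    """Per-condition multiplicative factors and how they were derived.

    ``reference`` is the geometric mean of the per-condition medians over
    the retained high-signal regions; each factor is reference / median_c,
    so applying the factors equalizes those medians at the reference.
    """

    factors: dict[str, float]
    reference: float
    raw_medians: dict[str, float]
    n_retained: int

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("scale factors must be positive")

    def __getitem__(self, condition: str) -> float:
        return self.factors[condition]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": list(self.factors),
                "median_raw": [self.raw_medians[c] for c in self.factors],
                "factor": [self.factors[c] for c in self.factors],
            }
        )


def median_equalization_factors(matrix: pd.DataFrame) -> ScaleFactors:
    """Scale factors that equalize per-condition median read counts over
    high-signal regions.

    ``matrix`` is regions x conditions of raw read counts. Procedure:
    (1) per-region cross-condition mean; (2) retain regions whose mean
    strictly exceeds the median of those means; (3) reference = geometric
    mean of the per-condition medians over retained regions; (4) factor_c =
    reference / median_c.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two conditions")
    if matrix.shape[0] < 4:
        raise ValueError("need at least four regions")
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative values in signal matrix")
    region_mean = values.mean(axis=1)
    retained = region_mean > np.median(region_mean)
    if retained.sum() == 0:
        raise ValueError("no region above the median signal level")
    medians = np.median(values[retained], axis=0)
    zero = np.flatnonzero(medians == 0)
    if len(zero):
        raise ValueError(
            f"condition {matrix.columns[zero[0]]!r} has zero median over retained regions"
        )
    reference = float(gmean(medians))
    return ScaleFactors(
        factors={c: reference / m for c, m in zip(matrix.columns, medians)},
        reference=reference,
        raw_medians={c: float(m) for c, m in zip(matrix.columns, medians)},
        n_retained=int(retained.sum()),
    )


def apply_factors(matrix: pd.DataFrame, factors: ScaleFactors) -> pd.DataFrame:
    """Multiply each condition column by its factor."""
    out = matrix.copy()
    for c in out.columns:
        out[c] = out[c] * factors[c]
    return out


def _track_by_chrom(track: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out = {}
    for chrom, grp in track.groupby("chrom", sort=False):
        order = np.argsort(grp["start"].to_numpy(), kind="stable")
        out[str(chrom)] = (
            grp["start"].to_numpy(dtype=np.int64)[order],
            grp["end"].to_numpy(dtype=np.int64)[order],
            grp["value"].to_numpy(dtype=float)[order],
        )
    return out


def region_read_counts(
    track: pd.DataFrame, regions: pd.DataFrame, factor: float = 1.0
) -> np.ndarray:
    """Normalized read count per region: sum over overlapping track segments
    of value x covered bases, times the condition's scale factor. A region
    on a chromosome absent from the track gets 0 (with a warning)."""
    if len(regions) == 0:
        raise ValueError("empty region set")
    by_chrom = _track_by_chrom(track)
    out = np.zeros(len(regions))
    warned: set[str] = set()
    for i, (chrom, rs, re_) in enumerate(zip(regions["chrom"], regions["start"], regions["end"])):
        if chrom not in by_chrom:
            if chrom not in warned:
                warnings.warn(f"chromosome {chrom!r} absent from signal track; counting 0")
                warned.add(chrom)
            continue
        ts, te, tv = by_chrom[chrom]
        j0 = np.searchsorted(te, rs, side="right")
        j1 = np.searchsorted(ts, re_, side="left")
        if j1 <= j0:
            continue
        cov = np.minimum(te[j0:j1], re_) - np.maximum(ts[j0:j1], rs)
        out[i] = float(np.sum(cov * tv[j0:j1]))
    return out * factor


def _bin_offsets(length: int, n_bins: int) -> np.ndarray:
    """Start offsets of n_bins near-equal sub-intervals; remainder bases go
    to the leftmost bins (so profiles are bit-reproducible)."""
    base, rem = divmod(length, n_bins)
    sizes = np.full(n_bins, base, dtype=np.int64)
    sizes[:rem] += 1
    return np.concatenate([[0], np.cumsum(sizes)[:-1]])


@dataclass
class Metaprofile:
    """Mean normalized per-base signal in each of n_bins scaled-position
    bins, averaged (unweighted) over regions."""

    n_bins: int
    values: np.ndarray
    n_regions: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_index": np.arange(self.n_bins), "mean_signal": self.values})


def metaplot(
    track: pd.DataFrame, regions: pd.DataFrame, n_bins: int, factor: float = 1.0
) -> Metaprofile:
    """Average signal profile over a region set.

    Each region is split into ``n_bins`` near-equal sub-intervals (remainder
    to the leftmost bins); per-bin mean per-base signal is scaled by
    ``factor``; minus-strand regions (when a strand column is present) are
    reversed per-base before binning so bin 0 is always the 5' end; the
    profile is the unweighted mean across regions.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(regions) == 0:
        raise ValueError("empty region set")
    widths = regions["end"].to_numpy() - regions["start"].to_numpy()
    if (widths < 1).any():
        raise ValueError("all regions must have length >= 1")
    if (widths < n_bins).any():
        raise ValueError("region shorter than n_bins")
    by_chrom = _track_by_chrom(track)
    strands = (
        regions["strand"].to_numpy()
        if "strand" in regions.columns
        else np.full(len(regions), ".")
    )
    acc = np.zeros(n_bins)
    for chrom, rs, re_, strand in zip(
        regions["chrom"], regions["start"], regions["end"], strands
    ):
        length = int(re_ - rs)
        cov = np.zeros(length)
        if chrom in by_chrom:
            ts, te, tv = by_chrom[chrom]
            j0 = np.searchsorted(te, rs, side="right")
            j1 = np.searchsorted(ts, re_, side="left")
            for s, e, v in zip(ts[j0:j1], te[j0:j1], tv[j0:j1]):
                cov[max(s - rs, 0) : min(e - rs, length)] += v
        if strand == "-":
            cov = cov[::-1]
        offsets = _bin_offsets(length, n_bins)
        sums = np.add.reduceat(cov, offsets)
        sizes = np.diff(np.concatenate([offsets, [length]]))
        acc += sums / sizes
    return Metaprofile(n_bins=n_bins, values=acc / len(regions) * factor, n_regions=len(regions))


def region_matrix(
    tracks: dict[str, pd.DataFrame],
    regions: pd.DataFrame,
    factors: ScaleFactors | dict[str, float] | None = None,
) -> pd.DataFrame:
    """Regions x conditions matrix of normalized read counts (row order =
    input region order); the export shape behind signal heatmaps."""
    names = [
        f"{c}:{s}-{e}" for c, s, e in zip(regions["chrom"], regions["start"], regions["end"])
    ]
    data = {}
    for cond, track in tracks.items():
        f = 1.0
        if factors is not None:
            f = factors[cond] if isinstance(factors, ScaleFactors) else float(factors[cond])
        data[cond] = region_read_counts(track, regions, factor=f)
    return pd.DataFrame(data, index=names)
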