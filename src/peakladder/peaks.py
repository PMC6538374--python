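"""Peak post-processing: high-depth exclusion, merging into considered
regions, max-group-mean filtering and threshold-based differential calls.

These steps consume an already-computed peak statistics table (one row per
peak: coordinates, total depth, per-condition group means, adjusted q-value,
fold change). Computing those statistics from raw counts is out of scope —
this module only applies the published thresholds.

Fold-change encoding
--------------------
``fold_change`` is a linear-scale ratio. Two equivalent encodings of the
"lower in treatment" direction are accepted: a plain ratio in (0, 1), or the
signed convention common in result tables (e.g. -7.9 meaning 7.9-fold
lower). Values >= 1 always mean higher in treatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import merge_intervals

__all__ = [
    "DifferentialCallConfig",
    "DifferentialCalls",
    "PRESETS",
    "group_mean_columns",
    "exclude_high_depth",
    "merge_considered_regions",
    "mgm_filter",
    "call_differential",
]


@dataclass(frozen=True)
class DifferentialCallConfig:
    """Thresholds for calling differentially accessible peaks.

    q_max: adjusted-significance ceiling (exclusive: q < q_max).
    fc_min: linear fold-change floor, > 1 (inclusive: |ratio| >= fc_min).
    mgm_min: max-group-mean floor in reads (exclusive: mgm > mgm_min).
    """

    q_max: float
    fc_min: float
    mgm_min: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.q_max <= 1.0):
            raise ValueError("q_max must be in (0, 1]")
        if self.fc_min <= 1.0:
            raise ValueError("fc_min must exceed 1 (linear scale)")
        if self.mgm_min < 0.0:
            raise ValueError("mgm_min must be non-negative")


#: The two published analysis regimes. ``steady_state`` is the q < 0.05,
#: FC > 1.5, mgm 8 regime; ``neural`` is q < 0.01, linear FC > 2 (printed
#: in the results; the methods text instead says log2 FC > 2 = linear 4 —
#: the discrepancy is left as a user-visible knob), mgm 32.
PRESETS = {
    "steady_state": DifferentialCallConfig(q_max=0.05, fc_min=1.5, mgm_min=8.0),
    "neural": DifferentialCallConfig(q_max=0.01, fc_min=2.0, mgm_min=32.0),
}


def group_mean_columns(stats: pd.DataFrame) -> list[str]:
    cols = [c for c in stats.columns if c.startswith("group_mean_")]
    if not cols:
        raise ValueError("stats table has no group_mean_<condition> columns")
    return cols


def exclude_high_depth(
    stats: pd.DataFrame, fraction: float = 0.001
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop the top ``fraction`` of peaks by aligned-read depth.

    Removes exactly ``floor(fraction * n)`` peaks of highest depth; depth
    ties are broken by (chrom, start) with the later-sorted peak removed
    first. Intended to run per input peak file, before merging. Returns
    ``(retained, removed)``, both in (chrom, start) order.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    if "depth" not in stats.columns:
        raise ValueError("stats table has no depth column")
    n_remove = math.floor(fraction * len(stats))
    order = stats.sort_values(["depth", "chrom", "start"], kind="mergesort")
    removed = order.iloc[len(stats) - n_remove :]
    retained = order.iloc[: len(stats) - n_remove]
    key = ["chrom", "start", "end"]
    return (
        retained.sort_values(key, kind="mergesort").reset_index(drop=True),
        removed.sort_values(key, kind="mergesort").reset_index(drop=True),
    )


def merge_considered_regions(peak_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of the peak sets from all conditions: overlapping (>=1 shared
    base) intervals coalesced, bookended intervals kept separate, output
    sorted by (chrom, start). This union is the statistical universe
    ("considered regions") for the peak-level tests."""
    if not peak_sets:
        raise ValueError("need at least one peak set")
    return merge_intervals(pd.concat(peak_sets, ignore_index=True)[["chrom", "start", "end"]])


def mgm_filter(stats: pd.DataFrame, mgm_min: float) -> pd.DataFrame:
    """Retain peaks whose max per-condition group mean strictly exceeds
    ``mgm_min`` reads (regions indistinguishable from background drop out)."""
    cols = group_mean_columns(stats)
    mgm = stats[cols].to_numpy(dtype=float).max(axis=1)
    return stats[mgm > mgm_min].reset_index(drop=True)


def _direction(fc: np.ndarray, fc_min: float) -> np.ndarray:
    """Return +1 (higher), -1 (lower) or 0 per peak given the fc_min floor."""
    out = np.zeros(len(fc), dtype=np.int8)
    out[fc >= fc_min] = 1
    lower = ((fc < 0) & (-fc >= fc_min)) | ((fc > 0) & (fc <= 1.0 / fc_min))
    out[lower] = -1
    return out


@dataclass
class DifferentialCalls:
    """Partition of a stats table into higher-accessibility (HA),
    lower-accessibility (LA) and unchanged peaks."""

    ha: pd.DataFrame
    la: pd.DataFrame
    unchanged: pd.DataFrame
    labels: pd.Series  # 'HA' / 'LA' / 'unchanged', aligned to the input

    def __post_init__(self) -> None:
        assert len(self.ha) + len(self.la) + len(self.unchanged) == len(self.labels)


def call_differential(stats: pd.DataFrame, config: DifferentialCallConfig) -> DifferentialCalls:
    """Label peaks HA / LA / unchanged by q-value and fold change.

    HA: q < q_max and ratio >= fc_min. LA: q < q_max and the inverse-contrast
    ratio >= fc_min. The three sets partition the input. The mgm floor is a
    separate step (:func:`mgm_filter`) applied beforehand.
    """
    for col in ("q_value", "fold_change"):
        if col not in stats.columns:
            raise ValueError(f"stats table has no {col} column")
        if stats[col].isna().any():
            raise ValueError(f"stats table has missing {col} values")
    q = stats["q_value"].to_numpy(dtype=float)
    if ((q < 0) | (q > 1)).any():
        raise ValueError("q_value outside [0, 1]")
    fc = stats["fold_change"].to_numpy(dtype=float)
    direction = _direction(fc, config.fc_min)
    sig = q < config.q_max
    labels = np.where(sig & (direction == 1), "HA", np.where(sig & (direction == -1), "LA", "unchanged"))
    labels = pd.Series(labels, index=stats.index, name="label")
    return DifferentialCalls(
        ha=stats[labels == "HA"].reset_index(drop=True),
        la=stats[labels == "LA"].reset_index(drop=True),
        unchanged=stats[labels == "unchanged"].reset_index(drop=True),
        labels=labels,
    )
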