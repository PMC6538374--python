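"""Hypergeometric enrichment machinery.

The central question throughout: are differentially expressed genes (or
feature overlaps) over-represented among the items reachable from a peak
set, relative to drawing the same number of items at random from the
universe? Every test reduces to an upper-tail hypergeometric probability on
counts (q, m, n, k): q observed hits among k drawn items, from a universe of
m marked and n unmarked items.

The distance ladder expands every differential peak by an increasing radius
d, unions the expanded ranges, counts the distinct gene TSS encompassed (k)
and how many carry the differential-expression label of interest (q), and
tests enrichment at each d. Its empirical null repeats the procedure on
many random peak subsets drawn from the full peak universe, matched to the
differential set in number and width-decile composition, and summarises the
resulting -log10 p values as a (5%, median, 95%) envelope per distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core import ChromSizes, closest_genes, overlap_any

logger = logging.getLogger(__name__)

__all__ = [
    "HypergeomCounts",
    "EnrichmentResult",
    "LadderResult",
    "CompositionResult",
    "hypergeom_upper_tail",
    "neg_log10",
    "ladder_enrichment",
    "ladder_with_null",
    "sample_matched_peak_sets",
    "null_envelope",
    "region_overlap_enrichment",
    "tss_window_enrichment",
    "geneset_composition",
    "closest_gene_composition",
    "default_distance_grid",
]

#: p-values are floored here before taking -log10, mirroring the saturation
#: conventions of the upstream statistics packages.
P_FLOOR = 1e-300

COMPOSITION_CLASSES = ("bivalent", "k4_only", "k27_only", "neither", "unclassified")


@dataclass(frozen=True)
class HypergeomCounts:
    """Counts for one upper-tail test: q hits among k drawn, universe of
    m marked + n unmarked items."""

    q: int
    m: int
    n: int
    k: int

    def __post_init__(self) -> None:
        bad = []
        if min(self.q, self.m, self.n, self.k) < 0:
            bad.append("negative count")
        if self.q > min(self.m, self.k):
            bad.append(f"q={self.q} exceeds min(m={self.m}, k={self.k})")
        if self.k > self.m + self.n:
            bad.append(f"k={self.k} exceeds universe m+n={self.m + self.n}")
        if bad:
            raise ValueError("invalid hypergeometric counts: " + "; ".join(bad))


def hypergeom_upper_tail(counts: HypergeomCounts, tail: str = "inclusive") -> float:
    """Upper-tail hypergeometric probability.

    ``inclusive`` returns P(X >= q) — the standard enrichment convention;
    ``exclusive`` returns P(X > q) — the literal behaviour of R's
    ``phyper(q, m, n, k, lower.tail=FALSE)``. Evaluated via the survival
    function of :class:`scipy.stats.hypergeom` (log-space internals).
    """
    c = counts
    M = c.m + c.n
    if tail == "inclusive":
        p = hypergeom.sf(c.q - 1, M, c.m, c.k)
    elif tail == "exclusive":
        p = hypergeom.sf(c.q, M, c.m, c.k)
    else:
        raise ValueError(f"unknown tail convention {tail!r}")
    return float(min(1.0, max(p, 0.0)))


def neg_log10(p: np.ndarray | float) -> np.ndarray | float:
    """-log10 of p, with p floored at P_FLOOR so saturated tests stay finite."""
    return -np.log10(np.maximum(p, P_FLOOR))


@dataclass(frozen=True)
class EnrichmentResult:
    """One overlap-enrichment test: its counts, p-value and conventions."""

    counts: HypergeomCounts
    p_value: float
    counting_mode: str
    tail: str = "inclusive"
    features_hit: int | None = None
    n_features: int | None = None

    def to_frame(self) -> pd.DataFrame:
        c = self.counts
        return pd.DataFrame(
            [
                {
                    "q": c.q,
                    "m": c.m,
                    "n": c.n,
                    "k": c.k,
                    "p_value": self.p_value,
                    "counting_mode": self.counting_mode,
                    "tail": self.tail,
                    "features_hit": self.features_hit,
                    "n_features": self.n_features,
                }
            ]
        )


# ---------------------------------------------------------------------------
# distance ladder
# ---------------------------------------------------------------------------


def default_distance_grid() -> np.ndarray:
    """5 kb steps to 100 kb, 25 kb steps to 500 kb, 100 kb steps to 2 Mb."""
    return np.concatenate(
        [
            np.arange(5_000, 100_001, 5_000),
            np.arange(125_000, 500_001, 25_000),
            np.arange(600_000, 2_000_001, 100_000),
        ]
    )


@dataclass
class LadderResult:
    """Observed distance-ladder curve, optionally with its random-null
    envelope (quantiles of -log10 p across matched random peak sets)."""

    distances: np.ndarray
    encompassed_tss: np.ndarray
    deg_hits: np.ndarray
    p_values: np.ndarray
    label: str
    tail: str
    n_random: int = 0
    null_q05: np.ndarray | None = None
    null_median: np.ndarray | None = None
    null_q95: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "d_bp": self.distances,
                "encompassed_tss": self.encompassed_tss,
                "deg_hits": self.deg_hits,
                "p_value": self.p_values,
                "neg_log10_p": neg_log10(self.p_values),
            }
        )
        if self.null_q95 is not None:
            df["null_q05"] = self.null_q05
            df["null_median"] = self.null_median
            df["null_q95"] = self.null_q95
        return df


class _TssIndex:
    """Sorted TSS positions per chromosome, overall and for the labelled
    subset; enables O(log G) counting inside a union of ranges."""

    def __init__(self, genes: pd.DataFrame, label: str):
        if len(genes) == 0:
            raise ValueError("empty gene table")
        self.total_genes = len(genes)
        self.m = int((genes["de_label"] == label).sum())
        self.all_tss: dict[str, np.ndarray] = {}
        self.label_tss: dict[str, np.ndarray] = {}
        for chrom, grp in genes.groupby("chrom", sort=False):
            t = np.sort(grp["tss"].to_numpy(dtype=np.int64))
            self.all_tss[str(chrom)] = t
            lt = grp.loc[grp["de_label"] == label, "tss"].to_numpy(dtype=np.int64)
            self.label_tss[str(chrom)] = np.sort(lt)


class _PeakArrays:
    """Per-chromosome sorted (start, end) arrays plus chromosome lengths."""

    def __init__(self, peaks: pd.DataFrame, sizes: ChromSizes):
        if len(peaks) == 0:
            raise ValueError("empty peak set")
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
        for chrom, grp in peaks.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy(dtype=np.int64)
            ends = grp["end"].to_numpy(dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            self.by_chrom[str(chrom)] = (starts[order], ends[order], sizes[str(chrom)])


def _count_in_union(starts, ends, positions) -> int:
    """Number of positions falling inside a disjoint sorted interval union."""
    if len(positions) == 0 or len(starts) == 0:
        return 0
    lo = np.searchsorted(positions, starts, side="left")
    hi = np.searchsorted(positions, ends, side="left")
    return int((hi - lo).sum())


def _merge_expanded(starts, ends, radius, length):
    s = np.maximum(starts - radius, 0)
    e = np.minimum(ends + radius, length)
    # expansion preserves start order, so a single cummax pass merges
    cummax = np.maximum.accumulate(e)
    new_block = np.empty(len(s), dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] >= cummax[:-1]
    idx = np.flatnonzero(new_block)
    return s[idx], np.maximum.reduceat(e, idx)


def _ladder_eval(
    peaks: _PeakArrays, tss: _TssIndex, radius: int
) -> tuple[int, int]:
    """(encompassed TSS count, labelled-hit count) at one expansion radius."""
    k = 0
    q = 0
    for chrom, (starts, ends, length) in peaks.by_chrom.items():
        if chrom not in tss.all_tss:
            continue
        ms, me = _merge_expanded(starts, ends, radius, length)
        k += _count_in_union(ms, me, tss.all_tss[chrom])
        q += _count_in_union(ms, me, tss.label_tss[chrom])
    return k, q


def _radii(distances: np.ndarray, range_mode: str) -> np.ndarray:
    if range_mode == "radius":
        return np.asarray(distances, dtype=np.int64)
    if range_mode == "total_width":
        return np.asarray(distances, dtype=np.int64) // 2
    raise ValueError(f"unknown range_mode {range_mode!r}")


def ladder_enrichment(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    label: str,
    distances: np.ndarray | list[int],
    sizes: ChromSizes,
    tail: str = "inclusive",
    range_mode: str = "radius",
) -> LadderResult:
    """Observed distance-ladder enrichment curve (no null envelope).

    For each distance d, peaks are widened by d on both sides ("radius"
    mode; "total_width" widens by d/2), the widened ranges are unioned, the
    distinct gene TSS inside the union are counted (k) along with those
    carrying ``label`` (q), and enrichment is tested against the whole gene
    table (m labelled, n others) with the upper-tail hypergeometric.
    """
    distances = np.asarray(distances, dtype=np.int64)
    if len(distances) == 0 or (np.diff(distances) <= 0).any():
        raise ValueError("distances must be non-empty and strictly ascending")
    tss = _TssIndex(genes, label)
    pk = _PeakArrays(peaks, sizes)
    radii = _radii(distances, range_mode)
    enc = np.zeros(len(distances), dtype=np.int64)
    hits = np.zeros(len(distances), dtype=np.int64)
    pvals = np.ones(len(distances))
    for i, r in enumerate(radii):
        k, q = _ladder_eval(pk, tss, int(r))
        enc[i] = k
        hits[i] = q
        pvals[i] = hypergeom_upper_tail(
            HypergeomCounts(q=q, m=tss.m, n=tss.total_genes - tss.m, k=k), tail=tail
        )
    return LadderResult(distances, enc, hits, pvals, label=label, tail=tail)


# ---------------------------------------------------------------------------
# matched random resampling null
# ---------------------------------------------------------------------------


def _width_bins(target_widths: np.ndarray) -> np.ndarray:
    """Interior decile edges of the target width distribution."""
    return np.quantile(target_widths, np.arange(0.1, 1.0, 0.1))


def _matched_draw_counts(
    universe_bins: np.ndarray, target_bins: np.ndarray, n_bins: int = 10
) -> np.ndarray:
    """Per-bin draw counts: the target's bin counts, with shortfalls in the
    universe borrowed from the nearest adjacent bins."""
    need = np.bincount(target_bins, minlength=n_bins)
    avail = np.bincount(universe_bins, minlength=n_bins)
    draw = np.minimum(need, avail)
    deficit = need - draw
    for b in np.flatnonzero(deficit):
        short = int(deficit[b])
        for offset in range(1, n_bins):
            for nb in (b - offset, b + offset):
                if short == 0 or not (0 <= nb < n_bins):
                    continue
                spare = int(avail[nb] - draw[nb])
                take = min(short, spare)
                if take > 0:
                    draw[nb] += take
                    short -= take
            if short == 0:
                break
        if short > 0:
            raise ValueError("universe smaller than target within all width bins")
        logger.warning(
            "width bin %d short by %d peaks; borrowed from adjacent bins", b, int(deficit[b])
        )
    return draw


def _sample_matched_indices(
    universe_widths: np.ndarray,
    target_widths: np.ndarray,
    n_sets: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    if n_sets < 0:
        raise ValueError("n_sets must be non-negative")
    if len(universe_widths) < len(target_widths):
        raise ValueError(
            f"universe ({len(universe_widths)}) smaller than target ({len(target_widths)})"
        )
    edges = _width_bins(target_widths)
    u_bins = np.digitize(universe_widths, edges)
    t_bins = np.digitize(target_widths, edges)
    draw = _matched_draw_counts(u_bins, t_bins)
    members = [np.flatnonzero(u_bins == b) for b in range(10)]
    sets = []
    for _ in range(n_sets):
        parts = [
            rng.choice(members[b], size=int(draw[b]), replace=False)
            for b in range(10)
            if draw[b] > 0
        ]
        sets.append(np.sort(np.concatenate(parts)) if parts else np.empty(0, dtype=np.int64))
    return sets


def sample_matched_peak_sets(
    universe: pd.DataFrame,
    target: pd.DataFrame,
    n_sets: int,
    seed: int,
) -> list[pd.DataFrame]:
    """Draw ``n_sets`` random peak sets from ``universe``, each matching the
    target in peak number and per-width-decile composition.

    Width-decile bin edges come from the target's own width quantiles; each
    random set draws, without replacement within the set, the target's
    per-bin counts from universe peaks in the same bin, borrowing from the
    nearest adjacent bin when a bin runs short (logged). Fully determined by
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    uw = (universe["end"] - universe["start"]).to_numpy(dtype=np.int64)
    tw = (target["end"] - target["start"]).to_numpy(dtype=np.int64)
    idx_sets = _sample_matched_indices(uw, tw, n_sets, rng)
    return [universe.iloc[ix].reset_index(drop=True) for ix in idx_sets]


def null_envelope(
    neg_log_p: np.ndarray | list,
    quantiles: tuple[float, float, float] = (0.05, 0.5, 0.95),
) -> np.ndarray:
    """Quantile envelope of the random-set significance curves.

    ``neg_log_p`` is (n_sets, n_distances) of -log10 p; returns an array of
    shape (len(quantiles), n_distances) using the linear-interpolation
    (type-7) quantile definition.
    """
    arr_list = [np.asarray(r, dtype=float) for r in neg_log_p]
    if len(arr_list) == 0:
        raise ValueError("need at least one random result")
    lengths = {len(r) for r in arr_list}
    if len(lengths) != 1:
        raise ValueError("ragged distance grids across random results")
    mat = np.vstack(arr_list)
    return np.quantile(mat, quantiles, axis=0)  # numpy default = type-7 linear


def ladder_with_null(
    target_peaks: pd.DataFrame,
    universe_peaks: pd.DataFrame,
    genes: pd.DataFrame,
    label: str,
    distances: np.ndarray | list[int],
    sizes: ChromSizes,
    n_random: int = 1000,
    seed: int = 0,
    tail: str = "inclusive",
    range_mode: str = "radius",
) -> LadderResult:
    """Observed ladder curve plus the matched-random-resampling envelope.

    ``n_random`` width/number-matched subsets of ``universe_peaks`` are each
    run through the identical ladder procedure; the (5%, median, 95%)
    quantiles of their -log10 p at each distance form the null envelope.
    """
    observed = ladder_enrichment(
        target_peaks, genes, label, distances, sizes, tail=tail, range_mode=range_mode
    )
    distances = observed.distances
    rng = np.random.default_rng(seed)
    uw = (universe_peaks["end"] - universe_peaks["start"]).to_numpy(dtype=np.int64)
    tw = (target_peaks["end"] - target_peaks["start"]).to_numpy(dtype=np.int64)
    idx_sets = _sample_matched_indices(uw, tw, n_random, rng)

    tss = _TssIndex(genes, label)
    radii = _radii(distances, range_mode)
    curves = np.empty((len(idx_sets), len(distances)))
    u_chrom = universe_peaks["chrom"].to_numpy()
    u_start = universe_peaks["start"].to_numpy(dtype=np.int64)
    u_end = universe_peaks["end"].to_numpy(dtype=np.int64)
    for s_i, ix in enumerate(idx_sets):
        sub = pd.DataFrame({"chrom": u_chrom[ix], "start": u_start[ix], "end": u_end[ix]})
        pk = _PeakArrays(sub, sizes)
        for d_i, r in enumerate(radii):
            k, q = _ladder_eval(pk, tss, int(r))
            p = hypergeom_upper_tail(
                HypergeomCounts(q=q, m=tss.m, n=tss.total_genes - tss.m, k=k), tail=tail
            )
            curves[s_i, d_i] = neg_log10(p)
    if len(idx_sets):
        env = null_envelope(curves)
        observed.null_q05, observed.null_median, observed.null_q95 = env
    observed.n_random = len(idx_sets)
    return observed


# ---------------------------------------------------------------------------
# region-overlap and TSS-window enrichment
# ---------------------------------------------------------------------------


def _coord_keys(df: pd.DataFrame) -> set[tuple]:
    return set(zip(df["chrom"], df["start"], df["end"]))


def region_overlap_enrichment(
    diff_peaks: pd.DataFrame,
    features: pd.DataFrame,
    universe_peaks: pd.DataFrame,
    counting_mode: str = "query_centric",
    tail: str = "inclusive",
) -> EnrichmentResult:
    """Is the differential peak set enriched for overlap with a feature set,
    relative to the full considered-peak universe?

    Counts: q = differential peaks overlapping >=1 feature; m = universe
    peaks overlapping >=1 feature; n = universe peaks overlapping none;
    k = number of differential peaks. The differential set must be a subset
    of the universe (matched by exact coordinates). ``feature_centric`` also
    reports how many features are hit (for statements like "127/684").
    """
    if counting_mode not in {"query_centric", "feature_centric"}:
        raise ValueError(f"unknown counting mode {counting_mode!r}")
    missing = _coord_keys(diff_peaks) - _coord_keys(universe_peaks)
    if missing:
        ex = sorted(missing)[0]
        raise ValueError(
            f"differential peak {ex[0]}:{ex[1]}-{ex[2]} absent from universe "
            f"({len(missing)} total); universes must match"
        )
    m = int(overlap_any(universe_peaks, features).sum())
    q = int(overlap_any(diff_peaks, features).sum())
    counts = HypergeomCounts(q=q, m=m, n=len(universe_peaks) - m, k=len(diff_peaks))
    features_hit = None
    if counting_mode == "feature_centric":
        features_hit = int(overlap_any(features, diff_peaks).sum())
    return EnrichmentResult(
        counts=counts,
        p_value=hypergeom_upper_tail(counts, tail=tail),
        counting_mode=counting_mode,
        tail=tail,
        features_hit=features_hit,
        n_features=len(features),
    )


def tss_window_enrichment(
    features: pd.DataFrame,
    genes: pd.DataFrame,
    de_label: str,
    window: int = 2500,
    sizes: ChromSizes | None = None,
    tail: str = "inclusive",
) -> EnrichmentResult:
    """Gene-centric enrichment: do labelled genes' TSS +/- window regions hit
    the feature set more often than the whole gene table does?

    The window is [tss - window, tss + window + 1), clipped to the
    chromosome when sizes are given. Counts: m = genes whose window hits a
    feature, n = the rest, k = genes with ``de_label``, q = labelled genes
    whose window hits a feature.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    tss = genes["tss"].to_numpy(dtype=np.int64)
    start = np.maximum(tss - window, 0)
    end = tss + window + 1
    if sizes is not None:
        lengths = genes["chrom"].map(dict(sizes)).to_numpy(dtype=np.int64)
        end = np.minimum(end, lengths)
    windows = pd.DataFrame({"chrom": genes["chrom"].to_numpy(), "start": start, "end": end})
    hit = overlap_any(windows, features) if len(features) else np.zeros(len(genes), bool)
    labelled = (genes["de_label"] == de_label).to_numpy()
    counts = HypergeomCounts(
        q=int((hit & labelled).sum()),
        m=int(hit.sum()),
        n=int(len(genes) - hit.sum()),
        k=int(labelled.sum()),
    )
    return EnrichmentResult(
        counts=counts,
        p_value=hypergeom_upper_tail(counts, tail=tail),
        counting_mode="gene_centric",
        tail=tail,
    )


# ---------------------------------------------------------------------------
# gene-set composition
# ---------------------------------------------------------------------------


@dataclass
class CompositionResult:
    """Counts and fractions of a gene list per chromatin class."""

    counts: dict[str, int]
    fractions: dict[str, float]
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromatin_class": list(self.counts),
                "count": list(self.counts.values()),
                "fraction": [self.fractions[c] for c in self.counts],
            }
        )


def _compose(classes: pd.Series) -> CompositionResult:
    filled = classes.fillna("unclassified")
    counts = {c: int((filled == c).sum()) for c in COMPOSITION_CLASSES}
    n = len(filled)
    fractions = {c: counts[c] / n for c in COMPOSITION_CLASSES}
    return CompositionResult(counts=counts, fractions=fractions, n=n)


def geneset_composition(gene_ids: list[str], genes: pd.DataFrame) -> CompositionResult:
    """Chromatin-class composition (bivalent / H3K4me3-only / H3K27me3-only /
    neither) of a gene list; every class is reported even at zero."""
    if len(gene_ids) == 0:
        raise ValueError("empty gene list")
    table = genes.set_index("gene_id")
    unknown = [g for g in gene_ids if g not in table.index]
    if unknown:
        raise KeyError(f"gene_id {unknown[0]!r} not in gene table")
    return _compose(table.loc[list(gene_ids), "chromatin_class"])


def closest_gene_composition(peaks: pd.DataFrame, genes: pd.DataFrame) -> CompositionResult:
    """Composition of the set of genes closest to the given peaks (a gene
    chosen by several peaks is counted once)."""
    nearest = closest_genes(peaks, genes)
    unique_ids = sorted(set(nearest["gene_id"]))
    return geneset_composition(unique_ids, genes)
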