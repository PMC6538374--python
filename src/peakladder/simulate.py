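"""Seeded synthetic-data generator for the whole pipeline.

Emulates, on a reduced two-chromosome genome, the structures the analysis
assumes: strand-aware gene TSS; a peak universe with log-normal widths and a
promoter-proximal placement bias; a planted differential peak set whose q
and fold-change values pass the published thresholds; a planted peak-to-gene
linkage (each differential peak links, with probability pi, one gene within
distance D and labels it concordantly: higher accessibility -> upregulated);
background differential-expression labels at a low rate; chromatin-class
labels with a configurable bivalent enrichment among differential genes;
enhancer / super-enhancer / TF-site feature sets; per-condition negative-
binomial read counts with planted global scale differences; and a few
injected regions of extreme depth mimicking alignment artifacts.

A truth manifest records every planted quantity so tests can score recovery.
Everything derives from one integer seed; identical configs give
byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ChromSizes
from .io import write_bed, write_table

__all__ = ["SimulationConfig", "SyntheticBundle", "simulate", "truth_check"]


@dataclass
class SimulationConfig:
    """All knobs of the generator, with the study-scale defaults.

    The genome is shrunk to 2 x 20 Mb so the full 1000-set resampling null
    runs in seconds; densities (genes, peaks per Mb) are kept comparable to
    a mammalian genome's gene-rich regions.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000}
    )
    n_genes: int = 1000
    min_tss_spacing: int = 5_000
    n_peaks: int = 5000
    peak_width_median: float = 400.0
    peak_width_log_sd: float = 0.5
    promoter_peak_fraction: float = 0.3
    promoter_peak_sd: float = 2_000.0
    n_diff_peaks: int = 300  # split evenly HA / LA
    linkage_distance: int = 50_000
    linkage_prob: float = 0.6
    background_de_rate: float = 0.02
    n_enhancers: int = 500
    enhancer_width: int = 1_000
    n_superenhancers: int = 30
    superenhancer_width_range: tuple[int, int] = (10_000, 50_000)
    n_tf_sites: int = 2_000
    tf_site_width: int = 200
    conditions: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "kd": 1.5}
    )
    nb_dispersion: float = 0.2
    depth_per_bp: float = 0.5
    n_replicates: int = 2
    n_artifact_regions: int = 3
    artifact_depth_multiplier: float = 100.0
    artifact_width: int = 2_000
    bivalent_fraction: float = 0.18
    bivalent_de_fraction: float = 0.29
    condition_peak_presence: float = 0.9
    noiseless: bool = False

    def __post_init__(self) -> None:
        for name in ("linkage_prob", "background_de_rate", "bivalent_fraction",
                     "bivalent_de_fraction", "condition_peak_presence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_genes", "n_peaks", "n_diff_peaks", "n_enhancers",
                     "n_superenhancers", "n_tf_sites", "n_artifact_regions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.linkage_distance >= max(self.chrom_lengths.values()):
            raise ValueError("linkage_distance must be below the longest chromosome")
        if len(self.conditions) < 2:
            raise ValueError("need at least two conditions")
        if any(s <= 0 for s in self.conditions.values()):
            raise ValueError("condition scales must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "superenhancer_width_range" in d:
            d["superenhancer_width_range"] = tuple(d["superenhancer_width_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SyntheticBundle:
    """In-memory bundle of every generated input plus the truth manifest."""

    config: SimulationConfig
    chrom_sizes: ChromSizes
    genes: pd.DataFrame
    peak_stats: pd.DataFrame  # master universe incl. artifacts
    peaks_by_condition: dict[str, pd.DataFrame]
    enhancers: pd.DataFrame
    superenhancers: pd.DataFrame
    tf_sites: pd.DataFrame
    tracks: dict[str, pd.DataFrame]
    manifest: dict

    def write(self, out_dir) -> dict[str, str]:
        """Write every file in its plain-text pipeline format; returns the
        path of each artifact by name."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}

        p = out / "chrom.sizes"
        with open(p, "w") as fh:
            for chrom, length in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{length}\n")
        paths["chrom_sizes"] = str(p)

        p = out / "genes.tsv"
        write_table(self.genes, p)
        paths["genes"] = str(p)

        p = out / "peak_stats.tsv"
        write_table(self.peak_stats, p)
        paths["peak_stats"] = str(p)

        for cond, peaks in self.peaks_by_condition.items():
            p = out / f"peaks_{cond}.bed"
            write_bed(peaks, p)
            paths[f"peaks_{cond}"] = str(p)

        for name, df in (
            ("enhancers", self.enhancers),
            ("superenhancers", self.superenhancers),
            ("tf_sites", self.tf_sites),
        ):
            p = out / f"{name}.bed"
            write_bed(df, p)
            paths[name] = str(p)

        for cond, track in self.tracks.items():
            p = out / f"signal_{cond}.bedGraph"
            track.to_csv(p, sep="\t", header=False, index=False, float_format="%.6g")
            paths[f"signal_{cond}"] = str(p)

        p = out / "manifest.json"
        with open(p, "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        paths["manifest"] = str(p)

        p = out / "config.yaml"
        cfg = asdict(self.config)
        cfg["superenhancer_width_range"] = list(cfg["superenhancer_width_range"])
        with open(p, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        paths["config"] = str(p)
        return paths


# ---------------------------------------------------------------------------


def _allocate_per_chrom(n: int, lengths: dict[str, int]) -> dict[str, int]:
    """Split n items across chromosomes proportionally to length (largest-
    remainder rounding; deterministic)."""
    total = sum(lengths.values())
    raw = {c: n * length / total for c, length in lengths.items()}
    alloc = {c: int(v) for c, v in raw.items()}
    short = n - sum(alloc.values())
    for c in sorted(raw, key=lambda c: raw[c] - alloc[c], reverse=True)[:short]:
        alloc[c] += 1
    return alloc


def _spaced_positions(rng, n: int, length: int, spacing: int) -> np.ndarray:
    """n sorted positions in [0, length) with pairwise gaps >= spacing."""
    slack = length - n * spacing
    if slack <= 0:
        raise ValueError("spacing x count exceeds chromosome length")
    base = np.sort(rng.integers(0, slack, size=n))
    return base + np.arange(n, dtype=np.int64) * spacing


def _nb_group_mean(rng, mean: np.ndarray, dispersion: float, n_replicates: int) -> np.ndarray:
    """Mean of n_replicates negative-binomial draws, each with
    var = mu + dispersion * mu^2 (a group mean, not a single library)."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    draws = rng.negative_binomial(r, p, size=(n_replicates, len(mean)))
    return draws.mean(axis=0)


def simulate(config: SimulationConfig, out_dir=None) -> SyntheticBundle:
    """Generate a full synthetic bundle (optionally writing it to disk)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sizes = ChromSizes(cfg.chrom_lengths)
    chroms = list(cfg.chrom_lengths)

    # --- genes -------------------------------------------------------------
    alloc = _allocate_per_chrom(cfg.n_genes, cfg.chrom_lengths)
    gene_rows = []
    for chrom in chroms:
        tss = _spaced_positions(rng, alloc[chrom], cfg.chrom_lengths[chrom], cfg.min_tss_spacing)
        strands = rng.choice(["+", "-"], size=alloc[chrom])
        gene_rows.append(pd.DataFrame({"chrom": chrom, "tss": tss, "strand": strands}))
    genes = pd.concat(gene_rows, ignore_index=True)
    genes.insert(0, "gene_id", [f"g{i:05d}" for i in range(len(genes))])

    # --- peak universe -----------------------------------------------------
    n_candidates = int(cfg.n_peaks * 1.4) + 50
    widths = np.round(
        np.exp(rng.normal(np.log(cfg.peak_width_median), cfg.peak_width_log_sd, n_candidates))
    ).astype(np.int64)
    widths = np.maximum(widths, 50)
    is_promoter = rng.random(n_candidates) < cfg.promoter_peak_fraction
    gene_pick = rng.integers(0, len(genes), size=n_candidates)
    offsets = np.round(rng.normal(0.0, cfg.promoter_peak_sd, n_candidates)).astype(np.int64)
    chrom_lengths_arr = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=np.int64)
    chrom_idx = rng.choice(
        len(chroms), size=n_candidates, p=chrom_lengths_arr / chrom_lengths_arr.sum()
    )
    centers = np.empty(n_candidates, dtype=np.int64)
    peak_chrom = np.empty(n_candidates, dtype=object)
    uni = rng.random(n_candidates)
    for i in range(n_candidates):
        if is_promoter[i]:
            g = genes.iloc[gene_pick[i]]
            peak_chrom[i] = g["chrom"]
            centers[i] = g["tss"] + offsets[i]
        else:
            peak_chrom[i] = chroms[chrom_idx[i]]
            centers[i] = int(uni[i] * cfg.chrom_lengths[peak_chrom[i]])
    starts = centers - widths // 2
    ends = starts + widths
    for ci, chrom in enumerate(chroms):
        mask = peak_chrom == chrom
        L = cfg.chrom_lengths[chrom]
        shift = np.maximum(-starts[mask], 0) - np.maximum(ends[mask] - L, 0)
        starts[mask] += shift
        ends[mask] += shift
    cand = pd.DataFrame({"chrom": peak_chrom, "start": starts, "end": ends})
    cand = cand.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    # greedy thinning so the universe is non-overlapping (as merged peak
    # calls would be)
    keep = np.zeros(len(cand), dtype=bool)
    last_end: dict[str, int] = {}
    for i, (chrom, s, e) in enumerate(zip(cand["chrom"], cand["start"], cand["end"])):
        if s >= last_end.get(chrom, -1):
            keep[i] = True
            last_end[chrom] = e
    cand = cand[keep].reset_index(drop=True)
    if len(cand) < cfg.n_peaks:
        raise ValueError("could not place the requested number of non-overlapping peaks")
    drop = rng.choice(len(cand), size=len(cand) - cfg.n_peaks, replace=False)
    peaks = cand.drop(index=drop).reset_index(drop=True)

    # --- differential labels and planted linkage ---------------------------
    n_diff = cfg.n_diff_peaks
    diff_idx = rng.choice(cfg.n_peaks, size=n_diff, replace=False)
    diff_label = np.array(["HA"] * (n_diff - n_diff // 2) + ["LA"] * (n_diff // 2))
    rng.shuffle(diff_label)
    peak_label = np.full(cfg.n_peaks, "unchanged", dtype=object)
    peak_label[diff_idx] = diff_label

    de_label = np.full(len(genes), "unchanged", dtype=object)
    gene_tss_by_chrom = {
        c: (grp["tss"].to_numpy(), grp.index.to_numpy())
        for c, grp in genes.groupby("chrom", sort=False)
    }
    linked_pairs = []
    for pi_idx in np.sort(diff_idx):
        if rng.random() >= cfg.linkage_prob:
            continue
        chrom = peaks.at[pi_idx, "chrom"]
        mid = (peaks.at[pi_idx, "start"] + peaks.at[pi_idx, "end"]) // 2
        want = "up" if peak_label[pi_idx] == "HA" else "down"
        tss_arr, gidx = gene_tss_by_chrom[chrom]
        near = np.abs(tss_arr - mid) <= cfg.linkage_distance
        ok = near & ((de_label[gidx] == "unchanged") | (de_label[gidx] == want))
        cand_g = gidx[ok]
        if len(cand_g) == 0:
            continue
        g = int(rng.choice(cand_g))
        de_label[g] = want
        linked_pairs.append(
            {
                "peak_chrom": str(chrom),
                "peak_start": int(peaks.at[pi_idx, "start"]),
                "peak_end": int(peaks.at[pi_idx, "end"]),
                "peak_label": str(peak_label[pi_idx]),
                "gene_id": str(genes.at[g, "gene_id"]),
                "distance": int(abs(int(genes.at[g, "tss"]) - mid)),
            }
        )
    background = np.flatnonzero(de_label == "unchanged")
    bg_mask = rng.random(len(background)) < cfg.background_de_rate
    bg_dir = rng.choice(["up", "down"], size=int(bg_mask.sum()))
    de_label[background[bg_mask]] = bg_dir
    genes["de_label"] = de_label

    # --- chromatin classes -------------------------------------------------
    base_rest = np.array([0.50, 0.07, 0.25])  # k4_only, k27_only, neither
    classes = np.empty(len(genes), dtype=object)
    is_de = de_label != "unchanged"
    for mask, p_biv in ((~is_de, cfg.bivalent_fraction), (is_de, cfg.bivalent_de_fraction)):
        n = int(mask.sum())
        probs = np.concatenate([[p_biv], base_rest / base_rest.sum() * (1 - p_biv)])
        classes[mask] = rng.choice(
            ["bivalent", "k4_only", "k27_only", "neither"], size=n, p=probs
        )
    genes["chromatin_class"] = classes

    # --- counts, q, fold change --------------------------------------------
    conds = list(cfg.conditions)
    scales = np.array([cfg.conditions[c] for c in conds])
    width_arr = (peaks["end"] - peaks["start"]).to_numpy(dtype=np.int64)
    base_mu = cfg.depth_per_bp * width_arr
    group_means = np.empty((cfg.n_peaks, len(conds)))
    for j, s in enumerate(scales):
        mu = base_mu * s
        group_means[:, j] = (
            mu if cfg.noiseless
            else _nb_group_mean(rng, mu, cfg.nb_dispersion, cfg.n_replicates)
        )
    is_ha = peak_label == "HA"
    is_la = peak_label == "LA"
    q_value = np.empty(cfg.n_peaks)
    q_value[is_ha | is_la] = 10.0 ** rng.uniform(-8.0, -2.2, int((is_ha | is_la).sum()))
    q_value[~(is_ha | is_la)] = rng.uniform(0.2, 1.0, int((~(is_ha | is_la)).sum()))
    fc = np.empty(cfg.n_peaks)
    magnitude = 2.0 * (1.0 + rng.exponential(0.6, cfg.n_peaks))
    null_ratio = 2.0 ** rng.normal(0.0, 0.2, cfg.n_peaks)
    fc[is_ha] = magnitude[is_ha]
    fc[is_la] = -magnitude[is_la]
    neutral = ~(is_ha | is_la)
    fc[neutral] = np.where(
        null_ratio[neutral] >= 1.0, null_ratio[neutral], -1.0 / null_ratio[neutral]
    )
    depth = group_means.sum(axis=1) * cfg.n_replicates

    peak_stats = peaks.copy()
    peak_stats["depth"] = depth
    for j, c in enumerate(conds):
        peak_stats[f"group_mean_{c}"] = group_means[:, j]
    peak_stats["q_value"] = q_value
    peak_stats["fold_change"] = fc
    peak_stats["diff_label"] = peak_label

    # --- artifact regions ---------------------------------------------------
    artifact_rows = []
    art_depth_base = depth.max() if cfg.n_peaks else 100.0
    for _ in range(cfg.n_artifact_regions):
        chrom = chroms[int(rng.integers(len(chroms)))]
        L = cfg.chrom_lengths[chrom]
        s = int(rng.integers(0, L - cfg.artifact_width))
        row = {"chrom": chrom, "start": s, "end": s + cfg.artifact_width}
        d = art_depth_base * cfg.artifact_depth_multiplier * (1.0 + rng.random())
        row["depth"] = d
        for c in conds:
            row[f"group_mean_{c}"] = d / (len(conds) * cfg.n_replicates)
        row["q_value"] = 1.0
        row["fold_change"] = 1.0
        row["diff_label"] = "artifact"
        artifact_rows.append(row)
    if artifact_rows:
        peak_stats = pd.concat(
            [peak_stats, pd.DataFrame(artifact_rows)], ignore_index=True
        )
        peak_stats = peak_stats.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)

    # --- per-condition peak files -------------------------------------------
    peaks_by_condition = {}
    regular = peak_stats[peak_stats["diff_label"] != "artifact"]
    artifacts = peak_stats[peak_stats["diff_label"] == "artifact"]
    for c in conds:
        present = rng.random(len(regular)) < cfg.condition_peak_presence
        sub = pd.concat(
            [regular[present][["chrom", "start", "end"]], artifacts[["chrom", "start", "end"]]],
            ignore_index=True,
        )
        peaks_by_condition[c] = sub.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)

    # --- feature sets -------------------------------------------------------
    def _uniform_features(n, width):
        rows = []
        idx = rng.choice(len(chroms), size=n, p=chrom_lengths_arr / chrom_lengths_arr.sum())
        for i in range(n):
            chrom = chroms[idx[i]]
            s = int(rng.integers(0, cfg.chrom_lengths[chrom] - width))
            rows.append({"chrom": chrom, "start": s, "end": s + width})
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    enhancers = _uniform_features(cfg.n_enhancers, cfg.enhancer_width)
    tf_sites = _uniform_features(cfg.n_tf_sites, cfg.tf_site_width)
    se_rows = []
    for _ in range(cfg.n_superenhancers):
        g = genes.iloc[int(rng.integers(len(genes)))]
        w = int(rng.integers(*cfg.superenhancer_width_range))
        L = cfg.chrom_lengths[g["chrom"]]
        s = max(0, min(int(g["tss"]) - w // 2, L - w))
        se_rows.append({"chrom": g["chrom"], "start": s, "end": s + w})
    superenhancers = (
        pd.DataFrame(se_rows, columns=["chrom", "start", "end"])
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )

    # --- signal tracks ------------------------------------------------------
    tracks = {}
    for c in conds:
        per_base = peak_stats[f"group_mean_{c}"].to_numpy() / (
            peak_stats["end"] - peak_stats["start"]
        ).to_numpy()
        tr = peak_stats[["chrom", "start", "end"]].copy()
        tr["value"] = per_base
        tracks[c] = tr[tr["value"] > 0].reset_index(drop=True)

    # --- manifest -----------------------------------------------------------
    manifest = {
        "seed": cfg.seed,
        "conditions": {c: float(cfg.conditions[c]) for c in conds},
        "noiseless": cfg.noiseless,
        "n_genes": int(len(genes)),
        "n_peaks": int(cfg.n_peaks),
        "de_counts": {
            lab: int((genes["de_label"] == lab).sum()) for lab in ("up", "down", "unchanged")
        },
        "diff_peaks": [
            {
                "chrom": str(r.chrom),
                "start": int(r.start),
                "end": int(r.end),
                "label": str(r.diff_label),
            }
            for r in peak_stats[peak_stats["diff_label"].isin(["HA", "LA"])].itertuples()
        ],
        "linked_pairs": linked_pairs,
        "artifact_regions": [
            {"chrom": str(r.chrom), "start": int(r.start), "end": int(r.end)}
            for r in artifacts.itertuples()
        ],
        "thresholds": {"q_max": 0.01, "fc_min": 2.0},
    }

    bundle = SyntheticBundle(
        config=cfg,
        chrom_sizes=sizes,
        genes=genes[["gene_id", "chrom", "strand", "tss", "de_label", "chromatin_class"]],
        peak_stats=peak_stats,
        peaks_by_condition=peaks_by_condition,
        enhancers=enhancers,
        superenhancers=superenhancers,
        tf_sites=tf_sites,
        tracks=tracks,
        manifest=manifest,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


# ---------------------------------------------------------------------------


def truth_check(bundle: SyntheticBundle) -> dict[str, bool]:
    """Verify the bundle is internally consistent with its truth manifest.

    Returns a named-check -> pass mapping (key "all" aggregates). Checks:
    chromosome references, differential peaks recoverable from the stats
    table by thresholding alone, artifact regions being the depth outliers,
    DE-label counts, and (in noiseless mode) exact recovery of the planted
    condition scales by median equalization.
    """
    from .peaks import DifferentialCallConfig, call_differential
    from .signal import median_equalization_factors

    checks: dict[str, bool] = {}
    sizes = bundle.chrom_sizes
    frames = [bundle.peak_stats, bundle.enhancers, bundle.superenhancers, bundle.tf_sites]
    frames += list(bundle.peaks_by_condition.values()) + list(bundle.tracks.values())
    ok = all(set(df["chrom"]) <= set(sizes) for df in frames)
    ok = ok and set(bundle.genes["chrom"]) <= set(sizes)
    checks["chromosomes_consistent"] = bool(ok)

    th = bundle.manifest["thresholds"]
    calls = call_differential(
        bundle.peak_stats, DifferentialCallConfig(q_max=th["q_max"], fc_min=th["fc_min"])
    )
    called = {
        (r.chrom, r.start, r.end, lab)
        for lab, df in (("HA", calls.ha), ("LA", calls.la))
        for r in df.itertuples()
    }
    planted = {
        (d["chrom"], d["start"], d["end"], d["label"]) for d in bundle.manifest["diff_peaks"]
    }
    checks["differential_peaks_match_thresholds"] = called == planted

    stats = bundle.peak_stats
    n_art = len(bundle.manifest["artifact_regions"])
    top = stats.nlargest(n_art, "depth")[["chrom", "start", "end"]]
    top_set = {tuple(r) for r in top.itertuples(index=False)}
    art_set = {
        (a["chrom"], a["start"], a["end"]) for a in bundle.manifest["artifact_regions"]
    }
    checks["artifacts_are_depth_outliers"] = top_set == art_set

    tallies = bundle.genes["de_label"].value_counts().to_dict()
    checks["de_counts_match"] = all(
        bundle.manifest["de_counts"][lab] == int(tallies.get(lab, 0))
        for lab in ("up", "down", "unchanged")
    )

    if bundle.config.noiseless:
        conds = list(bundle.config.conditions)
        regular = stats[stats["diff_label"] != "artifact"]
        mat = regular[[f"group_mean_{c}" for c in conds]].copy()
        mat.columns = conds
        sf = median_equalization_factors(mat)
        s = np.array([bundle.config.conditions[c] for c in conds])
        f = np.array([sf[c] for c in conds])
        prod = f * s  # factors undo planted scales up to one common constant
        checks["noiseless_scale_recovery"] = bool(
            np.allclose(prod, prod[0], rtol=1e-9, atol=0.0)
        )

    checks["all"] = all(checks.values())
    return checks
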