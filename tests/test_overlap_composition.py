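"""Region-overlap enrichment, TSS-window enrichment, and gene-set composition."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from peakladder import (
    closest_gene_composition,
    geneset_composition,
    region_overlap_enrichment,
    tss_window_enrichment,
)

from conftest import brute_force_overlap_any, random_intervals


def _df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestRegionOverlap:
    def test_no_overlap_gives_p_one(self):
        universe = _df([("chr1", i * 100, i * 100 + 50) for i in range(10)])
        features = _df([("chr2", 0, 1_000)])
        res = region_overlap_enrichment(universe.iloc[:3], features, universe)
        assert res.counts.q == 0 and res.p_value == 1.0

    def test_maximal_configuration(self):
        # universe of 10; 4 overlap the feature; diff set is exactly those 4:
        # the only favourable draw among C(10,4) = 210
        universe = _df([("chr1", i * 1_000, i * 1_000 + 100) for i in range(10)])
        features = _df([("chr1", 0, 3_150)])  # covers peaks 0..3
        diff = universe.iloc[:4]
        res = region_overlap_enrichment(diff, features, universe)
        assert (res.counts.q, res.counts.m, res.counts.n, res.counts.k) == (4, 4, 6, 4)
        assert res.p_value == pytest.approx(1 / 210, rel=1e-12)

    def test_diff_peak_outside_universe_rejected(self):
        universe = _df([("chr1", 0, 100), ("chr1", 200, 300)])
        rogue = _df([("chr1", 500, 600)])
        with pytest.raises(ValueError, match="absent from universe"):
            region_overlap_enrichment(rogue, universe, universe)

    def test_feature_centric_reports_features_hit(self):
        universe = _df([("chr1", 0, 100), ("chr1", 200, 300), ("chr1", 400, 500)])
        features = _df([("chr1", 50, 250), ("chr1", 1_000, 1_100)])
        res = region_overlap_enrichment(
            universe.iloc[:2], features, universe, counting_mode="feature_centric"
        )
        assert res.features_hit == 1 and res.n_features == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_p_matches_exhaustive_subset_enumeration(self, seed):
        """For k <= 6, P equals the fraction of all C(n_universe, k) diff-set
        choices with at least the observed number of feature overlaps."""
        rng = np.random.default_rng(seed)
        universe = random_intervals(rng, 12, domain=5_000).sort_values(
            ["chrom", "start"]).reset_index(drop=True)
        features = random_intervals(rng, 6, domain=5_000)
        k = int(rng.integers(2, 7))
        diff_idx = rng.choice(12, k, replace=False)
        diff = universe.iloc[diff_idx]
        res = region_overlap_enrichment(diff, features, universe)
        hit = brute_force_overlap_any(universe, features)
        observed_q = int(hit[diff_idx].sum())
        assert res.counts.q == observed_q
        favourable = sum(
            1 for combo in itertools.combinations(range(12), k)
            if int(hit[list(combo)].sum()) >= observed_q
        )
        assert res.p_value == pytest.approx(
            favourable / math.comb(12, k), rel=1e-10
        )


class TestTssWindow:
    def test_empty_features(self, toy_genes):
        res = tss_window_enrichment(_df([]), toy_genes, "up", window=2_500)
        assert res.counts.q == 0 and res.counts.m == 0 and res.p_value == 1.0

    def test_every_window_hit_is_certain(self, toy_genes):
        features = _df([("chr1", 0, 100_000)])
        res = tss_window_enrichment(features, toy_genes, "up", window=2_500)
        assert res.counts.q == res.counts.k == 2
        assert res.p_value == 1.0

    def test_window_is_symmetric_and_closed(self, toy_genes, toy_sizes):
        # a 1 bp feature exactly `window` downstream of the 10k TSS still hits
        features = _df([("chr1", 12_500, 12_501)])
        res = tss_window_enrichment(features, toy_genes, "up", window=2_500,
                                    sizes=toy_sizes)
        assert res.counts.m == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_per_gene_scan_and_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "chrom": rng.choice(["chr1", "chr2"], n),
                "strand": rng.choice(["+", "-"], n),
                "tss": rng.integers(0, 50_000, n),
                "de_label": rng.choice(["up", "unchanged"], n, p=[0.3, 0.7]),
                "chromatin_class": None,
            }
        )
        features = random_intervals(rng, 15, domain=50_000, chroms=("chr1", "chr2"))
        res = tss_window_enrichment(features, genes, "up", window=2_500)
        windows = pd.DataFrame(
            {
                "chrom": genes["chrom"],
                "start": np.maximum(genes["tss"] - 2_500, 0),
                "end": genes["tss"] + 2_501,
            }
        )
        hit = brute_force_overlap_any(windows, features)
        lab = (genes["de_label"] == "up").to_numpy()
        assert (res.counts.m, res.counts.k, res.counts.q) == (
            int(hit.sum()), int(lab.sum()), int((hit & lab).sum())
        )
        # enumeration oracle on the counts
        m, k, q = res.counts.m, res.counts.k, res.counts.q
        favourable = sum(
            math.comb(m, x) * math.comb(n - m, k - x)
            for x in range(q, min(m, k) + 1) if k - x <= n - m
        )
        assert res.p_value == pytest.approx(favourable / math.comb(n, k), rel=1e-10)


class TestComposition:
    def test_all_bivalent(self, toy_genes):
        res = geneset_composition(["g0", "g2"], toy_genes)
        assert res.fractions["bivalent"] == 1.0
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_classes_reported_not_dropped(self, toy_genes):
        res = geneset_composition(["g0"], toy_genes)
        assert res.counts["k27_only"] == 0
        assert "k27_only" in res.fractions

    def test_unclassified_bucket(self, toy_genes):
        res = geneset_composition(["g4"], toy_genes)
        assert res.fractions["unclassified"] == 1.0

    def test_unknown_gene_named(self, toy_genes):
        with pytest.raises(KeyError, match="gZZZ"):
            geneset_composition(["g0", "gZZZ"], toy_genes)

    def test_empty_list_rejected(self, toy_genes):
        with pytest.raises(ValueError):
            geneset_composition([], toy_genes)

    def test_fractions_match_tally_oracle(self):
        rng = np.random.default_rng(3)
        n = 200
        classes = rng.choice(
            ["bivalent", "k4_only", "k27_only", "neither", None], n
        )
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "chrom": "chr1",
                "strand": "+",
                "tss": np.arange(n) * 100,
                "de_label": "unchanged",
                "chromatin_class": classes,
            }
        )
        ids = [f"g{i}" for i in rng.choice(n, 80, replace=False)]
        res = geneset_composition(ids, genes)
        lookup = dict(zip(genes["gene_id"], classes))
        for cls in ("bivalent", "k4_only", "k27_only", "neither"):
            expected = sum(1 for g in ids if lookup[g] == cls)
            assert res.counts[cls] == expected
        assert res.counts["unclassified"] == sum(1 for g in ids if lookup[g] is None)
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-12)


class TestClosestGeneComposition:
    def test_one_peak_per_gene_recovers_full_composition(self, toy_genes):
        peaks = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": toy_genes["tss"] - 100,
                "end": toy_genes["tss"] + 100,
            }
        )
        res = closest_gene_composition(peaks, toy_genes)
        assert res.n == len(toy_genes)
        assert res.counts["bivalent"] == 2

    def test_two_peaks_one_gene_deduplicated(self, toy_genes):
        peaks = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [49_800, 50_050], "end": [49_900, 50_200]}
        )
        res = closest_gene_composition(peaks, toy_genes)
        assert res.n == 1

    def test_matches_nearest_plus_tally_oracle(self, toy_genes):
        rng = np.random.default_rng(17)
        peaks = random_intervals(rng, 30, domain=99_000)
        res = closest_gene_composition(peaks, toy_genes)
        chosen = set()
        for row in peaks.itertuples():
            dists = np.maximum.reduce(
                [row.start - toy_genes["tss"],
                 toy_genes["tss"] - (row.end - 1),
                 np.zeros(len(toy_genes), dtype=np.int64)]
            )
            best = dists.min()
            chosen.add(sorted(toy_genes.loc[dists == best, "gene_id"])[0])
        assert res.n == len(chosen)
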