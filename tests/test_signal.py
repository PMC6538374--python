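"""Median-equalization factors, region counts, metaprofiles."""

import numpy as np
import pandas as pd
import pytest

from peakladder import (
    apply_factors,
    median_equalization_factors,
    metaplot,
    region_matrix,
    region_read_counts,
)


def _matrix(rng, n_regions=20, conditions=("a", "b", "c")):
    base = rng.gamma(4.0, 25.0, n_regions)
    return pd.DataFrame({c: base * (i + 1) for i, c in enumerate(conditions)})


class TestMedianEqualization:
    def test_doubled_condition_gets_half_the_factor(self):
        rng = np.random.default_rng(0)
        base = rng.gamma(4.0, 25.0, 20)
        mat = pd.DataFrame({"A": base, "B": 2 * base})
        sf = median_equalization_factors(mat)
        assert sf["B"] / sf["A"] == pytest.approx(0.5, rel=1e-12)

    def test_identical_conditions_equal_factors(self):
        rng = np.random.default_rng(1)
        base = rng.gamma(4.0, 25.0, 20)
        mat = pd.DataFrame({"A": base, "B": base, "C": base})
        sf = median_equalization_factors(mat)
        assert len({round(v, 12) for v in sf.factors.values()}) == 1

    def test_step_by_step_oracle(self):
        """Independent spreadsheet-style recomputation of steps (1)-(4)."""
        rng = np.random.default_rng(2)
        mat = _matrix(rng)
        sf = median_equalization_factors(mat)
        means = mat.to_numpy().mean(axis=1)                     # (1)
        retained = mat.to_numpy()[means > np.median(means)]     # (2)
        medians = np.median(retained, axis=0)
        reference = float(np.exp(np.mean(np.log(medians))))     # (3)
        for j, c in enumerate(mat.columns):                     # (4)
            assert sf[c] == pytest.approx(reference / medians[j], rel=1e-12)
        assert sf.n_retained == int((means > np.median(means)).sum())

    def test_applying_factors_equalizes_retained_medians(self):
        rng = np.random.default_rng(3)
        mat = _matrix(rng, n_regions=101)
        sf = median_equalization_factors(mat)
        scaled = apply_factors(mat, sf)
        means = mat.to_numpy().mean(axis=1)
        retained = scaled[means > np.median(means)]
        meds = retained.median(axis=0).to_numpy()
        np.testing.assert_allclose(meds, meds[0], rtol=1e-9)

    def test_rescaling_neutrality(self):
        """Scaling one condition's raw counts by s changes its factor by 1/s."""
        rng = np.random.default_rng(4)
        mat = _matrix(rng, n_regions=50)
        sf0 = median_equalization_factors(mat)
        for s in (0.25, 3.0):
            mat2 = mat.copy()
            mat2["b"] = mat2["b"] * s
            sf1 = median_equalization_factors(mat2)
            # common reference shifts too, so compare the b:a ratio
            assert (sf1["b"] / sf1["a"]) == pytest.approx(
                (sf0["b"] / sf0["a"]) / s, rel=1e-9
            )

    def test_too_few_regions_or_conditions_rejected(self):
        with pytest.raises(ValueError):
            median_equalization_factors(pd.DataFrame({"a": [1.0, 2, 3, 4]}))
        with pytest.raises(ValueError):
            median_equalization_factors(
                pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
            )

    def test_zero_median_condition_rejected(self):
        mat = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [0.0, 0, 0, 0, 0]})
        with pytest.raises(ValueError, match="zero median"):
            median_equalization_factors(mat)


def _track(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


class TestRegionReadCounts:
    def test_constant_track_arithmetic(self):
        track = _track([("chr1", 0, 1_000, 2.5)])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [300]})
        out = region_read_counts(track, regions, factor=3.0)
        assert out[0] == pytest.approx(2.5 * 200 * 3.0)

    def test_uncovered_region_is_zero(self):
        track = _track([("chr1", 0, 100, 1.0)])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [600]})
        assert region_read_counts(track, regions)[0] == 0.0

    def test_missing_chromosome_warns_not_errors(self):
        track = _track([("chr1", 0, 100, 1.0)])
        regions = pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [10]})
        with pytest.warns(UserWarning, match="chrX"):
            out = region_read_counts(track, regions)
        assert out[0] == 0.0

    def test_matches_per_base_summation_oracle(self):
        rng = np.random.default_rng(5)
        domain = 5_000
        starts = np.sort(rng.choice(domain - 10, 30, replace=False))
        ends = np.minimum(starts + rng.integers(1, 120, 30), domain)
        keep = np.concatenate([[True], starts[1:] >= ends[:-1]])  # disjoint
        track = pd.DataFrame(
            {"chrom": "chr1", "start": starts[keep], "end": ends[keep],
             "value": rng.gamma(2.0, 1.0, int(keep.sum()))}
        )
        per_base = np.zeros(domain)
        for s, e, v in zip(track["start"], track["end"], track["value"]):
            per_base[s:e] = v
        region_starts = rng.integers(0, domain - 500, 10)
        regions = pd.DataFrame(
            {"chrom": "chr1", "start": region_starts,
             "end": region_starts + rng.integers(100, 500, 10)}
        )
        out = region_read_counts(track, regions)
        for i, (s, e) in enumerate(zip(regions["start"], regions["end"])):
            assert out[i] == pytest.approx(per_base[s:e].sum(), rel=1e-12)

    def test_additive_over_partition(self):
        track = _track([("chr1", 0, 400, 1.0), ("chr1", 400, 900, 0.5)])
        whole = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [800]})
        parts = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [100, 450], "end": [450, 800]}
        )
        assert region_read_counts(track, whole)[0] == pytest.approx(
            region_read_counts(track, parts).sum(), rel=1e-12
        )


class TestMetaplot:
    def test_constant_signal_flat_profile(self):
        track = _track([("chr1", 0, 10_000, 4.0)])
        regions = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [0, 1_000, 4_000],
             "end": [500, 1_700, 4_900]}
        )
        prof = metaplot(track, regions, n_bins=10, factor=0.5)
        np.testing.assert_allclose(prof.values, 4.0 * 0.5)

    def test_identity_binning_recovers_per_base_signal(self):
        values = [1.0, 3.0, 5.0, 2.0, 8.0]
        track = _track([("chr1", i, i + 1, v) for i, v in enumerate(values)])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [5]})
        prof = metaplot(track, regions, n_bins=5)
        np.testing.assert_allclose(prof.values, values)

    def test_minus_strand_region_reversed(self):
        values = [1.0, 3.0, 5.0, 2.0, 8.0]
        track = _track([("chr1", i, i + 1, v) for i, v in enumerate(values)])
        regions = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [5], "strand": ["-"]}
        )
        prof = metaplot(track, regions, n_bins=5)
        np.testing.assert_allclose(prof.values, values[::-1])

    def test_symmetric_signal_invariant_under_strand_flip(self):
        rng = np.random.default_rng(6)
        half = rng.gamma(2.0, 1.0, 50)
        sym = np.concatenate([half, half[::-1]])
        track = _track([("chr1", i, i + 1, v) for i, v in enumerate(sym)])
        plus = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [100], "strand": ["+"]}
        )
        minus = plus.assign(strand="-")
        np.testing.assert_allclose(
            metaplot(track, plus, 10).values, metaplot(track, minus, 10).values
        )

    def test_remainder_bases_go_left(self):
        # length 7 into 3 bins -> sizes (3, 2, 2)
        track = _track([("chr1", 0, 3, 1.0), ("chr1", 3, 7, 0.0)])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [7]})
        prof = metaplot(track, regions, n_bins=3)
        np.testing.assert_allclose(prof.values, [1.0, 0.0, 0.0])

    def test_matches_per_base_binning_oracle(self):
        rng = np.random.default_rng(7)
        domain = 2_000
        per_base = rng.gamma(2.0, 1.0, domain)
        track = _track(
            [("chr1", i, i + 1, v) for i, v in enumerate(per_base)]
        )
        regions = pd.DataFrame(
            {"chrom": ["chr1"] * 5,
             "start": [0, 100, 333, 700, 1_200],
             "end": [97, 301, 633, 1_100, 1_999]}
        )
        n_bins = 7
        prof = metaplot(track, regions, n_bins)
        acc = np.zeros(n_bins)
        for s, e in zip(regions["start"], regions["end"]):
            length = e - s
            base, rem = divmod(length, n_bins)
            sizes = [base + 1] * rem + [base] * (n_bins - rem)
            pos = s
            for b, size in enumerate(sizes):
                acc[b] += per_base[pos:pos + size].mean()
                pos += size
        np.testing.assert_allclose(prof.values, acc / 5, rtol=1e-12)

    def test_region_shorter_than_bins_rejected(self):
        track = _track([("chr1", 0, 100, 1.0)])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [5]})
        with pytest.raises(ValueError):
            metaplot(track, regions, n_bins=10)


class TestRegionMatrix:
    def test_single_cell_consistency(self):
        track = _track([("chr1", 0, 1_000, 2.0)])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500]})
        mat = region_matrix({"c1": track}, regions, factors={"c1": 1.5})
        expected = region_read_counts(track, regions, 1.5)[0]
        assert mat.loc["chr1:0-500", "c1"] == pytest.approx(expected)

    def test_row_order_follows_region_order(self):
        track = _track([("chr1", 0, 1_000, 1.0)])
        regions = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [500, 0], "end": [600, 100]}
        )
        mat = region_matrix({"c": track}, regions)
        assert list(mat.index) == ["chr1:500-600", "chr1:0-100"]

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(8)
        tracks = {}
        for cond in ("x", "y"):
            starts = np.arange(0, 4_000, 200)
            tracks[cond] = pd.DataFrame(
                {"chrom": "chr1", "start": starts, "end": starts + 200,
                 "value": rng.gamma(2.0, 1.0, len(starts))}
            )
        starts = rng.integers(0, 3_000, 8)
        regions = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + rng.integers(50, 800, 8)}
        )
        factors = {"x": 1.3, "y": 0.7}
        mat = region_matrix(tracks, regions, factors)
        for cond in tracks:
            np.testing.assert_allclose(
                mat[cond].to_numpy(),
                region_read_counts(tracks[cond], regions, factors[cond]),
            )
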