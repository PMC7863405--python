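import numpy as np
import pandas as pd
import pytest

from spikewin.genomic_io import ChromSizes, GenomicInterval
from spikewin.window_counting import (
    apply_blacklist,
    count_fragments,
    estimate_background,
    filter_by_background,
    tile_windows,
)

from conftest import brute_force_counts, random_fragments


class TestTiling:
    def test_window_enumeration(self):
        cs = ChromSizes(sizes={"c": 400})
        grid = tile_windows(cs, width=150, step=50)
        wins = grid.windows_for("c")
        assert len(wins) == 6
        assert wins[0] == GenomicInterval("c", 0, 150)
        assert wins[-1] == GenomicInterval("c", 250, 400)

    def test_boundary_lengths(self):
        assert tile_windows(ChromSizes(sizes={"c": 150})).n_windows["c"] == 1
        with pytest.warns(UserWarning):
            grid = tile_windows(ChromSizes(sizes={"c": 149}))
        assert grid.n_windows["c"] == 0

    def test_spike_contigs_not_tiled(self, small_sizes):
        grid = tile_windows(small_sizes)
        assert set(grid.n_windows) == {"chr1", "chr2"}
        spikes = grid.spike_windows()
        assert {iv.chrom for iv in spikes} == {"lambda", "phiX"}
        assert all(iv.start == 0 and iv.end == small_sizes[iv.chrom] for iv in spikes)

    def test_spike_tiling(self, small_sizes):
        grid = tile_windows(small_sizes, spike_tile=5000)
        lam = [iv for iv in grid.spike_windows() if iv.chrom == "lambda"]
        assert len(lam) == 10  # ceil(48502 / 5000)
        assert lam[-1].end == 48_502


class TestCounting:
    def test_single_fragment_two_windows(self):
        cs = ChromSizes(sizes={"c": 400})
        grid = tile_windows(cs)
        frags = {"s": pd.DataFrame({"chrom": ["c"], "start": [10], "end": [60]})}
        cm = count_fragments(frags, grid, max_fragment=800)
        # [10,60) overlaps [0,150) and [50,200) only
        assert cm.counts[:, 0].tolist() == [1, 1, 0, 0, 0, 0]

    def test_max_fragment_discards(self):
        cs = ChromSizes(sizes={"c": 2000})
        grid = tile_windows(cs)
        frags = {"s": pd.DataFrame({"chrom": ["c", "c"], "start": [0, 0], "end": [801, 800]})}
        cm = count_fragments(frags, grid, max_fragment=800)
        # only the 800 bp fragment counts
        assert cm.counts[0, 0] == 1

    def test_matches_brute_force_oracle(self, rng):
        cs = ChromSizes(sizes={"c": 10_000})
        grid = tile_windows(cs)
        wins = grid.windows_for("c")
        for _ in range(5):
            frags = random_fragments(rng, "c", 10_000, 500)
            cm = count_fragments({"s": frags}, grid, max_fragment=300)
            oracle = brute_force_counts(frags, wins, max_fragment=300)
            np.testing.assert_array_equal(cm.counts[:, 0], oracle)


class TestBackground:
    def test_uniform_rate(self):
        cs = ChromSizes(sizes={"c": 100_000})
        # 1 fragment per 100 bp, deterministic placement
        starts = np.arange(0, 100_000, 100)
        frags = {"s": pd.DataFrame({"chrom": "c", "start": starts, "end": starts + 50})}
        bg = estimate_background(frags, cs, bin_width=1000)
        assert bg.global_rate[0] == pytest.approx(0.01)

    def test_median_robust_to_peak(self, rng):
        cs = ChromSizes(sizes={"c": 100_000})
        starts = np.arange(0, 100_000, 100)
        peak = np.full(5000, 500)  # huge pile-up in one bin
        frags = {
            "s": pd.DataFrame(
                {
                    "chrom": "c",
                    "start": np.concatenate([starts, peak]),
                    "end": np.concatenate([starts + 50, peak + 50]),
                }
            )
        }
        bg = estimate_background(frags, cs, bin_width=1000)
        assert bg.global_rate[0] == pytest.approx(0.01)

    def test_empty_sample_warns_rate_zero(self):
        cs = ChromSizes(sizes={"c": 10_000})
        frags = {"s": pd.DataFrame(columns=["chrom", "start", "end"])}
        with pytest.warns(UserWarning):
            bg = estimate_background(frags, cs, bin_width=1000)
        assert bg.global_rate[0] == 0.0

    def test_blacklisted_bins_excluded(self):
        cs = ChromSizes(sizes={"c": 10_000})
        starts = np.arange(0, 1000, 10)  # everything in the first bin
        frags = {"s": pd.DataFrame({"chrom": "c", "start": starts, "end": starts + 50})}
        bl = [GenomicInterval("c", 0, 1000)]
        bg = estimate_background(frags, cs, bin_width=1000, blacklist=bl)
        assert bg.global_rate[0] == 0.0
        with pytest.raises(ValueError):
            estimate_background(frags, cs, bin_width=1000,
                                blacklist=[GenomicInterval("c", 0, 10_000)])


class TestRetentionFilter:
    def _matrix(self, counts_per_window, width=150):
        n = len(counts_per_window)
        from spikewin.window_counting import CountMatrix

        return CountMatrix(
            chroms=np.repeat("c", n).astype(object),
            starts=np.arange(n) * width,
            ends=np.arange(n) * width + width,
            samples=["s"],
            counts=np.asarray(counts_per_window, dtype=np.int64)[:, None],
            is_spike=np.zeros(n, dtype=bool),
        )

    def _bg(self, rate):
        from spikewin.window_counting import BackgroundEstimate

        return BackgroundEstimate(
            bin_width=1000, samples=["s"], global_rate=np.array([rate]),
            bin_chroms=np.array(["c"]), bin_starts=np.array([0]),
            bin_rates=np.array([[rate]]),
        )

    def test_strictly_greater_boundary(self):
        # window rate exactly 3x background -> dropped; above -> kept
        bg = self._bg(30 / (3 * 150.0))  # threshold count = 30 per window
        cm = self._matrix([30, 31, 29])
        rf = filter_by_background(cm, bg, min_fold=3)
        assert rf.retained.tolist() == [False, True, False]
        assert rf.n_input == 3 and rf.n_retained == 1

    def test_all_zero_matrix(self):
        rf = filter_by_background(self._matrix([0, 0]), self._bg(0.01))
        assert rf.n_retained == 0

    def test_monotone_in_min_fold(self, rng):
        counts = rng.integers(0, 200, size=40)
        cm = self._matrix(counts)
        bg = self._bg(0.05)
        prev = filter_by_background(cm, bg, min_fold=1).retained
        for fold in (2, 3, 5, 8):
            cur = filter_by_background(cm, bg, min_fold=fold).retained
            assert not np.any(cur & ~prev)  # raising fold never adds windows
            prev = cur

    def test_min_fold_must_be_positive(self):
        with pytest.raises(ValueError):
            filter_by_background(self._matrix([1]), self._bg(0.01), min_fold=0)


class TestBlacklist:
    def test_overlap_enumeration(self):
        cs = ChromSizes(sizes={"c": 400})
        grid = tile_windows(cs)
        cm = count_fragments({"s": pd.DataFrame(columns=["chrom", "start", "end"])}, grid, 800)
        filtered, n_removed = apply_blacklist(cm, [GenomicInterval("c", 100, 200)])
        # windows [0,150),[50,200),[100,250),[150,300) overlap -> 2 remain
        assert n_removed == 4
        assert filtered.n_rows == 2
        assert filtered.starts.tolist() == [200, 250]

    def test_empty_blacklist_is_identity(self):
        cs = ChromSizes(sizes={"c": 400})
        grid = tile_windows(cs)
        cm = count_fragments({"s": pd.DataFrame(columns=["chrom", "start", "end"])}, grid, 800)
        same, n = apply_blacklist(cm, [])
        assert n == 0 and same.n_rows == cm.n_rows

    def test_whole_contig_blacklist_warns(self):
        cs = ChromSizes(sizes={"c": 400})
        grid = tile_windows(cs)
        cm = count_fragments({"s": pd.DataFrame(columns=["chrom", "start", "end"])}, grid, 800)
        with pytest.warns(UserWarning):
            filtered, _ = apply_blacklist(cm, [GenomicInterval("c", 0, 400)])
        assert filtered.n_rows == 0
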