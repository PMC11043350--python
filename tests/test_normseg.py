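"""Normalization arithmetic, CBS and DP segmentation against brute-force
oracles, and level merging."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scnapipe import normseg
from scnapipe.normseg import (CBSConfig, JointSegConfig, MergeConfig,
                              RatioProfile, merge_levels, normalize,
                              segment_cbs, segment_joint)


from _oracles import brute_force_best_arc, brute_force_partition


def _dp_objective(X, segs_list, gamma):
    X = np.atleast_2d(X)
    obj = 0.0
    n_cuts = len(segs_list[0]) - 1
    for c, segs in enumerate(segs_list):
        for _, s in segs.iterrows():
            seg = X[c, int(s.start_bin):int(s.end_bin) + 1]
            obj += ((seg - seg.mean()) ** 2).sum()
    return obj + gamma * n_cuts


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalize:
    def _bins(self, gc):
        gc = np.asarray(gc, dtype=float)
        return pd.DataFrame({"chrom": "chr1",
                             "start": np.arange(len(gc)) * 10,
                             "end": (np.arange(len(gc)) + 1) * 10,
                             "gc": gc, "mappability": 1.0})

    def test_constant_counts_constant_gc_all_zero(self):
        bins = self._bins(np.full(50, 0.4))
        prof = normalize(np.full(50, 100), bins)
        np.testing.assert_allclose(prof.log2, 0.0, atol=1e-12)
        assert prof.gc_corrected

    def test_ratio_arithmetic(self):
        # counts [20,10,10]: ratios relative to the mean are [1.5,0.75,0.75]
        bins = self._bins([0.4, 0.4, 0.4])
        prof = normalize(np.array([20, 10, 10]), bins, gc_correct=False)
        mean = 40 / 3
        eps = 1 / (2 * mean)
        np.testing.assert_allclose(
            prof.log2, np.log2(np.array([1.5, 0.75, 0.75]) + eps))

    def test_linear_gc_trend_removed(self, rng):
        # counts exactly proportional to a linear function of GC collapse to
        # a constant after LOWESS correction
        n = 1000
        gc = rng.uniform(0.3, 0.6, size=n)
        counts = 1000 * (1 + 2 * (gc - 0.45))
        prof = normalize(counts, self._bins(gc))
        inner = (gc > 0.32) & (gc < 0.58)  # away from boundary effects
        assert prof.log2[inner].std() < 1e-2

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty cell"):
            normalize(np.zeros(10), self._bins(np.full(10, 0.4)))


# ---------------------------------------------------------------------------
# CBS
# ---------------------------------------------------------------------------

class TestCBS:
    def test_flat_profile_single_segment(self):
        prof = RatioProfile(log2=np.zeros(100),
                            chrom=np.repeat(["chr1", "chr2"], 50))
        seg = segment_cbs(prof, CBSConfig(seed=0))
        assert len(seg) == 2  # one per chromosome
        assert (seg["n_bins"] == 50).all()

    def test_clean_step_breakpoint_at_50(self, rng):
        x = np.concatenate([rng.normal(0, 0.1, 50), rng.normal(-1, 0.1, 50)])
        prof = RatioProfile(log2=x, chrom=np.full(100, "chr1"))
        seg = segment_cbs(prof, CBSConfig(seed=1))
        assert len(seg) == 2
        assert seg.iloc[0]["end_bin"] == 49 and seg.iloc[1]["start_bin"] == 50

    def test_tiny_step_not_split(self, rng):
        # step of 0.01 in noise sigma=0.5 is far below the permutation null
        x = np.concatenate([rng.normal(0, 0.5, 50), rng.normal(-0.01, 0.5, 50)])
        prof = RatioProfile(log2=x, chrom=np.full(100, "chr1"))
        seg = segment_cbs(prof, CBSConfig(seed=2))
        assert len(seg) == 1

    def test_segment_means_are_bin_means(self, rng):
        x = np.concatenate([rng.normal(0, 0.1, 40), rng.normal(1, 0.1, 60)])
        prof = RatioProfile(log2=x, chrom=np.full(100, "chr1"))
        seg = segment_cbs(prof, CBSConfig(seed=3))
        for _, s in seg.iterrows():
            np.testing.assert_allclose(
                s["mean"], x[int(s.start_bin):int(s.end_bin) + 1].mean(),
                atol=1e-12)

    def test_reproducible_under_seed(self, rng):
        x = rng.normal(0, 0.3, 120) + np.repeat([0, 0.6, 0], 40)
        prof = RatioProfile(log2=x, chrom=np.full(120, "chr1"))
        a = segment_cbs(prof, CBSConfig(seed=42))
        b = segment_cbs(prof, CBSConfig(seed=42))
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("n", [20, 60, 200])
    def test_first_split_matches_exhaustive_scan(self, n, rng):
        x = rng.normal(size=n) + np.where(np.arange(n) < n // 3, 0.8, 0.0)
        i, j, t = normseg._arc_t_max(x)
        oi, oj, ot = brute_force_best_arc(x)
        assert (i, j) == (oi, oj)
        assert t == pytest.approx(ot, rel=1e-10)


# ---------------------------------------------------------------------------
# joint / DP segmentation
# ---------------------------------------------------------------------------

class TestJointSegmentation:
    def test_huge_gamma_no_breakpoints(self, rng):
        X = rng.normal(size=(5, 40)) + np.tile(np.repeat([0, 2], 20), (5, 1))
        segs = segment_joint(X, np.full(40, "chr1"), JointSegConfig(gamma=1e9))
        assert all(len(s) == 1 for s in segs)

    def test_shared_breakpoint_recovered(self, rng):
        X = rng.normal(0, 0.2, size=(20, 100))
        X[:, 50:] += 1.0
        segs = segment_joint(X, np.full(100, "chr1"), JointSegConfig(gamma=40))
        assert len(segs[0]) == 2
        assert segs[0].iloc[1]["start_bin"] == 50
        # all cells share breakpoints, means are cell-specific
        for s in segs[1:]:
            np.testing.assert_array_equal(s["start_bin"], segs[0]["start_bin"])
        assert segs[3].iloc[1]["mean"] == pytest.approx(X[3, 50:].mean())

    def test_single_cell_equals_single_sample_partitioning(self, rng):
        x = rng.normal(size=16) + np.repeat([0, 1.5], 8)
        gamma = 2.0
        segs = segment_joint(x[None, :], np.full(16, "chr1"),
                             JointSegConfig(gamma=gamma))
        obj = _dp_objective(x[None, :], segs, gamma)
        best_obj, _ = brute_force_partition(x, gamma)
        assert obj == pytest.approx(best_obj, abs=1e-9)

    @pytest.mark.parametrize("n,cells,gamma", [
        (8, 1, 0.5), (12, 3, 2.0), (14, 2, 5.0), (20, 2, 3.0)])
    def test_dp_matches_exhaustive_partition_search(self, n, cells, gamma, rng):
        X = rng.normal(size=(cells, n)) + np.repeat(
            rng.integers(-1, 2, size=(cells, -(-n // 5))), 5, axis=1)[:, :n]
        segs = segment_joint(X, np.full(n, "chr1"), JointSegConfig(gamma=gamma))
        obj = _dp_objective(X, segs, gamma)
        best_obj, _ = brute_force_partition(X, gamma)
        assert obj == pytest.approx(best_obj, abs=1e-9)

    def test_breakpoint_count_monotone_in_gamma(self, rng):
        x = rng.normal(0, 0.3, size=60) + np.repeat([0, 1, 0], 20)
        n_breaks = []
        for gamma in (0.1, 1.0, 10.0, 100.0, 1e5):
            segs = segment_joint(x[None, :], np.full(60, "chr1"),
                                 JointSegConfig(gamma=gamma))
            n_breaks.append(len(segs[0]) - 1)
        assert n_breaks == sorted(n_breaks, reverse=True)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            JointSegConfig(gamma=-1)


# ---------------------------------------------------------------------------
# merge levels
# ---------------------------------------------------------------------------

class TestMergeLevels:
    def _segs(self, chrom, cuts, values):
        rows = []
        edges = [0] + cuts + [len(values)]
        for a, b in zip(edges[:-1], edges[1:]):
            rows.append((chrom, a, b - 1, b - a, values[a:b].mean()))
        return pd.DataFrame(rows, columns=normseg.SEGMENT_COLUMNS)

    def test_identical_adjacent_segments_merged(self):
        values = np.concatenate([np.full(10, 0.5), np.full(10, 0.5)])
        segs = self._segs("chr1", [10], values)
        out = merge_levels(segs, values)
        assert len(out) == 1
        assert out.iloc[0]["mean"] == pytest.approx(0.5)

    def test_clearly_distinct_segments_not_merged(self, rng):
        values = np.concatenate([rng.normal(0, 0.05, 30),
                                 rng.normal(-1, 0.05, 30)])
        segs = self._segs("chr1", [30], values)
        # direct rank-sum computation confirms p << 0.01
        p = stats.mannwhitneyu(values[:30], values[30:],
                               alternative="two-sided").pvalue
        assert p < 1e-10
        out = merge_levels(segs, values)
        assert len(out) == 2

    def test_single_segment_unchanged(self, rng):
        values = rng.normal(size=20)
        segs = self._segs("chr1", [], values)
        out = merge_levels(segs, values)
        pd.testing.assert_frame_equal(out, segs)

    def test_never_increases_count_and_idempotent(self, rng):
        values = rng.normal(0, 0.4, size=80)
        segs = self._segs("chr1", [10, 30, 35, 60], values)
        out1 = merge_levels(segs, values)
        assert len(out1) <= len(segs)
        out2 = merge_levels(out1, values)
        pd.testing.assert_frame_equal(out1, out2)

    def test_does_not_merge_across_chromosomes(self):
        values = np.concatenate([np.full(10, 0.1), np.full(10, 0.1)])
        segs = pd.DataFrame(
            [("chr1", 0, 9, 10, 0.1), ("chr2", 10, 19, 10, 0.1)],
            columns=normseg.SEGMENT_COLUMNS)
        out = merge_levels(segs, values)
        assert len(out) == 2
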