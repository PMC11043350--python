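"""Karyotype classes, event distance vs BFS oracle, trees and clone
clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from scnapipe import clonal
from scnapipe.clonal import (CloneConfig, KaryotypeConfig, altered_fraction,
                             annotate_genes, build_tree, classify_karyotype,
                             clone_profile, cluster_clones, distance_matrix,
                             event_distance)


from _oracles import bfs_all_event_distances, bfs_event_distance


def _bins_frame(chrom, length=500_000):
    n = len(chrom)
    return pd.DataFrame({"chrom": chrom,
                         "start": np.arange(n) * length,
                         "end": (np.arange(n) + 1) * length,
                         "gc": 0.4, "mappability": 1.0})


class TestKaryotype:
    def test_unaltered_male_cell(self):
        chrom = ["chr1"] * 10 + ["chrX"] * 2
        cn = np.array([2] * 10 + [1] * 2)
        assert altered_fraction(cn, _bins_frame(chrom), "male") == 0.0
        assert classify_karyotype(0.0) == "diploid"

    def test_male_x_gain_counts_by_length(self):
        # chrX at CN 2 in a male: altered fraction = X share of the genome
        chrom = ["chr1"] * 19 + ["chrX"]
        cn = np.array([2] * 19 + [2])
        assert altered_fraction(cn, _bins_frame(chrom), "male") == pytest.approx(0.05)

    def test_fraction_equals_brute_force_sum(self, rng):
        chrom = np.repeat([f"chr{i}" for i in range(5)] + ["chrX"], 20)
        bins = _bins_frame(chrom)
        for _ in range(10):
            cn = rng.integers(0, 5, size=len(chrom))
            expect = np.where(np.isin(chrom, ["chrX"]), 1, 2)
            manual = sum(
                5e5 for c, e in zip(cn, expect) if c != e) / (len(chrom) * 5e5)
            assert altered_fraction(cn, bins, "male") == pytest.approx(manual)

    @pytest.mark.parametrize("fraction,expected", [
        (0.0, "diploid"), (0.10, "pseudo-diploid"), (0.25, "pseudo-diploid"),
        (0.30, "aneuploid"), (1.0, "aneuploid")])
    def test_thresholds(self, fraction, expected):
        assert classify_karyotype(fraction) == expected

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError):
            KaryotypeConfig(sex="unknown")


class TestEventDistance:
    def test_single_bin_deletion(self):
        assert event_distance([2, 2, 2], [2, 1, 2]) == 1

    def test_two_events_example(self):
        # one full-width deletion plus one single-bin deletion
        assert event_distance([2, 2, 2, 2], [1, 1, 2, 1]) == 2
        assert bfs_event_distance([2, 2, 2, 2], [1, 1, 2, 1]) == 2

    def test_zero_unrecoverable(self):
        assert event_distance([2, 0, 2], [2, 1, 2]) == math.inf

    def test_identity_and_symmetry(self, rng):
        for _ in range(20):
            a = rng.integers(1, 5, size=6)
            b = rng.integers(1, 5, size=6)
            assert event_distance(a, a) == 0
            assert event_distance(a, b) == event_distance(b, a)

    def test_matches_bfs_exhaustively_small(self):
        # exhaustive over all ordered pairs of 3-bin profiles with CN <= 3:
        # one BFS per source reaches every target at once
        states = list(itertools.product(range(4), repeat=3))
        for a in states:
            reach = bfs_all_event_distances(a, cn_cap=6)
            for b in states:
                d = event_distance(a, b)
                o = reach.get(b, math.inf)
                assert d == o, (a, b, d, o)

    def test_matches_bfs_random_four_bins(self, rng):
        # randomized 4-bin instances with CN <= 4 (cap leaves headroom)
        for _ in range(40):
            a = rng.integers(0, 5, size=4)
            b = rng.integers(0, 5, size=4)
            d = event_distance(a, b)
            o = bfs_event_distance(a, b, cn_cap=7)
            assert d == o, (a, b, d, o)

    def test_triangle_inequality_spot_check(self, rng):
        for _ in range(50):
            a, b, c = (rng.integers(1, 5, size=5) for _ in range(3))
            assert (event_distance(a, c)
                    <= event_distance(a, b) + event_distance(b, c) + 1e-9)

    def test_per_chromosome_additivity(self):
        chrom = np.array(["chr1"] * 3 + ["chr2"] * 3)
        a = [2, 2, 2, 2, 2, 2]
        b = [1, 1, 2, 2, 3, 3]
        assert event_distance(a, b, chrom) == 2
        # without the chromosome boundary the events could not merge anyway
        assert event_distance(a, b) == 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            event_distance([2, 2], [2, 2, 2])


class TestTree:
    def test_three_leaf_additivity(self):
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = build_tree(D, ["a", "b", "c"])
        tips = {t.name: t for t in tree.tips()}
        for x, y, expected in [("a", "b", 4), ("a", "c", 6), ("b", "c", 8)]:
            assert tips[x].distance(tips[y]) == pytest.approx(expected)

    def test_identical_cells_zero_cherry(self):
        D = np.array([[0, 0, 5, 5], [0, 0, 5, 5],
                      [5, 5, 0, 2], [5, 5, 2, 0]], dtype=float)
        tree = build_tree(D, list("abcd"))
        tips = {t.name: t for t in tree.tips()}
        assert tips["a"].distance(tips["b"]) == pytest.approx(0.0)

    def test_trivial_tree_warning(self):
        with pytest.warns(UserWarning):
            tree = build_tree(np.array([[0.0, 3.0], [3.0, 0.0]]), ["a", "b"])
        assert {t.name for t in tree.tips()} == {"a", "b"}

    def test_clones_are_monophyletic(self, rng):
        # two clones separated by >= 10 events, within-clone <= 1
        base = np.full(30, 2)
        cl1 = base.copy(); cl1[2:12] = 1
        cl2 = base.copy(); cl2[15:28] = 3; cl2[0:2] = 1
        cells, labels = [], []
        for k, proto in enumerate((cl1, cl2)):
            for i in range(4):
                v = proto.copy()
                if i % 2:
                    v[29] = 3  # one private event
                cells.append(v)
                labels.append(k)
        D = distance_matrix(np.array(cells))
        tree = build_tree(D, [f"c{i}" for i in range(len(cells))])
        tips = {t.name: t for t in tree.tips()}
        within, between = [], []
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                d = tips[f"c{i}"].distance(tips[f"c{j}"])
                (within if labels[i] == labels[j] else between).append(d)
        assert max(within) < min(between)


class TestClones:
    def test_all_zero_distances_single_clone(self):
        D = np.zeros((4, 4))
        labels = cluster_clones(D, list("abcd"), CloneConfig(t=3, min_clone_size=1))
        assert labels.nunique() == 1

    def test_two_blocks_two_clones(self):
        D = np.full((6, 6), 10.0)
        D[:3, :3] = 0; D[3:, 3:] = 0
        np.fill_diagonal(D, 0)
        labels = cluster_clones(D, [f"c{i}" for i in range(6)],
                                CloneConfig(t=3, min_clone_size=1))
        assert labels.nunique() == 2
        assert labels.iloc[:3].nunique() == 1 and labels.iloc[3:].nunique() == 1

    def test_max_distance_guarantee(self, rng):
        D = rng.uniform(0, 10, size=(20, 20))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        cfg = CloneConfig(t=4, min_clone_size=1)
        labels = cluster_clones(D, [f"c{i}" for i in range(20)], cfg)
        for lab in labels.unique():
            members = np.flatnonzero(labels.values == lab)
            if len(members) > 1:
                assert D[np.ix_(members, members)].max() <= 4

    def test_small_clusters_become_noise(self):
        D = np.full((7, 7), 10.0)
        D[:5, :5] = 0; D[5:, 5:] = 0
        np.fill_diagonal(D, 0)
        labels = cluster_clones(D, [f"c{i}" for i in range(7)],
                                CloneConfig(t=3, min_clone_size=5))
        assert (labels.iloc[:5] == 0).all()
        assert (labels.iloc[5:] == -1).all()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            CloneConfig(t=-1)


class TestCloneProfiles:
    def test_identical_cells_profile(self):
        cn = np.array([[2, 1, 2], [2, 1, 2], [2, 1, 2]])
        np.testing.assert_array_equal(clone_profile(cn), [2, 1, 2])

    def test_median_ties_round_down(self):
        cn = np.array([[2, 2], [3, 1]])
        np.testing.assert_array_equal(clone_profile(cn), [2, 1])

    def test_gene_annotation_rules(self):
        chrom = ["chr1"] * 10
        bins = _bins_frame(chrom, length=100)
        profile = np.array([2, 2, 1, 1, 1, 2, 3, 3, 2, 2])
        genes = pd.DataFrame({
            "gene": ["DEL1", "NEUT", "AMP1", "EDGE"],
            "chrom": "chr1",
            "start": [250, 50, 620, 450],
            "end": [350, 150, 780, 550],
            "role": "TSG"})
        ann = annotate_genes(profile, bins, genes).set_index("gene")
        assert ann.loc["DEL1", "status"] == "deleted"
        assert ann.loc["NEUT", "status"] == "neutral"
        assert ann.loc["AMP1", "status"] == "amplified"
        # straddles the CN 1|2 boundary -> neutral under the all-bins rule
        assert ann.loc["EDGE", "status"] == "neutral"

    def test_gene_outside_genome_skipped(self):
        bins = _bins_frame(["chr1"] * 4, length=100)
        genes = pd.DataFrame({"gene": ["GHOST"], "chrom": ["chr9"],
                              "start": [0], "end": [100], "role": ["TSG"]})
        with pytest.warns(UserWarning, match="GHOST"):
            ann = annotate_genes(np.full(4, 2), bins, genes)
        assert len(ann) == 0
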