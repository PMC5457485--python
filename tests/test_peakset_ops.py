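import numpy as np
import pandas as pd
import pytest

from cistrodiff.genomic_io import CutProfile, GenomicInterval
from cistrodiff.peakset_ops import (
    PeakSet,
    annotate_region_class,
    correlation_cluster,
    cut_tree_groups,
    nearest_gene,
    overlap_counts,
    sort_and_merge,
    tag_count_matrix,
)
from conftest import random_intervals

SPACE = 6000  # coordinate space for mask oracles


def mask_of(intervals, chrom):
    m = np.zeros(SPACE, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            m[iv.start : iv.end] = True
    return m


def mask_runs(mask):
    """Maximal True runs of a boolean mask as (start, end) pairs."""
    padded = np.concatenate(([False], mask, [False])).astype(int)
    d = np.diff(padded)
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


class TestSortAndMerge:
    def test_overlapping_merged(self):
        out = sort_and_merge(
            [GenomicInterval("c", 0, 10), GenomicInterval("c", 5, 15)]
        )
        assert [(iv.start, iv.end) for iv in out] == [(0, 15)]

    def test_book_ended_merged(self):
        out = sort_and_merge(
            [GenomicInterval("c", 0, 10), GenomicInterval("c", 10, 20)]
        )
        assert [(iv.start, iv.end) for iv in out] == [(0, 20)]

    def test_merge_matches_mask_oracle_and_is_idempotent(self):
        rng = np.random.default_rng(4)
        ivs = random_intervals(rng, 1000, n_chroms=2, max_pos=SPACE - 200)
        merged = sort_and_merge(ivs)
        for chrom in ("chr1", "chr2"):
            got = [
                (iv.start, iv.end) for iv in merged if iv.chrom == chrom
            ]
            assert got == mask_runs(mask_of(ivs, chrom))
        again = sort_and_merge(merged.intervals)
        assert again.intervals == merged.intervals


class TestOverlapCounts:
    def test_identical_sets(self):
        ivs = [GenomicInterval("c", 0, 10), GenomicInterval("c", 50, 60)]
        a, b = PeakSet("A", ivs), PeakSet("B", list(ivs))
        s = overlap_counts([a, b])
        assert s.region_counts == {frozenset({"A", "B"}): 2}
        assert s.pairwise_fraction[("A", "B")] == 1.0

    def test_disjoint_sets(self):
        a = PeakSet("A", [GenomicInterval("c", 0, 10)])
        b = PeakSet("B", [GenomicInterval("c", 50, 60)])
        s = overlap_counts([a, b])
        assert s.count("A") == 1 and s.count("B") == 1
        assert s.count("A", "B") == 0
        assert s.pairwise_fraction[("A", "B")] == 0.0

    def test_unsupported_arity(self):
        a = PeakSet("A", [GenomicInterval("c", 0, 10)])
        with pytest.raises(ValueError, match="2 or 3"):
            overlap_counts([a])

    @pytest.mark.parametrize("n_sets", [2, 3])
    def test_matches_mask_oracle(self, n_sets):
        rng = np.random.default_rng(5)
        sets = [
            sort_and_merge(
                random_intervals(rng, 120, n_chroms=2, max_pos=SPACE - 200),
                label=f"S{i}",
            )
            for i in range(n_sets)
        ]
        summary = overlap_counts(sets)
        # oracle: subset assignment on per-base masks
        expected: dict[frozenset, int] = {}
        for chrom in ("chr1", "chr2"):
            masks = {s.label: mask_of(s.intervals, chrom) for s in sets}
            union = np.logical_or.reduce(list(masks.values()))
            for start, end in mask_runs(union):
                members = frozenset(
                    lab for lab, m in masks.items() if m[start:end].any()
                )
                expected[members] = expected.get(members, 0) + 1
        assert summary.region_counts == expected
        # conservation
        assert sum(summary.region_counts.values()) == len(summary.union)
        # relabel symmetry
        relabeled = overlap_counts(list(reversed(sets)))
        assert relabeled.region_counts == summary.region_counts

    def test_pairwise_fraction_matches_brute_force(self):
        rng = np.random.default_rng(55)
        a = sort_and_merge(
            random_intervals(rng, 150, n_chroms=1, max_pos=SPACE - 200), "A"
        )
        b = sort_and_merge(
            random_intervals(rng, 150, n_chroms=1, max_pos=SPACE - 200), "B"
        )
        s = overlap_counts([a, b])
        mb = mask_of(b.intervals, "chr1")
        frac = np.mean([mb[iv.start : iv.end].any() for iv in a.intervals])
        assert s.pairwise_fraction[("A", "B")] == pytest.approx(frac)


class TestTagCountMatrix:
    def test_counts_and_half_open_boundary(self):
        union = PeakSet("u", [GenomicInterval("c", 10, 20)])
        prof = CutProfile.from_positions(
            {("c", "+"): [10, 15, 19], ("c", "-"): [20]}  # 20 is exclusive
        )
        m = tag_count_matrix(union, {"s": prof})
        assert m.counts.iloc[0, 0] == 3

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tag_count_matrix(PeakSet("u", []), {})

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        union = sort_and_merge(
            random_intervals(rng, 60, n_chroms=2, max_pos=SPACE - 200), "u"
        )
        pos = {
            ("chr1", "+"): rng.integers(0, SPACE, 800).tolist(),
            ("chr1", "-"): rng.integers(0, SPACE, 800).tolist(),
            ("chr2", "+"): rng.integers(0, SPACE, 800).tolist(),
        }
        prof = CutProfile.from_positions(pos)
        m = tag_count_matrix(union, {"s": prof})
        all_pos = {k: np.asarray(v) for k, v in pos.items()}
        for i, iv in enumerate(union.intervals):
            expected = sum(
                int(((p >= iv.start) & (p < iv.end)).sum())
                for (chrom, _), p in all_pos.items()
                if chrom == iv.chrom
            )
            assert m.counts.iloc[i, 0] == expected

    def test_normalization_scales_to_ten_million(self):
        union = PeakSet("u", [GenomicInterval("c", 0, 100)])
        prof = CutProfile.from_positions({("c", "+"): list(range(50))})
        m = tag_count_matrix(union, {"s": prof})
        assert m.normalized.iloc[0, 0] == pytest.approx(50 * 1e7 / 50)


class TestCorrelationCluster:
    @staticmethod
    def _matrix(columns: dict):
        union = PeakSet(
            "u",
            [GenomicInterval("c", i * 100, i * 100 + 50) for i in range(
                len(next(iter(columns.values()))))],
        )
        counts = pd.DataFrame(columns, index=[
            f"{iv.chrom}:{iv.start}-{iv.end}" for iv in union.intervals
        ])
        from cistrodiff.peakset_ops import SampleCountMatrix

        return SampleCountMatrix(union, counts, counts.astype(float))

    def test_duplicated_sample_merges_first_at_height_zero(self):
        m = self._matrix({"a": [1, 5, 9], "b": [1, 5, 9], "c": [9, 1, 2]})
        clust = correlation_cluster(m)
        assert clust.correlation.loc["a", "b"] == pytest.approx(1.0)
        assert clust.linkage[0, 2] == pytest.approx(0.0)

    def test_hand_computed_pearson_on_toy(self):
        m = self._matrix({"a": [0, 1, 3], "b": [3, 1, 0]})
        clust = correlation_cluster(m)
        x = np.log2(np.array([0, 1, 3]) + 1)
        y = np.log2(np.array([3, 1, 0]) + 1)
        r = np.corrcoef(x, y)[0, 1]
        assert clust.correlation.loc["a", "b"] == pytest.approx(r)

    def test_correlation_matrix_properties(self, default_fixture):
        from cistrodiff.peakset_ops import overlap_counts as oc

        fx = default_fixture
        union = oc([fx.peaksets["cond1"], fx.peaksets["cond2"]]).union
        m = tag_count_matrix(union, fx.profiles)
        clust = correlation_cluster(m)
        corr = clust.correlation.to_numpy()
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        assert (corr >= -1 - 1e-12).all() and (corr <= 1 + 1e-12).all()

    def test_planted_groups_form_top_level_clusters(self, default_fixture):
        """Replicates of each condition must pair up under 2-way tree cut."""
        from cistrodiff.peakset_ops import overlap_counts as oc

        fx = default_fixture
        union = oc([fx.peaksets["cond1"], fx.peaksets["cond2"]]).union
        m = tag_count_matrix(union, fx.profiles)
        clust = correlation_cluster(m)
        labels = sorted(m.samples)
        groups = cut_tree_groups(clust.linkage, labels, 2)
        assert groups["cond1_rep1"] == groups["cond1_rep2"]
        assert groups["cond2_rep1"] == groups["cond2_rep2"]
        assert groups["cond1_rep1"] != groups["cond2_rep1"]

    def test_zero_variance_sample_named_in_error(self):
        m = self._matrix({"flat": [2, 2, 2], "b": [1, 2, 3]})
        with pytest.raises(ValueError, match="flat"):
            correlation_cluster(m)


class TestAnnotation:
    TSS = [
        GenomicInterval("chr1", 1000, 1001, name="A", strand="+"),
        GenomicInterval("chr1", 3000, 3001, name="B", strand="-"),
    ]

    def test_peak_on_tss_is_promoter(self):
        peaks = [GenomicInterval("chr1", 950, 1050)]
        assert annotate_region_class(peaks, self.TSS) == ["promoter"]

    def test_far_peak_is_distal(self):
        peaks = [GenomicInterval("chr1", 500_000, 500_100)]
        assert annotate_region_class(peaks, self.TSS) == ["distal"]

    def test_gene_body_gives_intragenic(self):
        peaks = [GenomicInterval("chr1", 10_000, 10_100)]
        bodies = [GenomicInterval("chr1", 9_000, 12_000, name="A")]
        assert annotate_region_class(peaks, self.TSS, gene_bodies=bodies) == [
            "intragenic"
        ]

    def test_nearest_gene_distance_zero_and_strand_sign(self):
        peaks = [GenomicInterval("chr1", 950, 1052)]  # center 1001 -> near A
        (gene, dist), = nearest_gene(
            peaks, [GenomicInterval("chr1", 1001, 1002, name="A", strand="+")]
        )
        assert gene == "A" and dist == 0
        # downstream of a minus-strand TSS is a negative genomic offset
        (gene, dist), = nearest_gene(
            [GenomicInterval("chr1", 2000, 2100)],  # center 2050
            [GenomicInterval("chr1", 2000, 2001, name="B", strand="-")],
        )
        assert gene == "B" and dist == -50

    def test_equidistant_tie_breaks_lexicographically(self):
        tss = [
            GenomicInterval("chr1", 900, 901, name="B", strand="+"),
            GenomicInterval("chr1", 1100, 1101, name="A", strand="+"),
        ]
        (gene, _), = nearest_gene([GenomicInterval("chr1", 950, 1050)], tss)
        assert gene == "A"

    def test_absent_chromosome_gives_none(self):
        (gene, dist), = nearest_gene(
            [GenomicInterval("chr9", 0, 10)], self.TSS
        )
        assert gene == "none" and dist == float("inf")

    def test_nearest_gene_matches_exhaustive_scan(self):
        rng = np.random.default_rng(9)
        tss = [
            GenomicInterval(
                f"chr{rng.integers(1, 3)}", int(p), int(p) + 1,
                name=f"g{i}", strand=("+", "-")[int(rng.integers(0, 2))],
            )
            for i, p in enumerate(rng.integers(0, 100_000, 80))
        ]
        peaks = random_intervals(rng, 100, n_chroms=2, max_pos=99_000)
        got = nearest_gene(peaks, tss)
        for peak, (gene, dist) in zip(peaks, got):
            center = (peak.start + peak.end) // 2
            cands = [t for t in tss if t.chrom == peak.chrom]
            best = min(cands, key=lambda t: (abs(center - t.start), t.name))
            assert gene == best.name
            assert abs(dist) == abs(center - best.start)

    def test_region_class_matches_brute_force(self):
        rng = np.random.default_rng(8)
        tss = [
            GenomicInterval("chr1", int(p), int(p) + 1, name=f"g{i}", strand="+")
            for i, p in enumerate(rng.integers(0, 50_000, 40))
        ]
        peaks = random_intervals(rng, 200, n_chroms=1, max_pos=49_000)
        got = annotate_region_class(peaks, tss, promoter_halfwidth=1500)
        for peak, label in zip(peaks, got):
            center = (peak.start + peak.end) // 2
            near = min(abs(center - t.start) for t in tss)
            assert label == ("promoter" if near <= 1500 else "distal")
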