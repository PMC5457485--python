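import numpy as np
import pandas as pd
import pytest

from cistrodiff.differential import (
    average_profile,
    chip_target_genes,
    classify_dhs_groups,
    de_genes,
    motif_density_tracks,
    rank_by_fold_change,
    signal_heatmap_matrix,
    target_overlap_fraction,
)
from cistrodiff.genomic_io import CutProfile, GenomicInterval
from cistrodiff.motif_scan import MotifHit, MotifHitSet
from cistrodiff.peakset_ops import PeakSet


def union_of(n=10, width=100, spacing=5000, chrom="c"):
    return PeakSet(
        "u",
        [GenomicInterval(chrom, i * spacing, i * spacing + width) for i in range(n)],
    )


def profile_at(counts_per_region, union, jitter_rng=None):
    """One cut-stack of the given size at each region center."""
    pos = []
    for iv, n in zip(union.intervals, counts_per_region):
        pos.extend([iv.center] * int(n))
    return CutProfile.from_positions({(union.intervals[0].chrom, "+"): pos})


class TestRankByFoldChange:
    def test_identical_profiles_give_fold_one_coordinate_order(self):
        union = union_of()
        prof = profile_at([3] * 10, union)
        ranked = rank_by_fold_change(union, prof, prof)
        assert np.allclose(ranked.fold_change, 1.0)
        assert list(ranked.order) == list(range(10))

    def test_matches_independent_sort_oracle(self):
        rng = np.random.default_rng(19)
        union = union_of(40)
        a = profile_at(rng.integers(0, 50, 40), union)
        b = profile_at(rng.integers(0, 50, 40), union)
        ranked = rank_by_fold_change(union, a, b, pseudocount=1.0)
        na = ranked.counts_a
        nb = ranked.counts_b
        fold = (nb + 1) / (na + 1)
        keys = [(f, iv.chrom, iv.start) for f, iv in zip(fold, union.intervals)]
        expected = sorted(range(40), key=lambda i: keys[i])
        assert list(ranked.order) == expected

    def test_pseudocount_must_be_positive(self):
        union = union_of(2)
        prof = profile_at([1, 1], union)
        with pytest.raises(ValueError):
            rank_by_fold_change(union, prof, prof, pseudocount=0)


class TestSignalHeatmap:
    def test_center_stack_lands_in_central_bin(self):
        union = union_of(3)
        prof = profile_at([7, 7, 7], union)
        ranked = rank_by_fold_change(union, prof, prof)
        hm = signal_heatmap_matrix(ranked, prof, window_bp=2000, n_bins=200)
        assert hm.shape == (3, 200)
        assert (hm.to_numpy().argmax(axis=1) == 100).all()
        assert (hm.sum(axis=1) == 7).all()

    def test_empty_profile_gives_zero_matrix(self):
        union = union_of(3)
        prof = profile_at([1, 1, 1], union)
        empty = CutProfile.from_positions({})
        ranked = rank_by_fold_change(union, prof, prof)
        hm = signal_heatmap_matrix(ranked, empty)
        assert (hm.to_numpy() == 0).all()

    def test_row_sums_conserve_window_counts(self):
        rng = np.random.default_rng(20)
        union = union_of(15)
        prof = CutProfile.from_positions(
            {
                ("c", "+"): rng.integers(0, 15 * 5000, 4000).tolist(),
                ("c", "-"): rng.integers(0, 15 * 5000, 4000).tolist(),
            }
        )
        ranked = rank_by_fold_change(union, prof, prof)
        hm = signal_heatmap_matrix(ranked, prof, window_bp=1500, n_bins=120)
        for row_id, iv in zip(hm.index, ranked.ranked_regions()):
            direct = prof.counts_in(iv.chrom, iv.center - 1500, iv.center + 1500)
            assert hm.loc[row_id].sum() == direct


class TestAverageProfile:
    def test_single_peak_returns_its_own_window(self):
        rng = np.random.default_rng(21)
        peaks = [GenomicInterval("c", 5000, 5100)]
        prof = CutProfile.from_positions(
            {("c", "+"): rng.integers(3000, 7000, 500).tolist()}
        )
        track = average_profile(peaks, prof, window_bp=1000)
        center = peaks[0].center
        direct = prof.window_array("c", center - 1000, center + 1000)
        assert np.array_equal(track, direct)

    def test_translation_invariance(self):
        rng = np.random.default_rng(211)
        base_pos = rng.integers(2000, 8000, 600)
        peaks = [GenomicInterval("c", 4000, 4200), GenomicInterval("c", 6000, 6300)]
        prof = CutProfile.from_positions({("c", "+"): base_pos.tolist()})
        shifted = CutProfile.from_positions({("c", "+"): (base_pos + 1000).tolist()})
        peaks_shifted = [
            GenomicInterval("c", p.start + 1000, p.end + 1000) for p in peaks
        ]
        assert np.array_equal(
            average_profile(peaks, prof, 1500),
            average_profile(peaks_shifted, shifted, 1500),
        )

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(212)
        peaks = [
            GenomicInterval("c", int(s), int(s) + 80)
            for s in rng.integers(3000, 30_000, 12)
        ]
        prof = CutProfile.from_positions(
            {
                ("c", "+"): rng.integers(0, 35_000, 3000).tolist(),
                ("c", "-"): rng.integers(0, 35_000, 3000).tolist(),
            }
        )
        track = average_profile(peaks, prof, window_bp=500)
        acc = np.zeros(1000)
        for p in peaks:
            c = (p.start + p.end) // 2
            acc += prof.window_array("c", c - 500, c + 500)
        assert np.allclose(track, acc / len(peaks))

    def test_no_peaks_rejected(self):
        with pytest.raises(ValueError):
            average_profile([], CutProfile.from_positions({}), 100)


class TestMotifDensityTracks:
    def test_no_hits_gives_zero_matrix(self):
        union = union_of(5)
        prof = profile_at([1] * 5, union)
        ranked = rank_by_fold_change(union, prof, prof)
        out = motif_density_tracks(ranked, {"m": MotifHitSet("m", [])})
        assert (out["m"]["raw"].to_numpy() == 0).all()

    def test_smoothing_window_one_is_identity(self):
        union = union_of(6)
        prof = profile_at([1] * 6, union)
        ranked = rank_by_fold_change(union, prof, prof)
        hits = MotifHitSet.build(
            "m",
            [MotifHit("m", GenomicInterval("c", iv.center, iv.center + 6), "+", 1.0)
             for iv in union.intervals[:3]],
        )
        out = motif_density_tracks(ranked, {"m": hits}, row_smoothing=1)
        assert out["m"]["raw"].equals(out["m"]["smoothed"])

    def test_planted_quartile_concentration(self):
        """A motif present only in bottom-ranked regions concentrates the
        smoothed track there."""
        rng = np.random.default_rng(22)
        union = union_of(40)
        a = profile_at([10] * 40, union)
        b = profile_at(np.arange(1, 41), union)  # increasing fold with index
        ranked = rank_by_fold_change(union, a, b)
        top_quartile = ranked.ranked_regions()[30:]
        hits = MotifHitSet.build(
            "m",
            [MotifHit("m", GenomicInterval("c", iv.center, iv.center + 6), "+", 1.0)
             for iv in top_quartile],
        )
        out = motif_density_tracks(ranked, {"m": hits}, row_smoothing=5)
        sm = out["m"]["smoothed"].to_numpy().sum(axis=1)
        assert sm[30:].mean() > 4 * max(sm[:20].mean(), 1e-9)


class TestClassifyDhsGroups:
    def test_rule_examples(self):
        union = union_of(2)
        groups = classify_dhs_groups(
            union, np.array([10.0, 5.0]), np.array([1.0, 6.0]),
            fold_threshold=2.0, pseudocount=1.0,
        )
        assert list(groups.group) == ["lost", "shared"]

    def test_partition_and_label_swap_symmetry(self):
        rng = np.random.default_rng(23)
        union = union_of(200)
        ctrl = rng.integers(0, 40, 200).astype(float)
        kd = rng.integers(0, 40, 200).astype(float)
        g = classify_dhs_groups(union, ctrl, kd)
        assert set(g.group.unique()) <= {"lost", "shared", "gained"}
        assert len(g.group) == 200  # partition: one label per region
        swapped = classify_dhs_groups(union, kd, ctrl)
        remap = {"lost": "gained", "gained": "lost", "shared": "shared"}
        assert list(swapped.group) == [remap[x] for x in g.group]

    def test_threshold_must_exceed_one(self):
        union = union_of(2)
        with pytest.raises(ValueError):
            classify_dhs_groups(union, np.ones(2), np.ones(2), fold_threshold=1.0)

    def test_matches_direct_rule(self):
        rng = np.random.default_rng(231)
        union = union_of(100)
        ctrl = rng.uniform(0, 30, 100)
        kd = rng.uniform(0, 30, 100)
        g = classify_dhs_groups(union, ctrl, kd, 2.0, 1.0)
        for lab, c, k in zip(g.group, ctrl, kd):
            if (c + 1) / (k + 1) >= 2:
                assert lab == "lost"
            elif (k + 1) / (c + 1) >= 2:
                assert lab == "gained"
            else:
                assert lab == "shared"


def make_expr(values: dict, timepoints=("t1",)):
    """values: gene -> (ctrl FPKM, kd FPKM), constant across timepoints."""
    cols = {}
    for tp in timepoints:
        cols[f"ctrl_{tp}_r1"] = [v[0] for v in values.values()]
        cols[f"kd_{tp}_r1"] = [v[1] for v in values.values()]
    expr = pd.DataFrame(cols, index=list(values))
    cond = {tp: [f"kd_{tp}_r1"] for tp in timepoints}
    ctrl = {tp: [f"ctrl_{tp}_r1"] for tp in timepoints}
    return expr, cond, ctrl


class TestDeGenes:
    def test_boundary_fold_included(self):
        # (2 + 1) / (1 + 1) = 1.5 exactly: closed boundary
        expr, cond, ctrl = make_expr({"g_edge": (1.0, 2.0), "g_flat": (5.0, 5.0)})
        out = de_genes(expr, cond, ctrl, fold_threshold=1.5)
        assert out.genes == ["g_edge"]

    def test_constant_gene_excluded(self):
        expr, cond, ctrl = make_expr({"g": (7.0, 7.0)})
        assert de_genes(expr, cond, ctrl).genes == []

    def test_sub_threshold_responder_excluded(self):
        expr, cond, ctrl = make_expr({"g": (10.0, 12.0)})  # 1.18-fold
        assert de_genes(expr, cond, ctrl, 1.5).genes == []

    def test_missing_control_column_rejected(self):
        expr, cond, ctrl = make_expr({"g": (1.0, 2.0)})
        ctrl["t1"] = ["ctrl_t9_r1"]
        with pytest.raises(ValueError, match="missing"):
            de_genes(expr, cond, ctrl)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(24)
        genes = {f"g{i}": (float(rng.uniform(1, 20)), float(rng.uniform(1, 20)))
                 for i in range(100)}
        expr, cond, ctrl = make_expr(genes)
        sizes = [len(de_genes(expr, cond, ctrl, t).genes)
                 for t in (1.01, 1.2, 1.5, 2.0, 3.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_noiseless_planted_recovery_exact(self):
        from cistrodiff.synthetic_data import (
            SyntheticDesign, expression_column_map, simulate_expression,
        )

        design = SyntheticDesign(seed=24, noise_sd=0.0)
        expr, truth = simulate_expression(design)
        cond, ctrl = expression_column_map(design)
        out = de_genes(expr, cond, ctrl, 1.5)
        assert set(out.genes) == set(truth["up"]) | set(truth["down"])
        # directions recorded correctly at the final timepoint
        last = design.timepoints[-1]
        for g in truth["up"]:
            assert out.direction.loc[g, last] == "up"
        for g in truth["down"]:
            assert out.direction.loc[g, last] == "down"


class TestTargetOverlap:
    TSS = [
        GenomicInterval("c", 10_000, 10_001, name="gA", strand="+"),
        GenomicInterval("c", 500_000, 500_001, name="gB", strand="+"),
    ]

    def test_promoter_peaks_give_fraction_one(self):
        peaks = [GenomicInterval("c", 9_900, 10_100)]
        out = target_overlap_fraction(["gA"], peaks, self.TSS)
        assert out.fraction == 1.0 and out.n_de_targets == 1

    def test_no_peaks_gives_zero(self):
        out = target_overlap_fraction(["gA"], [], self.TSS)
        assert out.fraction == 0.0

    def test_empty_de_set_undefined(self):
        out = target_overlap_fraction([], [GenomicInterval("c", 0, 10)], self.TSS)
        assert out.undefined

    def test_assignment_window_enforced(self):
        peaks = [GenomicInterval("c", 100_000, 100_200)]  # 90 kb from gA
        out = target_overlap_fraction(["gA"], peaks, self.TSS, assignment_window=50_000)
        assert out.fraction == 0.0

    def test_matches_brute_force_assignment(self):
        rng = np.random.default_rng(25)
        tss = [
            GenomicInterval("c", int(p), int(p) + 1, name=f"g{i}", strand="+")
            for i, p in enumerate(np.sort(rng.choice(1_000_000, 50, replace=False)))
        ]
        peaks = [
            GenomicInterval("c", int(s), int(s) + 200)
            for s in rng.integers(0, 1_000_000, 120)
        ]
        window = 50_000
        got = chip_target_genes(peaks, tss, window)
        expected = set()
        for p in peaks:
            center = (p.start + p.end) // 2
            best = min(tss, key=lambda t: (abs(center - t.start), t.name))
            if abs(center - best.start) <= window:
                expected.add(best.name)
        assert got == expected
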