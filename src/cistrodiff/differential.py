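"""Ranked fold-change comparisons, signal/motif density matrices, and
knockdown-response analysis: DHS change-group classification, differential
expression filtering, and ChIP-target overlap fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .genomic_io import CutProfile, GenomicInterval
from .motif_scan import MotifHitSet
from .peakset_ops import PeakSet, region_ids, TAGS_PER


@dataclass
class RankedComparison:
    """Union regions ordered by normalized tag-count fold change (b over a)."""

    regions: PeakSet
    counts_a: np.ndarray  # normalized tags per region
    counts_b: np.ndarray
    fold_change: np.ndarray
    order: np.ndarray  # permutation: ascending fold change

    def ranked_regions(self) -> list[GenomicInterval]:
        return [self.regions.intervals[i] for i in self.order]


def _normalized_counts(union: PeakSet, profile: CutProfile) -> np.ndarray:
    counts = np.array(
        [profile.counts_in(iv.chrom, iv.start, iv.end) for iv in union.intervals],
        dtype=float,
    )
    if profile.total_cuts > 0:
        counts *= TAGS_PER / profile.total_cuts
    return counts


def rank_by_fold_change(
    union: PeakSet,
    profile_a: CutProfile,
    profile_b: CutProfile,
    pseudocount: float = 1.0,
) -> RankedComparison:
    """Rank union regions by (b + pc) / (a + pc) on library-normalized tags.

    Ascending order; ties resolve by (chrom, start) so the ranking is a
    deterministic function of the inputs.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    a = _normalized_counts(union, profile_a)
    b = _normalized_counts(union, profile_b)
    fold = (b + pseudocount) / (a + pseudocount)
    keys = [(iv.chrom, iv.start) for iv in union.intervals]
    order = np.array(
        sorted(range(len(fold)), key=lambda i: (fold[i], keys[i])), dtype=np.int64
    )
    return RankedComparison(union, a, b, fold, order)


def _bin_edges(window_bp: int, n_bins: int) -> np.ndarray:
    """Integer bin edges over a 2*window_bp span; remainder goes to the last bin."""
    width = 2 * window_bp
    step = width // n_bins
    if step < 1:
        raise ValueError("more bins than bases in the window")
    edges = np.arange(0, step * n_bins + 1, step)
    edges[-1] = width
    return edges


def signal_heatmap_matrix(
    ranked: RankedComparison,
    profile: CutProfile,
    window_bp: int = 2000,
    n_bins: int = 200,
) -> pd.DataFrame:
    """Per-bin cut counts (both strands) around region centers, in ranked order."""
    edges = _bin_edges(window_bp, n_bins)
    rows = []
    ids = []
    for iv in ranked.ranked_regions():
        center = iv.center
        lo = center - window_bp
        track = profile.window_array(iv.chrom, max(lo, 0), center + window_bp)
        if lo < 0:  # pad so the window stays centered
            track = np.concatenate([np.zeros(-lo, dtype=track.dtype), track])
        binned = np.add.reduceat(track, edges[:-1])
        rows.append(binned)
        ids.append(f"{iv.chrom}:{iv.start}-{iv.end}")
    return pd.DataFrame(np.vstack(rows), index=ids)


def average_profile(
    peaks: Sequence[GenomicInterval],
    profile: CutProfile,
    window_bp: int = 2000,
) -> np.ndarray:
    """Mean per-position cut count over peaks, centered, length 2*window_bp."""
    if not peaks:
        raise ValueError("no peaks to average over")
    acc = np.zeros(2 * window_bp, dtype=float)
    for iv in peaks:
        center = (iv.start + iv.end) // 2
        lo = center - window_bp
        track = profile.window_array(iv.chrom, max(lo, 0), center + window_bp)
        if lo < 0:
            track = np.concatenate([np.zeros(-lo, dtype=track.dtype), track])
        acc += track
    return acc / len(peaks)


def motif_density_tracks(
    ranked: RankedComparison,
    hitsets: Mapping[str, MotifHitSet],
    window_bp: int = 1000,
    n_bins: int = 50,
    row_smoothing: int = 50,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Binary per-bin motif occurrence around ranked region centers.

    For each motif returns the raw 0/1 matrix and a display copy smoothed by
    a moving average over ``row_smoothing`` consecutive ranked rows.
    """
    edges = _bin_edges(window_bp, n_bins)
    regions = ranked.ranked_regions()
    ids = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in regions]
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for motif_id, hitset in hitsets.items():
        mids: dict[str, np.ndarray] = {}
        tmp: dict[str, list[int]] = {}
        for h in hitset.hits:
            tmp.setdefault(h.interval.chrom, []).append(
                (h.interval.start + h.interval.end) // 2
            )
        for chrom, v in tmp.items():
            mids[chrom] = np.sort(np.asarray(v, dtype=np.int64))
        mat = np.zeros((len(regions), n_bins), dtype=float)
        for r, iv in enumerate(regions):
            arr = mids.get(iv.chrom)
            if arr is None:
                continue
            center = iv.center
            lo, hi = center - window_bp, center + window_bp
            sel = arr[(arr >= lo) & (arr < hi)] - lo
            if sel.size:
                bins = np.searchsorted(edges, sel, side="right") - 1
                mat[r, np.clip(bins, 0, n_bins - 1)] = 1.0
        raw = pd.DataFrame(mat, index=ids)
        if row_smoothing > 1:
            smoothed = raw.rolling(
                window=row_smoothing, min_periods=1, center=True
            ).mean()
        else:
            smoothed = raw.copy()
        out[motif_id] = {"raw": raw, "smoothed": smoothed}
    return out


# ---------------------------------------------------------------------------
# Knockdown DHS groups


@dataclass
class ChangeGroups:
    """Partition of union regions into lost / shared / gained after treatment."""

    regions: PeakSet
    group: pd.Series  # index region id, values in {lost, shared, gained}
    fold_threshold: float

    def regions_in(self, label: str) -> list[GenomicInterval]:
        mask = (self.group == label).to_numpy()
        return [iv for iv, m in zip(self.regions.intervals, mask) if m]


def classify_dhs_groups(
    union: PeakSet,
    counts_control: np.ndarray,
    counts_kd: np.ndarray,
    fold_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> ChangeGroups:
    """lost if ctrl/kd >= threshold, gained if kd/ctrl >= threshold, else shared."""
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    ctrl = np.asarray(counts_control, dtype=float) + pseudocount
    kd = np.asarray(counts_kd, dtype=float) + pseudocount
    labels = np.where(
        ctrl / kd >= fold_threshold,
        "lost",
        np.where(kd / ctrl >= fold_threshold, "gained", "shared"),
    )
    series = pd.Series(labels, index=region_ids(union), name="group")
    return ChangeGroups(union, series, fold_threshold)


# ---------------------------------------------------------------------------
# Differential expression


@dataclass
class DEGenes:
    """Genes passing the fold-change filter, with per-timepoint log2 FC."""

    genes: list[str]
    log2_fc: pd.DataFrame  # qualifying genes x timepoints
    direction: pd.DataFrame  # 'up' / 'down' / 'flat' per timepoint
    linkage: np.ndarray | None
    order: list[str]


def de_genes(
    expr: pd.DataFrame,
    condition_cols: Mapping[str, Sequence[str]],
    control_cols: Mapping[str, Sequence[str]],
    fold_threshold: float = 1.5,
    pseudocount: float = 1.0,
) -> DEGenes:
    """Filter genes changing >= fold_threshold at >= 1 timepoint.

    ``condition_cols`` and ``control_cols`` map each timepoint to its
    replicate column names; replicates are averaged before the fold change
    (condition over control, on FPKM + pseudocount) is taken.  The boundary
    is closed: |log2 FC| == log2(threshold) qualifies.  Qualifying genes'
    FC profiles are clustered (average linkage, Euclidean) for display.
    """
    timepoints = list(condition_cols)
    if set(timepoints) != set(control_cols):
        raise ValueError("condition and control timepoints do not match")
    missing = [
        c
        for cols in list(condition_cols.values()) + list(control_cols.values())
        for c in cols
        if c not in expr.columns
    ]
    if missing:
        raise ValueError(f"missing expression columns: {missing}")
    fc = pd.DataFrame(index=expr.index)
    for tp in timepoints:
        cond = expr[list(condition_cols[tp])].mean(axis=1) + pseudocount
        ctrl = expr[list(control_cols[tp])].mean(axis=1) + pseudocount
        fc[tp] = np.log2(cond / ctrl)
    cut = np.log2(fold_threshold)
    qualifies = (fc.abs() >= cut).any(axis=1)
    sel = fc.loc[qualifies]
    direction = pd.DataFrame(
        np.where(sel >= cut, "up", np.where(sel <= -cut, "down", "flat")),
        index=sel.index,
        columns=sel.columns,
    )
    genes = sorted(sel.index)
    sel = sel.loc[genes]
    direction = direction.loc[genes]
    if len(genes) >= 2:
        from scipy.spatial.distance import pdist

        linkage = hierarchy.average(pdist(sel.to_numpy(), metric="euclidean"))
        order = [genes[i] for i in hierarchy.leaves_list(linkage)]
    else:
        linkage, order = None, list(genes)
    return DEGenes(genes, sel, direction, linkage, order)


# ---------------------------------------------------------------------------
# ChIP-target overlap


@dataclass
class TargetOverlap:
    """Fraction of differentially expressed genes that are ChIP targets."""

    n_de: int
    n_de_targets: int
    fraction: float
    undefined: bool = False


def chip_target_genes(
    chip_peaks: Sequence[GenomicInterval],
    tss_table: Sequence[GenomicInterval],
    assignment_window: int = 50_000,
) -> set[str]:
    """Genes with >= 1 peak assigned: nearest TSS to the peak center, within window."""
    from .peakset_ops import nearest_gene

    assignments = nearest_gene(chip_peaks, tss_table)
    return {
        gene
        for gene, dist in assignments
        if gene != "none" and abs(dist) <= assignment_window
    }


def target_overlap_fraction(
    de_gene_names: Sequence[str],
    chip_peaks: Sequence[GenomicInterval],
    tss_table: Sequence[GenomicInterval],
    assignment_window: int = 50_000,
) -> TargetOverlap:
    """Fraction of DE genes that are ChIP targets under the nearest-TSS rule."""
    if not de_gene_names:
        return TargetOverlap(0, 0, float("nan"), undefined=True)
    targets = chip_target_genes(chip_peaks, tss_table, assignment_window)
    n_de = len(de_gene_names)
    n_hit = sum(1 for g in de_gene_names if g in targets)
    return TargetOverlap(n_de, n_hit, n_hit / n_de)
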