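"""Peak-set algebra, tag-count matrices, sample correlation clustering, annotation.

The machinery behind cistrome comparison: merged union peak sets, subset
(Venn) assignment, per-sample DNase tag counting over a common region set,
and correlation-based hierarchical clustering of samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genomic_io import CutProfile, GenomicInterval

TAGS_PER = 1e7  # library-size normalisation target (tags per 10 million)


@dataclass
class PeakSet:
    """A labelled, sorted, merged collection of peaks."""

    label: str
    intervals: list[GenomicInterval]

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def sort_and_merge(
    intervals: Sequence[GenomicInterval], label: str = ""
) -> PeakSet:
    """Sort and merge overlapping or book-ended intervals into union spans."""
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return PeakSet(label, merged)


@dataclass
class OverlapSummary:
    """Venn-style decomposition of the merged union of 2-3 peak sets."""

    set_labels: tuple[str, ...]
    region_counts: dict[frozenset, int]
    union: PeakSet
    region_support: list[frozenset]
    pairwise_fraction: dict[tuple[str, str], float]

    def count(self, *labels: str) -> int:
        return self.region_counts.get(frozenset(labels), 0)


class _OverlapIndex:
    """Sorted per-chromosome start/end arrays for O(log n) overlap queries."""

    def __init__(self, peaks: PeakSet) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in peaks.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs, key=lambda iv: (iv.start, iv.end))
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends)

    def any_overlap(self, region: GenomicInterval) -> bool:
        entry = self._by_chrom.get(region.chrom)
        if entry is None:
            return False
        starts, ends = entry
        # first peak starting at/after region start; its left neighbour may
        # still reach into the region (peaks are merged, so one suffices)
        i = int(np.searchsorted(starts, region.start))
        if i < len(starts) and starts[i] < region.end:
            return True
        return i > 0 and ends[i - 1] > region.start


def overlap_counts(peaksets: Sequence[PeakSet]) -> OverlapSummary:
    """Assign each union region the subset of inputs overlapping it >= 1 bp.

    Also reports, per ordered pair (A, B), the fraction of A's own peaks
    that overlap at least one peak of B.
    """
    if not 2 <= len(peaksets) <= 3:
        raise ValueError(f"overlap_counts supports 2 or 3 sets, got {len(peaksets)}")
    labels = tuple(ps.label for ps in peaksets)
    if len(set(labels)) != len(labels):
        raise ValueError("peak set labels must be distinct")
    union = sort_and_merge(
        [iv for ps in peaksets for iv in ps.intervals], label="union"
    )
    indexes = {ps.label: _OverlapIndex(ps) for ps in peaksets}
    support: list[frozenset] = []
    counts: dict[frozenset, int] = {}
    for region in union.intervals:
        members = frozenset(
            ps.label for ps in peaksets if indexes[ps.label].any_overlap(region)
        )
        support.append(members)
        counts[members] = counts.get(members, 0) + 1
    fractions: dict[tuple[str, str], float] = {}
    for a in peaksets:
        for b in peaksets:
            if a.label == b.label:
                continue
            n = len(a.intervals)
            idx_b = indexes[b.label]
            k = sum(1 for iv in a.intervals if idx_b.any_overlap(iv))
            fractions[(a.label, b.label)] = k / n if n else float("nan")
    return OverlapSummary(labels, counts, union, support, fractions)


def unique_regions(summary: OverlapSummary, label: str) -> list[GenomicInterval]:
    """Union regions supported by exactly one named input set."""
    return [
        iv
        for iv, members in zip(summary.union.intervals, summary.region_support)
        if members == frozenset({label})
    ]


def shared_regions(summary: OverlapSummary) -> list[GenomicInterval]:
    """Union regions supported by all input sets."""
    full = frozenset(summary.set_labels)
    return [
        iv
        for iv, members in zip(summary.union.intervals, summary.region_support)
        if members == full
    ]


@dataclass
class SampleCountMatrix:
    """Regions x samples tag counts over a common union peak set."""

    regions: PeakSet
    counts: pd.DataFrame  # index = region id, columns = sample labels
    normalized: pd.DataFrame  # tags-per-10-million scaled

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def region_ids(peaks: PeakSet) -> list[str]:
    return [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in peaks.intervals]


def tag_count_matrix(
    union: PeakSet, profiles: Mapping[str, CutProfile]
) -> SampleCountMatrix:
    """Count each sample's cuts (both strands) falling inside each union region."""
    if len(union) == 0:
        raise ValueError("empty union peak set")
    ids = region_ids(union)
    data = {}
    for label, prof in profiles.items():
        data[label] = [
            prof.counts_in(iv.chrom, iv.start, iv.end) for iv in union.intervals
        ]
    counts = pd.DataFrame(data, index=ids)
    totals = {label: prof.total_cuts for label, prof in profiles.items()}
    norm = counts.astype(float)
    for label in norm.columns:
        if totals[label] > 0:
            norm[label] = norm[label] * (TAGS_PER / totals[label])
    return SampleCountMatrix(union, counts, norm)


@dataclass
class CorrelationClustering:
    """Sample correlation matrix with an average-linkage merge tree."""

    correlation: pd.DataFrame
    linkage: np.ndarray
    order: list[str]


def correlation_cluster(matrix: SampleCountMatrix) -> CorrelationClustering:
    """Pearson correlation of log2(normalized+1) columns, average linkage on 1-r.

    Leaf order is made deterministic by clustering samples in lexicographic
    label order; ties in the distance matrix then resolve identically on
    every run.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least 2 samples")
    if matrix.counts.shape[0] < 2:
        raise ValueError("need at least 2 regions")
    ordered = sorted(matrix.samples)
    logcounts = np.log2(matrix.normalized[ordered] + 1.0)
    stds = logcounts.std(axis=0, ddof=0)
    flat = stds[stds == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance sample(s): {', '.join(flat)}")
    corr = logcounts.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    linkage = hierarchy.average(squareform(dist, checks=False))
    leaves = hierarchy.leaves_list(linkage)
    order = [ordered[i] for i in leaves]
    return CorrelationClustering(corr, linkage, order)


def cut_tree_groups(linkage: np.ndarray, labels: Sequence[str], k: int) -> dict[str, int]:
    """Cut a linkage tree into k flat clusters; returns label -> cluster id."""
    assignment = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return {lab: int(c) for lab, c in zip(labels, assignment)}


# ---------------------------------------------------------------------------
# Annotation


def _tss_by_chrom(tss_table: Sequence[GenomicInterval]):
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in tss_table:
        by_chrom.setdefault(t.chrom, []).append(t)
    for rows in by_chrom.values():
        rows.sort(key=lambda t: (t.start, t.name or ""))
    return by_chrom


def nearest_gene(
    peaks: Sequence[GenomicInterval], tss_table: Sequence[GenomicInterval]
) -> list[tuple[str, float]]:
    """Nearest TSS to each peak center; ties broken by gene name.

    The returned distance is signed by the TSS strand: positive when the
    peak center lies downstream of the TSS (in the gene's direction of
    transcription), negative upstream.  Peaks on chromosomes absent from
    the table get ("none", inf).
    """
    if not tss_table:
        raise ValueError("empty TSS table")
    by_chrom = _tss_by_chrom(tss_table)
    out: list[tuple[str, float]] = []
    for peak in peaks:
        candidates = by_chrom.get(peak.chrom)
        if not candidates:
            out.append(("none", float("inf")))
            continue
        center = peak.center
        best = min(
            candidates, key=lambda t: (abs(center - t.start), t.name or "")
        )
        delta = center - best.start
        signed = -delta if best.strand == "-" else delta
        out.append((best.name or "", float(signed)))
    return out


def annotate_region_class(
    peaks: Sequence[GenomicInterval],
    tss_table: Sequence[GenomicInterval],
    promoter_halfwidth: int = 1500,
    gene_bodies: Sequence[GenomicInterval] | None = None,
) -> list[str]:
    """Label each peak promoter / intragenic / distal by its center position."""
    if not tss_table:
        raise ValueError("empty TSS table")
    by_chrom = _tss_by_chrom(tss_table)
    bodies_by_chrom: dict[str, list[GenomicInterval]] = {}
    if gene_bodies:
        for g in gene_bodies:
            bodies_by_chrom.setdefault(g.chrom, []).append(g)
    labels = []
    for peak in peaks:
        center = peak.center
        tss_rows = by_chrom.get(peak.chrom, [])
        if any(abs(center - t.start) <= promoter_halfwidth for t in tss_rows):
            labels.append("promoter")
            continue
        bodies = bodies_by_chrom.get(peak.chrom, [])
        if any(g.start <= center < g.end for g in bodies):
            labels.append("intragenic")
        else:
            labels.append("distal")
    return labels
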