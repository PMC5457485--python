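"""Digital footprint detection and bootstrap co-occupancy statistics.

Footprints are short spans inside accessible regions where strand-specific
DNase I cuts are depleted relative to their flanks.  Following the
Wellington approach, each candidate footprint is scored by two one-sided
binomial tests — forward-strand cuts in the footprint versus the upstream
shoulder, and reverse-strand cuts versus the downstream shoulder — whose
log10 probabilities are summed.  Motif hits overlapping footprints are
"occupied", and the significance of occupied motifs co-clustering near an
anchor peak set (e.g. a fusion-protein cistrome) is measured against a
bootstrap null of anchor-sized draws from the accessible-region universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .genomic_io import CutProfile, GenomicInterval
from .motif_scan import MotifHit, MotifHitSet
from .peakset_ops import PeakSet

LN10 = np.log(10.0)

DEFAULT_FP_SIZES = tuple(range(11, 27, 2))  # 11, 13, ..., 25
DEFAULT_SHOULDER = 35
DEFAULT_CUTOFF = -10.0


@dataclass(frozen=True)
class FootprintCall:
    """A called footprint with its binomial evidence retained for audit."""

    interval: GenomicInterval
    footprint_size: int
    score: float  # log10 p_fw + log10 p_rev, <= 0
    fw_footprint_cuts: int
    fw_shoulder_cuts: int
    rev_footprint_cuts: int
    rev_shoulder_cuts: int


def _log10_binom_lower(k: np.ndarray, n: np.ndarray, p: float) -> np.ndarray:
    """log10 P(X <= k) for X ~ Binom(n, p); zero-trial positions score 0."""
    out = np.zeros(len(k), dtype=float)
    nz = n > 0
    if nz.any():
        out[nz] = binom.logcdf(k[nz], n[nz], p) / LN10
    return out


def wellington_scan(
    profile: CutProfile,
    regions: PeakSet,
    fp_sizes: Sequence[int] = DEFAULT_FP_SIZES,
    shoulder_size: int = DEFAULT_SHOULDER,
    score_cutoff: float = DEFAULT_CUTOFF,
) -> list[FootprintCall]:
    """Score candidate footprints in each region and greedily call the best.

    For a footprint of size ``f`` starting at position ``s``, the forward
    test compares forward-strand cuts in [s, s+f) with the ``shoulder_size``
    window immediately upstream, under success probability
    f / (f + shoulder_size); the reverse test mirrors this downstream with
    reverse-strand cuts.  Per position the most negative score over
    ``fp_sizes`` is kept; non-overlapping footprints are then selected in
    ascending score order until ``score_cutoff`` is reached.
    """
    if shoulder_size <= 0:
        raise ValueError("shoulder_size must be positive")
    if not fp_sizes:
        raise ValueError("fp_sizes must be non-empty")
    calls: list[FootprintCall] = []
    for region in regions.intervals:
        calls.extend(
            _scan_region(
                profile, region, tuple(fp_sizes), shoulder_size, score_cutoff
            )
        )
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return calls


def _scan_region(
    profile: CutProfile,
    region: GenomicInterval,
    fp_sizes: tuple[int, ...],
    shoulder: int,
    cutoff: float,
) -> list[FootprintCall]:
    width = region.width
    fw = profile.window_array(region.chrom, region.start, region.end, "+")
    rv = profile.window_array(region.chrom, region.start, region.end, "-")
    cfw = np.concatenate(([0], np.cumsum(fw)))
    crv = np.concatenate(([0], np.cumsum(rv)))

    best_score = np.zeros(width)  # indexed by footprint start
    best_size = np.zeros(width, dtype=int)
    best_stats = {}
    any_candidate = np.zeros(width, dtype=bool)
    for f in fp_sizes:
        lo, hi = shoulder, width - f - shoulder  # valid start range, inclusive
        if hi < lo:
            continue
        starts = np.arange(lo, hi + 1)
        F_fw = cfw[starts + f] - cfw[starts]
        S_fw = cfw[starts] - cfw[starts - shoulder]
        F_rv = crv[starts + f] - crv[starts]
        S_rv = crv[starts + f + shoulder] - crv[starts + f]
        p_succ = f / (f + shoulder)
        score = _log10_binom_lower(F_fw, F_fw + S_fw, p_succ) + _log10_binom_lower(
            F_rv, F_rv + S_rv, p_succ
        )
        improved = np.where(
            ~any_candidate[starts] | (score < best_score[starts])
        )[0]
        for j in improved:
            s = int(starts[j])
            best_score[s] = score[j]
            best_size[s] = f
            best_stats[s] = (int(F_fw[j]), int(S_fw[j]), int(F_rv[j]), int(S_rv[j]))
        any_candidate[starts] = True

    candidates = np.flatnonzero(any_candidate & (best_score <= cutoff))
    if candidates.size == 0:
        return []
    order = candidates[np.argsort(best_score[candidates], kind="stable")]
    occupied = np.zeros(width, dtype=bool)
    calls = []
    for s in order:
        f = int(best_size[s])
        if occupied[s : s + f].any():
            continue
        occupied[s : s + f] = True
        ffw, sfw, frv, srv = best_stats[int(s)]
        calls.append(
            FootprintCall(
                GenomicInterval(
                    region.chrom, region.start + int(s), region.start + int(s) + f
                ),
                f,
                float(best_score[s]),
                ffw,
                sfw,
                frv,
                srv,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Occupied motifs


@dataclass(frozen=True)
class OccupiedMotif:
    """A motif hit overlapping a footprint, carrying the best footprint score."""

    hit: MotifHit
    footprint_score: float


def occupied_motifs(
    footprints: Sequence[FootprintCall],
    hitsets: Mapping[str, MotifHitSet],
) -> dict[str, list[OccupiedMotif]]:
    """Retain motif hits overlapping >= 1 bp with any footprint."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int, float]]] = {}
    for fp in footprints:
        tmp.setdefault(fp.interval.chrom, []).append(
            (fp.interval.start, fp.interval.end, fp.score)
        )
    for chrom, rows in tmp.items():
        rows.sort()
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        scores = np.array([r[2] for r in rows], dtype=float)
        by_chrom[chrom] = (starts, ends, scores)

    out: dict[str, list[OccupiedMotif]] = {}
    for motif_id, hitset in hitsets.items():
        kept = []
        for h in hitset.hits:
            entry = by_chrom.get(h.interval.chrom)
            if entry is None:
                continue
            starts, ends, scores = entry
            # footprints are non-overlapping; scan the small overlap window
            lo = int(np.searchsorted(ends, h.interval.start, side="right"))
            hi = int(np.searchsorted(starts, h.interval.end, side="left"))
            if hi > lo:
                kept.append(OccupiedMotif(h, float(scores[lo:hi].min())))
        out[motif_id] = kept
    return out


# ---------------------------------------------------------------------------
# Bootstrap co-occurrence


@dataclass
class CooccurrenceMatrix:
    """Per-motif observed co-occupancy near anchors with bootstrap null moments."""

    anchor_label: str
    table: pd.DataFrame  # index motif; observed, null_mean, null_sd, z, p_empirical
    n_boot: int
    window_bp: int
    n_anchors: int


def _near_indicator(
    centers_chrom: list[str],
    centers_pos: np.ndarray,
    occupied: Sequence[OccupiedMotif | MotifHit],
    window_bp: int,
) -> np.ndarray:
    """Boolean per region: center within window_bp of any occupied-motif midpoint."""
    mids: dict[str, list[int]] = {}
    for om in occupied:
        hit = om.hit if isinstance(om, OccupiedMotif) else om
        mids.setdefault(hit.interval.chrom, []).append(
            (hit.interval.start + hit.interval.end) // 2
        )
    sorted_mids = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in mids.items()}
    out = np.zeros(len(centers_pos), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(centers_chrom, centers_pos)):
        arr = sorted_mids.get(chrom)
        if arr is None:
            continue
        lo = np.searchsorted(arr, pos - window_bp, side="left")
        hi = np.searchsorted(arr, pos + window_bp, side="right")
        out[i] = hi > lo
    return out


def bootstrap_cooccurrence(
    anchor_peaks: PeakSet,
    occupied: Mapping[str, Sequence[OccupiedMotif | MotifHit]],
    universe: PeakSet,
    window_bp: int = 50,
    n_boot: int = 1000,
    seed: int = 0,
) -> CooccurrenceMatrix:
    """Significance of occupied motifs clustering within window_bp of anchors.

    observed(m): anchors whose center lies within ``window_bp`` of at least
    one occupied motif midpoint.  Null: ``n_boot`` draws of len(anchors)
    regions sampled uniformly without replacement from ``universe``,
    recomputing the count.  z is reported as NaN when the null is degenerate
    (sd 0); the empirical p (1 + #null >= observed) / (1 + n_boot) remains
    valid.
    """
    n_anchor = len(anchor_peaks)
    n_universe = len(universe)
    if n_universe < n_anchor:
        raise ValueError(
            f"universe ({n_universe}) smaller than anchor set ({n_anchor})"
        )
    motifs = sorted(occupied)
    uni_chroms = [iv.chrom for iv in universe.intervals]
    uni_centers = np.array([iv.center for iv in universe.intervals], dtype=np.int64)
    anc_chroms = [iv.chrom for iv in anchor_peaks.intervals]
    anc_centers = np.array([iv.center for iv in anchor_peaks.intervals], dtype=np.int64)

    indicator = np.zeros((n_universe, len(motifs)), dtype=bool)
    observed = np.zeros(len(motifs), dtype=np.int64)
    for j, m in enumerate(motifs):
        indicator[:, j] = _near_indicator(
            uni_chroms, uni_centers, occupied[m], window_bp
        )
        observed[j] = int(
            _near_indicator(anc_chroms, anc_centers, occupied[m], window_bp).sum()
        )

    rng = np.random.default_rng(seed)
    null_counts = np.empty((n_boot, len(motifs)), dtype=np.int64)
    for b in range(n_boot):
        idx = rng.choice(n_universe, size=n_anchor, replace=False)
        null_counts[b] = indicator[idx].sum(axis=0)

    null_mean = null_counts.mean(axis=0)
    null_sd = null_counts.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null_sd > 0, (observed - null_mean) / null_sd, np.nan)
    p_emp = (1 + (null_counts >= observed[None, :]).sum(axis=0)) / (1 + n_boot)

    table = pd.DataFrame(
        {
            "observed": observed,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "p_empirical": p_emp,
        },
        index=pd.Index(motifs, name="motif"),
    )
    return CooccurrenceMatrix(anchor_peaks.label, table, n_boot, window_bp, n_anchor)
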