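"""PWM and IUPAC-consensus motif scanning over DNA sequence.

Hits carry genome coordinates (via each sequence record's declared offset)
and log2-odds scores, and feed the enrichment, density-track and
footprint-co-occupancy stages.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import PWM, GenomicInterval, SequenceRecord, reverse_complement
from .peakset_ops import PeakSet

_BASE_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# In vitro selection consensi for the EVI1 zinc-finger domain, matched as
# exact degenerate strings (Y = C/T), not as PWMs
EVI1_ZF_CONSENSUS = "GAYAAGAYAAGATAA"
EVI1_SHORT_CONSENSUS = "TGACAAGATAA"

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


@dataclass(frozen=True)
class MotifHit:
    """One motif match: a genomic span, strand, and log2-odds score in bits."""

    motif_id: str
    interval: GenomicInterval
    strand: str
    score: float


@dataclass
class MotifHitSet:
    """Sorted, deduplicated hits of one motif."""

    motif_id: str
    hits: list[MotifHit]

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    @staticmethod
    def build(motif_id: str, hits: Sequence[MotifHit]) -> "MotifHitSet":
        seen = set()
        unique = []
        for h in sorted(
            hits, key=lambda h: (h.interval.chrom, h.interval.start, h.strand)
        ):
            key = (h.interval.chrom, h.interval.start, h.strand)
            if key not in seen:
                seen.add(key)
                unique.append(h)
        return MotifHitSet(motif_id, unique)


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_TO_INT[b] for b in seq), dtype=np.int8, count=len(seq))


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score every window of width L; windows containing N score -inf."""
    L = log_odds.shape[1]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    has_n = (windows == 4).any(axis=1)
    safe = np.where(windows == 4, 0, windows)
    scores = log_odds[safe, np.arange(L)].sum(axis=1)
    scores[has_n] = -np.inf
    return scores


def scan_pwm(
    sequence_set: Sequence[SequenceRecord],
    pwm: PWM,
    rel_threshold: float = 0.8,
) -> MotifHitSet:
    """Scan both strands for log-odds hits above a relative score threshold.

    The absolute threshold is ``rel_threshold * (max - min) + min`` where
    max/min are the best and worst attainable scores of the matrix.
    Windows containing N are skipped.  Reverse-strand hits are reported on
    genome (forward) coordinates with strand '-'.
    """
    if not 0 < rel_threshold <= 1:
        raise ValueError(f"rel_threshold must be in (0, 1], got {rel_threshold}")
    lo = pwm.log_odds()
    smin, smax = pwm.score_range()
    if smax <= smin:  # flat matrix (= background): no discriminative power
        return MotifHitSet(pwm.motif_id, [])
    threshold = rel_threshold * (smax - smin) + smin
    L = pwm.length
    hits: list[MotifHit] = []
    for rec in sequence_set:
        if len(rec) < L:
            continue
        for strand, seq in (("+", rec.sequence), ("-", reverse_complement(rec.sequence))):
            scores = _window_scores(_encode(seq), lo)
            for i in np.flatnonzero(scores >= threshold):
                if strand == "+":
                    start = rec.offset + int(i)
                else:
                    start = rec.offset + len(rec) - L - int(i)
                hits.append(
                    MotifHit(
                        pwm.motif_id,
                        GenomicInterval(rec.id, start, start + L),
                        strand,
                        float(scores[i]),
                    )
                )
    return MotifHitSet.build(pwm.motif_id, hits)


def _iupac_regex(consensus: str) -> re.Pattern:
    parts = []
    for c in consensus.upper():
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC code {c!r} in consensus")
        opts = IUPAC[c]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def reverse_complement_iupac(consensus: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[c] for c in consensus.upper()[::-1])


def match_iupac(
    sequence_set: Sequence[SequenceRecord], consensus: str
) -> MotifHitSet:
    """Exact degenerate matching of an IUPAC consensus on both strands."""
    fwd = _iupac_regex(consensus)
    rev = _iupac_regex(reverse_complement_iupac(consensus))
    L = len(consensus)
    hits: list[MotifHit] = []
    for rec in sequence_set:
        for strand, pattern in (("+", fwd), ("-", rev)):
            pos = 0
            while True:
                m = pattern.search(rec.sequence, pos)
                if m is None:
                    break
                start = rec.offset + m.start()
                hits.append(
                    MotifHit(
                        consensus,
                        GenomicInterval(rec.id, start, start + L),
                        strand,
                        0.0,
                    )
                )
                pos = m.start() + 1  # allow overlapping matches
    return MotifHitSet.build(consensus, hits)


def hits_in_peaks(
    hitset: MotifHitSet, peaks: PeakSet
) -> "pd.Series":
    """Count hits whose midpoint falls inside each peak (half-open).

    Returns a pandas Series indexed by "chrom:start-end"; presence is
    count >= 1.
    """
    import pandas as pd

    from .peakset_ops import region_ids

    mids_by_chrom: dict[str, np.ndarray] = {}
    tmp: dict[str, list[int]] = {}
    for h in hitset.hits:
        tmp.setdefault(h.interval.chrom, []).append(
            (h.interval.start + h.interval.end) // 2
        )
    for chrom, mids in tmp.items():
        mids_by_chrom[chrom] = np.sort(np.asarray(mids, dtype=np.int64))
    counts = []
    for iv in peaks.intervals:
        mids = mids_by_chrom.get(iv.chrom)
        if mids is None:
            counts.append(0)
            continue
        lo, hi = np.searchsorted(mids, (iv.start, iv.end))
        counts.append(int(hi - lo))
    return pd.Series(counts, index=region_ids(peaks), name=hitset.motif_id)


def hit_presence_table(
    hitsets: Mapping[str, MotifHitSet], peaks: PeakSet
) -> "pd.DataFrame":
    """Peaks x motifs table of hit counts (midpoint containment)."""
    import pandas as pd

    return pd.DataFrame({m: hits_in_peaks(hs, peaks) for m, hs in hitsets.items()})
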