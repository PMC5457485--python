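"""Unique-vs-union and shared-peak motif enrichment with clustered score matrices.

The enrichment statistic: unique (or shared) peaks of a pairwise comparison
are a sample drawn without replacement from the merged union of the two peak
sets, so motif presence in the target is tested against the union with an
exact hypergeometric test.  Scores are signed -log10 p: positive for
over-representation, negative for depletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import hypergeom

from .motif_scan import MotifHitSet, hit_presence_table
from .peakset_ops import (
    PeakSet,
    overlap_counts,
    shared_regions,
    unique_regions,
)

P_FLOOR = 1e-300


@dataclass
class EnrichmentResult:
    """One motif x one comparison: counts, fold, p-values and signed score."""

    motif_id: str
    comparison_id: str
    n_target: int
    k_target: int
    n_background: int
    k_background: int
    fold: float
    p_value: float
    log10_enrichment_score: float
    q_value: float = float("nan")
    undefined: bool = False


def enrichment_from_counts(
    motif_id: str, comparison_id: str, n: int, k: int, N: int, K: int
) -> EnrichmentResult:
    """Signed hypergeometric enrichment of k/n target peaks vs K/N union peaks.

    The target is modelled as n draws without replacement from the N union
    peaks of which K carry the motif; the reported p is the smaller of the
    upper tail P(X >= k) and lower tail P(X <= k), and the score is
    -log10 p with a positive sign for over-representation.
    """
    if n == 0:
        return EnrichmentResult(
            motif_id, comparison_id, 0, 0, N, K,
            float("nan"), float("nan"), 0.0, undefined=True,
        )
    target_rate = k / n
    union_rate = K / N if N else float("nan")
    fold = target_rate / union_rate if union_rate else float("inf")
    p_upper = max(float(hypergeom.sf(k - 1, N, K, n)), P_FLOOR)
    p_lower = max(float(hypergeom.cdf(k, N, K, n)), P_FLOOR)
    if p_upper <= p_lower:
        p, score = p_upper, -np.log10(p_upper)
    else:
        p, score = p_lower, np.log10(p_lower)
    return EnrichmentResult(
        motif_id, comparison_id, n, k, N, K, fold, p, float(score)
    )


def _score_presence(
    presence_target: np.ndarray,
    presence_union: np.ndarray,
    motif_id: str,
    comparison_id: str,
) -> EnrichmentResult:
    return enrichment_from_counts(
        motif_id,
        comparison_id,
        len(presence_target),
        int(presence_target.sum()),
        len(presence_union),
        int(presence_union.sum()),
    )


def _bh_adjust(results: list[EnrichmentResult]) -> None:
    """Benjamini-Hochberg across motifs within one comparison, in place."""
    defined = [r for r in results if not r.undefined]
    m = len(defined)
    if m == 0:
        return
    order = np.argsort([r.p_value for r in defined])
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, defined[idx].p_value * m / rank)
        q[idx] = prev
    for r, qv in zip(defined, q):
        r.q_value = float(qv)


def _enrich_target(
    target: Sequence,
    union: PeakSet,
    union_presence: pd.DataFrame,
    comparison_id: str,
) -> list[EnrichmentResult]:
    target_ids = {f"{iv.chrom}:{iv.start}-{iv.end}" for iv in target}
    mask = union_presence.index.isin(target_ids)
    results = []
    for motif_id in union_presence.columns:
        pres = (union_presence[motif_id].to_numpy() > 0)
        results.append(
            _score_presence(pres[mask], pres, motif_id, comparison_id)
        )
    _bh_adjust(results)
    return results


def unique_vs_union_enrichment(
    set_a: PeakSet,
    set_b: PeakSet,
    hitsets: Mapping[str, MotifHitSet],
) -> list[EnrichmentResult]:
    """Enrichment of each motif in A-unique and B-unique peaks vs the union.

    Unique peaks are union regions supported by exactly one input set;
    the background population is the full merged union of both sets.
    """
    summary = overlap_counts([set_a, set_b])
    union = summary.union
    presence = hit_presence_table(hitsets, union)
    results = []
    for ps in (set_a, set_b):
        uniq = unique_regions(summary, ps.label)
        results.extend(
            _enrich_target(uniq, union, presence, f"{ps.label}-unique")
        )
    return results


def shared_peak_enrichment(
    peaksets: Sequence[PeakSet],
    hitsets: Mapping[str, MotifHitSet],
    comparison_id: str | None = None,
) -> list[EnrichmentResult]:
    """Enrichment in regions supported by ALL input sets, vs the union."""
    summary = overlap_counts(peaksets)
    union = summary.union
    presence = hit_presence_table(hitsets, union)
    shared = shared_regions(summary)
    label = comparison_id or ("+".join(summary.set_labels) + "-shared")
    return _enrich_target(shared, union, presence, label)


def enrich_region_list(
    target: Sequence,
    universe: PeakSet,
    hitsets: Mapping[str, MotifHitSet],
    comparison_id: str,
) -> list[EnrichmentResult]:
    """Enrichment of an arbitrary subset of universe regions vs the universe."""
    presence = hit_presence_table(hitsets, universe)
    return _enrich_target(target, universe, presence, comparison_id)


@dataclass
class EnrichmentMatrix:
    """Motifs x comparisons matrix of signed scores with row/column linkage."""

    values: pd.DataFrame
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_order: list[str]
    col_order: list[str]


def enrichment_matrix_cluster(
    results: Sequence[EnrichmentResult],
) -> EnrichmentMatrix:
    """Arrange signed -log10 p scores into a hierarchically clustered matrix.

    Rows (motifs) and columns (comparisons) are sorted lexicographically
    before average-linkage Euclidean clustering, so tie-breaks are
    deterministic.  Undefined cells (empty target) contribute 0.
    """
    rows = sorted({r.motif_id for r in results})
    cols = sorted({r.comparison_id for r in results})
    if len(rows) < 2 or len(cols) < 2:
        raise ValueError("need at least 2 motifs and 2 comparisons")
    mat = pd.DataFrame(0.0, index=rows, columns=cols)
    for r in results:
        mat.loc[r.motif_id, r.comparison_id] = (
            0.0 if r.undefined else r.log10_enrichment_score
        )
    row_link = hierarchy.average(_pdist_or_zero(mat.to_numpy()))
    col_link = hierarchy.average(_pdist_or_zero(mat.to_numpy().T))
    row_order = [rows[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [cols[i] for i in hierarchy.leaves_list(col_link)]
    return EnrichmentMatrix(mat, row_link, col_link, row_order, col_order)


def _pdist_or_zero(arr: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return pdist(arr, metric="euclidean")


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": r.motif_id,
                "comparison": r.comparison_id,
                "n": r.n_target,
                "k": r.k_target,
                "N": r.n_background,
                "K": r.k_background,
                "fold": r.fold,
                "p": r.p_value,
                "q": r.q_value,
                "score": r.log10_enrichment_score,
                "undefined": r.undefined,
            }
            for r in results
        ]
    )
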