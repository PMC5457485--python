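#!/usr/bin/env python
"""Compare the two synthetic condition cistromes: peak-set overlap, sample
correlation clustering, and the ranked fold-change signal heatmap.

Writes overlap counts, the replicate correlation matrix with its leaf order,
ranked regions with fold changes, and a signal-heatmap PNG under
results/landscape/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from cistrodiff.differential import rank_by_fold_change, signal_heatmap_matrix
from cistrodiff.peakset_ops import (
    correlation_cluster,
    cut_tree_groups,
    overlap_counts,
    tag_count_matrix,
)
from cistrodiff.synthetic_data import SyntheticDesign, build_fixture

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    out = ROOT / "results" / "landscape"
    out.mkdir(parents=True, exist_ok=True)
    fx = build_fixture(SyntheticDesign(seed=SEED))

    # peak-set overlap (Venn decomposition)
    summary = overlap_counts([fx.peaksets["cond1"], fx.peaksets["cond2"]])
    rows = [
        {"subset": "+".join(sorted(s)), "count": c}
        for s, c in sorted(summary.region_counts.items(), key=lambda kv: sorted(kv[0]))
    ]
    pd.DataFrame(rows).to_csv(out / "overlap_counts.tsv", sep="\t", index=False)
    frac = summary.pairwise_fraction[("cond1", "cond2")]
    print(f"union regions: {len(summary.union)}; "
          f"fraction of condition-1 peaks overlapping condition 2: {frac:.3f} "
          f"(designed {fx.design.shared_fraction})")

    # replicate correlation clustering
    counts = tag_count_matrix(summary.union, fx.profiles)
    clust = correlation_cluster(counts)
    clust.correlation.to_csv(out / "correlation.tsv", sep="\t")
    (out / "leaf_order.txt").write_text("\n".join(clust.order) + "\n")
    groups = cut_tree_groups(clust.linkage, sorted(counts.samples), 2)
    print(f"correlation leaf order: {clust.order}")
    print(f"2-way tree cut: {groups} "
          "(replicates pair by condition)" if groups["cond1_rep1"] == groups["cond1_rep2"]
          else f"2-way tree cut: {groups}")

    # ranked fold-change heatmap (condition 2 over condition 1)
    ranked = rank_by_fold_change(summary.union, fx.pooled["cond1"], fx.pooled["cond2"])
    ids = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in ranked.ranked_regions()]
    pd.DataFrame(
        {
            "region": ids,
            "fold_change": ranked.fold_change[ranked.order],
        }
    ).to_csv(out / "ranked_regions.tsv", sep="\t", index=False)
    hm1 = signal_heatmap_matrix(ranked, fx.pooled["cond1"], 2000, 200)
    hm2 = signal_heatmap_matrix(ranked, fx.pooled["cond2"], 2000, 200)

    fig, axes = plt.subplots(1, 2, figsize=(7, 6), sharey=True)
    for ax, hm, label in zip(axes, (hm1, hm2), ("condition 1", "condition 2")):
        ax.imshow(
            np.log1p(hm.to_numpy()), aspect="auto", cmap="Blues",
            extent=[-2000, 2000, len(hm), 0], interpolation="nearest",
        )
        ax.set_title(label)
        ax.set_xlabel("bp from region center")
    axes[0].set_ylabel("union regions, ranked by fold change")
    fig.tight_layout()
    fig.savefig(out / "signal_heatmap.png", dpi=120)
    print(f"tables and heatmap -> {out}")


if __name__ == "__main__":
    main()
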