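#!/usr/bin/env python
"""Knockdown-response analysis on the synthetic fixture.

Treats condition 1 as control and condition 2 as the post-knockdown state:
classifies union DHS regions into lost/shared/gained by tag-count fold
change, tests motif enrichment in the gained group, filters the expression
time course for >= 1.5-fold responders, and measures what fraction of them
are peak targets by the nearest-TSS rule.  Writes tables under
results/knockdown/.
"""

import json
from pathlib import Path

from cistrodiff.differential import (
    _normalized_counts,
    de_genes,
    target_overlap_fraction,
)
from cistrodiff.enrichment import enrich_region_list, results_to_frame
from cistrodiff.motif_scan import scan_pwm
from cistrodiff.peakset_ops import overlap_counts
from cistrodiff.synthetic_data import (
    SyntheticDesign,
    build_fixture,
    builtin_pwms,
    expression_column_map,
)

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    out = ROOT / "results" / "knockdown"
    out.mkdir(parents=True, exist_ok=True)
    fx = build_fixture(SyntheticDesign(seed=SEED))
    pwms = builtin_pwms()
    hitsets = {m: scan_pwm(fx.genome, p, 0.9) for m, p in pwms.items()}

    # DHS change groups
    summary = overlap_counts([fx.peaksets["cond1"], fx.peaksets["cond2"]])
    ctrl = _normalized_counts(summary.union, fx.pooled["cond1"])
    kd = _normalized_counts(summary.union, fx.pooled["cond2"])
    from cistrodiff.differential import classify_dhs_groups

    groups = classify_dhs_groups(summary.union, ctrl, kd, fold_threshold=2.0)
    counts = groups.group.value_counts().to_dict()
    groups.group.to_csv(out / "dhs_groups.tsv", sep="\t")
    print(f"DHS change groups (control = condition 1): {counts}")

    enr = enrich_region_list(
        groups.regions_in("gained"), summary.union, hitsets, "gained"
    )
    df = results_to_frame(enr).sort_values("score", ascending=False)
    df.to_csv(out / "gained_enrichment.tsv", sep="\t", index=False)
    top = df.iloc[0]
    print(f"top motif in gained DHSs: {top.motif} (score {top.score:.1f})")

    # expression responders
    cond_cols, ctrl_cols = expression_column_map(fx.design)
    deg = de_genes(fx.expression, cond_cols, ctrl_cols, fold_threshold=1.5)
    deg.log2_fc.loc[deg.order].to_csv(out / "de_log2fc.tsv", sep="\t")
    truth = set(fx.truth.up_genes) | set(fx.truth.down_genes)
    got = set(deg.genes)
    tp = len(got & truth)
    f1 = 2 * tp / (len(got) + len(truth))
    print(f"{len(deg.genes)} responder genes at 1.5-fold "
          f"({len(truth)} planted; F1 {f1:.3f})")

    # fraction of upregulated responders that are condition-2 peak targets
    last = fx.design.timepoints[-1]
    up = [g for g in deg.genes if deg.direction.loc[g, last] == "up"]
    overlap = target_overlap_fraction(
        up, fx.peaksets["cond2"].intervals, fx.tss_table, assignment_window=50_000
    )
    print(f"upregulated responders that are condition-2 peak targets: "
          f"{overlap.n_de_targets}/{overlap.n_de} ({overlap.fraction:.2f})")

    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                "dhs_groups": counts,
                "gained_top_motif": str(top.motif),
                "n_de_genes": len(deg.genes),
                "de_f1": f1,
                "up_target_fraction": overlap.fraction,
            },
            fh,
            indent=1,
        )
    print(f"tables -> {out}")


if __name__ == "__main__":
    main()
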