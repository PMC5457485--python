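#!/usr/bin/env python
"""Generate the default synthetic two-condition fixture with known truth.

Writes the full fixture (FASTA genome, peak BEDs, strand-specific cut-site
BEDs, TSS table, expression table, truth JSON, manifest) under
scratch/fixture/ and a small summary of what was planted under
results/fixture_summary.json.
"""

import json
from collections import Counter
from pathlib import Path

from cistrodiff.synthetic_data import SyntheticDesign, generate_fixture

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    design = SyntheticDesign(seed=SEED)
    out = ROOT / "scratch" / "fixture"
    data = generate_fixture(design, out)

    kinds = Counter(pm.peak_kind for pm in data.truth.planted_motifs)
    motifs = Counter(pm.motif_id for pm in data.truth.planted_motifs)
    summary = {
        "seed": SEED,
        "n_peaks_per_condition": design.n_peaks,
        "designed_shared_fraction": design.shared_fraction,
        "planted_motifs_by_peak_kind": dict(kinds),
        "planted_motifs_by_motif": dict(motifs),
        "occupied_motifs": sum(pm.occupied for pm in data.truth.planted_motifs),
        "cut_totals": {k: p.total_cuts for k, p in data.profiles.items()},
        "de_truth": {
            "up": len(data.truth.up_genes),
            "down": len(data.truth.down_genes),
        },
    }
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    with open(results / "fixture_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)

    print(f"fixture written to {out}")
    print(f"planted {sum(motifs.values())} motifs across {design.n_peaks} peaks "
          f"per condition ({summary['occupied_motifs']} occupied)")
    print(f"summary -> {results / 'fixture_summary.json'}")


if __name__ == "__main__":
    main()
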