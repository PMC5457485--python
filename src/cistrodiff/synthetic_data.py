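"""Synthetic two-condition chromatin landscapes with known truth.

The generator emulates the statistical structure of a two-cistrome
comparison: two conditions whose peak sets share a designed fraction of
elements, condition-specific motif composition at unique peaks (a GATA-like
motif in condition 1; C/EBP-like plus E-box-like motifs in condition 2),
shared RUNX/ETS/AP-1-like motifs at common peaks, footprint-shaped cut
depletion at occupied motifs over peak-shaped cut enrichment, and a
knockdown-style expression time course in which responder genes change
progressively.  Every quantity the pipeline estimates (overlap fraction,
motif partitioning, footprint positions, co-occupancy, responder sets,
change groups) is recorded as truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genomic_io import (
    PWM,
    CutProfile,
    GenomicInterval,
    SequenceRecord,
    reverse_complement,
    write_bed,
    write_fasta,
    write_genome_sizes,
    write_pwm_counts,
)
from .peakset_ops import PeakSet, sort_and_merge

# Near-consensus motif models for the transcription factor families the
# two leukemia cistromes partition between.  Count matrices put 97 of 100
# observations on the consensus base, giving sharp but not degenerate PWMs.
MOTIF_CONSENSUS: dict[str, str] = {
    "GATA": "AGATAAG",
    "CEBP": "TTGCGCAA",
    "EBOX": "CAGCTG",
    "RUNX": "TGTGGTT",
    "ETS": "AGGAAGT",
    "AP1": "TGACTCA",
    "CTCF": "CCACTAGGGGGC",  # control; never planted
}

_BASES = "ACGT"


def builtin_pwm_counts() -> dict[str, np.ndarray]:
    """JASPAR-style count matrices (columns sum to 100) for the built-in motifs."""
    out = {}
    for motif_id, consensus in MOTIF_CONSENSUS.items():
        counts = np.ones((4, len(consensus)), dtype=int)
        for j, base in enumerate(consensus):
            counts[_BASES.index(base), j] = 97
        out[motif_id] = counts
    return out


def builtin_pwms(pseudocount: float = 0.8) -> dict[str, PWM]:
    return {
        motif_id: PWM.from_counts(motif_id, counts, pseudocount=pseudocount)
        for motif_id, counts in builtin_pwm_counts().items()
    }


@dataclass
class SyntheticDesign:
    """Parameters of the emulated study; defaults are the package's study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_peaks: int = 1000  # per condition
    peak_width: int = 130
    min_gap: int = 60
    shared_fraction: float = 0.3
    shared_jitter: int = 25  # boundary jitter of shared peaks in condition 2
    # motif -> planting fraction among that category's peaks
    cond1_motifs: tuple = (("GATA", 1.0),)
    cond2_motifs: tuple = (("CEBP", 1.0), ("EBOX", 0.6))
    shared_motifs: tuple = (("RUNX", 1.0), ("ETS", 0.7), ("AP1", 0.5))
    footprint_occupancy: float = 0.7
    footprint_span: int = 21  # protected span centered on an occupied motif
    peak_cut_rate: float = 1.5  # pooled cuts per bp per strand inside peaks
    background_cut_rate: float = 0.01  # pooled, outside peaks
    footprint_depletion: float = 0.02
    n_replicates: int = 2
    # expression time course
    n_genes: int = 1000
    n_up: int = 50
    n_down: int = 50
    fold_range: tuple = (2.0, 4.0)
    timepoints: tuple = ("d2", "d4", "d7", "d10")
    expr_replicates: int = 2
    noise_sd: float = 0.1  # log-normal sigma on each measurement
    target_linked_fraction: float = 0.7  # responders placed near unique peaks
    gene_peak_offset: int = 10_000

    def __post_init__(self) -> None:
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0, 1]")
        if min(self.peak_cut_rate, self.background_cut_rate) <= 0:
            raise ValueError("cut rates must be positive")
        if not 0 < self.footprint_depletion < 1:
            raise ValueError("footprint_depletion must be in (0, 1)")

    @property
    def genome_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass
class PlantedMotif:
    motif_id: str
    chrom: str
    start: int
    end: int
    strand: str
    peak_kind: str  # cond1_unique / cond2_unique / shared
    occupied: bool


@dataclass
class TruthSet:
    """Ground truth mirroring what the generator wrote into the fixture."""

    peak_kind: dict[str, str]  # "chrom:start-end" (condition-1 frame) -> kind
    planted_motifs: list[PlantedMotif]
    footprint_spans: list[GenomicInterval]  # protected spans (occupied motifs)
    up_genes: list[str]
    down_genes: list[str]


# ---------------------------------------------------------------------------
# Genome


def simulate_genome(design: SyntheticDesign, rng: np.random.Generator | None = None):
    """I.i.d. uniform ACGT chromosomes; returns (records, genome_sizes)."""
    rng = rng or np.random.default_rng(design.seed)
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    records = []
    for chrom, length in design.genome_sizes.items():
        codes = rng.integers(0, 4, size=length)
        seq = bytes(base_bytes[codes]).decode("ascii")
        records.append(SequenceRecord(chrom, seq))
    return records, design.genome_sizes


# ---------------------------------------------------------------------------
# Peaks and motifs


def _place_slots(design: SyntheticDesign, n_slots: int, rng: np.random.Generator):
    """Rejection-sample non-overlapping peak spans with a minimum gap."""
    chroms = list(design.genome_sizes)
    placed: dict[str, list[int]] = {c: [] for c in chroms}  # sorted starts
    slots: list[GenomicInterval] = []
    width, gap = design.peak_width, design.min_gap
    max_tries = 200 * n_slots
    tries = 0
    import bisect

    while len(slots) < n_slots:
        tries += 1
        if tries > max_tries:
            raise ValueError("genome too small for the requested peak count")
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        limit = design.genome_sizes[chrom] - width - gap
        start = int(rng.integers(gap, limit))
        starts = placed[chrom]
        i = bisect.bisect_left(starts, start)
        if i > 0 and start - starts[i - 1] < width + gap:
            continue
        if i < len(starts) and starts[i] - start < width + gap:
            continue
        starts.insert(i, start)
        slots.append(GenomicInterval(chrom, start, start + width))
    return slots


def plant_peaks_and_motifs(
    design: SyntheticDesign,
    genome: Sequence[SequenceRecord],
    rng: np.random.Generator | None = None,
):
    """Place peaks, partition them shared/unique, write motif consensi into
    the sequence, and flag footprint occupancy.

    Returns (peaksets: {cond1, cond2}, truth: TruthSet, edited genome records).
    """
    rng = rng or np.random.default_rng(design.seed + 1)
    n_shared = round(design.shared_fraction * design.n_peaks)
    n_unique = design.n_peaks - n_shared
    slots = _place_slots(design, n_shared + 2 * n_unique, rng)
    perm = rng.permutation(len(slots))
    shared_slots = [slots[i] for i in perm[:n_shared]]
    uniq1 = [slots[i] for i in perm[n_shared : n_shared + n_unique]]
    uniq2 = [slots[i] for i in perm[n_shared + n_unique :]]

    seqs = {rec.id: bytearray(rec.sequence, "ascii") for rec in genome}
    planted: list[PlantedMotif] = []
    footprints: list[GenomicInterval] = []
    consensus = MOTIF_CONSENSUS
    # keep motif midpoints far enough from peak edges that a footprint plus
    # both shoulders fits inside the peak
    margin = design.footprint_span // 2 + 36

    def plant(peaks, motif_plan, kind):
        for iv in peaks:
            taken: list[tuple[int, int]] = []
            for motif_id, frac in motif_plan:
                if rng.random() > frac:
                    continue
                word = consensus[motif_id]
                L = len(word)
                lo = iv.start + margin - L // 2
                hi = iv.end - margin - (L - L // 2)
                if hi < lo:
                    raise ValueError("peak too narrow for motif margin")
                start = None
                for _ in range(30):
                    cand = int(rng.integers(lo, hi + 1))
                    if all(cand + L <= s or cand >= e for s, e in taken):
                        start = cand
                        break
                if start is None:
                    continue
                taken.append((start, start + L))
                strand = "+" if rng.random() < 0.5 else "-"
                inserted = word if strand == "+" else reverse_complement(word)
                seqs[iv.chrom][start : start + L] = inserted.encode("ascii")
                occupied = bool(rng.random() < design.footprint_occupancy)
                planted.append(
                    PlantedMotif(
                        motif_id, iv.chrom, start, start + L, strand, kind, occupied
                    )
                )
                if occupied:
                    mid = start + L // 2
                    half = design.footprint_span // 2
                    footprints.append(
                        GenomicInterval(
                            iv.chrom, mid - half, mid - half + design.footprint_span
                        )
                    )

    plant(shared_slots, design.shared_motifs, "shared")
    plant(uniq1, design.cond1_motifs, "cond1_unique")
    plant(uniq2, design.cond2_motifs, "cond2_unique")

    # condition 2 sees the shared elements with jittered boundaries
    shared_jittered = []
    for iv in shared_slots:
        delta = int(rng.integers(-design.shared_jitter, design.shared_jitter + 1))
        shared_jittered.append(
            GenomicInterval(iv.chrom, iv.start + delta, iv.end + delta)
        )

    peaksets = {
        "cond1": sort_and_merge(shared_slots + uniq1, label="cond1"),
        "cond2": sort_and_merge(shared_jittered + uniq2, label="cond2"),
    }
    peak_kind = {}
    for iv in shared_slots:
        peak_kind[f"{iv.chrom}:{iv.start}-{iv.end}"] = "shared"
    for iv in uniq1:
        peak_kind[f"{iv.chrom}:{iv.start}-{iv.end}"] = "cond1_unique"
    for iv in uniq2:
        peak_kind[f"{iv.chrom}:{iv.start}-{iv.end}"] = "cond2_unique"

    edited = [
        SequenceRecord(rec.id, seqs[rec.id].decode("ascii")) for rec in genome
    ]
    truth = TruthSet(peak_kind, planted, footprints, [], [])
    return peaksets, truth, edited


# ---------------------------------------------------------------------------
# Cut profiles


def simulate_cuts(
    design: SyntheticDesign,
    peaks: PeakSet,
    occupied_spans: Sequence[GenomicInterval],
    rng: np.random.Generator | None = None,
    scale: float = 1.0,
) -> CutProfile:
    """Per-base Poisson cuts: background outside peaks, enriched inside,
    depleted within occupied-motif protection spans; strands independent.

    ``scale`` multiplies all rates (a single replicate of an n-replicate
    condition uses scale = 1/n so the pooled profile attains the design rate).
    """
    rng = rng or np.random.default_rng(design.seed + 2)
    dense: dict[tuple[str, str], np.ndarray] = {}
    for chrom, length in design.genome_sizes.items():
        lam = np.full(length, design.background_cut_rate * scale)
        for iv in peaks.intervals:
            if iv.chrom == chrom:
                lam[iv.start : iv.end] = design.peak_cut_rate * scale
        for fp in occupied_spans:
            if fp.chrom == chrom:
                lam[fp.start : fp.end] *= design.footprint_depletion
        for strand in ("+", "-"):
            dense[(chrom, strand)] = rng.poisson(lam)
    return CutProfile.from_dense(dense)


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    design: SyntheticDesign, rng: np.random.Generator | None = None
):
    """Knockdown-style time course: baseline log-normal FPKM, responders
    ramping monotonically to a per-gene maximum fold, multiplicative
    log-normal noise.  Returns (expression DataFrame, truth dict).
    """
    rng = rng or np.random.default_rng(design.seed + 3)
    genes = [f"G{i:04d}" for i in range(design.n_genes)]
    responders = rng.choice(
        design.n_genes, size=design.n_up + design.n_down, replace=False
    )
    up = sorted(genes[i] for i in responders[: design.n_up])
    down = sorted(genes[i] for i in responders[design.n_up :])
    base = np.exp(rng.normal(np.log(5.0), 1.0, size=design.n_genes))
    lo, hi = design.fold_range
    max_fold = rng.uniform(lo, hi, size=design.n_genes)
    direction = np.zeros(design.n_genes)
    idx = {g: i for i, g in enumerate(genes)}
    for g in up:
        direction[idx[g]] = 1.0
    for g in down:
        direction[idx[g]] = -1.0

    T = len(design.timepoints)
    cols = {}
    for t, tp in enumerate(design.timepoints, start=1):
        ramp = max_fold ** (t / T)
        fold = np.where(direction > 0, ramp, np.where(direction < 0, 1 / ramp, 1.0))
        for r in range(1, design.expr_replicates + 1):
            noise_kd = (
                np.exp(rng.normal(0, design.noise_sd, design.n_genes))
                if design.noise_sd > 0
                else 1.0
            )
            noise_ctrl = (
                np.exp(rng.normal(0, design.noise_sd, design.n_genes))
                if design.noise_sd > 0
                else 1.0
            )
            cols[f"kd_{tp}_r{r}"] = base * fold * noise_kd
            cols[f"ctrl_{tp}_r{r}"] = base * noise_ctrl
    expr = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    return expr, {"up": up, "down": down}


def expression_column_map(design: SyntheticDesign):
    """(condition_cols, control_cols) keyword maps for differential.de_genes."""
    cond = {
        tp: [f"kd_{tp}_r{r}" for r in range(1, design.expr_replicates + 1)]
        for tp in design.timepoints
    }
    ctrl = {
        tp: [f"ctrl_{tp}_r{r}" for r in range(1, design.expr_replicates + 1)]
        for tp in design.timepoints
    }
    return cond, ctrl


def place_genes(
    design: SyntheticDesign,
    truth: TruthSet,
    peaksets: Mapping[str, PeakSet],
    rng: np.random.Generator | None = None,
) -> list[GenomicInterval]:
    """TSS table: responders are preferentially placed near the unique peaks
    of the condition whose program they follow (up near condition-2-unique,
    down near condition-1-unique), the rest uniformly.
    """
    rng = rng or np.random.default_rng(design.seed + 4)
    genes = [f"G{i:04d}" for i in range(design.n_genes)]
    kinds = truth.peak_kind
    uniq1 = [k for k, v in kinds.items() if v == "cond1_unique"]
    uniq2 = [k for k, v in kinds.items() if v == "cond2_unique"]

    def parse(key: str) -> GenomicInterval:
        chrom, span = key.split(":")
        start, end = map(int, span.split("-"))
        return GenomicInterval(chrom, start, end)

    chroms = list(design.genome_sizes)
    rows = []
    up_set, down_set = set(truth.up_genes), set(truth.down_genes)
    for gene in genes:
        near = None
        if gene in up_set and uniq2 and rng.random() < design.target_linked_fraction:
            near = parse(uniq2[int(rng.integers(0, len(uniq2)))])
        elif gene in down_set and uniq1 and rng.random() < design.target_linked_fraction:
            near = parse(uniq1[int(rng.integers(0, len(uniq1)))])
        if near is not None:
            offset = int(rng.integers(-design.gene_peak_offset, design.gene_peak_offset + 1))
            chrom = near.chrom
            pos = int(np.clip(near.center + offset, 0, design.genome_sizes[chrom] - 2))
        else:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(0, design.genome_sizes[chrom] - 1))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append(GenomicInterval(chrom, pos, pos + 1, name=gene, score=0.0, strand=strand))
    rows.sort(key=lambda iv: (iv.chrom, iv.start, iv.name))
    return rows


# ---------------------------------------------------------------------------
# Co-occupancy layouts (occupied motifs placed directly, no cut simulation)


def _spaced_universe(
    rng: np.random.Generator, n_regions: int, half_width: int = 75
) -> PeakSet:
    """Non-overlapping regions on one synthetic chromosome, 1 kb grid."""
    centers = np.sort(
        rng.choice(
            np.arange(500, 40_000_000, 1000), size=n_regions, replace=False
        )
    )
    return PeakSet(
        "universe",
        [
            GenomicInterval("chr1", int(c - half_width), int(c + half_width))
            for c in centers
        ],
    )


def simulate_cooccurrence_null(
    seed: int,
    n_universe: int = 2000,
    n_anchor: int = 400,
    n_motifs: int = 4,
    window_bp: int = 50,
    hit_rate_range: tuple = (0.2, 0.5),
):
    """One null co-occupancy layout: anchors are a uniform draw from the
    universe and occupied motifs are placed independently of them, so the
    bootstrap empirical p-values should be uniform (conservatively, given
    count discreteness).

    Returns (anchors, occupied hits per motif, universe, bootstrap_seed).
    """
    from .motif_scan import MotifHit

    rng = np.random.default_rng(seed)
    universe = _spaced_universe(rng, n_universe)
    centers = np.array([iv.center for iv in universe.intervals])
    anchor_idx = rng.choice(n_universe, size=n_anchor, replace=False)
    anchors = PeakSet(
        "anchors",
        sorted(
            (universe.intervals[i] for i in anchor_idx),
            key=lambda iv: (iv.chrom, iv.start),
        ),
    )
    occupied = {}
    for m in range(n_motifs):
        rate = rng.uniform(*hit_rate_range)
        chosen = rng.random(n_universe) < rate
        hits = []
        for i in np.flatnonzero(chosen):
            c = int(centers[i] + rng.integers(-(window_bp - 10), window_bp - 9))
            hits.append(
                MotifHit(f"m{m}", GenomicInterval("chr1", c, c + 1), "+", 0.0)
            )
        occupied[f"m{m}"] = hits
    boot_seed = int(rng.integers(0, 2**31))
    return anchors, occupied, universe, boot_seed


def simulate_cooccurrence_planted(
    seed: int,
    n_universe: int = 500,
    n_anchor: int = 50,
    anchor_rate: float = 0.6,
    background_rate: float = 0.1,
    window_bp: int = 50,
):
    """Planted layout: the motif sits within the window at ``anchor_rate`` of
    anchors versus ``background_rate`` of other universe regions.

    Returns (anchors, occupied hits for motif "planted", universe, boot seed).
    """
    from .motif_scan import MotifHit

    rng = np.random.default_rng(seed)
    universe = _spaced_universe(rng, n_universe)
    centers = np.array([iv.center for iv in universe.intervals])
    anchor_idx = rng.choice(n_universe, size=n_anchor, replace=False)
    is_anchor = np.zeros(n_universe, dtype=bool)
    is_anchor[anchor_idx] = True
    anchors = PeakSet(
        "anchors",
        sorted(
            (universe.intervals[i] for i in anchor_idx),
            key=lambda iv: (iv.chrom, iv.start),
        ),
    )
    rate = np.where(is_anchor, anchor_rate, background_rate)
    chosen = rng.random(n_universe) < rate
    hits = []
    for i in np.flatnonzero(chosen):
        c = int(centers[i] + rng.integers(-(window_bp - 10), window_bp - 9))
        hits.append(
            MotifHit("planted", GenomicInterval("chr1", c, c + 1), "+", 0.0)
        )
    boot_seed = int(rng.integers(0, 2**31))
    return anchors, {"planted": hits}, universe, boot_seed


# ---------------------------------------------------------------------------
# Full fixture


@dataclass
class FixtureData:
    """In-memory handles to everything generate_fixture wrote."""

    design: SyntheticDesign
    genome: list[SequenceRecord]
    genome_sizes: dict[str, int]
    peaksets: dict[str, PeakSet]
    truth: TruthSet
    profiles: dict[str, CutProfile]  # "<cond>_rep<k>" replicate profiles
    pooled: dict[str, CutProfile]  # per-condition pooled profiles
    expression: pd.DataFrame
    tss_table: list[GenomicInterval]


def build_fixture(design: SyntheticDesign) -> FixtureData:
    """Run all simulators (deterministic in design.seed) without writing files."""
    rng = np.random.default_rng(design.seed)
    genome, sizes = simulate_genome(design, rng)
    peaksets, truth, genome = plant_peaks_and_motifs(design, genome, rng)

    profiles: dict[str, CutProfile] = {}
    pooled: dict[str, CutProfile] = {}
    scale = 1.0 / design.n_replicates
    for cond in ("cond1", "cond2"):
        # a condition's profile is depleted only at occupied motifs inside
        # that condition's own peaks
        spans = [
            fp
            for fp, pm in zip_footprints(truth)
            if pm.peak_kind == "shared" or pm.peak_kind == f"{cond}_unique"
        ]
        reps = []
        for r in range(1, design.n_replicates + 1):
            prof = simulate_cuts(design, peaksets[cond], spans, rng, scale=scale)
            profiles[f"{cond}_rep{r}"] = prof
            reps.append(prof)
        pooled[cond] = CutProfile.merge(reps)

    expr, expr_truth = simulate_expression(design, rng)
    truth.up_genes = expr_truth["up"]
    truth.down_genes = expr_truth["down"]
    tss = place_genes(design, truth, peaksets, rng)
    return FixtureData(
        design, genome, sizes, peaksets, truth, profiles, pooled, expr, tss
    )


def zip_footprints(truth: TruthSet):
    """Pair each footprint span with its occupied planted motif, in order."""
    occupied = [pm for pm in truth.planted_motifs if pm.occupied]
    return zip(truth.footprint_spans, occupied)


def generate_fixture(design: SyntheticDesign, out_dir) -> FixtureData:
    """Build the fixture and write it as FASTA/BED/TSV plus truth and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = build_fixture(design)

    write_fasta(data.genome, out / "genome.fa")
    write_genome_sizes(data.genome_sizes, out / "genome.sizes")
    write_pwm_counts(builtin_pwm_counts(), out / "motifs.jaspar")
    for cond, ps in data.peaksets.items():
        write_bed(ps.intervals, out / f"peaks_{cond}.bed")
    for label, prof in data.profiles.items():
        write_bed(prof.to_bed_records(), out / f"cuts_{label}.bed")
    write_bed(data.tss_table, out / "tss.bed")
    data.expression.to_csv(out / "expression.tsv", sep="\t")

    truth_json = {
        "peak_kind": data.truth.peak_kind,
        "planted_motifs": [asdict(pm) for pm in data.truth.planted_motifs],
        "footprint_spans": [
            {"chrom": fp.chrom, "start": fp.start, "end": fp.end}
            for fp in data.truth.footprint_spans
        ],
        "up_genes": data.truth.up_genes,
        "down_genes": data.truth.down_genes,
        "n_peaks_cond1": len(data.peaksets["cond1"]),
        "n_peaks_cond2": len(data.peaksets["cond2"]),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1)
    manifest = {"design": asdict(data.design)}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return data


def design_from_manifest(path) -> SyntheticDesign:
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    raw = manifest["design"]
    for key in ("cond1_motifs", "cond2_motifs", "shared_motifs"):
        raw[key] = tuple(tuple(x) for x in raw[key])
    raw["fold_range"] = tuple(raw["fold_range"])
    raw["timepoints"] = tuple(raw["timepoints"])
    return SyntheticDesign(**raw)
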